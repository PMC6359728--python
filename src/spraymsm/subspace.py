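"""Class-subspace learning and canonical-angle similarities.

This is the mathematical core of the package.  A class of image patterns is
modelled by the linear subspace spanned by the leading eigenvectors of the
pattern autocorrelation matrix

    C = (1/n) * sum_j x_j x_j^T,        x_j in R^k  (k = 64 by default),

the classic CLAFIC construction.  A single pattern is compared to a class
subspace by the angle between the vector and the subspace (the subspace
method, SM); two pattern *sets* are compared by the canonical (principal)
angles between their subspaces (the mutual subspace method, MSM).  Both
similarities are reported on the cos^2(theta) scale so they are directly
comparable and bounded in [0, 1].

Canonical cosines are computed as the singular values of B_P^T B_Q, where
B_P and B_Q are column-orthonormal bases; this is numerically preferable to
eigen-solving the product of projectors and mathematically equivalent.

Centering: the default autocorrelation is *uncentered* (second moment about
the origin), the usual CLAFIC/MSM convention for image patterns; mean
centering is available via ``centered=True`` for callers who prefer PCA
about the data centroid.  Both conventions are recorded in fitted models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import DegenerateDataError, InvalidInputError, InvalidParameterError

#: Relative eigenvalue threshold below which a direction is treated as rank
#: deficient.  Eigenvalues smaller than RANK_RTOL * lambda_max count as zero.
RANK_RTOL = 1e-12


@dataclass(frozen=True)
class AutocorrelationMatrix:
    """Second-moment matrix of a set of pattern vectors.

    Attributes
    ----------
    entries : (k, k) ndarray
        Symmetric positive-semidefinite matrix.
    n_samples : int
        Number of pattern vectors averaged.
    centered : bool
        True if the sample mean was subtracted first (covariance), False for
        the raw second moment about the origin (autocorrelation).
    """

    entries: np.ndarray
    n_samples: int
    centered: bool

    def __post_init__(self) -> None:
        m = np.asarray(self.entries, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise InvalidInputError(f"autocorrelation matrix must be square, got {m.shape}")
        if not np.allclose(m, m.T, atol=1e-10 * max(1.0, float(np.abs(m).max(initial=0.0)))):
            raise InvalidInputError("autocorrelation matrix must be symmetric")
        object.__setattr__(self, "entries", m)


@dataclass(frozen=True)
class Subspace:
    """Orthonormal basis of a class (or query) subspace.

    Attributes
    ----------
    basis : (k, d) ndarray
        Column-orthonormal eigenvectors, ordered by decreasing eigenvalue.
    eigenvalues : (d,) ndarray
        The matching eigenvalues, nonincreasing and nonnegative.
    contribution_rate : float
        Cumulative fraction of the total eigenvalue mass retained by the d
        leading eigenvectors, in (0, 1].
    """

    basis: np.ndarray
    eigenvalues: np.ndarray
    contribution_rate: float = 1.0

    def __post_init__(self) -> None:
        b = np.asarray(self.basis, dtype=float)
        ev = np.asarray(self.eigenvalues, dtype=float)
        if b.ndim != 2 or b.shape[1] < 1:
            raise InvalidInputError("basis must be a k x d matrix with d >= 1")
        if ev.shape != (b.shape[1],):
            raise InvalidInputError("eigenvalues must match the number of basis columns")
        gram = b.T @ b
        if not np.allclose(gram, np.eye(b.shape[1]), atol=1e-8):
            raise InvalidInputError("basis columns must be orthonormal")
        if np.any(np.diff(ev) > 1e-10 * max(1.0, abs(float(ev[0])))):
            raise InvalidInputError("eigenvalues must be nonincreasing")
        object.__setattr__(self, "basis", b)
        object.__setattr__(self, "eigenvalues", ev)

    @property
    def ambient_dim(self) -> int:
        return int(self.basis.shape[0])

    @property
    def dim(self) -> int:
        return int(self.basis.shape[1])


@dataclass(frozen=True)
class CanonicalAngleSet:
    """Cosines of the canonical angles between two subspaces.

    ``cosines`` holds min(d_P, d_Q) values in [0, 1], sorted nonincreasing;
    the first is the cosine of the smallest canonical angle, i.e. the
    closest pair of directions between the two subspaces.
    """

    cosines: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        c = np.asarray(self.cosines, dtype=float)
        if c.ndim != 1 or c.size < 1:
            raise InvalidInputError("cosines must be a nonempty 1-D array")
        if np.any(c < -1e-10) or np.any(c > 1 + 1e-10):
            raise InvalidInputError("canonical cosines must lie in [0, 1]")
        if np.any(np.diff(c) > 1e-10):
            raise InvalidInputError("canonical cosines must be sorted nonincreasing")
        object.__setattr__(self, "cosines", np.clip(c, 0.0, 1.0))

    @property
    def angles(self) -> np.ndarray:
        """Canonical angles in radians, nondecreasing."""
        return np.arccos(self.cosines)


def _as_matrix(vectors) -> np.ndarray:
    x = np.asarray(vectors, dtype=float)
    if x.ndim == 1:
        x = x[np.newaxis, :]
    if x.ndim != 2 or x.shape[0] < 1 or x.shape[1] < 1:
        raise InvalidInputError("expected a nonempty collection of equal-length vectors")
    if not np.all(np.isfinite(x)):
        raise InvalidInputError("pattern vectors must be finite")
    return x


def autocorrelation(vectors, centered: bool = False) -> AutocorrelationMatrix:
    """Second-moment matrix (1/n) * sum_j x_j x_j^T of the pattern vectors.

    Parameters
    ----------
    vectors : array-like, shape (n, k)
        Pattern vectors as rows.  A single 1-D vector is accepted.
    centered : bool
        Subtract the sample mean first (covariance about the centroid).
    """
    x = _as_matrix(vectors)
    n = x.shape[0]
    if centered:
        x = x - x.mean(axis=0)
    c = (x.T @ x) / n
    c = (c + c.T) / 2.0  # enforce exact symmetry against rounding
    return AutocorrelationMatrix(entries=c, n_samples=n, centered=centered)


def _eig_descending(c: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    evals, evecs = np.linalg.eigh(c)
    order = np.argsort(evals)[::-1]
    return np.clip(evals[order], 0.0, None), evecs[:, order]


def fit_subspace(
    vectors,
    *,
    dim: int | None = None,
    contribution: float | None = None,
    centered: bool = False,
) -> Subspace:
    """Fit a class subspace by eigen decomposition of the autocorrelation matrix.

    Exactly one dimension rule applies: a fixed dimension ``dim`` (1 <= d <= k)
    or a cumulative ``contribution`` threshold tau in (0, 1], in which case d
    is the smallest integer with sum_{i<=d} lambda_i / sum_i lambda_i >= tau.
    If neither is given, contribution = 0.95 is used.  A requested dimension
    exceeding the numerical rank of the data is clamped to the rank with a
    warning.

    Raises
    ------
    DegenerateDataError
        If the autocorrelation matrix is (numerically) zero.
    """
    if dim is not None and contribution is not None:
        raise InvalidParameterError("give either dim or contribution, not both")
    if dim is None and contribution is None:
        contribution = 0.95

    acm = autocorrelation(vectors, centered=centered)
    evals, evecs = _eig_descending(acm.entries)
    total = float(evals.sum())
    if total <= 0.0 or evals[0] <= 0.0:
        raise DegenerateDataError("autocorrelation matrix is zero; no subspace is defined")

    rank = int(np.count_nonzero(evals > RANK_RTOL * evals[0]))
    cum = np.cumsum(evals) / total

    if dim is not None:
        if not (1 <= dim <= acm.entries.shape[0]):
            raise InvalidParameterError(f"dim must be in [1, {acm.entries.shape[0]}], got {dim}")
        d = dim
        if d > rank:
            warnings.warn(
                f"requested subspace dimension {dim} exceeds data rank {rank}; "
                f"clamping to {rank}",
                RuntimeWarning,
                stacklevel=2,
            )
            d = rank
    else:
        if not (0.0 < contribution <= 1.0):
            raise InvalidParameterError(f"contribution must be in (0, 1], got {contribution}")
        d = int(np.searchsorted(cum, contribution - 1e-12) + 1)
        d = min(d, rank)

    return Subspace(
        basis=evecs[:, :d],
        eigenvalues=evals[:d],
        contribution_rate=float(cum[d - 1]),
    )


def canonical_cosines(p: Subspace, q: Subspace) -> CanonicalAngleSet:
    """Cosines of the canonical angles between two subspaces.

    Computed as the singular values of B_P^T B_Q, clipped to [0, 1] and
    sorted nonincreasing (numpy's SVD already returns them so).  The first
    cosine is the max over unit u in P, unit v in Q of u.v.
    """
    if p.ambient_dim != q.ambient_dim:
        raise InvalidInputError(
            f"ambient dimensions differ: {p.ambient_dim} vs {q.ambient_dim}"
        )
    s = np.linalg.svd(p.basis.T @ q.basis, compute_uv=False)
    return CanonicalAngleSet(cosines=np.clip(s, 0.0, 1.0))


def sm_similarity(pattern, s: Subspace) -> float:
    """Subspace-method similarity of a single pattern to a class subspace.

    Returns cos^2(theta) = sum_i (p . phi_i)^2 / ||p||^2, the squared norm of
    the projection of the normalized pattern onto the subspace.  Lies in
    [0, 1]; equals 1 iff the pattern lies inside the subspace.
    """
    p = np.asarray(pattern, dtype=float).ravel()
    if p.shape[0] != s.ambient_dim:
        raise InvalidInputError(
            f"pattern length {p.shape[0]} does not match ambient dimension {s.ambient_dim}"
        )
    nrm2 = float(p @ p)
    if nrm2 == 0.0:
        raise InvalidInputError("cannot compute an angle for the zero vector")
    proj = s.basis.T @ p
    return float(np.clip((proj @ proj) / nrm2, 0.0, 1.0))


def msm_similarity(
    p: Subspace,
    q: Subspace,
    aggregation: str = "first",
    t: int | None = None,
) -> float:
    """Mutual-subspace-method similarity between two subspaces.

    ``aggregation="first"`` returns cos^2 of the smallest canonical angle —
    the squared maximum of u.v over unit vectors in the two subspaces.
    ``aggregation="mean_top_t"`` returns the mean of the t largest squared
    canonical cosines (t defaults to all of them).
    """
    cas = canonical_cosines(p, q)
    sq = cas.cosines**2
    if aggregation == "first":
        return float(sq[0])
    if aggregation == "mean_top_t":
        if t is None:
            t = sq.size
        if not (1 <= t <= sq.size):
            raise InvalidParameterError(
                f"t must be in [1, {sq.size}] (number of canonical angles), got {t}"
            )
        return float(sq[:t].mean())
    raise InvalidParameterError(f"unknown aggregation {aggregation!r}")
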