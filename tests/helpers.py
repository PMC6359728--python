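"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: the canonical-cosine
oracle maximizes u.v by alternating projection between the subspaces
(never calling an SVD), and the resize oracle computes explicit block
means with Python loops.
"""

from __future__ import annotations

import numpy as np


def first_canonical_cosine_bruteforce(
    basis_p: np.ndarray,
    basis_q: np.ndarray,
    rng: np.random.Generator,
    n_starts: int = 5,
    iters: int = 2000,
) -> float:
    """max over unit u in span(P), unit v in span(Q) of u.v.

    Alternating maximization: given v, the best u is the normalized
    projection of v onto P, and vice versa; each step cannot decrease u.v,
    so the iteration climbs to the largest canonical cosine.  Several random
    starts guard against a start orthogonal to the optimal pair.
    """
    best = 0.0
    for _ in range(n_starts):
        v = basis_q @ rng.standard_normal(basis_q.shape[1])
        nv = np.linalg.norm(v)
        if nv == 0:
            continue
        v /= nv
        u = v
        for _ in range(iters):
            u = basis_p @ (basis_p.T @ v)
            nu = np.linalg.norm(u)
            if nu == 0:
                break
            u /= nu
            v = basis_q @ (basis_q.T @ u)
            nv = np.linalg.norm(v)
            if nv == 0:
                break
            v /= nv
        else:
            best = max(best, float(abs(u @ v)))
            continue
        # one subspace annihilated the iterate: the subspaces are orthogonal
        # along this direction; cosine contribution is 0
        best = max(best, 0.0)
    return best


def block_mean_resize(img: np.ndarray, size: int) -> np.ndarray:
    """Explicit block means for images whose sides are multiples of size."""
    h, w = img.shape
    assert h % size == 0 and w % size == 0
    bh, bw = h // size, w // size
    out = np.empty((size, size))
    for i in range(size):
        for j in range(size):
            out[i, j] = img[i * bh : (i + 1) * bh, j * bw : (j + 1) * bw].mean()
    return out


def random_subspace_basis(k: int, d: int, rng: np.random.Generator) -> np.ndarray:
    """Column-orthonormal basis of a uniformly random d-dim subspace of R^k."""
    q, _ = np.linalg.qr(rng.standard_normal((k, d)))
    return q[:, :d]


def max_principal_angle_sine(basis_a: np.ndarray, basis_b: np.ndarray) -> float:
    """sin of the largest principal angle between two equal-dim subspaces.

    Computed from the projection residual (I - A A^T) B, whose largest
    singular value is sin(theta_max).  Accurate for tiny angles where the
    cosine saturates at 1 in double precision.
    """
    residual = basis_b - basis_a @ (basis_a.T @ basis_b)
    return float(np.linalg.svd(residual, compute_uv=False).max())


def random_rotation(d: int, rng: np.random.Generator) -> np.ndarray:
    """Haar-ish random d x d orthogonal matrix."""
    q, r = np.linalg.qr(rng.standard_normal((d, d)))
    return q * np.sign(np.diag(r))
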