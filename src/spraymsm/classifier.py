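"""Offline training/testing protocol and online sliding-window classification.

Training builds one reference subspace per category from that category's
pattern vectors (PCA of the autocorrelation matrix).  Offline testing
follows the first-half-train / last-half-test protocol on a recorded
sequence and, by default, scores each test image individually by its angle
to every reference subspace (the subspace method); test images can instead
be grouped into consecutive sets and scored by the mutual subspace method.
Online testing slides a window of w consecutive pattern vectors (default
w = 4) along a preprocessed stream, fits a query subspace to each window
and assigns the window to the reference subspace with the smallest
canonical angle, i.e. the highest similarity.

Ties on similarity are broken in favour of the earliest category in model
order, and logged.  Models persist as an ``.npz`` array container plus a
JSON metadata sidecar.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError, InvalidParameterError
from .imaging import FrameStream
from .subspace import Subspace, fit_subspace, msm_similarity, sm_similarity

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 4


@dataclass(frozen=True)
class ReferenceModel:
    """Per-category reference subspaces plus the configuration that built them."""

    classes: tuple[str, ...]
    subspaces: tuple[Subspace, ...]
    preprocessing: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.classes) != len(self.subspaces):
            raise InvalidInputError("one subspace per class is required")
        if len(self.classes) < 1:
            raise InvalidInputError("a model needs at least one class")
        if len(set(self.classes)) != len(self.classes):
            raise InvalidInputError("class labels must be unique")
        k = {s.ambient_dim for s in self.subspaces}
        if len(k) > 1:
            raise InvalidInputError(f"all subspaces must share one ambient dimension, got {k}")

    @property
    def ambient_dim(self) -> int:
        return self.subspaces[0].ambient_dim

    def subspace(self, label: str) -> Subspace:
        return self.subspaces[self.classes.index(label)]


@dataclass(frozen=True)
class WindowBuffer:
    """Exactly w consecutive pattern vectors starting at start_index."""

    vectors: np.ndarray  # (w, k)
    start_index: int


@dataclass(frozen=True)
class ClassificationResult:
    """One classification decision with its per-category similarities."""

    predicted: str
    similarities: dict[str, float]
    window_start: int | None = None
    elapsed: float = 0.0


def split_first_last_half(stream, first: str = "floor"):
    """Split a sequence into a training half and a testing half.

    ``first="floor"`` puts floor(n/2) items in the training half (so an odd
    sequence trains on the smaller half); ``first="ceil"`` puts ceil(n/2)
    there.  Works on a FrameStream, an array of vectors, or any sequence.
    """
    if first not in ("floor", "ceil"):
        raise InvalidParameterError(f"first must be 'floor' or 'ceil', got {first!r}")
    n = len(stream)
    if n < 2:
        raise InvalidInputError("need at least 2 items to split into halves")
    cut = n // 2 if first == "floor" else (n + 1) // 2
    if isinstance(stream, FrameStream):
        head = FrameStream(
            frames=stream.frames[:cut],
            indices=stream.indices[:cut],
            label=stream.label,
            source_id=stream.source_id,
        )
        tail = FrameStream(
            frames=stream.frames[cut:],
            indices=stream.indices[cut:],
            label=stream.label,
            source_id=stream.source_id,
        )
        return head, tail
    return stream[:cut], stream[cut:]


def train_classifier(
    datasets: Mapping[str, np.ndarray],
    *,
    dim: int | None = None,
    contribution: float | None = None,
    centered: bool = False,
    preprocessing: dict | None = None,
) -> ReferenceModel:
    """Fit one reference subspace per category.

    ``datasets`` maps category label -> (n, k) matrix of pattern vectors.
    Each category needs at least 2 vectors.  The model records the dimension
    rule, centering flag and per-class training counts.
    """
    if len(datasets) < 1:
        raise InvalidInputError("no training categories given")
    classes = tuple(datasets.keys())
    subspaces = []
    counts = {}
    for label in classes:
        x = np.asarray(datasets[label], dtype=float)
        if x.ndim != 2 or x.shape[0] < 2:
            raise InvalidInputError(
                f"category {label!r} needs at least 2 training vectors, got shape {x.shape}"
            )
        subspaces.append(fit_subspace(x, dim=dim, contribution=contribution, centered=centered))
        counts[label] = int(x.shape[0])
    config = dict(preprocessing or {})
    config.update({"dim": dim, "contribution": contribution, "centered": centered})
    return ReferenceModel(
        classes=classes,
        subspaces=tuple(subspaces),
        preprocessing=config,
        provenance={"training_counts": counts},
    )


def _argmax_with_ties(classes: Sequence[str], sims: np.ndarray) -> str:
    best = int(np.argmax(sims))
    ties = np.flatnonzero(sims == sims[best])
    if ties.size > 1:
        logger.info(
            "similarity tie between %s; picking %s (earliest in model order)",
            [classes[i] for i in ties],
            classes[best],
        )
    return classes[best]


def classify_set(
    test_vectors,
    model: ReferenceModel,
    aggregation: str = "first",
    t: int | None = None,
    window_start: int | None = None,
) -> ClassificationResult:
    """Classify a set of pattern vectors against the reference subspaces.

    Fits a query subspace to the set (dimension capped at the set's rank)
    and predicts the category with the highest mutual-subspace similarity.
    A single vector cannot span a subspace of its own, so it falls back to
    the single-pattern angle similarity, with a logged notice.
    """
    x = np.asarray(test_vectors, dtype=float)
    if x.ndim == 1:
        x = x[np.newaxis, :]
    if x.shape[0] < 1:
        raise InvalidInputError("cannot classify an empty set of vectors")
    if x.shape[1] != model.ambient_dim:
        raise InvalidInputError(
            f"vector length {x.shape[1]} does not match model ambient dim {model.ambient_dim}"
        )

    start = time.perf_counter()
    if x.shape[0] == 1:
        logger.info("single test vector: falling back to single-pattern angle similarity")
        sims = np.array([sm_similarity(x[0], s) for s in model.subspaces])
    else:
        cfg = model.preprocessing
        d = cfg.get("dim")
        if d is not None:
            d = min(d, x.shape[0])  # a set of n patterns spans at most n dims
        query = fit_subspace(
            x,
            dim=d,
            contribution=cfg.get("contribution"),
            centered=bool(cfg.get("centered", False)),
        )
        sims = np.array(
            [msm_similarity(query, s, aggregation=aggregation, t=t) for s in model.subspaces]
        )
    elapsed = time.perf_counter() - start
    predicted = _argmax_with_ties(model.classes, sims)
    return ClassificationResult(
        predicted=predicted,
        similarities=dict(zip(model.classes, sims.tolist())),
        window_start=window_start,
        elapsed=elapsed,
    )


def sliding_windows(
    vectors, w: int = DEFAULT_WINDOW, stride: int = 1
) -> list[WindowBuffer]:
    """All windows of w consecutive pattern vectors, advancing by stride."""
    if w < 1 or stride < 1:
        raise InvalidParameterError("window size and stride must be >= 1")
    x = np.asarray(vectors, dtype=float)
    if x.ndim != 2:
        raise InvalidInputError("expected an (n, k) matrix of pattern vectors")
    n = x.shape[0]
    if n < w:
        logger.info("stream of %d vectors is shorter than window %d; no windows", n, w)
        return []
    return [WindowBuffer(vectors=x[s : s + w], start_index=s) for s in range(0, n - w + 1, stride)]


def online_classify(
    vectors,
    model: ReferenceModel,
    w: int = DEFAULT_WINDOW,
    stride: int = 1,
    aggregation: str = "first",
    t: int | None = None,
) -> tuple[list[ClassificationResult], pd.DataFrame]:
    """Classify every sliding window of a preprocessed stream.

    The stream is expected to be already subsampled and noise-filtered.
    Returns the per-window results and a similarity trace (one row per
    window, one column per category) suitable for plotting against time.
    """
    windows = sliding_windows(vectors, w=w, stride=stride)
    results = [
        classify_set(win.vectors, model, aggregation=aggregation, t=t, window_start=win.start_index)
        for win in windows
    ]
    trace = pd.DataFrame(
        [
            {"window_start": r.window_start, "predicted": r.predicted, **r.similarities}
            for r in results
        ]
    )
    return results, trace


def offline_protocol(
    datasets: Mapping[str, np.ndarray],
    *,
    first: str = "floor",
    set_size: int | None = None,
    dim: int | None = None,
    contribution: float | None = None,
    centered: bool = False,
) -> tuple[ReferenceModel, list[tuple[str, str]]]:
    """First-half-train / last-half-test evaluation on labeled sequences.

    ``datasets`` maps category -> (n, k) pattern matrix of one recorded
    sequence.  The first half of each category trains its reference
    subspace; the last half is classified.  With ``set_size=None`` each test
    image is scored individually by its angle to the reference subspaces;
    with ``set_size=s`` consecutive test images are grouped into sets of s
    and scored by the mutual subspace method (each image in a set inherits
    the set's decision).

    Returns the trained model and (true_label, predicted_label) pairs, one
    per test image.
    """
    train, test = {}, {}
    for label, x in datasets.items():
        tr, te = split_first_last_half(np.asarray(x, dtype=float), first=first)
        train[label], test[label] = tr, te
    model = train_classifier(train, dim=dim, contribution=contribution, centered=centered)

    pairs: list[tuple[str, str]] = []
    for label, x in test.items():
        if set_size is None:
            for v in x:
                res = classify_set(v, model)
                pairs.append((label, res.predicted))
        else:
            if set_size < 2:
                raise InvalidParameterError("set_size must be >= 2 (or None for per-image)")
            for s in range(0, x.shape[0], set_size):
                chunk = x[s : s + set_size]
                res = classify_set(chunk, model)
                pairs.extend((label, res.predicted) for _ in range(chunk.shape[0]))
    return model, pairs


# ---------------------------------------------------------------------------
# Model persistence: .npz array container + JSON metadata sidecar.

def save_model(model: ReferenceModel, path) -> None:
    """Write a model to ``path``.npz (arrays) and ``path``.json (metadata)."""
    path = Path(path)
    arrays = {}
    for i, s in enumerate(model.subspaces):
        arrays[f"basis_{i}"] = s.basis
        arrays[f"eigenvalues_{i}"] = s.eigenvalues
    np.savez(path.with_suffix(".npz"), **arrays)
    meta = {
        "classes": list(model.classes),
        "contribution_rates": [s.contribution_rate for s in model.subspaces],
        "preprocessing": model.preprocessing,
        "provenance": model.provenance,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2, sort_keys=True))


def load_model(path) -> ReferenceModel:
    """Load a model written by :func:`save_model`."""
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    with np.load(path.with_suffix(".npz")) as arrays:
        subspaces = tuple(
            Subspace(
                basis=arrays[f"basis_{i}"],
                eigenvalues=arrays[f"eigenvalues_{i}"],
                contribution_rate=rate,
            )
            for i, rate in enumerate(meta["contribution_rates"])
        )
    return ReferenceModel(
        classes=tuple(meta["classes"]),
        subspaces=subspaces,
        preprocessing=meta["preprocessing"],
        provenance=meta["provenance"],
    )
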