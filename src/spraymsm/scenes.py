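"""Synthetic aerial scene sequences for training and testing the classifier.

Real spray-area recognition runs on video of crop rows, canopy, bare soil
and farm structures shot from a UAV.  This module generates labeled frame
sequences with the statistical structure that the subspace classifier
actually exploits: each category has a fixed mean appearance (an 8x8
template upsampled to frame size), per-pixel Gaussian appearance noise, and
AR(1) frame-to-frame correlation emulating the slowly changing view from a
moving aircraft.  "Noise" segments of uniform random pixels emulate
takeoff/landing frames that belong to neither category.

The appearance model is deliberately minimal — template + AR(1) Gaussian
pixel noise — because within-class variation and temporal correlation are
all the mutual subspace method uses; photorealism, geometric distortion and
illumination effects are out of scope.

Default conditions: 64x64 frames, 200 frames per sequence (the scale of one
subsampled field video), appearance noise sd 0.05 on the [0, 1] intensity
scale, temporal correlation 0.6.  Sequences are bit-reproducible from their
seed; dataset generation derives per-sequence seeds as master seed +
sequence index.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .exceptions import InvalidParameterError
from .imaging import PATTERN_SIZE, FrameStream

#: Marker used in TransitionSpec segments for unstructured noise frames.
NOISE = "noise"

_DEFAULT_FRAME_SIZE = (64, 64)
_DEFAULT_SD = 0.05
_DEFAULT_CORR = 0.6
_DEFAULT_N_FRAMES = 200


def crop_rows_template(period: int = 2, low: float = 0.25, high: float = 0.75) -> np.ndarray:
    """8x8 template of alternating vertical bands, emulating crop rows/canopy."""
    cols = (np.arange(PATTERN_SIZE) // period) % 2
    row = np.where(cols == 0, low, high)
    return np.tile(row, (PATTERN_SIZE, 1)).ravel()

def bare_soil_template(level: float = 0.5) -> np.ndarray:
    """Flat 8x8 template, emulating bare soil / roads with uniform appearance."""
    return np.full(PATTERN_SIZE * PATTERN_SIZE, level)


@dataclass(frozen=True)
class SceneParams:
    """Generation parameters for one labeled scene sequence.

    Attributes
    ----------
    class_id : str
        Category label (e.g. "spray" / "non_spray").
    base_pattern : (64,) ndarray in [0, 1]
        Class mean appearance at the 8x8 working scale; upsampled to
        ``frame_size`` before noise is added.
    within_class_sd : float >= 0
        Per-pixel Gaussian appearance spread on the [0, 1] scale.
    temporal_corr : float in [0, 1)
        AR(1) lag-1 correlation of the noise field between successive frames.
    frame_size : (height, width)
    n_frames : int >= 1
    seed : int
    """

    class_id: str
    base_pattern: np.ndarray = field(default_factory=crop_rows_template)
    within_class_sd: float = _DEFAULT_SD
    temporal_corr: float = _DEFAULT_CORR
    frame_size: tuple[int, int] = _DEFAULT_FRAME_SIZE
    n_frames: int = _DEFAULT_N_FRAMES
    seed: int = 0

    def __post_init__(self) -> None:
        pat = np.asarray(self.base_pattern, dtype=float).ravel()
        if pat.size != PATTERN_SIZE * PATTERN_SIZE:
            raise InvalidParameterError(
                f"base_pattern must have {PATTERN_SIZE * PATTERN_SIZE} elements, got {pat.size}"
            )
        if np.any(pat < 0) or np.any(pat > 1):
            raise InvalidParameterError("base_pattern values must lie in [0, 1]")
        if self.within_class_sd < 0:
            raise InvalidParameterError("within_class_sd must be nonnegative")
        if not (0.0 <= self.temporal_corr < 1.0):
            raise InvalidParameterError("temporal_corr must lie in [0, 1)")
        h, w = self.frame_size
        if h < 1 or w < 1:
            raise InvalidParameterError(f"frame_size must be positive, got {self.frame_size}")
        if self.n_frames < 1:
            raise InvalidParameterError(f"n_frames must be >= 1, got {self.n_frames}")
        object.__setattr__(self, "base_pattern", pat)
        object.__setattr__(self, "frame_size", (int(h), int(w)))


@dataclass(frozen=True)
class TransitionSpec:
    """An ordered flight profile of class segments and noise segments.

    ``segments`` is a sequence of (SceneParams | NOISE, n_frames) pairs;
    noise segments are uniform random pixels drawn from
    ``noise_intensity_range`` on the [0, 1] scale — maximally unlike either
    class template.
    """

    segments: tuple
    noise_intensity_range: tuple[float, float] = (0.0, 1.0)
    frame_size: tuple[int, int] = _DEFAULT_FRAME_SIZE
    seed: int = 0

    def __post_init__(self) -> None:
        segs = tuple(self.segments)
        if not segs:
            raise InvalidParameterError("segments must be nonempty")
        for kind, n in segs:
            if n < 1:
                raise InvalidParameterError("segment lengths must be >= 1")
            if not (kind == NOISE or isinstance(kind, SceneParams)):
                raise InvalidParameterError(
                    "each segment must be a SceneParams or the noise marker"
                )
        lo, hi = self.noise_intensity_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise InvalidParameterError("noise_intensity_range must be within [0, 1]")
        object.__setattr__(self, "segments", segs)

    @property
    def total_frames(self) -> int:
        return sum(n for _, n in self.segments)


def _upsample_template(pattern: np.ndarray, frame_size: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbour upsample of the 8x8 template to the frame size."""
    tpl = pattern.reshape(PATTERN_SIZE, PATTERN_SIZE)
    h, w = frame_size
    rows = (np.arange(h) * PATTERN_SIZE) // h
    cols = (np.arange(w) * PATTERN_SIZE) // w
    return tpl[np.ix_(rows, cols)]


def _to_rgb_uint8(intensity: np.ndarray) -> np.ndarray:
    """Quantize a [0, 1] intensity field to an 8-bit RGB frame."""
    u8 = np.rint(np.clip(intensity, 0.0, 1.0) * 255.0).astype(np.uint8)
    return np.repeat(u8[:, :, np.newaxis], 3, axis=2)


def generate_scene_sequence(params: SceneParams, rng: np.random.Generator | None = None) -> FrameStream:
    """Generate one labeled frame sequence.

    Frame t has intensity clip(template + sd * z_t, 0, 1) where z_t is a
    stationary AR(1) Gaussian field: z_0 ~ N(0, 1) per pixel and
    z_t = rho * z_{t-1} + sqrt(1 - rho^2) * eps_t, so every frame has unit
    marginal noise variance and lag-1 autocorrelation rho.  Deterministic
    given ``params.seed`` (unless an explicit rng is passed).
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    h, w = params.frame_size
    template = _upsample_template(params.base_pattern, params.frame_size)
    rho = params.temporal_corr
    sd = params.within_class_sd

    frames = []
    z = rng.standard_normal((h, w)) if sd > 0 else np.zeros((h, w))
    for _ in range(params.n_frames):
        frames.append(_to_rgb_uint8(template + sd * z))
        if sd > 0:
            z = rho * z + np.sqrt(1.0 - rho * rho) * rng.standard_normal((h, w))
    return FrameStream.from_arrays(frames, label=params.class_id)


def generate_two_class_dataset(
    params_a: SceneParams,
    params_b: SceneParams,
    n_sequences_per_class: int,
    seed: int | None = None,
) -> list[FrameStream]:
    """Balanced labeled dataset of synthetic sequences for two categories.

    Per-sequence seeds are master seed + sequence index (class A takes
    indices 0..n-1, class B takes n..2n-1), so any sequence can be
    regenerated in isolation.  The master seed defaults to ``params_a.seed``.
    """
    if params_a.class_id == params_b.class_id:
        raise InvalidParameterError(
            f"the two classes must have distinct class_ids, both are {params_a.class_id!r}"
        )
    if n_sequences_per_class < 1:
        raise InvalidParameterError("n_sequences_per_class must be >= 1")
    master = params_a.seed if seed is None else seed
    out = []
    for i in range(n_sequences_per_class):
        out.append(generate_scene_sequence(replace(params_a, seed=master + i)))
    for i in range(n_sequences_per_class):
        out.append(
            generate_scene_sequence(replace(params_b, seed=master + n_sequences_per_class + i))
        )
    return out


def flight_transition_stream(spec: TransitionSpec) -> tuple[FrameStream, list[str]]:
    """Render a flight profile into one stream plus per-frame ground truth.

    Returns the concatenated frame stream and a parallel list of labels
    (class_id of the segment, or "noise").  Class segments keep their own
    appearance parameters but are re-sized to the spec's frame size; each
    segment draws from an independent child RNG of the spec seed so the
    stream is reproducible as a whole.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.frame_size
    frames: list[np.ndarray] = []
    labels: list[str] = []
    for kind, n in spec.segments:
        child = np.random.default_rng(rng.integers(0, 2**31 - 1))
        if kind == NOISE:
            lo, hi = spec.noise_intensity_range
            for _ in range(n):
                frames.append(_to_rgb_uint8(rng_uniform(child, lo, hi, (h, w))))
                labels.append(NOISE)
        else:
            seg_params = replace(kind, n_frames=n, frame_size=spec.frame_size)
            seg = generate_scene_sequence(seg_params, rng=child)
            frames.extend(seg.frames)
            labels.extend([kind.class_id] * n)
    return FrameStream.from_arrays(frames), labels


def rng_uniform(rng: np.random.Generator, lo: float, hi: float, shape) -> np.ndarray:
    return rng.uniform(lo, hi, size=shape) if hi > lo else np.full(shape, lo)


def default_two_class_params(
    separable: bool = True,
    seed: int = 0,
    n_frames: int = _DEFAULT_N_FRAMES,
    temporal_corr: float = _DEFAULT_CORR,
) -> tuple[SceneParams, SceneParams]:
    """Standard study conditions: a spray / non-spray scene pair.

    ``separable=True`` gives the crop-rows vs bare-soil templates, whose
    distance is an order of magnitude above the appearance noise;
    ``separable=False`` gives both classes the *same* template, so any
    classifier can only perform at chance — the calibration condition.
    """
    spray_tpl = crop_rows_template()
    non_tpl = bare_soil_template() if separable else spray_tpl
    a = SceneParams(
        class_id="spray",
        base_pattern=spray_tpl,
        n_frames=n_frames,
        temporal_corr=temporal_corr,
        seed=seed,
    )
    b = replace(a, class_id="non_spray", base_pattern=non_tpl, seed=seed + 1)
    return a, b
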