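"""Frame ingestion and the preprocessing path: subsample, grayscale, 8x8, vectorize.

Every pattern vector the classifier sees comes through this module: an RGB
frame is converted to grayscale with ITU-R BT.601 luma weights
(0.299, 0.587, 0.114), resized to 8x8 by exact area (block) averaging, and
flattened row-major into a 64-element feature vector.  Pixel values stay on
the 0-255 scale; the angle-based similarities downstream are scale
invariant, so no further normalization is applied here.

Frame sources may be directories of PNG/JPEG frames (read in lexicographic
order), video files decodable by imageio, in-memory arrays, or an existing
:class:`FrameStream`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .exceptions import EmptyStreamError, InvalidInputError, InvalidParameterError

#: ITU-R BT.601 luma weights for R, G, B.
BT601_WEIGHTS = (0.299, 0.587, 0.114)

#: Side length of the working pattern; vectors are PATTERN_SIZE**2 long.
PATTERN_SIZE = 8

_IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg", ".bmp", ".tif", ".tiff"}


@dataclass(frozen=True)
class FrameStream:
    """An ordered sequence of frames with their source indices.

    Frames are H x W x 3 uint8 arrays (or H x W after grayscale conversion);
    ``indices`` records each frame's position in the original source and is
    strictly increasing.
    """

    frames: tuple = ()
    indices: tuple = ()
    label: str | None = None
    source_id: str | None = None

    def __post_init__(self) -> None:
        frames = tuple(np.asarray(f) for f in self.frames)
        indices = tuple(int(i) for i in self.indices)
        if len(frames) != len(indices):
            raise InvalidInputError("frames and indices must have equal length")
        if any(b <= a for a, b in zip(indices, indices[1:])):
            raise InvalidInputError("frame indices must be strictly increasing")
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "indices", indices)

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[np.ndarray]:
        return iter(self.frames)

    @classmethod
    def from_arrays(
        cls, frames: Sequence[np.ndarray], label: str | None = None, source_id: str | None = None
    ) -> "FrameStream":
        return cls(
            frames=tuple(frames),
            indices=tuple(range(len(frames))),
            label=label,
            source_id=source_id,
        )


def _load_source(source) -> FrameStream:
    """Decode a frame source of any supported kind into a FrameStream."""
    if isinstance(source, FrameStream):
        return source
    if isinstance(source, (str, Path)):
        import imageio.v3 as iio

        path = Path(source)
        if path.is_dir():
            files = sorted(
                p for p in path.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES
            )
            if not files:
                raise EmptyStreamError(f"no image files found in {path}")
            frames = [iio.imread(f) for f in files]
            return FrameStream.from_arrays(frames, source_id=str(path))
        if not path.exists():
            raise InvalidInputError(f"source {path} does not exist")
        frames = list(iio.imiter(path))
        if not frames:
            raise EmptyStreamError(f"no frames decoded from {path}")
        return FrameStream.from_arrays(frames, source_id=str(path))
    # assume an in-memory sequence of arrays
    frames = list(source)
    if not frames:
        raise EmptyStreamError("empty frame sequence")
    return FrameStream.from_arrays(frames)


def extract_frames(source, sampling_interval: int = 1) -> FrameStream:
    """Subsample a frame source, keeping frame 0 and then every s-th frame.

    The kept frames are those at source indices 0, s, 2s, ...; the original
    indices are retained on the returned stream so downstream bookkeeping
    can refer back to the source.
    """
    if sampling_interval < 1:
        raise InvalidParameterError(f"sampling_interval must be >= 1, got {sampling_interval}")
    stream = _load_source(source)
    if len(stream) == 0:
        raise EmptyStreamError("source decoded to zero frames")
    # keep the first frame, then every s-th by position, so repeated passes
    # with intervals a then b equal a single pass with interval a*b
    kept = [
        (f, i)
        for pos, (f, i) in enumerate(zip(stream.frames, stream.indices))
        if pos % sampling_interval == 0
    ]
    return FrameStream(
        frames=tuple(f for f, _ in kept),
        indices=tuple(i for _, i in kept),
        label=stream.label,
        source_id=stream.source_id,
    )


def to_grayscale(frame: np.ndarray) -> np.ndarray:
    """BT.601 luma conversion of an 8-bit RGB frame, rounded to nearest integer."""
    f = np.asarray(frame)
    if f.ndim == 2:  # already grayscale
        return f.astype(np.uint8, copy=False)
    if f.ndim != 3 or f.shape[2] != 3:
        raise InvalidInputError(f"expected an H x W x 3 frame, got shape {f.shape}")
    w = np.asarray(BT601_WEIGHTS)
    gray = f.astype(float) @ w
    return np.rint(gray).astype(np.uint8)


def _area_weights(n_src: int, n_dst: int) -> np.ndarray:
    """Row-stochastic (n_dst, n_src) matrix averaging source cells into target cells.

    Target cell i covers the source interval [i*n_src/n_dst, (i+1)*n_src/n_dst);
    each source cell contributes in proportion to its overlap with that
    footprint, so integer downscales reduce to exact block means.
    """
    w = np.zeros((n_dst, n_src))
    for i in range(n_dst):
        lo = i * n_src / n_dst
        hi = (i + 1) * n_src / n_dst
        for j in range(int(np.floor(lo)), int(np.ceil(hi))):
            w[i, j] = min(hi, j + 1.0) - max(lo, float(j))
        w[i] /= hi - lo
    return w


def resize_and_vectorize(gray: np.ndarray, size: int = PATTERN_SIZE) -> np.ndarray:
    """Area-average a grayscale frame to size x size and flatten row-major.

    Returns a float vector of length size**2 on the 0-255 pixel scale.
    """
    g = np.asarray(gray, dtype=float)
    if g.ndim != 2 or g.shape[0] < 1 or g.shape[1] < 1:
        raise InvalidInputError(f"expected a nonempty 2-D grayscale image, got shape {g.shape}")
    wh = _area_weights(g.shape[0], size)
    ww = _area_weights(g.shape[1], size)
    small = wh @ g @ ww.T
    return small.ravel(order="C")


def frame_to_vector(frame: np.ndarray, size: int = PATTERN_SIZE) -> np.ndarray:
    """Full preprocessing of one frame: grayscale -> size x size -> vector."""
    return resize_and_vectorize(to_grayscale(frame), size=size)


def vectorize_stream(stream: FrameStream, size: int = PATTERN_SIZE) -> np.ndarray:
    """Preprocess every frame of a stream into an (n, size**2) pattern matrix."""
    if len(stream) == 0:
        raise EmptyStreamError("cannot vectorize an empty stream")
    return np.stack([frame_to_vector(f, size=size) for f in stream.frames])


def remove_noise_frames(stream: FrameStream, noise_mask: Sequence[bool]) -> FrameStream:
    """Drop the frames marked True in the mask, preserving order and indices.

    Mirrors manual noise marking of takeoff/landing and field entry/exit
    frames that belong to neither category; the mask typically comes from a
    ground-truth manifest.
    """
    mask = list(noise_mask)
    if len(mask) != len(stream):
        raise InvalidInputError(
            f"noise mask length {len(mask)} does not match stream length {len(stream)}"
        )
    kept = [(f, i) for (f, i, m) in zip(stream.frames, stream.indices, mask) if not m]
    return FrameStream(
        frames=tuple(f for f, _ in kept),
        indices=tuple(i for _, i in kept),
        label=stream.label,
        source_id=stream.source_id,
    )


def write_manifest(path, labels: Sequence[str], noise_label: str = "noise") -> None:
    """Write a per-frame ground-truth manifest CSV (frame_index,label,is_noise)."""
    df = pd.DataFrame(
        {
            "frame_index": np.arange(len(labels)),
            "label": list(labels),
            "is_noise": [lab == noise_label for lab in labels],
        }
    )
    df.to_csv(path, index=False)


def read_manifest(path) -> pd.DataFrame:
    """Read a manifest CSV written by :func:`write_manifest`."""
    df = pd.read_csv(path)
    required = {"frame_index", "label", "is_noise"}
    if not required.issubset(df.columns):
        raise InvalidInputError(f"manifest must have columns {sorted(required)}")
    return df


def relabel(stream: FrameStream, label: str | None) -> FrameStream:
    """Return the same stream with a different category label."""
    return replace(stream, label=label)
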