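"""Image preprocessing and kymograph construction.

The raw unit of data is a calibrated single-channel time-lapse :class:`Movie`
(frames ``T×H×W``, pixel size in µm, frame interval in s).  Processing follows
the standard workflow for in vivo organelle-trafficking movies:

1. translation registration against a reference frame (integer shifts),
2. temporal-percentile background subtraction plus per-frame median filtering,
3. a temporal standard-deviation projection to reveal moving puncta as curves,
4. resampling along a hand-traced axon polyline into a :class:`Kymograph`
   (time × arc-length matrix) on which all tracking happens.

Coordinates are 0-based pixels; polyline vertices are ``(x, y)`` =
``(column, row)``.  Kymograph rows are time, columns arc length from the path
start, reported in µm.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import tifffile
from scipy import ndimage
from skimage.registration import phase_cross_correlation

__all__ = [
    "Movie",
    "AxonPath",
    "Kymograph",
    "register_frames",
    "enhance",
    "sd_projection",
    "build_kymograph",
    "read_movie",
    "write_movie",
]


@dataclass
class Movie:
    """Calibrated single-channel fluorescence time-lapse."""

    frames: np.ndarray  # (T, H, W), non-negative intensities
    pixel_size_um: float
    frame_interval_s: float
    channel: str = ""
    movie_id: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise ValueError("movie must be a T×H×W stack with T ≥ 2")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("movie intensities must be finite")
        if self.pixel_size_um <= 0 or self.frame_interval_s <= 0:
            raise ValueError("calibrations must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape

    @property
    def duration_s(self) -> float:
        return self.n_frames * self.frame_interval_s


@dataclass
class AxonPath:
    """Ordered axon polyline in pixel coordinates with a sampling width.

    ``vertices`` is an ``(N, 2)`` array of ``(x, y)`` pixel positions, N ≥ 2,
    consecutive vertices distinct.  ``width_px`` is the odd perpendicular
    sampling width used when reducing a movie to a kymograph.
    """

    vertices: np.ndarray
    width_px: int = 5

    def __post_init__(self) -> None:
        self.vertices = np.atleast_2d(np.asarray(self.vertices, dtype=float))
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2 or len(self.vertices) < 2:
            raise ValueError("path needs ≥2 (x, y) vertices")
        seg = np.diff(self.vertices, axis=0)
        if np.any(np.hypot(seg[:, 0], seg[:, 1]) == 0):
            raise ValueError("consecutive path vertices must be distinct")
        if self.width_px < 1 or self.width_px % 2 == 0:
            raise ValueError("width_px must be odd and ≥ 1")

    @property
    def arc_length_px(self) -> float:
        seg = np.diff(self.vertices, axis=0)
        return float(np.hypot(seg[:, 0], seg[:, 1]).sum())

    def arc_length_um(self, pixel_size_um: float) -> float:
        return self.arc_length_px * pixel_size_um

    def reversed(self) -> "AxonPath":
        return AxonPath(self.vertices[::-1].copy(), self.width_px)

    def resample(self, n_samples: int) -> tuple[np.ndarray, np.ndarray]:
        """Resample to `n_samples` equidistant points; returns (points, tangents)."""
        seg = np.diff(self.vertices, axis=0)
        seglen = np.hypot(seg[:, 0], seg[:, 1])
        cum = np.concatenate([[0.0], np.cumsum(seglen)])
        s = np.linspace(0.0, cum[-1], n_samples)
        x = np.interp(s, cum, self.vertices[:, 0])
        y = np.interp(s, cum, self.vertices[:, 1])
        pts = np.column_stack([x, y])
        tang = np.gradient(pts, axis=0)
        norm = np.hypot(tang[:, 0], tang[:, 1])
        norm[norm == 0] = 1.0
        return pts, tang / norm[:, None]


@dataclass
class Kymograph:
    """Time × arc-length intensity matrix along an axon path."""

    data: np.ndarray  # (T, S), values ≥ 0
    col_spacing_um: float  # arc-length step between columns
    frame_interval_s: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("kymograph must be 2-D (time × position)")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_cols(self) -> int:
        return self.data.shape[1]

    @property
    def length_um(self) -> float:
        return (self.n_cols - 1) * self.col_spacing_um

    def positions_um(self) -> np.ndarray:
        return np.arange(self.n_cols) * self.col_spacing_um


def _shift_frame(frame: np.ndarray, dy: int, dx: int) -> np.ndarray:
    """Integer translation with zero-filled borders."""
    out = np.zeros_like(frame)
    h, w = frame.shape
    ys = slice(max(dy, 0), min(h + dy, h))
    xs = slice(max(dx, 0), min(w + dx, w))
    ys_src = slice(max(-dy, 0), min(h - dy, h))
    xs_src = slice(max(-dx, 0), min(w - dx, w))
    out[ys, xs] = frame[ys_src, xs_src]
    return out


def register_frames(movie: Movie, reference: int = 0) -> tuple[Movie, list[tuple[int, int]]]:
    """Correct rigid x–y drift by integer-pixel cross-correlation alignment.

    Each frame is translated by the integer shift that maximises its
    cross-correlation with the `reference` frame; borders are zero-filled.
    Returns the registered movie and the applied ``(dy, dx)`` shift per frame.
    """
    ref = movie.frames[reference]
    if ref.max() == 0:
        warnings.warn("reference frame is all zero; no registration applied")
        return replace(movie, frames=movie.frames.copy()), [(0, 0)] * movie.n_frames

    shifts: list[tuple[int, int]] = []
    out = np.empty_like(movie.frames)
    for t in range(movie.n_frames):
        frame = movie.frames[t]
        if frame.max() == 0:
            warnings.warn(f"frame {t} is all zero; shift (0, 0) assumed")
            dy = dx = 0
        else:
            shift, _, _ = phase_cross_correlation(ref, frame, upsample_factor=1,
                                                  normalization=None)
            dy, dx = int(round(shift[0])), int(round(shift[1]))
        shifts.append((dy, dx))
        out[t] = _shift_frame(frame, dy, dx)
    return replace(movie, frames=out), shifts


def enhance(movie: Movie, background_percentile: float = 20.0,
            median_radius_px: int = 1) -> Movie:
    """Temporal-percentile background subtraction + per-frame median filter.

    The background is the per-pixel temporal percentile of the stack; it is
    subtracted and the result clipped at zero, then each frame is median
    filtered with a square footprint of half-width `median_radius_px`
    (radius 0 disables filtering).  Output intensities are never negative.
    """
    if not (0 <= background_percentile < 100):
        raise ValueError("background_percentile must be in [0, 100)")
    if median_radius_px < 0:
        raise ValueError("median_radius_px must be ≥ 0")
    bg = np.percentile(movie.frames, background_percentile, axis=0)
    sub = np.clip(movie.frames - bg[None], 0.0, None)
    if median_radius_px > 0:
        size = 2 * median_radius_px + 1
        sub = np.stack([ndimage.median_filter(f, size=size) for f in sub])
    return replace(movie, frames=sub)


def sd_projection(movie: Movie) -> np.ndarray:
    """Per-pixel temporal standard deviation; moving puncta show up as curves."""
    return movie.frames.std(axis=0)


def build_kymograph(movie: Movie, path: AxonPath) -> Kymograph:
    """Resample a movie along an axon path into a time × arc-length matrix.

    The path is resampled at ≈1-pixel arc-length steps; for every sample and
    frame the intensity is the maximum over ``path.width_px`` pixels taken
    perpendicular to the path (bilinear interpolation).  The maximum (rather
    than a mean) preserves punctum peaks on curved axons.  Column spacing is
    symmetric in the path ends, so reversing the path flips columns exactly.
    """
    arc = path.arc_length_px
    n_cols = int(np.ceil(arc)) + 1
    pts, tang = path.resample(n_cols)
    normal = np.column_stack([-tang[:, 1], tang[:, 0]])
    half = path.width_px // 2
    offsets = np.arange(-half, half + 1)
    # sample coordinates, shape (S, W)
    xs = pts[:, 0][:, None] + normal[:, 0][:, None] * offsets[None, :]
    ys = pts[:, 1][:, None] + normal[:, 1][:, None] * offsets[None, :]
    T, H, W = movie.shape
    if xs.min() < 0 or ys.min() < 0 or xs.max() > W - 1 or ys.max() > H - 1:
        raise ValueError("sampling width extends outside the frame")
    coords = np.stack([ys.ravel(), xs.ravel()])
    data = np.empty((T, n_cols))
    for t in range(T):
        vals = ndimage.map_coordinates(movie.frames[t], coords, order=1,
                                       mode="constant")
        data[t] = vals.reshape(n_cols, len(offsets)).max(axis=1)
    col_um = (arc / (n_cols - 1)) * movie.pixel_size_um
    return Kymograph(data, col_spacing_um=col_um,
                     frame_interval_s=movie.frame_interval_s,
                     provenance={"movie_id": movie.movie_id,
                                 "channel": movie.channel,
                                 "width_px": path.width_px,
                                 "reduction": "max"})


def write_movie(movie: Movie, tiff_path) -> None:
    """Write a movie as multi-page TIFF plus a JSON calibration sidecar."""
    tifffile.imwrite(str(tiff_path), movie.frames.astype(np.float32))
    meta = {"pixel_size_um": movie.pixel_size_um,
            "frame_interval_s": movie.frame_interval_s,
            "channel": movie.channel,
            "movie_id": movie.movie_id}
    with open(str(tiff_path) + ".json", "w") as fh:
        json.dump(meta, fh, indent=1)


def read_movie(tiff_path) -> Movie:
    frames = tifffile.imread(str(tiff_path))
    try:
        with open(str(tiff_path) + ".json") as fh:
            meta = json.load(fh)
    except FileNotFoundError:
        meta = {}
    return Movie(frames,
                 pixel_size_um=meta.get("pixel_size_um", 1.0),
                 frame_interval_s=meta.get("frame_interval_s", 1.0),
                 channel=meta.get("channel", ""),
                 movie_id=meta.get("movie_id", ""))
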