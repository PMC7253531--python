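"""From fluorescence movies to normalized ΔF/F0 traces.

The processing chain mirrors standard wide-field somatic calcium imaging:
square ROIs are placed on bright somata, the ROI pixel mean gives the raw
fluorescence F*(t), which is smoothed with a short moving average (5 frames =
250 ms at 20 FPS), corrected for slow drift by subtracting a cubic spline
through 25-s block means, and normalized to

    ΔF/F0 (%) = 100 · (F* − F0) / F0 ,

with F0 a robust (low-percentile) estimate of the resting fluorescence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy.interpolate import CubicSpline
from scipy.ndimage import maximum_filter

from .errors import BoundsError, DegenerateBaselineError, ParameterError

__all__ = [
    "MovieStack",
    "ROISet",
    "RawTrace",
    "NormalizedTrace",
    "detect_rois",
    "extract_traces",
    "smooth",
    "correct_drift",
    "estimate_f0",
    "normalize_dff",
    "fov_extent",
    "write_traces_csv",
    "read_traces_csv",
    "write_rois_csv",
    "read_rois_csv",
]


@dataclass
class MovieStack:
    """Single-channel fluorescence movie: ``frames`` is (time, y, x)."""

    frames: np.ndarray
    geometry: "object" = None  # AcquisitionGeometry; kept loose to avoid cycles

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ParameterError("movie frames must be a 3-D (time, y, x) array")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    def to_tiff(self, path) -> None:
        tifffile.imwrite(str(path), self.frames)

    @classmethod
    def from_tiff(cls, path, geometry=None) -> "MovieStack":
        return cls(frames=tifffile.imread(str(path)), geometry=geometry)


@dataclass
class ROISet:
    """Square ROIs of side ``size_px`` centered at ``centers`` (0-based (y, x))."""

    centers: list[tuple[int, int]]
    size_px: int = 7

    def __post_init__(self) -> None:
        if self.size_px < 1 or self.size_px % 2 == 0:
            raise ParameterError("roi size must be an odd positive integer")
        self.centers = [(int(y), int(x)) for y, x in self.centers]

    def __len__(self) -> int:
        return len(self.centers)

    @property
    def half(self) -> int:
        return (self.size_px - 1) // 2


@dataclass
class RawTrace:
    """ROI-averaged fluorescence F*(t) in camera units, one value per frame."""

    values: np.ndarray
    fps: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ParameterError("trace must be a non-empty 1-D array")
        if self.fps <= 0:
            raise ParameterError("fps must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ParameterError("trace values must be finite")

    @property
    def n_frames(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        return self.n_frames / self.fps


@dataclass
class NormalizedTrace:
    """ΔF/F0 trace in percent, with the baseline ``f0`` it was derived from."""

    values: np.ndarray
    f0: float
    fps: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.f0 <= 0:
            raise ParameterError("f0 must be strictly positive")

    @property
    def n_frames(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        return self.n_frames / self.fps


def detect_rois(
    brightness_image: np.ndarray,
    size_px: int = 7,
    intensity_threshold: float = 0.0,
    min_separation_px: float = 7.0,
) -> ROISet:
    """Place square ROIs on local brightness maxima of a summary image.

    Candidate centers are local maxima (3×3 neighborhood) strictly above
    ``intensity_threshold`` whose ROI fits inside the frame.  Candidates are
    accepted greedily in order of decreasing brightness (ties broken
    row-major) subject to a minimum Euclidean center separation, so the
    result is deterministic.
    """
    img = np.asarray(brightness_image, dtype=float)
    if img.ndim != 2:
        raise ParameterError("brightness image must be 2-D")
    if not np.all(np.isfinite(img)) or np.any(img < 0):
        raise ParameterError("brightness image must be finite and non-negative")
    half = (size_px - 1) // 2
    if size_px < 1 or size_px % 2 == 0:
        raise ParameterError("size_px must be odd and positive")

    local_max = img == maximum_filter(img, size=3, mode="nearest")
    mask = local_max & (img > intensity_threshold)
    # ROI must fit inside the frame
    mask[:half, :] = False
    mask[:, :half] = False
    if half:
        mask[-half:, :] = False
        mask[:, -half:] = False
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        return ROISet(centers=[], size_px=size_px)
    order = np.lexsort((xs, ys, -img[ys, xs]))
    accepted: list[tuple[int, int]] = []
    min_sep2 = float(min_separation_px) ** 2
    for i in order:
        y, x = int(ys[i]), int(xs[i])
        if all((y - ay) ** 2 + (x - ax) ** 2 >= min_sep2 for ay, ax in accepted):
            accepted.append((y, x))
    return ROISet(centers=accepted, size_px=size_px)


def extract_traces(movie: MovieStack, rois: ROISet) -> list[RawTrace]:
    """Average movie pixels inside each ROI at every frame.

    The trace value at frame t is the arithmetic mean of the ROI's
    ``size_px²`` pixels at t.
    """
    frames = np.asarray(movie.frames, dtype=float)
    _, h, w = frames.shape
    half = rois.half
    fps = getattr(movie.geometry, "fps", None) or 1.0
    traces = []
    for y, x in rois.centers:
        if y - half < 0 or x - half < 0 or y + half >= h or x + half >= w:
            raise BoundsError(f"ROI at ({y}, {x}) extends outside the frame")
        block = frames[:, y - half : y + half + 1, x - half : x + half + 1]
        traces.append(RawTrace(values=block.mean(axis=(1, 2)), fps=float(fps)))
    return traces


def smooth(trace: RawTrace, window_frames: int = 5) -> RawTrace:
    """Centered moving average; edges use symmetric shrunken windows.

    The window shrinks symmetrically near the ends (at index i it spans
    ``2·min(i, n−1−i, (w−1)/2) + 1`` frames), so the output has the same
    length and no padded values.  A 5-frame window at 20 FPS spans 250 ms.
    """
    v = trace.values
    n = v.size
    w = int(window_frames)
    if w < 1 or w % 2 == 0:
        raise ParameterError("window_frames must be odd and >= 1")
    if w > n:
        raise ParameterError("window_frames exceeds trace length")
    half = (w - 1) // 2
    out = np.convolve(v, np.ones(w) / w, mode="same")
    for i in range(half):
        h = i  # symmetric half-width at the edges
        out[i] = v[: 2 * h + 1].mean()
        out[n - 1 - i] = v[n - 1 - 2 * h :].mean()
    return RawTrace(values=out, fps=trace.fps)


def _block_spline(v: np.ndarray, fps: float, block_s: float) -> np.ndarray:
    """Cubic spline (natural BC) through block-center / block-mean knots."""
    n = v.size
    block_frames = int(round(block_s * fps))
    n_blocks = n // block_frames
    if n_blocks < 2:
        raise ParameterError("trace must span at least two drift blocks")
    edges = [i * block_frames for i in range(n_blocks)] + [n]  # fold remainder into last block
    centers = np.array([(edges[i] + edges[i + 1] - 1) / 2.0 for i in range(n_blocks)])
    means = np.array([v[edges[i] : edges[i + 1]].mean() for i in range(n_blocks)])
    spline = CubicSpline(centers, means, bc_type="natural")
    return spline(np.arange(n, dtype=float))


def correct_drift(trace: RawTrace, block_s: float = 25.0) -> RawTrace:
    """Remove slow drift by subtracting a block-mean spline of the signal.

    The signal is divided into ``block_s``-wide blocks; a cubic spline
    interpolates the block means at block centers and is subtracted from the
    trace.  Adding back the spline's mean restores the overall fluorescence
    level, so firing transients and the baseline F0 are preserved while
    fluctuations slower than the block scale are removed.
    """
    s = _block_spline(trace.values, trace.fps, block_s)
    corrected = trace.values - s + s.mean()
    return RawTrace(values=corrected, fps=trace.fps)


def estimate_f0(trace: RawTrace, percentile: float = 10.0) -> float:
    """Robust baseline estimate: a low percentile of the (corrected) trace.

    Calcium transients are sparse positive excursions, so a low percentile
    of the drift-corrected trace tracks the resting level.  Raises
    :class:`DegenerateBaselineError` if the estimate is not positive.
    """
    f0 = float(np.percentile(trace.values, percentile))
    if f0 <= 0:
        raise DegenerateBaselineError(f"baseline estimate {f0!r} is not positive")
    return f0


def normalize_dff(trace: RawTrace, f0: float) -> NormalizedTrace:
    """Normalize to percent ΔF/F0: ``100·(F* − F0)/F0``."""
    if f0 <= 0:
        raise ParameterError("f0 must be strictly positive")
    return NormalizedTrace(values=100.0 * (trace.values - f0) / f0, f0=f0, fps=trace.fps)


def fov_extent(n_pixels: float, um_per_px: float) -> float:
    """Field-of-view extent in millimetres for ``n_pixels`` at ``um_per_px``."""
    if n_pixels < 0 or um_per_px < 0:
        raise ParameterError("inputs must be non-negative")
    return n_pixels * um_per_px / 1000.0


# --------------------------------------------------------------------------
# CSV interfaces

def write_traces_csv(path, traces: list, ids: list | None = None) -> None:
    """Write traces as CSV: column 1 ``time_s``, then one column per ROI id."""
    if not traces:
        raise ParameterError("no traces to write")
    fps = traces[0].fps
    n = traces[0].values.size
    ids = ids if ids is not None else list(range(len(traces)))
    data = {"time_s": np.arange(n) / fps}
    for roi_id, tr in zip(ids, traces):
        data[str(roi_id)] = tr.values
    pd.DataFrame(data).to_csv(path, index=False)


def read_traces_csv(path) -> tuple[list[RawTrace], list[str]]:
    """Read a trace CSV written by :func:`write_traces_csv`."""
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    if t.size < 2:
        raise ParameterError("trace CSV must contain at least two frames")
    fps = 1.0 / float(np.median(np.diff(t)))
    ids = [c for c in df.columns if c != "time_s"]
    traces = [RawTrace(values=df[c].to_numpy(dtype=float), fps=fps) for c in ids]
    return traces, ids


def write_rois_csv(path, rois: ROISet, ids: list | None = None) -> None:
    ids = ids if ids is not None else list(range(len(rois)))
    rows = [
        {"roi_id": i, "y_px": y, "x_px": x, "size_px": rois.size_px}
        for i, (y, x) in zip(ids, rois.centers)
    ]
    pd.DataFrame(rows, columns=["roi_id", "y_px", "x_px", "size_px"]).to_csv(path, index=False)


def read_rois_csv(path) -> ROISet:
    df = pd.read_csv(path)
    size = int(df["size_px"].iloc[0]) if len(df) else 7
    return ROISet(centers=list(zip(df["y_px"], df["x_px"])), size_px=size)
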