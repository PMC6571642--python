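"""Pupil detection and 2-D eye-position tracking for video-oculography.

Infrared-goggle eye videos show a dark pupil on a lighter iris and sclera.
Each frame is processed in a fixed order: a circle Hough transform gates the
frame (no plausible circular dark region means the eye is closed or the
detector has failed), the frame is binarized with an adaptive threshold, the
boundary of the dark pupil region is extracted, and an ellipse is fitted to
those edge points.  The ellipse center, referenced to the first valid frame
of the clip, gives the horizontal and vertical eye-position traces from
which transient (frame-to-frame) velocities and beat directions are derived.

Positions are kept in image pixels throughout: no pixel-to-degree
calibration is applied, so downstream velocity thresholds are expressed in
pixels per second.  Image coordinates are used (origin top-left, x
rightward, y downward); the mapping to clinical up/down-beat conventions is
applied at the feature-encoding stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from skimage.draw import disk as _disk
from skimage.feature import canny
from skimage.filters import threshold_otsu
from scipy.ndimage import binary_erosion
from skimage.measure import EllipseModel, label as _label
from skimage.transform import hough_circle, hough_circle_peaks

__all__ = [
    "Frame",
    "PupilFit",
    "EyeTrace",
    "DetectionParams",
    "UntrackableClipError",
    "detect_pupil",
    "track_clip",
    "transient_velocities",
    "axis_direction",
]


class UntrackableClipError(RuntimeError):
    """Raised when a clip contains no frame with a detectable pupil."""


@dataclass(frozen=True)
class Frame:
    """A single 8-bit grayscale video frame.

    Attributes
    ----------
    pixels : ndarray of uint8, shape (H, W)
    index : int
        Position of the frame within its clip.
    timestamp : float
        Acquisition time in seconds; strictly increasing within a clip.
    """

    pixels: np.ndarray
    index: int = 0
    timestamp: float = 0.0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError("frame pixels must be a 2-D array")
        object.__setattr__(self, "pixels", px.astype(np.uint8, copy=False))


@dataclass
class PupilFit:
    """Result of pupil detection in one frame.

    When ``found`` is False the geometric fields are undefined and must not
    be read.  ``score`` is the circle Hough accumulator value of the best
    candidate (0 when no candidate exists) and is used by the clip-level
    blink rule.
    """

    found: bool
    center_x: float = float("nan")
    center_y: float = float("nan")
    semi_major: float = float("nan")
    semi_minor: float = float("nan")
    orientation: float = float("nan")
    score: float = 0.0


@dataclass
class EyeTrace:
    """Horizontal/vertical pupil-center trace for one clip.

    ``x`` and ``y`` are raw pixel coordinates (NaN where invalid); ``valid``
    is False on blink or detection-failure frames.  The reference point is
    the pupil center in the first valid frame.
    """

    frame_rate: float
    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray
    reference_x: float
    reference_y: float

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (len(self.x) == len(self.y) == len(self.valid)):
            raise ValueError("x, y and valid must have equal length")

    def __len__(self) -> int:
        return len(self.x)


@dataclass
class DetectionParams:
    """Tunable thresholds of the pupil detector.

    The Hough radius range should bracket the expected pupil radius in
    pixels.  ``hough_floor`` is the absolute accumulator score below which a
    frame is declared pupil-free (blink); ``blink_fraction`` additionally
    rejects frames whose score falls below that fraction of the clip median
    score.  The binarization threshold is Otsu's value clamped to
    ``otsu_clamp`` gray levels, which guards against low-contrast frames
    where Otsu would split the iris instead of the pupil.  Invalid runs of
    at most ``max_gap`` frames are bridged by linear interpolation before
    velocities are computed; longer runs split the trace into segments.
    """

    min_radius: int = 10
    max_radius: int = 60
    radius_step: int = 3
    canny_sigma: float = 2.0
    hough_floor: float = 0.2
    blink_fraction: float = 0.5
    otsu_clamp: int = 100
    max_gap: int = 5

    def radii(self) -> np.ndarray:
        return np.arange(self.min_radius, self.max_radius + 1, self.radius_step)


def _ellipse_from_points(points_xy: np.ndarray) -> tuple[float, float, float, float, float] | None:
    """Fit an ellipse to boundary points; return (cx, cy, a, b, theta) or None."""
    if len(points_xy) < 5:
        return None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = EllipseModel.from_estimate(points_xy.astype(float))
        except Exception:
            return None
    if not model:  # failed estimation yields a falsy object
        return None
    cx, cy = model.center
    a, b = model.axis_lengths
    theta = model.theta
    if not np.all(np.isfinite([cx, cy, a, b, theta])) or a <= 0 or b <= 0:
        return None
    if b > a:
        a, b = b, a
        theta += np.pi / 2
    return float(cx), float(cy), float(a), float(b), float(theta % np.pi)


def detect_pupil(frame: Frame, params: DetectionParams | None = None) -> PupilFit:
    """Locate the pupil in a single frame.

    Processing order: circle Hough gate on Canny edges, threshold
    binarization, boundary extraction of the dark region selected by the
    Hough circle, ellipse fit to the boundary points.  If the ellipse fit is
    degenerate the center of gravity of the dark region (weighted by
    darkness below the threshold) is used instead.

    Never raises on degenerate image content: a uniform or pupil-free frame
    returns ``found=False``.
    """
    params = params or DetectionParams()
    px = frame.pixels
    if px.shape[0] < 64 or px.shape[1] < 64:
        raise ValueError("frame must be at least 64x64 pixels")
    if int(px.max()) - int(px.min()) < 10:
        return PupilFit(found=False)  # near-uniform: blink or dropout

    edges = canny(px.astype(float) / 255.0, sigma=params.canny_sigma)
    if not edges.any():
        return PupilFit(found=False)
    radii = params.radii()
    accum = hough_circle(edges, radii)
    scores, cxs, cys, rads = hough_circle_peaks(accum, radii, total_num_peaks=1)
    if len(scores) == 0 or scores[0] < params.hough_floor:
        return PupilFit(found=False, score=float(scores[0]) if len(scores) else 0.0)
    score = float(scores[0])
    hx, hy, hr = int(cxs[0]), int(cys[0]), int(rads[0])

    thr = min(float(threshold_otsu(px)), float(params.otsu_clamp))
    mask = px <= thr
    if not mask.any():
        return PupilFit(found=False, score=score)

    labels = _label(mask)
    rr, cc = _disk((hy, hx), hr, shape=labels.shape)
    inside = labels[rr, cc]
    inside = inside[inside > 0]
    if inside.size == 0:
        return PupilFit(found=False, score=score)
    comp = labels == np.bincount(inside).argmax()

    boundary = comp & ~binary_erosion(comp)
    pts = np.argwhere(boundary)[:, ::-1]  # (x, y)
    fit = _ellipse_from_points(pts)
    if fit is None:
        # center-of-gravity fallback, weighted by darkness below threshold
        ys, xs = np.nonzero(comp)
        w = thr - px[ys, xs].astype(float) + 1.0
        cx = float(np.average(xs, weights=w))
        cy = float(np.average(ys, weights=w))
        a = b = float(np.sqrt(comp.sum() / np.pi))
        return PupilFit(True, cx, cy, a, b, 0.0, score)
    cx, cy, a, b, theta = fit
    return PupilFit(True, cx, cy, a, b, theta, score)


def track_clip(
    frames: Sequence[Frame],
    params: DetectionParams | None = None,
    frame_rate: float | None = None,
) -> tuple[EyeTrace, list[PupilFit]]:
    """Track the pupil center across a clip.

    Returns one (x, y, valid) entry per frame plus the per-frame fits (the
    fits carry the ellipse geometry needed by the torsion stage).  Frames
    whose Hough score falls below ``blink_fraction`` of the clip median are
    re-flagged as blinks even if a circle was nominally found.

    Raises
    ------
    UntrackableClipError
        If no frame yields a valid pupil fit.
    """
    params = params or DetectionParams()
    if len(frames) < 2:
        raise ValueError("a clip needs at least 2 frames")
    fits = [detect_pupil(f, params) for f in frames]

    found_scores = [f.score for f in fits if f.found]
    if found_scores:
        med = float(np.median(found_scores))
        for f in fits:
            if f.found and f.score < params.blink_fraction * med:
                f.found = False
    valid = np.array([f.found for f in fits], dtype=bool)
    if not valid.any():
        raise UntrackableClipError("no frame with a detectable pupil")

    x = np.array([f.center_x if f.found else np.nan for f in fits])
    y = np.array([f.center_y if f.found else np.nan for f in fits])

    if frame_rate is None:
        ts = np.array([f.timestamp for f in frames], dtype=float)
        dt = np.diff(ts)
        frame_rate = 1.0 / float(np.median(dt)) if np.all(dt > 0) else 30.0

    first = int(np.flatnonzero(valid)[0])
    trace = EyeTrace(
        frame_rate=float(frame_rate),
        x=x,
        y=y,
        valid=valid,
        reference_x=float(x[first]),
        reference_y=float(y[first]),
    )
    return trace, fits


def _segments(valid: np.ndarray, max_gap: int) -> list[np.ndarray]:
    """Split valid-frame indices into segments; gaps > max_gap break a segment."""
    idx = np.flatnonzero(valid)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > max_gap + 1)
    return np.split(idx, breaks + 1)


def transient_velocities(
    trace: EyeTrace,
    axis: str = "horizontal",
    max_gap: int | None = None,
) -> np.ndarray:
    """Frame-to-frame velocities (pixels/second) along one axis.

    ``v[i] = (p[i] - p[i-1]) * frame_rate`` over consecutive valid frames;
    short invalid runs (length <= max_gap) are bridged by linear
    interpolation of position before differencing, longer runs split the
    trace and velocities are never differenced across the split.
    """
    if axis not in ("horizontal", "vertical"):
        raise ValueError(f"unknown axis {axis!r}")
    p = trace.x if axis == "horizontal" else trace.y
    if int(trace.valid.sum()) < 2:
        raise UntrackableClipError("need at least 2 valid frames for velocities")
    gap = 5 if max_gap is None else max_gap
    vels: list[np.ndarray] = []
    for seg in _segments(trace.valid, gap):
        if seg.size < 2:
            continue
        full = np.arange(seg[0], seg[-1] + 1)
        interp = np.interp(full, seg, p[seg])
        vels.append(np.diff(interp) * trace.frame_rate)
    if not vels:
        raise UntrackableClipError("no segment with 2 or more valid frames")
    return np.concatenate(vels)


def axis_direction(velocities: Sequence[float]) -> int:
    """Direction of movement along an axis: the sign of the velocity sum.

    Returns +1, -1, or 0; an exactly zero sum means no net movement and is
    treated downstream as "no nystagmus on this axis".
    """
    v = np.asarray(velocities, dtype=float)
    if v.size == 0:
        raise ValueError("empty velocity sequence")
    return int(np.sign(v.sum()))
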