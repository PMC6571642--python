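"""Torsional eye-movement estimation by polar cross-correlation of the iris.

Torsion (rotation of the eye about the line of sight) cannot be read from
the pupil center.  Instead, an annulus of iris texture around the fitted
pupil is unwrapped to polar coordinates, turning rotation into horizontal
translation of a gray-level profile.  The profile of the previous frame is
the reference and the current frame's profile is the template; the angular
shift maximizing their normalized cross-correlation is the per-pair torsion
increment, and increments are accumulated into a cumulative torsion trace.

The annulus is sampled along two lateral 90-degree arcs centered on the
horizontal meridian, which avoids eyelid occlusion of the upper and lower
iris.  Matching is done on overlapping patches of the angular profile and
the per-patch shifts are aggregated by their median, so a locally distorted
stretch of texture (a reflection, an eyelash) cannot drag the estimate.
Sub-bin precision comes from parabolic interpolation through the
correlation peak.

Sign convention: positive torsion is counterclockwise in the displayed
image.  The mapping to clinical extorsion/intorsion labels is applied at
the feature-encoding stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import map_coordinates

from .pupil import Frame, PupilFit

__all__ = [
    "IrisStrip",
    "TorsionTrace",
    "TorsionParams",
    "polar_unwrap",
    "rotation_shift",
    "torsion_trace",
    "overall_torsion",
]

#: Two lateral 90-degree arcs (degrees, visual angle CCW from the +x axis).
LATERAL_ARCS: tuple[tuple[float, float], ...] = ((-45.0, 45.0), (135.0, 225.0))
FULL_CIRCLE: tuple[tuple[float, float], ...] = ((0.0, 360.0),)


@dataclass
class IrisStrip:
    """Polar-unwrapped iris annulus.

    Rows are radial samples, columns angular bins; ``theta`` holds the bin
    center angle of every column in degrees.  Samples falling outside the
    source frame are NaN and are excluded from correlation.
    """

    intensities: np.ndarray
    theta: np.ndarray
    theta_step: float
    r_inner: float
    r_outer: float
    source_frame: int = 0

    @property
    def n_columns(self) -> int:
        return self.intensities.shape[1]

    def column_profile(self) -> np.ndarray:
        """Mean gray level of each angular bin (NaN where fully occluded)."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.intensities, axis=0)


@dataclass
class TorsionTrace:
    """Cumulative torsion angle per frame (degrees, + = CCW in image)."""

    angles: np.ndarray
    valid: np.ndarray
    frame_rate: float

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if len(self.angles) != len(self.valid):
            raise ValueError("angles and valid must have equal length")

    def __len__(self) -> int:
        return len(self.angles)


@dataclass
class TorsionParams:
    """Geometry and matching parameters of the torsion estimator.

    The annulus is placed relative to the fitted pupil: inner radius
    ``r_inner_scale`` x semi-major axis (clear of the pupil margin), outer
    radius ``r_outer_scale`` x semi-major.  ``theta_step`` is the angular
    bin width in degrees and bounds the quantization of a single-pair
    estimate; ``window_deg`` bounds the per-pair rotation search.  Patches
    of ``patch_bins`` bins with stride ``patch_stride`` are matched
    independently; a patch only votes when its peak normalized correlation
    reaches ``corr_floor``.
    """

    r_inner_scale: float = 1.15
    r_outer_scale: float = 1.8
    n_radial: int = 8
    theta_step: float = 1.0
    arcs: tuple[tuple[float, float], ...] = LATERAL_ARCS
    window_deg: float = 15.0
    corr_floor: float = 0.2
    patch_bins: int = 30
    patch_stride: int = 15


def polar_unwrap(frame: Frame, fit: PupilFit, params: TorsionParams | None = None) -> IrisStrip:
    """Unwrap the iris annulus around the fitted pupil to polar coordinates.

    Each (radius, angle) sample is bilinearly interpolated from the frame.
    Angles follow the visual convention: measured counterclockwise from the
    +x axis in the displayed image (image y points down, so the sampled
    y-coordinate is ``cy - r sin(theta)``).
    """
    params = params or TorsionParams()
    if not fit.found:
        raise ValueError("polar_unwrap requires a successful pupil fit")
    r_in = params.r_inner_scale * fit.semi_major
    r_out = params.r_outer_scale * fit.semi_major
    radii = np.linspace(r_in, r_out, params.n_radial)
    theta = np.concatenate(
        [
            np.arange(a0, a1, params.theta_step) + params.theta_step / 2.0
            for a0, a1 in params.arcs
        ]
    )
    th = np.deg2rad(theta)
    xs = fit.center_x + radii[:, None] * np.cos(th)[None, :]
    ys = fit.center_y - radii[:, None] * np.sin(th)[None, :]
    h, w = frame.pixels.shape
    if np.all((xs < 0) | (xs > w - 1) | (ys < 0) | (ys > h - 1)):
        raise ValueError("iris annulus lies entirely outside the frame")
    vals = map_coordinates(
        frame.pixels.astype(float),
        np.stack([ys.ravel(), xs.ravel()]),
        order=1,
        mode="constant",
        cval=np.nan,
    ).reshape(params.n_radial, theta.size)
    return IrisStrip(vals, theta, params.theta_step, r_in, r_out, frame.index)


def _arc_runs(theta: np.ndarray, step: float) -> list[tuple[int, int]]:
    """Contiguous column runs (arc pieces) as half-open [start, end) pairs."""
    breaks = np.flatnonzero(np.diff(theta) > 1.5 * step)
    edges = [0, *(breaks + 1), theta.size]
    return [(edges[i], edges[i + 1]) for i in range(len(edges) - 1)]


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    m = np.isfinite(a) & np.isfinite(b)
    if m.sum() < 8:
        return -np.inf
    a, b = a[m] - a[m].mean(), b[m] - b[m].mean()
    d = np.sqrt((a * a).sum() * (b * b).sum())
    if d == 0:
        return -np.inf
    return float((a * b).sum() / d)


def rotation_shift(
    reference: IrisStrip,
    template: IrisStrip,
    params: TorsionParams | None = None,
) -> tuple[float, bool]:
    """Angular shift (degrees) rotating ``reference`` into ``template``.

    Returns ``(delta_deg, valid)``.  The column profile of the template is
    matched against the reference over integer bin shifts within the search
    window, independently for overlapping patches that never span an arc
    boundary; each qualifying patch contributes a parabolically refined
    shift and the median of the patch votes is returned.  When no patch
    reaches the correlation floor the estimate is flagged invalid.

    A template rotated counterclockwise by ``d`` relative to the reference
    yields ``delta_deg = +d``.
    """
    params = params or TorsionParams()
    if reference.n_columns != template.n_columns or reference.theta_step != template.theta_step:
        raise ValueError("strips must share angular geometry")
    f = reference.column_profile()
    g = template.column_profile()
    w = int(round(params.window_deg / params.theta_step))
    votes: list[float] = []
    for start, end in _arc_runs(reference.theta, params.theta_step):
        span = end - start
        n = min(params.patch_bins, span)
        for p0 in range(start, end - n + 1, params.patch_stride):
            corrs = np.full(2 * w + 1, -np.inf)
            for k, s in enumerate(range(-w, w + 1)):
                lo = max(p0 + s, start)
                hi = min(p0 + s + n, end)
                if hi - lo < max(8, n // 2):
                    continue
                corrs[k] = _ncc(g[lo - s : hi - s], f[lo:hi])
            best = int(np.argmax(corrs))
            if not np.isfinite(corrs[best]) or corrs[best] < params.corr_floor:
                continue
            s_best = best - w
            # parabolic sub-bin refinement through the peak
            delta = 0.0
            if 0 < best < 2 * w and np.all(np.isfinite(corrs[best - 1 : best + 2])):
                c0, c1, c2 = corrs[best - 1 : best + 2]
                denom = c0 - 2 * c1 + c2
                if denom < 0:
                    delta = float(np.clip(0.5 * (c0 - c2) / denom, -0.5, 0.5))
            votes.append(-(s_best + delta) * params.theta_step)
    if not votes:
        return float("nan"), False
    return float(np.median(votes)), True


def torsion_trace(
    frames: Sequence[Frame],
    fits: Sequence[PupilFit],
    params: TorsionParams | None = None,
    frame_rate: float = 30.0,
    mode: str = "incremental",
) -> TorsionTrace:
    """Cumulative torsion over a clip.

    ``incremental`` (default): each frame is matched against the previous
    valid frame and increments are accumulated — drift can accumulate but
    the estimate survives slow texture change.  ``first_frame``: every
    frame is matched against the first valid frame, immune to drift but
    limited to rotations inside the search window.

    Invalid pairs (blink, failed fit, correlation below the floor)
    propagate the last cumulative value with ``valid=False``; accumulation
    resumes on the next valid pair.
    """
    params = params or TorsionParams()
    if len(frames) != len(fits):
        raise ValueError("frames and fits must be aligned")
    if mode not in ("incremental", "first_frame"):
        raise ValueError(f"unknown mode {mode!r}")
    n = len(frames)
    angles = np.zeros(n)
    valid = np.zeros(n, dtype=bool)
    prev_strip: IrisStrip | None = None
    cum = 0.0
    for i in range(n):
        if not fits[i].found:
            angles[i] = cum
            continue
        try:
            strip = polar_unwrap(frames[i], fits[i], params)
        except ValueError:
            angles[i] = cum
            continue
        if prev_strip is None:
            prev_strip = strip
            angles[i] = 0.0
            valid[i] = True
            continue
        d, ok = rotation_shift(prev_strip, strip, params)
        if ok:
            if mode == "incremental":
                cum += d
                prev_strip = strip
            else:
                cum = d
            angles[i] = cum
            valid[i] = True
        else:
            angles[i] = cum
            if mode == "incremental":
                prev_strip = strip  # resynchronize after a bad pair
    return TorsionTrace(angles, valid, frame_rate)


def overall_torsion(trace: TorsionTrace, method: str = "signed_sum") -> float:
    """Summarize a torsion trace into a single velocity (degrees/second).

    ``signed_sum`` — mean signed per-pair increment times the frame rate
    (mean torsional velocity); beats in alternating directions cancel.
    ``mean_sample_distance`` — mean absolute increment times the frame
    rate; sensitive to outliers, retained for comparison.
    """
    if method not in ("signed_sum", "mean_sample_distance"):
        raise ValueError(f"unknown method {method!r}")
    pair_ok = trace.valid[1:] & trace.valid[:-1]
    inc = np.diff(trace.angles)[pair_ok]
    if trace.valid.sum() < 2 or inc.size == 0:
        raise ValueError("need at least 2 valid entries for overall torsion")
    if method == "signed_sum":
        return float(inc.sum() * trace.frame_rate / inc.size)
    return float(np.abs(inc).mean() * trace.frame_rate)
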