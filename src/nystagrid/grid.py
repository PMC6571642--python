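"""Grid-image feature encoding of a positional-test battery.

The diagnostic examination for benign paroxysmal positional vertigo (BPPV)
consists of ten positional tests, each provoking (or not) nystagmus whose
slow-phase velocity is measured along three axes: horizontal, vertical and
torsional.  The whole battery is summarized as a 3x10 "grid image": one
column per positional test, one row per axis, each cell an 8-bit value
encoding the signed nystagmus amplitude of that (axis, test) pair.  Neutral
or missing cells take the mid-gray value 128; amplitudes are clamped to
+/- ``amplitude_cap`` (default 1000) and mapped affinely so that +cap
encodes as 255 and -cap as 1.  This small image is the sole input of the
canal classifier.

Clinical sign conventions used in a grid cell:

* horizontal: + = rightward beating (image +x),
* vertical:   + = upbeat (negative image y),
* torsional:  + = counterclockwise in the displayed image (the patient's
  clockwise, camera facing the eye).

Measured slow-phase velocities (pixels/s or degrees/s) are converted to
the dimensionless amplitude scale of the grid with per-axis scale factors,
since no pixel-to-degree calibration is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .pupil import EyeTrace, UntrackableClipError, transient_velocities
from .torsion import TorsionTrace

__all__ = [
    "TEST_ORDER",
    "AXES",
    "CLASS_LABELS",
    "PositionalTest",
    "AxisSummary",
    "TestBattery",
    "GridImage",
    "NEUTRAL",
    "summarize_test",
    "is_normal",
    "build_grid",
    "decode_grid",
    "slow_phase_velocity",
]

#: The ten positional tests, in fixed column order.  Lateralized maneuvers
#: (supine roll, Dix-Hallpike and its return-to-sitting) appear once per
#: side; together with bow, lean, lying-down and straight head-hanging they
#: make up the ten-test battery.
TEST_ORDER: tuple[str, ...] = (
    "bow",
    "lean",
    "lying_down",
    "roll_right",
    "roll_left",
    "head_hanging",
    "dix_hallpike_right",
    "dix_hallpike_left",
    "sit_up_right",
    "sit_up_left",
)

#: Row order of the grid image.
AXES: tuple[str, str, str] = ("horizontal", "vertical", "torsional")

#: The eight BPPV classes: posterior canal (PSC), geotropic and ageotropic
#: lateral canal (LSC), anterior canal (ASC), each right or left.
CLASS_LABELS: tuple[str, ...] = (
    "psc_right",
    "psc_left",
    "lsc_geo_right",
    "lsc_geo_left",
    "lsc_ageo_right",
    "lsc_ageo_left",
    "asc_right",
    "asc_left",
)

NEUTRAL: int = 128

#: Velocity units per amplitude unit: horizontal/vertical in px/s,
#: torsional in deg/s.  With the default cap of 1000, the grid spans
#: +/-100 px/s and +/-10 deg/s of slow-phase velocity.
AXIS_VELOCITY_SCALE: dict[str, float] = {
    "horizontal": 0.1,
    "vertical": 0.1,
    "torsional": 0.01,
}

#: Normality thresholds on |overall slow-phase velocity|; a battery where
#: every test stays strictly below these on all axes is "normal" and the
#: pipeline stops before classification.
NORMAL_THRESHOLDS: dict[str, float] = {
    "horizontal": 5.0,  # px/s
    "vertical": 5.0,    # px/s
    "torsional": 2.0,   # deg/s
}


@dataclass(frozen=True)
class PositionalTest:
    identifier: str
    laterality: str = "none"  # left / right / none

    def __post_init__(self) -> None:
        if self.identifier not in TEST_ORDER:
            raise ValueError(f"unknown positional test {self.identifier!r}")


@dataclass
class AxisSummary:
    """Per-axis nystagmus summary of one positional test.

    ``overall_velocity`` is the mean slow-phase velocity (signed, clinical
    convention); ``direction`` is its sign.
    """

    axis: str
    overall_velocity: float
    direction: int

    def __post_init__(self) -> None:
        if self.axis not in AXES:
            raise ValueError(f"unknown axis {self.axis!r}")


class TestBattery:
    """Mapping from positional-test identifier to its three axis summaries."""

    def __init__(self, results: dict[str, dict[str, AxisSummary]] | None = None):
        self.results: dict[str, dict[str, AxisSummary]] = {}
        for test, axes in (results or {}).items():
            for s in axes.values():
                self.set(test, s)

    def set(self, test: str, summary: AxisSummary) -> None:
        if test not in TEST_ORDER:
            raise ValueError(f"unknown positional test {test!r}")
        self.results.setdefault(test, {})[summary.axis] = summary

    def velocity(self, test: str, axis: str) -> float | None:
        s = self.results.get(test, {}).get(axis)
        return None if s is None else s.overall_velocity

    def __len__(self) -> int:
        return len(self.results)


@dataclass
class GridImage:
    """3x10 matrix of 8-bit values; rows = axes, columns = TEST_ORDER."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.shape != (3, 10):
            raise ValueError("grid image must be 3x10")
        if v.min() < 0 or v.max() > 255:
            raise ValueError("grid values must lie in [0, 255]")
        self.values = v.astype(np.uint8)


def slow_phase_velocity(velocities: np.ndarray, fast_factor: float = 2.0) -> float:
    """Mean slow-phase velocity from a transient-velocity sequence.

    Samples whose magnitude exceeds ``fast_factor`` times the 75th
    percentile of |v| are labeled fast (resetting) phases and removed; the
    mean of the remainder is the slow-phase summary.  Returns 0 when
    nothing remains.
    """
    v = np.asarray(velocities, dtype=float)
    if v.size == 0:
        return 0.0
    cut = fast_factor * np.percentile(np.abs(v), 75)
    slow = v[np.abs(v) <= cut] if cut > 0 else v
    return float(slow.mean()) if slow.size else 0.0


def summarize_test(
    trace_2d: EyeTrace | None,
    trace_t: TorsionTrace | None,
    fast_factor: float = 2.0,
) -> dict[str, AxisSummary]:
    """Summarize one positional test's traces into three axis summaries.

    Velocities are converted to the clinical sign convention (vertical is
    negated because image y points down).  An untrackable clip yields three
    neutral summaries rather than an error so that a battery with one
    failed clip can still be encoded.
    """
    out: dict[str, AxisSummary] = {}
    for axis in ("horizontal", "vertical"):
        vel = 0.0
        if trace_2d is not None:
            try:
                v = transient_velocities(trace_2d, axis)
                vel = slow_phase_velocity(v, fast_factor)
            except UntrackableClipError:
                vel = 0.0
        if axis == "vertical":
            vel = -vel  # image y down -> clinical upbeat positive
        out[axis] = AxisSummary(axis, vel, int(np.sign(vel)))
    vel_t = 0.0
    if trace_t is not None:
        pair_ok = trace_t.valid[1:] & trace_t.valid[:-1]
        inc = np.diff(trace_t.angles)[pair_ok]
        if inc.size:
            vel_t = slow_phase_velocity(inc * trace_t.frame_rate, fast_factor)
    out["torsional"] = AxisSummary("torsional", vel_t, int(np.sign(vel_t)))
    return out


def is_normal(battery: TestBattery, thresholds: dict[str, float] | None = None) -> bool:
    """Normality short-circuit: True iff every overall velocity is strictly
    below its axis threshold across all tests (a velocity exactly at the
    threshold counts as abnormal).  A normal result terminates the pipeline
    before grid encoding and classification."""
    thr = thresholds or NORMAL_THRESHOLDS
    for axes in battery.results.values():
        for s in axes.values():
            if abs(s.overall_velocity) >= thr[s.axis]:
                return False
    return True


def _battery_amplitudes(
    battery: TestBattery, scales: dict[str, float]
) -> np.ndarray:
    """3x10 signed amplitudes (NaN = missing) from a velocity battery."""
    amp = np.full((3, 10), np.nan)
    for j, test in enumerate(TEST_ORDER):
        for i, axis in enumerate(AXES):
            v = battery.velocity(test, axis)
            if v is not None:
                amp[i, j] = v / scales[axis]
    return amp


def build_grid(
    battery: TestBattery | np.ndarray,
    amplitude_cap: float = 1000.0,
    scales: dict[str, float] | None = None,
) -> GridImage:
    """Encode a test battery (or a raw 3x10 amplitude array) as a grid image.

    Cell value = ``128 + round(127 * clamp(a, -cap, +cap) / cap)``: zero
    amplitude maps to the neutral 128, +cap to 255, -cap to 1.  Missing
    tests (or NaN amplitudes) encode as 128.  When a :class:`TestBattery`
    is given, velocities are first converted to amplitude units with the
    per-axis scales.
    """
    if isinstance(battery, TestBattery):
        amp = _battery_amplitudes(battery, scales or AXIS_VELOCITY_SCALE)
    else:
        amp = np.asarray(battery, dtype=float)
        if amp.shape != (3, 10):
            raise ValueError("amplitude array must be 3x10")
    cap = float(amplitude_cap)
    vals = np.full((3, 10), NEUTRAL, dtype=float)
    m = np.isfinite(amp)
    vals[m] = NEUTRAL + np.round(127.0 * np.clip(amp[m], -cap, cap) / cap)
    return GridImage(vals)


def decode_grid(grid: GridImage, amplitude_cap: float = 1000.0) -> np.ndarray:
    """Signed amplitudes (3x10) from a grid image: ``(v - 128)/127 * cap``.

    Inverse of :func:`build_grid` up to the encoding quantization step of
    ``cap/127`` per cell.
    """
    return (grid.values.astype(float) - NEUTRAL) / 127.0 * float(amplitude_cap)
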