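"""Polar unwrapping, rotation estimation and torsion traces."""

import numpy as np
import pytest

import nystagrid as ng
from nystagrid.pupil import Frame, PupilFit
from nystagrid.torsion import (
    FULL_CIRCLE,
    IrisStrip,
    TorsionParams,
    overall_torsion,
    polar_unwrap,
    rotation_shift,
    torsion_trace,
)


def _fit(cx=100.0, cy=80.0, a=20.0):
    return PupilFit(True, cx, cy, a, a, 0.0, 1.0)


def exhaustive_shift(ref: IrisStrip, tpl: IrisStrip, window_bins: int) -> float:
    """Oracle: global integer-shift correlation argmax over the window."""
    f, g = ref.column_profile(), tpl.column_profile()
    best, best_c = 0, -np.inf
    for s in range(-window_bins, window_bins + 1):
        a = np.roll(g, -s)  # undo a rotation of +s bins
        m = np.isfinite(a) & np.isfinite(f)
        aa, ff = a[m] - a[m].mean(), f[m] - f[m].mean()
        den = np.sqrt((aa * aa).sum() * (ff * ff).sum())
        c = (aa * ff).sum() / den if den > 0 else -np.inf
        if c > best_c:
            best, best_c = s, c
    return best * ref.theta_step


def _random_strip(rng, n_cols=180, smooth=5):
    raw = rng.normal(0, 1, (8, n_cols + 2 * smooth))
    kern = np.ones(2 * smooth + 1) / (2 * smooth + 1)
    sm = np.apply_along_axis(lambda r: np.convolve(r, kern, "valid"), 1, raw)
    theta = np.arange(n_cols) + 0.5
    return IrisStrip(100 + 40 * sm, theta, 1.0, 20.0, 36.0)


class TestPolarUnwrap:
    def test_concentric_rings_give_identical_columns(self):
        yy, xx = np.mgrid[0:160, 0:200]
        r = np.hypot(xx - 100, yy - 80)
        # smooth radial pattern: interpolation error stays small per column
        img = (128 + 80 * np.sin(r / 5.0)).clip(0, 255).astype(np.uint8)
        strip = polar_unwrap(Frame(img), _fit(), TorsionParams(arcs=FULL_CIRCLE))
        spread = np.nanmax(strip.intensities, 1) - np.nanmin(strip.intensities, 1)
        assert spread.max() < 3  # rotational symmetry -> constant rows

    def test_radial_spoke_lights_one_column(self):
        yy, xx = np.mgrid[0:160, 0:200]
        theta = np.degrees(np.arctan2(-(yy - 80.0), xx - 100.0)) % 360
        img = np.full((160, 200), 50, np.uint8)
        img[np.abs(theta - 90) < 1.5] = 250
        strip = polar_unwrap(Frame(img), _fit(), TorsionParams(arcs=FULL_CIRCLE))
        prof = strip.column_profile()
        assert abs(strip.theta[int(np.nanargmax(prof))] - 90) <= 2

    def test_annulus_outside_frame_raises(self):
        img = np.full((160, 200), 128, np.uint8)
        with pytest.raises(ValueError):
            polar_unwrap(Frame(img), _fit(cx=2000.0, cy=2000.0))

    def test_geometry_follows_fit(self):
        img = np.random.default_rng(0).integers(0, 255, (160, 200)).astype(np.uint8)
        p = TorsionParams()
        strip = polar_unwrap(Frame(img), _fit(a=20.0), p)
        assert strip.r_inner == pytest.approx(1.15 * 20)
        assert strip.r_outer == pytest.approx(1.8 * 20)
        assert strip.n_columns == 180  # two 90-degree arcs at 1 degree/bin


class TestRotationShift:
    def test_self_shift_is_zero(self):
        strip = _random_strip(np.random.default_rng(1))
        d, ok = rotation_shift(strip, strip)
        assert ok and abs(d) <= 0.5

    @pytest.mark.parametrize("k", [1, 5, -9, 14])
    def test_circular_shift_recovered(self, k):
        strip = _random_strip(np.random.default_rng(2))
        rolled = IrisStrip(
            np.roll(strip.intensities, k, axis=1),
            strip.theta, strip.theta_step, strip.r_inner, strip.r_outer,
        )
        d, ok = rotation_shift(strip, rolled)
        assert ok and abs(d - k * strip.theta_step) <= strip.theta_step / 2

    def test_antisymmetry(self):
        rng = np.random.default_rng(3)
        a = _random_strip(rng)
        b = IrisStrip(np.roll(a.intensities, 4, 1), a.theta, 1.0, a.r_inner, a.r_outer)
        dab, _ = rotation_shift(a, b)
        dba, _ = rotation_shift(b, a)
        assert abs(dab + dba) <= 0.5

    def test_matches_exhaustive_oracle_on_random_pairs(self):
        rng = np.random.default_rng(4)
        params = TorsionParams()
        for _ in range(100):
            a = _random_strip(rng)
            k = int(rng.integers(-14, 15))
            b = IrisStrip(np.roll(a.intensities, k, 1), a.theta, 1.0, a.r_inner, a.r_outer)
            d, ok = rotation_shift(a, b, params)
            oracle = exhaustive_shift(a, b, 15)
            assert ok and abs(d - oracle) <= params.theta_step

    def test_uncorrelated_strips_flagged_invalid(self):
        rng = np.random.default_rng(5)
        a = _random_strip(rng)
        flat = IrisStrip(np.full_like(a.intensities, 100.0), a.theta, 1.0, a.r_inner, a.r_outer)
        _, ok = rotation_shift(a, flat)
        assert not ok


class TestTorsionTrace:
    def test_static_eye_stays_near_zero(self):
        frames, _, _ = ng.render_eye_video(ng.SynthVideoSpec(duration=0.5, noise_sd=0.0, seed=8))
        _, fits = ng.track_clip(frames)
        tt = torsion_trace(frames, fits, frame_rate=30.0)
        assert np.abs(tt.angles[tt.valid]).max() <= 0.5

    def test_constant_rotation_recovered(self, rotation_clip):
        _, frames, _, ttruth = rotation_clip
        _, fits = ng.track_clip(frames)
        tt = torsion_trace(frames, fits, frame_rate=30.0)
        err = np.abs(tt.angles - ttruth.angles)[tt.valid]
        assert err.max() <= 1.0  # within one angular bin throughout

    def test_blink_breaks_then_resumes(self):
        spec = ng.SynthVideoSpec(
            slow_phase_velocity=(0.0, 0.0, 12.0), beat_frequency=0.0,
            duration=1.0, blink_frames=(10,), seed=9,
        )
        frames, _, ttruth = ng.render_eye_video(spec)
        _, fits = ng.track_clip(frames)
        tt = torsion_trace(frames, fits, frame_rate=30.0)
        assert not tt.valid[10]
        # accumulation resumes: final angle tracks truth up to the lost frame
        assert tt.angles[-1] == pytest.approx(ttruth.angles[-1], abs=1.5)


class TestOverallTorsion:
    def _trace(self, increments, fps):
        return ng.TorsionTrace(np.concatenate([[0], np.cumsum(increments)]),
                               np.ones(len(increments) + 1, bool), fps)

    def test_zero_increments(self):
        t = self._trace([0.0] * 5, 10.0)
        assert overall_torsion(t, "signed_sum") == 0
        assert overall_torsion(t, "mean_sample_distance") == 0

    def test_alternating_beats_cancel_in_signed_sum(self):
        t = self._trace([1, -1, 1, -1], 10.0)
        assert overall_torsion(t, "signed_sum") == pytest.approx(0.0)
        assert overall_torsion(t, "mean_sample_distance") == pytest.approx(10.0)

    def test_constant_rotation_velocity(self):
        t = self._trace([0.5] * 10, 30.0)
        assert overall_torsion(t, "signed_sum") == pytest.approx(15.0)

    def test_too_few_valid_entries(self):
        t = ng.TorsionTrace([0.0], [True], 30.0)
        with pytest.raises(ValueError):
            overall_torsion(t)
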