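"""Synthetic data: class-conditional grid images and rendered eye videos.

Two generators live here.

**Grid sampler.**  Training data for the canal classifier is synthesized,
not recorded: each BPPV class is a template assigning a Gaussian (mean, SD)
of signed nystagmus amplitude to the (positional test, axis) cells that the
excited semicircular canal activates, and a grid image is drawn by sampling
every templated cell from its Gaussian (untemplated cells sit at the
neutral value, optionally jittered by a background Gaussian).  Datasets are
exactly class-balanced: every class contributes the same number of grids to
each split, so class incidence is 1/8 by construction.

**Video renderer.**  A deliberately simple eye-video model used to validate
the tracking stages against known ground truth: a dark anti-aliased pupil
ellipse over a striated iris annulus over a light sclera.  The pupil
position follows a jerk-nystagmus sawtooth (slow drift at the stated
slow-phase velocity with an instantaneous fast reset every beat), iris
striations rotate per the torsion schedule, and blink frames are rendered
near-uniform.  Ground-truth traces are returned at frame resolution.  The
renderer is not photorealistic and makes no attempt at eyelids, reflections
or camera distortion.

Every output is a pure function of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .grid import AXES, CLASS_LABELS, TEST_ORDER, GridImage, build_grid
from .pupil import EyeTrace, Frame
from .torsion import TorsionTrace

__all__ = [
    "ClassTemplate",
    "GridDataset",
    "SynthVideoSpec",
    "default_templates",
    "sample_grid",
    "generate_dataset",
    "render_eye_video",
]

_T = {name: i for i, name in enumerate(TEST_ORDER)}
_A = {name: i for i, name in enumerate(AXES)}


@dataclass
class ClassTemplate:
    """Gaussian amplitude template of one BPPV class.

    ``cells`` maps (test identifier, axis) to (mean, SD) of the signed
    amplitude on the grid scale (cap 1000); unlisted cells are neutral with
    SD ``background_sd``.
    """

    bppv_class: str
    cells: dict[tuple[str, str], tuple[float, float]]
    background_sd: float = 20.0

    def mean_grid(self) -> GridImage:
        """Deterministic grid encoding the template means (SD ignored)."""
        amp = np.zeros((3, 10))
        for (test, axis), (mu, _sd) in self.cells.items():
            amp[_A[axis], _T[test]] = mu
        return build_grid(amp)


@dataclass
class GridDataset:
    """Aligned grids and labels for one split.

    ``grids`` has shape (N, 3, 10) uint8; ``labels`` holds integer indices
    into :data:`nystagrid.grid.CLASS_LABELS`.
    """

    grids: np.ndarray
    labels: np.ndarray
    split: str
    seed: int

    def __post_init__(self) -> None:
        if len(self.grids) != len(self.labels):
            raise ValueError("grids and labels must be aligned")

    def __len__(self) -> int:
        return len(self.grids)

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=len(CLASS_LABELS))


def default_templates(
    affected: float = 400.0,
    contralateral: float = 200.0,
    sd: float = 80.0,
    background_sd: float = 20.0,
) -> list[ClassTemplate]:
    """The eight canonical BPPV class templates.

    Canal-to-pattern rules:

    * PSC (posterior): torsional + upbeat nystagmus in the Dix-Hallpike
      column of the affected side; torsion sign follows the side (+ right).
    * geotropic LSC: horizontal nystagmus beating toward the lower ear in
      both supine-roll columns (roll right -> rightward +, roll left ->
      leftward -), stronger on the affected side.
    * ageotropic LSC: horizontal nystagmus beating toward the upper ear in
      both roll columns (roll right -> -, roll left -> +), stronger when
      rolling toward the unaffected side.
    * ASC (anterior): torsional + downbeat nystagmus in the straight
      head-hanging column, echoed more weakly in the Dix-Hallpike column
      of the affected side; torsion sign follows the side.

    Amplitudes are on the grid scale (cap 1000); defaults put active cells
    well clear of neutral after 8-bit encoding while the SD keeps classes
    overlapping enough for a non-trivial learning task.
    """
    a, c = float(affected), float(contralateral)
    tpl = {
        "psc_right": {
            ("dix_hallpike_right", "vertical"): (a, sd),
            ("dix_hallpike_right", "torsional"): (a, sd),
        },
        "psc_left": {
            ("dix_hallpike_left", "vertical"): (a, sd),
            ("dix_hallpike_left", "torsional"): (-a, sd),
        },
        "lsc_geo_right": {
            ("roll_right", "horizontal"): (a, sd),
            ("roll_left", "horizontal"): (-c, sd),
        },
        "lsc_geo_left": {
            ("roll_right", "horizontal"): (c, sd),
            ("roll_left", "horizontal"): (-a, sd),
        },
        "lsc_ageo_right": {
            ("roll_right", "horizontal"): (-c, sd),
            ("roll_left", "horizontal"): (a, sd),
        },
        "lsc_ageo_left": {
            ("roll_right", "horizontal"): (-a, sd),
            ("roll_left", "horizontal"): (c, sd),
        },
        "asc_right": {
            ("head_hanging", "vertical"): (-a, sd),
            ("head_hanging", "torsional"): (a, sd),
            ("dix_hallpike_right", "vertical"): (-c, sd),
            ("dix_hallpike_right", "torsional"): (c, sd),
        },
        "asc_left": {
            ("head_hanging", "vertical"): (-a, sd),
            ("head_hanging", "torsional"): (-a, sd),
            ("dix_hallpike_left", "vertical"): (-c, sd),
            ("dix_hallpike_left", "torsional"): (-c, sd),
        },
    }
    return [
        ClassTemplate(name, cells, background_sd=background_sd)
        for name, cells in ((lbl, tpl[lbl]) for lbl in CLASS_LABELS)
    ]


def sample_grid(
    template: ClassTemplate,
    seed: int | np.random.Generator,
    amplitude_cap: float = 1000.0,
) -> GridImage:
    """Draw one grid image from a class template.

    Templated cells are sampled from their Gaussians, untemplated cells
    from N(0, background_sd); amplitudes are clamped to the cap and encoded
    with the standard affine map.  The same seed always yields the same
    grid.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mu = np.zeros((3, 10))
    sigma = np.full((3, 10), float(template.background_sd))
    for (test, axis), (m, s) in template.cells.items():
        mu[_A[axis], _T[test]] = m
        sigma[_A[axis], _T[test]] = s
    amp = np.clip(rng.normal(mu, sigma), -amplitude_cap, amplitude_cap)
    return build_grid(amp, amplitude_cap)


def generate_dataset(
    n_train_per_class: int,
    n_val_per_class: int,
    templates: list[ClassTemplate] | None = None,
    seed: int = 0,
) -> tuple[GridDataset, GridDataset]:
    """Generate class-balanced training and validation grid datasets.

    Produces exactly ``n_train_per_class * 8`` training grids and
    ``n_val_per_class * 8`` validation grids with per-class incidence
    exactly 1/8 in each split.  The two splits consume disjoint random
    streams spawned from the seed, so enlarging one split never perturbs
    the other.
    """
    if n_train_per_class < 1 or n_val_per_class < 1:
        raise ValueError("per-class counts must be >= 1")
    templates = templates if templates is not None else default_templates()
    if len(templates) != len(CLASS_LABELS):
        raise ValueError(f"expected {len(CLASS_LABELS)} templates")
    train_ss, val_ss = np.random.SeedSequence(seed).spawn(2)
    out = []
    for split, n_per, ss in (
        ("training", n_train_per_class, train_ss),
        ("validation", n_val_per_class, val_ss),
    ):
        rng = np.random.default_rng(ss)
        grids = np.empty((n_per * len(templates), 3, 10), dtype=np.uint8)
        labels = np.empty(n_per * len(templates), dtype=np.int64)
        k = 0
        for ci, tpl in enumerate(templates):
            for _ in range(n_per):
                grids[k] = sample_grid(tpl, rng).values
                labels[k] = ci
                k += 1
        order = rng.permutation(k)
        out.append(GridDataset(grids[order], labels[order], split, seed))
    return out[0], out[1]


# --------------------------------------------------------------------------
# Eye-video renderer
# --------------------------------------------------------------------------

@dataclass
class SynthVideoSpec:
    """Parameters of a rendered eye video with known ground truth.

    ``slow_phase_velocity`` is (horizontal px/s, vertical px/s, torsional
    deg/s) in *image* coordinates (positive y down, positive torsion CCW).
    ``beat_frequency`` > 0 renders jerk nystagmus: slow drift with an
    instantaneous reset each beat period; 0 renders pure drift (no resets).
    ``iris_harmonics`` controls striation granularity — the number of
    random angular harmonics composing the iris texture.
    """

    frame_shape: tuple[int, int] = (160, 200)  # (H, W)
    pupil_center: tuple[float, float] = (100.0, 80.0)  # (x, y)
    pupil_radii: tuple[float, float] = (22.0, 19.0)  # (semi-major x, semi-minor y)
    iris_radius: float = 55.0
    iris_harmonics: int = 12
    slow_phase_velocity: tuple[float, float, float] = (0.0, 0.0, 0.0)
    beat_frequency: float = 0.0
    blink_frames: tuple[int, ...] = ()
    noise_sd: float = 2.0
    frame_rate: float = 30.0
    duration: float = 2.0
    seed: int = 0

    def n_frames(self) -> int:
        return int(round(self.duration * self.frame_rate))


def _sawtooth_offset(t: np.ndarray, v: float, f: float) -> np.ndarray:
    """Displacement schedule: slow drift at v, reset every 1/f seconds."""
    if v == 0.0:
        return np.zeros_like(t)
    if f <= 0.0:
        return v * t
    period = 1.0 / f
    off = v * np.mod(t, period)
    return off - off.mean()  # keep the pupil near its nominal center


def _render_frame(
    spec: SynthVideoSpec,
    cx: float,
    cy: float,
    rot_deg: float,
    profile: np.ndarray,
    rng: np.random.Generator,
    blink: bool,
) -> np.ndarray:
    h, w = spec.frame_shape
    if blink:
        img = np.full((h, w), 228.0)
    else:
        yy, xx = np.mgrid[0:h, 0:w].astype(float)
        dx, dy = xx - cx, yy - cy
        r = np.hypot(dx, dy)
        # visual angle: CCW positive in the displayed image (y points down)
        theta = np.degrees(np.arctan2(-dy, dx))
        img = np.full((h, w), 228.0)  # sclera
        # iris: base shade + angular striations rotating with torsion
        n = profile.size
        idx = np.mod(theta - rot_deg, 360.0) / 360.0 * n
        i0 = idx.astype(int) % n
        fr = idx - np.floor(idx)
        stri = profile[i0] * (1 - fr) + profile[(i0 + 1) % n] * fr
        iris = 150.0 + 38.0 * stri
        a_iris = np.clip(spec.iris_radius + 0.5 - r, 0.0, 1.0)  # soft 1px edge
        img = img * (1 - a_iris) + iris * a_iris
        # pupil: dark anti-aliased ellipse
        ra, rb = spec.pupil_radii
        d = np.sqrt((dx / ra) ** 2 + (dy / rb) ** 2)
        a_pup = np.clip((1.0 - d) * min(ra, rb) + 0.5, 0.0, 1.0)
        img = img * (1 - a_pup) + 25.0 * a_pup
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, img.shape)
    return np.clip(img, 0, 255).astype(np.uint8)


def render_eye_video(
    spec: SynthVideoSpec,
) -> tuple[list[Frame], EyeTrace, TorsionTrace]:
    """Render a clip and its ground-truth traces.

    Returns ``(frames, eye_trace, torsion_trace)``; the traces hold the
    exact pupil-center schedule (absolute image coordinates) and cumulative
    torsion in degrees, with ``valid=False`` on blink frames.
    """
    h, w = spec.frame_shape
    cx0, cy0 = spec.pupil_center
    ra, rb = spec.pupil_radii
    if not (0 < cx0 < w and 0 < cy0 < h) or spec.iris_radius >= min(cx0, cy0, w - cx0, h - cy0):
        raise ValueError("eye geometry exceeds the frame")
    n = spec.n_frames()
    if n < 2:
        raise ValueError("spec must yield at least 2 frames")
    rng = np.random.default_rng(spec.seed)
    # periodic striation profile, normalized to roughly unit amplitude
    k = np.arange(1, spec.iris_harmonics + 1)
    amps = rng.uniform(0.5, 1.0, k.size) / np.sqrt(k)
    phases = rng.uniform(0, 2 * np.pi, k.size)
    ang = np.linspace(0, 2 * np.pi, 720, endpoint=False)
    prof = np.sum(amps[:, None] * np.cos(k[:, None] * ang[None, :] + phases[:, None]), axis=0)
    prof = prof / np.max(np.abs(prof))

    t = np.arange(n) / spec.frame_rate
    vx, vy, vt = spec.slow_phase_velocity
    ox = _sawtooth_offset(t, vx, spec.beat_frequency)
    oy = _sawtooth_offset(t, vy, spec.beat_frequency)
    orot = _sawtooth_offset(t, vt, spec.beat_frequency)
    blinks = set(spec.blink_frames)

    frames: list[Frame] = []
    for i in range(n):
        img = _render_frame(
            spec, cx0 + ox[i], cy0 + oy[i], orot[i], prof, rng, blink=(i in blinks)
        )
        frames.append(Frame(img, index=i, timestamp=float(t[i])))

    valid = np.array([i not in blinks for i in range(n)])
    trace = EyeTrace(
        frame_rate=spec.frame_rate,
        x=cx0 + ox,
        y=cy0 + oy,
        valid=valid,
        reference_x=float(cx0 + ox[valid.argmax()]),
        reference_y=float(cy0 + oy[valid.argmax()]),
    )
    ttrace = TorsionTrace(orot - orot[valid.argmax()], valid.copy(), spec.frame_rate)
    return frames, trace, ttrace
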