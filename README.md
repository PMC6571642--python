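# nystagrid

Video-oculography nystagmus quantification and semicircular-canal
classification for benign paroxysmal positional vertigo (BPPV).

BPPV is diagnosed from the pattern of nystagmus — involuntary eye
oscillation with a slow drift phase and a fast reset — provoked by
positional maneuvers such as the Dix–Hallpike and supine-roll tests. The
excited canal determines the pattern: posterior-canal BPPV produces
torsional + upbeat nystagmus in the Dix–Hallpike position, lateral-canal
BPPV produces horizontal nystagmus (geotropic: beating toward the lower
ear; ageotropic: toward the upper ear) in the roll test, anterior-canal
BPPV produces torsional + downbeat nystagmus in head-hanging positions.
Reading these patterns reliably requires specialist experience that
primary-care and emergency settings often lack; this package implements a
decision-support pipeline that does the reading automatically.

## Pipeline

1. **Pupil tracking** (`nystagrid.pupil`) — per frame: circle Hough gate
   (also the blink detector) → threshold binarization → edge extraction →
   ellipse fit. Produces horizontal/vertical position traces in pixels,
   referenced to the first valid frame, and transient (frame-to-frame)
   velocities v[i] = (p[i] − p[i−1])·f.
2. **Torsion** (`nystagrid.torsion`) — an iris annulus is unwrapped to
   polar coordinates, so ocular rotation becomes translation of the
   angular gray-level profile; the shift maximizing normalized
   cross-correlation between consecutive frames (median over overlapping
   patches, parabolic sub-bin refinement) is the torsion increment.
3. **Feature grid** (`nystagrid.grid`) — each of ten positional tests is
   summarized by per-axis mean slow-phase velocity; a battery whose
   velocities all stay below the normality thresholds short-circuits the
   pipeline ("normal"). Otherwise the battery is encoded as a 3×10 8-bit
   grid image: rows = horizontal/vertical/torsional, columns = tests,
   cell = 128 + round(127·a/1000) for signed amplitude a (neutral = 128).
4. **Classifier** (`nystagrid.classifier`) — a small CNN (3×3 conv →
   batch-norm → ReLU blocks, softmax over 8 classes) trained on synthetic
   grids sampled from class-conditional Gaussians
   (`nystagrid.synthetic`), plus a deterministic rule-based classifier
   implementing the canal rules directly as an independent oracle.
5. **Evaluation** (`nystagrid.evaluation`) — one-vs-rest confusion-matrix
   metrics (precision TP/(TP+FP), sensitivity TP/(TP+FN), specificity
   TN/(TN+FP), F1), micro/macro averages, no-information rate with an
   exact one-tailed binomial test, ROC/AUROC, and stratified k-fold
   cross-validation with t-based 95% confidence intervals.

## Worked example

Classify a lateral-canal case from two rendered supine-roll clips
(+40 px/s slow phase rolling right, −20 px/s rolling left — geotropic,
right ear affected):

```python
import nystagrid as ng

battery = ng.TestBattery()
for test, vx, seed in (("roll_right", 40.0, 0), ("roll_left", -20.0, 1)):
    spec = ng.SynthVideoSpec(slow_phase_velocity=(vx, 0.0, 0.0),
                             beat_frequency=1.0, duration=2.0, seed=seed)
    frames, _, _ = ng.render_eye_video(spec)
    trace, fits = ng.track_clip(frames)
    torsion = ng.torsion_trace(frames, fits, frame_rate=30.0)
    for s in ng.summarize_test(trace, torsion).values():
        battery.set(test, s)

print(ng.is_normal(battery))
grid = ng.build_grid(battery)
print(grid.values[0].tolist())
print(ng.rule_classify(grid))
```

Output:

```
False
[128, 128, 128, 179, 103, 128, 128, 128, 128, 128]
lsc_geo_right
```

The recovered slow-phase velocities are 40.09 and −19.92 px/s (ground
truth 40 and −20). The battery is not normal, so it is encoded: the
horizontal row shows 179 in the roll-right column (amplitude +400, i.e.
+40 px/s) and 103 in the roll-left column (−200), all other cells neutral
at 128. The opposing horizontal beats toward the lower ear with the
stronger response on the right give right geotropic lateral-canal BPPV.

The same pipeline is scriptable from the shell:

```sh
nystagrid synth --out data/ --n-train 1000 --n-val 250 --seed 0
nystagrid train --data data/ --out model/
nystagrid diagnose clips/ --model model/model.npz --out dx/
```

## Scope

Single-canal BPPV classification from eye videos or pre-extracted grid
images. Multi-canal disease, non-BPPV vestibular disorders, gaze
calibration to degrees, and goggle hardware control are out of scope.
See `docs/methods.md` for models, conventions, parameter rationale and
limitations.
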