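# lvseg

Automatic segmentation of the left ventricle (LV) from short-axis cine
cardiac MR images, for researchers who need a fully testable, dependency-light
reference implementation of a residual U-Net segmentation pipeline — from raw
cine frames to contour metrics and clinical indices — without any external
imaging data.

## What it implements

**Model.** An improved residual U-Net for extracting the LV endocardium and
epicardium from 2-D short-axis slices. Contracting and expanding paths are
built from residual units with three families of skip connections:

* *short* skips inside each residual unit — an additive identity path plus a
  concatenative path re-injecting the unit input into the second convolution;
* *medium* skips feeding the raw model input, through a strided 1×1
  convolution, into every contracting step by channel concatenation;
* *long* skips from each contracting level to the matching expanding level.

Convolutions are optionally depth-wise separable: for an `m×n×c₁ → m×n×c₂`
block, a 3×3 convolution produces S1 (`c₂/2` channels) and a per-channel 3×3
convolution of S1 produces S2 (`c₂/2`); the output is `[S1, S2]`. The block
carries `9·c₁·c₂/2 + 9·c₂/2` kernel weights instead of `9·c₁·c₂`, e.g. 2448
vs 4608 for 16→32 channels. A 1×1 convolution + per-pixel softmax head keeps
the output at input resolution. Both flags (`use_short_skip`,
`use_medium_skip`) and the convolution type are configurable, so the plain
residual U-Net and the intermediate ablation variants are all expressible.

The network and its training loop run on a small numpy reverse-mode autograd
engine included in `lvseg.nn` (im2col + BLAS convolutions, a numba kernel for
the depth-wise pass); no deep-learning framework is required.

**Pipeline.** ROI localization by per-pixel temporal variation + k-means
(fixed 128×128 crops, clamped into the frame); ten-fold training augmentation
(original + rotations of 45°…315° + horizontal/vertical flips); training with
a learning rate decayed linearly from 0.001 to 0.0001 at epoch 120 and held
constant after.

**Evaluation.** Per slice: dice metric `DM = 2|A_s∩A_g| / (|A_s|+|A_g|)` and
average perpendicular distance (APD) between predicted and reference
contours in mm (symmetric point-to-segment); a contour is *good* iff
APD < 5 mm. Per case: percentage of good contours (PGC) over all slices, and
mean DM/APD over the good slices only. Clinical indices: slab-summed volumes,
`LVM = (V_epi^ED − V_end^ED)·1.05` g, `EF = 100·(V_end^ED − V_end^ES)/V_end^ED` %,
plus Bland–Altman limits of agreement and OLS regression between automatic
and manual values.

**Phantom.** A synthetic cine generator (bright circular blood pool in a
darker myocardial ring, ED/ES phase change, base→apex taper, center jitter,
optional sinusoidal boundary wobble, additive noise) with exact ground-truth
masks and contours, so every stage is testable end to end without MR data.

## Worked example

```python
import numpy as np
from lvseg.phantom import PhantomConfig, generate_case
from lvseg.roi import locate_lv_center, crop_roi
from lvseg.metrics import evaluate_case
from lvseg.clinical import clinical_indices

cfg = PhantomConfig(seed=0)              # 256x256 frames, 1.367 mm/px, 8 mm slices
case = generate_case(cfg, seed=7)
print(f"case: {len(case.phase_slices('ED'))} ED + {len(case.phase_slices('ES'))} ES slices")

center = locate_lv_center([s.image for s in case.slices])
print(f"estimated LV center: ({center[0]:.1f}, {center[1]:.1f}) "
      f"true: ({case.slices[0].center[0]:.1f}, {case.slices[0].center[1]:.1f})")
roi = crop_roi(case.slices[0].image, center, size=128)
print(f"ROI offset in frame: {roi.offset}")

ed, es = case.phase_slices("ED"), case.phase_slices("ES")
preds = [np.roll(s.endo_mask, 2, axis=1) for s in ed]   # a 2-px-shifted "prediction"
cm = evaluate_case(preds, [s.endo_mask for s in ed], cfg.pixel_spacing_mm)
print(f"PGC {cm.pgc_percent:.2f}%  mean DM {cm.mean_dm_of_good:.3f}  "
      f"mean APD {cm.mean_apd_of_good:.2f} mm")

idx = clinical_indices([s.endo_mask for s in ed], [s.endo_mask for s in es],
                       [s.epi_mask for s in ed], cfg.pixel_spacing_mm,
                       cfg.slice_thickness_mm)
print(f"LVM {idx.lvm_g:.1f} g   EF {idx.ef_percent:.1f}%")
```

Output:

```
case: 12 ED + 12 ES slices
estimated LV center: (122.0, 123.5) true: (122.0, 123.5)
ROI offset in frame: (58, 59)
PGC 100.00%  mean DM 0.907  mean APD 1.65 mm
LVM 179.5 g   EF 57.7%
```

The cine stack localizes the LV exactly on this phantom; a prediction shifted
by 2 px (2.7 mm) still has every contour under the 5 mm "good" threshold
(PGC 100%), overlaps the truth at DM 0.91, and sits 1.65 mm from it on
average. The ground-truth masks give an LV mass of 179.5 g and an ejection
fraction of 57.7% for this simulated heart.

A full run — simulate, crop, augment, train both binary models, predict,
evaluate, compute clinical agreement — is one command:

```bash
lvseg run --config examples/tiny.yaml --seed 0 --out runs/demo
```

which writes `report.csv` (per-case PGC/DM/APD with MEAN/STD rows),
`clinical.csv` and `agreement.yaml` into the run directory, alongside the
exact `config.yaml` that produced them.

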