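# bpequant

Quantitative analysis of **background parenchymal enhancement (BPE)** in
breast DCE-MRI: segmentation of fibroglandular tissue (FGT) and computation
of the thresholded enhancement metric **BPE20%**, together with the cohort
statistics used to relate BPE to treatment response and recurrence-free
survival. The package is aimed at imaging researchers who have pre/early
post-contrast volume pairs (NIfTI) plus an operator chest-wall delimitation,
and want reproducible, per-patient quantitative FGT/BPE measures and
cohort-level analyses — and at anyone who wants to validate such a pipeline
against ground truth, via the built-in synthetic phantom generator.

## The measurement

For each study (one pre-contrast fat-suppressed T1 volume `I_pre`, one early
post-contrast volume `I_post` registered onto the pre-contrast grid):

```
R_voxel = (I_post − I_pre) / I_pre                    per-voxel enhancement ratio
FGT%    = V_FGT / V_Breast × 100                      glandular volume fraction
V_BPE   = Σ_{voxel ∈ FGT} V_voxel  s.t.  R_voxel ≥ 20%
BPE20%  = V_BPE / V_FGT × 100                         enhancing fraction of FGT
ΔBPE20% = (BPE20%_post − BPE20%_pre)/BPE20%_pre × 100 intrasubject change
```

The pipeline runs N4 bias-field correction, translation/rigid registration
of the post volume onto the pre-contrast grid, supervised chest-wall
delimitation (control points or an exclusion mask), two-class fuzzy C-means
FGT segmentation, then the metrics above. The statistics layer provides
diagnostic accuracy with 95% CIs, Cohen/Fleiss kappa, Pearson correlation,
Student t tests, and a multivariate Cox proportional-hazards wrapper for
recurrence-free survival. `docs/methods.md` documents every model choice,
default and limitation.

## Worked example

Generate a phantom with known truth (10% FGT, 30% of FGT voxels enhancing at
50%, a 30% bias field, 2 mm motion, 5% noise) and run the full pipeline:

```python
import numpy as np
from bpequant import (PhantomParams, ChestWallSpec, RunConfig,
                      generate_phantom, run_patient, diagnostic_accuracy)
from bpequant.phantom import chest_wall_plane_y

params = PhantomParams(seed=7, spacing=(1.0, 1.0, 1.0), fgt_fraction=0.10,
                       enhancing_fraction=0.30, bias_amplitude=0.3,
                       motion_translation=(2.0, 0.0, 0.0), noise_sigma=0.05)
pre, post, truth = generate_phantom(params)
print(f"truth: FGT% = {truth.fgt_pct_true:.1f}, BPE20% = {truth.bpe20_true:.1f}")

y_wall = chest_wall_plane_y(params)
rng = np.random.default_rng(0)
pts = np.column_stack([rng.uniform(0, 64, 12), np.full(12, y_wall), rng.uniform(0, 64, 12)])
record = run_patient(pre, post, ChestWallSpec(control_points=pts),
                     RunConfig(), patient_id="phantom7")
print(f"measured: FGT% = {record['fgt_pct']:.1f}, BPE20% = {record['bpe20_pct']:.1f}, "
      f"recovered motion = {np.round(record['reg_translation_mm'], 2)} mm")

acc = diagnostic_accuracy(tp=25, fn=2, fp=12, tn=63)
print(f"sensitivity {acc.sensitivity:.0f}% (95% CI {acc.ci_sensitivity[0]:.0f}-{acc.ci_sensitivity[1]:.0f}), "
      f"specificity {acc.specificity:.0f}% (95% CI {acc.ci_specificity[0]:.0f}-{acc.ci_specificity[1]:.0f})")
```

Output:

```
truth: FGT% = 10.0, BPE20% = 30.0
measured: FGT% = 10.0, BPE20% = 31.9, recovered motion = [2.   0.02 0.08] mm
sensitivity 93% (95% CI 83-100), specificity 84% (95% CI 76-92)
```

The pipeline recovers the glandular fraction exactly and BPE20% within two
points of truth at the most adverse noise/bias settings (the residual +1.9
is per-voxel noise pushing non-enhancing ratios across the 20% cut); motion
is recovered to under a tenth of a voxel. The diagnostic-accuracy call
summarises a 2×2 response table: of 27 patients with pathological complete
response, 25 were radiologically complete (sensitivity 93%), and of 75
without, 12 were falsely radiologically complete (specificity 84%).

The same steps are available from a shell: `bpequant phantom`,
`bpequant quantify`, `bpequant cohort` (manifest of patients/timepoints →
table + ΔBPE20% + statistics battery) and `bpequant stats`.

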