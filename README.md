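# ventdose

Predicting symptomatic radiation pneumonitis (RP, grade >= 2) after
thoracic radiotherapy from 4D-CT-based lung-function images.

Thoracic radiotherapy plans are conventionally constrained by dose-volume
histogram (DVH) limits that treat all lung tissue as equally functional.
4D-CT ventilation imaging estimates *regional* lung function from routinely
acquired respiration-resolved CT: a deformable registration between
peak-inhale and peak-exhale phases yields a displacement field `u`, from
which ventilation is computed either from CT density change

    V_HU = (HU_ex − HU_in∘(x+u)) / (HU_in∘(x+u) + 1000)

or directly from the registration geometry

    V_Jac = det(I + ∇u) − 1.

Weighting dose statistics by percentile-normalized ventilation gives
dose-function histogram (DFH) features (fMLD, fV5–fV50) alongside the
classical DVH features (MLD, V5–V50, computed on EQD2-converted dose with
α/β = 3 Gy). `ventdose` implements this whole chain and the associated
prediction protocol — repeated stratified 70/30 splits, training-only
Z-scoring, RBF-SVM with (C, γ) tuned by Bayesian optimization of 5-fold
inner-CV AUC, paired comparison of four nested feature sets (clinical;
+DVH; +DFH; +DVH+DFH) with Wilcoxon/Mann–Whitney/Spearman statistics —
plus a synthetic phantom cohort generator with closed-form ground truth,
so every stage is testable without patient data.

Intended users: medical-physics and outcomes-modelling researchers who
want a reproducible, fully tested reference implementation of DFH-based
toxicity modelling, or a controlled test bed for protocol experiments.

## Worked example

```python
import numpy as np
from ventdose import (CohortSpec, SplitScheme, make_cohort, run_experiment,
                      compare_feature_sets)
from ventdose.modeling import FEATURE_SETS

# 85 synthetic patients; RP labels follow a logistic model on fV20
_, table = make_cohort(CohortSpec(n_patients=85,
                                  label_model={"fV20": 2.0}, seed=21))
print(f"incidence: {table['rp'].mean():.3f}")

sets = {k: FEATURE_SETS[k] for k in ("clinical", "clinical+dvh+dfh")}
res = run_experiment(table, sets, SplitScheme(n_repeats=50, seed=22))
for name in sets:
    print(name, f"median test AUC: {np.median(res.test_aucs(name)):.3f}")
print("paired Wilcoxon p:",
      compare_feature_sets(res.runs['clinical+dvh+dfh'], res.runs['clinical']))
```

prints

```
incidence: 0.294
clinical median test AUC: 0.659
clinical+dvh+dfh median test AUC: 0.825
paired Wilcoxon p: 2.0127845918365675e-08
```

The labels were generated from fV20, so the feature set containing the
dose-function features recovers the signal (AUC 0.83) while clinical
features alone sit near chance plus geometric leakage (0.66); the paired
test over the 50 shared splits confirms the gap.

The same protocol is available from the shell:

```
ventdose run-all --out results/ --seed 21
ventdose simulate --out cohort/ --seed 3
ventdose ventilate --inhale in.nii --exhale ex.nii --field dvf.nii \
    --lung-mask lung.nii --metric hu --out function.nii
```

`run-all` writes feature tables, per-repeat run CSVs, summary tables,
correlation matrices and a hash manifest for both ventilation metrics.

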