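# liverprog

Multimodal CT + clinical survival prediction for unresectable
hepatocellular carcinoma (HCC) under immune-checkpoint-inhibitor therapy
— rebuilt as a desk-scale, fully testable Python workbench.

Identifying which advanced-HCC patients will benefit from immunotherapy
combinations is a live clinical problem.  One published answer is a
multimodal fusion (MMF) system: three 3D deep survival networks read
triphasic contrast CT (arterial / portal-venous / delayed), their risk
scores are fused by a random survival forest (RSF) into an *Ensemble-DL
signature*, and a second RSF fuses that signature with baseline clinical
covariates into the final MMF risk score for overall survival (OS) and
progression-free survival (PFS).  The original patient cohorts are not
redistributable, so this package pairs a faithful implementation of every
stage with a synthetic cohort generator whose hazard structure is known
exactly — letting each component be validated against ground truth.

The package is aimed at researchers building or auditing imaging-based
survival models: every stage is importable on its own, and the whole
chain runs end-to-end on a laptop CPU in minutes.

## What's inside

| module | contents |
|---|---|
| `liverprog.synthetic` | liver/tumor phantoms, correlated clinical covariates, right-censored Weibull outcomes with hazard `h0(t)·exp(Σβ·x)` |
| `liverprog.preprocess` | isotropic resampling, HU window [−200, 250], slice-wise CLAHE, liver-box crop, fixed-cube 4D input with provenance |
| `liverprog.radiomics` | 642 IBSI-style features per patient (14 shape + 18 first-order + 75 texture × 2 regions × 3 phases) and the three-step selection: univariate Cox C-index > 0.55 → iterative VIF ≤ 10 → RSF permutation importance > 0.05 |
| `liverprog.nets` | three 3D survival networks (tumor-gated CNN, autoencoder-pretrained encoder, per-axis conv-attention) trained with the Breslow Cox partial likelihood on a small built-in autodiff engine |
| `liverprog.fusion` | Ensemble-DL signature, MMF score (with cross-fitted stacking), clinical benchmark, mRECIST comparator |
| `liverprog.evaluate` | Harrell C-index with bootstrap CIs, paired-bootstrap model comparison, IPCW time-dependent AUC, KM/log-rank/HR, optimal cutoffs, subgroup reports |
| `liverprog.interpret` | 3D Grad-CAM, permutation-sampling Shapley values, signature↔feature Spearman correlations |
| `liverprog.pipeline` / CLI | config-driven end-to-end runs, NIfTI/CSV cohort I/O, `liverprog` console script |

## Worked example

```python
import numpy as np
from liverprog import (simulate_cohort, preprocess_scan, extract_features,
                       harrell_cindex)
from liverprog.synthetic import default_config
from liverprog.datatypes import labels_to_arrays

cfg = default_config(n_patients=60, seed=7)
scans, clinical, os_labels, pfs_labels, truth = simulate_cohort(cfg)

mi = preprocess_scan(scans[0], edge=32)
print("input tensor:", mi.array.shape, "range", (mi.array.min(), mi.array.max()))

row = extract_features(scans[0])
print("radiomic features:", len(row))
print("tumor arterial GLCM contrast:", round(row["T_A_glcmContrast"], 3))

t, e = labels_to_arrays(os_labels)
res = harrell_cindex(truth.lp, t, e, n_bootstrap=200, seed=0)
print(f"oracle-LP OS C-index: {res.point:.3f} "
      f"(95% CI {res.ci_lower:.3f}-{res.ci_upper:.3f})")
```

prints

```
input tensor: (3, 32, 32, 32) range (0.0, 1.0)
radiomic features: 642
tumor arterial GLCM contrast: 0.335
oracle-LP OS C-index: 0.823 (95% CI 0.763-0.874)
```

The 60-patient cohort is generated with the default study conditions
(Weibull baseline, ~35 % censoring).  The preprocessed tensor is the
(A, V, D)-stacked network input in [0, 1]; the 642 features follow the
`{region}_{phase}_{class}{Name}` convention; and the C-index of the true
latent linear predictor (~0.82 on this draw) is the ceiling any fitted
model can approach on this cohort.

A full end-to-end run — simulate, preprocess, radiomics + selection,
train the three networks, fuse, evaluate, explain — is one call:

```python
from liverprog import RunConfig, run_pipeline
art = run_pipeline(RunConfig(output_dir="runs/demo", n_patients=60,
                             edge=32, epochs=5, seed=0))
```

or, from a shell, `liverprog run-all --output runs/demo --seed 0`.  The
output directory contains the risk profile CSV (one column per model per
endpoint), evaluation reports (JSON + Markdown), selection traces,
training curves, a Grad-CAM NIfTI volume and Shapley attributions, all
reproducible bit-for-bit from the resolved config it also writes.

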