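# pdxrad

Automated tumor segmentation and radiomic-feature robustness analysis for
multi-contrast preclinical MRI.

Preclinical imaging of patient-derived xenograft (PDX) tumor models relies
on manual tumor delineation, which is slow and poorly reproducible across
observers. `pdxrad` implements a complete, testable pipeline around that
problem for co-registered T1w/T2w small-animal MR volumes:

* **Segmentation networks** — five 2-D encoder–decoder architectures
  sharing one I/O contract: U-Net, dense U-Net, residual U-Net, recurrent
  residual U-Net (R2U-Net), and the dense recurrent residual U-Net
  (D-R2UNet) that combines dense concatenations, residual shortcuts and
  recurrent convolutional layers with two time steps. Trained with soft
  Dice loss ``1 − (2|P·T|+ε)/(|P|+|T|+ε)``, Adam, Xavier initialization,
  geometric augmentation, and a binarization threshold chosen at the
  crossing of the training precision/recall curves. Runs on plain
  numpy/CPU via a small built-in autodiff core.
* **STAPLE consensus** — expectation-maximization that fuses several
  expert masks D_ij into a posterior weight map W_i while estimating each
  rater's sensitivity p_j and specificity q_j
  (E-step: W_i ∝ π Π_j p_j^{D_ij}(1−p_j)^{1−D_ij};
  M-step: p_j = ΣW_iD_ij/ΣW_i, q_j = Σ(1−W_i)(1−D_ij)/Σ(1−W_i)).
* **Segmentation metrics** — F1/Dice = 2TP/(2TP+FP+FN), precision, recall,
  accuracy and voxelwise ROC AUC, with undefined values reported as
  missing, plus cohort summaries with bootstrap CIs.
* **Radiomics** — an IBSI-style 3-D bank of exactly 144 features per
  contrast (12 morphological, 18 statistical, 23 histogram, 24 GLCM,
  16 GLRLM, 16 GLSZM, 16 GLDZM, 14 NGLDM, 5 NGTDM) with 26-voxel
  connectivity, 64-level fixed-bin quantization for histogram features and
  64-level Lloyd–Max quantization for texture features; four redundant
  candidates (Compactness 1/2, Spherical Disproportion, GLCM Sum Average)
  are computed and excluded.
* **Robustness statistics** — Spearman correlation (exact permutation
  p-values at small n) between consensus- and network-derived feature
  tables, Lin's concordance correlation coefficient
  CCC = 2s_xy/(s_x²+s_y²+(x̄−ȳ)²) for test–retest reproducibility,
  Bland–Altman volume agreement, boundary-sensitivity banding
  (robust iff −0.4 ≤ ρ(ΔFeature, ΔV) ≤ 0.4), and complete-linkage
  clustering of feature-change profiles on correlation distance.
* **Synthetic phantoms** — a first-class generator of two-contrast
  volumes with lumpy ellipsoidal tumors and simulated raters with known
  sensitivity/specificity/jitter, so every stage is testable without any
  real data.

See `docs/methods.md` for the models, assumptions and numerical choices.

## Worked example

Run the desk-scale end-to-end study — generate a 6-subject phantom cohort
(64×64, 8 slices), fuse three simulated raters with STAPLE, train a
D-R2UNet for 10 epochs against the consensus, and score the held-out
subjects:

```python
from pdxrad.study import run_study

res = run_study(seed=1)
print(f"test F1 vs STAPLE consensus: {res['test_f1']:.3f}")
print(f"volume CCC (pred vs truth):  {res['volume_ccc']:.3f}")
print(f"BA bias (STAPLE vs net):     {res['ba_bias_percent']:+.1f}%")
print(f"STAPLE sensitivity MAE:      {res['staple_sensitivity_mae']:.4f}")
```

prints (about 40 s on one CPU):

```
test F1 vs STAPLE consensus: 0.983
volume CCC (pred vs truth):  0.985
BA bias (STAPLE vs net):     -3.7%
STAPLE sensitivity MAE:      0.0117
```

The network overlaps the consensus almost perfectly on held-out phantoms
(F1 0.983), predicted volumes agree with analytic truth (CCC 0.985 across
all six subjects), the network over-segments STAPLE volumes slightly
(negative Bland–Altman bias), and STAPLE recovers the simulated rater
sensitivities to about 0.01.

The same pipeline is scriptable from the shell with per-stage outputs
(DICOM/NIfTI/CSV/JSON):

```bash
pdxrad all --config myconfig.json          # simulate → … → robustness
pdxrad features --config myconfig.json    # any single stage
```

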