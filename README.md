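# dcesub

Low-blood-volume tumor subvolume extraction from DCE-MRI temporal features,
with a Tofts-model digital phantom and a pharmacokinetic reference path.

## The problem

Dynamic contrast-enhanced MRI (DCE-MRI) records a signal–time curve in every
voxel while a gadolinium bolus passes through the tissue. In head-and-neck
cancers, tumor subvolumes with **low blood volume (LBV)** — poorly perfused
regions — are candidates for radiotherapy dose intensification, but mapping
them conventionally requires voxelwise pharmacokinetic (PK) model fitting, a
slow two-step process. `dcesub` implements the fast alternative: classify each
tumor voxel as low vs. high blood volume directly from **temporal features**
of its normalized enhancement curve, then assemble the contiguous LBV
subvolume (s-LBV). The PK path is retained as the reference that labels
training voxels and grounds the evaluation.

## Method

1. **Normalization** (per voxel): ΔS(t) = (S(t) − S₀)/S₀, then
   ΔS_N(t) = ΔS(t)/AIF_max, where S₀ is the mean pre-onset signal and AIF_max
   the peak arterial enhancement. A 32-point dyadic window starting at the
   arterial onset time is analyzed.
2. **Features**: either the full Haar wavelet decomposition
   W = [A₅, D₅, …, D₁] (averaging convention, so A₅ = window mean ∝ AUC/2⁵),
   or projections onto the leading principal components of the training
   curves.
3. **Selection**: correlation-based feature subset selection (CFS merit
   M = k·r̄_cf / √(k + k(k−1)·r̄_ff)) with best-first or greedy forward
   search for Haar coefficients; top-k eigenvalue order for PCA.
4. **Classification**: soft-margin RBF-kernel SVM (C = 200, γ = 0.2) with
   cross-validated Platt-type sigmoid calibration; a voxel is c-LBV when
   P(c-LBV) > 0.5 strictly.
5. **Subvolume assembly**: classified voxels are grouped into 26-connected
   components; components smaller than 1 cc are discarded. Agreement with a
   reference is scored by voxel accuracy and the Dice coefficient
   DSC = 2|G∩R|/(|G|+|R|).

Ground truth comes from the two-compartment Tofts model,
C_t(t) = v_p·C_p(t) + K^trans ∫₀ᵗ C_p(τ)e^{−k_ep(t−τ)}dτ, fitted voxelwise by
bounded multi-start least squares; blood volume is 100·v_p (%) and voxels
with BV < 7.6% are labeled LBV. The built-in phantom renders a 4-D series
from known voxelwise (v_p, K^trans, k_ep) maps — classes are separated by
construction of the v_p ranges — under a native ~3 s/60-frame dialect or an
alternate ~7.7 s/32-frame dialect, so every pipeline claim can be checked in
closed loop.

## Worked example

```python
import numpy as np
from dcesub import AcquisitionConfig, SubvolumeModel, generate_phantom, extract_aif

acq = AcquisitionConfig(noise_sd_rel=0.05, seed=17)
series, tumor, artery, truth = generate_phantom(acq, seed=17)
aif = extract_aif(series, artery)
model = SubvolumeModel.from_series(series, tumor, aif, truth.label_map,
                                   feature_kind="wt")
results = model.fit(test_fraction=0.3, seed=0)
print(results.summary())
print(results.evaluate(truth.label_map, min_volume_cc=1.0))
```

prints

```
Low-blood-volume subvolume classifier
====================================================
features              Haar coefficients
selected              coefficients (1, 2, 3, 9) (CFS merit 0.851)
SVM                   RBF, C=200, gamma=0.2
training curves       2132
validation curves     913
split seed            0
----------------------------------------------------
held-out accuracy     99.8%
====================================================
accuracy_pct: 99.74
dice_slbv: 0.9967
dice_lbv_plus_hbv: 0.9987
slbv_fraction_pct: 29.56
n_voxels: 3045
slbv_volume_cc: 3.285
```

The CFS search picked the approximation coefficient A₅ (#1) and
low-frequency detail coefficients — the global-shape end of the spectrum —
and the SVM separates the constructed LBV blobs (≈30% of the 3045-voxel
tumor) from the high-BV bulk almost perfectly at 5% signal noise; the
assembled s-LBV overlaps the truth subvolume at DSC 0.997 after the 1-cc
filter on both masks.

A CLI exposes the same pipeline over NIfTI files:

```bash
dcesub simulate --out phantom/ --seed 17
dcesub train --mode pca --out run/
dcesub predict --bundle run/bundle_pca
dcesub sensitivity --bundle run/bundle_pca
```

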