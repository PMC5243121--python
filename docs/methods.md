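# Methods

## Signal model and normalization

Tissue curves are treated as linear in contrast-agent concentration:
S(t) = S₀·(1 + ΔS(t)). The package operates entirely on normalized
enhancement ΔS_N(t) = ((S(t) − S₀)/S₀)/AIF_max, which removes scanner gain
and injection-strength differences; the SPGR signal equation and T1
calibration are deliberately out of scope. S₀ is the mean signal over the
frames before the arterial onset (minimum 3 frames — fewer would make the
baseline noise-dominated). Voxels with a nonpositive baseline are excluded
and logged, never imputed.

The analysis window is 32 consecutive samples starting at the arterial onset
sample *inclusive*: dyadic length for the wavelet transform, long enough at
~3 s sampling to cover the first pass, the peak and the early washout while
discarding the pre-contrast run-in and the flat late tail.

## Arterial input function

The AIF is the mean relative enhancement of the top 10% most-enhancing
artery-mask voxels (both fractions configurable). The automatic onset
operator places the onset one frame before the first crossing of 10% of the
peak: for a curve rising smoothly from zero the crossing sample already
carries substantial enhancement, so backing off one frame lands on the
bolus-arrival sample. Because onset and peak are routinely reviewed manually
in practice, both can be overridden explicitly, and the override is a
first-class code path.

The phantom's analytic AIF is a gamma-variate rise
(t′/αβ)^α·e^{α−t′/β} plus a delayed mono-exponential washout term
w·(1−e^{−t′/r})·e^{−t′/τ} (defaults α = 3, β = 4 s, w = 0.3, r = 12 s,
τ = 120 s, onset 30 s, peak enhancement 2.5). The washout term has no
closed-form maximum, so the sampled curve is rescaled by its own maximum —
max(curve) equals the requested peak exactly. With w = 0 the curve is a pure
gamma-variate whose continuous mode is exactly αβ, which is what the
transform tests exploit.

## Tofts model and the PK reference path

The two-compartment Tofts forward model is
C_t(t) = v_p·C_p(t) + K^trans·∫₀ᵗ C_p(τ)·e^{−k_ep(t−τ)}dτ with rates in
1/min; the convolution is evaluated by the trapezoid rule on the acquisition
grid (a cached lower-triangular lag/weight matrix turns each model
evaluation into one masked matrix–vector product). Fitting is bounded
trust-region least squares (v_p ∈ [0,1], K^trans ∈ [0,5]/min,
k_ep ∈ [0,10]/min, tolerances 1e-8) from three starts
(0.02, 0.1, 0.3), (0.1, 0.3, 0.8), (0.3, 1.0, 2.0); the lowest residual
wins, and a start is skipped early once a fit reaches numerical zero
residual. A voxel where every start fails is flagged and skipped rather than
raising — map-level fitting must survive bad voxels.

Blood volume is reported as BV% = 100·v_p. A hematocrit-style correction
would be a constant factor and is exposed as `bv_scale`; the labeling
threshold of 7.6% splits c-LBV (label 0) from c-HBV (label 1), with the
boundary value assigned to c-HBV ("< threshold" is LBV).

## Haar convention

One analysis step maps a pair (a, b) to the average (a+b)/2 and the
half-difference (a−b)/2. This unnormalized convention makes the final
approximation coefficient exactly the window mean (A_J ∝ AUC/2^J), which is
the property the feature analysis leans on; the orthonormal √2 variant
differs per coefficient by known diagonal factors and is available via
`ortho=True` (it is cross-checked against PyWavelets in the tests). Detail
sign is d = (first − second)/2 — fixed so that global coefficient indices
are reproducible: #1 = A₅, #2 = D₅, #3–4 = D₄, #5–8 = D₃, #9–16 = D₂,
#17–32 = D₁, details time-ascending within each level.

## Feature selection

CFS merit M = k·r̄_cf/√(k + k(k−1)·r̄_ff) with Pearson (point-biserial)
correlations taken as absolute values; a zero-variance feature contributes
zero correlation. Pearson on raw coefficients is deterministic and
binning-free — a deliberate divergence from Weka-style discretized symmetric
uncertainty. Best-first search keeps an open list of scored subsets, expands
the best unexpanded subset by single-feature additions, and stops after 5
consecutive expansions without a new global best; greedy forward search
stops at the first non-improving step. Ties break toward the lowest feature
index. Note the redundancy penalty is a tendency, not a theorem: duplicating
a feature whose class correlation is above the subset mean can raise the
merit; the guarantee tested is for equally class-correlated features.

For PCA features, selection is simply the k = 4 leading components, fitted
on training curves only, with a deterministic sign convention
(largest-magnitude loading positive).

## Classifier

RBF-kernel soft-margin SVM at C = 200, γ = 0.2, on z-scored features
(training statistics). Posterior probabilities come from a cross-validated
Platt-type sigmoid over decision values (`CalibratedClassifierCV`,
`ensemble=False`: one final model, calibrated on out-of-fold decisions). The
c-LBV assignment rule is strictly P > 0.5, so a voxel exactly at 0.5 is
high-BV. Class weighting is off by default but exposed. Training sets are
stratified-subsampled to 20,000 curves per class so RBF training stays
desk-scale even for large curve collections; the phantom never reaches the
cap. The train/validation split is 70/30 at curve level, stratified by
class, with a fixed seed.

## Subvolume assembly

Probabilities are scattered back onto the 3-D grid (NaN marks in-mask voxels
excluded during preprocessing and counts as below threshold). Components are
26-connected — the full 3-D neighborhood, chosen so that diagonal contact
does not fragment a subvolume — and components below 1 cc are discarded.
When scoring against a reference, the 1-cc filter is applied symmetrically
to both masks: filtering only the prediction would bias the Dice coefficient
structurally. This is configurable. Two empty masks give Dice = NaN with a
warning rather than an arbitrary value, since "no subvolume survived the
filter" is a legitimate clinical outcome.

The "LBV + HBV" Dice — the overlap of correctly classified voxels with the
full tumor — is computed between the correctness mask and the tumor mask;
with a fully covered tumor it equals 2·acc/(1 + acc).

## The phantom: what it emulates and what it does not

The default phantom is a 40×40×16 grid (native voxels 1.56×1.56×1.5 mm³)
holding an ellipsoidal tumor of ≈3000 voxels with two spherical low-BV blobs
(radii 5 and 4.5 voxels, ≈30% of the tumor, each comfortably above 1 cc), an
8-voxel-tall artery box carrying the AIF, 60 frames at 3 s (alternate
dialect: 32 frames at 7.7 s, 2 mm isotropic). Kinetics per tumor voxel:
v_p ~ U(0.01, 0.05) in the blobs and U(0.10, 0.25) outside — disjoint across
the 7.6% BV threshold, so labels are exact by construction —
K^trans ~ U(0.05, 0.5)/min and k_ep = K^trans/v_e with v_e ~ U(0.2, 0.5),
drawn independently of class for shape diversity. Noise is additive
Gaussian on the signal with SD = noise_sd_rel·S₀ (defaults 0.02; 0.05 as the
stress level), emulating the high-SNR regime of modern 3 T acquisitions.
Parameter draws depend only on the seed and geometry, never on the
acquisition dialect, so the same phantom can be re-rendered at a different
frame rate with identical truth maps.

Not emulated: motion, B1 inhomogeneity, partial-volume mixtures, bolus
arrival-time dispersion across voxels and patients, nonlinear
signal–concentration response, and the kinetic-parameter correlations of
real tumors. Consequently the phantom classes are far better separated than
clinical curve populations — held-out accuracies here sit near 100% where
clinical data would land near 80% — so passing tests demonstrate pipeline
correctness and closed-loop consistency, not clinical performance.

A specific known limitation: because every training curve shares a single
AIF and exact onset alignment, PCA projections are much more sensitive to
a deliberately mis-specified onset than they would be on heterogeneous
multi-patient data (high-order components have tiny variance, so z-scoring
amplifies a systematic shift). The Haar/CFS feature set selects
low-frequency, global-shape coefficients and tolerates ±1-frame onset errors
with a few points of accuracy loss; the AIF-sensitivity experiment therefore
runs on the wavelet classifier, and the onset-shift effect is quoted at
nominal peak scale.

## Problem sizes and numerical choices

The pharmacokinetic round trip runs on a reduced phantom (24×24×12,
≈800 tumor voxels) — parameter recovery is per-voxel, so more voxels add
runtime, not information. Classification experiments use the full default
phantom (~3000 voxels). Resampling is linear interpolation on the original
time span (output length floor(span/dt_out)+1); the alternate dialect is
resampled from 7.7 s to 4.1 s (59 samples) before windowing so the 32-point
window spans a physiologic interval comparable to the native 3 s training
data. All randomness flows through explicit seeds; identical configuration
and seed reproduce every array bit-for-bit.
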