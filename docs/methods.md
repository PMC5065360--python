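# Methods

## Signal model and tensor estimation

The forward model is the mono-exponential Stejskal–Tanner decay
`S = S0 exp(−b gᵀDg)` with a symmetric, positive semi-definite 3×3
tensor `D` in mm²/s per voxel. The acquisition is a clinical-style
1.5 T protocol: one b = 0 measurement plus 12 directions at
b = 1000 s/mm², grid 48×48×24 voxels at 1.8×1.8×4 mm. The 12
directions are a fixed electrostatic-repulsion set (minimum antipodal
Coulomb energy, optimized once and frozen as the text fixture
`src/gliodti/data/dir12.txt`); a fixed set was preferred over a
scanner-specific one because the exact directions are irrelevant to
the downstream statistics but bit-reproducibility is not.

Estimation solves `ln S_i = ln S0 − b_i gᵢᵀDgᵢ` by ordinary least
squares for the 6 unique tensor components and ln S0 (`fit_tensor`).
OLS was chosen over iterative nonlinear fits for determinism and
speed; a one-pass weighted refinement (weights = squared predicted
signals) is available behind `weighted=True` for low-SNR work.
Voxels containing any non-positive signal cannot be log-transformed
and are flagged invalid (NaN downstream) instead of fitted; a
rank-deficient gradient design (collinear directions) rejects the
whole volume with the deficient rank named. Multiple b = 0 entries
enter the regression as separate rows rather than being pre-averaged.

Eigenvalues are sorted descending; values below the clamp floor of
1e-12 mm²/s are raised to it and the affected voxels counted
(`n_clamped` in reports). The floor keeps maps physical under noise
without hiding the problem. The scalar maps are AD = λ₁,
RD = (λ₂+λ₃)/2, MD = (λ₁+λ₂+λ₃)/3, so `ad ≥ md ≥ rd` and
`md = (ad + 2·rd)/3` hold identically at valid voxels.

Internal computation is in mm²/s; every report and CSV uses
10⁻³ mm²/s, the convention of the clinical tables.

## Noise model

Noisy acquisitions replace each measurement by
`sqrt((S+ε₁)² + ε₂²)` with independent zero-mean Gaussians of
standard deviation σ = max(S0)/SNR — Rician magnitude noise, the
standard single-coil MRI model. The default SNR of 20 is typical for
1.5 T diffusion imaging. Referencing σ to the *maximum* S0 makes the
brightest region (the CSF cavity, S0 = 2) the SNR anchor, so tissue
regions see proportionally lower effective SNR.

## Phantom

The default phantom mirrors the post-resection geometry the biomarker
analysis assumes: a white-matter background with literature-typical
eigenvalues (1.7, 0.4, 0.3)×10⁻³ mm²/s; a CSF-filled resection cavity
(isotropic 3.0×10⁻³); a T2w-hyperintense zone adjacent to the cavity;
and a focal lesion nested inside that zone. Zone and lesion
diffusivities are tied to the cohort group means: the stable group for
the zone, the transformed group for the lesion.

Two styles exist because the published group means of AD, MD and RD
are minima over patients and are not algebraically consistent with a
single tensor (MD ≠ (AD+2·RD)/3 for the printed values):

- `isotropic` — zone and lesion isotropic at the group-mean axial
  diffusivity (1.28 and 0.72×10⁻³). All three maps coincide per
  region; used for exactness checks.
- `prolate` (pipeline default) — axially symmetric tensors with
  λ₁ = group-mean AD and λ₂ = λ₃ = group-mean RD, making MD the
  implied (AD+2·RD)/3 (1.073 and 0.613×10⁻³). The three maps then
  carry distinct contrasts, as in real tissue.

Geometry invariants are enforced at build time: full grid coverage,
lesion strictly inside the T2w zone, unit principal directions, sorted
non-negative eigenvalues, positive S0. Optional "artifact voxels"
emulate blood-product/susceptibility voxels and feed the exclusion
mask honored by the ROI readout before minimum extraction.

## ROI readout and reader emulation

ROI statistics (mean, sample SD with n−1, minimum, argmin) are taken
over in-mask voxels after dropping NaNs and exclusion-mask voxels.
Ties at the minimum resolve to the smallest x-fastest linear index so
runs are platform-independent. The second reader is emulated by
randomly toggling the one-voxel boundary shell of the first reader's
mask (each outer-shell voxel added, each inner-shell voxel removed,
with probability 0.3 under a seed): agreement statistics need
non-identical but strongly overlapping masks, which is what
independent human readers produce.

The CNR statistic averages the two readers' ROI means and sums the two
reader-averaged SDs (tumor + surround) in the denominator, exactly as
defined in the Model section of the README.

## Cohort generator

Per-subject biomarkers (AD_min/MD_min/RD_min, 10⁻³ mm²/s) are drawn
from group-wise normals — stable: 1.28±0.31 / 1.00±0.26 / 0.97±0.26;
transformed: 0.72±0.23 / 0.64±0.21 / 0.56±0.20 — with group sizes
29/18 by default. Negative draws are redrawn (truncation at zero;
physically required, numerically negligible at these means). The three
parameters are drawn independently per subject; real minima are
strongly correlated across maps, so cross-parameter joint statistics
of the generator should not be over-interpreted. Inter-reader ratings
for kappa are per-subject binary "restriction present" judgments,
emulated by thresholding each reader's noise-perturbed biomarker
(Gaussian reader noise, SD 0.08×10⁻³) at the ROC cutoff.

## Statistics layer

- **ROC**: positivity rule "value ≤ threshold"; curve evaluated at
  midpoints between consecutive sorted unique values plus ±∞; AUC by
  trapezoid (equal to Mann–Whitney concordance with ½ credit for
  ties, property-tested); operating cutoff maximizes Youden's J with
  ties broken toward the smaller cutoff; SE by Hanley–McNeil.
- **PPV** = 100·TP/(TP+FP) at the chosen cutoff; undefined (error)
  when no test is positive.
- **Weighted kappa**: κ = 1 − Σwᵢⱼoᵢⱼ / Σwᵢⱼeᵢⱼ with linear weights by
  default (quadratic available); binary ratings make the weighting
  irrelevant. Band labels: 0<κ≤0.20 slight, ≤0.40 fair, ≤0.60
  moderate, ≤0.80 very good, ≤1 substantial. Degenerate marginals
  (expected agreement 1) raise instead of returning a number.
- **Group comparison**: per-parameter one-way two-group ANOVA
  (F = pooled-t², property-tested), two-sided p, Bonferroni factor 3
  (one comparison per biomarker), group means/SDs and t-based 95% CIs.

## Problem sizes and determinism

Default runs use the 48×48×24 grid (≈55k voxels, seconds per fit) and
the 29/18 cohort; convergence checks use 10 000 subjects per group and
500 replicated cohorts. Every stochastic stage takes an explicit seed
and is bit-reproducible; pipeline reports embed the package version
and a configuration hash.

## What the synthetic data does and does not show

The phantom has piecewise-constant tensors, no partial-volume mixing,
no eddy-current or motion artifacts, and no registration step (maps
are intrinsically co-registered by construction, which real DTI-to-
FLAIR comparisons are not). The cohort generator reproduces the
marginal group distributions, not the within-patient correlation
structure or any longitudinal dynamics. Passing tests therefore
demonstrate the correctness of the estimators and statistics under
the stated models — not clinical performance on patient data.

Two further limitations are worth stating. At SNR 20 with 13
measurements, the median relative MD error in the T2w zone is ≈5%,
dropping to ≈2% only around SNR 50 (error ∝ 1/SNR). And because MD
averages the three eigenvalues it is the least noisy map, so under
the default noise level MD attains the largest CNR even though the
AD effect size (group-mean difference) is the largest; the robust
ordering the pipeline asserts is CNR(AD) > CNR(RD), with the
AD-vs-MD ranking depending on the noise level and ROI SD structure.
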