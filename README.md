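# gliodti

Quantitative diffusion-tensor (DTI) biomarkers for MRI surveillance of
resected WHO grade II glioma. After gross-tumor resection, low-grade
gliomas are followed for years; malignant transformation (MT) into an
anaplastic tumor is conventionally flagged by new contrast enhancement
on T1w imaging. Rising cellularity, however, restricts water diffusion
and can show up in diffusion-derived maps at the same time or earlier.
`gliodti` implements the complete quantitative workflow needed to study
that signal on synthetic data: DWI phantom simulation, tensor fitting,
diffusivity-map generation, ROI-minimum biomarker readout with a
two-reader contrast statistic, and the ROC / PPV / kappa / ANOVA
statistics layer that ranks the three candidate biomarkers.

It is aimed at researchers in quantitative neuro-oncology imaging who
want a reproducible, fully synthetic testbed for minimum-diffusivity
biomarkers — no patient data is required or included.

## Model

Each DWI measurement follows the Stejskal–Tanner decay
`S_i = S0 · exp(−b_i · gᵢᵀ D gᵢ)` with a symmetric diffusion tensor `D`
(mm²/s) per voxel; noisy acquisitions add Rician magnitude noise
`sqrt((S+ε₁)² + ε₂²)`, σ = max(S0)/SNR. The tensor is fitted by
log-linear least squares (7 unknowns: 6 tensor components + ln S0).
From the sorted eigenvalues λ₁ ≥ λ₂ ≥ λ₃:

    AD = λ₁        (axial diffusivity)
    RD = (λ₂+λ₃)/2 (radial diffusivity)
    MD = (λ₁+λ₂+λ₃)/3 = ADC (mean diffusivity)

The per-patient biomarker is the minimum map value inside the tumor
ROI (`AD_min`/`MD_min`/`RD_min`). Tumor-to-surround contrast uses the
two-reader CNR

    CNR = [ (D_t2w,r1 + D_t2w,r2)/2 − (D_tum,r1 + D_tum,r2)/2 ] / STD
    STD = (SD_t2w,r1 + SD_t2w,r2)/2 + (SD_tum,r1 + SD_tum,r2)/2

and discrimination between stable and transformed patients uses ROC
analysis with a low-is-positive rule (test positive when the value is
≤ the cutoff; cutoff by Youden's J, AUC by trapezoid = Mann–Whitney
concordance, SE by Hanley–McNeil), plus weighted Cohen's kappa for
inter-reader agreement and a two-group one-way ANOVA with Bonferroni
correction (factor 3 for the three biomarkers).

## Worked example

```python
>>> import gliodti as g
>>> report = g.run_cohort_pipeline(g.CohortConfig(seed=1))
>>> round(report["roc"]["ad"]["auc"], 3)
0.939
>>> report["signal_drop_percent"]
{'ad': 64.1, 'md': 73.0, 'rd': 63.9}
```

The AUC of 0.939 says that in a simulated 29-stable / 18-transformed
cohort a randomly chosen transformed patient has a lower `AD_min` than
a randomly chosen stable patient about 94% of the time. The signal
drops say the early-transformation subgroup means (0.82/0.73/0.62
×10⁻³ mm²/s) sit at 64.1%, 73.0% and 63.9% of the respective
stable-group levels (1.28/1.00/0.97) — the hallmark of a forming
diffusion restriction.

The numbered drivers under `analysis/` run the same workflow as a
narrative sequence — `01` simulates the phantom study, `02` fits the
tensors and reports map precision, `03` does the two-reader ROI/CNR
readout, `04` the cohort statistics — writing their tables under
`results/` (volumes go to `scratch/`). A `gliodti` console command
exposes the individual stages (`gliodti simulate phantom`,
`gliodti fit`, `gliodti roi`, `gliodti stats roc`, ...).

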