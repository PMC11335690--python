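# Methods

This note documents the models implemented in glymkit, the choices made
where the underlying methods leave the design open, what the synthetic data
emulate, and the limits of what passing tests demonstrate.

## ePVS segmentation

**Model.** Perivascular spaces carry CSF-like signal — dark on T1w, bright
on T2w — so on white-matter-normalized images the EPC ratio `T1w/T2w`
(guarded by `epsilon = 1e-6` in the denominator) turns them into strong dark
tubes on a background near 1. Tubularity is measured by the standard
multiscale Hessian vesselness: eigenvalues are ordered by magnitude, the
plate term uses `R_A = |λ2|/|λ3|`, the blob term `R_B = |λ1|/√(|λ2λ3|)`, the
structureness term the Frobenius norm, and dark-tube polarity requires
`λ2, λ3 > 0` on the original image (the implementation negates the image and
tests `λ2, λ3 < 0`). Scale normalization is `σ²H` (γ = 2); the output is the
maximum over scales.

**Parameters.**

| parameter | default | why |
|---|---|---|
| working grid | 0.7 mm isotropic | sub-voxel tubes at the native 1 mm³ resolution become multi-voxel |
| scales | 0.35, 0.7, 1.05 mm | sub-voxel to ~1.5-voxel tube radii on the working grid |
| α, β | 0.5, 0.5 | standard plate/blob discrimination constants |
| c | auto (half max ‖H‖_F over region), or frozen per-scale values | absolute structureness varies with contrast; see calibration |
| h (WM / BG) | 2e-7 / 3e-7 | reference absolute thresholds; meaningful only for a matching vesselness scaling |
| min cluster | 9 voxels (26-connectivity, ≥ comparison) | ≈3.09 mm³ at 0.7 mm |
| normalization statistic | WM median | robust to PVS inclusions inside the mask |

**Region conditioning.** Tissue-boundary intensity edges are themselves
ridge-like and fire a tubularity filter throughout the Gaussian support.
Before filtering, voxels outside the region core (the mask eroded by a
2-voxel partial-volume guard, L∞) are replaced by the core's median EPC, so
boundary contrast never enters the Hessian while tubes keep their internal
contrast. A noise-free, tube-free region therefore yields exactly zero
vesselness. No anatomy-specific (e.g. periventricular) exclusion zone is
applied.

**Threshold calibration.** Absolute vesselness values are only comparable
across images when the structureness constant is fixed:
`fit_structureness_c` freezes per-scale `c` on a calibration image, and
`calibrate_threshold` bisects `h` (40 halvings; burden is monotone
non-increasing in `h`) until the segmented burden matches a known target on
a noise-free phantom. The demo pipeline calibrates `(c, h)` once and holds
both fixed across subjects. Burden granularity is limited by the minimum
cluster size, so calibration matches the target up to one cluster.

## DTI-ALPS

**Fits.** The kurtosis-extended log-signal model is linear in the 6 unique
components of D and the 15 unique components of `V = MD²·W`; `fit_dki_lls`
solves the joint 22-parameter system by least squares (exact for noiseless
data; the two-shell scheme's design matrix has full rank 22), then recovers
`W = V/MD²`. `fit_dti_wls` is the tensor-only estimator: OLS start plus one
reweighting pass with weights equal to squared predicted signals. Signals
≤ 0 are clipped to 1e-10 with a logged count; negative tensor eigenvalues
are counted and reported, never silently altered. When two shells are
present the D entering ALPS comes from the kurtosis fit; a DTI-only mode
serves single-shell data.

**ROIs and index.** Four axial square ROIs (16 mm² each, 1-slice slab,
mirror-symmetric bilateral pairs) sit in the projection-fiber (principal
axis Z) and association-fiber (principal axis Y) systems. The index
averages each diffusivity term over left and right before forming the
single ratio (average-then-ratio); `per_side_ratio=True` gives the
ratio-then-average alternative, identical for symmetric fields. In the
phantom standard space the ROI centers are known a priori, replacing manual
placement; axes follow X = left–right, Y = anterior–posterior,
Z = inferior–superior.

## Synthetic data

**Structural phantoms** are nested-box tissue layouts (GM shell, WM block,
BG block, CSF ventricle) with straight-cylinder PVS inclusions rendered by
6× supersampling (center-in-cylinder per subvoxel; at 6× the cylinder-volume
discretization error stays under ~2% for mm-scale radii, whereas 3× is
alignment-sensitive up to ~13%). The true burden is computed from the
supersampled occupancy before noise and is exact by construction. Tubes are
straight, not tortuous, so the tubularity assumption of the filter is met
by construction — passing recovery tests therefore bounds algorithmic
error, not anatomic realism. Default contrast: WM (1.00, 0.45), GM (0.70,
0.70), BG (0.78, 0.62), CSF (0.15, 1.00) in (T1w, T2w) arbitrary units;
Gaussian noise sd 0.02 per channel; tube radii 0.4–0.8 mm, lengths 3–8 mm.

**DWI phantoms** evaluate the exact forward model per region and add
Gaussian or Rician noise (two independent channels of sd
mean-S0/SNR; magnitude taken). The ALPS phantom defaults to isotropic
kurtosis K = 1.0, typical of cerebral white matter: tissue is not
mono-exponential, and on a b = 2500 s/mm² shell the kurtosis term is what
keeps signals above the Rician noise floor, as in vivo. A mono-exponential
(K = 0) phantom at SNR 30 drives the outer shell below the floor and biases
the kurtosis-fit diffusivities — a physically unrealistic regime for this
protocol (and the emulated pipeline additionally denoises upstream, which
is out of scope here). K = None remains available for analytic DTI checks.

**Synthetic cohort.** One control visit; two mTBI visits sharing subject
random effects. Generative structure: log WM-ePVS linear in age (and
group), ALPS linearly decreasing in age, symptom count Poisson with
log-link on WM-ePVS plus a group offset, chronic memory problem logistic in
(education, CT/MRI finding, acute WM-ePVS, acute ALPS), BG-ePVS with a
subject random intercept (sd τ = 0.25) and a visit effect (+0.10), and
jointly drawn ALPS/PSQI visit ratios with correlation ρ = −0.42. Default
coefficients were calibrated once so control marginals approximate
WM-ePVS 0.40 ± 0.18 %, ALPS 1.51 ± 0.12, PSQI ≈ 6.5 ± 3.5, age-correlations
≈ +0.65 / −0.37, and the memory-model coefficients use the published-style
logistic estimates (education −0.237, CT/MRI −1.646, WM-ePVS +3.551, ALPS
+9.307) with the intercept set to −11.2 for ≈50% outcome prevalence. These
are generator defaults, not estimates of any real cohort. PSQI is stored as
a continuous 0–21 score so stored visit ratios retain the target
correlation exactly; RPQ items are integer 0–4 and the memory flag is, by
construction, identical to (memory item ≥ 2). When a drawn symptom count of
zero conflicts with a drawn memory flag the count is raised to one (the
flag logically implies ≥ 1 symptom); this affects ~2% of rows and is far
below the estimation error of the Poisson link at the tested sizes.

## Statistics

Welch t-tests with Satterthwaite df (pooled-variance is deliberately not
used); Pearson chi-squared without continuity correction; Pearson r with
the t-transform p; OLS adjustment for age and sex with the partial
correlation derived from the marker t statistic; REML random-intercept
mixed model with Wald tests (boundary τ² = 0 fits are reported, not
errored); RPQ total is the plain sum of all 22 ratings (range 0–88), a
symptom is an item rated ≥ 2. Stepwise logistic selection is bidirectional
on AIC from the intercept-only model; complete separation raises with
advice to use the L2-penalized mode. AUC is the tie-corrected concordance
probability (Mann–Whitney); two models are compared by paired bootstrap
(resampling subjects, normal approximation on the bootstrap sd of ΔAUC;
degenerate zero-sd differences report p = 1; single-class resamples are
redrawn with a logged count; 2000 resamples by default, seed mandatory).
FDR is Benjamini–Hochberg; one family per analysis block. BH adjusted
values are *not* idempotent in general (re-ranking ties can raise earlier
entries), so the invariant tested is dominance (re-adjustment never
decreases), alongside exact agreement with the brute-force min-over-tail
definition.

## Numerical and scaling choices

Linear resampling uses order-1 interpolation (no overshoot) on a grid
covering the same world extent; labels resample nearest-neighbour. The
demo computes image-based markers for a small number of per-subject
phantoms (default 3) and runs the statistics battery on the full generator
cohort; problem sizes throughout (40³ structural grids, 24×24×12 DWI grids,
n = 2000 recovery cohorts, 50 Rician replicates, 500–2000 calibration
replicates) were chosen so the full suite and the acceptance script each
complete in minutes on a single CPU while keeping Monte-Carlo error well
inside the tested tolerances.

## Known limitations

No realistic anatomy (block phantoms; straight tubes); no susceptibility,
eddy-current or motion simulation — registration, denoising and bias-field
correction are assumed upstream; BG-ePVS inherits the lower contrast of
deep gray matter and is less reliable than WM-ePVS; absolute `h` thresholds
from other implementations do not transfer without recalibration; the
bootstrap AUC comparison relies on a normal approximation and is only
approximately calibrated at small n; cohort coefficients are a stylized
effect structure, so statistical conclusions about real patients cannot be
drawn from synthetic runs.
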