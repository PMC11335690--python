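# glymkit

Quantitative MRI markers of the brain's glymphatic (perivascular clearance)
system, with fully synthetic test beds:

* **ePVS burden** — automatic segmentation of enlarged perivascular spaces
  from co-registered T1w/T2w images, reported as the percentage of a region's
  volume (white matter or basal ganglia) occupied by detected spaces;
* **DTI-ALPS index** — diffusivity along the perivascular axis of the deep
  medullary veins, sampled from diffusion-tensor maps in projection- and
  association-fiber ROIs at the level of the lateral-ventricle body;
* the **longitudinal / predictive statistics** used to relate both markers
  to post-concussion symptoms in a two-visit mild-TBI cohort;
* **phantom and cohort simulators** with analytic ground truth, so every
  stage is testable without any imaging download.

The package is aimed at neuroimaging methods developers who need a tested,
reproducible reference implementation of these markers, and at anyone who
wants to study their statistical behaviour under controlled conditions.

## The markers

**ePVS burden.** After upsampling to a 0.7 mm working grid and normalizing
T1w and T2w to the white-matter median, the enhanced perivascular contrast
image is the ratio `EPC = T1w / T2w`; perivascular spaces (CSF-like: dark on
T1w, bright on T2w) are strong dark tubes in EPC. Multiscale Frangi
vesselness with Hessian eigenvalues `|λ1| ≤ |λ2| ≤ |λ3|`,

    V = (1 − exp(−R_A²/2α²)) · exp(−R_B²/2β²) · (1 − exp(−S²/2c²)),
    R_A = |λ2|/|λ3|,  R_B = |λ1|/√(|λ2 λ3|),  S = ‖H‖_F,

is thresholded at `h` and cleaned with a 26-connected minimum cluster size
of 9 voxels (≈3 mm³); then

    ePVS burden = 100% × ePVS volume / region volume.

Because the absolute vesselness scale is implementation-dependent, the
package ships a calibration routine that fixes `(c, h)` on a noise-free
phantom with known burden (plus a quantile-threshold mode).

**DTI-ALPS.** From a two-shell diffusion acquisition (2 × b=0, 45 directions
at b=1000, 90 at b=2500 s/mm²) the diffusion-kurtosis signal model

    ln S(b,g) = ln S0 − b·gᵀDg + (1/6)·b²·MD²·W(g)

is inverted by linear least squares for the tensor D (and kurtosis tensor
W); with Dxx/Dyy/Dzz the diagonal tensor maps in the scanner frame
(X = left–right, Y = anterior–posterior, Z = inferior–superior) and four
bilateral 16 mm² ROIs,

    ALPS = mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc),

where each term is first averaged over the left and right ROIs. An
isotropic medium gives ALPS = 1 exactly; higher values indicate preserved
diffusion along the perivascular axis.

**Statistics.** Welch t and chi-squared group tests, Pearson age
correlations, age/sex-adjusted OLS associations with partial correlations, a
random-intercept linear mixed model for the visit effect, per-subject
6-12-month / 14-day ratio correlations, bidirectional AIC-stepwise logistic
prediction of chronic memory problems, tie-corrected ROC/AUC with a paired
bootstrap AUC comparison, and Benjamini–Hochberg FDR.

## Worked example

`examples/02_alps_from_dwi_phantom.py` builds a Rician-noise (SNR 30) DWI
phantom whose analytic ALPS is 1.5, fits the kurtosis model and evaluates
the ROIs:

```
analytic ground-truth ALPS: 1.5000
estimated ALPS at SNR 30:   1.5363
  Dxx (projection, bilateral mean): 1.54e-03 mm^2/s
  Dyy (projection):                 1.01e-03 mm^2/s
  Dxx (association):                1.53e-03 mm^2/s
  Dzz (association):                9.85e-04 mm^2/s
```

The four means are the bilateral ROI averages entering the ratio; the
estimate sits within a few percent of the ground truth, and is exact to
1e-9 without noise. `examples/01_epvs_from_structural_phantom.py` does the
same for ePVS burden (true 0.345% vs estimated 0.387% on a noisy phantom
after calibration), and `examples/03_cohort_statistics.py` runs the whole
statistics battery on a synthetic 37-control / 44-patient cohort.

There is also a thin CLI:

```bash
glymkit demo --seed 4 --out demo_out     # simulate -> markers -> stats
glymkit simulate cohort --out cohort.csv --seed 1
glymkit stats --cohort cohort.csv --out stats_out --seed 1
```

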