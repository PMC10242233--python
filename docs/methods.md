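# Methods

## Scientific setting

Overnight orthokeratology (ortho-k) slows axial elongation in myopic
children, but response varies widely, and efficacy can normally be judged
only after a year of wear. The choroid — the vascular layer between the
retinal pigment epithelium (RPE)–Bruch's membrane complex and the sclera —
responds to the altered optical signal within weeks, so early choroidal
measurements are candidate predictive biomarkers. `choroidkit` implements
the full measurement-and-prediction chain: image-level quantification of
choroidal vascularity and choriocapillaris perfusion, and cohort-level
statistics linking those measurements to annualized one-year axial-length
(AL) elongation.

## Image-level quantification

### Choroidal vascularity from a B-scan

The choroid band on a horizontal macular B-scan is bounded by the outer
border of the RPE–Bruch's membrane complex (upper) and the choroid–sclera
interface (lower). Within a 6-mm region of interest (ROI) centred on the
fovea the band is split into dark vessel lumens and bright stroma:

- **LA** (luminal area, mm²) — lumen pixels × pixel area,
- **SA** (stromal area, mm²) — remaining band pixels × pixel area,
- **TCA** = LA + SA, **CVI** = 100·LA/TCA (%),
- **SFCT** — band height at the fovea column × axial scale (µm).

*Magnification correction.* The transverse scale of a fundus image is
proportional to (AL − 1.82) mm (Littmann–Bennett reduced-eye model); the
device calibration assumes a 24.385-mm reference eye. The lateral pixel
scale is multiplied by (AL − 1.82)/(24.385 − 1.82) before areas are
computed; the axial scale is optical-path-determined and left uncorrected.

*Binarization.* Lumen/stroma separation uses Niblack local thresholding
(pixel is lumen iff intensity < local mean + k·local SD) with k = −0.2 and
a physically square 200-µm window, the de-facto convention of the CVI
literature. Two implementation choices matter:

1. the window is converted to pixels per axis (rows from the axial scale,
   columns from the lateral scale), since OCT pixels are anisotropic;
2. pixels outside the segmented band are replaced by the band mean before
   the local statistics are computed, so bright retinal/scleral tissue
   cannot bias windows that straddle a boundary. The comparison is strict
   (`<`), so a zero-variance band yields no lumen.

*Segmentation.* Device or ground-truth boundaries are accepted as-is
(after validation). The built-in fallback is gradient-based: per column,
the upper boundary is the strongest bright-to-dark transition within 12
rows below the brightest reflector (the RPE complex), the lower boundary
is the deepest contiguous run of rising gradient (the choroid–sclera
interface, the deepest persistent dark-to-bright edge); both are median-
smoothed across columns (9-px kernel). On default phantoms the mean
absolute boundary error is about 0.5 px (tested at ≤ 2 px).

### Choriocapillaris flow deficits

Flow deficits (CcFD) on the enface choriocapillaris angiogram are
segmented with Phansalkar local thresholding
(t = m·(1 + p·e^(−q·m) + k·(s/r − 1)), k = 0.25, r = 0.5, p = 2, q = 10,
intensities min–max normalized to [0, 1]) over a 60-µm window —
scikit-image has no Phansalkar operator, so the local moments are computed
with uniform filters directly. Connected components smaller than a
24-µm-equivalent-diameter circle (≈ 452 µm²) are removed as noise.
CcFD% = 100 × deficit area / ROI area over the 5-mm-diameter circle
centred on the fovea (pixel-centre membership test, no anti-aliasing).
Because of the min–max normalization the deficit pattern is invariant to
intensity gain.

## Synthetic data

### B-scan phantom

Layers from top: vitreous (20), retina (200), a 25-µm RPE band (255),
choroid stroma (default 160) with elliptical lumens (default 90), sclera
(210); additive Gaussian noise (SD 8) clipped to [0, 255]. Default
geometry: 9 × 3 mm at 10 (lateral) × 5 (axial) µm/px; choroid thickness
follows a mild parabolic dome peaking at `sfct_um` at the fovea. Lumen
ellipses (semi-axes 20–80 µm) are placed at seed-determined positions and
accepted only while the ROI luminal fraction stays within +0.009 of the
target; placement stops once it is within ±0.009, guaranteeing the
documented ±0.01 tolerance (a bounded-rejection error fires if the
configured lumen sizes cannot land in the band). Speckle statistics,
radial-scan geometry and 3-D volumes are deliberately not modelled: the
phantom tests the measurement chain, not device realism, so recovery
results do not certify performance on real OCT speckle or on segmentation
of pathological choroids.

### Choriocapillaris phantom

A Gaussian-smoothed white-noise field (correlation length 15 µm at
6000/512 µm/px) is thresholded at the empirical quantile of the in-circle
values equal to the target deficit fraction, giving an exact-fraction
ground-truth mask (±0.005 by construction); deficit pixels are rendered
dark (50) on a bright flow background (180) with additive noise.

### Cohort generator

One row per child: age, sex, spherical-equivalent refraction, AL, mean
keratometry, baseline choroidal metrics, one-month changes, wear days and
annualized one-year elongation. Marginals default to the study-population
summary values (e.g. age 10.31 ± 1.45 y, AL 24.77 ± 0.73 mm, CVI
60.50 ± 3.07 %, SFCT 245.41 ± 50.86 µm, one-month ΔSFCT 10.62 ± 19.98 µm);
sex is Bernoulli(0.48 male); wear days uniform on 350–380 (about a year
of wear with scheduling jitter).

Three baseline marginals (LA, SA, CVI) cannot all be honored exactly
under the identities TCA = LA + SA and CVI = 100·LA/TCA. The generator
draws SA ~ N(0.55, 0.10²) and CVI ~ N(60.50, 3.07²) and derives
LA = SA·CVI/(100 − CVI): a delta-method expansion shows the induced LA
marginal is ≈ N(0.84, 0.19²), matching the configured 0.84 ± 0.18 almost
exactly, so all three summaries are effectively honored while the
identities hold row by row. Other orderings (e.g. deriving SA) miss an SD
by ≈ 40%.

The outcome is generated by a single structural model

    elongation = β₀ + β_CVI·CVI₀ + β_ΔSFCT·(ΔSFCT/10) + β_age·age
                 + β_sex·1[male] + ε,   ε ~ N(0, σ²)

with β_CVI = −0.023 mm/%, β_ΔSFCT = −0.035 mm/10 µm and β_age = β_sex = 0
by default. β₀ and σ are calibrated analytically (no simulation) so that
the mean and SD of elongation are 0.19 and 0.17 mm/year at the covariate
means; with the defaults β₀ ≈ 1.619 and σ ≈ 0.138.

The one-month changes (ΔLA, ΔSA, ΔSFCT) are jointly Gaussian.
corr(ΔLA, ΔSFCT) = 0.8 and corr(ΔSA, ΔLA) = 0.6 by default, and
corr(ΔSA, ΔSFCT) is fixed to their product. This choice makes ΔSFCT
project onto ΔLA alone in the population regression, so a model that
includes ΔLA (and ΔSA) but not ΔSFCT shows an attenuated ΔLA effect of
β_ΔSFCT·0.8·σ_ΔSFCT/σ_ΔLA ≈ −0.008 mm per 0.01 mm² — i.e. the generator
reproduces, from one underlying association, the behaviour of the two
collinearity-split regression models. The reported inter-correlations of
the real cohort are not public; these defaults are configurable and not
asserted as measured values. Covariates other than the change block are
independent, which understates the (weak) real-world correlations among
baseline biometrics.

## Cohort statistics

- **Annualization**: elongation (mm/year) = ΔAL × 365 / wear-days.
- **Median split**: slow progression iff annualized elongation ≤ cohort
  median (mean of the middle two for even n).
- **Screening**: Pearson when both variable and outcome pass Shapiro–Wilk
  at α = 0.05, Spearman otherwise; selection at P < 0.05. Shapiro–Wilk is
  evaluated on at most the first 5000 values (its P is unreliable beyond).
- **Group comparisons**: t-test when both groups pass normality,
  Mann-Whitney otherwise; chi-squared for categorical variables.
- **Multivariable models**: OLS with 95% CIs on scaled predictors
  (areas per 0.01 mm², SFCT per 10 µm, CVI per 1 %), always adjusted for
  age and sex. Model 1 = {CVI₀, LA₀, ΔLA, ΔSA}; model 2 = {CVI₀, LA₀,
  ΔSFCT}; baseline LA is carried in both by design. Rank-deficient designs
  raise an error naming the most collinear pair; variance-inflation
  factors above 5 warn.
- **Discrimination**: maximum-likelihood logistic fits (no penalty; BFGS
  fallback when separation makes the Newton Hessian singular), AUC by the
  rank (Mann–Whitney) formulation with ties counted ½, 95% CI from the
  DeLong variance; paired model comparisons by the fast midrank DeLong
  test (placement values); IDI with the asymptotic two-sample SE and
  two-sided Z test. Degenerate inputs (identical probabilities) give
  IDI = 0 with an undefined P and a warning.
- **Nomogram**: per-variable points = 100·(βv − min contribution)/C with
  C the widest |β|·range among predictors (widest effect = 100 points);
  the total-points axis inverts affinely to the linear predictor, so the
  nomogram probability equals the logistic probability exactly (tested at
  10⁻⁶); out-of-range inputs are clamped with a warning.

All procedures are deterministic given the table; the only randomness in
the test suite is in seeded simulations and the permutation oracle used to
cross-check DeLong.

## Verification sizes

Law-of-large-number checks on the generator use n = 20 000; coefficient
recovery uses a single n = 5000 cohort plus 100 replicates at n = 50 for
CI coverage (90–98% observed); the discrimination consistency check
averages 200 replicates of 25 + 25 subjects; phantom recovery uses one
default-size phantom per target. These sizes put Monte-Carlo error well
inside each tolerance while keeping the full suite under a minute.

## Known limitations

- The exact binarization and flow-deficit rules of the original device
  software are unpublished; Niblack/Phansalkar with the stated windows are
  field conventions, and all parameters are configurable.
- Phantoms do not emulate speckle, projection artifacts, motion or signal
  loss; recovery tolerances quantify algorithmic correctness only.
- The cohort generator reproduces marginals and one linear effect
  structure, not the full joint distribution of a real clinic population;
  absolute AUCs of multi-predictor models on synthetic cohorts depend on
  the configured correlation structure.
- Fovea localization is taken from metadata; automatic foveal detection
  and radial/volumetric averaging are out of scope.
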