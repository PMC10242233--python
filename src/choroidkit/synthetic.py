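"""Synthetic phantoms and cohorts with known ground truth.

Three generators cover the inputs of the analysis pipeline:

* :func:`generate_bscan_phantom` — a macular OCT B-scan with a choroid band
  (bright stroma, dark elliptical vessel lumens) between known boundaries,
  with the luminal pixel fraction inside the 6-mm region of interest driven
  to a configurable target.
* :func:`generate_cc_phantom` — an enface choriocapillaris angiogram with
  dark flow-deficit patches occupying a configurable fraction of the 5-mm
  fovea-centred circle.
* :func:`generate_cohort` — a cohort of ortho-k-treated myopic children with
  baseline biometrics, one-month choroidal changes, and an annualized
  one-year axial-length elongation produced by a known linear model.

Every generator is fully determined by its ``seed``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import ellipse as _draw_ellipse

__all__ = [
    "Marginal",
    "CohortGenParams",
    "BScanPhantomSpec",
    "AngioPhantomSpec",
    "PhantomTruth",
    "generate_cohort",
    "generate_bscan_phantom",
    "generate_cc_phantom",
    "COHORT_COLUMNS",
]


class Marginal(NamedTuple):
    """Mean and standard deviation of a Normal marginal."""

    mean: float
    sd: float


#: Column dictionary for the cohort table (name -> description with units).
COHORT_COLUMNS: dict[str, str] = {
    "subject_id": "unique subject identifier",
    "age_years": "age at baseline (years)",
    "sex": "male/female",
    "ser_d": "spherical equivalent refraction (D)",
    "al_mm": "axial length at baseline (mm)",
    "k_d": "average corneal keratometry, central 3 mm (D)",
    "la0_mm2": "baseline choroidal luminal area, 6-mm ROI (mm^2)",
    "sa0_mm2": "baseline choroidal stromal area, 6-mm ROI (mm^2)",
    "tca0_mm2": "baseline total choroidal area = LA + SA (mm^2)",
    "sfct0_um": "baseline subfoveal choroidal thickness (um)",
    "cvi0_pct": "baseline choroidal vascularity index = 100*LA/TCA (%)",
    "ccfd0_pct": "baseline choriocapillaris flow-deficit percentage (%)",
    "d_la_mm2": "one-month change in luminal area (mm^2)",
    "d_sa_mm2": "one-month change in stromal area (mm^2)",
    "d_tca_mm2": "one-month change in total choroidal area (mm^2)",
    "d_sfct_um": "one-month change in subfoveal choroidal thickness (um)",
    "d_cvi_pct": "one-month change in CVI (%)",
    "d_ccfd_pct": "one-month change in CcFD (%)",
    "d_k_d": "one-month change in average keratometry (D)",
    "wear_days": "days of ortho-k lens wear over the follow-up",
    "d_al_raw_mm": "raw axial-length change over the follow-up (mm)",
    "d_al_annualized_mm_yr": "annualized one-year AL elongation (mm/year)",
}


@dataclass
class CohortGenParams:
    """Parameters of the synthetic ortho-k cohort generator.

    Marginal distributions default to the study-population summary values
    (means and SDs) for myopic children aged 8-12 treated with overnight
    orthokeratology.  The outcome — annualized one-year axial elongation —
    is generated by a linear structural model on baseline CVI and the
    one-month SFCT change (scaled per 10 um), optionally with age and sex
    terms::

        elongation = b0 + b_cvi0*CVI0 + b_dsfct*(dSFCT/10)
                     + b_age*age + b_sex*1[male] + eps,   eps ~ N(0, sd^2)

    ``beta0`` and ``residual_sd`` default to ``None`` meaning *calibrated*:
    beta0 is chosen so the mean elongation at the covariate means equals
    ``target_mean_elongation`` and residual_sd so the marginal SD of the
    elongation equals ``target_sd_elongation``.

    Baseline identities (TCA = LA + SA, CVI = 100*LA/TCA) are enforced by
    drawing SA and CVI from their marginals and deriving LA; the induced LA
    marginal closely matches the configured one (see the methods note).
    """

    n: int = 50
    seed: int = 0
    # baseline marginals
    age: Marginal = Marginal(10.31, 1.45)
    ser: Marginal = Marginal(-2.86, 1.09)
    al: Marginal = Marginal(24.77, 0.73)
    k: Marginal = Marginal(43.43, 1.29)
    la0: Marginal = Marginal(0.84, 0.18)  # validated, derived from sa0 & cvi0
    sa0: Marginal = Marginal(0.55, 0.10)
    sfct0: Marginal = Marginal(245.41, 50.86)
    cvi0: Marginal = Marginal(60.50, 3.07)
    ccfd0: Marginal = Marginal(13.53, 1.76)
    # one-month changes
    d_la: Marginal = Marginal(0.03, 0.07)
    d_sa: Marginal = Marginal(0.02, 0.05)
    d_sfct: Marginal = Marginal(10.62, 19.98)
    d_k: Marginal = Marginal(-1.47, 1.01)
    d_ccfd: Marginal = Marginal(0.0, 1.0)
    sex_male_prob: float = 0.48
    # structural coefficients (outcome units: mm/year)
    beta0: float | None = None  # calibrated when None
    beta_cvi0: float = -0.023  # per 1 % CVI
    beta_dsfct: float = -0.035  # per 10 um SFCT change
    beta_age: float = 0.0  # per year
    beta_sex: float = 0.0  # male vs female
    residual_sd: float | None = None  # calibrated when None
    target_mean_elongation: float = 0.19
    target_sd_elongation: float = 0.17
    # cross-correlations among one-month changes
    corr_dla_dsfct: float = 0.8
    corr_dsa_dla: float = 0.6
    wear_days_range: tuple[int, int] = (350, 380)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        for name in ("age", "ser", "al", "k", "la0", "sa0", "sfct0", "cvi0",
                     "ccfd0", "d_la", "d_sa", "d_sfct", "d_k", "d_ccfd"):
            m = getattr(self, name)
            if not isinstance(m, Marginal):
                m = Marginal(*m)
                setattr(self, name, m)
            if m.sd < 0:
                raise ValueError(f"marginal {name!r} has negative SD {m.sd}")
        for name in ("corr_dla_dsfct", "corr_dsa_dla"):
            r = getattr(self, name)
            if not -1.0 <= r <= 1.0:
                raise ValueError(f"{name} must be in [-1, 1], got {r}")
        if not 0.0 <= self.sex_male_prob <= 1.0:
            raise ValueError("sex_male_prob must be in [0, 1]")
        lo, hi = self.wear_days_range
        if lo <= 0 or hi < lo:
            raise ValueError(f"invalid wear_days_range {self.wear_days_range}")

    # -- calibration -----------------------------------------------------

    def change_correlation_matrix(self) -> np.ndarray:
        """3x3 correlation matrix of (dLA, dSA, dSFCT).

        corr(dSA, dSFCT) is fixed to corr_dsa_dla * corr_dla_dsfct so that
        dSFCT projects onto dLA alone in the population regression.
        """
        r_ls = self.corr_dla_dsfct
        r_as = self.corr_dsa_dla
        r_af = r_as * r_ls
        return np.array([
            [1.0, r_as, r_ls],
            [r_as, 1.0, r_af],
            [r_ls, r_af, 1.0],
        ])

    def effective_beta0(self) -> float:
        if self.beta0 is not None:
            return self.beta0
        mean_lp = (
            self.beta_cvi0 * self.cvi0.mean
            + self.beta_dsfct * self.d_sfct.mean / 10.0
            + self.beta_age * self.age.mean
            + self.beta_sex * self.sex_male_prob
        )
        return self.target_mean_elongation - mean_lp

    def effective_residual_sd(self) -> float:
        if self.residual_sd is not None:
            return self.residual_sd
        explained = (
            (self.beta_cvi0 * self.cvi0.sd) ** 2
            + (self.beta_dsfct * self.d_sfct.sd / 10.0) ** 2
            + (self.beta_age * self.age.sd) ** 2
            + self.beta_sex ** 2 * self.sex_male_prob * (1 - self.sex_male_prob)
        )
        resid_var = self.target_sd_elongation ** 2 - explained
        if resid_var < 0:
            raise ValueError(
                "target_sd_elongation smaller than the SD explained by the "
                "structural coefficients; set residual_sd explicitly"
            )
        return math.sqrt(resid_var)


def generate_cohort(params: CohortGenParams) -> tuple[pd.DataFrame, dict]:
    """Generate a synthetic ortho-k cohort.

    Returns
    -------
    table : pandas.DataFrame
        One row per subject, columns as in :data:`COHORT_COLUMNS`.
    truth : dict
        The generating coefficients actually used (after calibration),
        including ``beta0`` and ``residual_sd``.
    """
    p = params
    rng = np.random.default_rng(p.seed)

    corr = p.change_correlation_matrix()
    eigvals = np.linalg.eigvalsh(corr)
    if eigvals.min() < -1e-12:
        raise ValueError(
            f"change correlation matrix is not positive semi-definite "
            f"(min eigenvalue {eigvals.min():.3g})"
        )

    n = p.n
    age = rng.normal(p.age.mean, p.age.sd, n)
    ser = rng.normal(p.ser.mean, p.ser.sd, n)
    al = rng.normal(p.al.mean, p.al.sd, n)
    k = rng.normal(p.k.mean, p.k.sd, n)
    sfct0 = np.maximum(rng.normal(p.sfct0.mean, p.sfct0.sd, n), 1.0)
    ccfd0 = np.clip(rng.normal(p.ccfd0.mean, p.ccfd0.sd, n), 0.0, 100.0)
    # SA and CVI drawn, LA derived so CVI = 100*LA/(LA+SA) holds exactly
    sa0 = np.maximum(rng.normal(p.sa0.mean, p.sa0.sd, n), 1e-3)
    cvi0 = np.clip(rng.normal(p.cvi0.mean, p.cvi0.sd, n), 1.0, 99.0)
    la0 = sa0 * cvi0 / (100.0 - cvi0)
    tca0 = la0 + sa0

    male = rng.random(n) < p.sex_male_prob

    # correlated one-month changes
    sds = np.array([p.d_la.sd, p.d_sa.sd, p.d_sfct.sd])
    means = np.array([p.d_la.mean, p.d_sa.mean, p.d_sfct.mean])
    cov = corr * np.outer(sds, sds)
    changes = rng.multivariate_normal(means, cov, size=n, method="svd")
    d_la, d_sa, d_sfct = changes.T
    d_tca = d_la + d_sa
    d_k = rng.normal(p.d_k.mean, p.d_k.sd, n)
    d_ccfd = rng.normal(p.d_ccfd.mean, p.d_ccfd.sd, n)

    la1 = np.maximum(la0 + d_la, 1e-3)
    tca1 = np.maximum(tca0 + d_tca, 2e-3)
    d_cvi = 100.0 * la1 / tca1 - cvi0

    beta0 = p.effective_beta0()
    residual_sd = p.effective_residual_sd()
    eps = rng.normal(0.0, residual_sd, n)
    elong = (
        beta0
        + p.beta_cvi0 * cvi0
        + p.beta_dsfct * d_sfct / 10.0
        + p.beta_age * age
        + p.beta_sex * male.astype(float)
        + eps
    )

    wear = rng.integers(p.wear_days_range[0], p.wear_days_range[1] + 1, n)
    d_al_raw = elong * wear / 365.0

    table = pd.DataFrame({
        "subject_id": [f"S{i:04d}" for i in range(n)],
        "age_years": age,
        "sex": np.where(male, "male", "female"),
        "ser_d": ser,
        "al_mm": al,
        "k_d": k,
        "la0_mm2": la0,
        "sa0_mm2": sa0,
        "tca0_mm2": tca0,
        "sfct0_um": sfct0,
        "cvi0_pct": cvi0,
        "ccfd0_pct": ccfd0,
        "d_la_mm2": d_la,
        "d_sa_mm2": d_sa,
        "d_tca_mm2": d_tca,
        "d_sfct_um": d_sfct,
        "d_cvi_pct": d_cvi,
        "d_ccfd_pct": d_ccfd,
        "d_k_d": d_k,
        "wear_days": wear,
        "d_al_raw_mm": d_al_raw,
        "d_al_annualized_mm_yr": elong,
    })
    truth = {
        "beta0": beta0,
        "beta_cvi0": p.beta_cvi0,
        "beta_dsfct_per10um": p.beta_dsfct,
        "beta_age": p.beta_age,
        "beta_sex": p.beta_sex,
        "residual_sd": residual_sd,
        "seed": p.seed,
    }
    return table, truth


# ---------------------------------------------------------------------------
# B-scan phantom
# ---------------------------------------------------------------------------

@dataclass
class BScanPhantomSpec:
    """Geometry, optics and contrast of a synthetic macular B-scan.

    Distances are physical; pixel geometry follows from the two scales
    (pixels are anisotropic, as on swept-source devices).  The choroid band
    sits between a flat upper boundary (outer border of the RPE-Bruch's
    membrane complex) and a lower boundary (choroid-sclera interface) whose
    depth follows ``thickness_profile`` (default: a mild parabolic dome that
    peaks at the fovea with value ``sfct_um``).
    """

    width_mm: float = 9.0
    depth_mm: float = 3.0
    lateral_scale: float = 10.0  # um/pixel before magnification correction
    axial_scale: float = 5.0  # um/pixel
    sfct_um: float = 245.0
    thickness_profile: np.ndarray | None = None  # per-column thickness, um
    luminal_fraction_target: float = 0.605
    lumen_size_range: tuple[float, float] = (20.0, 80.0)  # ellipse semi-axes, um
    stroma_intensity: float = 160.0
    lumen_intensity: float = 90.0
    noise_sd: float = 8.0
    seed: int = 0
    roi_width_mm: float = 6.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.luminal_fraction_target <= 1.0:
            raise ValueError("luminal_fraction_target must be in [0, 1]")
        if self.lumen_intensity >= self.stroma_intensity:
            raise ValueError("lumen_intensity must be < stroma_intensity")
        if self.width_mm < self.roi_width_mm:
            raise ValueError(
                f"width_mm ({self.width_mm}) must be >= roi_width_mm "
                f"({self.roi_width_mm}) so the ROI fits"
            )
        if self.lateral_scale <= 0 or self.axial_scale <= 0:
            raise ValueError("scales must be positive")
        if self.lumen_size_range[0] <= 0 or \
                self.lumen_size_range[1] < self.lumen_size_range[0]:
            raise ValueError(f"invalid lumen_size_range {self.lumen_size_range}")


@dataclass
class PhantomTruth:
    """Ground truth accompanying a phantom image."""

    lumen_mask: np.ndarray | None = None
    deficit_mask: np.ndarray | None = None
    boundary_upper: np.ndarray | None = None
    boundary_lower: np.ndarray | None = None
    fovea_column: int | None = None
    center: tuple[float, float] | None = None
    true_metrics: dict = field(default_factory=dict)


def _bscan_geometry(spec: BScanPhantomSpec):
    n_cols = int(round(spec.width_mm * 1000.0 / spec.lateral_scale))
    n_rows = int(round(spec.depth_mm * 1000.0 / spec.axial_scale))
    fovea_col = n_cols // 2
    cols = np.arange(n_cols)
    if spec.thickness_profile is not None:
        prof = np.asarray(spec.thickness_profile, dtype=float)
        if prof.shape != (n_cols,):
            raise ValueError(
                f"thickness_profile must have {n_cols} entries, got {prof.shape}"
            )
    else:
        # mild dome: 10% thinning at the image edges
        x = (cols - fovea_col) / (n_cols / 2.0)
        prof = spec.sfct_um * (1.0 - 0.10 * x ** 2)
    upper_row = int(round(0.40 * n_rows))
    t_px = np.round(prof / spec.axial_scale).astype(int)
    lower = upper_row + t_px
    if lower.max() >= n_rows:
        raise ValueError("choroid band exceeds image depth; increase depth_mm")
    upper = np.full(n_cols, upper_row, dtype=int)
    return n_rows, n_cols, fovea_col, upper, lower


def generate_bscan_phantom(
    spec: BScanPhantomSpec,
    max_failures: int = 2000,
) -> tuple[np.ndarray, PhantomTruth]:
    """Render a B-scan phantom and its ground truth.

    Dark elliptical lumens are added one at a time (accepted only while the
    luminal fraction inside the 6-mm ROI stays below target + tolerance)
    until the fraction is within +/-0.01 of ``luminal_fraction_target``.

    Raises
    ------
    RuntimeError
        If the target fraction cannot be reached after ``max_failures``
        consecutive rejected placements.
    """
    rng = np.random.default_rng(spec.seed)
    n_rows, n_cols, fovea_col, upper, lower = _bscan_geometry(spec)

    rows = np.arange(n_rows)[:, None]
    band = (rows >= upper[None, :]) & (rows <= lower[None, :])

    half_cols = spec.roi_width_mm * 1000.0 / (2.0 * spec.lateral_scale)
    c0 = int(round(fovea_col - half_cols))
    c1 = int(round(fovea_col + half_cols))
    roi_cols = np.zeros(n_cols, dtype=bool)
    roi_cols[c0:c1] = True
    band_roi = band & roi_cols[None, :]
    n_band_roi = int(band_roi.sum())

    lumen = np.zeros((n_rows, n_cols), dtype=bool)
    target = spec.luminal_fraction_target
    tol = 0.009
    count = 0
    failures = 0
    a_lo, a_hi = spec.lumen_size_range
    while count / n_band_roi < target - tol:
        cc = rng.uniform(0, n_cols)
        rr = rng.uniform(upper[int(cc)], lower[int(cc)] + 1)
        semi_c = rng.uniform(a_lo, a_hi) / spec.lateral_scale
        semi_r = rng.uniform(a_lo, a_hi) / spec.axial_scale
        er, ec = _draw_ellipse(rr, cc, semi_r, semi_c, shape=(n_rows, n_cols))
        new = band[er, ec] & ~lumen[er, ec]
        gained = int((new & band_roi[er, ec]).sum())
        if (count + gained) / n_band_roi <= target + tol:
            lumen[er[new], ec[new]] = True
            count += gained
            failures = 0
        else:
            failures += 1
            if failures > max_failures:
                raise RuntimeError(
                    f"could not reach luminal fraction {target} within "
                    f"tolerance after {max_failures} rejected placements; "
                    f"reduce lumen_size_range"
                )

    # render
    img = np.full((n_rows, n_cols), 20.0)  # vitreous
    retina_top = upper - int(round(220.0 / spec.axial_scale))
    rpe_top = upper - max(int(round(25.0 / spec.axial_scale)), 1)
    retina = (rows >= retina_top[None, :]) & (rows < rpe_top[None, :])
    rpe = (rows >= rpe_top[None, :]) & (rows < upper[None, :])
    sclera = rows > lower[None, :]
    img[retina] = 200.0
    img[rpe] = 255.0
    img[band] = spec.stroma_intensity
    img[lumen] = spec.lumen_intensity
    img[sclera] = 210.0
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, img.shape)
    img = np.clip(img, 0, 255).astype(np.uint8)

    px_area_mm2 = spec.lateral_scale * spec.axial_scale * 1e-6
    la = count * px_area_mm2
    sa = (n_band_roi - count) * px_area_mm2
    tca = la + sa
    truth = PhantomTruth(
        lumen_mask=lumen,
        boundary_upper=upper,
        boundary_lower=lower,
        fovea_column=fovea_col,
        true_metrics={
            "LA_mm2": la,
            "SA_mm2": sa,
            "TCA_mm2": tca,
            "CVI_pct": 100.0 * la / tca if tca > 0 else float("nan"),
            "SFCT_um": spec.sfct_um,
            "luminal_fraction": count / n_band_roi,
        },
    )
    return img, truth


# ---------------------------------------------------------------------------
# Choriocapillaris phantom
# ---------------------------------------------------------------------------

@dataclass
class AngioPhantomSpec:
    """Synthetic enface choriocapillaris angiogram (square field).

    Flow deficits are the sub-threshold set of a Gaussian-smoothed random
    field; thresholding at the empirical quantile of the field inside the
    5-mm circle pins the deficit fraction to the target.
    ``correlation_length_um`` sets the patch granularity.
    """

    field_mm: float = 6.0
    scale: float = 6000.0 / 512.0  # um/pixel (512 px across 6 mm)
    deficit_fraction_target: float = 0.135
    correlation_length_um: float = 15.0
    flow_intensity: float = 180.0
    deficit_intensity: float = 50.0
    noise_sd: float = 6.0
    seed: int = 0
    roi_diameter_mm: float = 5.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.deficit_fraction_target <= 1.0:
            raise ValueError("deficit_fraction_target must be in [0, 1]")
        if self.field_mm < self.roi_diameter_mm:
            raise ValueError(
                f"field_mm ({self.field_mm}) must be >= roi_diameter_mm "
                f"({self.roi_diameter_mm}) so the circular ROI fits"
            )
        if self.scale <= 0:
            raise ValueError("scale must be positive")


def generate_cc_phantom(
    spec: AngioPhantomSpec,
) -> tuple[np.ndarray, PhantomTruth]:
    """Render a choriocapillaris phantom and its ground-truth deficit mask."""
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.field_mm * 1000.0 / spec.scale))
    center = ((n - 1) / 2.0, (n - 1) / 2.0)

    fld = rng.standard_normal((n, n))
    sigma = spec.correlation_length_um / spec.scale
    fld = ndimage.gaussian_filter(fld, sigma=sigma)

    yy, xx = np.mgrid[0:n, 0:n]
    r_px = spec.roi_diameter_mm * 1000.0 / (2.0 * spec.scale)
    circle = (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= r_px ** 2

    target = spec.deficit_fraction_target
    if target <= 0.0:
        deficit = np.zeros((n, n), dtype=bool)
    elif target >= 1.0:
        deficit = np.ones((n, n), dtype=bool)
    else:
        thr = np.quantile(fld[circle], target)
        deficit = fld < thr

    img = np.where(deficit, spec.deficit_intensity, spec.flow_intensity)
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, img.shape)
    img = np.clip(img, 0, 255).astype(np.uint8)

    n_circle = int(circle.sum())
    n_def = int((deficit & circle).sum())
    px_area_mm2 = spec.scale ** 2 * 1e-6
    truth = PhantomTruth(
        deficit_mask=deficit,
        center=center,
        true_metrics={
            "deficit_area_mm2": n_def * px_area_mm2,
            "roi_area_mm2": n_circle * px_area_mm2,
            "ccfd_percent": 100.0 * n_def / n_circle,
            "deficit_fraction": n_def / n_circle,
        },
    )
    return img, truth
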