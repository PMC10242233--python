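"""Choroidal vascularity quantification from a macular OCT B-scan.

The choroid is the region between the outer border of the retinal pigment
epithelium (RPE)-Bruch's membrane complex and the choroid-sclera interface.
Within a 6-mm fovea-centred region of interest the band is binarized into
dark vessel lumens (luminal area, LA) and bright interstitial stroma
(stromal area, SA); the summary metrics are

* ``TCA = LA + SA`` (total choroidal area, mm^2),
* ``CVI = 100 * LA / TCA`` (choroidal vascularity index, %),
* ``SFCT`` — choroid thickness at the fovea column (um).

Lateral pixel scale is corrected for ocular magnification from the eye's
axial length before areas are computed (Littmann-Bennett proportionality).

Conventions: pixel coordinates are 0-based with row 0 at the top; a
boundary at row ``r`` includes row ``r`` in the choroid band; ROI columns
form the half-open interval ``[c_start, c_end)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_niblack

__all__ = [
    "BScanImage",
    "ChoroidSegmentation",
    "BinarizationConfig",
    "ChoroidMetrics",
    "REFERENCE_AXIAL_LENGTH_MM",
    "correct_lateral_scale",
    "segment_choroid",
    "binarize_lumen",
    "compute_choroid_metrics",
    "quantify_bscan",
]

#: Emmetropic reference eye axial length (mm) for magnification correction.
REFERENCE_AXIAL_LENGTH_MM = 24.385

#: Nodal-point offset of the Littmann-Bennett reduced eye (mm).
_BENNETT_OFFSET_MM = 1.82


@dataclass
class BScanImage:
    """A horizontal OCT B-scan through the fovea.

    ``lateral_scale`` is the nominal (pre-correction) lateral pixel pitch;
    apply :func:`correct_lateral_scale` with ``axial_length_mm`` before
    area computation.
    """

    intensity: np.ndarray  # rows = axial, cols = lateral, origin top-left
    lateral_scale: float  # um/pixel, nominal
    axial_scale: float  # um/pixel
    fovea_column: int
    axial_length_mm: float = REFERENCE_AXIAL_LENGTH_MM

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity)
        if self.intensity.ndim != 2 or self.intensity.size == 0:
            raise ValueError("intensity must be a non-empty 2-D array")
        if not np.all(np.isfinite(np.asarray(self.intensity, dtype=float))):
            raise ValueError("intensities must be finite")
        if self.lateral_scale <= 0 or self.axial_scale <= 0:
            raise ValueError("pixel scales must be positive")
        if not 0 <= self.fovea_column < self.intensity.shape[1]:
            raise ValueError(
                f"fovea_column {self.fovea_column} outside image width "
                f"{self.intensity.shape[1]}"
            )


@dataclass
class ChoroidSegmentation:
    """Per-column row indices of the two choroid boundaries."""

    upper: np.ndarray  # RPE-Bruch's membrane complex outer border
    lower: np.ndarray  # choroid-sclera interface

    def __post_init__(self) -> None:
        self.upper = np.asarray(self.upper, dtype=int)
        self.lower = np.asarray(self.lower, dtype=int)
        if self.upper.shape != self.lower.shape or self.upper.ndim != 1:
            raise ValueError("boundaries must be 1-D arrays of equal length")

    def validate(self, n_rows: int) -> "ChoroidSegmentation":
        bad = np.nonzero(self.lower < self.upper)[0]
        if bad.size:
            raise ValueError(
                f"lower boundary above upper boundary at columns {bad[:5].tolist()}"
            )
        if self.upper.min() < 0 or self.lower.max() >= n_rows:
            raise ValueError("boundaries outside image rows")
        return self

    def band_mask(self, n_rows: int) -> np.ndarray:
        rows = np.arange(n_rows)[:, None]
        return (rows >= self.upper[None, :]) & (rows <= self.lower[None, :])


@dataclass
class BinarizationConfig:
    """Local-threshold (Niblack) configuration for lumen/stroma separation.

    A pixel is lumen iff ``intensity < local_mean + k * local_SD`` over a
    physically square window of side ``window_um`` (strict less-than, so a
    zero-variance band yields no lumen).
    """

    window_um: float = 200.0
    k: float = -0.2
    denoise: bool = True  # 3x3 median pre-filter

    def __post_init__(self) -> None:
        if self.window_um <= 0:
            raise ValueError("window_um must be positive")


@dataclass
class ChoroidMetrics:
    LA: float  # mm^2
    SA: float  # mm^2
    TCA: float  # mm^2
    CVI: float  # %, NaN when TCA == 0
    SFCT: float  # um
    roi_width_mm: float = 6.0

    def to_dict(self) -> dict:
        return {
            "LA_mm2": self.LA,
            "SA_mm2": self.SA,
            "TCA_mm2": self.TCA,
            "CVI_pct": self.CVI,
            "SFCT_um": self.SFCT,
            "roi_width_mm": self.roi_width_mm,
        }


def correct_lateral_scale(
    nominal_scale: float,
    axial_length_mm: float,
    reference_al_mm: float = REFERENCE_AXIAL_LENGTH_MM,
) -> float:
    """Magnification-corrected lateral pixel scale (um/pixel).

    The transverse image scale is proportional to ``AL - 1.82`` mm
    (Littmann-Bennett reduced-eye proportionality); the device calibration
    assumes a reference eye of ``reference_al_mm``.  Longer eyes image a
    larger retinal extent per pixel, so the corrected scale increases with
    axial length.  The axial scale needs no such correction.
    """
    if nominal_scale <= 0:
        raise ValueError("nominal_scale must be positive")
    if axial_length_mm <= _BENNETT_OFFSET_MM:
        raise ValueError(
            f"axial_length_mm = {axial_length_mm} is degenerate "
            f"(must exceed {_BENNETT_OFFSET_MM} mm)"
        )
    if not 15.0 <= axial_length_mm <= 35.0:
        warnings.warn(
            f"axial length {axial_length_mm} mm outside the plausible "
            "15-35 mm range",
            stacklevel=2,
        )
    factor = (axial_length_mm - _BENNETT_OFFSET_MM) / (
        reference_al_mm - _BENNETT_OFFSET_MM
    )
    return nominal_scale * factor


def segment_choroid(
    bscan: BScanImage,
    provided: ChoroidSegmentation | None = None,
    smooth_px: int = 9,
    grad_threshold: float = 5.0,
    upper_search_px: int = 12,
) -> ChoroidSegmentation:
    """Return choroid boundaries, validating provided ones or estimating.

    When ``provided`` is given (device or ground-truth segmentation) it is
    validated and returned unchanged.  Otherwise a gradient-based estimate
    is made per column: the upper boundary at the strongest bright-to-dark
    transition just below the brightest band (searched within
    ``upper_search_px`` rows, since the RPE complex is the brightest
    reflector and the choroid starts at its outer edge), the lower boundary
    at the deepest dark-to-bright transition run (the choroid-sclera
    interface); both are median-smoothed across columns.
    """
    img = np.asarray(bscan.intensity, dtype=float)
    n_rows, n_cols = img.shape
    if provided is not None:
        return provided.validate(n_rows)

    sm = ndimage.gaussian_filter1d(img, sigma=2.0, axis=0)
    grad = np.diff(sm, axis=0)  # grad[r] = I[r+1] - I[r]
    bright = np.argmax(sm, axis=0)

    upper = np.full(n_cols, -1, dtype=int)
    lower = np.full(n_cols, -1, dtype=int)
    for c in range(n_cols):
        g = grad[:, c]
        lo = bright[c]
        if lo >= n_rows - 2:
            continue
        win = g[lo:lo + upper_search_px]
        i = int(np.argmin(win))
        if win[i] > -grad_threshold:
            continue
        u = lo + i + 1  # first row past the steepest drop
        pos = np.nonzero(g[u:] > grad_threshold)[0]
        if pos.size == 0:
            continue
        # deepest contiguous run of rising gradient = choroid-sclera edge
        pos_set = set(pos.tolist())
        run_end = int(pos[-1])
        run_start = run_end
        while run_start - 1 in pos_set:
            run_start -= 1
        seg = g[u + run_start:u + run_end + 1]
        lower_c = u + run_start + int(np.argmax(seg))
        upper[c] = u
        lower[c] = lower_c

    ok = (upper >= 0) & (lower >= 0)
    if ok.mean() < 0.9:
        raise RuntimeError(
            f"boundary transitions found in only {100 * ok.mean():.0f}% of "
            "columns; cannot segment the choroid"
        )
    # fill failed columns by nearest valid neighbour before smoothing
    idx = np.arange(n_cols)
    for arr in (upper, lower):
        good = idx[ok]
        arr[~ok] = np.interp(idx[~ok], good, arr[good]).astype(int)
    k = smooth_px if smooth_px % 2 == 1 else smooth_px + 1
    upper = ndimage.median_filter(upper, size=k, mode="nearest")
    lower = ndimage.median_filter(lower, size=k, mode="nearest")
    lower = np.maximum(lower, upper)
    return ChoroidSegmentation(upper=upper, lower=lower).validate(n_rows)


def _odd_window(window_um: float, scale: float) -> int:
    w = int(round(window_um / scale))
    if w < 3:
        raise ValueError(
            f"local-threshold window of {w} px (window_um={window_um}, "
            f"scale={scale} um/px) is below 3 px; increase window_um"
        )
    return w if w % 2 == 1 else w + 1


def binarize_lumen(
    bscan: BScanImage,
    seg: ChoroidSegmentation,
    config: BinarizationConfig | None = None,
) -> np.ndarray:
    """Binary lumen mask inside the choroid band (Niblack local threshold).

    The window is converted to pixels per axis (axial rows, lateral
    columns) so it is physically square despite anisotropic pixels.
    Pixels outside the band are replaced by the band mean before the local
    statistics are computed, so bright retinal/scleral tissue does not bias
    windows near the boundaries; the returned mask is empty outside the
    band.
    """
    config = config or BinarizationConfig()
    img = np.asarray(bscan.intensity, dtype=float)
    n_rows, _ = img.shape
    seg.validate(n_rows)
    band = seg.band_mask(n_rows)

    w_r = _odd_window(config.window_um, bscan.axial_scale)
    w_c = _odd_window(config.window_um, bscan.lateral_scale)

    work = img.copy()
    if config.denoise:
        work = ndimage.median_filter(work, size=3)
    fill = work[band].mean() if band.any() else 0.0
    work = np.where(band, work, fill)

    thresh = threshold_niblack(work, window_size=(w_r, w_c), k=config.k)
    return (work < thresh) & band


def compute_choroid_metrics(
    lumen_mask: np.ndarray,
    seg: ChoroidSegmentation,
    lateral_scale: float,
    axial_scale: float,
    fovea_column: int,
    roi_width_mm: float = 6.0,
) -> ChoroidMetrics:
    """Areas and thickness over the fovea-centred ROI.

    ``lateral_scale`` should already be magnification-corrected.  LA/SA are
    pixel counts times the physical pixel area; SFCT is the band height at
    the fovea column.  CVI is reported as NaN (with a warning) when the ROI
    contains no choroid pixels.
    """
    lumen_mask = np.asarray(lumen_mask, dtype=bool)
    n_rows, n_cols = lumen_mask.shape
    seg.validate(n_rows)

    half_cols = roi_width_mm * 1000.0 / (2.0 * lateral_scale)
    c0 = int(round(fovea_column - half_cols))
    c1 = int(round(fovea_column + half_cols))
    if c0 < 0 or c1 > n_cols:
        raise ValueError(
            f"ROI columns [{c0}, {c1}) exceed image width {n_cols}"
        )

    band = seg.band_mask(n_rows)
    roi = np.zeros(n_cols, dtype=bool)
    roi[c0:c1] = True
    band_roi = band & roi[None, :]
    if np.any(lumen_mask & ~band):
        raise ValueError("lumen mask has pixels outside the choroid band")

    px_area_mm2 = lateral_scale * axial_scale * 1e-6
    n_lumen = int((lumen_mask & band_roi).sum())
    n_band = int(band_roi.sum())
    la = n_lumen * px_area_mm2
    sa = (n_band - n_lumen) * px_area_mm2
    tca = la + sa
    if tca > 0:
        cvi = 100.0 * la / tca
    else:
        warnings.warn("TCA is zero in the ROI; CVI undefined", stacklevel=2)
        cvi = float("nan")
    sfct = (seg.lower[fovea_column] - seg.upper[fovea_column]) * axial_scale
    return ChoroidMetrics(
        LA=la, SA=sa, TCA=tca, CVI=cvi, SFCT=sfct, roi_width_mm=roi_width_mm
    )


def quantify_bscan(
    bscan: BScanImage,
    provided_seg: ChoroidSegmentation | None = None,
    config: BinarizationConfig | None = None,
    roi_width_mm: float = 6.0,
    reference_al_mm: float = REFERENCE_AXIAL_LENGTH_MM,
) -> tuple[ChoroidMetrics, np.ndarray, ChoroidSegmentation]:
    """Full B-scan pipeline: correct scale, segment, binarize, measure."""
    corrected = correct_lateral_scale(
        bscan.lateral_scale, bscan.axial_length_mm, reference_al_mm
    )
    seg = segment_choroid(bscan, provided_seg)
    lumen = binarize_lumen(bscan, seg, config)
    metrics = compute_choroid_metrics(
        lumen, seg, corrected, bscan.axial_scale, bscan.fovea_column,
        roi_width_mm,
    )
    return metrics, lumen, seg
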