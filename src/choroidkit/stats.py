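"""Cohort statistics: from choroidal metrics to elongation prediction.

The analysis chain mirrors standard practice for treatment-response
biomarker studies in myopia control:

1. annualize the axial-length (AL) change by actual lens-wear days;
2. screen candidate variables against the outcome with Pearson or
   Spearman correlation, gated by Shapiro-Wilk normality;
3. compare slow vs fast progressors (median split) with t /
   Mann-Whitney / chi-squared tests as appropriate;
4. fit age- and sex-adjusted multivariable linear models on scaled
   predictors (two models to sidestep the collinearity of the one-month
   choroidal changes);
5. evaluate discrimination of slow progression with logistic models:
   rank-based AUC with DeLong confidence intervals, paired DeLong tests
   between models, and integrated discrimination improvement (IDI).

All procedures are deterministic given the input table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import variance_inflation_factor

__all__ = [
    "annualize_elongation",
    "dichotomize_by_median",
    "ScreenResult",
    "screen_univariable",
    "GroupComparison",
    "compare_groups",
    "LinearFit",
    "fit_linear_model",
    "LogisticFit",
    "RocCurve",
    "roc_from_scores",
    "fit_logistic_and_roc",
    "delong_compare",
    "IdiResult",
    "compute_idi",
    "auc_rank",
    "MODEL1_PREDICTORS",
    "MODEL2_PREDICTORS",
    "DEFAULT_SCREEN_VARIABLES",
    "PREDICTOR_UNITS",
]

OUTCOME = "d_al_annualized_mm_yr"

#: Unit of one scaled predictor step: areas per 0.01 mm^2, SFCT per 10 um,
#: everything else per natural unit (CVI per 1 %, age per year).
PREDICTOR_UNITS: dict[str, float] = {
    "la0_mm2": 0.01,
    "sa0_mm2": 0.01,
    "tca0_mm2": 0.01,
    "d_la_mm2": 0.01,
    "d_sa_mm2": 0.01,
    "d_tca_mm2": 0.01,
    "sfct0_um": 10.0,
    "d_sfct_um": 10.0,
}

MODEL1_PREDICTORS = ("cvi0_pct", "la0_mm2", "d_la_mm2", "d_sa_mm2")
MODEL2_PREDICTORS = ("cvi0_pct", "la0_mm2", "d_sfct_um")

DEFAULT_SCREEN_VARIABLES = (
    "age_years", "ser_d", "al_mm", "k_d",
    "la0_mm2", "sa0_mm2", "tca0_mm2", "sfct0_um", "cvi0_pct", "ccfd0_pct",
    "d_la_mm2", "d_sa_mm2", "d_tca_mm2", "d_sfct_um", "d_cvi_pct",
    "d_ccfd_pct", "d_k_d",
)

_SHAPIRO_ALPHA = 0.05
_SHAPIRO_MAX_N = 5000  # W statistic p-values are unreliable beyond this


def annualize_elongation(delta_al_mm, wear_days):
    """AL change scaled to a 365-day year of actual lens wear (mm/year)."""
    delta_al_mm = np.asarray(delta_al_mm, dtype=float)
    wear_days = np.asarray(wear_days, dtype=float)
    if np.any(wear_days <= 0):
        raise ValueError("wear_days must be positive")
    out = delta_al_mm * 365.0 / wear_days
    return float(out) if out.ndim == 0 else out


def dichotomize_by_median(values) -> tuple[float, np.ndarray]:
    """Median split of the outcome into slow (<= median) and fast groups.

    Returns the median (mean of the middle two for even n) and an array of
    ``"slow"`` / ``"fast"`` labels.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot dichotomize an empty array")
    med = float(np.median(values))
    labels = np.where(values <= med, "slow", "fast")
    return med, labels


def _slow_bool(labels) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.dtype == bool:
        return labels
    return labels == "slow"


def _is_normal(x: np.ndarray) -> bool:
    x = np.asarray(x, dtype=float)
    if x.size < 3 or np.ptp(x) == 0:
        return False
    if x.size > _SHAPIRO_MAX_N:
        x = x[:_SHAPIRO_MAX_N]
    return sps.shapiro(x).pvalue > _SHAPIRO_ALPHA


@dataclass
class ScreenResult:
    variable: str
    method: str  # "pearson" or "spearman"
    r: float
    p: float
    n: int
    selected: bool


def screen_univariable(
    table: pd.DataFrame,
    outcome: str = OUTCOME,
    variables: tuple[str, ...] | None = None,
    alpha: float = 0.05,
) -> list[ScreenResult]:
    """Correlate each candidate variable with the outcome.

    Pearson when both the variable and the outcome pass Shapiro-Wilk
    normality (alpha 0.05), Spearman otherwise; ``selected`` flags
    P < ``alpha``.  Constant variables are reported with NaN and a warning.
    """
    if variables is None:
        variables = tuple(v for v in DEFAULT_SCREEN_VARIABLES if v in table)
    results = []
    for var in variables:
        sub = table[[var, outcome]].dropna()
        x = sub[var].to_numpy(dtype=float)
        y = sub[outcome].to_numpy(dtype=float)
        if x.size < 3:
            raise ValueError(f"fewer than 3 complete pairs for {var!r}")
        if np.ptp(x) == 0:
            warnings.warn(f"variable {var!r} is constant; correlation "
                          "undefined", stacklevel=2)
            results.append(ScreenResult(var, "pearson", float("nan"),
                                        float("nan"), x.size, False))
            continue
        if _is_normal(x) and _is_normal(y):
            r, p = sps.pearsonr(x, y)
            method = "pearson"
        else:
            r, p = sps.spearmanr(x, y)
            method = "spearman"
        results.append(ScreenResult(var, method, float(r), float(p),
                                    x.size, bool(p < alpha)))
    return results


@dataclass
class GroupComparison:
    variable: str
    test: str  # "t", "mannwhitney", "chi2"
    p: float
    group_a: dict
    group_b: dict
    statistic: float


def compare_groups(
    table: pd.DataFrame,
    labels,
    variables: tuple[str, ...] | None = None,
) -> list[GroupComparison]:
    """Compare slow vs fast groups variable by variable.

    Continuous variables use an independent t-test when both groups pass
    Shapiro-Wilk normality, Mann-Whitney otherwise; categorical variables
    use the chi-squared test on the contingency table.
    """
    slow = _slow_bool(labels)
    if slow.all() or (~slow).all():
        raise ValueError("both groups must be non-empty")
    if variables is None:
        variables = tuple(
            v for v in ("sex",) + DEFAULT_SCREEN_VARIABLES if v in table
        )
    results = []
    for var in variables:
        col = table[var]
        categorical = (col.dtype == object or col.dtype.name == "category"
                       or col.dtype == bool)
        if categorical:
            ctab = pd.crosstab(slow, col)
            chi2, p, _, _ = sps.chi2_contingency(ctab)
            results.append(GroupComparison(
                var, "chi2", float(p),
                group_a={"counts": col[slow].value_counts().to_dict()},
                group_b={"counts": col[~slow].value_counts().to_dict()},
                statistic=float(chi2),
            ))
            continue
        a = col[slow].to_numpy(dtype=float)
        b = col[~slow].to_numpy(dtype=float)
        if a.size < 2 or b.size < 2:
            raise ValueError(
                f"group with fewer than 2 observations for continuous "
                f"variable {var!r}"
            )
        summ_a = {"mean": float(a.mean()), "sd": float(a.std(ddof=1)),
                  "n": int(a.size)}
        summ_b = {"mean": float(b.mean()), "sd": float(b.std(ddof=1)),
                  "n": int(b.size)}
        if _is_normal(a) and _is_normal(b):
            stat, p = sps.ttest_ind(a, b)
            test = "t"
        else:
            stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
            test = "mannwhitney"
        results.append(GroupComparison(var, test, float(p), summ_a, summ_b,
                                       float(stat)))
    return results


# ---------------------------------------------------------------------------
# multivariable linear models
# ---------------------------------------------------------------------------

@dataclass
class LinearFit:
    model_label: str
    terms: list[dict]  # name, beta, ci_low, ci_high, p, unit
    n: int
    r_squared: float
    vif: dict[str, float]

    def term(self, name: str) -> dict:
        for t in self.terms:
            if t["name"] == name:
                return t
        raise KeyError(name)


def _design(table: pd.DataFrame, predictors, covariates) -> pd.DataFrame:
    X = pd.DataFrame(index=table.index)
    for p in predictors:
        X[p] = table[p].astype(float) / PREDICTOR_UNITS.get(p, 1.0)
    for c in covariates:
        if c == "sex":
            X["sex_male"] = (table["sex"] == "male").astype(float)
        else:
            X[c] = table[c].astype(float)
    return X


def fit_linear_model(
    table: pd.DataFrame,
    predictors,
    outcome: str = OUTCOME,
    covariates: tuple[str, ...] = ("age_years", "sex"),
    model_label: str = "model",
    vif_warn: float = 5.0,
) -> LinearFit:
    """Age- and sex-adjusted OLS of annualized elongation on scaled predictors.

    Predictor scaling: choroidal areas per 0.01 mm^2, SFCT per 10 um, CVI
    per 1 %.  Coefficients are reported with 95% confidence intervals and
    two-sided P values; variance inflation factors above ``vif_warn``
    trigger a collinearity warning.
    """
    cols = list(predictors) + [c for c in covariates] + [outcome]
    data = table[[c for c in dict.fromkeys(cols)]].dropna()
    X = _design(data, predictors, covariates)
    y = data[outcome].astype(float)
    if len(data) < X.shape[1] + 2:
        raise ValueError(
            f"only {len(data)} complete cases for {X.shape[1]} predictors"
        )

    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        corr = np.corrcoef(X.to_numpy(), rowvar=False)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.nanargmax(np.abs(corr)), corr.shape)
        raise ValueError(
            f"rank-deficient design matrix; most collinear columns: "
            f"{X.columns[i]!r} and {X.columns[j]!r}"
        )

    vif = {}
    if X.shape[1] > 1:
        arr = sm.add_constant(X.to_numpy())
        for idx, name in enumerate(X.columns):
            vif[name] = float(variance_inflation_factor(arr, idx + 1))
        high = {k: v for k, v in vif.items() if v > vif_warn}
        if high:
            warnings.warn(
                f"high collinearity (VIF > {vif_warn}) for: {sorted(high)}",
                stacklevel=2,
            )

    fit = sm.OLS(y, sm.add_constant(X)).fit()
    ci = fit.conf_int(alpha=0.05)
    terms = []
    for name in ["const"] + list(X.columns):
        terms.append({
            "name": name,
            "beta": float(fit.params[name]),
            "ci_low": float(ci.loc[name, 0]),
            "ci_high": float(ci.loc[name, 1]),
            "p": float(fit.pvalues[name]),
            "unit": PREDICTOR_UNITS.get(name, 1.0),
        })
    return LinearFit(model_label=model_label, terms=terms, n=len(data),
                     r_squared=float(fit.rsquared), vif=vif)


# ---------------------------------------------------------------------------
# discrimination: AUC / ROC / DeLong / IDI
# ---------------------------------------------------------------------------

def auc_rank(scores, positive) -> float:
    """AUC by the rank (Mann-Whitney) formulation; ties count 1/2."""
    scores = np.asarray(scores, dtype=float)
    positive = _slow_bool(positive)
    m = int(positive.sum())
    n = int((~positive).sum())
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    ranks = sps.rankdata(scores)
    return float((ranks[positive].sum() - m * (m + 1) / 2.0) / (m * n))


def _delong_placements(scores: np.ndarray, positive: np.ndarray):
    """Placement values and AUC (Sun-Xu midrank formulation)."""
    x = scores[positive]
    y = scores[~positive]
    m, n = x.size, y.size
    tx = sps.rankdata(x)
    ty = sps.rankdata(y)
    tz = sps.rankdata(np.concatenate([x, y]))
    v01 = (tz[:m] - tx) / n  # one placement per positive
    v10 = 1.0 - (tz[m:] - ty) / m  # one per negative
    auc = float(v01.mean())
    return v01, v10, auc


def delong_variance(scores, positive) -> tuple[float, float]:
    """(AUC, DeLong variance) for one score vector."""
    positive = _slow_bool(positive)
    v01, v10, auc = _delong_placements(np.asarray(scores, float), positive)
    s01 = v01.var(ddof=1) if v01.size > 1 else 0.0
    s10 = v10.var(ddof=1) if v10.size > 1 else 0.0
    return auc, s01 / v01.size + s10 / v10.size


@dataclass
class LogisticFit:
    """A fitted logistic model for slow progression."""

    predictors: tuple[str, ...]
    params: dict[str, float]  # includes "const"; per scaled predictor unit
    model_label: str = "logistic"

    def linear_predictor(self, table: pd.DataFrame) -> np.ndarray:
        X = _design(table, [p for p in self.predictors if p != "sex"],
                    ["sex"] if "sex" in self.predictors else [])
        lp = np.full(len(X), self.params["const"])
        for name in X.columns:
            lp = lp + self.params[name] * X[name].to_numpy()
        return lp

    def predict_proba(self, table: pd.DataFrame) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.linear_predictor(table)))


@dataclass
class RocCurve:
    auc: float
    ci_low: float
    ci_high: float
    fpr: np.ndarray
    tpr: np.ndarray
    model_label: str
    scores: np.ndarray = field(repr=False, default=None)
    positive: np.ndarray = field(repr=False, default=None)
    model: LogisticFit | None = None


def roc_from_scores(scores, labels, model_label: str = "score") -> RocCurve:
    """ROC of a raw score for discriminating slow progression.

    AUC by the rank formulation, 95% CI from the DeLong variance, and the
    full (FPR, TPR) staircase over all score thresholds.
    """
    scores = np.asarray(scores, dtype=float)
    positive = _slow_bool(labels)
    if positive.sum() < 2 or (~positive).sum() < 2:
        raise ValueError("each class needs at least 2 members")
    auc, var = delong_variance(scores, positive)
    half = 1.959963984540054 * np.sqrt(var)

    order = np.argsort(-scores, kind="stable")
    sorted_pos = positive[order]
    tps = np.cumsum(sorted_pos)
    fps = np.cumsum(~sorted_pos)
    # collapse tied thresholds
    distinct = np.nonzero(np.diff(scores[order]))[0]
    idx = np.r_[distinct, sorted_pos.size - 1]
    tpr = np.r_[0.0, tps[idx] / positive.sum()]
    fpr = np.r_[0.0, fps[idx] / (~positive).sum()]
    return RocCurve(
        auc=auc,
        ci_low=max(0.0, auc - half),
        ci_high=min(1.0, auc + half),
        fpr=fpr,
        tpr=tpr,
        model_label=model_label,
        scores=scores,
        positive=positive,
    )


def fit_logistic_and_roc(
    table: pd.DataFrame,
    predictors,
    labels,
    model_label: str = "logistic",
) -> RocCurve:
    """Maximum-likelihood logistic fit of slow progression + its ROC.

    Predictors are scaled as in :func:`fit_linear_model`; ``sex`` may be
    included and is coded male = 1.  The returned curve carries the fitted
    :class:`LogisticFit` (used for nomogram construction and IDI).
    """
    positive = _slow_bool(labels)
    plain = [p for p in predictors if p != "sex"]
    covs = ["sex"] if "sex" in predictors else []
    X = _design(table, plain, covs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # separation warnings on toy data
        logit = sm.Logit(positive.astype(float), sm.add_constant(X))
        try:
            fit = logit.fit(disp=0, maxiter=200)
        except Exception:
            # Newton's Hessian is singular under (near-)perfect separation;
            # BFGS still yields a usable diverging direction
            fit = logit.fit(disp=0, maxiter=500, method="bfgs")
    params = {k: float(v) for k, v in fit.params.items()}
    model = LogisticFit(predictors=tuple(predictors), params=params,
                        model_label=model_label)
    probs = model.predict_proba(table)
    roc = roc_from_scores(probs, positive, model_label)
    roc.model = model
    return roc


def delong_compare(roc_a: RocCurve, roc_b: RocCurve) -> tuple[float, float]:
    """Paired DeLong test between two ROC curves on the same subjects.

    Returns (AUC_a - AUC_b, two-sided P).  The covariance of the two AUCs
    is estimated from the per-subject placement values.
    """
    if roc_a.scores is None or roc_b.scores is None:
        raise ValueError("ROC curves must carry their scores")
    if roc_a.scores.size != roc_b.scores.size or \
            not np.array_equal(roc_a.positive, roc_b.positive):
        raise ValueError("DeLong comparison requires the same subjects and "
                         "labels in both models")
    positive = roc_a.positive
    v01a, v10a, auc_a = _delong_placements(roc_a.scores, positive)
    v01b, v10b, auc_b = _delong_placements(roc_b.scores, positive)
    m, n = v01a.size, v10a.size
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    S = s01 / m + s10 / n
    d = auc_a - auc_b
    var = S[0, 0] + S[1, 1] - 2.0 * S[0, 1]
    if var <= 0 or abs(d) < 1e-15:
        return float(d), 1.0 if abs(d) < 1e-15 else 0.0
    z = d / np.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return float(d), float(p)


@dataclass
class IdiResult:
    idi: float
    ci_low: float
    ci_high: float
    z: float
    p: float


def compute_idi(p_new, p_old, labels) -> IdiResult:
    """Integrated discrimination improvement of a new model over an old one.

    IDI = [mean(p_new | slow) - mean(p_new | fast)]
        - [mean(p_old | slow) - mean(p_old | fast)],
    with the asymptotic two-sample SE on the per-subject probability
    differences and a two-sided Z test.
    """
    p_new = np.asarray(p_new, dtype=float)
    p_old = np.asarray(p_old, dtype=float)
    if np.any((p_new < 0) | (p_new > 1) | (p_old < 0) | (p_old > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    positive = _slow_bool(labels)
    if positive.sum() == 0 or (~positive).sum() == 0:
        raise ValueError("both classes must be present")
    d = p_new - p_old
    d_slow = d[positive]
    d_fast = d[~positive]
    idi = float(d_slow.mean() - d_fast.mean())
    var = 0.0
    if d_slow.size > 1:
        var += d_slow.var(ddof=1) / d_slow.size
    if d_fast.size > 1:
        var += d_fast.var(ddof=1) / d_fast.size
    se = float(np.sqrt(var))
    if se == 0.0:
        warnings.warn("degenerate probabilities: IDI SE is zero, P "
                      "undefined", stacklevel=2)
        return IdiResult(idi, idi, idi, float("nan"), float("nan"))
    z = idi / se
    p = 2.0 * sps.norm.sf(abs(z))
    half = 1.959963984540054 * se
    return IdiResult(idi, idi - half, idi + half, float(z), float(p))
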