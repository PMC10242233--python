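"""Nomogram construction from a fitted logistic model.

A nomogram maps each predictor value to a point score on a shared 0-100
scale (100 points = the widest coefficient-times-range effect among the
predictors), so that the sum of points is an affine transform of the
logistic linear predictor and can be mapped back to a predicted
probability of slow axial-length progression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .stats import LogisticFit, PREDICTOR_UNITS

__all__ = ["NomogramModel", "build_nomogram", "score_subject",
           "render_nomogram"]


@dataclass
class NomogramModel:
    """Point scales of a logistic prediction model.

    For predictor ``j`` with coefficient ``beta_j`` (per scaled unit) over
    the declared scaled range ``[lo_j, hi_j]``::

        points_j(v) = 100 * (beta_j * v - min(beta_j*lo_j, beta_j*hi_j)) / C
        C = max_j |beta_j| * (hi_j - lo_j)

    so every variable scores 0 at the range end that argues against slow
    progression and the widest-effect variable spans exactly 100 points.
    The total maps back through ``lp = base_lp + C * total / 100`` and the
    logistic inverse.
    """

    terms: list[dict]  # name, beta, lo, hi (scaled units), unit
    intercept: float
    points_scale: float  # C: linear-predictor span of 100 points
    base_lp: float  # intercept + sum of minimal contributions

    def to_dict(self) -> dict:
        return {
            "terms": self.terms,
            "intercept": self.intercept,
            "points_scale": self.points_scale,
            "base_lp": self.base_lp,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NomogramModel":
        return cls(terms=d["terms"], intercept=d["intercept"],
                   points_scale=d["points_scale"], base_lp=d["base_lp"])

    def points_for(self, name: str, value: float) -> float:
        """Points of one predictor at a raw (unscaled) value."""
        for t in self.terms:
            if t["name"] == name:
                v = value / t["unit"]
                lo, hi = t["lo"], t["hi"]
                if not lo <= v <= hi:
                    warnings.warn(
                        f"{name} = {value} outside the declared range; "
                        "clamped", stacklevel=2,
                    )
                    v = min(max(v, lo), hi)
                c_min = min(t["beta"] * lo, t["beta"] * hi)
                return 100.0 * (t["beta"] * v - c_min) / self.points_scale
        raise KeyError(name)

    def probability(self, total_points: float) -> float:
        lp = self.base_lp + self.points_scale * total_points / 100.0
        return float(1.0 / (1.0 + np.exp(-lp)))


def build_nomogram(
    fit: LogisticFit,
    ranges: dict[str, tuple[float, float]],
) -> NomogramModel:
    """Construct the point scales of a fitted logistic model.

    ``ranges`` gives each predictor's raw (unscaled) value range, e.g. the
    observed cohort min/max; binary sex uses (0, 1) with male = 1.
    """
    terms = []
    spans = []
    for name in fit.predictors:
        key = "sex_male" if name == "sex" else name
        beta = fit.params[key]
        unit = PREDICTOR_UNITS.get(name, 1.0)
        lo_raw, hi_raw = ranges[name]
        lo, hi = sorted((lo_raw / unit, hi_raw / unit))
        if not np.isfinite([lo, hi]).all():
            raise ValueError(f"range for {name!r} must be finite")
        terms.append({"name": name, "beta": float(beta), "lo": float(lo),
                      "hi": float(hi), "unit": unit})
        spans.append(abs(beta) * (hi - lo))
    C = float(max(spans))
    if C <= 0:
        raise ValueError("all predictors have zero effect span; nomogram "
                         "undefined")
    base_lp = fit.params["const"] + sum(
        min(t["beta"] * t["lo"], t["beta"] * t["hi"]) for t in terms
    )
    return NomogramModel(terms=terms, intercept=float(fit.params["const"]),
                         points_scale=C, base_lp=float(base_lp))


def score_subject(
    nomogram: NomogramModel,
    values: dict[str, float],
) -> tuple[dict[str, float], float, float]:
    """Per-variable points, total points and predicted probability.

    ``values`` are raw (unscaled) predictor values; ``sex`` may be given
    as "male"/"female" or 1/0.
    """
    points = {}
    for t in nomogram.terms:
        name = t["name"]
        v = values[name]
        if name == "sex" and isinstance(v, str):
            v = 1.0 if v == "male" else 0.0
        points[name] = nomogram.points_for(name, float(v))
    total = float(sum(points.values()))
    prob = nomogram.probability(total)
    return points, total, prob


def render_nomogram(nomogram: NomogramModel, path: str) -> None:
    """Draw the nomogram axes (points scale, one axis per variable,
    total-points axis and probability axis) to an image file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n_var = len(nomogram.terms)
    fig, ax = plt.subplots(figsize=(8, 1.2 * (n_var + 3)))
    ax.set_xlim(-0.18, 1.02)
    ax.axis("off")
    rows = n_var + 3

    def axis_line(y, ticks, tick_labels, label):
        ax.plot([0, 1], [y, y], color="k", lw=1)
        for t, s in zip(ticks, tick_labels):
            ax.plot([t, t], [y - 0.06, y + 0.06], color="k", lw=0.8)
            ax.text(t, y + 0.10, s, ha="center", va="bottom", fontsize=7)
        ax.text(-0.02, y, label, ha="right", va="center", fontsize=9)

    y = rows
    axis_line(y, np.linspace(0, 1, 11),
              [f"{p:.0f}" for p in np.linspace(0, 100, 11)], "Points")
    for t in nomogram.terms:
        y -= 1
        c_min = min(t["beta"] * t["lo"], t["beta"] * t["hi"])
        span = abs(t["beta"]) * (t["hi"] - t["lo"])
        vals = np.linspace(t["lo"], t["hi"], 6) * t["unit"]
        pos = [(t["beta"] * v / t["unit"] - c_min) / nomogram.points_scale
               for v in vals]
        order = np.argsort(pos)
        axis_line(y, np.array(pos)[order],
                  [f"{vals[i]:.3g}" for i in order], t["name"])
        del span
    y -= 1
    max_total = 100.0 * sum(
        abs(t["beta"]) * (t["hi"] - t["lo"]) for t in nomogram.terms
    ) / nomogram.points_scale
    totals = np.linspace(0, max_total, 9)
    axis_line(y, totals / max_total, [f"{v:.0f}" for v in totals],
              "Total points")
    y -= 1
    probs = np.array([nomogram.probability(v) for v in totals])
    axis_line(y, totals / max_total, [f"{p:.2f}" for p in probs],
              "P(slow progression)")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
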