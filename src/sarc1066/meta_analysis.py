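"""Fixed-effects inverse-variance meta-analysis with Higgins I².

Per-site estimates are pooled with weights w_i = 1/se_i²:

    pooled = Σ w_i θ_i / Σ w_i,   se(pooled) = (Σ w_i)^(−1/2)

Heterogeneity: Cochran's Q = Σ w_i (θ_i − pooled)², Higgins
I² = max(0, 100·(Q − (k−1))/Q) with a chi-square(k−1) p-value; I² below
50 % is classed low, 50–75 % moderate, 75 %+ high. Logistic terms are
pooled on the log-odds scale and reported exponentiated — odds ratios are
never averaged directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .association_models import SiteFit

__all__ = ["PooledEstimate", "pool_fixed", "heterogeneity",
           "build_pooled_tables", "format_pooled_table"]

_Z = stats.norm.ppf(0.975)


@dataclass
class PooledEstimate:
    outcome: str
    stratum: str
    term: str
    k: int
    estimate: float          # linear or log-odds scale
    se: float
    ci_low: float
    ci_high: float
    q: float
    i2: float                # percent
    q_pvalue: float
    het_class: str
    exponentiated: bool = False

    @property
    def or_(self) -> float:
        return float(np.exp(self.estimate))

    @property
    def or_ci(self) -> tuple[float, float]:
        return float(np.exp(self.ci_low)), float(np.exp(self.ci_high))


def _het_class(i2: float) -> str:
    if i2 >= 75.0:
        return "high"
    if i2 >= 50.0:
        return "moderate"
    return "low"


def pool_fixed(estimates, ses, *, outcome: str = "", stratum: str = "",
               term: str = "", exponentiated: bool = False) -> PooledEstimate:
    """Inverse-variance fixed-effects pool of k site estimates."""
    theta = np.asarray(estimates, dtype=float)
    se = np.asarray(ses, dtype=float)
    if theta.shape != se.shape or theta.ndim != 1:
        raise ValueError("estimates and ses must be equal-length vectors")
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    k = len(theta)
    if k == 0:
        raise ValueError("nothing to pool")
    if k == 1:
        warnings.warn(f"{term}: single estimate; passing through unpooled", stacklevel=2)
        return PooledEstimate(outcome, stratum, term, 1, float(theta[0]), float(se[0]),
                              float(theta[0] - _Z * se[0]), float(theta[0] + _Z * se[0]),
                              np.nan, np.nan, np.nan, "n/a", exponentiated)
    w = 1.0 / se ** 2
    pooled = float(np.sum(w * theta) / np.sum(w))
    pooled_se = float(np.sum(w) ** -0.5)
    q, i2, p, cls = heterogeneity(theta, se, pooled)
    return PooledEstimate(
        outcome, stratum, term, k, pooled, pooled_se,
        pooled - _Z * pooled_se, pooled + _Z * pooled_se,
        q, i2, p, cls, exponentiated,
    )


def heterogeneity(estimates, ses, pooled: float | None = None):
    """Cochran's Q, Higgins I² (percent, floored at 0), p-value, class."""
    theta = np.asarray(estimates, dtype=float)
    se = np.asarray(ses, dtype=float)
    k = len(theta)
    if k < 2:
        raise ValueError("heterogeneity needs k >= 2")
    w = 1.0 / se ** 2
    if pooled is None:
        pooled = float(np.sum(w * theta) / np.sum(w))
    q = float(np.sum(w * (theta - pooled) ** 2))
    i2 = 0.0 if q == 0.0 else max(0.0, 100.0 * (q - (k - 1)) / q)
    p = float(stats.chi2.sf(q, k - 1))
    return q, i2, p, _het_class(i2)


def build_pooled_tables(site_fits: list[SiteFit]) -> pd.DataFrame:
    """One pooled row per outcome × stratum × term across non-flagged fits.

    Flagged site fits (separation, non-convergence, too few cases) are
    excluded from every term they touch; a term present in fewer than two
    sites is passed through with ``k = 1`` and a flag in ``het_class``.
    Logistic outcomes are pooled on the log-odds scale (``exponentiated``
    marks rows whose estimate should be read as exp()).
    """
    rows = []
    usable = [f for f in site_fits if f.ok]
    keys = sorted({(f.outcome, f.stratum) for f in usable})
    for outcome, stratum in keys:
        group = [f for f in usable if (f.outcome, f.stratum) == (outcome, stratum)]
        terms: list[str] = []
        for f in group:
            for t in f.params["term"]:
                if t not in terms:
                    terms.append(t)
        for term in terms:
            est, ses_ = [], []
            for f in group:
                row = f.params[f.params["term"] == term]
                if len(row) == 1 and np.isfinite(row["se"].iloc[0]) and row["se"].iloc[0] > 0:
                    est.append(float(row["estimate"].iloc[0]))
                    ses_.append(float(row["se"].iloc[0]))
            if not est:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pooled = pool_fixed(est, ses_, outcome=outcome, stratum=stratum,
                                    term=term, exponentiated=outcome != "smi")
            rows.append(vars(pooled))
    return pd.DataFrame(rows)


def format_pooled_table(pooled: pd.DataFrame) -> str:
    """Markdown rendering: coefficients to 3 dp, ORs to 2 dp, I² to 1 dp."""
    lines = []
    for (outcome, stratum), sub in pooled.groupby(["outcome", "stratum"]):
        lines.append(f"\n### {outcome} ({stratum})\n")
        lines.append("| term | k | estimate (95% CI) | I² (p) |")
        lines.append("|---|---|---|---|")
        for _, r in sub.iterrows():
            if r["exponentiated"]:
                est = (f"{np.exp(r['estimate']):.2f} "
                       f"({np.exp(r['ci_low']):.2f}, {np.exp(r['ci_high']):.2f})")
            else:
                est = f"{r['estimate']:.3f} ({r['ci_low']:.3f}, {r['ci_high']:.3f})"
            i2 = "–" if not np.isfinite(r["i2"]) else f"{r['i2']:.1f}% ({r['q_pvalue']:.3f})"
            lines.append(f"| {r['term']} | {r['k']} | {est} | {i2} |")
    return "\n".join(lines)
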