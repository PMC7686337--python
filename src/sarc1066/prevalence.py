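"""Crude per-site prevalence with Wald 95% confidence intervals.

The Wald interval p ± z·sqrt(p(1−p)/n) is the default because it is the
form whose bounds round-trip the published per-site prevalence table;
Wilson and Clopper–Pearson intervals are available behind ``method`` for
real use. Denominators are records with a computable case flag
(complete-case) in the non-imputation path; the imputation path pools the
per-imputation proportions and Wald variances by Rubin's rules on the
proportion scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .imputation import ImputationSet, pool_rubin

__all__ = ["PrevalenceEstimate", "wald_ci", "estimate_prevalence",
           "prevalence_over_imputations", "prevalence_table"]

_Z = stats.norm.ppf(0.975)


@dataclass
class PrevalenceEstimate:
    site: str
    outcome: str
    n: int
    k: int
    p: float
    ci_low: float
    ci_high: float
    method: str = "wald"


def wald_ci(p: float, n: int, z: float = _Z) -> tuple[float, float]:
    """Normal-approximation binomial CI, clipped to [0, 1]."""
    half = z * np.sqrt(p * (1.0 - p) / n)
    return max(0.0, p - half), min(1.0, p + half)


def estimate_prevalence(flags: pd.DataFrame, site: str, outcome: str,
                        method: str = "wald") -> PrevalenceEstimate:
    """Crude prevalence of ``outcome`` in ``site`` over non-missing flags."""
    col = flags.loc[flags["site"] == site, outcome]
    col = col.dropna()
    n = len(col)
    if n == 0:
        raise ValueError(f"no records with computable {outcome} flag in {site}")
    k = int(col.sum())
    p = k / n
    if method == "wald":
        lo, hi = wald_ci(p, n)
        if k in (0, n):
            warnings.warn(
                f"{site}/{outcome}: boundary prevalence {p:.0%}; Wald CI degenerate",
                stacklevel=2,
            )
    elif method == "wilson":
        lo, hi = stats.binomtest(k, n).proportion_ci(method="wilson")
    elif method == "exact":
        lo, hi = stats.binomtest(k, n).proportion_ci(method="exact")
    else:
        raise ValueError(f"unknown CI method {method!r}")
    return PrevalenceEstimate(site=site, outcome=outcome, n=n, k=k, p=p,
                              ci_low=float(lo), ci_high=float(hi), method=method)


def prevalence_over_imputations(
    flag_tables: list[pd.DataFrame], site: str, outcome: str,
) -> PrevalenceEstimate:
    """Rubin-pooled prevalence across m completed-and-flagged datasets.

    Takes the per-imputation proportion and its Wald variance, pools on the
    proportion scale, and reports the pooled CI (clipped to [0, 1]).
    """
    ps, vs, ns = [], [], []
    for flags in flag_tables:
        est = estimate_prevalence(flags, site, outcome)
        ps.append(est.p)
        vs.append(est.p * (1 - est.p) / est.n)
        ns.append(est.n)
    pooled = pool_rubin(ps, vs)
    return PrevalenceEstimate(
        site=site, outcome=outcome, n=int(np.mean(ns)),
        k=int(round(pooled.estimate * np.mean(ns))), p=pooled.estimate,
        ci_low=max(0.0, pooled.ci_low), ci_high=min(1.0, pooled.ci_high),
        method=f"wald+rubin(m={pooled.m})",
    )


def prevalence_table(flags: pd.DataFrame,
                     outcomes=("sarcopenia", "sarcopenic_obesity"),
                     method: str = "wald") -> pd.DataFrame:
    """Per-site prevalence for each outcome, one row per site × outcome."""
    rows = []
    for site in sorted(flags["site"].unique()):
        for outcome in outcomes:
            est = estimate_prevalence(flags, site, outcome, method=method)
            rows.append(vars(est))
    return pd.DataFrame(rows)
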