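"""Multiple imputation of missing weight and Rubin's-rules combination.

Weight is the only variable imputed (the study design treats all other
model covariates complete-case). The imputation is *proper*: for each of
the m completed datasets the linear regression of weight on the auxiliary
set is refit among complete cases, the residual variance and coefficients
are drawn from their posterior under the standard noninformative prior
(scaled inverse-chi-squared for sigma^2, normal for beta given sigma^2 —
the same scheme as Stata's ``mi impute regress``), and each missing weight
is drawn from the resulting predictive normal. Imputed draws are never
truncated; implausible values (outside (25, 250) kg) are counted in the
diagnostics.

Rubin's rules: pooled estimate = mean of the m estimates; total variance
T = W + (1 + 1/m) B with W the mean within-imputation variance and B the
between-imputation sample variance; large-sample degrees of freedom
(m - 1)(1 + W / ((1 + 1/m) B))^2, collapsing to a normal interval when
B = 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import CohortTable, load_dictionary

__all__ = [
    "DEFAULT_AUXILIARIES",
    "ImputationSet",
    "RubinPooled",
    "impute_weight",
    "pool_rubin",
]

#: auxiliary variables of the weight-imputation model
DEFAULT_AUXILIARIES = (
    "age", "height", "sex", "education", "marital", "assets",
    "phys_activity", "alcohol", "smoking", "walk_time_10m",
    "dementia", "depression", "stroke", "diabetes",
)

_NUMERIC_AUX = ("age", "height", "assets", "walk_time_10m",
                "dementia", "depression", "stroke", "diabetes")


@dataclass
class RubinPooled:
    estimate: float
    within: float
    between: float
    total: float
    df: float
    ci_low: float
    ci_high: float
    m: int


@dataclass
class ImputationSet:
    """m completed datasets plus bookkeeping.

    Every originally observed cell is identical across the m tables; every
    originally missing weight is filled in each. Records that could not be
    imputed (an auxiliary itself missing) stay missing and are listed in
    ``unimputed_pids``.
    """

    m: int
    tables: list[pd.DataFrame]
    imputed_pids: tuple[str, ...]
    unimputed_pids: tuple[str, ...]
    seed: int
    auxiliaries: tuple[str, ...]
    diagnostics: dict = field(default_factory=dict)


def _design_matrix(df: pd.DataFrame, auxiliaries: Sequence[str]) -> tuple[np.ndarray, list[str]]:
    """Reference-coded design matrix (reference = first enum category)."""
    enums = load_dictionary().enums
    cols: list[np.ndarray] = [np.ones(len(df))]
    names = ["const"]
    for aux in auxiliaries:
        if aux in _NUMERIC_AUX:
            cols.append(df[aux].to_numpy(dtype=float))
            names.append(aux)
        elif aux in enums:
            for level in enums[aux][1:]:
                cols.append((df[aux].to_numpy() == level).astype(float))
                names.append(f"{aux}[{level}]")
        else:
            raise ValueError(f"unknown auxiliary {aux!r}")
    return np.column_stack(cols), names


def impute_weight(
    table: CohortTable,
    m: int = 50,
    seed: int = 0,
    auxiliaries: Sequence[str] = DEFAULT_AUXILIARIES,
) -> ImputationSet:
    """Proper normal-model multiple imputation of missing weight.

    Deterministic given ``seed``. Raises if the complete cases cannot
    support the regression (fewer than predictors + 2 rows); a table with
    no missing weight returns m identical copies with a warning.
    """
    if m < 2:
        raise ValueError("m must be >= 2")
    df = table.df
    missing = df["weight"].isna()
    if not missing.any():
        warnings.warn("no missing weight; returning m identical copies", stacklevel=2)
        return ImputationSet(
            m=m, tables=[df.copy() for _ in range(m)],
            imputed_pids=(), unimputed_pids=(), seed=seed,
            auxiliaries=tuple(auxiliaries),
            diagnostics={"note": "no missing weight"},
        )

    aux_complete = df[list(auxiliaries)].notna().all(axis=1)
    donors = (~missing) & aux_complete
    targets = missing & aux_complete
    unimputed = missing & ~aux_complete

    X_all, names = _design_matrix(df, auxiliaries)
    X = X_all[donors.to_numpy()]
    y = df.loc[donors, "weight"].to_numpy(dtype=float)
    n, p = X.shape
    if n < p + 2:
        raise ValueError(
            f"only {n} complete cases for {p} predictors; cannot impute"
        )

    XtX = X.T @ X
    XtX_inv = np.linalg.pinv(XtX)
    beta_hat = XtX_inv @ (X.T @ y)
    resid = y - X @ beta_hat
    rss = float(resid @ resid)
    nu = n - p
    r2 = 1.0 - rss / float(((y - y.mean()) ** 2).sum())

    L = np.linalg.cholesky(XtX_inv + 1e-12 * np.eye(p))
    X_mis = X_all[targets.to_numpy()]
    rng = np.random.default_rng(seed)

    tables: list[pd.DataFrame] = []
    flagged = []
    for _ in range(m):
        sigma2 = rss / rng.chisquare(nu)
        beta = beta_hat + np.sqrt(sigma2) * (L @ rng.standard_normal(p))
        draws = X_mis @ beta + np.sqrt(sigma2) * rng.standard_normal(len(X_mis))
        flagged.append(int(((draws < 25.0) | (draws > 250.0)).sum()))
        completed = df.copy()
        completed.loc[targets, "weight"] = draws
        tables.append(completed)

    return ImputationSet(
        m=m,
        tables=tables,
        imputed_pids=tuple(df.loc[targets, "pid"]),
        unimputed_pids=tuple(df.loc[unimputed, "pid"]),
        seed=seed,
        auxiliaries=tuple(auxiliaries),
        diagnostics={
            "n_complete_cases": int(n),
            "n_imputed": int(targets.sum()),
            "n_unimputed": int(unimputed.sum()),
            "r2_complete_case": float(r2),
            "implausible_draws_per_imputation": flagged,
            "terms": names,
        },
    )


def pool_rubin(estimates: Sequence[float], variances: Sequence[float],
               alpha: float = 0.05) -> RubinPooled:
    """Combine m point estimates and their variances by Rubin's rules."""
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    if q.shape != u.shape:
        raise ValueError("estimates and variances differ in length")
    m = len(q)
    if m < 2:
        raise ValueError("need at least 2 imputations to pool")
    est = float(q.mean())
    within = float(u.mean())
    between = float(q.var(ddof=1))
    total = within + (1.0 + 1.0 / m) * between
    if between > 0:
        df = (m - 1) * (1.0 + within / ((1.0 + 1.0 / m) * between)) ** 2
        crit = stats.t.ppf(1.0 - alpha / 2.0, df)
    else:
        df = np.inf
        crit = stats.norm.ppf(1.0 - alpha / 2.0)
    half = crit * np.sqrt(total)
    return RubinPooled(
        estimate=est, within=within, between=between, total=total,
        df=float(df), ci_low=est - half, ci_high=est + half, m=m,
    )
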