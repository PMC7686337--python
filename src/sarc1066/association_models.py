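"""Per-site multivariable models.

Two model families, mirroring the analysis plan:

* linear regression of SMI, fitted separately per gender within each site
  (SMI is not normal in the pooled sample), on age, education, marital
  status, number of assets, %BF, physical activity, alcohol, smoking and
  limiting impairments, adjusted for dementia, depression, diabetes and
  stroke;
* logistic regression of sarcopenia / sarcopenic obesity per site on the
  same covariates plus sex (%BF is excluded from the sarcopenic-obesity
  model, whose definition already conditions on high %BF).

Categoricals are reference-coded (education ref = none, marital ref =
never, activity ref = low, alcohol ref = no/heavy, smoking ref = never,
impairments ref = none, sex ref = female); age in single years and assets
as a 0–7 count. Complete-case within stratum for covariates other than
weight; weight missingness is the imputation module's business.

Fits are never silently wrong: rank-deficient terms are dropped with a
warning and recorded, non-convergence and (quasi-)separation are flagged,
and flagged fits are excluded from meta-analytic pooling downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .data_model import load_dictionary
from .imputation import pool_rubin

__all__ = ["ModelSpec", "SiteFit", "default_spec", "build_design",
           "fit_linear_smi", "fit_logistic_case", "fit_over_imputations",
           "fit_all_sites"]

_ADJUSTMENTS = ("dementia", "depression", "diabetes", "stroke")
_SEPARATION_COEF = 12.0
_SEPARATION_SE = 50.0


@dataclass
class ModelSpec:
    outcome: str
    covariates: tuple[str, ...]
    adjustments: tuple[str, ...] = _ADJUSTMENTS
    min_cases: int = 10
    min_rows_over_terms: int = 5

    def terms(self) -> tuple[str, ...]:
        return self.covariates + self.adjustments


def default_spec(outcome: str) -> ModelSpec:
    """The standard covariate set for each outcome."""
    base = ("age", "education", "marital", "assets", "pbf", "phys_activity",
            "alcohol", "smoking", "impairments")
    if outcome == "smi":
        return ModelSpec(outcome="smi", covariates=base)
    if outcome == "sarcopenia":
        return ModelSpec(outcome="sarcopenia", covariates=("sex",) + base)
    if outcome == "sarcopenic_obesity":
        cov = tuple(t for t in ("sex",) + base if t != "pbf")
        return ModelSpec(outcome="sarcopenic_obesity", covariates=cov)
    raise ValueError(f"unknown outcome {outcome!r}")


@dataclass
class SiteFit:
    site: str
    stratum: str                       # "female" / "male" / "all"
    outcome: str
    params: pd.DataFrame               # columns: term, estimate, se
    n: int
    ok: bool = True
    flags: dict = field(default_factory=dict)


_NUMERIC_TERMS = ("age", "assets", "pbf", "dementia", "depression",
                  "diabetes", "stroke")


def build_design(df: pd.DataFrame, terms) -> pd.DataFrame:
    """Reference-coded design matrix with intercept, as a named DataFrame."""
    enums = load_dictionary().enums
    out = {"const": np.ones(len(df))}
    for t in terms:
        if t in _NUMERIC_TERMS:
            out[t] = df[t].to_numpy(dtype=float)
        elif t in enums:
            for level in enums[t][1:]:
                out[f"{t}[{level}]"] = (df[t].to_numpy() == level).astype(float)
        else:
            raise ValueError(f"unknown model term {t!r}")
    return pd.DataFrame(out, index=df.index)


def _complete_cases(df: pd.DataFrame, cols) -> pd.DataFrame:
    return df.dropna(subset=[c for c in cols if c in df.columns])


def _drop_degenerate(X: pd.DataFrame, site: str) -> tuple[pd.DataFrame, list[str]]:
    """Drop constant (empty-category) columns; the intercept stays."""
    dropped = [c for c in X.columns if c != "const" and X[c].nunique() <= 1]
    if dropped:
        warnings.warn(f"{site}: dropping degenerate term(s) {dropped}", stacklevel=3)
    return X.drop(columns=dropped), dropped


def fit_linear_smi(df: pd.DataFrame, site: str, gender: str,
                   spec: ModelSpec | None = None) -> SiteFit:
    """OLS of SMI within one site × gender stratum."""
    spec = spec or default_spec("smi")
    sub = df[(df["site"] == site) & (df["sex"] == gender)]
    sub = _complete_cases(sub, ("smi",) + spec.terms())
    X = build_design(sub, spec.terms())
    X, dropped = _drop_degenerate(X, site)
    if len(sub) < X.shape[1] + spec.min_rows_over_terms:
        raise ValueError(
            f"{site}/{gender}: {len(sub)} complete cases for {X.shape[1]} terms"
        )
    y = sub["smi"].to_numpy(dtype=float)
    flags: dict = {"dropped_terms": dropped}
    if np.ptp(y) == 0.0:
        warnings.warn(f"{site}/{gender}: constant outcome; degenerate fit", stacklevel=2)
        params = pd.DataFrame({
            "term": X.columns,
            "estimate": [y[0]] + [0.0] * (X.shape[1] - 1),
            "se": 0.0,
        })
        return SiteFit(site, gender, "smi", params, len(sub), ok=False,
                       flags={**flags, "constant_outcome": True})
    res = sm.OLS(y, X).fit()
    params = pd.DataFrame({"term": X.columns, "estimate": res.params.to_numpy(),
                           "se": res.bse.to_numpy()})
    return SiteFit(site, gender, "smi", params, int(res.nobs), ok=True, flags=flags)


def fit_logistic_case(df: pd.DataFrame, site: str,
                      spec: ModelSpec | None = None,
                      outcome: str | None = None) -> SiteFit:
    """Maximum-likelihood logistic fit of a case flag within one site.

    Separation and non-convergence produce a flagged (``ok=False``) fit
    rather than an exception, so pooling can exclude the site with a log
    entry instead of aborting a multi-site run.
    """
    spec = spec or default_spec(outcome or "sarcopenia")
    outcome = outcome or spec.outcome
    sub = df[df["site"] == site]
    sub = _complete_cases(sub, (outcome,) + spec.terms())
    y = sub[outcome].to_numpy(dtype=float)
    n_case, n_noncase = int(y.sum()), int((1 - y).sum())
    X = build_design(sub, spec.terms())
    X, dropped = _drop_degenerate(X, site)
    flags: dict = {"dropped_terms": dropped, "n_cases": n_case}
    if min(n_case, n_noncase) < spec.min_cases:
        return SiteFit(site, "all", outcome, pd.DataFrame(columns=["term", "estimate", "se"]),
                       len(sub), ok=False, flags={**flags, "insufficient_cases": True})
    # an indicator level with zero cases (or zero non-cases) among its members
    # is quasi-complete separation: its MLE diverges and stalls Newton, so the
    # term is set aside before fitting and reported with infinite SE
    def _is_indicator(col):
        v = X[col].to_numpy()
        return col != "const" and np.isin(v, (0.0, 1.0)).all() and (v == 1).any()

    sep_cols = [c for c in X.columns if _is_indicator(c)
                and (y[X[c].to_numpy() == 1].sum() == 0
                     or (1 - y[X[c].to_numpy() == 1]).sum() == 0)]
    X_fit = X.drop(columns=sep_cols)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X_fit).fit(disp=0, maxiter=200, tol=1e-8)
        converged = bool(res.mle_retvals.get("converged", True))
        bse = res.bse.to_numpy()
        est = res.params.to_numpy()
        # residual instability (huge coefficient or SE) is excluded per term:
        # infinite SE keeps it out of any pool without discarding the fit
        unstable = (np.abs(est) > _SEPARATION_COEF) | (bse > _SEPARATION_SE)
        bse = np.where(unstable, np.inf, bse)
        params = pd.DataFrame({"term": X_fit.columns, "estimate": est, "se": bse})
        if sep_cols:
            params = pd.concat([params, pd.DataFrame(
                {"term": sep_cols, "estimate": np.nan, "se": np.inf})],
                ignore_index=True)
        if unstable.any() or sep_cols:
            flags.update(separation=True, separated_terms=sorted(
                set(sep_cols) | set(np.asarray(X_fit.columns)[unstable])))
        if not converged:
            flags.update(converged=False)
        return SiteFit(site, "all", outcome, params, int(res.nobs),
                       ok=converged, flags=flags)
    except (np.linalg.LinAlgError, ValueError) as err:
        return SiteFit(site, "all", outcome, pd.DataFrame(columns=["term", "estimate", "se"]),
                       len(sub), ok=False, flags={**flags, "error": str(err)})


def fit_over_imputations(flag_tables, fit_fn, *args,
                         on_failure: str = "warn", **kwargs) -> SiteFit:
    """Fit per completed dataset and Rubin-pool each term.

    ``fit_fn`` is :func:`fit_linear_smi` or :func:`fit_logistic_case`;
    positional/keyword arguments are forwarded. A failed single-imputation
    fit is skipped with a warning (``on_failure='warn'``) or aborts
    (``'raise'``).
    """
    fits = []
    for i, t in enumerate(flag_tables):
        fit = fit_fn(t, *args, **kwargs)
        if not fit.ok:
            msg = f"imputation {i}: fit flagged {fit.flags}"
            if on_failure == "raise":
                raise RuntimeError(msg)
            warnings.warn(msg, stacklevel=2)
            continue
        fits.append(fit)
    if len(fits) < 2:
        raise RuntimeError("fewer than 2 successful imputation fits; cannot pool")
    terms = fits[0].params["term"]
    if not all(f.params["term"].equals(terms) for f in fits[1:]):
        raise RuntimeError("imputation fits disagree on model terms")
    rows = []
    for j, term in enumerate(terms):
        est = [f.params["estimate"].iloc[j] for f in fits]
        var = [f.params["se"].iloc[j] ** 2 for f in fits]
        pooled = pool_rubin(est, var)
        rows.append((term, pooled.estimate, np.sqrt(pooled.total)))
    ref = fits[0]
    params = pd.DataFrame(rows, columns=["term", "estimate", "se"])
    return SiteFit(ref.site, ref.stratum, ref.outcome, params,
                   n=int(np.mean([f.n for f in fits])), ok=True,
                   flags={"m_pooled": len(fits), "m_supplied": len(flag_tables)})


def fit_all_sites(flags: pd.DataFrame,
                  outcomes=("smi", "sarcopenia", "sarcopenic_obesity")) -> list[SiteFit]:
    """Every per-site fit the pooled tables need (linear per gender)."""
    fits: list[SiteFit] = []
    for site in sorted(flags["site"].unique()):
        if "smi" in outcomes:
            for gender in ("female", "male"):
                try:
                    fits.append(fit_linear_smi(flags, site, gender))
                except ValueError as err:
                    warnings.warn(str(err), stacklevel=2)
        for outcome in outcomes:
            if outcome == "smi":
                continue
            fits.append(fit_logistic_case(flags, site, default_spec(outcome)))
    return fits
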