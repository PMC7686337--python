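"""Stratified quintile cut-offs and case flags.

Case definitions (all quintile-based, inclusive boundaries):

* low skeletal muscle mass — SMI at or below the 20th percentile of its
  site × sex stratum (cut-offs are country-specific only for SMI, because
  body composition differs across populations);
* slow gait — gait speed at or below the 20th percentile of its
  sex × age-band × height-band stratum, pooled across sites;
* high body fat — %BF at or above the 80th percentile of its sex stratum,
  pooled across sites;
* sarcopenia = low SMM AND slow gait;
* sarcopenic obesity = sarcopenia AND high %BF.

Any missing ingredient makes the dependent flags missing. Quantiles use
linear interpolation between order statistics ("type 7") by default; the
estimator is configurable because statistical packages differ here.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "AGE_BANDS",
    "StratumError",
    "assign_age_band",
    "assign_height_band",
    "add_strata",
    "derive_cutoffs",
    "derive_all_cutoffs",
    "flag_cases",
    "FLAG_COLUMNS",
]

#: age bands used for gait stratification (also the descriptive-table bands)
AGE_BANDS = ((65, 69), (70, 74), (75, 79), (80, np.inf))

FLAG_COLUMNS = ("low_smm", "slow_gait", "high_pbf", "sarcopenia", "sarcopenic_obesity")

#: stratifiers per definition (gait and %BF pooled across sites by default)
DEFAULT_STRATA = {
    "low_smi": ("site", "sex"),
    "slow_gait": ("sex", "age_band", "height_band"),
    "high_pbf": ("sex",),
}
DEFINITION_VARS = {"low_smi": "smi", "slow_gait": "gait_speed", "high_pbf": "pbf"}
DEFINITION_LEVELS = {"low_smi": 0.20, "slow_gait": 0.20, "high_pbf": 0.80}


class StratumError(ValueError):
    pass


def assign_age_band(age) -> pd.Series:
    age = pd.Series(np.asarray(age, dtype=float))
    labels = []
    for lo, hi in AGE_BANDS:
        labels.append(f"{lo:.0f}+" if np.isinf(hi) else f"{lo:.0f}-{hi:.0f}")
    out = pd.Series(pd.NA, index=age.index, dtype=object)
    for (lo, hi), lab in zip(AGE_BANDS, labels):
        out[(age >= lo) & (age <= hi)] = lab
    return out


def assign_height_band(height, sex, n_bands: int = 3,
                       edges: dict[str, np.ndarray] | None = None):
    """Within-sex height bands (tertiles of the pooled sample by default).

    Returns ``(labels, edges)``; pass ``edges`` back in to reuse a previously
    computed grid (e.g. when re-flagging a completed dataset).
    """
    height = pd.Series(np.asarray(height, dtype=float))
    sex = pd.Series(np.asarray(sex, dtype=object), index=height.index)
    if edges is None:
        edges = {}
        for s in sex.dropna().unique():
            vals = height[(sex == s) & height.notna()]
            qs = np.linspace(0, 1, n_bands + 1)[1:-1]
            edges[str(s)] = np.quantile(vals, qs) if len(vals) else np.array([])
    labels = pd.Series(pd.NA, index=height.index, dtype=object)
    for s, e in edges.items():
        m = (sex == s) & height.notna()
        idx = np.searchsorted(e, height[m].to_numpy(), side="right")
        labels[m] = [f"H{i + 1}" for i in idx]
    return labels, edges


def add_strata(df: pd.DataFrame, height_edges=None):
    """Append ``age_band`` and ``height_band`` columns; returns (df, edges)."""
    out = df.copy()
    out["age_band"] = assign_age_band(out["age"]).to_numpy()
    bands, edges = assign_height_band(out["height"], out["sex"], edges=height_edges)
    out["height_band"] = bands.to_numpy()
    return out, edges


def derive_cutoffs(
    df: pd.DataFrame,
    definition: str,
    strata: tuple[str, ...] | None = None,
    *,
    quantile_method: str = "linear",
    min_stratum_size: int = 20,
) -> pd.DataFrame:
    """Empirical quantile threshold per stratum for one case definition.

    Missing values are excluded from the quantile computation. Strata with
    fewer contributing values than ``min_stratum_size`` keep their threshold
    but are flagged; a stratum with no non-missing values raises
    :class:`StratumError` naming it.
    """
    if definition not in DEFINITION_VARS:
        raise ValueError(f"unknown definition {definition!r}")
    strata = strata or DEFAULT_STRATA[definition]
    var = DEFINITION_VARS[definition]
    level = DEFINITION_LEVELS[definition]

    rows = []
    for key, sub in df.groupby(list(strata), dropna=False, observed=True):
        key = key if isinstance(key, tuple) else (key,)
        vals = sub[var].dropna().to_numpy()
        if len(vals) == 0:
            raise StratumError(
                f"{definition}: stratum {dict(zip(strata, key))} has no usable values"
            )
        row = dict(zip(strata, key))
        row.update(
            definition=definition,
            threshold=float(np.quantile(vals, level, method=quantile_method)),
            n=len(vals),
            level=level,
            small_stratum=len(vals) < min_stratum_size,
        )
        rows.append(row)
    cols = ["definition", *strata, "threshold", "n", "level", "small_stratum"]
    return pd.DataFrame(rows)[cols]


def derive_all_cutoffs(df: pd.DataFrame, **kwargs) -> dict[str, pd.DataFrame]:
    """Cut-off tables for all three definitions (df must carry strata columns)."""
    return {d: derive_cutoffs(df, d, **kwargs) for d in DEFINITION_VARS}


def _lookup(df: pd.DataFrame, cutoffs: pd.DataFrame, definition: str) -> np.ndarray:
    strata = [c for c in cutoffs.columns
              if c not in ("definition", "threshold", "n", "level", "small_stratum")]
    merged = df[strata].merge(
        cutoffs[strata + ["threshold"]], on=strata, how="left", validate="many_to_one"
    )
    thr = merged["threshold"].to_numpy()
    present = df[strata].notna().all(axis=1).to_numpy()
    if np.any(np.isnan(thr) & present):
        missing = df.loc[np.isnan(thr) & present, strata].drop_duplicates()
        raise StratumError(
            f"{definition}: no cut-off for strata\n{missing.to_string(index=False)}"
        )
    return thr


def flag_cases(df: pd.DataFrame, cutoffs: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Per-record case flags (1.0 / 0.0 / NaN) from derived values and cut-offs.

    Inclusive boundary rule: a value exactly at its threshold is flagged
    ("lowest quintile" includes its boundary). Composites obey the nesting
    sarcopenic_obesity ⇒ sarcopenia ⇒ low_smm exactly; a missing ingredient
    makes every flag that depends on it missing.
    """
    out = df.copy()
    smi_thr = _lookup(df, cutoffs["low_smi"], "low_smi")
    gait_thr = _lookup(df, cutoffs["slow_gait"], "slow_gait")
    pbf_thr = _lookup(df, cutoffs["high_pbf"], "high_pbf")

    smi = df["smi"].to_numpy(dtype=float)
    speed = df["gait_speed"].to_numpy(dtype=float)
    pbf = df["pbf"].to_numpy(dtype=float)

    with np.errstate(invalid="ignore"):
        low = np.where(np.isnan(smi) | np.isnan(smi_thr), np.nan,
                       (smi <= smi_thr).astype(float))
        slow = np.where(np.isnan(speed) | np.isnan(gait_thr), np.nan,
                        (speed <= gait_thr).astype(float))
        high = np.where(np.isnan(pbf) | np.isnan(pbf_thr), np.nan,
                        (pbf >= pbf_thr).astype(float))

    sarc = low * slow          # NaN-propagating logical AND on {0, 1}
    sarc_ob = sarc * high
    out["low_smm"] = low
    out["slow_gait"] = slow
    out["high_pbf"] = high
    out["sarcopenia"] = sarc
    out["sarcopenic_obesity"] = sarc_ob
    return out
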