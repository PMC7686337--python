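"""Cohort data dictionary, validation, and delimited-text I/O.

One row of a cohort table describes one study participant aged 65 or over:
site, basic anthropometry (height in metres, weight in kilograms — possibly
missing), the 10-metre walk time in seconds, socio-demographic and lifestyle
covariates, and four binary disease flags (dementia, depression, diabetes,
stroke) consumed as pre-computed indicators.

Validation is total: every input row is either accepted into the cohort or
appears exactly once in the rejects report with the offending field and
reason. Nothing is silently dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml
from scipy import stats

__all__ = [
    "DataDictionary",
    "CohortTable",
    "SchemaError",
    "load_dictionary",
    "validate_cohort",
    "read_cohort",
    "write_cohort",
    "describe_by_group",
    "GROUP_LABELS",
]

#: case-status groups used by the descriptive table
GROUP_LABELS = ("no_sarcopenia", "sarcopenia_only", "sarcopenic_obesity")

_INT_COLUMNS = ("age", "assets", "dementia", "depression", "diabetes", "stroke")
_FLOAT_COLUMNS = ("height", "weight", "walk_time_10m")


class SchemaError(ValueError):
    """A structural problem with an input table (e.g. a missing column)."""


@dataclass(frozen=True)
class DataDictionary:
    """Canonical column names, enumerations, bounds, and the site registry."""

    schema_version: str
    columns: tuple[str, ...]
    enums: Mapping[str, tuple[str, ...]]
    bounds: Mapping[str, Mapping[str, float]]
    binary_flags: tuple[str, ...]
    sites: Mapping[str, Mapping[str, str]]

    def site_ethnicity(self, site: str) -> str:
        try:
            return self.sites[site]["ethnicity"]
        except KeyError:
            return "white_hispanic"


def load_dictionary() -> DataDictionary:
    """Load the versioned data dictionary shipped with the package."""
    text = resources.files("sarc1066").joinpath("data/dictionary.yaml").read_text()
    raw = yaml.safe_load(text)
    return DataDictionary(
        schema_version=raw["schema_version"],
        columns=tuple(raw["columns"]),
        enums={k: tuple(v) for k, v in raw["enums"].items()},
        bounds=raw["bounds"],
        binary_flags=tuple(raw["binary_flags"]),
        sites=raw["sites"],
    )


_DICT = load_dictionary()


@dataclass
class CohortTable:
    """A validated person-level cohort.

    ``df`` holds one row per participant with the canonical columns of the
    data dictionary; ``rejects`` holds rows that failed validation (pid,
    field, reason), so that acceptance + rejection partition the input.
    """

    df: pd.DataFrame
    provenance: str = ""
    schema_version: str = _DICT.schema_version
    rejects: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["pid", "field", "reason"])
    )

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:  # record-identical, missing preserved
        if not isinstance(other, CohortTable):
            return NotImplemented
        try:
            pd.testing.assert_frame_equal(
                self.df.reset_index(drop=True), other.df.reset_index(drop=True)
            )
        except AssertionError:
            return False
        return True


def _row_errors(df: pd.DataFrame, dictionary: DataDictionary) -> pd.DataFrame:
    """Return one (pid, field, reason) row per invariant violation."""
    errs: list[tuple[object, str, str]] = []
    pid = df["pid"]

    age = pd.to_numeric(df["age"], errors="coerce")
    bad = age.isna() | (age < 65) | (age != np.floor(age))
    for p, a in zip(pid[bad], df["age"][bad]):
        reason = "age < 65" if pd.notna(pd.to_numeric(a, errors="coerce")) else "unparseable age"
        errs.append((p, "age", reason))

    height = pd.to_numeric(df["height"], errors="coerce")
    bad = height.isna() | (height <= 1.0) | (height >= 2.2)
    for p in pid[bad]:
        errs.append((p, "height", "height outside (1.0, 2.2) m"))

    weight = pd.to_numeric(df["weight"], errors="coerce")
    present = df["weight"].notna()
    bad = present & (weight.isna() | (weight <= 25.0) | (weight >= 250.0))
    for p in pid[bad]:
        errs.append((p, "weight", "weight outside (25, 250) kg"))

    wt10 = pd.to_numeric(df["walk_time_10m"], errors="coerce")
    present = df["walk_time_10m"].notna()
    bad = present & (wt10.isna() | (wt10 <= 0.0))
    for p in pid[bad]:
        errs.append((p, "walk_time_10m", "walk time not > 0 s"))

    assets = pd.to_numeric(df["assets"], errors="coerce")
    bad = assets.isna() | ~assets.isin(range(8))
    for p in pid[bad]:
        errs.append((p, "assets", "assets not in 0..7"))

    for col, allowed in dictionary.enums.items():
        bad = ~df[col].isin(allowed)
        for p, v in zip(pid[bad], df[col][bad]):
            errs.append((p, col, f"{v!r} not in {list(allowed)}"))

    for col in dictionary.binary_flags:
        v = pd.to_numeric(df[col], errors="coerce")
        bad = v.isna() | ~v.isin((0, 1))
        for p in pid[bad]:
            errs.append((p, col, "flag not 0/1"))

    dup = pid.duplicated(keep=False) & pid.duplicated(keep="first")
    for p in pid[dup]:
        errs.append((p, "pid", "duplicate pid"))

    return pd.DataFrame(errs, columns=["pid", "field", "reason"])


def validate_cohort(
    df: pd.DataFrame,
    dictionary: DataDictionary | None = None,
    provenance: str = "",
) -> CohortTable:
    """Validate a raw table against the data dictionary.

    Rows violating any invariant go to ``rejects`` (one entry per violation);
    the remaining rows form the cohort with canonical dtypes and column order.

    Raises
    ------
    SchemaError
        If a mandatory column is absent.
    """
    dictionary = dictionary or _DICT
    missing = [c for c in dictionary.columns if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")

    df = df[list(dictionary.columns)].copy()
    rejects = _row_errors(df, dictionary)
    bad_pids = set(rejects["pid"])
    keep = ~df["pid"].isin(bad_pids)
    clean = df[keep].copy()

    for col in _INT_COLUMNS:
        clean[col] = pd.to_numeric(clean[col]).astype(np.int64)
    for col in _FLOAT_COLUMNS:
        clean[col] = pd.to_numeric(clean[col]).astype(np.float64)
    clean["pid"] = clean["pid"].astype(str)
    for col in list(dictionary.enums) + ["site"]:
        clean[col] = clean[col].astype(str)

    return CohortTable(
        df=clean.reset_index(drop=True),
        provenance=provenance,
        schema_version=dictionary.schema_version,
        rejects=rejects.reset_index(drop=True),
    )


def read_cohort(
    path,
    delimiter: str = ",",
    column_map: Mapping[str, str] | None = None,
    dictionary: DataDictionary | None = None,
) -> CohortTable:
    """Read and validate a delimited person-level table.

    Parameters
    ----------
    path
        CSV (or other delimiter) file, UTF-8, empty fields meaning missing.
    column_map
        Optional mapping from the file's header names to canonical names.
    """
    raw = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False, na_values=[""])
    if column_map:
        raw = raw.rename(columns=dict(column_map))
    return validate_cohort(raw, dictionary=dictionary, provenance=str(path))


def write_cohort(table: CohortTable, path, delimiter: str = ",") -> None:
    """Write a cohort as delimited text, canonical column order.

    Missing values are serialised as empty fields (never ``NaN`` text), so
    write → read → write is byte-idempotent.
    """
    out = table.df[list(_DICT.columns)].copy()
    # floats printed via repr round-trip exactly; integers stay integers
    with open(path, "w", encoding="utf-8", newline="") as fh:
        out.to_csv(fh, sep=delimiter, index=False, na_rep="")


def write_rejects(table: CohortTable, path) -> None:
    table.rejects.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# descriptive table (case-status breakdown with chi-square tests)
# ---------------------------------------------------------------------------

_DESCRIPTIVE_VARS = (
    "sex", "education", "marital", "smoking", "alcohol",
    "phys_activity", "impairments",
)


def describe_by_group(
    table: CohortTable,
    grouping: pd.Series | np.ndarray | Iterable,
    variables: tuple[str, ...] = _DESCRIPTIVE_VARS,
) -> pd.DataFrame:
    """Column-percentage breakdown of categorical variables by case status.

    For every site and categorical variable, reports the percentage of each
    category within each case-status group and a chi-square test (no
    continuity correction) of homogeneity across the groups present. When any
    expected cell count is below 5 the p-value row carries a warning flag;
    with fewer than two non-empty groups the p-value is omitted.
    """
    groups = pd.Series(np.asarray(grouping, dtype=object), index=table.df.index)
    bad = groups.dropna()[~groups.dropna().isin(GROUP_LABELS)]
    if len(bad):
        raise ValueError(f"unknown group label(s): {sorted(set(bad))}")

    rows = []
    df = table.df
    for site, site_idx in df.groupby("site").groups.items():
        g = groups.loc[site_idx]
        sub = df.loc[site_idx]
        for var in variables:
            ct = pd.crosstab(sub[var], g.rename("group"))
            ct = ct.reindex(columns=[c for c in GROUP_LABELS if c in ct.columns])
            nonempty = [c for c in ct.columns if ct[c].sum() > 0]
            if len(nonempty) >= 2:
                obs = ct[nonempty].to_numpy(dtype=float)
                obs = obs[obs.sum(axis=1) > 0]
                if obs.shape[0] >= 2:
                    chi2, p, _, expected = stats.chi2_contingency(obs, correction=False)
                    low_expected = bool((expected < 5).any())
                else:
                    chi2, p, low_expected = 0.0, 1.0, False
            else:
                chi2, p, low_expected = np.nan, np.nan, False
                warnings.warn(
                    f"{site}/{var}: fewer than two non-empty groups; p-value omitted",
                    stacklevel=2,
                )
            for cat in ct.index:
                row = {"site": site, "variable": var, "category": cat}
                for grp in GROUP_LABELS:
                    if grp in ct.columns and ct[grp].sum() > 0:
                        row[f"pct_{grp}"] = 100.0 * ct.loc[cat, grp] / ct[grp].sum()
                        row[f"n_{grp}"] = int(ct.loc[cat, grp])
                    else:
                        row[f"pct_{grp}"] = np.nan
                        row[f"n_{grp}"] = int(ct.loc[cat, grp]) if grp in ct.columns else 0
                row["chi2"] = chi2
                row["p_value"] = p
                row["low_expected_count"] = low_expected
                rows.append(row)
    return pd.DataFrame(rows)
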