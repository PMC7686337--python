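"""Derived body-composition quantities.

All five operations are pure and vectorised: they accept scalars or aligned
arrays/Series and propagate missing values (NaN). Nothing is ever clipped or
dropped — out-of-range derived values are only flagged, so downstream
quantile cut-offs see exactly the data the equations produce.

The two prediction equations (both published, anthropometry-only):

* percent body fat:  %BF = 1.20·BMI + 0.23·age − 10.8·sex − 5.4
* appendicular skeletal muscle mass (kg):
  ASM = 0.244·weight + 7.80·height + 6.6·sex − 0.098·age + race − 3.3

with sex coded female = 0 / male = 1 and ``race`` an additive ethnicity
constant resolved from site configuration (0 for White/Hispanic populations;
the Asian and Black constants below follow the cited equation source, whose
secondary citations disagree on the Asian sign — the constant cancels out of
within-site quintile cut-offs either way).

SMI = ASM / BMI; gait speed = 10 m / walk time.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "ETHNICITY_CONSTANTS",
    "compute_bmi",
    "compute_pbf",
    "compute_asm",
    "compute_smi",
    "compute_gait_speed",
    "add_derived",
    "DERIVED_COLUMNS",
]

ETHNICITY_CONSTANTS = {"white_hispanic": 0.0, "asian": -1.2, "black": 1.4}

DERIVED_COLUMNS = ("bmi", "pbf", "asm", "smi", "gait_speed")

_PBF_BOUNDS = (3.0, 75.0)
_ASM_BOUNDS = (0.0, 60.0)


def _sex_code(sex):
    """female → 0, male → 1; numeric codes pass through."""
    arr = np.asarray(sex)
    if arr.dtype.kind in "OU":
        return np.where(arr == "male", 1.0, 0.0)
    return arr.astype(float)


def compute_bmi(weight, height):
    """Body mass index, kg/m². Missing weight propagates to missing BMI."""
    return np.asarray(weight, dtype=float) / np.asarray(height, dtype=float) ** 2


def compute_pbf(bmi, age, sex, *, warn_out_of_range: bool = True):
    """Percent body fat from BMI, age and sex (male = 1).

    Values outside the physiologic band [3, 75] are flagged with a warning
    but returned unmodified.
    """
    pbf = 1.20 * np.asarray(bmi, dtype=float) + 0.23 * np.asarray(age, dtype=float) \
        - 10.8 * _sex_code(sex) - 5.4
    if warn_out_of_range:
        with np.errstate(invalid="ignore"):
            bad = (pbf < _PBF_BOUNDS[0]) | (pbf > _PBF_BOUNDS[1])
        if np.any(bad):
            warnings.warn(
                f"{int(np.sum(bad))} %BF value(s) outside [3, 75]; kept unclipped",
                stacklevel=2,
            )
    return pbf


def compute_asm(weight, height, age, sex, ethnicity="white_hispanic",
                *, warn_out_of_range: bool = True):
    """Appendicular skeletal muscle mass (kg) from the anthropometric equation.

    ``ethnicity`` is a label in :data:`ETHNICITY_CONSTANTS` (or an aligned
    array of labels, resolved per record). Negative or > 60 kg values are
    flagged, not clipped.
    """
    if isinstance(ethnicity, str):
        race = ETHNICITY_CONSTANTS[ethnicity]
    else:
        race = np.vectorize(ETHNICITY_CONSTANTS.__getitem__, otypes=[float])(
            np.asarray(ethnicity)
        )
    asm = (
        0.244 * np.asarray(weight, dtype=float)
        + 7.80 * np.asarray(height, dtype=float)
        + 6.6 * _sex_code(sex)
        - 0.098 * np.asarray(age, dtype=float)
        + race
        - 3.3
    )
    if warn_out_of_range:
        with np.errstate(invalid="ignore"):
            bad = (asm < _ASM_BOUNDS[0]) | (asm > _ASM_BOUNDS[1])
        if np.any(bad):
            warnings.warn(
                f"{int(np.sum(bad))} ASM value(s) outside [0, 60] kg; kept unclipped",
                stacklevel=2,
            )
    return asm


def compute_smi(asm, bmi):
    """Skeletal muscle mass index = ASM / BMI (missing propagates)."""
    return np.asarray(asm, dtype=float) / np.asarray(bmi, dtype=float)


def compute_gait_speed(walk_time_10m, *, warn_nonpositive: bool = True):
    """Gait speed in m/s over 10 m. Non-positive times become missing."""
    t = np.asarray(walk_time_10m, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        bad = t <= 0
        speed = np.where(bad, np.nan, 10.0 / t)
    if warn_nonpositive and np.any(bad):
        warnings.warn(
            f"{int(np.sum(bad))} non-positive walk time(s) set to missing",
            stacklevel=2,
        )
    return speed


def add_derived(df: pd.DataFrame, site_ethnicity=None,
                *, warn_out_of_range: bool = False) -> pd.DataFrame:
    """Append bmi / pbf / asm / smi / gait_speed columns to a cohort frame.

    ``site_ethnicity`` maps site label → ethnicity; unknown sites default to
    ``white_hispanic`` (ethnicity is a site-level attribute, not per-person).
    A record yields missing body composition iff weight or height is missing;
    gait speed is missing iff walk time is missing or non-positive.
    """
    site_ethnicity = site_ethnicity or {}
    out = df.copy()
    eth = out["site"].map(lambda s: site_ethnicity.get(s, "white_hispanic"))
    out["bmi"] = compute_bmi(out["weight"], out["height"])
    out["pbf"] = compute_pbf(out["bmi"], out["age"], out["sex"],
                             warn_out_of_range=warn_out_of_range)
    out["asm"] = compute_asm(out["weight"], out["height"], out["age"], out["sex"],
                             eth.to_numpy(), warn_out_of_range=warn_out_of_range)
    out["smi"] = compute_smi(out["asm"], out["bmi"])
    out["gait_speed"] = compute_gait_speed(out["walk_time_10m"],
                                           warn_nonpositive=False)
    return out
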