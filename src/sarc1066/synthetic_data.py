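"""Multi-site synthetic cohort generator with known ground truth.

The generator emulates the structure of a multi-country population-based
survey of adults aged 65+ (nine urban/rural catchment sites in six
low- and middle-income countries): site-specific age/sex structure,
covariate prevalences, anthropometry, a 10-metre walk time, and a
missing-at-random weight mechanism concentrated in two sites.

Ground truth is *induced, not labelled*. Three embedded components make
downstream parameter-recovery tests meaningful:

1. **Structural SMI.** Each person's skeletal muscle mass index follows an
   exact linear model in the analysis covariates,
   ``SMI = a_site_sex + b_age (age-75) + b_pbf (%BF-36) + ... + eps``,
   with normal noise. %BF is drawn first; height and weight are then
   *solved* from the body-composition equations (BMI from the %BF equation,
   height from the quadratic the muscle-mass equation implies) so that the
   pipeline's derived SMI reproduces the structural value exactly. Heights
   and weights land in realistic ranges as a by-product.

2. **Logistic sarcopenia propensity.** An explicit propensity
   ``pi(X) = expit(site intercept + th_male male + th_age (age-75) + ...)``
   decides who occupies the joint tail (low-SMI and slow-gait quintiles).
   Conditional on the realised low-SMI flag, each person's probability of
   also being in the slow-gait tail is ``pi/P(low SMI | X)``, which makes
   ``P(sarcopenia | X) = pi(X)`` exactly — so the male log-odds ratio is a
   well-defined estimand of the downstream logistic model. Persons outside
   the low-SMI tail fill the remaining slow-gait mass uniformly per gait
   stratum (target 20 % per stratum).

3. **Gait marginals.** Within each gait stratum (sex × age band × height
   band, the pipeline's own grid) walk speed is lognormal around a linear
   predictor in age, height and sex, so speed falls with age and rises with
   height on average; the rank coupling above only permutes persons within
   a stratum.

The propensity is clipped into the feasible envelope ``pi <= P(low|X)``
where the two models disagree in the far tails; the clipped fraction is
reported in the provenance JSON and is designed to be well under 1 %.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit, logit, ndtr, ndtri

from .anthropometrics import ETHNICITY_CONSTANTS, add_derived
from .case_definitions import add_strata, derive_cutoffs
from .data_model import CohortTable, load_dictionary, validate_cohort

__all__ = [
    "ConfigurationError",
    "SiteProfile",
    "TruthSpec",
    "default_profiles",
    "default_truth",
    "load_profiles",
    "load_truth",
    "simulate_cohort",
    "apply_missingness",
    "REF_AGE",
    "REF_PBF",
    "REF_ASSETS",
]

# global centring constants for structural models (centring moves only the
# site intercepts, never the slopes the recovery tests target)
REF_AGE = 75.0
REF_PBF = 36.0
REF_ASSETS = 5.0
_REF_HEIGHT = 1.55

_AGE_BAND_EDGES = ((65, 69), (70, 74), (75, 79), (80, None))


class ConfigurationError(ValueError):
    pass


@dataclass
class SiteProfile:
    """Sampling parameters for one site."""

    site: str
    n: int
    ethnicity: str = "white_hispanic"
    #: probabilities over the age bands 65-69 / 70-74 / 75-79 / 80+
    age_band_probs: tuple[float, ...] = (0.31, 0.29, 0.21, 0.19)
    #: mean residual years beyond 80 in the open band (shifted exponential)
    age_tail_scale: float = 3.5
    female_prob: float = 0.65
    pbf_mean: Mapping[str, float] = field(default_factory=lambda: {"female": 42.0, "male": 30.0})
    pbf_sd: Mapping[str, float] = field(default_factory=lambda: {"female": 5.0, "male": 5.0})
    #: structural SMI at reference (age 75, %BF 36, assets 5, ref categories)
    smi_intercept: Mapping[str, float] = field(default_factory=lambda: {"female": 0.60, "male": 0.98})
    smi_sigma: Mapping[str, float] = field(default_factory=lambda: {"female": 0.06, "male": 0.07})
    #: log gait-speed model: intercept at reference + slopes (speed in m/s)
    gait: Mapping[str, float] = field(default_factory=lambda: {
        "log_speed_intercept": -0.11, "age_slope": -0.016,
        "height_slope": 0.55, "male_effect": 0.03, "sigma": 0.22,
    })
    education_probs: tuple[float, ...] = (0.15, 0.30, 0.30, 0.17, 0.08)
    marital_probs: tuple[float, ...] = (0.08, 0.50, 0.32, 0.10)
    assets_p: float = 0.75
    smoking_ever: float = 0.12
    alcohol_moderate: float = 0.06
    activity_high: float = 0.60
    impairment_probs: tuple[float, ...] = (0.42, 0.44, 0.14)
    dementia: float = 0.09
    depression: float = 0.12
    diabetes: float = 0.17
    stroke: float = 0.07
    #: marginal weight-missingness rate and MAR (logit) slopes
    weight_missing_rate: float = 0.0
    mar_age_slope: float = 0.0
    mar_male: float = 0.0
    mar_height_slope: float = 0.0
    #: sarcopenia-propensity intercept (logit scale, at reference female)
    propensity_intercept: float = -3.3

    def validate(self) -> None:
        def _probs(p, name, k):
            p = tuple(p)
            if len(p) != k or any(x < 0 for x in p) or abs(sum(p) - 1.0) > 1e-8:
                raise ConfigurationError(f"{self.site}: {name} must be {k} probabilities summing to 1")
        if self.n < 1:
            raise ConfigurationError(f"{self.site}: n must be >= 1")
        if self.ethnicity not in ETHNICITY_CONSTANTS:
            raise ConfigurationError(f"{self.site}: unknown ethnicity {self.ethnicity!r}")
        _probs(self.age_band_probs, "age_band_probs", 4)
        _probs(self.education_probs, "education_probs", 5)
        _probs(self.marital_probs, "marital_probs", 4)
        _probs(self.impairment_probs, "impairment_probs", 3)
        for name in ("female_prob", "assets_p", "smoking_ever", "alcohol_moderate",
                     "activity_high", "dementia", "depression", "diabetes", "stroke",
                     "weight_missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{self.site}: {name}={v} outside [0, 1]")
        for sex in ("female", "male"):
            if self.pbf_sd[sex] <= 0 or self.smi_sigma[sex] <= 0:
                raise ConfigurationError(f"{self.site}: noise SDs must be > 0")
        if self.gait["sigma"] <= 0:
            raise ConfigurationError(f"{self.site}: gait sigma must be > 0")


@dataclass
class TruthSpec:
    """Embedded effects: linear on SMI (per sex) and log-odds on propensity.

    ``smi_effects[sex]`` maps term → per-unit effect on SMI; numeric terms
    are centred (age at 75, %BF at 36, assets at 5), categorical terms are
    written ``"column=level"`` and act as reference-coded shifts.
    ``propensity`` maps the same kind of term → log-odds-ratio on the
    sarcopenia propensity (``"male"`` is the male-vs-female log-OR).
    """

    smi_effects: Mapping[str, Mapping[str, float]] = field(default_factory=lambda: {
        "female": {"age": -0.002, "pbf": -0.003, "assets": 0.0025,
                   "education=secondary": 0.006, "education=tertiary": 0.012,
                   "phys_activity=high": 0.003},
        "male": {"age": -0.002, "pbf": -0.003, "assets": 0.0025,
                 "education=secondary": 0.006, "education=tertiary": 0.012,
                 "phys_activity=high": 0.003},
    })
    propensity: Mapping[str, float] = field(default_factory=lambda: {
        "male": float(np.log(2.8)), "age": float(np.log(1.03)),
        "pbf": float(np.log(1.03)), "assets": float(np.log(0.95)),
    })
    #: target slow-gait mass per gait stratum (the quintile level)
    slow_mass: float = 0.20

    def validate(self) -> None:
        for sex, eff in self.smi_effects.items():
            for k, v in eff.items():
                if not np.isfinite(v):
                    raise ConfigurationError(f"smi_effects[{sex}][{k}] not finite")
        for k, v in self.propensity.items():
            if not np.isfinite(v):
                raise ConfigurationError(f"propensity[{k}] not finite")


# ---------------------------------------------------------------------------
# default nine-site profile set (marginals loosely calibrated to the study's
# descriptive table; exact joint distributions are unknowable and not claimed)
# ---------------------------------------------------------------------------

_SITE_DEFAULTS: dict[str, dict] = {
    "cuba": dict(
        n=1913, age_band_probs=(0.310, 0.294, 0.216, 0.180), female_prob=0.657,
        smi_intercept={"female": 0.625, "male": 0.988},
        education_probs=(0.02, 0.20, 0.32, 0.28, 0.18),
        marital_probs=(0.09, 0.46, 0.28, 0.17), assets_p=0.90,
        smoking_ever=0.13, alcohol_moderate=0.035, activity_high=0.66,
        impairment_probs=(0.43, 0.46, 0.11), depression=0.15, diabetes=0.20,
        weight_missing_rate=0.30, mar_age_slope=0.035, mar_male=0.15,
        propensity_intercept=-3.30,
    ),
    "dominican_republic": dict(
        n=1085, age_band_probs=(0.316, 0.306, 0.195, 0.183), female_prob=0.688,
        smi_intercept={"female": 0.605, "male": 0.995},
        education_probs=(0.19, 0.50, 0.19, 0.08, 0.04),
        marital_probs=(0.07, 0.32, 0.39, 0.22), assets_p=0.70,
        smoking_ever=0.10, alcohol_moderate=0.04, activity_high=0.65,
        impairment_probs=(0.36, 0.44, 0.20), depression=0.20, diabetes=0.18,
        propensity_intercept=-3.45,
    ),
    "peru_urban": dict(
        n=832, age_band_probs=(0.290, 0.276, 0.224, 0.210), female_prob=0.655,
        smi_intercept={"female": 0.590, "male": 0.950},
        education_probs=(0.02, 0.06, 0.31, 0.38, 0.23),
        marital_probs=(0.11, 0.59, 0.25, 0.05), assets_p=0.95,
        smoking_ever=0.045, alcohol_moderate=0.075, activity_high=0.64,
        impairment_probs=(0.55, 0.35, 0.10), depression=0.08, diabetes=0.12,
        propensity_intercept=-3.35,
    ),
    "peru_rural": dict(
        n=410, age_band_probs=(0.359, 0.271, 0.185, 0.185), female_prob=0.539,
        smi_intercept={"female": 0.588, "male": 0.945},
        education_probs=(0.12, 0.24, 0.52, 0.08, 0.04),
        marital_probs=(0.12, 0.61, 0.23, 0.04), assets_p=0.58,
        smoking_ever=0.02, alcohol_moderate=0.015, activity_high=0.77,
        impairment_probs=(0.67, 0.28, 0.05), depression=0.07, diabetes=0.06,
        propensity_intercept=-3.10,
    ),
    "mexico_urban": dict(
        n=684, age_band_probs=(0.278, 0.354, 0.200, 0.168), female_prob=0.659,
        smi_intercept={"female": 0.585, "male": 0.965},
        education_probs=(0.19, 0.38, 0.23, 0.11, 0.09),
        marital_probs=(0.06, 0.51, 0.35, 0.08), assets_p=0.86,
        smoking_ever=0.095, alcohol_moderate=0.11, activity_high=0.63,
        impairment_probs=(0.41, 0.42, 0.17), depression=0.13, diabetes=0.25,
        propensity_intercept=-3.35,
    ),
    "mexico_rural": dict(
        n=634, age_band_probs=(0.330, 0.276, 0.208, 0.186), female_prob=0.617,
        smi_intercept={"female": 0.580, "male": 0.960},
        education_probs=(0.33, 0.50, 0.11, 0.04, 0.02),
        marital_probs=(0.03, 0.57, 0.36, 0.04), assets_p=0.53,
        smoking_ever=0.04, alcohol_moderate=0.06, activity_high=0.54,
        impairment_probs=(0.33, 0.47, 0.20), depression=0.14, diabetes=0.22,
        propensity_intercept=-3.30,
    ),
    "china_urban": dict(
        n=692, age_band_probs=(0.340, 0.332, 0.217, 0.111), female_prob=0.593,
        ethnicity="asian", smi_intercept={"female": 0.605, "male": 0.990},
        education_probs=(0.20, 0.14, 0.23, 0.31, 0.12),
        marital_probs=(0.002, 0.758, 0.22, 0.02), assets_p=0.80,
        smoking_ever=0.175, alcohol_moderate=0.055, activity_high=0.51,
        impairment_probs=(0.30, 0.46, 0.24), depression=0.05, diabetes=0.15,
        propensity_intercept=-3.20,
    ),
    "china_rural": dict(
        n=692, age_band_probs=(0.456, 0.308, 0.172, 0.064), female_prob=0.569,
        ethnicity="asian", age_tail_scale=2.5,
        smi_intercept={"female": 0.600, "male": 0.980},
        education_probs=(0.53, 0.12, 0.28, 0.06, 0.01),
        marital_probs=(0.025, 0.645, 0.33, 0.00), assets_p=0.85,
        smoking_ever=0.30, alcohol_moderate=0.14, activity_high=0.51,
        impairment_probs=(0.48, 0.42, 0.10), depression=0.04, diabetes=0.08,
        propensity_intercept=-3.55,
    ),
    "puerto_rico": dict(
        n=907, age_band_probs=(0.245, 0.281, 0.271, 0.203), female_prob=0.692,
        smi_intercept={"female": 0.615, "male": 0.983},
        education_probs=(0.02, 0.17, 0.17, 0.42, 0.22),
        marital_probs=(0.07, 0.53, 0.27, 0.13), assets_p=0.97,
        smoking_ever=0.03, alcohol_moderate=0.08, activity_high=0.57,
        impairment_probs=(0.26, 0.51, 0.23), depression=0.18, diabetes=0.28,
        weight_missing_rate=0.25, mar_age_slope=0.035, mar_male=0.10,
        propensity_intercept=-3.25,
    ),
}


def default_profiles(n: int | None = None,
                     weight_missing: bool = True) -> list[SiteProfile]:
    """The nine shipped site profiles.

    ``n`` overrides every site's sample size; ``weight_missing=False`` zeroes
    the missingness mechanism (complete-data cohorts for recovery tests).
    """
    out = []
    for site, kw in _SITE_DEFAULTS.items():
        kw = dict(kw)
        if n is not None:
            kw["n"] = n
        if not weight_missing:
            kw.update(weight_missing_rate=0.0, mar_age_slope=0.0,
                      mar_male=0.0, mar_height_slope=0.0)
        out.append(SiteProfile(site=site, **kw))
    return out


def default_truth() -> TruthSpec:
    return TruthSpec()


def load_profiles(path) -> list[SiteProfile]:
    """Read site profiles from YAML (list of mappings, keys as SiteProfile)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    profiles = []
    for entry in raw:
        entry = dict(entry)
        for key in ("age_band_probs", "education_probs", "marital_probs",
                    "impairment_probs"):
            if key in entry:
                entry[key] = tuple(entry[key])
        profiles.append(SiteProfile(**entry))
    return profiles


def load_truth(path) -> TruthSpec:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return TruthSpec(**raw)


# ---------------------------------------------------------------------------
# sampling helpers
# ---------------------------------------------------------------------------

_EDU_LEVELS = ("none", "incomplete_primary", "primary", "secondary", "tertiary")
_MARITAL_LEVELS = ("never", "married_cohab", "widowed", "divorced_sep")
_IMP_LEVELS = ("none", "one_two", "three_plus")


def _draw_ages(rng, profile: SiteProfile) -> np.ndarray:
    bands = rng.choice(4, size=profile.n, p=np.asarray(profile.age_band_probs))
    ages = np.empty(profile.n, dtype=np.int64)
    for b, (lo, hi) in enumerate(_AGE_BAND_EDGES):
        m = bands == b
        if hi is not None:
            ages[m] = rng.integers(lo, hi + 1, size=m.sum())
        else:
            tail = np.minimum(rng.exponential(profile.age_tail_scale, size=m.sum()), 18.0)
            ages[m] = lo + np.floor(tail).astype(np.int64)
    return ages


def _ordinal_from_latent(latent_u: np.ndarray, probs, levels) -> np.ndarray:
    cum = np.cumsum(np.asarray(probs, dtype=float))[:-1]
    idx = np.searchsorted(cum, latent_u, side="right")
    return np.asarray(levels, dtype=object)[idx]


def _solve_height(bmi, smi, age, male, race):
    """Positive root of 0.244 h^2 + (7.8/B) h + ((6.6 s - 0.098 a + r - 3.3)/B - SMI) = 0."""
    a = 0.244
    b = 7.8 / bmi
    c = (6.6 * male - 0.098 * age + race - 3.3) / bmi - smi
    disc = b * b - 4 * a * c
    disc = np.maximum(disc, 0.0)
    return (-b + np.sqrt(disc)) / (2 * a)


def _term_matrix(df: pd.DataFrame, effects: Mapping[str, float]) -> np.ndarray:
    """Linear predictor contribution of a term → effect mapping (centred)."""
    lp = np.zeros(len(df))
    for term, eff in effects.items():
        if term == "male":
            lp += eff * (df["sex"].to_numpy() == "male")
        elif term == "age":
            lp += eff * (df["age"].to_numpy(dtype=float) - REF_AGE)
        elif term == "pbf":
            lp += eff * (df["pbf"].to_numpy(dtype=float) - REF_PBF)
        elif term == "assets":
            lp += eff * (df["assets"].to_numpy(dtype=float) - REF_ASSETS)
        elif "=" in term:
            col, level = term.split("=", 1)
            lp += eff * (df[col].to_numpy() == level)
        else:
            raise ConfigurationError(f"unknown truth term {term!r}")
    return lp


# ---------------------------------------------------------------------------
# main generator
# ---------------------------------------------------------------------------

def _simulate_site_frame(rng, profile: SiteProfile, truth: TruthSpec) -> pd.DataFrame:
    n = profile.n
    age = _draw_ages(rng, profile)
    sex = np.where(rng.uniform(size=n) < profile.female_prob, "female", "male")
    male = (sex == "male").astype(float)

    # single latent SES factor couples education and assets
    ses = rng.normal(size=n)
    edu_latent = 0.6 * ses + np.sqrt(1 - 0.36) * rng.normal(size=n)
    edu_u = ndtr(edu_latent)
    education = _ordinal_from_latent(edu_u, profile.education_probs, _EDU_LEVELS)
    assets_p = np.clip(profile.assets_p + 0.08 * ses, 0.02, 0.98)
    assets = rng.binomial(7, assets_p)

    marital = _ordinal_from_latent(rng.uniform(size=n), profile.marital_probs, _MARITAL_LEVELS)
    impairments = _ordinal_from_latent(rng.uniform(size=n), profile.impairment_probs, _IMP_LEVELS)
    smoking = np.where(rng.uniform(size=n) < profile.smoking_ever, "ever", "never")
    alcohol = np.where(rng.uniform(size=n) < profile.alcohol_moderate, "moderate", "none_or_heavy")
    activity = np.where(rng.uniform(size=n) < profile.activity_high, "high", "low")

    df = pd.DataFrame({
        "pid": [f"{profile.site}-{i:05d}" for i in range(n)],
        "site": profile.site,
        "age": age,
        "sex": sex,
        "education": education,
        "marital": marital,
        "assets": assets,
        "smoking": smoking,
        "alcohol": alcohol,
        "phys_activity": activity,
        "impairments": impairments,
        "dementia": rng.binomial(1, profile.dementia, size=n),
        "depression": rng.binomial(1, profile.depression, size=n),
        "diabetes": rng.binomial(1, profile.diabetes, size=n),
        "stroke": rng.binomial(1, profile.stroke, size=n),
    })

    # --- %BF and structural SMI, inverted to height and weight -------------
    pbf_mean = np.where(male == 1, profile.pbf_mean["male"], profile.pbf_mean["female"])
    pbf_sd = np.where(male == 1, profile.pbf_sd["male"], profile.pbf_sd["female"])
    pbf = rng.normal(pbf_mean, pbf_sd)
    # truncate in BMI space (the quantity with physiologic bounds) and map
    # back so the (%BF, BMI, age, sex) quadruple stays equation-consistent
    bmi = (pbf - 0.23 * age + 10.8 * male + 5.4) / 1.2
    bmi = np.clip(bmi, 17.0, 44.0)
    pbf = 1.2 * bmi + 0.23 * age - 10.8 * male - 5.4
    df["pbf"] = pbf

    sigma = np.where(male == 1, profile.smi_sigma["male"], profile.smi_sigma["female"])
    alpha = np.where(male == 1, profile.smi_intercept["male"], profile.smi_intercept["female"])
    mu = alpha.copy()
    for s in ("female", "male"):
        m = sex == s
        mu[m] += _term_matrix(df[m], truth.smi_effects[s])
    eps = np.clip(rng.normal(size=n), -4.0, 4.0) * sigma
    smi = mu + eps
    df["smi_mu"] = mu

    race = ETHNICITY_CONSTANTS[profile.ethnicity]
    height = _solve_height(bmi, smi, age, male, race)
    # the quadratic lands in (1.0, 2.2) m for all realistic draws; clamp the
    # pathological remainder and note it (SMI exactness is lost only there)
    clamped = (height <= 1.25) | (height >= 2.10)
    height = np.clip(height, 1.25, 2.10)
    df["height"] = np.round(height, 4)
    df["weight"] = np.round(bmi * df["height"] ** 2, 2)
    df["_height_clamped"] = clamped
    df["smi_sigma"] = sigma
    return df


def simulate_cohort(
    profiles: Sequence[SiteProfile],
    truth: TruthSpec | None = None,
    seed: int = 0,
    *,
    apply_missing: bool = True,
) -> CohortTable:
    """Generate a multi-site cohort with embedded ground truth.

    Identical ``(profiles, truth, seed)`` yield an identical table. The
    returned table's ``provenance`` is a JSON record of the seed, per-site
    sample sizes, the truth spec, and coupling diagnostics (clip fractions).
    """
    if not profiles:
        raise ConfigurationError("at least one site profile required")
    for p in profiles:
        p.validate()
    if len({p.site for p in profiles}) != len(profiles):
        raise ConfigurationError("duplicate site labels in profiles")
    truth = truth or default_truth()
    truth.validate()

    rng = np.random.default_rng(seed)
    frames = [_simulate_site_frame(rng, p, truth) for p in profiles]
    df = pd.concat(frames, ignore_index=True)
    df["walk_time_10m"] = np.nan      # placeholder until gait is generated

    # --- realised low-SMI tail (the pipeline's own cut-off machinery) ------
    dictionary = load_dictionary()
    eth = {p.site: p.ethnicity for p in profiles}
    derived = add_derived(df, eth)
    derived, _ = add_strata(derived)
    cut = derive_cutoffs(derived, "low_smi", min_stratum_size=1)
    thr = derived[["site", "sex"]].merge(cut, on=["site", "sex"], how="left")["threshold"].to_numpy()
    low = derived["smi"].to_numpy() <= thr

    # analytic P(low | X) under the structural model, at the realised cut-off
    p_low = ndtr((thr - df["smi_mu"].to_numpy()) / df["smi_sigma"].to_numpy())
    p_low = np.clip(p_low, 1e-6, 1 - 1e-6)

    # --- logistic sarcopenia propensity ------------------------------------
    intercept = df["site"].map({p.site: p.propensity_intercept for p in profiles}).to_numpy()
    lp = intercept + _term_matrix(df, truth.propensity)
    pi = expit(lp)
    clipped = pi > p_low
    pi_eff = np.minimum(pi, p_low)

    # conditional slow-gait designation probability
    r = np.where(low, pi_eff / p_low, 0.0)

    # fill the remaining slow mass uniformly per gait stratum
    strata_key = derived["sex"].astype(str) + "|" + derived["age_band"].astype(str) \
        + "|" + derived["height_band"].astype(str)
    r = pd.Series(r, index=derived.index)
    base_clip = 0
    for _, idx in derived.groupby(strata_key).groups.items():
        n_g = len(idx)
        in_low = low[idx]
        need = truth.slow_mass * n_g - r.loc[idx[in_low]].sum()
        n_rest = int((~in_low).sum())
        if n_rest:
            base = need / n_rest
            if base < 0 or base > 1:
                base_clip += n_g
            r.loc[idx[~in_low]] = np.clip(base, 0.0, 1.0)
    slow = rng.uniform(size=len(df)) < r.to_numpy()

    # --- walk speed: stratified lognormal marginal, rank-coupled ------------
    u = np.where(slow, rng.uniform(0.0, truth.slow_mass, size=len(df)),
                 rng.uniform(truth.slow_mass, 1.0, size=len(df)))
    g = df["site"].map({p.site: p.gait for p in profiles})
    nu = np.array([gi["log_speed_intercept"] for gi in g]) \
        + np.array([gi["age_slope"] for gi in g]) * (df["age"].to_numpy(dtype=float) - REF_AGE) \
        + np.array([gi["height_slope"] for gi in g]) * (df["height"].to_numpy() - _REF_HEIGHT) \
        + np.array([gi["male_effect"] for gi in g]) * (df["sex"].to_numpy() == "male")
    sig = np.array([gi["sigma"] for gi in g])
    log_speed = np.empty(len(df))
    for _, idx in derived.groupby(strata_key).groups.items():
        m_g = nu[idx].mean()
        s_g = sig[idx].mean()
        log_speed[idx] = m_g + s_g * ndtri(u[idx])
    speed = np.exp(log_speed)
    df["walk_time_10m"] = np.round(10.0 / speed, 3)

    out = df[list(dictionary.columns)].copy()
    table = validate_cohort(out, dictionary=dictionary)
    if len(table.rejects):
        raise ConfigurationError(
            f"generator produced {len(table.rejects)} invalid row(s); first: "
            f"{table.rejects.iloc[0].to_dict()}"
        )
    diagnostics = {
        "propensity_clip_fraction": float(np.mean(clipped)),
        "base_rate_clip_fraction": float(base_clip / len(df)),
        "height_clamp_fraction": float(df["_height_clamped"].mean()),
    }
    table.provenance = json.dumps({
        "generator": "sarc1066.synthetic_data.simulate_cohort",
        "seed": int(seed),
        "sites": {p.site: p.n for p in profiles},
        "truth": {"smi_effects": {k: dict(v) for k, v in truth.smi_effects.items()},
                  "propensity": dict(truth.propensity)},
        "diagnostics": diagnostics,
    }, sort_keys=True)

    if apply_missing and any(p.weight_missing_rate > 0 for p in profiles):
        table = apply_missingness(table, profiles, seed=seed + 1)
    return table


def apply_missingness(table: CohortTable, profiles: Sequence[SiteProfile],
                      seed: int = 0) -> CohortTable:
    """Set weight to missing, MAR in site, age, sex and height.

    Per site, the missingness probability is logistic:
    ``logit p = logit(rate) + b_age (age-75) + b_male male + b_height (h-1.55)``.
    A rate of 0 removes nothing; a rate of 1 removes the whole site. All
    other fields are untouched.
    """
    for p in profiles:
        p.validate()
    rng = np.random.default_rng(seed)
    df = table.df.copy()
    for p in sorted(profiles, key=lambda q: q.site):
        m = (df["site"] == p.site).to_numpy()
        if not m.any() or p.weight_missing_rate <= 0:
            continue
        if p.weight_missing_rate >= 1:
            df.loc[m, "weight"] = np.nan
            continue
        lp = logit(p.weight_missing_rate) \
            + p.mar_age_slope * (df.loc[m, "age"].to_numpy(dtype=float) - REF_AGE) \
            + p.mar_male * (df.loc[m, "sex"].to_numpy() == "male") \
            + p.mar_height_slope * (df.loc[m, "height"].to_numpy() - _REF_HEIGHT)
        drop = rng.uniform(size=int(m.sum())) < expit(lp)
        rows = np.flatnonzero(m)[drop]
        df.iloc[rows, df.columns.get_loc("weight")] = np.nan
    out = CohortTable(df=df, provenance=table.provenance,
                      schema_version=table.schema_version, rejects=table.rejects)
    return out
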