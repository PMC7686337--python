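"""End-to-end orchestration: simulate/read → derive → impute → classify →
prevalence → associate → meta, with provenance.

Every stage writes delimited text into the output directory; the
provenance JSON records the configuration, seeds, package version and
per-stage row counts, and contains everything needed to reproduce the run
byte-for-byte. Identical config + seed ⇒ identical output files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .anthropometrics import add_derived
from .association_models import (default_spec, fit_all_sites, fit_logistic_case,
                                 fit_linear_smi, fit_over_imputations)
from .case_definitions import add_strata, derive_all_cutoffs, flag_cases
from .data_model import CohortTable, load_dictionary, read_cohort, write_cohort
from .imputation import DEFAULT_AUXILIARIES, impute_weight
from .meta_analysis import build_pooled_tables, format_pooled_table
from .prevalence import prevalence_over_imputations, prevalence_table
from .synthetic_data import (SiteProfile, TruthSpec, default_profiles,
                             default_truth, load_profiles, load_truth,
                             simulate_cohort)

__all__ = ["RunConfig", "run_all", "imputation_trigger"]

log = logging.getLogger("sarc1066")

ARTIFACTS = ("cohort.csv", "derived.csv", "cutoffs.csv", "flags.csv",
             "prevalence.csv", "site_fits.csv", "pooled.csv")


@dataclass
class RunConfig:
    """Everything one analysis run needs; loadable from YAML/JSON."""

    out_dir: str = "results"
    seed: int = 0
    input_path: str | None = None           # read a cohort instead of simulating
    column_map: Mapping[str, str] | None = None
    profiles: Sequence[SiteProfile] | None = None
    truth: TruthSpec | None = None
    n_per_site: int | None = None           # override profile sample sizes
    imputation_enabled: bool = True
    imputation_m: int = 50
    imputation_threshold: float = 0.10      # site weight-missingness trigger
    imputation_sites: tuple[str, ...] | None = None   # explicit override
    auxiliaries: tuple[str, ...] = DEFAULT_AUXILIARIES
    cutoff_scope: str = "per_imputation"    # or "complete_case"
    quantile_method: str = "linear"
    min_stratum_size: int = 20
    outcomes: tuple[str, ...] = ("smi", "sarcopenia", "sarcopenic_obesity")
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "profiles" in raw and raw["profiles"]:
            raw["profiles"] = [SiteProfile(**p) for p in raw["profiles"]]
        if "truth" in raw and raw["truth"]:
            raw["truth"] = TruthSpec(**raw["truth"])
        for key in ("imputation_sites", "auxiliaries", "outcomes"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def analytic_config(self) -> dict:
        """The configuration minus keys that cannot affect results."""
        skip = {"out_dir", "log_level"}
        return {k: v for k, v in vars(self).items() if k not in skip}

    def digest(self) -> str:
        """Stable hash of the analytic configuration (for provenance)."""
        def _enc(o):
            if isinstance(o, (SiteProfile, TruthSpec)):
                return vars(o)
            if isinstance(o, tuple):
                return list(o)
            return str(o)
        blob = json.dumps(self.analytic_config(), default=_enc, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def imputation_trigger(table: CohortTable, threshold: float = 0.10,
                       explicit: Sequence[str] | None = None) -> list[str]:
    """Sites whose weight-missingness exceeds ``threshold``.

    An explicit site list overrides the threshold rule entirely.
    """
    if explicit is not None:
        return sorted(explicit)
    frac = table.df.groupby("site")["weight"].apply(lambda s: s.isna().mean())
    return sorted(frac[frac > threshold].index)


def _derive_and_flag(df: pd.DataFrame, site_eth, config: RunConfig,
                     height_edges=None):
    derived = add_derived(df, site_eth)
    derived, edges = add_strata(derived, height_edges)
    cutoffs = derive_all_cutoffs(derived, quantile_method=config.quantile_method,
                                 min_stratum_size=config.min_stratum_size)
    flags = flag_cases(derived, cutoffs)
    return derived, cutoffs, flags, edges


def _cutoffs_frame(cutoffs: dict[str, pd.DataFrame]) -> pd.DataFrame:
    frames = []
    for d, t in cutoffs.items():
        frames.append(t.assign(definition=d))
    out = pd.concat(frames, ignore_index=True)
    order = ["definition", "site", "sex", "age_band", "height_band",
             "threshold", "n", "level", "small_stratum"]
    for c in order:
        if c not in out.columns:
            out[c] = pd.NA
    return out[order]


def _fits_frame(fits) -> pd.DataFrame:
    rows = []
    for f in fits:
        for _, r in f.params.iterrows():
            rows.append({"site": f.site, "stratum": f.stratum, "outcome": f.outcome,
                         "term": r["term"], "estimate": r["estimate"], "se": r["se"],
                         "n": f.n, "ok": f.ok, "flags": json.dumps(f.flags, default=str)})
        if not len(f.params):
            rows.append({"site": f.site, "stratum": f.stratum, "outcome": f.outcome,
                         "term": None, "estimate": np.nan, "se": np.nan,
                         "n": f.n, "ok": f.ok, "flags": json.dumps(f.flags, default=str)})
    return pd.DataFrame(rows)


def run_all(config: RunConfig) -> dict:
    """Run the full analysis; returns the result bundle and writes artifacts.

    Writes cohort, derived cohort, cut-offs, flags, per-site prevalence,
    site fits, pooled tables (CSV + Markdown) and a provenance JSON into
    ``config.out_dir``. Raises on stage failure with the stage named.
    """
    logging.basicConfig(stream=sys.stderr, level=config.log_level,
                        format="%(levelname)s %(name)s: %(message)s")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dictionary = load_dictionary()
    timings: dict[str, float] = {}
    counts: dict[str, int] = {}

    def stage(name):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()
                log.info("stage %s ...", name)
                return self
            def __exit__(self, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self.t0, 3)
                if exc_type is not None:
                    log.error("stage %s FAILED: %s", name, exc)
                else:
                    log.info("stage %s done (%.2fs)", name, timings[name])
                return False
        return _T()

    # --- acquire cohort ----------------------------------------------------
    with stage("cohort"):
        if config.input_path:
            table = read_cohort(config.input_path, column_map=config.column_map)
            site_eth = {s: dictionary.site_ethnicity(s) for s in table.df["site"].unique()}
        else:
            profiles = list(config.profiles or default_profiles())
            if config.n_per_site is not None:
                for p in profiles:
                    p.n = config.n_per_site
            truth = config.truth or default_truth()
            table = simulate_cohort(profiles, truth, seed=config.seed)
            site_eth = {p.site: p.ethnicity for p in profiles}
        write_cohort(table, out / "cohort.csv")
        if len(table.rejects):
            table.rejects.to_csv(out / "rejects.csv", index=False)
        counts["cohort"] = len(table)
        counts["rejected"] = len(table.rejects)

    # --- imputation decision -----------------------------------------------
    with stage("imputation_trigger"):
        sites_to_impute = []
        if config.imputation_enabled and table.df["weight"].isna().any():
            sites_to_impute = imputation_trigger(
                table, config.imputation_threshold, config.imputation_sites)
        counts["sites_imputed"] = len(sites_to_impute)
        counts["weight_missing"] = int(table.df["weight"].isna().sum())

    imp_set = None
    if sites_to_impute:
        with stage("impute"):
            # impute only the triggered sites' records; others stay complete-case
            mask = table.df["site"].isin(sites_to_impute) | table.df["weight"].notna()
            sub = CohortTable(df=table.df[mask].reset_index(drop=True))
            imp_set = impute_weight(sub, m=config.imputation_m,
                                    seed=config.seed + 1,
                                    auxiliaries=config.auxiliaries)
            counts["imputed_records"] = len(imp_set.imputed_pids)
            (out / "imputation_diagnostics.json").write_text(
                json.dumps(imp_set.diagnostics, sort_keys=True, default=str) + "\n")

    # --- derive / classify / estimate --------------------------------------
    if imp_set is None:
        with stage("classify"):
            derived, cutoffs, flags, _ = _derive_and_flag(table.df, site_eth, config)
            derived.to_csv(out / "derived.csv", index=False)
            _cutoffs_frame(cutoffs).to_csv(out / "cutoffs.csv", index=False)
            flags.to_csv(out / "flags.csv", index=False)
            counts["flagged"] = int(flags["sarcopenia"].notna().sum())
        with stage("prevalence"):
            prev = prevalence_table(flags)
            prev.to_csv(out / "prevalence.csv", index=False)
        with stage("associate"):
            fits = fit_all_sites(flags, outcomes=config.outcomes)
            _fits_frame(fits).to_csv(out / "site_fits.csv", index=False)
    else:
        with stage("classify"):
            edges = None
            flag_tables = []
            if config.cutoff_scope == "complete_case":
                cc = imp_set.tables[0][imp_set.tables[0]["weight"].notna()]
                _, cc_cuts, _, edges = _derive_and_flag(cc, site_eth, config)
            for t in imp_set.tables:
                derived = add_derived(t, site_eth)
                derived, edges = add_strata(derived, edges)
                if config.cutoff_scope == "complete_case":
                    cutoffs = cc_cuts
                else:
                    cutoffs = derive_all_cutoffs(
                        derived, quantile_method=config.quantile_method,
                        min_stratum_size=config.min_stratum_size)
                flag_tables.append(flag_cases(derived, cutoffs))
            # first completed dataset's derived table + cut-offs are the artifacts
            flag_tables[0].to_csv(out / "derived.csv", index=False)
            _cutoffs_frame(cutoffs).to_csv(out / "cutoffs.csv", index=False)
            flag_tables[0].to_csv(out / "flags.csv", index=False)
            counts["flagged"] = int(flag_tables[0]["sarcopenia"].notna().sum())
        with stage("prevalence"):
            rows = []
            for site in sorted(flag_tables[0]["site"].unique()):
                for outcome in ("sarcopenia", "sarcopenic_obesity"):
                    est = prevalence_over_imputations(flag_tables, site, outcome)
                    rows.append(vars(est))
            prev = pd.DataFrame(rows)
            prev.to_csv(out / "prevalence.csv", index=False)
        with stage("associate"):
            fits = []

            def _try_pool(*args):
                try:
                    fits.append(fit_over_imputations(flag_tables, *args))
                except (RuntimeError, ValueError) as err:
                    log.warning("skipping pooled fit: %s", err)

            for site in sorted(flag_tables[0]["site"].unique()):
                for gender in ("female", "male"):
                    if "smi" in config.outcomes:
                        _try_pool(fit_linear_smi, site, gender)
                for outcome in config.outcomes:
                    if outcome != "smi":
                        _try_pool(fit_logistic_case, site, default_spec(outcome))
            _fits_frame(fits).to_csv(out / "site_fits.csv", index=False)

    with stage("meta"):
        pooled = build_pooled_tables(fits)
        pooled.to_csv(out / "pooled.csv", index=False)
        (out / "pooled.md").write_text(format_pooled_table(pooled) + "\n")

    provenance = {
        "package": "sarc1066",
        "version": __version__,
        "config_digest": config.digest(),
        "config": json.loads(json.dumps(config.analytic_config(), default=str)),
        "seed": config.seed,
        "cohort_provenance": table.provenance,
        "stage_counts": counts,
        "sites_imputed": sites_to_impute,
    }
    (out / "provenance.json").write_text(
        json.dumps(provenance, sort_keys=True, indent=1) + "\n")
    log.info("timings: %s", timings)
    return {"table": table, "prevalence": prev, "fits": fits, "pooled": pooled,
            "provenance": provenance, "out_dir": str(out)}
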