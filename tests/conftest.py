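import numpy as np
import pandas as pd
import pytest

import sarc1066 as s


@pytest.fixture(scope="session")
def three_site_cohort():
    """Small complete-data cohort (3 sites x 600) reused across tests."""
    profiles = s.default_profiles(n=600, weight_missing=False)[:3]
    table = s.simulate_cohort(profiles, seed=42)
    return table, profiles


@pytest.fixture(scope="session")
def three_site_flags(three_site_cohort):
    table, profiles = three_site_cohort
    eth = {p.site: p.ethnicity for p in profiles}
    derived = s.add_derived(table.df, eth)
    derived, _ = s.add_strata(derived)
    cutoffs = s.derive_all_cutoffs(derived, min_stratum_size=5)
    return s.flag_cases(derived, cutoffs)


def make_raw_frame(rows):
    """Build a raw cohort DataFrame from per-row dicts with sane defaults."""
    defaults = dict(
        site="cuba", age=72, sex="female", height=1.55, weight=62.0,
        walk_time_10m=11.0, education="primary", marital="married_cohab",
        assets=5, smoking="never", alcohol="none_or_heavy",
        phys_activity="high", impairments="none",
        dementia=0, depression=0, diabetes=0, stroke=0,
    )
    out = []
    for i, row in enumerate(rows):
        rec = {"pid": f"p{i:03d}", **defaults, **row}
        out.append(rec)
    return pd.DataFrame(out)
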