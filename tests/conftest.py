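import warnings

import numpy as np
import pandas as pd
import pytest

import arealrisk as ar
from arealrisk import strata

warnings.filterwarnings("ignore", category=FutureWarning)


def make_counts(rows):
    """Build a validated count table from sparse row dicts (zero-filled)."""
    defaults = {"region_id": "R1", "population": 100, "events": 0}
    full = [{**defaults, **r} for r in rows]
    return ar.io.validate_counts(pd.DataFrame(full))


def full_grid_counts(areas, years, population=1000, events=2, region="R1"):
    """A complete area x period x stratum grid with constant cells."""
    rows = []
    for a in areas:
        for y in years:
            for (s, r, g) in strata.STRATA:
                rows.append({"area_id": a, "region_id": region, "year": y,
                             "sex": s, "race": r, "age_group": g,
                             "population": population, "events": events})
    return ar.io.validate_counts(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def small_dataset():
    """A seeded 6x6 synthetic dataset shared by read-only tests."""
    return ar.generate(ar.SyntheticScenario(nrows=6, ncols=6, seed=42))


@pytest.fixture(scope="session")
def small_fit(small_dataset):
    """A short two-chain fit on the 36-area dataset (read-only)."""
    table = ar.sir_table(small_dataset.counts)
    spec = ar.RiskModelSpec(chains=2, iterations=1200, burn_in=600, thin=3,
                            seed=9)
    return ar.fit(table, small_dataset.covariates, small_dataset.icar, spec)
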