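import math

import numpy as np
import pandas as pd
import pytest

import arealrisk as ar
from arealrisk import standardize, strata
from arealrisk.errors import ValidationError

from conftest import full_grid_counts, make_counts


def brute_force_rates(counts):
    """Independent oracle: per-stratum pooled quotient by explicit loops."""
    rates = {}
    for key in strata.STRATA:
        ev = pop = 0
        for _, row in counts.iterrows():
            if (row["sex"], row["race"], row["age_group"]) == key:
                ev += row["events"]
                pop += row["population"]
        rates[key] = ev / pop
    return rates


class TestReferenceRates:
    def test_pooled_quotient_single_stratum(self):
        rows = [{"area_id": a, "year": 2010, "sex": "men", "race": "white",
                 "age_group": "40-59", "population": 100, "events": e}
                for a, e in (("A", 2), ("B", 3))]
        rates = ar.reference_rates(make_counts(rows))
        r = rates.set_index(["sex", "race", "age_group"])["rate"]
        assert r[("men", "white", "40-59")] == pytest.approx(0.025)

    def test_all_zero_events_give_zero_rates(self):
        counts = full_grid_counts(["A", "B"], [2010], events=0)
        rates = ar.reference_rates(counts)
        assert (rates["rate"] == 0).all() and len(rates) == 16

    def test_matches_brute_force_on_random_toy(self):
        ds = ar.generate(ar.SyntheticScenario(nrows=1, ncols=5, seed=7,
                                              n_periods=2))
        rates = ar.reference_rates(ds.counts)
        oracle = brute_force_rates(ds.counts)
        for _, row in rates.iterrows():
            key = (row["sex"], row["race"], row["age_group"])
            assert row["rate"] == pytest.approx(oracle[key], rel=1e-12)

    def test_zero_population_stratum_named_in_strict_mode(self):
        counts = full_grid_counts(["A"], [2010], population=10, events=0)
        counts.loc[(counts["sex"] == "men") & (counts["race"] == "white") &
                   (counts["age_group"] == "80+"), "population"] = 0
        with pytest.raises(ValidationError, match="men/white/80"):
            ar.reference_rates(counts, allow_empty_strata=False)

    def test_empty_stratum_gets_zero_rate_by_default(self):
        rows = [{"area_id": "A", "year": 2010, "sex": "men", "race": "white",
                 "age_group": "40-59", "population": 100, "events": 5}]
        rates = ar.reference_rates(make_counts(rows))
        r = rates.set_index(["sex", "race", "age_group"])["rate"]
        assert r[("men", "white", "40-59")] == pytest.approx(0.05)
        assert r.drop(("men", "white", "40-59")).eq(0).all()


class TestExpectedCounts:
    def test_internal_identity_single_area(self):
        ds = ar.generate(ar.SyntheticScenario(nrows=1, ncols=1, seed=3))
        table = ar.sir_table(ds.counts)
        assert table["expected"].sum() == pytest.approx(
            table["observed"].sum(), rel=1e-12)

    def test_identical_populations_give_identical_E(self):
        counts = full_grid_counts(["A", "B"], [2010], population=500, events=1)
        table = ar.sir_table(counts)
        e = table.set_index("area_id")["expected"]
        assert e["A"] == pytest.approx(e["B"], rel=1e-12)

    def test_hand_computed_double_sum(self):
        # 3 areas x 2 periods, one stratum populated, rate = 9/600
        rows = []
        pops = {"A": 100, "B": 50, "C": 150}
        evs = {"A": 2, "B": 1, "C": 6}
        for a in pops:
            for y in (2010, 2011):
                rows.append({"area_id": a, "year": y, "sex": "women",
                             "race": "white", "age_group": "60-69",
                             "population": pops[a], "events": evs[a] // 2
                             if y == 2011 else evs[a] - evs[a] // 2})
        table = ar.sir_table(make_counts(rows))
        rate = 9 / 600
        for a in pops:
            got = table[table["area_id"] == a]["expected"]
            assert np.allclose(got, pops[a] * rate)

    def test_conservation_on_synthetic(self, small_dataset):
        table = ar.sir_table(small_dataset.counts)
        total_o = table["observed"].sum()
        assert abs(table["expected"].sum() - total_o) / total_o < 1e-9

    def test_scale_equivariance(self):
        counts = full_grid_counts(["A", "B"], [2010, 2011],
                                  population=300, events=3)
        rates = ar.reference_rates(counts)
        e1 = ar.expected_counts(counts, rates)
        scaled = counts.copy()
        scaled["population"] *= 10
        rates10 = rates.copy()
        rates10["rate"] /= 10
        e2 = ar.expected_counts(scaled, rates10)
        assert np.allclose(e1["expected"], e2["expected"])


class TestRatio:
    @pytest.mark.parametrize("observed, expected, want", [
        (10, 10.0, 1.0),
        (0, 4.0, 0.0),
        (3, 2.0, 1.5),
    ])
    def test_simple_quotients(self, observed, expected, want):
        assert standardize.ratio(observed, expected) == pytest.approx(want)

    def test_zero_over_zero_is_undefined_not_zero(self):
        assert math.isnan(standardize.ratio(0, 0.0))

    def test_positive_observed_with_zero_expected_is_error(self):
        with pytest.raises(ValidationError):
            standardize.ratio(3, 0.0)

    def test_region_ratio_sums_before_dividing(self):
        table = pd.DataFrame({
            "area_id": ["A", "B", "C"], "region_id": ["R"] * 3,
            "year": [2010] * 3,
            "observed": [1, 2, 3], "expected": [2.0, 2.0, 2.0],
        })
        out = standardize.aggregate_ratio(table, by="region")
        assert out["ratio"].iloc[0] == pytest.approx(1.0)
        # mean of area ratios would be (0.5 + 1.0 + 1.5)/3 = 1.0 here too,
        # so check a case where the two disagree
        table.loc[0, "expected"] = 0.5
        out = standardize.aggregate_ratio(table, by="region")
        assert out["ratio"].iloc[0] == pytest.approx(6 / 4.5)

    def test_pooled_period_aggregation(self):
        table = pd.DataFrame({
            "area_id": ["A", "A"], "region_id": ["R", "R"],
            "year": [2010, 2011],
            "observed": [1, 3], "expected": [2.0, 2.0],
        })
        out = standardize.aggregate_ratio(table, by="area", pool_periods=True)
        assert out["ratio"].iloc[0] == pytest.approx(1.0)

    def test_per_year_reference_option(self, small_dataset):
        table = ar.sir_table(small_dataset.counts, per_year_reference=True)
        # year-specific internal reference conserves within every year
        per_year = table.groupby("year")[["observed", "expected"]].sum()
        assert np.allclose(per_year["observed"], per_year["expected"])
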