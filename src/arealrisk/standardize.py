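"""Indirect standardization: per-stratum reference rates, expected counts,
and standardized incidence / mortality ratios (SIR / SMR).

Reference rates are internal by default: the pooled per-stratum event rate
over all areas and all periods.  Expected counts are then
``E_it = sum_s n_its * rate_s``, and the ratio for any aggregation level is
observed-over-expected with numerators and denominators summed first (ratio
of sums, never mean of ratios).  Internal standardization implies the
conservation identity ``sum_it E_it == sum_it O_it``.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from . import strata
from .errors import ValidationError

_STRATUM = list(strata.STRATUM_COLUMNS)


def reference_rates(counts: pd.DataFrame, per_year: bool = False,
                    allow_empty_strata: bool = True) -> pd.DataFrame:
    """Pooled per-stratum event rates over all areas (and periods).

    With ``per_year=True`` the pooling is within each calendar year instead
    (a year-specific reference), adding a ``year`` column.

    A stratum with zero population everywhere contributes nothing to any
    expected count; by default its rate is 0 (such strata arise naturally
    from the zero-fill contract on sparse toy tables).  With
    ``allow_empty_strata=False`` it is an error naming the stratum.
    """
    keys = _STRATUM + (["year"] if per_year else [])
    agg = counts.groupby(keys, as_index=False)[["events", "population"]].sum()
    zero = agg["population"] == 0
    if zero.any() and not allow_empty_strata:
        bad = agg.loc[zero, keys].astype(str).agg("/".join, axis=1)
        raise ValidationError(
            f"stratum with zero population everywhere: {', '.join(bad)}")
    with np.errstate(invalid="ignore"):
        agg["rate"] = np.where(agg["population"] > 0,
                               agg["events"] / agg["population"].replace(0, 1),
                               0.0)
    return agg[keys + ["rate"]]


def expected_counts(counts: pd.DataFrame, rates: pd.DataFrame) -> pd.DataFrame:
    """Expected events per area-period: E_it = sum_s population_its * rate_s."""
    per_year = "year" in rates.columns
    keys = _STRATUM + (["year"] if per_year else [])
    missing = (counts[keys].drop_duplicates().merge(rates, on=keys, how="left")
               ["rate"].isna())
    if missing.any():
        raise ValidationError("reference rates do not cover all 16 strata")
    merged = counts.merge(rates, on=keys, how="left")
    merged["expected"] = merged["population"] * merged["rate"]
    out = (merged.groupby(["area_id", "region_id", "year"], as_index=False)
           ["expected"].sum())
    return out


def observed_counts(counts: pd.DataFrame) -> pd.DataFrame:
    return (counts.groupby(["area_id", "region_id", "year"], as_index=False)
            ["events"].sum().rename(columns={"events": "observed"}))


def ratio(observed: float, expected: float) -> float:
    """Observed / expected; NaN for the undefined 0/0 case.

    A positive observed count with zero expected is impossible under
    internal standardization and is treated as an error.
    """
    if expected < 0:
        raise ValidationError("expected count must be non-negative")
    if expected == 0:
        if observed == 0:
            return math.nan
        raise ValidationError(
            f"observed {observed} events with zero expected count")
    return observed / expected


def sir_table(counts: pd.DataFrame, rates: pd.DataFrame | None = None,
              per_year_reference: bool = False) -> pd.DataFrame:
    """Per-area-per-year observed, expected and ratio under internal rates.

    The same computation serves incidence (SIR) and mortality (SMR): the
    outcome is whatever event the count table records.
    """
    if rates is None:
        rates = reference_rates(counts, per_year=per_year_reference)
    obs = observed_counts(counts)
    exp_ = expected_counts(counts, rates)
    table = obs.merge(exp_, on=["area_id", "region_id", "year"])
    table["ratio"] = [ratio(o, e) for o, e in
                      zip(table["observed"], table["expected"])]
    return table


def aggregate_ratio(table: pd.DataFrame, by: str = "region",
                    pool_periods: bool = False) -> pd.DataFrame:
    """Aggregate a ratio table by summing numerators and denominators first.

    ``by`` is "region" (sum member areas) or "area" (identity on areas);
    ``pool_periods=True`` additionally sums over years.
    """
    if by == "region":
        keys = ["region_id"]
    elif by == "area":
        keys = ["area_id", "region_id"]
    else:
        raise ValueError(f"unknown aggregation level: {by!r}")
    if not pool_periods:
        keys = keys + ["year"]
    agg = table.groupby(keys, as_index=False)[["observed", "expected"]].sum()
    agg["ratio"] = [ratio(o, e) for o, e in
                    zip(agg["observed"], agg["expected"])]
    return agg


def write_ratio_csv(table: pd.DataFrame, path: str | Path,
                    outcome: str = "sir") -> None:
    if outcome not in ("sir", "smr"):
        raise ValueError("outcome must be 'sir' or 'smr'")
    out = table.copy()
    out["outcome"] = outcome
    out.to_csv(path, index=False)
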