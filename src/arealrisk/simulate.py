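"""Seeded synthetic areal datasets with known ground truth.

The generator emulates the statistical structure the analysis assumes: a
lattice of areas grouped into regions, log-normal area populations split
across the 16 demographic strata with age-decreasing shares, a development
index covariate, a latent BYM risk surface (constrained-ICAR structured
effect plus iid heterogeneity), a shared linear trend with area-specific
slope deviations, and Poisson event counts.  Every draw is fully determined
by the scenario and its seed, and the truth record retains every latent
quantity so recovery tests can compare posterior estimates against it.

Baseline stratum rates are loosely shaped like ischemic-heart-disease
hospitalization (roughly fourfold increase from the youngest to the oldest
age group, higher in men); their absolute magnitudes are arbitrary — only
the structure matters for testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as ario
from . import strata
from .graph import (AdjacencyGraph, ICARStructure, build_adjacency,
                    grid_polygons, icar_structure, sample_icar)

_AGE_MULT = {"40-59": 1.0, "60-69": 2.0, "70-79": 3.0, "80+": 4.0}
_SEX_MULT = {"men": 1.0, "women": 0.75}
_RACE_MULT = {"white": 1.0, "non_white": 0.9}

#: Stratum population shares (within the 40+ population), roughly matching a
#: southern-Brazil age/sex/race composition.
_AGE_SHARE = {"40-59": 0.68, "60-69": 0.18, "70-79": 0.10, "80+": 0.04}
_SEX_SHARE = {"men": 0.489, "women": 0.511}
_RACE_SHARE = {"white": 0.703, "non_white": 0.297}


def default_rates(base: float = 0.004) -> dict[tuple[str, str, str], float]:
    """Annual per-person baseline event rates for the 16 strata."""
    return {(s, r, a): base * _SEX_MULT[s] * _RACE_MULT[r] * _AGE_MULT[a]
            for (s, r, a) in strata.STRATA}


@dataclass(frozen=True)
class SyntheticScenario:
    """Ground-truth parameters of one synthetic study.

    A scenario either specifies a lattice (``nrows`` x ``ncols`` unit
    squares, queen contiguity) or supplies an explicit graph.  ``seed``
    together with the scenario fully determines the dataset.
    """

    nrows: int = 10
    ncols: int = 10
    graph: AdjacencyGraph | None = None
    n_periods: int = 12
    first_year: int = 2010
    baseline_rates: dict = field(default_factory=default_rates)
    pop_median: float = 8_700.0
    pop_sigma: float = 1.2
    beta_ipdm: float = -2.0
    beta_small: float = 1.0
    beta_medium: float = 0.5
    beta_t: float = 0.3
    tau_u: float = 4.0
    tau_v: float = 16.0
    tau_delta: float = 25.0
    zero_latent: bool = False      # force u = v = delta = 0 exactly
    areas_per_region: int = 20
    seed: int = 0

    def __post_init__(self):
        for rate in self.baseline_rates.values():
            if not 0.0 <= rate < 1.0:
                raise ValueError("baseline rates must lie in [0, 1)")


@dataclass
class SyntheticDataset:
    counts: pd.DataFrame
    covariates: pd.DataFrame
    graph: AdjacencyGraph
    icar: ICARStructure
    geometries: dict | None
    truth: dict
    scenario: SyntheticScenario


def recovery_scenario(seed: int = 0) -> SyntheticScenario:
    """The 200-area reference scenario for parameter-recovery checks.

    A strong small-municipality effect (log-RR 3.3, RR about 27) against
    the large-area reference, on a 20 x 10 lattice over 12 periods.
    """
    return SyntheticScenario(nrows=20, ncols=10, beta_small=3.3,
                             beta_medium=1.8, beta_ipdm=-2.0, seed=seed)


def generate(scenario: SyntheticScenario) -> SyntheticDataset:
    """Draw one complete synthetic dataset from a scenario."""
    rng = np.random.default_rng(scenario.seed)

    if scenario.graph is not None:
        graph, geoms = scenario.graph, None
    else:
        geoms = grid_polygons(scenario.nrows, scenario.ncols)
        graph = build_adjacency(geoms, rule="queen")
    ids = list(graph.ids)
    n = len(ids)
    icar = icar_structure(graph)

    totals = np.round(scenario.pop_median *
                      np.exp(scenario.pop_sigma * rng.standard_normal(n))
                      ).astype(np.int64)
    ipdm = rng.uniform(0.3, 0.9, size=n)
    size_class = np.array([ario.classify_size(p) for p in totals])

    if scenario.zero_latent:
        u = np.zeros(n)
        v = np.zeros(n)
        delta = np.zeros(n)
    else:
        u = sample_icar(icar, scenario.tau_u, rng)
        v = rng.standard_normal(n) / math.sqrt(scenario.tau_v)
        delta = sample_icar(icar, scenario.tau_delta, rng)

    x_small = (size_class == "small").astype(float)
    x_medium = (size_class == "medium").astype(float)
    lin = (scenario.beta_ipdm * ipdm + scenario.beta_small * x_small +
           scenario.beta_medium * x_medium)

    T = scenario.n_periods
    t_scaled = np.arange(T) / (T - 1) if T > 1 else np.zeros(1)
    years = scenario.first_year + np.arange(T)
    # theta_it = exp(x_i'b + u_i + v_i + (b_t + d_i) t)
    log_theta = (lin + u + v)[:, None] + \
        (scenario.beta_t + delta)[:, None] * t_scaled[None, :]
    theta = np.exp(log_theta)

    shares = np.array([_SEX_SHARE[s] * _RACE_SHARE[r] * _AGE_SHARE[a]
                       for (s, r, a) in strata.STRATA])
    rates = np.array([scenario.baseline_rates[k] for k in strata.STRATA])
    pops = np.round(totals[:, None] * shares[None, :]).astype(np.int64)  # (n, 16)

    mean = pops[:, None, :] * rates[None, None, :] * theta[:, :, None]
    events = rng.poisson(mean)
    events = np.minimum(events, pops[:, None, :])  # respect events <= population

    region_of = _assign_regions(ids, scenario.areas_per_region)
    rows = {
        "area_id": np.repeat(ids, T * 16),
        "region_id": np.repeat([region_of[a] for a in ids], T * 16),
        "year": np.tile(np.repeat(years, 16), n),
        "sex": np.tile([s for (s, _, _) in strata.STRATA], n * T),
        "race": np.tile([r for (_, r, _) in strata.STRATA], n * T),
        "age_group": np.tile([a for (_, _, a) in strata.STRATA], n * T),
        "population": np.tile(pops, (1, T)).reshape(-1),
        "events": events.reshape(-1),
    }
    counts = ario.validate_counts(pd.DataFrame(rows))

    covariates = pd.DataFrame({
        "area_id": ids,
        "ipdm": ipdm,
        "population_total": totals,
        "size_class": size_class,
    })

    truth = {
        "ids": tuple(ids),
        "years": tuple(int(y) for y in years),
        "u": u, "v": v, "delta": delta,
        "beta": {"ipdm": scenario.beta_ipdm, "small": scenario.beta_small,
                 "medium": scenario.beta_medium},
        "beta_t": scenario.beta_t,
        "linear_predictor": lin,
        "theta": theta,
        "stratum_rates": dict(zip(strata.STRATA, rates)),
        "stratum_populations": pops,
        "region_of": region_of,
    }
    return SyntheticDataset(counts=counts, covariates=covariates, graph=graph,
                            icar=icar, geometries=geoms, truth=truth,
                            scenario=scenario)


def _assign_regions(ids: list[str], areas_per_region: int) -> dict[str, str]:
    n_regions = max(1, round(len(ids) / areas_per_region))
    per = math.ceil(len(ids) / n_regions)
    return {a: f"R{i // per:02d}" for i, a in enumerate(ids)}


def truth_rr(dataset: SyntheticDataset) -> pd.DataFrame:
    """The generator's own theta_it per area-period (long format)."""
    t = dataset.truth
    n, T = t["theta"].shape
    return pd.DataFrame({
        "area_id": np.repeat(t["ids"], T),
        "year": np.tile(t["years"], n),
        "theta": t["theta"].reshape(-1),
    })


def expected_events(dataset: SyntheticDataset) -> np.ndarray:
    """Analytic E[O_its] = n_its * rate_s * theta_it, shape (n, T, 16)."""
    t = dataset.truth
    rates = np.array([t["stratum_rates"][k] for k in strata.STRATA])
    return (t["stratum_populations"][:, None, :] * rates[None, None, :] *
            t["theta"][:, :, None])


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the dataset in the pipeline's canonical file dialects."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / "counts.csv",
        "covariates": outdir / "covariates.csv",
        "adjacency": outdir / "adjacency.txt",
        "truth_rr": outdir / "truth_rr.csv",
    }
    ario.write_counts(dataset.counts, paths["counts"])
    ario.write_covariates(dataset.covariates, paths["covariates"])
    dataset.graph.write_edge_list(paths["adjacency"])
    truth_rr(dataset).to_csv(paths["truth_rr"], index=False)
    if dataset.geometries is not None:
        paths["geometry"] = outdir / "geometry.geojson"
        feats = [ario.geometry_feature(a, g, {})
                 for a, g in sorted(dataset.geometries.items())]
        ario.write_geojson(feats, paths["geometry"])
    return paths
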