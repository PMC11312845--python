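"""Reading, validating and writing the pipeline's tabular and geometric inputs.

Canonical dialects
------------------
* counts CSV: columns ``area_id, region_id, year, sex, race, age_group,
  population, events`` (header required, UTF-8, comma separated).  One table
  per outcome (hospitalizations or deaths).  Upstream extraction — e.g. ICD-10
  I20–I25 filtering of registry exports — is a documented contract on this
  file, not something this package performs.
* covariates CSV: columns ``area_id, ipdm, population_total``; the size class
  is derived from ``population_total``.
* geometry: either a GeoJSON FeatureCollection whose features carry an
  ``area_id`` property, or a whitespace-separated undirected edge list with
  one edge per line.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from shapely.geometry import mapping as shapely_mapping, shape as shapely_shape

from . import strata
from .errors import GeometryError, SchemaError, ValidationError

COUNT_COLUMNS = (
    "area_id", "region_id", "year", "sex", "race", "age_group",
    "population", "events",
)

#: Population thresholds (persons) separating small / medium / large areas.
SMALL_MAX = 25_000        # exclusive upper bound of "small"
MEDIUM_MAX = 100_000      # inclusive upper bound of "medium"

SIZE_CLASSES = ("small", "medium", "large")


def classify_size(population: int | float) -> str:
    """Municipality size class from total population.

    Intervals are [0, 25000) -> small, [25000, 100000] -> medium,
    (100000, inf) -> large.
    """
    if population < 0:
        raise ValidationError(f"negative population: {population}")
    if population < SMALL_MAX:
        return "small"
    if population <= MEDIUM_MAX:
        return "medium"
    return "large"


def _require_columns(df: pd.DataFrame, required: tuple[str, ...], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing required column(s): {', '.join(missing)}")


def read_counts(path: str | Path, schema: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read and validate a stratified count table, zero-filling the full grid.

    Parameters
    ----------
    path : CSV file with the canonical columns.
    schema : optional mapping from canonical column names to the file's
        column names, for files with non-canonical headers.

    Returns
    -------
    A validated DataFrame covering the complete area x period x stratum grid
    (missing cells zero-filled with population 0, events 0), sorted on
    (area_id, year, sex, race, age_group).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})
    _require_columns(df, COUNT_COLUMNS, f"counts file {path.name}")
    return validate_counts(df[list(COUNT_COLUMNS)].copy())


def validate_counts(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a stratified count table and zero-fill the full grid."""
    _require_columns(df, COUNT_COLUMNS, "counts table")
    df = df.copy()
    df["area_id"] = df["area_id"].astype(str)
    df["region_id"] = df["region_id"].astype(str)
    df["sex"] = df["sex"].map(strata.normalize_sex)
    df["race"] = df["race"].map(strata.normalize_race)
    df["age_group"] = df["age_group"].map(strata.normalize_age_group)
    for col in ("year", "population", "events"):
        vals = pd.to_numeric(df[col], errors="raise")
        if not np.allclose(vals, np.round(vals)):
            raise ValidationError(f"column {col!r} must be integer-valued")
        df[col] = vals.astype(np.int64)
    for col in ("population", "events"):
        if (df[col] < 0).any():
            bad = df.index[df[col] < 0].tolist()
            raise ValidationError(f"negative {col} in rows {bad}")
    over = df["events"] > df["population"]
    if over.any():
        rows = df.loc[over, ["area_id", "year", "sex", "race", "age_group",
                             "population", "events"]]
        raise ValidationError(
            "events exceed population in rows:\n" + rows.to_string(index=False)
        )
    key = ["area_id", "year", "sex", "race", "age_group"]
    dup = df.duplicated(subset=key)
    if dup.any():
        raise ValidationError(f"duplicate (area, period, stratum) keys in rows "
                              f"{df.index[dup].tolist()}")
    regions = df.groupby("area_id")["region_id"].nunique()
    multi = regions[regions > 1]
    if not multi.empty:
        raise ValidationError(
            f"areas mapped to multiple regions: {', '.join(multi.index)}")

    # zero-fill the complete area x period x stratum grid
    areas = sorted(df["area_id"].unique())
    years = sorted(df["year"].unique())
    grid = pd.MultiIndex.from_product(
        [areas, years, strata.SEXES, strata.RACES, strata.AGE_GROUPS],
        names=key,
    )
    df = (df.set_index(key).reindex(grid)
            .fillna({"population": 0, "events": 0}))
    region_of = df["region_id"].dropna().groupby(level="area_id").first().to_dict()
    df = df.reset_index()
    df["region_id"] = df["area_id"].map(region_of)
    df[["population", "events"]] = df[["population", "events"]].astype(np.int64)
    return df[list(COUNT_COLUMNS)].sort_values(key, ignore_index=True)


def write_counts(df: pd.DataFrame, path: str | Path) -> None:
    """Write a stratified count table in the canonical CSV dialect."""
    _require_columns(df, COUNT_COLUMNS, "counts table")
    df[list(COUNT_COLUMNS)].to_csv(path, index=False)


def read_covariates(path: str | Path) -> pd.DataFrame:
    """Read area-level covariates: development index and derived size class.

    Returns a DataFrame with columns area_id, ipdm, population_total,
    size_class.  Missing or out-of-range values are hard errors — no
    imputation is attempted.
    """
    df = pd.read_csv(path)
    _require_columns(df, ("area_id", "ipdm", "population_total"),
                     f"covariates file {Path(path).name}")
    return validate_covariates(df)


def validate_covariates(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["area_id"] = df["area_id"].astype(str)
    if df["area_id"].duplicated().any():
        raise ValidationError("duplicate area_id in covariates")
    if df[["ipdm", "population_total"]].isna().any().any():
        bad = df.loc[df[["ipdm", "population_total"]].isna().any(axis=1), "area_id"]
        raise ValidationError(f"missing covariate values for areas: "
                              f"{', '.join(bad)}")
    if ((df["ipdm"] < 0) | (df["ipdm"] > 1)).any():
        raise ValidationError("ipdm values must lie in [0, 1]")
    df["size_class"] = df["population_total"].map(classify_size)
    return df[["area_id", "ipdm", "population_total", "size_class"]]


def write_covariates(df: pd.DataFrame, path: str | Path) -> None:
    df[["area_id", "ipdm", "population_total"]].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# geometry / adjacency input


def read_geometry(path: str | Path, known_ids: set[str] | None = None):
    """Read area geometry (GeoJSON) or a plain-text adjacency edge list.

    Returns either ``dict[area_id, shapely geometry]`` (GeoJSON input) or a
    list of ``(a, b)`` edge tuples (edge-list input); both are accepted by
    :func:`arealrisk.graph.build_adjacency`.

    With ``known_ids`` given (the area ids present in the count table),
    edge-list ids outside that set are an error.  GeoJSON input returns all
    geometries regardless; the caller selects the ones it needs.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    stripped = text.lstrip()
    if stripped.startswith("{"):
        return _parse_geojson(text, path)
    return _parse_edge_list(text, known_ids)


def _parse_geojson(text: str, path: Path) -> dict:
    doc = json.loads(text)
    if doc.get("type") != "FeatureCollection":
        raise GeometryError(f"{path.name}: expected a GeoJSON FeatureCollection")
    geoms: dict[str, object] = {}
    for feat in doc.get("features", []):
        props = feat.get("properties") or {}
        if "area_id" not in props:
            raise GeometryError(f"{path.name}: feature without an 'area_id' property")
        aid = str(props["area_id"])
        if aid in geoms:
            raise GeometryError(f"duplicate area_id in geometry: {aid}")
        geom = shapely_shape(feat["geometry"])
        if not geom.is_valid:
            raise GeometryError(f"invalid geometry for area {aid}")
        geoms[aid] = geom
    return geoms


def _parse_edge_list(text: str, known_ids: set[str] | None) -> list[tuple[str, str]]:
    edges: list[tuple[str, str]] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise GeometryError(f"edge list line {lineno}: expected two ids, got {line!r}")
        a, b = parts
        if a == b:
            raise GeometryError(f"edge list line {lineno}: self-loop {a!r}")
        if known_ids is not None:
            for x in (a, b):
                if x not in known_ids:
                    raise GeometryError(f"edge list line {lineno}: unknown area id {x!r}")
        edges.append((a, b))
    return edges


def write_geojson(features: list[dict], path: str | Path) -> None:
    """Write a FeatureCollection with plain-JSON serialization."""
    doc = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(doc, indent=None, sort_keys=True),
                          encoding="utf-8")


def geometry_feature(area_id: str, geom, properties: dict) -> dict:
    props = {"area_id": area_id, **properties}
    return {"type": "Feature", "properties": props,
            "geometry": shapely_mapping(geom)}
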