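"""Analysis outputs: region-year trend tables and GeoJSON risk maps.

The canonical products are CSV tables and RFC 7946 FeatureCollections; any
cartographic styling is left to downstream GIS tools.
"""

from __future__ import annotations

import json
import math
import platform
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import GeometryError, ValidationError
from .io import geometry_feature, write_geojson

#: slopes within this tolerance of zero are called "flat"
SLOPE_TOLERANCE = 1e-6


def region_trends(rr_table: pd.DataFrame, min_years: int = 3,
                  tolerance: float = SLOPE_TOLERANCE) -> pd.DataFrame:
    """Per-region OLS slope of mean relative risk on year, with a direction.

    Input is a region-year table with columns region_id, year, mean_rr.
    Regions with fewer than ``min_years`` years are skipped with a warning.
    Direction is "rising" for slope > tolerance, "falling" for slope <
    -tolerance, otherwise "flat".
    """
    required = {"region_id", "year", "mean_rr"}
    missing = required - set(rr_table.columns)
    if missing:
        raise ValidationError(f"trend table missing columns: {sorted(missing)}")
    out_rows = []
    for region, grp in rr_table.groupby("region_id"):
        grp = grp.sort_values("year")
        if grp["year"].nunique() < min_years:
            warnings.warn(f"region {region}: fewer than {min_years} years, "
                          f"skipped", stacklevel=2)
            continue
        slope = np.polyfit(grp["year"].to_numpy(dtype=float),
                           grp["mean_rr"].to_numpy(dtype=float), 1)[0]
        if slope > tolerance:
            direction = "rising"
        elif slope < -tolerance:
            direction = "falling"
        else:
            direction = "flat"
        for _, row in grp.iterrows():
            out_rows.append({"region_id": region, "year": int(row["year"]),
                             "mean_rr": float(row["mean_rr"]),
                             "slope": float(slope), "direction": direction})
    return pd.DataFrame(out_rows,
                        columns=["region_id", "year", "mean_rr",
                                 "slope", "direction"])


_MAP_FIELDS = ("rr", "observed", "expected", "ratio")


def export_maps(table: pd.DataFrame, geometries: dict,
                path: str | Path | None = None) -> dict:
    """Join an area-level risk table to geometry as a FeatureCollection.

    Numeric properties are rounded to 6 decimals (lossless at that
    precision on re-read); undefined ratios become JSON null, never 0.
    """
    missing = [a for a in table.get("area_id", pd.Series(dtype=str)).astype(str)
               if a not in geometries]
    if missing:
        raise GeometryError(f"areas without geometry: {', '.join(missing)}")
    features = []
    for _, row in table.iterrows():
        props = {}
        for f in _MAP_FIELDS:
            if f not in table.columns:
                continue
            val = row[f]
            if val is None or (isinstance(val, float) and math.isnan(val)):
                props[f] = None
            elif isinstance(val, float) and not math.isfinite(val):
                raise ValidationError(f"non-finite {f} for area {row['area_id']}")
            else:
                props[f] = round(float(val), 6)
        aid = str(row["area_id"])
        features.append(geometry_feature(aid, geometries[aid], props))
    doc = {"type": "FeatureCollection", "features": features}
    if path is not None:
        write_geojson(features, path)
    return doc


def read_map_table(path: str | Path) -> pd.DataFrame:
    """Re-read an exported risk map back into the area-level table."""
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    rows = []
    for feat in doc.get("features", []):
        props = feat.get("properties", {})
        row = {"area_id": str(props["area_id"])}
        for f in _MAP_FIELDS:
            if f in props:
                row[f] = math.nan if props[f] is None else float(props[f])
        rows.append(row)
    return pd.DataFrame(rows)


def write_manifest(path: str | Path, *, seed: int, config: dict,
                   outputs: dict[str, str] | None = None) -> None:
    """Record the run configuration needed to reproduce outputs exactly."""
    import arealrisk

    doc = {
        "package": "arealrisk",
        "version": arealrisk.__version__,
        "python": platform.python_version(),
        "seed": seed,
        "config": config,
        "outputs": outputs or {},
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True,
                                     default=str), encoding="utf-8")
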