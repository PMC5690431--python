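"""Reading and writing the pipeline's tabular and geographic artifacts.

CSV is the canonical interchange format; GeoJSON carries the same properties
plus point (centroid) or polygon geometry. Coordinates are planar projected
metres throughout — no CRS transformation is performed, and that convention
is declared in every artifact's metadata sidecar.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import mapping, shape, Point

NUMERIC_COLUMNS = (
    "u",
    "v",
    "total_children",
    "underweight",
    "healthy",
    "overweight",
    "obese",
    "education_raw",
    "immigrants_raw",
    "income",
    "fastfood_exposure",
    "park_exposure",
    "walkscore",
    "pathway_km",
)


def _validate(table: pd.DataFrame, numeric_columns: Iterable[str]) -> pd.DataFrame:
    if "id" not in table.columns:
        raise ValueError("table has no 'id' column")
    dup = table["id"][table["id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate neighbourhood ids: {sorted(set(dup))[:5]}")
    for col in numeric_columns:
        if col not in table.columns:
            continue
        coerced = pd.to_numeric(table[col], errors="coerce")
        bad = coerced.isna() & table[col].notna()
        if bad.any():
            row = int(np.where(bad)[0][0])
            raise ValueError(f"non-numeric value in column {col!r} at row {row}: {table[col].iloc[row]!r}")
        table[col] = coerced
    return table


def read_table(path: str | Path, numeric_columns: Iterable[str] = NUMERIC_COLUMNS) -> pd.DataFrame:
    """Read a neighbourhood table from CSV or GeoJSON.

    Column order is irrelevant and unknown columns are preserved untouched.
    GeoJSON features contribute their properties; if ``u``/``v`` are absent
    they are filled from the geometry's centroid (projected metres).
    """
    path = Path(path)
    if path.stat().st_size == 0:
        raise ValueError(f"{path} is empty")
    if path.suffix.lower() in (".geojson", ".json"):
        with open(path) as fh:
            gj = json.load(fh)
        if gj.get("type") != "FeatureCollection":
            raise ValueError(f"{path} is not a GeoJSON FeatureCollection")
        rows = []
        for feat in gj["features"]:
            props = dict(feat.get("properties") or {})
            if "id" not in props and "id" in feat:
                props["id"] = feat["id"]
            geom = feat.get("geometry")
            if geom is not None and ("u" not in props or "v" not in props):
                c = shape(geom).centroid
                props.setdefault("u", c.x)
                props.setdefault("v", c.y)
            rows.append(props)
        table = pd.DataFrame(rows)
    else:
        table = pd.read_csv(path, float_precision="round_trip")
        if table.empty and table.columns.empty:
            raise ValueError(f"{path} contains no data")
    return _validate(table, numeric_columns)


def write_table(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a table as CSV at full precision (floats round-trip exactly)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False, float_format=lambda v: format(v, ".17g"))
    return path


def write_geojson_table(table: pd.DataFrame, path: str | Path, geometry=None) -> Path:
    """Write a table as a GeoJSON FeatureCollection.

    ``geometry`` maps id to a shapely geometry or GeoJSON dict; by default a
    Point is built from the ``u``/``v`` centroid columns.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    features = []
    for _, row in table.iterrows():
        props = {k: (v.item() if isinstance(v, np.generic) else v) for k, v in row.items()}
        if geometry is not None:
            geom = geometry[row["id"]]
            geom = mapping(geom) if hasattr(geom, "__geo_interface__") else geom
        else:
            geom = mapping(Point(float(row["u"]), float(row["v"])))
        features.append({"type": "Feature", "id": str(row["id"]), "geometry": geom, "properties": props})
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
    return path


def config_hash(config_dict: dict) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(config_dict, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_metadata(path: str | Path, seed: int, cfg_hash: str, extra: dict | None = None) -> Path:
    """Sidecar JSON stamping an artifact with its seed and config hash."""
    meta = {
        "seed": seed,
        "config_hash": cfg_hash,
        "crs": "planar projected metres (no transformation applied)",
    }
    if extra:
        meta.update(extra)
    side = Path(str(path) + ".meta.json")
    with open(side, "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
    return side


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON configuration mapping."""
    path = Path(path)
    with open(path) as fh:
        if path.suffix.lower() in (".yaml", ".yml"):
            cfg = yaml.safe_load(fh)
        else:
            cfg = json.load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"configuration in {path} must be a mapping")
    return cfg
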