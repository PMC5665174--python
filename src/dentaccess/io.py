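"""Readers and writers: CSV tables, YAML config, GeoJSON export.

Interchange formats are deliberately plain: RFC-4180 CSV for tabular
data (tracts, providers, long-format distances, demand, reports), YAML
for configuration, GeoJSON point features for mapping. Coordinates are
WGS84 lon/lat decimal degrees; distances are statute miles throughout.
Every table directory carries a ``schema.json`` sidecar naming the
column schemas; loaders validate columns and report offending rows by
number.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .demand import NeedModel, Tract
from .distances import (
    AccessStandards,
    DistanceMatrix,
    build_distance_matrix,
    distance_matrix_from_table,
)
from .supply import ProviderSite
from .synthetic import ProblemInstance, SyntheticConfig

__all__ = [
    "tracts_to_frame",
    "providers_to_frame",
    "tracts_from_frame",
    "providers_from_frame",
    "instance_from_frames",
    "write_instance",
    "load_instance",
    "export_geojson",
    "save_config",
    "load_config",
]

TRACT_COLUMNS = {
    "tract_id": str,
    "county_id": str,
    "lon": float,
    "lat": float,
    "rural": bool,
    "children_public": float,
    "children_private": float,
    "children_excluded": float,
    "vehicle_fraction": float,
    "high_risk_fraction": float,
}
PROVIDER_COLUMNS = {
    "provider_id": str,
    "office_id": str,
    "lon": float,
    "lat": float,
    "rural": bool,
    "capacity_hours": float,
    "accepts_public": bool,
    "public_caseload_fraction": float,
}


def _canonical(df: pd.DataFrame, columns: dict) -> pd.DataFrame:
    return df[list(columns)].astype(
        {c: t for c, t in columns.items() if t is not str}
    )


def tracts_to_frame(tracts: Sequence[Tract]) -> pd.DataFrame:
    return _canonical(
        pd.DataFrame([dataclasses.asdict(t) for t in tracts]), TRACT_COLUMNS
    )


def providers_to_frame(providers: Sequence[ProviderSite]) -> pd.DataFrame:
    return _canonical(
        pd.DataFrame([dataclasses.asdict(p) for p in providers]), PROVIDER_COLUMNS
    )


def _validate_frame(df: pd.DataFrame, columns: dict, what: str) -> pd.DataFrame:
    missing = set(columns) - set(df.columns)
    if missing:
        raise ValueError(f"{what} table missing columns: {sorted(missing)}")
    out = df.copy()
    for col, typ in columns.items():
        if typ is float:
            coerced = pd.to_numeric(out[col], errors="coerce")
            bad = coerced.isna() & out[col].notna()
            if bad.any():
                rows = (np.nonzero(bad.to_numpy())[0] + 1).tolist()[:5]
                raise ValueError(
                    f"{what} table column {col!r} non-numeric at row(s) {rows}"
                )
            if coerced.isna().any():
                rows = (np.nonzero(coerced.isna().to_numpy())[0] + 1).tolist()[:5]
                raise ValueError(f"{what} table column {col!r} empty at row(s) {rows}")
            out[col] = coerced.astype(float)
        elif typ is bool:
            if out[col].dtype != bool:
                out[col] = (
                    out[col]
                    .astype(str)
                    .str.strip()
                    .str.lower()
                    .map({"true": True, "false": False, "1": True, "0": False})
                )
                if out[col].isna().any():
                    rows = (np.nonzero(out[col].isna().to_numpy())[0] + 1).tolist()[:5]
                    raise ValueError(
                        f"{what} table column {col!r} not boolean at row(s) {rows}"
                    )
        else:
            out[col] = out[col].astype(str)
    id_col = f"{what}_id"
    if id_col in out.columns and out[id_col].duplicated().any():
        dupes = out.loc[out[id_col].duplicated(), id_col].tolist()[:5]
        raise ValueError(f"duplicate {id_col} values: {dupes}")
    return out


def tracts_from_frame(df: pd.DataFrame) -> list[Tract]:
    df = _validate_frame(df, TRACT_COLUMNS, "tract")
    return [Tract(**{k: row[k] for k in TRACT_COLUMNS}) for _, row in df.iterrows()]


def providers_from_frame(df: pd.DataFrame) -> list[ProviderSite]:
    df = _validate_frame(df, PROVIDER_COLUMNS, "provider")
    return [
        ProviderSite(**{k: row[k] for k in PROVIDER_COLUMNS}) for _, row in df.iterrows()
    ]


def instance_from_frames(
    tracts: pd.DataFrame,
    providers: pd.DataFrame,
    distances: pd.DataFrame | None = None,
    *,
    standards: AccessStandards | None = None,
    need_model: NeedModel | None = None,
) -> ProblemInstance:
    """Assemble a validated instance from tabular inputs.

    With no distance table, haversine distances are computed; with one,
    it is passed through as an external-table metric.
    """
    tr = tracts_from_frame(tracts)
    pr = providers_from_frame(providers)
    if distances is None:
        D = build_distance_matrix(tr, pr)
    else:
        D = distance_matrix_from_table(distances, tr, pr)
    return ProblemInstance(
        tracts=tuple(tr),
        providers=tuple(pr),
        distance=D,
        standards=standards or AccessStandards(),
        need_model=need_model or NeedModel(),
    )


_SCHEMA = {
    "tracts.csv": {k: t.__name__ for k, t in TRACT_COLUMNS.items()},
    "providers.csv": {k: t.__name__ for k, t in PROVIDER_COLUMNS.items()},
    "distances.csv": {"tract_id": "str", "provider_id": "str", "miles": "float"},
}


def write_instance(
    instance: ProblemInstance, outdir: str | Path, *, write_distances: bool = True
) -> Path:
    """Write tracts.csv, providers.csv, (optionally) distances.csv,
    instance.geojson, config.yaml and the schema sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tracts_to_frame(instance.tracts).to_csv(outdir / "tracts.csv", index=False)
    providers_to_frame(instance.providers).to_csv(outdir / "providers.csv", index=False)
    if write_distances:
        instance.distance.to_long_frame().to_csv(outdir / "distances.csv", index=False)
    export_geojson(instance.tracts, None, outdir / "instance.geojson")
    save_config(
        {
            "standards": dataclasses.asdict(instance.standards),
            "distance_metric": instance.distance.metric,
        },
        outdir / "config.yaml",
    )
    (outdir / "schema.json").write_text(json.dumps(_SCHEMA, indent=2))
    return outdir


def load_instance(
    indir: str | Path,
    *,
    use_distance_table: bool | None = None,
    standards: AccessStandards | None = None,
    need_model: NeedModel | None = None,
) -> ProblemInstance:
    """Load an instance directory written by :func:`write_instance`.

    ``use_distance_table=None`` uses distances.csv when present.
    """
    indir = Path(indir)
    tracts = pd.read_csv(indir / "tracts.csv")
    providers = pd.read_csv(indir / "providers.csv")
    dist_path = indir / "distances.csv"
    distances = None
    if use_distance_table is None:
        use_distance_table = dist_path.exists()
    if use_distance_table:
        if not dist_path.exists():
            raise FileNotFoundError(f"no distance table at {dist_path}")
        distances = pd.read_csv(dist_path)
    cfg_path = indir / "config.yaml"
    if standards is None and cfg_path.exists():
        cfg = load_config(cfg_path)
        if "standards" in cfg:
            standards = AccessStandards(**cfg["standards"])
    return instance_from_frames(
        tracts, providers, distances, standards=standards, need_model=need_model
    )


def export_geojson(
    tracts: Sequence[Tract],
    access_report: pd.DataFrame | None,
    path: str | Path,
    group: str = "public",
) -> Path:
    """Tract centroids as a GeoJSON FeatureCollection.

    When an access report is given, the chosen group's measures become
    feature properties; otherwise measure properties are null.
    """
    by_tract = {}
    if access_report is not None:
        sub = access_report[access_report["group"] == group]
        by_tract = {
            row["tract_id"]: {
                "met_need": float(row["met_need"]),
                "mean_travel_mi": float(row["mean_travel_mi"]),
                "scarcity": float(row["scarcity"]),
                "service_level": str(row["service_level"]),
            }
            for _, row in sub.iterrows()
        }
    features = []
    for t in tracts:
        props = {
            "tract_id": t.tract_id,
            "county_id": t.county_id,
            "rural": bool(t.rural),
            "met_need": None,
            "mean_travel_mi": None,
            "scarcity": None,
            "service_level": None,
        }
        props.update(by_tract.get(t.tract_id, {}))
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [t.lon, t.lat]},
                "properties": props,
            }
        )
    doc = {"type": "FeatureCollection", "features": features}
    path = Path(path)
    path.write_text(json.dumps(doc))
    return path


def save_config(config: dict | SyntheticConfig, path: str | Path) -> Path:
    if isinstance(config, SyntheticConfig):
        config = dataclasses.asdict(config)
    path = Path(path)
    path.write_text(yaml.safe_dump(_to_plain(config), sort_keys=True))
    return path


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _to_plain(obj):
    """YAML-safe conversion (tuples -> lists, numpy scalars -> python)."""
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.bool_):
        return bool(obj)
    return obj
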