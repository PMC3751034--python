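"""Readers/writers for the interchange formats and the run manifest.

CSV dialect: comma-separated, UTF-8, header row, empty field = missing
(the only missing-value marker).  Years are integers; coordinates are
planar kilometres written with six decimals.  Road networks travel as
GeoJSON LineString features (properties ``traffic_weight``,
``intersection_boost``) or as flat CSV; meteorological summaries as
YAML/JSON.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dispersion import MetSummary, RoadSegment, StabilityClass
from .dose import YearSeries

FLOAT_FMT = "%.6f"


# --- road network ----------------------------------------------------------

def write_network_geojson(segments, path) -> None:
    features = []
    for s in segments:
        features.append({
            "type": "Feature",
            "geometry": {"type": "LineString",
                         "coordinates": [[round(s.x1, 6), round(s.y1, 6)],
                                         [round(s.x2, 6), round(s.y2, 6)]]},
            "properties": {"id": s.id, "traffic_weight": s.traffic_weight,
                           "intersection_boost": s.intersection_boost},
        })
    Path(path).write_text(json.dumps(
        {"type": "FeatureCollection", "features": features}))


def read_network_geojson(path) -> list[RoadSegment]:
    data = json.loads(Path(path).read_text())
    segs = []
    for f in data["features"]:
        (x1, y1), (x2, y2) = f["geometry"]["coordinates"][:2]
        p = f.get("properties", {})
        segs.append(RoadSegment(
            id=str(p.get("id", len(segs))), x1=x1, y1=y1, x2=x2, y2=y2,
            traffic_weight=float(p.get("traffic_weight", 1.0)),
            intersection_boost=float(p.get("intersection_boost", 1.0))))
    return segs


def write_network_csv(segments, path) -> None:
    pd.DataFrame([{
        "id": s.id, "x1": s.x1, "y1": s.y1, "x2": s.x2, "y2": s.y2,
        "traffic_weight": s.traffic_weight,
        "intersection_boost": s.intersection_boost,
    } for s in segments]).to_csv(path, index=False, float_format=FLOAT_FMT)


def read_network_csv(path) -> list[RoadSegment]:
    df = pd.read_csv(path)
    return [RoadSegment(id=str(r.id), x1=r.x1, y1=r.y1, x2=r.x2, y2=r.y2,
                        traffic_weight=r.traffic_weight,
                        intersection_boost=r.intersection_boost)
            for r in df.itertuples()]


# --- met summaries ---------------------------------------------------------

def met_to_dict(met: MetSummary) -> dict:
    return {
        "month": met.month,
        "sector_probs": [float(p) for p in met.sector_probs],
        "sector_speeds": [float(s) for s in met.sector_speeds],
        "stability_classes": [
            {"probability": c.probability,
             "sigma_y": list(c.sigma_y), "sigma_z": list(c.sigma_z)}
            for c in met.stability_classes],
        "mixing_height": met.mixing_height,
        "background": met.background,
    }


def met_from_dict(d: dict) -> MetSummary:
    classes = tuple(
        StabilityClass(probability=c["probability"],
                       sigma_y=tuple(c["sigma_y"]),
                       sigma_z=tuple(c["sigma_z"]))
        for c in d.get("stability_classes", []))
    return MetSummary(month=d.get("month", 1),
                      sector_probs=np.asarray(d["sector_probs"]),
                      sector_speeds=np.asarray(d["sector_speeds"]),
                      stability_classes=classes,
                      mixing_height=d.get("mixing_height", 800.0),
                      background=d.get("background", 0.0))


def write_met_yaml(met_by_month, path) -> None:
    if isinstance(met_by_month, MetSummary):
        met_by_month = [met_by_month]
    Path(path).write_text(yaml.safe_dump(
        [met_to_dict(m) for m in met_by_month], sort_keys=False))


def read_met_yaml(path) -> list[MetSummary]:
    data = yaml.safe_load(Path(path).read_text())
    if isinstance(data, dict):
        data = [data]
    return [met_from_dict(d) for d in data]


# --- annual series ---------------------------------------------------------

def write_series_csv(series: YearSeries, path,
                     value_name: str = "value") -> None:
    pd.DataFrame({"year": series.years(),
                  value_name: [series.values[y] for y in series.years()]}
                 ).to_csv(path, index=False)


def read_series_csv(path, boundary_year: int | None = None,
                    value_name: str | None = None) -> YearSeries:
    df = pd.read_csv(path)
    col = value_name or df.columns[1]
    return YearSeries(dict(zip(df["year"].astype(int), df[col].astype(float))),
                      boundary_year=boundary_year)


# --- cohort tables ---------------------------------------------------------

def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_residences_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["in_area"] = df["in_area"].astype(bool)
    for col in ("start_year", "end_year", "subject_id", "residence_id"):
        df[col] = df[col].astype(int)
    return df


def read_subjects_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("subject_id", "case", "birth_year", "diagnosis_year"):
        if col in df.columns:
            df[col] = df[col].astype(int)
    return df


def write_transfer_csv(transfer: pd.DataFrame, path) -> None:
    """Transfer-value table (subject_id, residence_id, year, [month,] D)."""
    transfer.to_csv(path, index=False)


def write_doses_csv(doses: pd.DataFrame, pdi: pd.DataFrame, path) -> None:
    out = doses.merge(pdi[["subject_id", "pdi"]], on="subject_id")
    cols = ["subject_id", "form", "z_total", "z_calc", "z_imp", "pdi"]
    out[cols].to_csv(path, index=False)


# --- config and manifest ---------------------------------------------------

def config_to_dict(cfg) -> dict:
    return dataclasses.asdict(cfg)


def load_config(path, cls):
    data = yaml.safe_load(Path(path).read_text()) or {}
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown config fields: {sorted(unknown)}")
    for f in dataclasses.fields(cls):
        if f.name in data and isinstance(data[f.name], list):
            data[f.name] = tuple(data[f.name])
    return cls(**data)


def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(path, config, master_seed: int,
                   imputation_seeds=None, input_files=None,
                   fallback_counts=None, warnings_count: int = 0) -> dict:
    """Run manifest: everything needed to reproduce a run byte-identically."""
    manifest = {
        "config": config_to_dict(config) if dataclasses.is_dataclass(config)
        else dict(config),
        "master_seed": int(master_seed),
        "imputation_seeds": [int(s) for s in (imputation_seeds or [])],
        "input_digests": {str(p): file_digest(p)
                          for p in (input_files or [])},
        "fallback_counts": fallback_counts or {},
        "warnings": warnings_count,
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
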