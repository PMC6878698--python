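"""File I/O: CSV schemas for every pipeline artifact and GeoJSON export.

All CSVs are UTF-8, comma-delimited, with a mandatory header row and
RFC-4180 quoting (pandas defaults). County FIPS codes are read as strings
so leading zeros survive. Every writer here has a matching reader and the
pair round-trips exactly.

The GeoJSON export is a FeatureCollection with one Point feature per PHD
(coordinates in [longitude, latitude] order, per the GeoJSON standard) and
one geometry-less feature per county carrying the FIPS code and estimated
smoking proportion; county polygons are joined externally by FIPS.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .categories import COVARIATE_LEVELS, COVARIATE_ORDER
from .errors import ValidationError
from .harmonize import RAW_COLUMNS
from .microsim import CountyEstimate, PHDRecord, SmokerEstimate

SURVEY_COLUMNS = RAW_COLUMNS + ["smokes"]


def write_survey_csv(path, raw: pd.DataFrame) -> None:
    cols = [c for c in SURVEY_COLUMNS if c in raw.columns]
    raw[cols].to_csv(path, index=False)


def read_survey_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"state": str, "hispanic": str})
    if "children_at_home" in df.columns:
        df["children_at_home"] = (
            df["children_at_home"].astype(str).str.lower().isin(["true", "yes", "1"])
        )
    return df


def _marginal_columns() -> list[str]:
    return [
        f"{cov}::{lev}" for cov in COVARIATE_ORDER for lev in COVARIATE_LEVELS[cov]
    ]


PHD_BASE_COLUMNS = [
    "phd_id",
    "name",
    "state",
    "county_fips",
    "latitude",
    "longitude",
    "n_residents",
]


def write_phd_csv(path, phds: list[PHDRecord]) -> None:
    rows = []
    for p in phds:
        row = {
            "phd_id": p.phd_id,
            "name": p.name,
            "state": p.state,
            "county_fips": p.county_fips,
            "latitude": p.latitude,
            "longitude": p.longitude,
            "n_residents": p.n_residents,
        }
        for cov in COVARIATE_ORDER:
            vec = np.asarray(p.marginals[cov], dtype=float)
            for lev, frac in zip(COVARIATE_LEVELS[cov], vec):
                row[f"{cov}::{lev}"] = frac
        rows.append(row)
    pd.DataFrame(rows, columns=PHD_BASE_COLUMNS + _marginal_columns()).to_csv(
        path, index=False
    )


def read_phd_csv(path) -> list[PHDRecord]:
    df = pd.read_csv(path, dtype={"county_fips": str, "state": str, "phd_id": str})
    missing = [c for c in PHD_BASE_COLUMNS + _marginal_columns() if c not in df.columns]
    if missing:
        raise ValidationError(f"PHD table {path} missing column(s) {missing}")
    phds = []
    for _, row in df.iterrows():
        marginals = {
            cov: np.array(
                [row[f"{cov}::{lev}"] for lev in COVARIATE_LEVELS[cov]], dtype=float
            )
            for cov in COVARIATE_ORDER
        }
        phd = PHDRecord(
            phd_id=row["phd_id"],
            name=row["name"],
            state=row["state"],
            county_fips=row["county_fips"],
            latitude=float(row["latitude"]),
            longitude=float(row["longitude"]),
            n_residents=int(row["n_residents"]),
            marginals=marginals,
        )
        phd.validate()
        phds.append(phd)
    return phds


def write_tax_csv(path, tax_by_state: dict[str, float]) -> None:
    pd.DataFrame(
        {"state": sorted(tax_by_state), "tax_usd_per_pack": [tax_by_state[s] for s in sorted(tax_by_state)]}
    ).to_csv(path, index=False)


def read_tax_csv(path) -> dict[str, float]:
    df = pd.read_csv(path, dtype={"state": str})
    if not {"state", "tax_usd_per_pack"} <= set(df.columns):
        raise ValidationError(f"tax table {path} needs columns state, tax_usd_per_pack")
    return dict(zip(df["state"].str.upper(), df["tax_usd_per_pack"].astype(float)))


def write_estimates_csv(path, estimates: list[SmokerEstimate]) -> None:
    rows = [
        {
            "phd_id": e.phd_id,
            "n_residents": e.n_residents,
            "estimated_smokers_mean": e.estimated_smokers_mean,
            "estimated_smokers_sd": e.estimated_smokers_sd,
            "interval_lo": e.percentile_interval[0],
            "interval_hi": e.percentile_interval[1],
            "bootstrap_counts": ";".join(f"{c:g}" for c in e.bootstrap_counts),
        }
        for e in estimates
    ]
    cols = [
        "phd_id",
        "n_residents",
        "estimated_smokers_mean",
        "estimated_smokers_sd",
        "interval_lo",
        "interval_hi",
        "bootstrap_counts",
    ]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_estimates_csv(path) -> list[SmokerEstimate]:
    df = pd.read_csv(path, dtype={"phd_id": str, "bootstrap_counts": str})
    return [
        SmokerEstimate(
            phd_id=row["phd_id"],
            n_residents=int(row["n_residents"]),
            estimated_smokers_mean=float(row["estimated_smokers_mean"]),
            estimated_smokers_sd=float(row["estimated_smokers_sd"]),
            bootstrap_counts=np.array(
                [float(c) for c in row["bootstrap_counts"].split(";")]
            ),
            percentile_interval=(float(row["interval_lo"]), float(row["interval_hi"])),
        )
        for _, row in df.iterrows()
    ]


def write_county_csv(path, counties: list[CountyEstimate]) -> None:
    pd.DataFrame(
        [
            {
                "county_fips": c.county_fips,
                "total_phd_residents": c.total_phd_residents,
                "estimated_smokers": c.estimated_smokers,
                "estimated_proportion": c.estimated_proportion,
            }
            for c in counties
        ],
        columns=[
            "county_fips",
            "total_phd_residents",
            "estimated_smokers",
            "estimated_proportion",
        ],
    ).to_csv(path, index=False)


def read_county_csv(path) -> list[CountyEstimate]:
    df = pd.read_csv(path, dtype={"county_fips": str})
    return [
        CountyEstimate(
            county_fips=row["county_fips"],
            total_phd_residents=int(row["total_phd_residents"]),
            estimated_smokers=float(row["estimated_smokers"]),
        )
        for _, row in df.iterrows()
    ]


def export_geojson(
    county_estimates: list[CountyEstimate],
    phd_records: list[PHDRecord],
    estimates: list[SmokerEstimate],
    roi: pd.DataFrame | None = None,
) -> dict:
    """FeatureCollection: PHD point layer plus county property features.

    Coordinates are [longitude, latitude]; invalid coordinates raise an
    error naming the development.
    """
    est_by_id = {e.phd_id: e for e in estimates}
    roi_by_id: dict[str, dict[str, float]] = {}
    if roi is not None:
        for _, row in roi.iterrows():
            roi_by_id.setdefault(row["phd_id"], {})[row["intervention"]] = float(
                row["roi"]
            )
    features = []
    for p in phd_records:
        if not (-90.0 <= p.latitude <= 90.0 and -180.0 <= p.longitude <= 180.0):
            raise ValidationError(
                f"{p.phd_id}: invalid coordinates lat={p.latitude}, lon={p.longitude}"
            )
        props = {"phd_id": p.phd_id, "name": p.name, "n_residents": p.n_residents}
        est = est_by_id.get(p.phd_id)
        if est is not None:
            props["estimated_smokers_mean"] = est.estimated_smokers_mean
            props["interval_lo"] = est.percentile_interval[0]
            props["interval_hi"] = est.percentile_interval[1]
        if p.phd_id in roi_by_id:
            props["roi"] = roi_by_id[p.phd_id]
        features.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "Point",
                    "coordinates": [p.longitude, p.latitude],
                },
                "properties": props,
            }
        )
    for c in county_estimates:
        features.append(
            {
                "type": "Feature",
                "geometry": None,  # polygons joined externally by FIPS
                "properties": {
                    "county_fips": c.county_fips,
                    "total_phd_residents": c.total_phd_residents,
                    "estimated_smokers": c.estimated_smokers,
                    "estimated_proportion": c.estimated_proportion,
                },
            }
        )
    return {"type": "FeatureCollection", "features": features}


def write_geojson(path, doc: dict) -> None:
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def read_geojson(path) -> dict:
    return json.loads(Path(path).read_text())
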