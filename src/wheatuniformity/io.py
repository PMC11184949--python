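"""Readers and writers for the pipeline's on-disk formats.

* trait rasters — NPZ (values, mask, gsd_m and tags) per raster;
* plot ROIs — GeoJSON FeatureCollections of polygons in a local planar
  metre frame (no CRS handling: plot trials, not maps);
* point clouds — whitespace-delimited XYZ text;
* tables — CSV with documented headers;
* linear models — JSON (names, coefficients, intercept, provenance).

Round trips preserve values, masks and coordinates to floating-point
representation.  No function mutates its inputs on disk.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import mapping, shape

from .assoc import LinearModel
from .raster import TraitRaster

YIELD_TABLE_COLUMNS = ["plot_id", "yield_mg_ha", "biomass_mg_ha"]
UNIFORMITY_COLUMNS = ["plot_id", "stage", "trait", "index", "abbreviation", "value"]


# -- rasters ----------------------------------------------------------------

def write_raster(raster: TraitRaster, path: str | Path) -> Path:
    path = Path(path)
    np.savez(
        path,
        values=raster.values,
        mask=raster.mask,
        gsd_m=raster.gsd_m,
        trait=raster.trait,
        plot_id=raster.plot_id,
        stage="" if raster.stage is None else raster.stage,
    )
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def read_raster(path: str | Path) -> TraitRaster:
    with np.load(path, allow_pickle=False) as z:
        stage = str(z["stage"])
        return TraitRaster(
            values=z["values"],
            mask=z["mask"],
            gsd_m=float(z["gsd_m"]),
            trait=str(z["trait"]),
            plot_id=str(z["plot_id"]),
            stage=stage or None,
        )


# -- ROIs -------------------------------------------------------------------

def write_rois(rois: dict[str, shapely.Polygon], path: str | Path) -> Path:
    path = Path(path)
    fc = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "properties": {"plot_id": pid},
                "geometry": mapping(poly),
            }
            for pid, poly in rois.items()
        ],
    }
    path.write_text(json.dumps(fc, indent=1))
    return path


def read_rois(path: str | Path) -> dict[str, shapely.Polygon]:
    fc = json.loads(Path(path).read_text())
    return {
        f["properties"]["plot_id"]: shape(f["geometry"]) for f in fc["features"]
    }


# -- point clouds -----------------------------------------------------------

def write_xyz(points: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    np.savetxt(path, np.asarray(points, float), fmt="%.6f")
    return path


def read_xyz(path: str | Path) -> np.ndarray:
    pts = np.loadtxt(path, ndmin=2)
    if pts.shape[1] != 3:
        raise ValueError(f"expected 3 columns (x y z), got {pts.shape[1]}")
    return pts


# -- tables -----------------------------------------------------------------

def read_yield_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in YIELD_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"malformed outcomes CSV {path}: missing columns {missing}; "
            f"expected header {YIELD_TABLE_COLUMNS}"
        )
    return df


def read_uniformity_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in UNIFORMITY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"malformed uniformity CSV {path}: missing columns {missing}; "
            f"expected header {UNIFORMITY_COLUMNS}"
        )
    return df


# -- models -----------------------------------------------------------------

def write_model(model: LinearModel, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(
        json.dumps(
            {
                "predictor_names": list(model.predictor_names),
                "coefficients": list(model.coefficients),
                "intercept": model.intercept,
                "response": model.response,
                "provenance": model.provenance,
            },
            indent=1,
        )
    )
    return path


def read_model(path: str | Path) -> LinearModel:
    raw = json.loads(Path(path).read_text())
    return LinearModel(
        predictor_names=tuple(raw["predictor_names"]),
        coefficients=tuple(raw["coefficients"]),
        intercept=float(raw["intercept"]),
        response=raw["response"],
        provenance=raw.get("provenance", "fitted"),
    )
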