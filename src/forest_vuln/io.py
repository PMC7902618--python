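"""Readers and writers for the pipeline's on-disk formats.

Gridded stacks travel as NetCDF (classic format via the scipy backend),
disturbance patches as a GeoJSON FeatureCollection in grid coordinates
(x = column, y = row, polygon per footprint rectangle hull), generator
truth as a JSON sidecar, and fitted models as a joblib archive with a
JSON metadata twin.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import joblib
import numpy as np
import xarray as xr
from shapely.geometry import Point, box, shape

from .biomass_recon import BiomassStack
from .disturbance_loss import DisturbancePatch
from .model_training import ValidationReport, VulnerabilityModel
from .synth import GeneratorTruth

NETCDF_ENGINE = "scipy"


# --------------------------------------------------------------------------
# NetCDF stacks


def write_dataset(ds: xr.Dataset, path) -> Path:
    path = Path(path)
    enc = ds.copy()
    for name, var in enc.variables.items():
        if var.dtype == bool:
            enc[name] = var.astype(np.int8)
    enc.to_netcdf(path, engine=NETCDF_ENGINE)
    return path


def read_dataset(path, bool_vars=("gain_mask", "forest_mask")) -> xr.Dataset:
    ds = xr.load_dataset(path, engine=NETCDF_ENGINE)
    for name in bool_vars:
        if name in ds:
            ds[name] = ds[name].astype(bool)
    return ds


def write_stack(stack: BiomassStack, path) -> Path:
    ds = xr.Dataset(
        {"biomass": (("year", "y", "x"), stack.biomass)},
        coords={"year": stack.years},
        attrs={"resolution": stack.resolution, **stack.attrs},
    )
    return write_dataset(ds, path)


def read_stack(path) -> BiomassStack:
    ds = read_dataset(path)
    attrs = dict(ds.attrs)
    res = float(attrs.pop("resolution", 100.0))
    return BiomassStack(list(ds["year"].values), ds["biomass"].values,
                        resolution=res, attrs=attrs)


# --------------------------------------------------------------------------
# GeoJSON patches


def _footprint_polygon(cells: np.ndarray):
    # pixel-edge bounding box of the (rectangular) footprint;
    # x = column, y = row, cell (r, c) spans [c, c+1] x [r, r+1]
    rows, cols = cells[:, 0], cells[:, 1]
    return box(cols.min(), rows.min(), cols.max() + 1, rows.max() + 1)


def patches_to_geojson(patches: list[DisturbancePatch]) -> dict:
    features = []
    for p in patches:
        poly = _footprint_polygon(p.cells)
        features.append({
            "type": "Feature",
            "geometry": poly.__geo_interface__,
            "properties": {
                "id": p.id, "type": p.type, "year": int(p.year),
                "area": float(p.area), "clean": bool(p.clean),
                "pft_fractions": {k: float(v)
                                  for k, v in p.pft_fractions.items()},
            },
        })
    return {"type": "FeatureCollection", "features": features}


def write_patches(patches: list[DisturbancePatch], path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(patches_to_geojson(patches)))
    return path


def patches_from_geojson(fc: dict, grid_shape: tuple[int, int]
                         ) -> list[DisturbancePatch]:
    """Rebuild patches; a cell belongs to a footprint iff its center falls
    inside the polygon (half-open pixel convention)."""
    ny, nx = grid_shape
    out = []
    for feat in fc["features"]:
        poly = shape(feat["geometry"])
        minx, miny, maxx, maxy = poly.bounds
        cells = []
        for r in range(max(0, int(np.floor(miny))),
                       min(ny, int(np.ceil(maxy)) + 1)):
            for c in range(max(0, int(np.floor(minx))),
                           min(nx, int(np.ceil(maxx)) + 1)):
                if poly.buffer(1e-9).contains(Point(c + 0.5, r + 0.5)):
                    cells.append((r, c))
        props = feat["properties"]
        out.append(DisturbancePatch(
            id=props["id"], type=props["type"], year=int(props["year"]),
            cells=np.asarray(cells, dtype=int), area=float(props["area"]),
            pft_fractions=dict(props.get("pft_fractions", {})),
            clean=bool(props.get("clean", True))))
    return out


def read_patches(path, grid_shape) -> list[DisturbancePatch]:
    return patches_from_geojson(json.loads(Path(path).read_text()), grid_shape)


# --------------------------------------------------------------------------
# truth sidecar


def write_truth(truths, path) -> Path:
    """Write one truth or a {disturbance: truth} mapping as JSON."""
    if isinstance(truths, GeneratorTruth):
        truths = {truths.disturbance: truths}
    payload = {k: t.to_dict() for k, t in truths.items()}
    Path(path).write_text(json.dumps(payload, indent=1))
    return Path(path)


def read_truth(path) -> dict[str, GeneratorTruth]:
    payload = json.loads(Path(path).read_text())
    return {k: GeneratorTruth.from_dict(d) for k, d in payload.items()}


# --------------------------------------------------------------------------
# model bundles


def write_model(model: VulnerabilityModel, directory,
                report: ValidationReport | None = None) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = f"{model.disturbance}_{model.pft}"
    joblib.dump(model, directory / f"{stem}.joblib")
    meta = {
        "disturbance": model.disturbance, "pft": model.pft,
        "features": model.features, "hyperparams": model.hyperparams,
        "seed": model.seed,
        "importances": model.importances,
        "feature_ranges": {k: list(v) for k, v in model.feature_ranges.items()},
    }
    if report is not None:
        meta["validation"] = report.to_dict()
    (directory / f"{stem}.json").write_text(json.dumps(meta, indent=1))
    return directory / f"{stem}.joblib"


def read_model(path) -> VulnerabilityModel:
    return joblib.load(path)


def file_sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
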