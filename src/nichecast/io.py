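"""File formats: ESRI ASCII grids, point CSVs and the study manifest.

All rasters are written as ESRI ASCII grids (plain text, one file per
layer) on the package's fixed WGS84 lon/lat convention; points travel as
``species,lon,lat`` CSVs.  A JSON manifest records every artifact a study
writes together with its stage, seed and content hash, so reruns can be
verified byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import os
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import ClimateStack, Grid, PointSet
from .projection import BinaryRange

NODATA = -9999.0


def _check_prj(path: Path) -> None:
    """Reject sidecar projection files that are not WGS84 lon/lat."""
    prj = path.with_suffix(".prj")
    if prj.exists():
        text = prj.read_text()
        if "WGS" not in text or "1984" not in text.replace("_", " "):
            raise ValueError(
                f"{prj} does not describe WGS84; re-project inputs to "
                "geographic WGS84 (EPSG:4326) before use"
            )


def write_ascii_grid(path, values: np.ndarray, grid: Grid,
                     nodata: float = NODATA, fmt: str = "%.10g") -> None:
    """Write one layer as an ESRI ASCII grid (row 0 = north)."""
    path = Path(path)
    vals = np.asarray(values, dtype=float)
    if vals.shape != grid.shape:
        raise ValueError("value shape does not match grid")
    lon0, lat0 = grid.origin
    yll = lat0 - grid.n_rows * grid.cell_size
    out = np.where(np.isfinite(vals), vals, nodata)
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {lon0!r}\n")
        fh.write(f"yllcorner {yll!r}\n")
        fh.write(f"cellsize {grid.cell_size!r}\n")
        fh.write(f"NODATA_value {nodata:g}\n")
        np.savetxt(fh, out, fmt=fmt)


def read_ascii_grid(path) -> tuple[np.ndarray, Grid]:
    """Read an ESRI ASCII grid; NODATA cells become NaN."""
    path = Path(path)
    _check_prj(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            pos = fh.tell()
            line = fh.readline()
            key, _, val = line.partition(" ")
            key = key.strip().lower()
            if key in ("ncols", "nrows", "xllcorner", "yllcorner",
                       "cellsize", "nodata_value"):
                header[key] = float(val)
            else:
                fh.seek(pos)
                break
        values = np.loadtxt(fh, ndmin=2)
    n_rows = int(header["nrows"])
    n_cols = int(header["ncols"])
    if values.shape != (n_rows, n_cols):
        raise ValueError(f"{path}: data shape {values.shape} does not match "
                         f"header ({n_rows}, {n_cols})")
    cell = header["cellsize"]
    origin = (header["xllcorner"], header["yllcorner"] + n_rows * cell)
    grid = Grid(n_rows=n_rows, n_cols=n_cols, cell_size=cell, origin=origin)
    nodata = header.get("nodata_value", NODATA)
    values = np.where(values == nodata, np.nan, values)
    return values, grid


def write_stack(directory, stack: ClimateStack) -> list[Path]:
    """One ASCII grid per layer, named after the layer; NODATA cells are
    written consistently across every layer."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, layer in zip(stack.layer_names, stack.values):
        vals = np.where(stack.valid, layer, np.nan)
        p = directory / f"{name}.asc"
        write_ascii_grid(p, vals, stack.grid)
        paths.append(p)
    return paths


def read_stack(paths) -> ClimateStack:
    """Assemble a stack from per-layer ASCII grids sharing one geometry.
    A cell NODATA in any layer is excluded (masked) in all of them."""
    paths = [Path(p) for p in paths]
    if not paths:
        raise ValueError("no layer files given")
    layers, names = [], []
    grid = None
    for p in paths:
        vals, g = read_ascii_grid(p)
        if grid is None:
            grid = g
        else:
            grid.require_same(g)
        layers.append(vals)
        names.append(p.stem)
    values = np.stack(layers)
    valid = np.isfinite(values).all(axis=0)
    return ClimateStack(grid=grid, values=values, layer_names=names, valid=valid)


def write_binary_range(path, brange: BinaryRange) -> None:
    write_ascii_grid(path, brange.mask.astype(float), brange.grid, fmt="%d")


def read_binary_range(path, species: str = "", scenario: str = "",
                      threshold_rule: str = "") -> BinaryRange:
    vals, grid = read_ascii_grid(path)
    return BinaryRange(grid=grid, mask=np.nan_to_num(vals) > 0.5,
                       species=species, scenario=scenario,
                       threshold_rule=threshold_rule)


def write_points_csv(path, points: PointSet | list[PointSet]) -> None:
    """Points as ``species,lon,lat`` (cell-center coordinates)."""
    sets = points if isinstance(points, list) else [points]
    frames = [pd.DataFrame({"species": s.species, "lon": s.lon, "lat": s.lat})
              for s in sets]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_points_csv(path, grid: Grid) -> list[PointSet]:
    """Read a points CSV and snap each species' points onto the grid."""
    df = pd.read_csv(path)
    missing = {"species", "lon", "lat"} - set(df.columns)
    if missing:
        raise ValueError(f"points CSV lacks columns: {sorted(missing)}")
    out = []
    for name, sub in df.groupby("species", sort=True):
        rows, cols = grid.locate(sub["lon"].to_numpy(), sub["lat"].to_numpy())
        out.append(PointSet(grid=grid, rows=rows, cols=cols, species=str(name)))
    return out


# -- manifest --------------------------------------------------------------


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class Manifest:
    """Artifact registry for one study run."""

    def __init__(self, root) -> None:
        self.root = Path(root)
        self.entries: list[dict] = []

    def add(self, path, stage: str, seed: int | None = None,
            inputs: list[str] | None = None) -> None:
        path = Path(path)
        self.entries.append({
            "file": os.path.relpath(path, self.root),
            "stage": stage,
            "seed": seed,
            "inputs": inputs or [],
            "sha256": file_sha256(path),
        })

    def write(self, name: str = "manifest.json") -> Path:
        out = self.root / name
        with open(out, "w") as fh:
            json.dump({"artifacts": self.entries}, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return out
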