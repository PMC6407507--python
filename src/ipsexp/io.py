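"""Plain-text raster and table I/O.

Grids are stored as ESRI ASCII rasters (``.asc``), a widely supported
text format, one file per layer; a stack is a directory of ``.asc`` files
plus a ``stack.json`` sidecar carrying layer names, scenario and GCM tags.
Tables are CSV with a header row.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import GridSpec
from .regions import EcoregionMap
from .stack import ClimateStack

__all__ = [
    "write_ascii_grid",
    "read_ascii_grid",
    "write_stack",
    "read_stack",
    "write_ecoregions",
    "read_ecoregions",
]

_NODATA = -99999.0


def write_ascii_grid(path, array: np.ndarray, grid: GridSpec, nodata: float = _NODATA) -> None:
    """Write one layer as an ESRI ASCII raster (rows written north to south)."""
    path = Path(path)
    array = np.asarray(array, dtype=float)
    if array.shape != grid.shape:
        raise ValueError("array shape does not match grid")
    data = array.copy()
    data[grid.nodata_mask] = nodata
    data = np.where(np.isnan(data), nodata, data)
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {grid.origin_lon!r}\n"
        f"yllcorner {grid.origin_lat!r}\n"
        f"cellsize {grid.cell_size!r}\n"
        f"NODATA_value {nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        # ESRI ASCII stores the northernmost row first; our row 0 is south.
        np.savetxt(fh, data[::-1], fmt="%.10g")


def read_ascii_grid(path) -> tuple[np.ndarray, GridSpec]:
    """Read an ESRI ASCII raster; nodata cells come back as NaN."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, value = fh.readline().split()
            header[key.lower()] = float(value)
        data = np.loadtxt(fh)
    data = np.atleast_2d(data)[::-1].copy()
    nodata = header.get("nodata_value", _NODATA)
    mask = data == nodata
    data[mask] = np.nan
    grid = GridSpec(
        n_rows=int(header["nrows"]),
        n_cols=int(header["ncols"]),
        cell_size=header["cellsize"],
        origin_lon=header["xllcorner"],
        origin_lat=header["yllcorner"],
        nodata_mask=mask,
    )
    return data, grid


def write_stack(directory, stack: ClimateStack) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for code, layer in stack.layers.items():
        write_ascii_grid(directory / f"{code}.asc", layer, stack.grid)
    meta = {
        "layers": stack.codes,
        "scenario": stack.scenario,
        "gcm": stack.gcm,
    }
    (directory / "stack.json").write_text(json.dumps(meta, indent=2, sort_keys=True))


def read_stack(directory) -> ClimateStack:
    directory = Path(directory)
    meta = json.loads((directory / "stack.json").read_text())
    layers: dict[str, np.ndarray] = {}
    grid: GridSpec | None = None
    for code in meta["layers"]:
        data, g = read_ascii_grid(directory / f"{code}.asc")
        data = np.where(np.isnan(data), 0.0, data)
        layers[code] = data
        grid = g if grid is None else grid
        if not g.same_geometry(grid):
            raise ValueError(f"layer {code} is not co-registered with the stack")
        grid.nodata_mask |= g.nodata_mask
    assert grid is not None
    return ClimateStack(grid, layers, scenario=meta["scenario"], gcm=meta.get("gcm"))


def write_ecoregions(directory, regions: EcoregionMap, name: str = "ecoregions") -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_ascii_grid(directory / f"{name}.asc", regions.labels.astype(float), regions.grid)
    regions.meta.to_csv(directory / f"{name}.csv", index=False)


def read_ecoregions(directory, name: str = "ecoregions") -> EcoregionMap:
    directory = Path(directory)
    data, grid = read_ascii_grid(directory / f"{name}.asc")
    labels = np.where(np.isnan(data), -1, data).astype(int)
    meta = pd.read_csv(directory / f"{name}.csv")
    return EcoregionMap(grid, labels, meta)
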