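"""Project-file schema: plain HDF5 with self-describing attributes.

One project file holds every pipeline stage:

    /metadata              cell, centering, subdivision, Laue operators, seeds
    /background            binned background map
    /peaks                 fitted peak shape and sigma cutoff
    /observations/<sweep>  observation tables (one group per sweep)
    /truth/<sweep>         simulator ground-truth sidecar (tests only)
    /model                 scaling-model parameter grids
    /merged                merged intensity table (plus optional half sets)
    /map                   symmetry-expanded 3-D array
    /log                   run log (one string per CLI invocation)

Array datasets are chunked and gzip-compressed; tables are stored one
dataset per column so they round-trip losslessly through pandas.
"""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd

from .corrections import BackgroundMap
from .grid_symmetry import MillerGrid, UnitCell
from .map_tools import ReciprocalMap
from .peak_masking import PeakShape
from .scaling import ParamGrid, ScalingModel

SCHEMA_VERSION = "1"

__all__ = [
    "write_metadata", "read_metadata", "write_table", "read_table",
    "write_background", "read_background", "write_peak_shape",
    "read_peak_shape", "write_model", "read_model", "write_map", "read_map",
    "append_log", "write_merged_tsv",
]


def _require(f: h5py.File, path: str) -> h5py.Group:
    if path in f:
        del f[path]
    g = f.create_group(path)
    g.attrs["schema_version"] = SCHEMA_VERSION
    return g


def write_metadata(f: h5py.File, grid: MillerGrid, **extra):
    g = _require(f, "metadata")
    g.attrs["NX_class"] = "NXentry"
    cell = grid.cell
    g.create_dataset(
        "cell", data=[cell.a, cell.b, cell.c, cell.alpha, cell.beta, cell.gamma]
    )
    g.create_dataset("subdivision", data=np.asarray(grid.subdivision))
    g.attrs["centering"] = grid.centering
    g.create_dataset("laue_ops", data=grid.laue_ops)
    for key, val in extra.items():
        g.attrs[key] = val


def read_metadata(f: h5py.File) -> MillerGrid:
    g = f["metadata"]
    cell = UnitCell(*np.asarray(g["cell"]))
    return MillerGrid(
        cell,
        tuple(int(n) for n in np.asarray(g["subdivision"])),
        str(g.attrs["centering"]),
        np.asarray(g["laue_ops"]),
    )


def write_table(f: h5py.File, path: str, table: pd.DataFrame):
    g = _require(f, path)
    g.attrs["columns"] = json.dumps(list(table.columns))
    g.attrs["n_rows"] = len(table)
    for col in table.columns:
        data = table[col].to_numpy()
        kwargs = {}
        if len(data):
            kwargs = {"chunks": True, "compression": "gzip"}
        g.create_dataset(col, data=data, **kwargs)


def read_table(f: h5py.File, path: str) -> pd.DataFrame:
    g = f[path]
    cols = json.loads(g.attrs["columns"])
    return pd.DataFrame({c: np.asarray(g[c]) for c in cols})


def write_background(f: h5py.File, bmap: BackgroundMap, path: str = "background"):
    g = _require(f, path)
    g.create_dataset("rate", data=bmap.rate, chunks=True, compression="gzip")
    g.create_dataset("valid", data=bmap.valid, chunks=True, compression="gzip")
    g.create_dataset("bin_sizes", data=np.asarray(bmap.bin_sizes))
    for d, centers in enumerate(bmap.centers):
        g.create_dataset(f"centers_{d}", data=centers)


def read_background(f: h5py.File, path: str = "background") -> BackgroundMap:
    g = f[path]
    return BackgroundMap(
        np.asarray(g["rate"]),
        np.asarray(g["valid"]).astype(bool),
        tuple(int(n) for n in np.asarray(g["bin_sizes"])),
        tuple(np.asarray(g[f"centers_{d}"]) for d in range(3)),
    )


def write_peak_shape(f: h5py.File, shape: PeakShape, n_sigma: float, path: str = "peaks"):
    g = _require(f, path)
    g.create_dataset("mean", data=np.asarray(shape.mean))
    g.create_dataset("covariance", data=np.asarray(shape.covariance))
    g.attrs["n_points"] = shape.n_points
    g.attrs["n_sigma"] = n_sigma


def read_peak_shape(f: h5py.File, path: str = "peaks"):
    g = f[path]
    shape = PeakShape(
        np.asarray(g["mean"]), np.asarray(g["covariance"]), int(g.attrs["n_points"])
    )
    return shape, float(g.attrs["n_sigma"])


def write_model(f: h5py.File, model: ScalingModel, path: str = "model"):
    g = _require(f, path)
    for kind, entry in model.params.items():
        kg = g.create_group(kind)
        grids = {"global": entry} if kind == "d" else entry
        for sweep, grid in grids.items():
            sg = kg.create_group(str(sweep))
            sg.attrs["kind"] = kind
            sg.create_dataset("values", data=grid.values)
            for d, ax in enumerate(grid.axes):
                sg.create_dataset(f"axis_{d}", data=ax)


def read_model(f: h5py.File, path: str = "model") -> ScalingModel:
    g = f[path]
    params: dict = {}
    for kind in g:
        entry = {}
        for sweep in g[kind]:
            sg = g[kind][sweep]
            axes = tuple(
                np.asarray(sg[f"axis_{d}"])
                for d in range(len([k for k in sg if k.startswith("axis_")]))
            )
            grid = ParamGrid(kind, axes, np.asarray(sg["values"]))
            key = sweep if sweep == "global" else _sweep_key(sweep)
            entry[key] = grid
        if kind == "d":
            params["d"] = entry["global"]
        else:
            params[kind] = entry
    return ScalingModel(params)


def _sweep_key(name: str):
    try:
        return int(name)
    except ValueError:
        return name


def write_map(f: h5py.File, rmap: ReciprocalMap, path: str = "map"):
    g = _require(f, path)
    g.create_dataset("data", data=rmap.data, chunks=True, compression="gzip")
    g.attrs["missing"] = "nan"
    g.create_dataset("bounds", data=np.asarray(rmap.bounds))
    for d, ax in enumerate(rmap.axes):
        g.create_dataset(f"axis_{d}", data=ax)


def read_map(f: h5py.File, grid: MillerGrid, path: str = "map") -> ReciprocalMap:
    g = f[path]
    bounds = tuple((int(lo), int(hi)) for lo, hi in np.asarray(g["bounds"]))
    return ReciprocalMap(np.asarray(g["data"]), bounds, grid)


def append_log(f: h5py.File, message: str):
    if "log" not in f:
        f.create_dataset(
            "log", shape=(0,), maxshape=(None,), dtype=h5py.string_dtype()
        )
    log = f["log"]
    log.resize((len(log) + 1,))
    log[-1] = message


def write_merged_tsv(merged: pd.DataFrame, path, subdivision):
    """Merged table as TSV with fractional Miller-index columns."""
    out = pd.DataFrame(
        {
            "h": merged["i"] / subdivision[0],
            "k": merged["j"] / subdivision[1],
            "l": merged["k"] / subdivision[2],
        }
    )
    for col in merged.columns:
        if col not in ("i", "j", "k", "asu_key"):
            out[col] = merged[col].to_numpy()
    out.to_csv(path, sep="\t", index=False, float_format="%.8g")
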