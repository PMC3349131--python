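"""Run container I/O.

A finished run is persisted as a single NPZ archive holding the field arrays
(temperature, dose, masks, velocity, power), the grid metadata, the per-event
log (for treatments) and provenance (package version, seed, timestamp).
Round-trips are lossless for the arrays; provenance timestamps naturally
differ between otherwise identical runs.
"""

from __future__ import annotations

import datetime
import io
import json
import zipfile
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .grid import Grid

__all__ = ["save_run", "load_run", "RunContainer"]

_FORMAT_VERSION = 1


class RunContainer(dict):
    """Dict of arrays plus ``meta`` (dict) and optional ``log`` (DataFrame)."""

    meta: dict
    log: pd.DataFrame | None


def save_run(path, arrays: dict, grid: Grid, meta: dict | None = None,
             log: pd.DataFrame | None = None, seed=None) -> Path:
    """Write a run container.

    Parameters
    ----------
    arrays : dict of name -> ndarray
        Named datasets (e.g. T, dose, vessel_id, w, P).
    grid : Grid
        Stored as metadata (spacing, shape, mode).
    meta : dict, optional
        Extra JSON-serializable metadata (config echo, labels).
    log : DataFrame, optional
        Per-event treatment log.
    """
    path = Path(path)
    payload = {k: np.asarray(v) for k, v in arrays.items()}
    header = {
        "format_version": _FORMAT_VERSION,
        "package_version": __version__,
        "created": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "seed": seed,
        "grid": {"spacing": list(grid.spacing), "shape": list(grid.shape),
                 "mode": grid.mode},
        "meta": meta or {},
    }
    payload["_header"] = np.frombuffer(
        json.dumps(header).encode(), dtype=np.uint8)
    if log is not None:
        # "table" keeps the column dtypes through the JSON round trip
        payload["_log"] = np.frombuffer(
            log.to_json(orient="table", index=False).encode(), dtype=np.uint8)
    np.savez_compressed(path, **payload)
    return path


def load_run(path) -> RunContainer:
    """Read a run container written by :func:`save_run`.

    Raises a clean ``ValueError`` on truncated or foreign files and warns on
    a newer format version.
    """
    path = Path(path)
    try:
        with np.load(path, allow_pickle=False) as npz:
            data = {k: npz[k] for k in npz.files}
    except (zipfile.BadZipFile, OSError, KeyError) as err:
        raise ValueError(f"{path} is not a readable run container: {err}") from err
    if "_header" not in data:
        raise ValueError(f"{path} has no run-container header")
    header = json.loads(bytes(data.pop("_header")).decode())
    if header.get("format_version", 0) > _FORMAT_VERSION:
        import warnings

        warnings.warn(
            f"{path}: written by a newer format "
            f"(v{header['format_version']} > v{_FORMAT_VERSION})", stacklevel=2)
    out = RunContainer(data)
    out.meta = header
    g = header["grid"]
    out.grid = Grid(spacing=tuple(g["spacing"]), shape=tuple(g["shape"]),
                    mode=g["mode"])
    if "_log" in out:
        out.log = pd.read_json(io.BytesIO(bytes(out.pop("_log"))), orient="table")
    else:
        out.log = None
    return out
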