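"""File I/O: CF-style gridded files, CSV tables, YAML configs and
provenance sidecars.

Gridded fields travel as netCDF (classic NETCDF3_64BIT via the scipy
backend) with dimensions ``(year, lat, lon)`` and unit attributes; 1-D
series and sweep tables as plain CSV.  Every CLI run writes a JSON
sidecar echoing the resolved configuration, seed and package version so
scenario-versus-control bookkeeping stays auditable.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import xarray as xr
import yaml

__all__ = [
    "read_grid",
    "write_grid",
    "read_series_csv",
    "load_config",
    "write_provenance",
]


def write_grid(data: xr.Dataset | xr.DataArray, path) -> None:
    """Write a gridded field as classic netCDF."""
    ds = data.to_dataset() if isinstance(data, xr.DataArray) else data
    ds.to_netcdf(path, engine="scipy", format="NETCDF3_64BIT")


def read_grid(path, var: str | None = None):
    """Read a gridded file; returns the Dataset, or one DataArray if
    ``var`` is given."""
    ds = xr.load_dataset(path, engine="scipy", decode_times=False)
    if var is not None:
        if var not in ds:
            raise KeyError(f"variable '{var}' not in {path} (has {list(ds)})")
        return ds[var]
    return ds


def read_series_csv(path, year_col: str = "year", value_col: str | None = None):
    """Read an annual series from CSV; returns (years, values) arrays.

    With ``value_col`` unset, the first non-year column is used.
    """
    df = pd.read_csv(path)
    if year_col not in df.columns:
        raise ValueError(f"CSV {path} lacks a '{year_col}' column")
    if value_col is None:
        others = [c for c in df.columns if c != year_col]
        if not others:
            raise ValueError(f"CSV {path} has no value column")
        value_col = others[0]
    return df[year_col].to_numpy(), df[value_col].to_numpy(dtype=float)


def load_config(path) -> dict:
    """Load a YAML key/value config file (empty file -> empty dict)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        return {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping of parameter: value")
    return cfg


def write_provenance(out_path, stage: str, config: dict, seed: int | None = None) -> None:
    """Write a ``<output>.provenance.json`` sidecar next to an output file.

    Contents are deterministic (no timestamps) so reruns with the same
    config reproduce the sidecar bit for bit.
    """
    from . import __version__

    sidecar = Path(str(out_path) + ".provenance.json")
    record = {
        "package": "n15emerge",
        "version": __version__,
        "stage": stage,
        "seed": seed,
        "config": config,
    }
    sidecar.write_text(json.dumps(record, indent=2, sort_keys=True, default=str) + "\n")
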