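"""Offline biogeochemical delta15N_NO3 tendency diagnostic.

Within a grid cell, the only internal biogeochemical source of nitrate is
nitrification of remineralized ammonium, and the main sinks are new
production and denitrification.  Given the heavy- and light-isotope flux
of each process, the net biogeochemical inputs-minus-outputs ratio gives
the signature toward which local biogeochemistry pushes the nitrate pool:

    tendency = ((15nitr - 15new - 15den) / (14nitr - 14new - 14den) - 1) * 1000

Because only within-cell fluxes enter, the diagnostic isolates local
biogeochemical effects from circulation (transport) effects; differencing
the tendency between a scenario and a reference run shows where
biogeochemistry alone would drive delta15N_NO3 up or down.  Isotopic
signatures of upstream processes (remineralization, excretion, nitrogen
fixation) are assumed to be carried implicitly by the nitrification flux;
no fractionation is applied here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import xarray as xr

__all__ = [
    "FluxFields",
    "FLUX_VARIABLES",
    "biogeochem_delta_tendency",
    "tendency_change",
]

#: Variable names of the six per-cell fluxes (mmol N m-3 yr-1).
FLUX_VARIABLES = ("nitr15", "nitr14", "new15", "new14", "den15", "den14")

#: Mask codes on the ``flag`` variable of the tendency output.
FLAG_OK = 0
FLAG_SMALL_NET = 1  # |net light flux| below tolerance
FLAG_UNPHYSICAL = 2  # net heavy / net light < 0 (implied negative abundance)

#: Default denominator tolerance as a fraction of the cell's gross
#: light-isotope flux.
DEFAULT_REL_TOL = 1e-6


@dataclass(frozen=True)
class FluxFields:
    """Per-cell nitrate source/sink flux pairs (heavy, light).

    Each field is an array (any shared shape; typically lat x lon) of
    non-negative flux magnitudes in mmol N m-3 yr-1, heavy fluxes under
    the enrichment-weighted standard-ratio-1 convention.
    """

    nitr15: np.ndarray
    nitr14: np.ndarray
    new15: np.ndarray
    new14: np.ndarray
    den15: np.ndarray
    den14: np.ndarray

    def __post_init__(self) -> None:
        shape = np.shape(self.nitr14)
        for name in FLUX_VARIABLES:
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != shape:
                raise ValueError(f"flux '{name}' shape {arr.shape} != {shape}")
            if np.any(arr[np.isfinite(arr)] < 0):
                raise ValueError(f"flux '{name}' must be non-negative")
            object.__setattr__(self, name, arr)

    @property
    def shape(self) -> tuple[int, ...]:
        return np.shape(self.nitr14)

    @classmethod
    def from_dataset(cls, ds: xr.Dataset) -> "FluxFields":
        missing = [v for v in FLUX_VARIABLES if v not in ds]
        if missing:
            raise ValueError(f"dataset lacks flux variables: {missing}")
        return cls(**{v: ds[v].to_numpy() for v in FLUX_VARIABLES})

    def to_dataset(self, coords=None, dims=None) -> xr.Dataset:
        dims = dims if dims is not None else tuple(f"dim_{i}" for i in range(len(self.shape)))
        ds = xr.Dataset(
            {
                v: xr.DataArray(getattr(self, v), dims=dims, attrs={"units": "mmol m-3 yr-1"})
                for v in FLUX_VARIABLES
            }
        )
        if coords is not None:
            ds = ds.assign_coords(coords)
        return ds


def _as_fluxes(fluxes) -> FluxFields:
    if isinstance(fluxes, FluxFields):
        return fluxes
    if isinstance(fluxes, xr.Dataset):
        return FluxFields.from_dataset(fluxes)
    raise TypeError("fluxes must be a FluxFields or an xarray Dataset")


def biogeochem_delta_tendency(fluxes, tol: float | None = None):
    """Signature (permil) toward which within-cell biogeochemistry pushes
    nitrate.

    Parameters
    ----------
    fluxes
        :class:`FluxFields` or a Dataset with the six flux variables.
    tol
        Absolute tolerance on the net light-isotope flux below which the
        ratio is considered numerically meaningless and masked.  By
        default, ``1e-6`` of each cell's gross light flux (sum of flux
        magnitudes).

    Returns
    -------
    (numpy.ma.MaskedArray, numpy.ndarray)
        The per-mil tendency with invalid cells masked, and an integer
        flag array (0 valid, 1 near-zero net flux, 2 unphysical ratio).
    """
    f = _as_fluxes(fluxes)
    net14 = f.nitr14 - f.new14 - f.den14
    net15 = f.nitr15 - f.new15 - f.den15
    gross14 = np.abs(f.nitr14) + np.abs(f.new14) + np.abs(f.den14)
    if tol is None:
        tol_arr = DEFAULT_REL_TOL * gross14
    else:
        if tol <= 0:
            raise ValueError("tol must be positive")
        tol_arr = np.full(f.shape, float(tol))

    flag = np.full(f.shape, FLAG_OK, dtype=np.int8)
    small = np.abs(net14) < tol_arr
    flag[small] = FLAG_SMALL_NET
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = net15 / net14
    unphysical = ~small & (ratio < 0)
    flag[unphysical] = FLAG_UNPHYSICAL

    tendency = (ratio - 1.0) * 1000.0
    masked = np.ma.masked_where(flag != FLAG_OK, tendency)
    return masked, flag


def tendency_change(scenario, reference, tol: float | None = None):
    """Scenario-minus-reference biogeochemical tendency (permil).

    Masked wherever either side is masked; the pattern shows where local
    biogeochemical fluxes alone would alter delta15N_NO3 under the
    scenario, excluding upstream and circulation changes.
    """
    s = _as_fluxes(scenario)
    r = _as_fluxes(reference)
    if s.shape != r.shape:
        raise ValueError(f"geometry mismatch: {s.shape} vs {r.shape}")
    ts, flag_s = biogeochem_delta_tendency(s, tol)
    tr, flag_r = biogeochem_delta_tendency(r, tol)
    change = ts - tr  # masked arithmetic propagates either mask
    flag = np.where(flag_s != FLAG_OK, flag_s, flag_r).astype(np.int8)
    return change, flag
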