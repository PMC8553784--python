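"""Synthetic gridded fields with known truth for exercising the detector
and the flux diagnostic.

The generator emulates the *statistical* structure the emergence method
assumes, not any particular ocean model: a multi-century stationary
control with AR(1) interannual noise (and optional linear model drift),
scenario runs sharing the control's noise statistics with spatially
varying linear ramp trends switched on at known onset years, and per-cell
nitrate flux pairs with prescribed isotopic signatures.  Because onset
years, ramp rates and signatures are known exactly, detector output can
be scored against ground truth (detection lag, false emergences,
signature recovery).

All randomness flows from an explicit integer seed; identical spec and
seed give bit-identical fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import xarray as xr

from .isoflux import FluxFields
from .isotopes import heavy_from_delta

__all__ = ["SyntheticSpec", "gen_control", "gen_scenario", "gen_flux_fields"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Geometry, noise and trend structure of the synthetic study.

    Defaults mirror the emergence study conditions: a 1801-2100 span
    (300-year control), a low-latitude grid, AR(1) interannual noise with
    lag-1 autocorrelation ``phi = 0.5``, and ramp trends beginning in
    2000.

    Attributes
    ----------
    nlat, nlon
        Grid size; latitudes are cell centers spanning ``lat_range``.
    year_start, year_end
        Annual span of every generated series (inclusive).
    control_mean
        Stationary mean of the control (tracer units).
    control_drift
        Linear model drift of the control (units yr-1); the detector must
        remove it, so it is zero by default but exercised in tests.
    phi
        AR(1) coefficient of the interannual noise, |phi| < 1.
    innovation_sd
        SD of the AR(1) innovations; the marginal (interannual) SD is
        ``innovation_sd / sqrt(1 - phi**2)``.
    onset_year
        Year the scenario ramp switches on (scalar, applied everywhere).
    ramp_rate
        Ramp slope after onset (units yr-1), before the amplitude mask.
    amplitude
        Optional (nlat, nlon) multiplicative mask on the ramp; 1
        everywhere when None.
    seed
        Base seed; generators derive independent streams from it.
    """

    nlat: int = 16
    nlon: int = 32
    lat_range: tuple[float, float] = (-45.0, 45.0)
    year_start: int = 1801
    year_end: int = 2100
    control_mean: float = 5.0
    control_drift: float = 0.0
    phi: float = 0.5
    innovation_sd: float = 0.1
    onset_year: int = 2000
    ramp_rate: float = -0.01
    amplitude: np.ndarray | None = field(default=None)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= abs(self.phi) < 1:
            raise ValueError("phi must satisfy |phi| < 1")
        if self.innovation_sd <= 0:
            raise ValueError("innovation_sd must be positive")
        if self.nlat < 1 or self.nlon < 1:
            raise ValueError("grid must have at least one cell")
        if not self.year_start <= self.onset_year <= self.year_end:
            raise ValueError("onset_year must lie within the year span")
        if self.amplitude is not None:
            amp = np.asarray(self.amplitude, dtype=float)
            if amp.shape != (self.nlat, self.nlon):
                raise ValueError(
                    f"amplitude shape {amp.shape} != {(self.nlat, self.nlon)}"
                )
            object.__setattr__(self, "amplitude", amp)

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.year_start, self.year_end + 1)

    @property
    def lats(self) -> np.ndarray:
        lo, hi = self.lat_range
        edges = np.linspace(lo, hi, self.nlat + 1)
        return 0.5 * (edges[:-1] + edges[1:])

    @property
    def lons(self) -> np.ndarray:
        edges = np.linspace(0.0, 360.0, self.nlon + 1)
        return 0.5 * (edges[:-1] + edges[1:])

    @property
    def marginal_sd(self) -> float:
        """Stationary SD of the AR(1) noise."""
        return self.innovation_sd / np.sqrt(1.0 - self.phi**2)

    def with_overrides(self, **kwargs) -> "SyntheticSpec":
        return replace(self, **kwargs)


def _ar1_noise(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) noise, shape (nyear, nlat, nlon).

    The initial state is drawn from the stationary distribution so the
    series has no spin-up transient.
    """
    nyear = spec.years.size
    shape = (spec.nlat, spec.nlon)
    e = np.empty((nyear,) + shape)
    e[0] = rng.normal(0.0, spec.marginal_sd, shape)
    innov = rng.normal(0.0, spec.innovation_sd, (nyear - 1,) + shape)
    for t in range(1, nyear):
        e[t] = spec.phi * e[t - 1] + innov[t - 1]
    return e


def _wrap(spec: SyntheticSpec, values: np.ndarray, name: str, **attrs) -> xr.DataArray:
    return xr.DataArray(
        values,
        coords={"year": spec.years, "lat": spec.lats, "lon": spec.lons},
        dims=("year", "lat", "lon"),
        name=name,
        attrs=attrs,
    )


def gen_control(spec: SyntheticSpec, seed: int | None = None) -> xr.DataArray:
    """Control run: stationary mean + optional drift + AR(1) noise."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    t = spec.years - spec.years[0]
    base = spec.control_mean + spec.control_drift * t
    values = base[:, None, None] + _ar1_noise(spec, rng)
    return _wrap(spec, values, "tracer", role="control")


def gen_scenario(spec: SyntheticSpec, seed: int | None = None) -> xr.Dataset:
    """Scenario run: control-statistics noise plus per-cell linear ramps.

    An independent AR(1) realization with the control's noise parameters
    is superposed on the control's mean state; after ``onset_year`` each
    cell gains a linear ramp ``ramp_rate * amplitude[cell]``.  The true
    onset year and effective per-cell rate are stored as ground truth for
    parameter-recovery scoring (onset is flagged missing where the
    effective rate is zero).
    """
    base_seed = spec.seed if seed is None else seed
    # offset stream: scenario noise independent of a control drawn from the same seed
    rng = np.random.default_rng((int(base_seed), 1))
    t = spec.years - spec.years[0]
    base = spec.control_mean + spec.control_drift * t
    values = base[:, None, None] + _ar1_noise(spec, rng)

    amp = spec.amplitude if spec.amplitude is not None else np.ones((spec.nlat, spec.nlon))
    rate = spec.ramp_rate * amp
    since_onset = np.clip(spec.years - spec.onset_year, 0, None).astype(float)
    values = values + since_onset[:, None, None] * rate[None, :, :]

    da = _wrap(spec, values, "tracer", role="scenario")
    onset = np.where(rate != 0.0, float(spec.onset_year), np.nan)
    return xr.Dataset(
        {
            "tracer": da,
            "true_onset": xr.DataArray(onset, dims=("lat", "lon"),
                                       coords={"lat": spec.lats, "lon": spec.lons}),
            "true_rate": xr.DataArray(rate, dims=("lat", "lon"),
                                      coords={"lat": spec.lats, "lon": spec.lons}),
        }
    )


def gen_flux_fields(signatures, magnitudes, shape=(1,)) -> FluxFields:
    """Flux pairs with prescribed signatures for the tendency diagnostic.

    Parameters
    ----------
    signatures
        Mapping of process name (``nitr``, ``new``, ``den``) to delta15N
        signature (permil).
    magnitudes
        Mapping of process name to light-isotope flux magnitude — scalar
        (uniform) or an array of ``shape``.
    shape
        Grid shape of the output fields.

    The heavy flux of each process is ``light * (1 + delta/1000)``, so a
    single-process case fed to the tendency diagnostic returns the
    prescribed signature exactly.
    """
    out = {}
    for proc in ("nitr", "new", "den"):
        mag = np.broadcast_to(
            np.asarray(magnitudes.get(proc, 0.0), dtype=float), shape
        ).copy()
        if np.any(mag < 0):
            raise ValueError(f"magnitude of '{proc}' must be non-negative")
        sig = float(signatures.get(proc, 0.0))
        out[f"{proc}14"] = mag
        out[f"{proc}15"] = heavy_from_delta(mag, sig)
    return FluxFields(**out)
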