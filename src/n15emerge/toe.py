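"""Time of Emergence (ToE) of forced trends in annual-mean tracer series.

A forced signal has "emerged" at a grid cell when its anomaly relative to
a stationary control climate exceeds a noise envelope and stays outside
it through the end of the simulation.  The chain per cell is:

1. fit the control's linear trend and mean (``control_stats``) and take
   the control's detrended interannual standard deviation as the noise;
2. express the scenario as an additive anomaly about the control's
   trendline (``anomaly``);
3. smooth with a centered 11-year boxcar to filter decadal variability
   (``boxcar_smooth``);
4. find the first year from which ``|anomaly| > k * noise_sd`` holds for
   every remaining year (``toe_year``; default ``k = 2``, a ~95%
   envelope).  Temporary excursions that later re-enter the envelope are
   rejected, which makes the estimate conservative.

Gridded wrappers (``toe_map``, ``emerged_fraction``) apply the chain per
cell over (year, lat, lon) arrays and summarise emergence as the
cos(latitude)-weighted fraction of a low-latitude region (default
45S-45N) whose cells have emerged by a given year.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr
from scipy import stats

__all__ = [
    "ControlStats",
    "ToEMap",
    "control_stats",
    "anomaly",
    "boxcar_smooth",
    "toe_year",
    "toe_map",
    "emerged_fraction",
    "emergence_curve",
    "pattern_agreement",
]

#: Minimum control length (years) for a stable noise estimate.
MIN_CONTROL_YEARS = 30

#: Status codes carried in ToEMap.status.
STATUS_EMERGED = 0
STATUS_NEVER = 1
STATUS_MISSING = 2

#: Fill value used when writing ToE maps to disk ("never emerged").
TOE_NEVER_FILL = -1


@dataclass(frozen=True)
class ControlStats:
    """Linear trend, mean and interannual noise of a control series.

    ``slope`` and ``mean`` describe the control's OLS trendline about
    ``ref_year`` (the mean control year, so the fit is exactly centered);
    ``noise_sd`` is the standard deviation of the control after removing
    that trendline — the raw, unsmoothed interannual variability.
    """

    slope: float
    mean: float
    noise_sd: float
    ref_year: float

    def trendline(self, years) -> np.ndarray:
        years = np.asarray(years, dtype=float)
        return self.mean + self.slope * (years - self.ref_year)


def _check_years(years) -> np.ndarray:
    years = np.asarray(years)
    if years.ndim != 1 or years.size < 2:
        raise ValueError("years must be a 1-D array of length >= 2")
    if np.any(np.diff(years) != 1):
        raise ValueError("years must be consecutive integers")
    return years.astype(float)


def control_stats(years, values) -> ControlStats:
    """Fit the control trendline and estimate interannual noise.

    Raises on series shorter than 30 years or with zero residual
    variance (a constant or perfectly linear control has no noise to
    define an envelope).
    """
    years = _check_years(years)
    values = np.asarray(values, dtype=float)
    if values.shape != years.shape:
        raise ValueError("years and values must have matching shape")
    if years.size < MIN_CONTROL_YEARS:
        raise ValueError(f"control must span >= {MIN_CONTROL_YEARS} years")
    ref = float(years.mean())
    x = years - ref
    slope = float(np.dot(x, values - values.mean()) / np.dot(x, x))
    mean = float(values.mean())
    resid = values - mean - slope * x
    sd = float(resid.std(ddof=0))
    if sd <= 1e-12 * max(1.0, float(np.abs(values).max())):
        raise ValueError("control series has zero interannual noise")
    return ControlStats(slope=slope, mean=mean, noise_sd=sd, ref_year=ref)


def anomaly(years, values, ctrl: ControlStats) -> np.ndarray:
    """Additive anomaly of a series about the control's trendline.

    The control processed with its own stats varies about zero with no
    residual trend; forced scenarios deviate from zero.
    """
    years = np.asarray(years, dtype=float)
    values = np.asarray(values, dtype=float)
    return values - ctrl.trendline(years)


def boxcar_smooth(values, window: int = 11, axis: int = -1) -> np.ndarray:
    """Centered flat (boxcar) moving average preserving series length.

    Near the edges the window shrinks symmetrically to the points
    available (down to a single point at the endpoints), so the smoothed
    series is defined through the final year — required by the
    persistence rule.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 1")
    values = np.asarray(values, dtype=float)
    if window == 1:
        return values.copy()
    values = np.moveaxis(values, axis, 0)
    n = values.shape[0]
    half = window // 2
    # cumulative sum with a leading zero: sum over [a, b] = c[b+1] - c[a]
    c = np.concatenate(
        [np.zeros((1,) + values.shape[1:]), np.cumsum(values, axis=0)], axis=0
    )
    idx = np.arange(n)
    h = np.minimum(half, np.minimum(idx, n - 1 - idx))
    lo, hi = idx - h, idx + h
    width = (hi - lo + 1).astype(float)
    shape = (n,) + (1,) * (values.ndim - 1)
    out = (c[hi + 1] - c[lo]) / width.reshape(shape)
    return np.moveaxis(out, 0, axis)


def toe_year(years, anomaly_smoothed, noise_sd, k: float = 2.0):
    """First year from which the anomaly permanently exceeds the envelope.

    Returns the first year ``Y`` such that ``|anomaly| > k * noise_sd``
    for every year from ``Y`` to the end of the series, or ``None`` if
    the signal never permanently emerges.  Excursions that later drop
    back inside the envelope are rejected.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    years = np.asarray(years)
    a = np.asarray(anomaly_smoothed, dtype=float)
    exceed = np.abs(a) > k * float(noise_sd)
    if not exceed[-1]:
        return None
    # length of the True suffix
    not_exceed = np.flatnonzero(~exceed)
    start = 0 if not_exceed.size == 0 else int(not_exceed[-1]) + 1
    return int(years[start])


def _suffix_emergence(exceed: np.ndarray) -> np.ndarray:
    """Index of the start of the trailing all-True run along axis 0
    (-1 where the final year does not exceed)."""
    nyear = exceed.shape[0]
    rev = exceed[::-1]
    run = np.cumprod(rev, axis=0, dtype=bool)
    suffix_len = run.sum(axis=0)
    start = nyear - suffix_len
    return np.where(suffix_len > 0, start, -1)


@dataclass
class ToEMap:
    """Per-cell emergence year with region bookkeeping.

    ``toe`` holds the emergence year (float, NaN where never/missing);
    ``status`` distinguishes emerged (0), never-emerged (1) and missing
    input (2); ``weights`` are the area weights used for region
    fractions; ``region`` is the low-latitude mask.
    """

    toe: xr.DataArray
    status: xr.DataArray
    weights: xr.DataArray
    region: xr.DataArray

    @classmethod
    def from_dataset(
        cls, ds: xr.Dataset, region_bounds: tuple[float, float] = (-45.0, 45.0)
    ) -> "ToEMap":
        """Rebuild a ToEMap from a dataset written by :meth:`to_dataset`."""
        if "toe" not in ds or "status" not in ds:
            raise ValueError("dataset lacks 'toe'/'status' variables")
        toe = ds["toe"].where(ds["toe"] != TOE_NEVER_FILL)
        lat = ds["lat"].to_numpy()
        shape = ds["toe"].shape
        coords = {"lat": ds["lat"], "lon": ds["lon"]}
        w2d = np.broadcast_to(_area_weights(lat)[:, None], shape).copy()
        region = (lat >= region_bounds[0]) & (lat <= region_bounds[1])
        region2d = np.broadcast_to(region[:, None], shape).copy()
        return cls(
            toe=toe,
            status=ds["status"].astype("i1"),
            weights=xr.DataArray(w2d, coords=coords, dims=("lat", "lon")),
            region=xr.DataArray(region2d, coords=coords, dims=("lat", "lon")),
        )

    def to_dataset(self) -> xr.Dataset:
        toe_enc = self.toe.fillna(TOE_NEVER_FILL)
        ds = xr.Dataset(
            {
                "toe": toe_enc.assign_attrs(
                    long_name="time of emergence",
                    units="year",
                    fill_value_meaning=f"{TOE_NEVER_FILL} = never emerged or missing",
                ),
                "status": self.status.assign_attrs(
                    flag_values="0 1 2", flag_meanings="emerged never missing"
                ),
                "region": self.region.astype("i4"),
            }
        )
        return ds


def _area_weights(lat: np.ndarray) -> np.ndarray:
    w = np.cos(np.deg2rad(lat))
    return np.clip(w, 0.0, None)


def toe_map(
    scenario: xr.DataArray,
    control: xr.DataArray,
    k: float = 2.0,
    window: int = 11,
    region_bounds: tuple[float, float] = (-45.0, 45.0),
) -> ToEMap:
    """Apply the full ToE chain per grid cell.

    Parameters
    ----------
    scenario, control
        Annual-mean fields with dimensions ``(year, lat, lon)`` on the
        same grid.  The year axes may differ; the control supplies noise
        statistics, the scenario supplies the assessed series.
    k
        Noise-envelope multiplier (default 2 SD).
    window
        Boxcar width in years (odd; default 11).
    region_bounds
        Latitude band for area summaries (default 45S-45N).
    """
    for da, name in ((scenario, "scenario"), (control, "control")):
        if tuple(da.dims) != ("year", "lat", "lon"):
            raise ValueError(f"{name} must have dims (year, lat, lon), got {da.dims}")
    if not (
        np.array_equal(scenario["lat"], control["lat"])
        and np.array_equal(scenario["lon"], control["lon"])
    ):
        raise ValueError("scenario and control grids differ")

    cyears = control["year"].to_numpy()
    syears = scenario["year"].to_numpy()
    _check_years(cyears)
    _check_years(syears)
    if cyears.size < MIN_CONTROL_YEARS:
        raise ValueError(f"control must span >= {MIN_CONTROL_YEARS} years")

    cv = control.to_numpy()
    sv = scenario.to_numpy()
    missing = np.any(~np.isfinite(cv), axis=0) | np.any(~np.isfinite(sv), axis=0)
    # missing cells are flagged and excluded below; zero-fill keeps the
    # vectorized arithmetic warning-free
    cv = np.where(missing, 0.0, cv)
    sv = np.where(missing, 0.0, sv)

    # vectorized control fit (centered OLS per cell)
    ref = cyears.mean()
    x = (cyears - ref)[:, None, None]
    cmean = cv.mean(axis=0)
    slope = np.sum(x * (cv - cmean), axis=0) / np.sum(x * x)
    resid = cv - cmean - slope * x
    noise_sd = np.sqrt(np.mean(resid**2, axis=0))
    degenerate = ~(noise_sd > 0)
    missing = missing | degenerate

    anom = sv - (cmean + slope * (syears - ref)[:, None, None])
    smooth = boxcar_smooth(anom, window=window, axis=0)
    with np.errstate(invalid="ignore"):
        exceed = np.abs(smooth) > k * noise_sd
    start = _suffix_emergence(exceed)

    toe_vals = np.where(start >= 0, syears[np.clip(start, 0, None)], np.nan).astype(float)
    toe_vals = np.where(missing, np.nan, toe_vals)
    status = np.where(missing, STATUS_MISSING, np.where(start >= 0, STATUS_EMERGED, STATUS_NEVER))

    coords = {"lat": scenario["lat"], "lon": scenario["lon"]}
    lat = scenario["lat"].to_numpy()
    w2d = np.broadcast_to(_area_weights(lat)[:, None], toe_vals.shape).copy()
    region = (lat >= region_bounds[0]) & (lat <= region_bounds[1])
    region2d = np.broadcast_to(region[:, None], toe_vals.shape).copy()

    return ToEMap(
        toe=xr.DataArray(toe_vals, coords=coords, dims=("lat", "lon"), name="toe"),
        status=xr.DataArray(status.astype("i1"), coords=coords, dims=("lat", "lon"), name="status"),
        weights=xr.DataArray(w2d, coords=coords, dims=("lat", "lon"), name="weights"),
        region=xr.DataArray(region2d, coords=coords, dims=("lat", "lon"), name="region"),
    )


def emerged_fraction(toemap: ToEMap, by_year: float) -> float:
    """Area-weighted percentage of the region emerged by ``by_year``.

    Cells with missing input are excluded from both numerator and
    denominator; the result is non-decreasing in ``by_year``.
    """
    status = toemap.status.to_numpy()
    valid = toemap.region.to_numpy() & (status != STATUS_MISSING)
    w = toemap.weights.to_numpy()
    denom = float(w[valid].sum())
    if denom == 0:
        raise ValueError("region contains no valid cells")
    toe = toemap.toe.to_numpy()
    emerged = valid & (status == STATUS_EMERGED) & (toe <= by_year)
    return 100.0 * float(w[emerged].sum()) / denom


def emergence_curve(toemap: ToEMap, years) -> pd.DataFrame:
    """Emerged area percentage for each year in ``years`` (columns:
    ``year``, ``percent``)."""
    return pd.DataFrame(
        {"year": list(years), "percent": [emerged_fraction(toemap, y) for y in years]}
    )


def pattern_agreement(field_a, field_b) -> float:
    """Spearman rank correlation between two fields, cell by cell.

    Compares the spatial patterns of two 2-D fields over the cells where
    both are finite (ties receive average ranks).  Used to quantify how
    well one experiment reproduces the change pattern of another.
    """
    a = np.asarray(getattr(field_a, "values", field_a), dtype=float)
    b = np.asarray(getattr(field_b, "values", field_b), dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3:
        raise ValueError("need at least 3 common unmasked cells")
    rho = stats.spearmanr(a[ok], b[ok]).statistic
    return float(rho)
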