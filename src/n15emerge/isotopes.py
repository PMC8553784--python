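"""Shared nitrogen-isotope bookkeeping conventions and tracer utilities.

All heavy-isotope pools in this package are *enrichment-weighted* amounts:
the light pool carries the total nitrogen of a reservoir, while the heavy
pool carries the same quantity scaled by the reservoir's isotope ratio
relative to a standard ratio that is set to exactly 1.  Under this
convention a reservoir with light pool ``L`` and isotopic signature
``d`` (permil) stores a heavy pool ``L * (1 + d / 1000)``, and

    delta15N = (heavy / light - 1) * 1000

recovers the signature.  This keeps the isotope arithmetic linear and
makes mass balance of the heavy pools exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DETECTION_THRESHOLD",
    "EUPHOTIC_LIGHT_FRACTION",
    "TWILIGHT_LIGHT_FRACTION",
    "PoolPair",
    "ZoneBounds",
    "delta15n",
    "heavy_from_delta",
    "mask_below_detection",
    "nstar",
    "depth_zone_bounds",
]

#: Minimum nitrate concentration (mmol N m-3) for a credible isotopic
#: measurement; values below this are masked before interpretation.
DETECTION_THRESHOLD = 0.3

#: Fraction of incident surface irradiance at the euphotic-zone bottom.
EUPHOTIC_LIGHT_FRACTION = 1e-3

#: Fraction of incident surface irradiance at the twilight-zone bottom.
TWILIGHT_LIGHT_FRACTION = 1e-6


@dataclass(frozen=True)
class PoolPair:
    """A (light, heavy) nitrogen pool pair under the standard-ratio-1 convention.

    Parameters
    ----------
    light
        Total nitrogen of the reservoir (e.g. mmol N m-3 or Tg N).
    heavy
        Enrichment-weighted heavy pool in the same units.
    """

    light: float
    heavy: float

    def __post_init__(self) -> None:
        if self.light < 0 or self.heavy < 0:
            raise ValueError("pool amounts must be non-negative")

    @property
    def delta(self) -> float:
        """Isotopic signature of the pair in permil."""
        return delta15n(self.light, self.heavy)


def delta15n(light, heavy):
    """Isotopic signature (permil) of a pool pair: ``(heavy/light - 1) * 1000``.

    Parameters
    ----------
    light, heavy
        Scalars or arrays of matching shape.  ``light`` must be strictly
        positive everywhere; mask undetectable values first.
    """
    light = np.asarray(light, dtype=float)
    heavy = np.asarray(heavy, dtype=float)
    if light.shape != heavy.shape:
        raise ValueError(f"shape mismatch: {light.shape} vs {heavy.shape}")
    if np.any(light <= 0):
        raise ValueError("delta15n undefined for light pool <= 0; mask first")
    out = (heavy / light - 1.0) * 1000.0
    return float(out) if out.ndim == 0 else out


def heavy_from_delta(light, delta):
    """Enrichment-weighted heavy pool for a given light pool and signature.

    Inverse of :func:`delta15n`: returns ``light * (1 + delta / 1000)``.
    """
    light = np.asarray(light, dtype=float)
    delta = np.asarray(delta, dtype=float)
    out = light * (1.0 + delta / 1000.0)
    return float(out) if out.ndim == 0 else out


def mask_below_detection(conc, delta, threshold: float = DETECTION_THRESHOLD):
    """Mask isotopic values where the substrate is below the detection limit.

    Parameters
    ----------
    conc
        Concentration field (mmol N m-3).
    delta
        Signature field (permil), same shape as ``conc``.
    threshold
        Concentration below which no isotopic measurement is credible.

    Returns
    -------
    numpy.ma.MaskedArray
        ``delta`` with cells where ``conc < threshold`` flagged invalid.
        Already-masked input cells stay masked (idempotent).
    """
    conc = np.ma.asarray(conc)
    delta = np.ma.asarray(delta)
    if conc.shape != delta.shape:
        raise ValueError(f"shape mismatch: {conc.shape} vs {delta.shape}")
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    invalid = np.ma.getmaskarray(delta) | np.ma.filled(conc < threshold, True)
    return np.ma.masked_where(invalid, delta)


def nstar(nitrate, phosphate):
    """Excess nitrate relative to Redfield stoichiometry: ``NO3 - 16 * PO4``."""
    nitrate = np.asarray(nitrate, dtype=float)
    phosphate = np.asarray(phosphate, dtype=float)
    if nitrate.shape != phosphate.shape:
        raise ValueError(f"shape mismatch: {nitrate.shape} vs {phosphate.shape}")
    out = nitrate - 16.0 * phosphate
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ZoneBounds:
    """Bottom depths (m) of the light-defined layers.

    Either bound is ``None`` when the profile never attenuates to the
    corresponding light level (open-ended zone).
    """

    euphotic_bottom: float | None
    twilight_bottom: float | None

    @property
    def euphotic_open(self) -> bool:
        return self.euphotic_bottom is None

    @property
    def twilight_open(self) -> bool:
        return self.twilight_bottom is None


def depth_zone_bounds(
    depth,
    irradiance_fraction,
    euphotic_fraction: float = EUPHOTIC_LIGHT_FRACTION,
    twilight_fraction: float = TWILIGHT_LIGHT_FRACTION,
) -> ZoneBounds:
    """Bottom depths of the euphotic and twilight zones from a light profile.

    The euphotic zone spans the surface down to ``euphotic_fraction``
    (default 0.1%) of incident irradiance; the twilight zone continues down
    to ``twilight_fraction`` (default 0.0001%).  Crossing depths are found
    by interpolation that is linear in depth versus log(irradiance
    fraction), matching the near-exponential attenuation of light in
    seawater.

    Parameters
    ----------
    depth
        Strictly increasing sample depths (m), starting at the surface.
    irradiance_fraction
        Fraction of surface irradiance at each depth; strictly decreasing,
        equal to 1 at the surface.
    """
    z = np.asarray(depth, dtype=float)
    f = np.asarray(irradiance_fraction, dtype=float)
    if z.shape != f.shape or z.ndim != 1:
        raise ValueError("depth and irradiance profiles must be matching 1-D arrays")
    if z.size < 2:
        raise ValueError("need at least two profile samples")
    if np.any(np.diff(z) <= 0):
        raise ValueError("depths must be strictly increasing")
    if np.any(np.diff(f) > 0):
        raise ValueError("irradiance fraction must be non-increasing with depth")
    if not np.isclose(f[0], 1.0):
        raise ValueError("profile must start at fraction 1 at the surface")
    if np.any(f <= 0):
        raise ValueError("irradiance fractions must be positive for log interpolation")

    logf = np.log(f)

    def crossing(threshold: float) -> float | None:
        lt = np.log(threshold)
        if logf[-1] > lt:  # never attenuates that far
            return None
        i = int(np.argmax(logf <= lt))  # first sample at/below threshold
        if logf[i] == lt:
            return float(z[i])
        frac = (lt - logf[i - 1]) / (logf[i] - logf[i - 1])
        return float(z[i - 1] + frac * (z[i] - z[i - 1]))

    return ZoneBounds(crossing(euphotic_fraction), crossing(twilight_fraction))
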