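# Methods

## Isotope bookkeeping

All heavy-isotope pools are *enrichment-weighted*: the light pool of a
reservoir holds its total nitrogen, and the heavy pool holds the same
amount multiplied by the reservoir's ¹⁵N:¹⁴N ratio relative to a standard
ratio fixed at exactly 1. δ¹⁵N = (heavy/light − 1)·1000 is then exact
arithmetic, heavy pools obey the same linear conservation laws as light
pools, and a reservoir at 5‰ with 2 mmol m⁻³ of nitrogen stores a heavy
pool of 2.010. This is a bookkeeping convention, not a claim about true
¹⁵N abundances; it is internally consistent because every flux in the
package carries its source reservoir's ratio (optionally modified by a
fractionation factor).

δ¹⁵N is undefined where the light pool vanishes. The package masks such
values (explicit invalid flags, never zeros) rather than guessing;
downstream statistics skip masked cells. The same policy applies to the
observational detection limit: nitrate signatures where the concentration
is below 0.3 mmol m⁻³ are masked, since no isotopic measurement is
credible there.

Depth zones are defined by light: the euphotic zone reaches 0.1% of
incident irradiance and the twilight zone continues to 0.0001%. Crossing
depths are interpolated linearly in depth versus log(irradiance), which
is exact for exponential attenuation and minimizes bias on coarse
vertical grids; profiles that never attenuate to a threshold return an
open-ended flag instead of a depth.

## The 0D water-parcel model

### Model structure

State: DIN, PON, ExpN and heavy twins DI¹⁵N, PO¹⁵N, Exp¹⁵N
(mmol N m⁻³). Per-day fluxes:

- μ_max = mu0·e^(T·T_growth), with mu0 = 0.6 d⁻¹ and T_growth = ln(1.066)
  (the Eppley temperature coefficient), giving μ_max ≈ 1.9 d⁻¹ at 18 °C;
- N_lim = DIN/(DIN + K_DIN); uptake = μ_max·L_lim·min(Fe_lim, N_lim)·PON.
  Light and iron limitation are fixed constants — they cap growth
  immediately after upwelling when nitrogen is replete, standing in for
  the co-limitations of high-nutrient low-chlorophyll waters;
- heavy uptake = uptake·(DI¹⁵N/DIN)·(1 − N_lim·ε_phy/1000), with
  ε_phy = 5‰. Scaling ε by N_lim is the model's central biological
  assumption: nitrogen-limited cells take what they can get and stop
  discriminating. Because PON is continuously exported, the parcel is an
  open system rather than a closed Rayleigh distillation;
- detritus = P_resp·PON²/(PON + K_resp) + P_mort·PON², split by
  f_recycled = clamp(f_recmin + T_rec·e^(T·T_growth), 0, 1) into
  recycling (back to DIN) and export (to ExpN), both carrying the PON
  ratio unmodified. The clamp is needed because the exponential form is
  unbounded in temperature and a fraction must stay physical.

### Integration

Explicit forward Euler, default dt = 0.05 day over 100 days. The stated
dynamics are difference equations, so Euler plus a convergence check is
the faithful and auditable choice; halving dt moves the final δ¹⁵N_POM by
~0.003‰ at the defaults, well below any quantity interpreted from the
model. Outflows of each pool are capped by proportional scaling so no
pool can go negative within a step; rounding residue within 1e-12 of zero
is absorbed to exactly zero. One known artifact of the hard cap: if a
step drains DIN *exactly* to zero while fractionation is active, a trace
of heavy nitrogen (order DIN·N_lim·ε/1000) is stranded in the empty pool.
The complete-consumption regime therefore uses dt = 0.005 day, at which
the drawdown resolves smoothly and the exported pool closes the isotope
budget to well under 0.01‰. Total nitrogen and total heavy nitrogen are
conserved to ~1e-15 relative (the pool equations sum to zero by
construction).

### Calibration of defaults

mu0, T_growth, ε_phy, the 100-day duration and the 18 °C reference are
fixed by the model's definition. The remaining constants are free slots;
the shipped defaults were calibrated once, jointly, to the model's
published behavioural anchors — μ_max(18 °C) ≈ 1.9 d⁻¹, a
0.19‰-per-10%-DIN-decline sweep slope, ±0.03‰ slope spread under ±4 °C,
~10% NPP loss per 10% DIN reduction, and nitrogen drawn down to limiting
levels (N_lim < 0.1) by day 100 — then rounded to clean values:

| parameter | value | units | role |
|---|---|---|---|
| K_DIN | 4.0 | mmol N m⁻³ | nitrogen half-saturation |
| L_lim | 0.9 | – | light limitation factor |
| Fe_lim | 1.0 | – | iron limitation factor |
| P_resp | 0.05 | d⁻¹ | linear respiration |
| K_resp | 0.25 | mmol N m⁻³ | respiration saturation |
| P_mort | 0.5 | (mmol N m⁻³)⁻¹ d⁻¹ | quadratic mortality |
| f_recmin | 0.3 | – | minimum recycled fraction |
| T_rec | 0.1 | – | recycling temperature scale |
| DIN_init | 5.0 | mmol N m⁻³ | upwelled nitrogen |
| PON_init | 0.1 | mmol N m⁻³ | seed biomass |
| δ¹⁵N init | 5.0 | ‰ | both pools, mean-ocean-like |

With these defaults the sweep slope is 0.195‰ per 10% and the ±4 °C
half-spread 0.034‰. The slope's mechanism: a smaller initial DIN pool
pushes the parcel into the nitrogen-limited regime earlier, so less of
the transit happens under active fractionation, the residual DIN is less
enriched, and the PON standing at the end of the run — built
progressively from that residual pool — is isotopically lighter.

### Diagnostics and conventions

- "Final δ¹⁵N_POM" is read as the signature of the standing PON pool at
  day 100 (the particulate matter present once nitrogen is depleted to
  limiting levels); the signature of cumulative export is computed and
  reported alongside, since either reading is defensible.
- Integrated NPP is Σ uptake·dt, the model's only primary-production
  flux.
- The sweep covers reductions 0–50% in 10% steps and the per-10% rate is
  an ordinary least-squares slope over the sweep — the least-surprising
  estimator for a stated per-10% rule; the slope estimator requires at
  least three sweep points including the unreduced baseline. The fitted
  range affects the third decimal only.
- Temperature sensitivity recomputes the slope at T − ΔT, T, T + ΔT
  (ΔT = 4 °C) and reports half the range of the three slopes.

## Time of Emergence

Per cell: (1) OLS trendline and mean of the control, centered on the mean
control year; the noise is the SD of the *raw, unsmoothed* control after
removing that trendline — detrending first, so a drifting control does
not inflate the envelope; (2) the scenario anomaly is the series minus
the control trendline (additive, not divisive — "normalized" is read as
subtraction, since the processed control must vary about zero even for
near-zero-mean tracers); (3) an 11-year centered boxcar whose window
shrinks symmetrically at the edges (minimum one point), preserving
series length so the persistence rule can be assessed to the final year;
(4) emergence at the first year from which |anomaly| strictly exceeds
k·SD (k = 2, a ~95% envelope) through the end year. Requiring persistence
to the end rejects temporary excursions and makes the estimate
conservative; the end year is whatever the scenario series ends at (2100
in the default synthetic span), exposed as a truncation option in the
CLI.

Controls must span ≥ 30 years for a usable noise estimate; the default
synthetic control spans 300 (1801–2100). Area fractions weight cells by
cos(latitude) over the 45°S–45°N band by default, excluding cells with
missing input from numerator and denominator. Pattern agreement between
two fields is Spearman rank correlation over common unmasked cells
(average ranks for ties), requiring at least three cells.

With k = 2 and the persistence rule, control-versus-control comparisons
on AR(1) noise with lag-1 autocorrelation 0.5 show a measured spurious
emergence rate of ~5% of cells (reported by the acceptance script, not
asserted as an exact bound; positive autocorrelation inflates it above
the nominal white-noise rate because the boxcar-smoothed anomaly decays
slowly once outside the envelope near the end of the series).

## Biogeochemical flux tendency

The diagnostic is a pure ratio of within-cell net fluxes; no neighbour
access, so circulation effects are excluded by construction. Numerical
policy (the ratio is meaningless near zero net flux): cells where the net
light-isotope flux is smaller than 1e-6 of the cell's gross light flux
are masked with a "small net flux" flag, and cells where net heavy and
net light fluxes have opposite signs — implying a negative isotope
abundance — are masked as unphysical rather than clipped. Net fluxes of
either sign are otherwise valid: net biogeochemical nitrate loss is
physical in denitrification zones. Isotopic signatures of the processes
feeding nitrification (remineralization, excretion, nitrogen fixation)
are assumed to arrive implicitly in the nitrification flux pair; no
fractionation is applied inside the diagnostic.

## Synthetic fields

The generator emulates the statistical structure the detector assumes,
nothing more: AR(1) interannual noise (the simplest process with decadal
persistence, φ = 0.5 by default, initialized from the stationary
distribution so there is no spin-up transient), optional linear control
drift, and scenario runs that share the control's noise parameters (as an
independent realization) plus per-cell linear ramps switched on at a
known onset year — anthropogenic-like signals are quasi-monotonic ramps
at this level of abstraction. Default innovation SD 0.1 gives a marginal
SD of ~0.115 tracer units; the default ramp (−0.01 units yr⁻¹ from 2000)
then emerges roughly two decades after onset. True onsets and rates are
stored with the scenario for recovery scoring. Seeds are explicit and
mandatory; identical spec and seed give bit-identical fields.

What the generator does *not* emulate: spatial covariance (cells are
independent), realistic land/sea geometry, seasonal or sub-annual
variability, nonlinear or non-monotonic forced responses, and any actual
ocean-model field. Passing recovery tests therefore demonstrate that the
detector behaves correctly under its own statistical assumptions — not
that those assumptions hold for any particular ocean simulation.

## Problem sizes

The recovery study in the acceptance script uses 32 × 16 cells × 300
years × 3 ramp rates × 20 seeds (~31k cell decisions) and a 4-seed
control-versus-control false-positive measurement; the detector chain is
fully vectorized, so the whole script completes in seconds. The parcel
experiments integrate 2000 steps per run (40,000 for the fine-step
mass-balance case).

## I/O and formats

Gridded fields are read and written as classic netCDF (NETCDF3_64BIT via
xarray's scipy backend) with dimensions (year, lat, lon) and unit
attributes; ToE maps encode "never emerged" with a documented fill value
of −1 plus an explicit status variable (emerged / never / missing).
Tables and 1-D series are plain CSV; configs are YAML mappings whose keys
mirror the dataclass parameter names. Every CLI output gets a
deterministic provenance sidecar (stage, resolved config, seed, package
version — no timestamps, so reruns are bit-identical).

## Known limitations

- The parcel model has no advection, no iron or light dynamics, no
  explicit zooplankton, and a single phytoplankton pool; its transit is
  purely the parcel's own time axis.
- The calibrated constants are stand-ins chosen to reproduce the model's
  behavioural anchors, not measured rates; conclusions should rest on the
  calibrated behaviour, not on individual constant values.
- The ToE false-positive rate is measured, not controlled; no
  field-significance or multiple-testing correction is applied across
  cells.
- The flux diagnostic depends entirely on the quality of the input flux
  decomposition; it cannot detect upstream biological changes by design.
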