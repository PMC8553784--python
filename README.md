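# n15emerge

Tools for studying how intensifying nitrogen limitation of low-latitude
phytoplankton is fingerprinted by nitrogen isotopes (δ¹⁵N), built for
marine-biogeochemistry researchers who want the isotope mechanism, the
detectability question and the flux bookkeeping in one tested package.

The ocean's low latitudes (45°S–45°N) are nitrogen-limited, so changes to
the marine nitrogen cycle — driven by climate change and atmospheric
nitrogen deposition — control long-term trends in net primary production
(NPP). Because phytoplankton prefer the light isotope (¹⁴N) when nitrogen
is plentiful but lose that preference as nitrogen becomes limiting, the
isotopic composition of nitrate (δ¹⁵N_NO₃) and particulate organic matter
(δ¹⁵N_POM) records shifts in nitrogen supply and utilization. The package
implements three connected components:

1. **A 0D water-parcel model** (`n15emerge.parcel`). A parcel of
   upwelled water carries dissolved inorganic nitrogen (DIN), particulate
   organic nitrogen (PON) and exported nitrogen (ExpN), plus
   enrichment-weighted heavy-isotope twins, over a 100-day transit to the
   subtropical gyre. Growth follows μ_max = 0.6 d⁻¹·e^(T·T_growth) with
   Michaelis–Menten nitrogen limitation N_lim = DIN/(DIN + K_DIN); uptake
   fractionates by ε_phy = 5‰ scaled by N_lim (open-system behaviour, so
   fractionation shuts down as nitrogen runs out); detritus from linear
   respiration and quadratic mortality is split between recycling and
   permanent export by a temperature-dependent fraction. The headline
   result is a rule of thumb: every 10% decline in initially upwelled DIN
   costs ~10% of integrated NPP and lowers the final δ¹⁵N_POM by
   ~0.19 ± 0.03‰ (the uncertainty from ±4 °C temperature changes).

2. **Time-of-Emergence (ToE) detection** (`n15emerge.toe`). For annual
   (year, lat, lon) tracer fields, each cell's scenario series is
   expressed as an anomaly about the linear trend and mean of a
   multi-century control, smoothed with an 11-year boxcar, and compared
   with a 2-standard-deviation envelope of the control's raw interannual
   variability. A trend has emerged in the first year from which it stays
   outside the envelope through the end of the simulation; temporary
   excursions are rejected. Area summaries use cos(latitude) weights over
   the low-latitude band, and spatial patterns are compared with
   Spearman rank correlation.

3. **A biogeochemical δ¹⁵N_NO₃ flux diagnostic** (`n15emerge.isoflux`).
   Within each cell, nitrification is the only internal nitrate source
   and new production and denitrification the sinks. The diagnostic

   Δδ¹⁵N_NO₃ = ((¹⁵NO₃ⁿⁱᵗʳ − ¹⁵NO₃ⁿᵉʷ − ¹⁵NO₃ᵈᵉⁿ) /
                (¹⁴NO₃ⁿⁱᵗʳ − ¹⁴NO₃ⁿᵉʷ − ¹⁴NO₃ᵈᵉⁿ) − 1) · 1000

   gives the signature toward which local biogeochemistry pushes nitrate,
   cleanly separated from circulation effects.

A synthetic-field generator (`n15emerge.synthetic`) produces control and
scenario grids with AR(1) interannual noise and linear ramp trends with
known onset years, plus flux fields with prescribed signatures, so every
detector result can be scored against ground truth. Shared isotope
conventions live in `n15emerge.isotopes` (heavy pools are
enrichment-weighted with the standard ratio set to 1, so
δ¹⁵N = (heavy/light − 1)·1000 exactly).

## Worked example

```python
import n15emerge as n15

# the calibrated parcel and its upwelling sweep
sweep = n15.upwelling_sweep(n15.ParcelParams())
print(sweep[["reduction", "integrated_npp", "final_delta_pom"]].round(3))
print("decline per 10%:", round(n15.slope_per_10pct(sweep), 3), "permil")
print("T +/- 4C half-spread:", round(n15.temperature_sensitivity(n15.ParcelParams()), 3))
```

prints

```
   reduction  integrated_npp  final_delta_pom
0        0.0          12.680            6.994
1        0.1          11.382            6.810
2        0.2          10.086            6.621
3        0.3           8.790            6.426
4        0.4           7.494            6.226
5        0.5           6.201            6.019
decline per 10%: 0.195 permil
T +/- 4C half-spread: 0.034
```

Each 10% cut in the initial 5 mmol m⁻³ of upwelled DIN removes ~10% of
the parcel's integrated NPP and ~0.19‰ from the final particulate
signature; warming or cooling the parcel by 4 °C moves that slope by
~0.03‰. Detection on synthetic fields:

```python
spec = n15.SyntheticSpec(nlat=16, nlon=32, phi=0.5, ramp_rate=-0.01,
                         onset_year=2000, seed=3)
tm = n15.toe_map(n15.gen_scenario(spec)["tracer"], n15.gen_control(spec))
print("emerged by 2100:", round(n15.emerged_fraction(tm, 2100), 1), "%")
```

reports `emerged by 2100: 100.0 %` with a median detected emergence near
2024 — about two decades after the true onset, the expected lag for a
ramp of 0.01 units yr⁻¹ against interannual noise of ~0.12 units.

The same workflow is scriptable from the shell:

```sh
n15emerge parcel sweep --out sweep.csv
n15emerge synth control --set seed=3 --out control.nc
n15emerge synth scenario --set seed=3 --set ramp_rate=-0.01 --out scenario.nc
n15emerge toe detect --control control.nc --scenario scenario.nc --out toe.nc
n15emerge toe fraction --toe-map toe.nc --out curve.csv
```

Every command writes a deterministic `.provenance.json` sidecar recording
the resolved configuration and seed.

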