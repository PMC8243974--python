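# Methods

This note documents the model equations, parameter provenance, the
synthetic forcing, numerical choices and limitations of `plastisink`.

## The biofouling model

Each virtual particle is a pristine sphere (radius `r_pl`, polymer density
`ρ_pl`) carrying an attached algal surface density `A` (cells per m² of the
pristine surface). `A` evolves by the classic biofouling balance of the
Kooi et al. (2017) model:

    dA/dt = A_A β_A / θ_pl + µ_A A − m_A A − Q10^((T−20)/10) R20 A

* **Collision source.** The encounter kernel `β_A` (m³ s⁻¹) sums three
  collision mechanisms between the fouled particle (total radius `r_tot`)
  and ambient algal cells of equivalent-sphere radius
  `r_A = (3 V_A / 4π)^(1/3)`:

      β_Brownian  = 4π (D_pl + D_A)(r_tot + r_A),   D_i = k_B T_K / (6π µ r_i)
      β_settling  = ½ π r_tot² |V_s|
      β_shear     = 1.3 γ (r_tot + r_A)³

  with `T_K = T + 273.16` and dynamic viscosity `µ` from the local seawater
  state. The kernel is U-shaped in particle radius: Brownian diffusivity
  (`∝ 1/r`) dominates below ~1 µm, contact mechanisms above. Dividing by
  the pristine surface area `θ_pl = 4π r_pl²` converts the volumetric
  encounter rate into a surface-density source. Attachment is irreversible
  and instantaneous; there is no detachment or defouling term.
* **Growth.** `µ_A = pp / phyto` (converted d⁻¹ → s⁻¹): primary
  productivity and phytoplankton biomass pass through the same
  nitrogen-to-cell conversion, which cancels algebraically, so the growth
  rate is independent of the conversion constant. Zero biomass returns zero
  growth.
* **Losses.** Constant grazing/mortality `m_A = 0.39 d⁻¹` and respiration
  `R20 = 0.1 d⁻¹` at 20 °C with `Q10 = 2` (the rate doubles per +10 °C).

Biofilm geometry and density: the film volume is `V_bf = V_A · A · θ_pl`;
the fouled radius is `r_pl (1 + V_bf/V_pl)^(1/3)` (exact at `A = 0`); the
bulk density is the volume-weighted mean of `ρ_pl` and the biofilm density,
which it approaches monotonically as `A → ∞`.

### Parameter provenance

Defaults are shipped in `src/plastisink/data/kooi_defaults.yaml` with
units and provenance per entry: `V_A = 2×10⁻¹⁶ m³`, `ρ_bf = 1388 kg m⁻³`,
shear rate `γ = 1.7×10⁵ d⁻¹ (≈ 2 s⁻¹)`, `m_A`, `R20`, `Q10` as above —
the constants of the published Kooi et al. (2017) biofouling model.
Nitrogen conversions: 14.007 mg N per mmol N, and 356.04×10⁹ algal cells
per **mg** N (the Menden-Deuer & Lessard median carbon/cell value as used
in nitrogen terms). The units of the cell conversion are genuinely
ambiguous in the literature (per mg vs per g N, three orders of
magnitude); the constant is exposed in `KooiParams` and the default
follows the per-mg reading. To make simulated dynamics independent of that
choice, both the idealized column and the synthetic-ocean generator are
parameterized directly in *ambient cell concentration* (cells m⁻³) and
*specific growth rate* (d⁻¹) — the two quantities the biofilm equation
actually consumes — and derive the stored phytoplankton-nitrogen fields
through whatever conversion is active.

## Settling velocity

The signed settling velocity of the fouled sphere follows the
dimensionless Dietrich (1982) law:

    D*  = |ρ_tot − ρ_sw| g d³ / (ρ_sw ν²)          (d = 2 r_tot)
    ω*  = 1.71×10⁻⁴ D*²                            for D* < 0.05 (Stokes regime)
        = 10^(−3.76715 + 1.92944 log D* − 0.09815 log²D* − 0.00575 log³D* + 0.00056 log⁴D*)
    |V_s| = ( |ρ_tot − ρ_sw|/ρ_sw · g · ω* · ν )^(1/3)

negative (down) when the particle is denser than seawater, positive (up)
when lighter, zero at neutral buoyancy. The quadratic branch reproduces
Stokes' law (exact coefficient 1/5832 ≈ 1.715×10⁻⁴) to within 0.3%. The
two published branches do not meet exactly: at `D* = 0.05` the quadratic
exceeds the polynomial by 14.9%. We keep the published coefficients and
breakpoint rather than smoothing them, and test monotonicity within each
branch; for the particle sizes in scope the breakpoint is crossed at
negligible velocities. Beyond the law's stated validity (`D* > 5×10⁹`,
reached only by centimetre-scale debris) `ω*` is clamped at the bound and
a warning is emitted, since extrapolating the quartic produces runaway
velocities.

## Seawater

Density is the 55-term polynomial TEOS-10 equation of state (Roquet et
al. 2015, Boussinesq form, including the vertical reference profile),
evaluated directly on model temperature/salinity treated as conservative
temperature and absolute salinity — an exact identity for synthetic
forcing, and a <0.01 kg m⁻³ class approximation elsewhere. Pressure is
depth in metres (1 dbar ≈ 1 m; surface-ocean focus). The implementation
reproduces the published check value ρ(SA=30 g kg⁻¹, CT=10 °C, z=1000 m) =
1027.45056 kg m⁻³ to 1×10⁻³ and standard-ocean σ₀ = 28.1063 to 6×10⁻⁴.
Dynamic viscosity follows the Sharqawy et al. (2010) seawater correlation
(pure-water check value 1.002×10⁻³ Pa s at 20 °C); kinematic viscosity is
µ/ρ. Viscosity variation over ocean conditions is weak but real — ν
roughly halves from 0 to 30 °C (measured spread factor 2.21 over T ∈
[0, 30] °C, S ∈ [33, 37] g kg⁻¹).

## Integration

* **Scheme.** Positions advance by fourth-order Runge-Kutta on
  `(u, v, w + V_s)`, with `V_s` recomputed at every substage from the local
  seawater state and the current biofilm load; `A` is held fixed within a
  step and then advanced by one forward-Euler step using the step-start
  environment (operator splitting; `A` varies on day scales, the step on
  30 s scales). Degree↔metre conversion uses the local cosine-latitude
  metric.
* **Time step.** Default dt = 30 s, configurable. Convergence is tested:
  halving the step near the operating scale changes a 5-day column biofilm
  load by <0.5% and a 15-day first sinking depth by <1 m. Desk-scale runs
  in the test suite and acceptance script use dt = 60–1200 s after those
  checks.
* **Surface clamp.** Initially buoyant particles are held at the release
  depth (0.6 m, the model surface) with recorded vertical velocity 0
  whenever their net vertical velocity points upward there; a downward net
  velocity releases the clamp. Comparisons use a 10⁻⁶ m tolerance. This
  prevents meaningless oscillation between 0 and 0.6 m.
* **Boundaries.** A particle reaching the provider's seafloor or latitude
  edge is frozen in place and flagged; its subsequent stored velocity is
  zero. Release rows placed exactly on the grid's edge latitude can freeze
  immediately if advected poleward — global releases should stay inside
  the forcing domain.
* **Toggles.** Biofouling off forces `dA/dt ≡ 0`; advection off zeroes
  `(u, v, w)`; horizontal-only zeroes `w`; vertical-only zeroes `(u, v)`.
* **Output.** Snapshots every 12 h (configurable multiple of dt), stored
  at `k·Δt_out, k = 1…horizon/Δt_out` — a 90-day run stores exactly 180
  positions. Each snapshot records position, `A`, the net vertical
  velocity, the settling velocity and clamp/freeze flags; the running
  maximum |V_s| per particle is tracked at substage resolution.

## Diagnostics

`T_s` is the time of the first stored snapshot whose net vertical velocity
is strictly downward (tolerance 10⁻¹² m s⁻¹, so the clamp's exact zero
never counts); particles with no such snapshot carry a NaN sentinel.
`Z_s` follows depth from that snapshot to the first snapshot where the
velocity is no longer downward (or the final depth if sinking persists);
the trajectory afterwards is ignored. Both are evaluated at the stored
12-h resolution, not the internal 30 s step — a deliberate choice that
matches what a trajectory archive can support; with 12-h snapshots `T_s`
is quantized to half days. Seasonal maps average `T_s` per release
location over the seasons in which the particle sinks; summary medians are
over sinking particles only (stated in the output metadata).

## Synthetic ocean

The generator emulates the large-scale structure that drives biofouling,
on a regular 2°×2° A-grid with 20 depth levels (0.6–800 m) and 73
five-day means over a 365-day climatological year (periodic in time and
longitude):

* surface ambient algae blended in log space: mid-ocean background
  3×10⁸ cells m⁻³, five subtropical gyres suppressed to 5×10⁷, an
  equatorial band raised to 5×10⁹, and hemispheric spring blooms (×10,
  peaking mid-April at 35–65°N and mid-October at 35–65°S), floored at
  2×10⁷ everywhere; biology decays below the mixed layer (50 m e-folding);
* specific growth 0.2–1.2 d⁻¹ with the same spatial structure;
* seasonal mixed-layer depth (30 m base, +70 m in late-winter mid-latitudes)
  and an SST climatology (28 °C equator to −1 °C poles, ±3 °C seasonal);
* anticyclonic gyre-scale swirls plus zonal trade/westerly bands (≤0.5 m/s,
  decaying over 200 m), equatorial upwelling and gyre-interior downwelling
  of ~2×10⁻⁵ m s⁻¹ tapered to ~0 at the surface (kinematic boundary
  condition — surface departure is driven by biofouling, not by spurious
  vertical advection);
* an idealized three-continent land mask; velocities are zero on land
  columns and tracers are smooth analytic fields everywhere, so
  land-adjacent interpolation always draws ocean-like values;
* a seeded lognormal (σ = 0.05) standing noise pattern on the biology:
  runs are bit-reproducible for a fixed seed.

What it does **not** emulate: mesoscale eddies and fronts, realistic
coastlines and bathymetry (uniform 800 m floor), tripolar C-grid staggering
(sampling is regular-grid trilinear + linear in time), nutrient dynamics
(growth enters only through the productivity/biomass ratio), and
interannual variability. Passing tests on this world demonstrate the
model's mechanisms — size-selective sinking, gyre retention of 1 mm–10 µm
particles, bloom-season responses — not quantitative agreement with any
particular ocean state; global medians for the larger size classes depend
on the full forcing fields and are outside desk scale.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run desk-scale configurations
chosen as the package's own defaults for fast, deterministic verification:
a 10° global release (≈474 ocean points) for the global diagnostics, 25-point
regional boxes, a 5-day horizon at dt = 600 s for the smallest-particle
timescale, 30 days at dt = 30 s for the equatorial column, and 90 days at
dt = 600 s for the velocity-envelope run (after the dt-convergence checks
above).

## Known limitations

* No turbulence or wind-driven mixing; no beaching, fragmentation, grazing
  feedbacks or defouling below the euphotic zone (particles that stall at
  depth are simply followed to their first stall).
* The equations are not meant for particles much above 1 mm radius; the
  settling law is clamped rather than extrapolated beyond its validity.
* Forward-Euler biofilm stepping requires dt ≪ 1/(net biofilm rate); at
  multi-hour steps in bloom conditions the exponential growth phase incurs
  percent-level error (quantified by the convergence tests).
* `T_s`/`Z_s` are snapshot-resolution quantities; sub-12 h sinking onsets
  are reported as the first half-day.
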