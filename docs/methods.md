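# Methods

This note documents the model structure, the parameters that matter, what
the synthetic forcing generator does and does not emulate, the numerical
choices, and the known limitations of `nitriver`.

## Model structure and assumptions

The simulator couples three components on a rectangular grid of land
cells (0-based, row-major, latitude-first; cells are areas, with a mean
cell area of ~3.6×10¹² m² so that tens of cells carry a global-scale land
area of order 10¹⁴ m²):

1. **Terrestrial cycling** per land-use tile (primary, secondary,
   cropland, pasture). Eleven pools per tile. All process fluxes are
   donor-controlled first order; each step applies, in a fixed operator
   order: external inputs → plant uptake → allocation/litterfall →
   decomposition → nitrification → soil denitrification → leaching →
   harvest/grazing/fire. Every transfer over a step is the exact
   exponential fraction `1 − exp(−k·dt)` of the donor pool, which makes
   the update unconditionally positive and lets the budget close exactly.
2. **Freshwater cycling and routing.** Leached NO₃⁻, NH₄⁺ and DON are
   split between a cell's lake (by lake area fraction) and its river
   reach; the lake drains into the reach and reaches advect downstream
   along an acyclic single-downstream-neighbor network to coastal
   outlets. In-water mineralization (DON→NH₄), nitrification (NH₄→NO₃)
   and denitrification (NO₃→gas) are first order.
3. **Scenario engine.** Spin-up to equilibrium under a repeated forcing
   year, then a transient run with annual forcings held piecewise
   constant within the year (365-day calendar). The annual flux ledger
   (TgN yr⁻¹) records every input, output, and storage compartment.

Input rules: fertilizer enters cropland mineral pools only (a warning is
logged and no input is registered if a cell has fertilizer but no
cropland); deposition enters all tiles at an equal per-area rate; the
managed-land manure stream is applied to cropland and pasture, the
grassland stream to pasture only; BNF is simulated, down-regulated by
mineral N, with a cultivation-induced extra on cropland.

Land-use transitions are applied at year boundaries as an area-conserving
mixing: shrinking tiles keep their pool densities and cede the N on the
lost area to the expanding tiles. Cell-total N in every pool is invariant
under the transition, which is what keeps multi-decade budget closure at
machine precision while cropland expands.

Manure handling follows the data situation the scenarios describe:
gridded applications exist from 2002 onward for SSP2-4.5, SSP4-3.4 and
SSP5-8.5; requesting manure under SSP1-2.6 raises an error (a custom
trajectory can be supplied instead). Before 2002 the engine reconstructs
applications by recycling the previous year's simulated grazing and crop
harvest (`managed = f_crop·harvest`, `grassland = f_graze·grazing`),
giving a smooth transition into the data period. Net harvest is reported
as gross harvest minus recycled manure (clipped at zero for reporting
only; ledger arithmetic uses the unclipped value).

## Key equations

* **Q10 temperature adjustment** (soil nitrification/denitrification and
  all freshwater kinetics): `f(T) = Q10^((T − T_ref)/10)`, `Q10 = 2`,
  `T_ref = 20 °C`. The ratio per +10 °C is exactly Q10 at any T.
* **Freshwater denitrification**: uptake velocity `v_f = a·C^b`
  (`a = 35 m yr⁻¹` at 1 mgN L⁻¹, `b = −0.5`, config-exposed), converted
  to a volumetric first-order rate by dividing by water depth and scaled
  by the Q10 factor. With `−1 < b < 0`, removal efficiency falls while
  areal removal still rises with concentration: heavily loaded rivers
  export a disproportionate share of their inputs, and conversely high
  in-stream removal damps load responses where inputs are large. The
  constants are order-of-magnitude stand-ins for reach-scale regression
  estimates; all tests rest on the structural contracts, not on these
  values.
* **CO₂ fertilization**: multiplier `m = 1 + β ln(C/C_ref)` on potential
  uptake demand (`β = 0.35`, `C_ref = 285 ppm`), identically 1 when the
  toggle is off.
* **Plant uptake**: `U = D·A/(D + A)` with demand `D = u_pot·m·dt` and
  availability `A = (1 − e^(−k_avail·dt))·(NH₄+NO₃)`. The harmonic-mean
  co-limitation was chosen over a hard `min(D, A)`: the min form is
  insensitive to CO₂ whenever availability binds and exports marginal
  fertilizer one-for-one whenever demand binds, so it cannot produce
  both a CO₂-fertilization response and a damped (<1) export response to
  fertilizer steps. The smooth form is monotone in both arguments and
  has the same limits.
* **Leaching**: first-order rates `λ = coeff · runoff_fraction ·
  (P/P_ref)` on NO₃ (coeff 3.0 yr⁻¹), NH₄ (0.6 yr⁻¹; sorption) and, for
  DON, on fast litter + slow soil (0.02 yr⁻¹). Runoff fraction is a
  prescribed forcing (default 0.3) because the package does not implement
  physical hydrology; reach/lake volumes are discharge × residence time
  (10 days / 0.5 yr) with prescribed depths (1 m / 5 m).

## Synthetic forcing generator

The generator is first-class, tested code. It produces annual gridded
drivers from piecewise-linear global anchor trajectories distributed over
cells by fixed spatial patterns (fertilizer ∝ cropland area, deposition ∝
area with a random pattern, manure ∝ agricultural area), plus optional
AR(1) interannual noise on climate (default relative amplitude 0.02).
Anchor values were chosen once so that:

* late-century (2079–2099) global fertilizer totals sit in the
  100–210 TgN yr⁻¹ range and are ordered SSP2-4.5 (~200) > SSP1-2.6
  (~150) > SSP5-8.5 (~110);
* deposition, warming and precipitation are ordered by emission level
  (SSP5-8.5 > SSP2-4.5 > SSP1-2.6), with end-of-century warming of
  4.8/2.9/1.7 °C relative to 1861 and precipitation scaling at 2 % per
  °C;
* CO₂ reaches ~1100/600/446 ppm by 2099;
* SSP5-8.5 manure peaks in the 2040s and declines after the 2060s.

The historical portion (≤2014) is identical across scenarios for a given
seed, so paired experiments diverge only through their projections, and
the spin-up state can be shared across scenarios within a suite.

What the generator does **not** emulate: real spatial covariance of
climate and agriculture, sub-annual seasonality, hydroclimate extremes,
downscaled CMIP6 fields, or the actual magnitudes of any specific
catchment. Passing tests therefore demonstrate structural/sign properties
of the process chain (ordering, damping, conservation, calibration), not
agreement with observed rivers.

**Perturbation experiments.** The precipitation perturbation multiplies
each cell by a linear ramp from 1 in 2020 to a per-cell factor solved so
that the 2080–2099 mean exceeds the 1986–2005 mean by exactly the target
(+7.6 % by default); the temperature perturbation is an additive ramped
offset with the same end-point contract (+5.3 °C by default). Additive
rather than proportional for temperature, because a proportional factor
on a Celsius field is ill-defined across 0 °C; the realized-increase
contract is the only verifiable statement. Solving per cell (rather than
one global factor) makes the global area-weighted change exact *and*
makes perturbation commute with spatial subsetting. The CO₂ experiment
freezes concentration at its 2014 value.

## Numerical choices

* Default process step 30 days for scenario runs (config-exposed down to
  sub-daily); spin-up uses monthly steps. The exponential/operator-split
  update is positivity-preserving and exactly conservative at any step;
  step size only affects accuracy of fast-process competition. A guard
  raises if `rate × dt` exceeds 25 for the fastest configured process,
  naming the rate.
* Spin-up uses a drift criterion — relative change of every storage
  compartment over a 50-year window below tolerance (default 1e-4 for
  library calls, 1e-3 in the scenario suite) — rather than a fixed
  duration; desk-scale turnover (passive soil 0.02 yr⁻¹) equilibrates in
  a few hundred years.
* Routing is vectorized by topological level (longest path to an outlet);
  upstream outflow generated within a step feeds the downstream reach in
  the same step. Freshwater concentrations are frozen at the step start
  for the denitrification coefficient; the concentration floor is
  1e-6 mgN L⁻¹.
* Ties in synthetic steepest-descent routing are broken by a seeded
  random field; the network is acyclic by construction (every hop
  strictly reduces breadth-first distance to the ocean).
* The 21-year moving average uses truncated windows at the series edges
  (config-switchable to valid-only). Correlation p-values use the
  t-approximation, cross-checked against a permutation oracle in tests;
  no multiple-testing correction is applied.
* Percent period changes with a zero base mean are flagged NaN, not
  raised.
* Desk-scale problem sizes used by the test suite: 3×3 to 6×6 grids,
  1950–2099 scenario runs at monthly steps, 10 random replicates for the
  ordering property.

## Design choices where the design was open

* Within a cell the lake discharges into the reach and the reach
  discharges downstream (the alternative ordering is a config switch away
  in principle; the choice is logged here).
* Deposition enters via land tiles only; no direct deposition on water
  surfaces.
* Urban land is grouped into secondary land; no separate urban tile.
* pcGDP series are diagnostic metadata for ordering regions on
  cross-plots; they never feed back into the simulation.
* Per-capita-GDP, region membership (contiguous blocks of land cells),
  and spatial driver patterns are synthetic; region codes follow the
  11-region world-region convention (NAM, PAO, WEU, CPA, PAS, LAC, EEU,
  FSU, MEA, SAS, AFR).
* The internal unit system is kgN–m–yr with centralized conversion to
  TgN yr⁻¹ for reporting; rates in this field are quoted per day or per
  year, and a seconds-based clock would only multiply conversion sites.

## Known limitations

* One effective vegetation pool per tile: plant-functional-type
  competition, explicit crop phenology and wood-product pools are not
  resolved; PFT identity can only enter through parameter sets.
* No carbon co-simulation (C stoichiometry is folded into rate
  parameters), no phosphorus limitation, no sewage, no dams or water
  management, no sediment/particulate N, and no N₂O/N₂ split of
  denitrification.
* Hydrology is prescribed (runoff fraction, residence times, depths),
  not simulated; discharge extremes and their load impacts are out of
  scope.
* Equilibrium spin-up plus smooth forcings means simulated trajectories
  respond to trends, not to interannual hydroclimate variability beyond
  the small AR(1) noise.
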