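# nitriver

Desk-scale, process-based simulation of terrestrial–freshwater nitrogen
cycling and river N delivery to the coastal ocean under socioeconomic
climate scenarios.

## The problem

River export of dissolved nitrogen (DN = dissolved inorganic N, DIN, plus
dissolved organic N, DON) drives coastal eutrophication. How it evolves
over the 21st century depends on the interplay of fertilizer use,
atmospheric deposition, biological N fixation (BNF), manure recycling,
land-use change, warming, precipitation, and CO₂ fertilization of
vegetation. `nitriver` provides a compact, fully mass-conserving
process model of this chain for scientists who want to study the
*structure* of these responses — scenario orderings, budget ledgers,
damping of load responses relative to input changes, regional contrasts —
at a scale that runs in seconds to minutes on one CPU.

## The model

On a gridded land domain, each cell carries four land-use tiles (primary,
secondary, cropland, pasture; the 12 LUH2 classes are grouped into these
four) and 17 N pools:

* 5 vegetation pools (leaves, fine roots, sapwood, heartwood, labile),
* 4 organic soil pools (fast/slow litter, slow/passive soil),
* 2 inorganic soil pools (NH₄⁺, NO₃⁻),
* 6 freshwater pools (river and lake DON, NH₄⁺, NO₃⁻).

All transformations are donor-controlled first order with analytically
integrated (exponential) updates, so pools stay non-negative at any step
and the budget closes to machine precision:

```
dS/dt = (fertilizer + deposition + BNF + manure)
      − (DIN load + DON load + gross harvest + soil denit + freshwater denit + fire)
```

Plant uptake is co-limited by demand and mineral-N availability,
`U = D·A/(D+A)`, with demand scaled by a logarithmic CO₂-fertilization
multiplier `1 + β ln(C/C_ref)`. Leached NO₃⁻/NH₄⁺/DON enter a
single-downstream-neighbor river network; in-stream mineralization,
nitrification and denitrification are first order, temperature-adjusted by
a Q10 factor (rates double per +10 °C at the default Q10 = 2), and the
denitrification coefficient is concentration-dependent through an uptake
velocity v_f = a·C^b (b ≤ 0) divided by water depth. Routing follows the
acyclic drainage graph to coastal outlets.

A synthetic forcing generator supplies SSP-style scenario drivers with the
qualitative cross-scenario structure that matters for N loads (fertilizer
SSP2-4.5 > SSP1-2.6 > SSP5-8.5; deposition/temperature/precipitation
ordered by emissions; manure projections available from 2002 for
SSP2-4.5/SSP4-3.4/SSP5-8.5 only, peaking in the 2040s under SSP5-8.5),
plus climate/CO₂ perturbation experiments (ramped +7.6 % precipitation or
+5.3 °C by 2080–2099 relative to 1986–2005; CO₂ frozen at 2014).

## Worked example

```python
import nitriver as nr
from nitriver.engine import run_suite

domain, net, regions = nr.build_synthetic_domain(4, 4, land_fraction=1.0, seed=3)
specs = [nr.ScenarioSpec(name=n, start_year=1950, seed=3)
         for n in ("SSP1-2.6", "SSP2-4.5", "SSP5-8.5")]
out = run_suite(specs, domain, net, regions, dt_days=30.0)
print(out.summary[["scenario", "dn_base", "dn_eval", "dn_change_pct"]])
```

prints (global river DN loads in TgN yr⁻¹, means over 2000–2020 and
2079–2099, and the percent change between them):

```
   scenario    dn_base    dn_eval  dn_change_pct
0  SSP1-2.6  47.325008  59.343334      25.395298
1  SSP2-4.5  47.508439  72.445590      52.489938
2  SSP5-8.5  47.101425  42.093970     -10.631217
```

The late-century load ranking follows the fertilizer ranking
(SSP2-4.5 > SSP1-2.6 > SSP5-8.5), not the emissions ranking: the
fossil-fuel scenario has the strongest warming and deposition but the
lowest fertilizer use, and its loads respond accordingly. This is the
qualitative behaviour the package is built to expose; absolute numbers
depend on the synthetic forcing magnitudes and grid (see
`docs/methods.md`).

A CLI mirrors the library:

```bash
nitriver validate-domain --grid 6x6
nitriver make-forcings --scenario SSP2-4.5 --grid 6x6 --seed 1 --out forcings.nc
nitriver simulate --config run.yaml --out results/
nitriver suite --config suite.yaml
```

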