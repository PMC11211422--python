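"""Model parameters with units and desk-scale defaults.

Every rate is expressed per year at the reference temperature ``t_ref``;
temperature sensitivity enters through a Q10 factor (see
:func:`nitriver.freshwater.temperature_factor`). All parameters are
config-exposed; the defaults aim at order-of-magnitude realism for a
coarse global tiling, not at reproducing any particular catchment.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field


class ParamError(ValueError):
    """Raised for inadmissible parameter values."""


@dataclass
class TerrestrialParams:
    """Vegetation/soil N cycling parameters (kgN, m2, yr)."""

    # plant uptake: min(potential demand x CO2 multiplier, available mineral N)
    uptake_potential: float = 0.012   # kgN m-2 yr-1 potential N demand
    uptake_avail_rate: float = 10.0   # yr-1, max first-order draw on mineral N
    co2_beta: float = 0.35            # logarithmic CO2-fertilization strength
    co2_ref: float = 285.0            # ppm, pre-industrial reference

    # allocation of labile plant N to structural pools
    alloc_rate: float = 5.0           # yr-1 out of labile storage
    alloc_leaves: float = 0.45
    alloc_fine_roots: float = 0.30
    alloc_sapwood: float = 0.15
    alloc_heartwood: float = 0.10

    # turnover (litterfall / mortality)
    k_leaf_turnover: float = 1.0      # yr-1, leaves + fine roots -> fast litter
    k_wood_turnover: float = 0.05     # yr-1, sapwood + heartwood -> slow litter

    # decomposition cascade, with a mineralized fraction to ammonium per transfer
    k_fast_litter: float = 2.0        # yr-1
    k_slow_litter: float = 0.3        # yr-1
    k_slow_soil: float = 0.04         # yr-1
    k_passive_soil: float = 0.02      # yr-1 (fully mineralized)
    mineralization_fraction: float = 0.45

    # inorganic soil transformations (Q10-adjusted)
    k_nitrification: float = 10.0     # yr-1 at t_ref, NH4 -> NO3
    k_soil_denitrification: float = 0.8  # yr-1 at t_ref, NO3 -> gas
    q10: float = 2.0
    t_ref: float = 20.0               # degC

    # biological N fixation (down-regulated by mineral N)
    bnf_max: float = 0.0025           # kgN m-2 yr-1 at zero mineral N
    bnf_floor: float = 0.0003         # kgN m-2 yr-1 asymptotic floor
    bnf_half_sat: float = 0.002       # kgN m-2 mineral N at half down-regulation
    bnf_cultivated: float = 0.002     # kgN m-2 yr-1 extra on cropland (legumes)

    # leaching: first-order rate = coeff x runoff_fraction x (precip / precip_ref)
    leach_no3: float = 3.0            # yr-1 dimensionless coefficient
    leach_nh4: float = 0.6            # yr-1 (NH4 sorbs; less mobile)
    leach_don: float = 0.02           # yr-1 on fast litter + slow soil
    precip_ref: float = 1000.0        # kg m-2 yr-1

    # harvest / grazing / fire (continuous first-order removal)
    k_crop_harvest: float = 1.5       # yr-1 on cropland leaves + labile
    k_grazing: float = 0.8            # yr-1 on pasture leaves
    k_wood_harvest: float = 0.02      # yr-1 on secondary sapwood + heartwood
    k_fire: float = 0.01              # yr-1 on non-crop vegetation + litter

    # speciation of applied inputs
    fert_no3_fraction: float = 0.5    # rest enters ammonium
    dep_no3_fraction: float = 0.5
    manure_nh4_fraction: float = 0.5  # rest enters fast litter as organic N

    #: updates with rate x dt above this resolve < 1e-11 of a pool and signal
    #: a step too coarse for the fastest configured process
    max_rate_dt: float = 25.0


@dataclass
class ManureParams:
    """Historical manure reconstruction from simulated grazing/harvest."""

    f_grazing: float = 0.45   # fraction of grazed N returned as grassland manure
    f_crop: float = 0.25      # fraction of crop harvest N returned as managed manure

    def validate(self) -> None:
        for name in ("f_grazing", "f_crop"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ParamError(f"{name} must lie in [0, 1], got {v}")


@dataclass
class RateParams:
    """Freshwater kinetics (first-order, Q10 temperature-adjusted).

    Mineralization and nitrification coefficients are prescribed.
    Denitrification uses a concentration-dependent uptake velocity
    v_f = a * C**b (m yr-1, C in mgN L-1), converted to a volumetric
    first-order rate by dividing by water depth.
    """

    k_min: float = 0.05 * 365.0   # yr-1 at t_ref, DON -> NH4 (0.05 d-1)
    k_nit: float = 0.10 * 365.0   # yr-1 at t_ref, NH4 -> NO3 (0.10 d-1)
    vf_a: float = 35.0            # m yr-1 uptake velocity at 1 mgN L-1
    vf_b: float = -0.5            # dimensionless, <= 0 (efficiency loss)
    q10: float = 2.0              # rate ratio per +10 degC
    t_ref: float = 20.0           # degC
    conc_floor: float = 1e-6      # mgN L-1 floor for the power law

    def validate(self) -> None:
        if self.k_min < 0 or self.k_nit < 0 or self.vf_a < 0:
            raise ParamError("k_min, k_nit, vf_a must be >= 0")
        if self.vf_b > 0:
            raise ParamError("vf_b must be <= 0")
        if self.q10 <= 1:
            raise ParamError("q10 must be > 1")


@dataclass
class HydroParams:
    """Prescribed desk-scale hydrology (full physical hydrology is out of scope)."""

    runoff_fraction: float = 0.3   # fraction of precipitation becoming runoff
    tau_reach: float = 10.0 / 365.0  # yr, reach residence time
    tau_lake: float = 0.5          # yr, lake residence time
    reach_depth: float = 1.0       # m
    lake_depth: float = 5.0        # m
    min_volume: float = 1.0e3      # m3 floor to keep concentrations finite


@dataclass
class ModelParams:
    """Bundle of all process parameters."""

    terrestrial: TerrestrialParams = field(default_factory=TerrestrialParams)
    manure: ManureParams = field(default_factory=ManureParams)
    freshwater: RateParams = field(default_factory=RateParams)
    hydro: HydroParams = field(default_factory=HydroParams)

    def validate(self) -> None:
        self.manure.validate()
        self.freshwater.validate()

    def with_overrides(self, overrides: dict) -> "ModelParams":
        """Return a copy with dotted-key overrides, e.g. {'freshwater.q10': 2.2}."""
        p = dataclasses.replace(
            self,
            terrestrial=dataclasses.replace(self.terrestrial),
            manure=dataclasses.replace(self.manure),
            freshwater=dataclasses.replace(self.freshwater),
            hydro=dataclasses.replace(self.hydro),
        )
        for key, value in overrides.items():
            group, _, name = key.partition(".")
            if not name:
                raise ParamError(f"override key must be 'group.name': {key!r}")
            try:
                target = getattr(p, group)
            except AttributeError:
                raise ParamError(f"unknown parameter group {group!r}") from None
            if not hasattr(target, name):
                raise ParamError(f"unknown parameter {key!r}")
            setattr(target, name, float(value))
        p.validate()
        return p
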