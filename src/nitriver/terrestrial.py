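"""Vegetation and soil nitrogen cycling per land-use tile.

Each land cell carries four land-use tiles (primary, secondary, cropland,
pasture) and each tile eleven N pools: five vegetation pools (leaves, fine
roots, sapwood, heartwood, labile storage), four organic soil pools (fast
and slow litter, slow and passive soil), and two inorganic pools (ammonium,
nitrate). The stepper is a donor-controlled first-order pool network with
analytically integrated (exponential) updates and operator splitting in a
fixed order:

    inputs -> uptake -> allocation/litterfall -> decomposition ->
    nitrification -> denitrification -> leaching -> harvest/grazing/fire

Exponential updates guarantee non-negativity for any admissible step, and
every transfer is recorded, so the per-tile mass budget closes to machine
precision.

Input rules: fertilizer enters cropland mineral pools only; atmospheric
deposition enters all tiles at an equal per-area rate; manure from managed
lands goes to cropland and pasture, manure from grasslands to pasture only;
biological N fixation is simulated and down-regulated by mineral N, with a
cultivation-induced component on cropland.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields as dc_fields

import numpy as np

from .domain import CROPLAND, N_TILES, PASTURE, PRIMARY, SECONDARY
from .params import ManureParams, TerrestrialParams

logger = logging.getLogger(__name__)

# pool indices
LEAVES, FINE_ROOTS, SAPWOOD, HEARTWOOD, LABILE = 0, 1, 2, 3, 4
FAST_LITTER, SLOW_LITTER, SLOW_SOIL, PASSIVE_SOIL = 5, 6, 7, 8
AMMONIUM, NITRATE = 9, 10
N_POOLS = 11
POOL_NAMES = ("leaves", "fine_roots", "sapwood", "heartwood", "labile",
              "fast_litter", "slow_litter", "slow_soil", "passive_soil",
              "ammonium", "nitrate")

VEGETATION_POOLS = (LEAVES, FINE_ROOTS, SAPWOOD, HEARTWOOD, LABILE)
ORGANIC_POOLS = (FAST_LITTER, SLOW_LITTER, SLOW_SOIL, PASSIVE_SOIL)
MINERAL_POOLS = (AMMONIUM, NITRATE)


class TerrestrialError(ValueError):
    """Raised for inadmissible forcing or stepping conditions."""


@dataclass
class TerrestrialState:
    """Pools in kgN per m2 of tile, shape (n_cells, 4, 11)."""

    pools: np.ndarray

    @classmethod
    def zeros(cls, n_cells: int) -> "TerrestrialState":
        return cls(np.zeros((n_cells, N_TILES, N_POOLS)))

    def copy(self) -> "TerrestrialState":
        return TerrestrialState(self.pools.copy())

    def validate(self) -> None:
        if self.pools.ndim != 3 or self.pools.shape[1:] != (N_TILES, N_POOLS):
            raise TerrestrialError("pools must have shape (n_cells, 4, 11)")
        if np.any(self.pools < 0):
            raise TerrestrialError("all pools must be >= 0")

    def compartment_totals(self, tile_area: np.ndarray) -> dict[str, float]:
        """Total kgN per compartment; tile_area is (n_cells, 4) in m2."""
        w = tile_area[:, :, None]
        return {
            "vegetation": float((self.pools[:, :, list(VEGETATION_POOLS)] *
                                 w).sum()),
            "organic_soil": float((self.pools[:, :, list(ORGANIC_POOLS)] *
                                   w).sum()),
            "inorganic_soil": float((self.pools[:, :, list(MINERAL_POOLS)] *
                                     w).sum()),
        }


@dataclass
class TerrestrialFluxes:
    """Per-step fluxes in kgN per m2 of tile, each (n_cells, 4).

    ``runoff_*`` are the lateral exports handed to the freshwater system;
    ``harvest`` = crop harvest + grazing + wood harvest (gross).
    """

    fertilizer: np.ndarray
    deposition: np.ndarray
    bnf: np.ndarray
    manure_applied: np.ndarray
    uptake: np.ndarray
    litterfall: np.ndarray
    mineralization: np.ndarray
    nitrification: np.ndarray
    soil_denitrification: np.ndarray
    fire_emission: np.ndarray
    crop_harvest: np.ndarray
    grazing: np.ndarray
    wood_harvest: np.ndarray
    runoff_no3: np.ndarray
    runoff_nh4: np.ndarray
    runoff_don: np.ndarray

    @classmethod
    def zeros(cls, n_cells: int) -> "TerrestrialFluxes":
        names = [f.name for f in dc_fields(cls)]
        return cls(**{k: np.zeros((n_cells, N_TILES)) for k in names})

    @property
    def harvest(self) -> np.ndarray:
        return self.crop_harvest + self.grazing + self.wood_harvest

    def inputs_total(self) -> np.ndarray:
        return (self.fertilizer + self.deposition + self.bnf
                + self.manure_applied)

    def outputs_total(self) -> np.ndarray:
        return (self.soil_denitrification + self.fire_emission + self.harvest
                + self.runoff_no3 + self.runoff_nh4 + self.runoff_don)


def q10_factor(temp: np.ndarray | float, q10: float, t_ref: float):
    """Q10 temperature adjustment: 1 at t_ref, x q10 per +10 degC."""
    return q10 ** ((np.asarray(temp, dtype=float) - t_ref) / 10.0)


def co2_multiplier(co2: float, params: TerrestrialParams,
                   enabled: bool = True) -> float:
    """Logarithmic CO2-fertilization multiplier on potential N uptake.

    1 at the reference concentration, 1 + beta*ln(C/C_ref) otherwise
    (floored at zero); identically 1 when fertilization is disabled.
    """
    if co2 <= 0:
        raise TerrestrialError("CO2 must be > 0")
    if not enabled:
        return 1.0
    return max(0.0, 1.0 + params.co2_beta * np.log(co2 / params.co2_ref))


def bnf(state: TerrestrialState, params: TerrestrialParams) -> np.ndarray:
    """Biological N fixation rate, kgN m-2 yr-1, per (cell, tile).

    Natural fixation is down-regulated by the mineral N pool (fixation is
    energetically expensive where mineral N is plentiful): it decays from
    ``bnf_max`` at zero mineral N toward the ``bnf_floor`` asymptote.
    Cropland tiles get an additional cultivation-induced term (legume
    crops).
    """
    mineral = state.pools[:, :, AMMONIUM] + state.pools[:, :, NITRATE]
    natural = params.bnf_floor + (params.bnf_max - params.bnf_floor) / (
        1.0 + mineral / params.bnf_half_sat)
    out = natural.copy()
    out[:, CROPLAND] += params.bnf_cultivated
    return out


def recycle_manure(grazing_flux: np.ndarray, crop_harvest_flux: np.ndarray,
                   params: ManureParams) -> tuple[np.ndarray, np.ndarray]:
    """Reconstruct manure application streams from simulated production.

    Used for the historical era before gridded manure data exist: a
    fraction of grazed N returns as the grassland stream (pasture only) and
    a fraction of crop harvest N returns as the managed-land stream
    (cropland + pasture). Total manure never exceeds grazing + harvest.
    Inputs and outputs are kgN per m2 of cell per yr.
    """
    params.validate()
    g = np.asarray(grazing_flux, dtype=float)
    h = np.asarray(crop_harvest_flux, dtype=float)
    if np.any(g < 0) or np.any(h < 0):
        raise TerrestrialError("grazing and harvest fluxes must be >= 0")
    return params.f_crop * h, params.f_grazing * g  # (managed, grassland)


def net_harvest(harvest: np.ndarray, recycled: np.ndarray,
                clip: bool = True) -> np.ndarray:
    """Net harvest = gross harvest minus internally recycled manure.

    Reported values are clipped at zero (with a warning) if recycling
    exceeds gross harvest in a step; budget arithmetic elsewhere always
    uses the unclipped difference.
    """
    out = np.asarray(harvest, dtype=float) - np.asarray(recycled, dtype=float)
    if clip and np.any(out < 0):
        logger.warning("recycled manure exceeds gross harvest in %d entries; "
                       "clipping net harvest at 0 for reporting",
                       int(np.sum(out < 0)))
        out = np.maximum(out, 0.0)
    return out


def apply_tile_transition(state: TerrestrialState, old_frac: np.ndarray,
                          new_frac: np.ndarray) -> TerrestrialState:
    """Rebalance per-tile pool densities after land-use transitions.

    Shrinking tiles keep their density and cede the N on the lost area to
    a per-cell pool that is mixed into the expanding tiles, so cell-total
    N in every pool is conserved exactly (deforestation for agriculture,
    abandonment to secondary land, etc.).
    """
    delta = new_frac - old_frac  # (n_cells, 4)
    if not np.any(delta):
        return state
    dens = state.pools
    loss = np.maximum(-delta, 0.0)
    gain = np.maximum(delta, 0.0)
    pot = (loss[:, :, None] * dens).sum(axis=1)          # (n_cells, N_POOLS)
    total_gain = gain.sum(axis=1)                         # (n_cells,)
    share = np.divide(gain, total_gain[:, None],
                      out=np.zeros_like(gain), where=total_gain[:, None] > 0)
    mass = dens * old_frac[:, :, None] + share[:, :, None] * pot[:, None, :]
    new_dens = np.divide(mass, new_frac[:, :, None],
                         out=dens.copy(), where=new_frac[:, :, None] > 0)
    # keep donor-tile densities where area only shrank (mass already ceded)
    keep = (gain == 0.0)[:, :, None]
    out = np.where(keep, dens, new_dens)
    # tiles that vanished entirely carry no area; zero their densities
    out = np.where((new_frac == 0.0)[:, :, None], 0.0, out)
    return TerrestrialState(out)


@dataclass
class TerrestrialForcing:
    """One step's forcing slice (per-cell arrays, rates per year)."""

    fertilizer: np.ndarray      # kgN m-2(cell) yr-1
    deposition: np.ndarray
    manure_managed: np.ndarray
    manure_grass: np.ndarray
    precip: np.ndarray          # kg m-2 yr-1
    temp: np.ndarray            # degC
    runoff_fraction: np.ndarray
    co2: float                  # ppm
    tiles: np.ndarray           # (n_cells, 4) fractions


def _decay_frac(rate, dt: float):
    """Fraction of a pool removed by a first-order process over dt."""
    return -np.expm1(-np.asarray(rate) * dt)


def step_terrestrial(
    state: TerrestrialState,
    forcing: TerrestrialForcing,
    params: TerrestrialParams,
    dt: float,
    co2_fertilization_on: bool = True,
) -> tuple[TerrestrialState, TerrestrialFluxes]:
    """Advance all tiles by one step of length ``dt`` years.

    Returns the new state and the per-tile flux record; fluxes are in kgN
    per m2 of tile per step. Raises on negative forcing or on a step too
    coarse for the fastest configured rate.
    """
    if dt <= 0:
        raise TerrestrialError("dt must be > 0")
    for name in ("fertilizer", "deposition", "manure_managed", "manure_grass",
                 "precip"):
        if np.any(getattr(forcing, name) < 0):
            raise TerrestrialError(f"negative forcing: {name}")
    arr = q10_factor(forcing.temp, params.q10, params.t_ref)[:, None]
    fastest = {
        "uptake_avail_rate": params.uptake_avail_rate,
        "k_nitrification": float(np.max(params.k_nitrification * arr)),
        "k_fast_litter": params.k_fast_litter,
        "alloc_rate": params.alloc_rate,
    }
    worst = max(fastest, key=fastest.get)
    if fastest[worst] * dt > params.max_rate_dt:
        raise TerrestrialError(
            f"dt={dt} yr too large for rate {worst} = {fastest[worst]:.3g} "
            f"yr-1 (rate*dt exceeds {params.max_rate_dt})")

    x = state.pools.copy()
    fl = TerrestrialFluxes.zeros(x.shape[0])
    tiles = forcing.tiles

    # ---- inputs (per-cell rates converted to per-tile-area rates) ----
    crop_frac = tiles[:, CROPLAND]
    agro_frac = tiles[:, CROPLAND] + tiles[:, PASTURE]
    past_frac = tiles[:, PASTURE]

    def _tile_rate(cell_rate, frac, what):
        rate = np.divide(cell_rate, frac, out=np.zeros_like(frac),
                         where=frac > 0)
        lost = (cell_rate > 0) & (frac <= 0)
        if np.any(lost):
            logger.warning("%s applied to %d cells with zero receiving tile "
                           "area; input not registered", what,
                           int(np.sum(lost)))
        return rate

    fert = _tile_rate(forcing.fertilizer, crop_frac, "fertilizer") * dt
    fl.fertilizer[:, CROPLAND] = fert
    x[:, CROPLAND, NITRATE] += fert * params.fert_no3_fraction
    x[:, CROPLAND, AMMONIUM] += fert * (1 - params.fert_no3_fraction)

    dep = forcing.deposition[:, None] * dt  # equal per-area rate, all tiles
    fl.deposition += dep
    x[:, :, NITRATE] += dep * params.dep_no3_fraction
    x[:, :, AMMONIUM] += dep * (1 - params.dep_no3_fraction)

    man_managed = _tile_rate(forcing.manure_managed, agro_frac,
                             "managed-land manure") * dt
    man_grass = _tile_rate(forcing.manure_grass, past_frac,
                           "grassland manure") * dt
    man = np.zeros_like(fl.manure_applied)
    man[:, CROPLAND] = man_managed
    man[:, PASTURE] = man_managed + man_grass
    fl.manure_applied += man
    x[:, :, AMMONIUM] += man * params.manure_nh4_fraction
    x[:, :, FAST_LITTER] += man * (1 - params.manure_nh4_fraction)

    fix = bnf(TerrestrialState(x), params) * dt
    fl.bnf += fix
    x[:, :, LABILE] += fix

    # ---- plant uptake: co-limited by demand (x CO2 multiplier) and by
    # available mineral N; the harmonic-mean form D*A/(D+A) is smooth and
    # monotone in both, so elevated CO2 always raises uptake and extra
    # mineral N is never exported one-for-one ----
    mult = co2_multiplier(float(forcing.co2), params, co2_fertilization_on)
    demand = params.uptake_potential * mult * dt
    avail_frac = _decay_frac(params.uptake_avail_rate, dt)
    mineral = x[:, :, AMMONIUM] + x[:, :, NITRATE]
    avail = avail_frac * mineral
    uptake = np.divide(demand * avail, demand + avail,
                       out=np.zeros_like(avail), where=(demand + avail) > 0)
    share_nh4 = np.divide(x[:, :, AMMONIUM], mineral,
                          out=np.zeros_like(mineral), where=mineral > 0)
    x[:, :, AMMONIUM] -= uptake * share_nh4
    x[:, :, NITRATE] -= uptake * (1 - share_nh4)
    x[:, :, LABILE] += uptake
    fl.uptake += uptake

    # ---- allocation and litterfall ----
    alloc = x[:, :, LABILE] * _decay_frac(params.alloc_rate, dt)
    x[:, :, LABILE] -= alloc
    x[:, :, LEAVES] += alloc * params.alloc_leaves
    x[:, :, FINE_ROOTS] += alloc * params.alloc_fine_roots
    x[:, :, SAPWOOD] += alloc * params.alloc_sapwood
    x[:, :, HEARTWOOD] += alloc * params.alloc_heartwood

    leaf_fall = _decay_frac(params.k_leaf_turnover, dt)
    for p in (LEAVES, FINE_ROOTS):
        moved = x[:, :, p] * leaf_fall
        x[:, :, p] -= moved
        x[:, :, FAST_LITTER] += moved
        fl.litterfall += moved
    wood_fall = _decay_frac(params.k_wood_turnover, dt)
    for p in (SAPWOOD, HEARTWOOD):
        moved = x[:, :, p] * wood_fall
        x[:, :, p] -= moved
        x[:, :, SLOW_LITTER] += moved
        fl.litterfall += moved

    # ---- decomposition cascade with partial mineralization ----
    fmin = params.mineralization_fraction
    cascade = ((FAST_LITTER, SLOW_LITTER, params.k_fast_litter, fmin),
               (SLOW_LITTER, SLOW_SOIL, params.k_slow_litter, fmin),
               (SLOW_SOIL, PASSIVE_SOIL, params.k_slow_soil, fmin),
               (PASSIVE_SOIL, None, params.k_passive_soil, 1.0))
    for src, dst, k, f in cascade:
        moved = x[:, :, src] * _decay_frac(k, dt)
        x[:, :, src] -= moved
        x[:, :, AMMONIUM] += moved * f
        fl.mineralization += moved * f
        if dst is not None:
            x[:, :, dst] += moved * (1 - f)

    # ---- nitrification and soil denitrification (Q10-adjusted) ----
    nitr = x[:, :, AMMONIUM] * _decay_frac(params.k_nitrification * arr, dt)
    x[:, :, AMMONIUM] -= nitr
    x[:, :, NITRATE] += nitr
    fl.nitrification += nitr

    denit = x[:, :, NITRATE] * _decay_frac(
        params.k_soil_denitrification * arr, dt)
    x[:, :, NITRATE] -= denit
    fl.soil_denitrification += denit

    # ---- leaching to the freshwater system ----
    wet = (forcing.runoff_fraction * forcing.precip / params.precip_ref)[:, None]
    for p, coeff, name in ((NITRATE, params.leach_no3, "runoff_no3"),
                           (AMMONIUM, params.leach_nh4, "runoff_nh4")):
        moved = x[:, :, p] * _decay_frac(coeff * wet, dt)
        x[:, :, p] -= moved
        getattr(fl, name)[:] += moved
    for p in (FAST_LITTER, SLOW_SOIL):
        moved = x[:, :, p] * _decay_frac(params.leach_don * wet, dt)
        x[:, :, p] -= moved
        fl.runoff_don += moved

    # ---- harvest, grazing, wood harvest, fire ----
    ch = _decay_frac(params.k_crop_harvest, dt)
    for p in (LEAVES, LABILE):
        moved = x[:, CROPLAND, p] * ch
        x[:, CROPLAND, p] -= moved
        fl.crop_harvest[:, CROPLAND] += moved
    moved = x[:, PASTURE, LEAVES] * _decay_frac(params.k_grazing, dt)
    x[:, PASTURE, LEAVES] -= moved
    fl.grazing[:, PASTURE] += moved
    wh = _decay_frac(params.k_wood_harvest, dt)
    for p in (SAPWOOD, HEARTWOOD):
        moved = x[:, SECONDARY, p] * wh
        x[:, SECONDARY, p] -= moved
        fl.wood_harvest[:, SECONDARY] += moved
    burn = _decay_frac(params.k_fire, dt)
    for tile in (PRIMARY, SECONDARY, PASTURE):
        for p in VEGETATION_POOLS + (FAST_LITTER, SLOW_LITTER):
            moved = x[:, tile, p] * burn
            x[:, tile, p] -= moved
            fl.fire_emission[:, tile] += moved

    new = TerrestrialState(x)
    return new, fl


def cell_runoff(fl: TerrestrialFluxes, tiles: np.ndarray,
                cell_area: np.ndarray) -> np.ndarray:
    """Lateral N export per cell and species, kgN per step, shape (n, 3).

    Species order: (DON, NH4, NO3) — matching the freshwater state layout.
    """
    w = tiles * cell_area[:, None]
    return np.stack([(fl.runoff_don * w).sum(axis=1),
                     (fl.runoff_nh4 * w).sum(axis=1),
                     (fl.runoff_no3 * w).sum(axis=1)], axis=1)
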