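"""In-stream and in-lake nitrogen transformation and routing.

Each land cell hosts a river reach and, where ``lake_fraction`` > 0, a
lake. Both carry three dissolved N pools (DON, ammonium, nitrate; kgN).
Within a water body, first-order kinetics transform DON -> NH4
(mineralization), NH4 -> NO3 (nitrification) and NO3 -> gas
(denitrification), all temperature-adjusted by a Q10 factor that doubles
rates per +10 degC at the default Q10 = 2.

Denitrification is concentration-dependent: an uptake velocity
v_f = a * C**b (m yr-1, C in mgN L-1, b <= 0) divided by water depth gives
the volumetric first-order rate, so removal *efficiency* falls as nitrate
concentration rises while areal removal still increases for b > -1 — the
mechanism by which heavily loaded rivers export a disproportionate share
of their inputs.

Lateral inputs are split between lake and reach by the lake area fraction;
the lake drains into its own cell's reach, and reaches advect downstream
along the flow network to coastal outlets. Advection over a step moves the
exponential fraction 1 - exp(-dt/tau) of each pool (tau = residence time),
which preserves positivity at any step size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .domain import FlowNetwork, GridDomain, OUTLET
from .params import HydroParams, RateParams
from .units import KG_M3_TO_MG_L, WATER_DENSITY

# species indices (shared with terrestrial cell_runoff)
DON, NH4, NO3 = 0, 1, 2
SPECIES = ("DON", "NH4", "NO3")


class FreshwaterError(ValueError):
    """Raised for invalid freshwater states or forcing."""


@dataclass
class FreshwaterState:
    """River and lake N pools, kgN, each (n_cells, 3)."""

    river: np.ndarray
    lake: np.ndarray

    @classmethod
    def zeros(cls, n_cells: int) -> "FreshwaterState":
        return cls(np.zeros((n_cells, 3)), np.zeros((n_cells, 3)))

    def copy(self) -> "FreshwaterState":
        return FreshwaterState(self.river.copy(), self.lake.copy())

    def total(self) -> float:
        return float(self.river.sum() + self.lake.sum())


@dataclass
class Hydrology:
    """Per-cell water volumes and turnover, derived from runoff forcing.

    ``discharge`` accumulates local runoff down the network; volumes are
    discharge x residence time (floored), depths are prescribed.
    """

    discharge: np.ndarray      # m3 yr-1 leaving each cell's reach
    reach_volume: np.ndarray   # m3
    lake_volume: np.ndarray    # m3 (zero where no lake)
    reach_depth: float
    lake_depth: float
    tau_reach: float
    tau_lake: float


def build_hydrology(domain: GridDomain, net: FlowNetwork,
                    precip: np.ndarray, runoff_fraction: np.ndarray,
                    hp: HydroParams,
                    levels: list[np.ndarray] | None = None) -> Hydrology:
    """Accumulate local runoff downstream and derive water volumes."""
    local = precip * runoff_fraction * domain.cell_area / WATER_DENSITY
    local = np.where(domain.land_mask, local, 0.0)
    q = local.copy()
    if levels is None:
        levels = net.topo_levels(domain)
    for level in levels:
        ds = net.downstream[level]
        inland = ds >= 0
        np.add.at(q, ds[inland], q[level][inland])
    reach_vol = np.maximum(q * hp.tau_reach, hp.min_volume)
    lake_vol = np.where(domain.lake_fraction > 0,
                        np.maximum(q * hp.tau_lake, hp.min_volume), 0.0)
    return Hydrology(discharge=q, reach_volume=reach_vol, lake_volume=lake_vol,
                     reach_depth=hp.reach_depth, lake_depth=hp.lake_depth,
                     tau_reach=hp.tau_reach, tau_lake=hp.tau_lake)


def temperature_factor(temp, params: RateParams):
    """Q10 temperature adjustment of freshwater rate coefficients.

    Equals 1 at the reference temperature and multiplies by exactly
    ``params.q10`` for every +10 degC (doubling at the default Q10 = 2).
    """
    return params.q10 ** ((np.asarray(temp, dtype=float) - params.t_ref) / 10.0)


def denitrification_coefficient(no3_concentration, depth, temp,
                                params: RateParams):
    """First-order volumetric denitrification rate, yr-1.

    k = (a * C**b / depth) * Q10-factor, with the concentration floored at
    ``params.conc_floor`` so the power law stays finite at C -> 0.
    """
    depth = np.asarray(depth, dtype=float)
    if np.any(depth <= 0):
        raise FreshwaterError("depth must be > 0")
    c = np.maximum(np.asarray(no3_concentration, dtype=float),
                   params.conc_floor)
    vf = params.vf_a * c ** params.vf_b
    return vf / depth * temperature_factor(temp, params)


def partition_reach_lake(cell_inputs: np.ndarray, lake_fraction
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Split lateral inputs between reach and lake by lake area fraction."""
    lf = np.asarray(lake_fraction, dtype=float)
    if np.any((lf < 0) | (lf > 1)):
        raise FreshwaterError("lake_fraction must lie in [0, 1]")
    lake_share = cell_inputs * lf[..., None]
    return cell_inputs - lake_share, lake_share


def _transform(pools: np.ndarray, volume: np.ndarray, depth: float,
               temp: np.ndarray, params: RateParams, dt: float
               ) -> tuple[np.ndarray, np.ndarray]:
    """Apply within-body kinetics; returns (new pools, denitrified mass)."""
    tf = temperature_factor(temp, params)
    out = pools.copy()
    m = out[:, DON] * -np.expm1(-params.k_min * tf * dt)
    out[:, DON] -= m
    out[:, NH4] += m
    n = out[:, NH4] * -np.expm1(-params.k_nit * tf * dt)
    out[:, NH4] -= n
    out[:, NO3] += n
    conc = KG_M3_TO_MG_L * np.divide(out[:, NO3], volume,
                                     out=np.zeros_like(volume),
                                     where=volume > 0)
    kd = denitrification_coefficient(conc, depth, temp, params)
    d = out[:, NO3] * -np.expm1(-kd * dt)
    out[:, NO3] -= d
    return out, d


def step_freshwater(
    state: FreshwaterState,
    lateral: np.ndarray,          # kgN per step, (n_cells, 3), species order
    temp: np.ndarray,             # degC per cell
    domain: GridDomain,
    net: FlowNetwork,
    hydro: Hydrology,
    params: RateParams,
    dt: float,
    levels: list[np.ndarray] | None = None,
) -> tuple[FreshwaterState, np.ndarray, np.ndarray]:
    """Advance the freshwater system one step of ``dt`` years.

    Returns (new state, outlet loads (n_cells, 3) kgN delivered to the
    coastal ocean this step, denitrified mass per cell). Processing order:
    lakes everywhere, then reaches by topological level so that upstream
    outflow generated this step feeds the downstream reach within the step.
    """
    if dt <= 0:
        raise FreshwaterError("dt must be > 0")
    for name, a in (("state.river", state.river), ("state.lake", state.lake),
                    ("lateral", lateral), ("temp", temp)):
        if np.any(~np.isfinite(a)):
            bad = np.unique(np.argwhere(~np.isfinite(a))[:, 0]).tolist()
            raise FreshwaterError(f"NaN/inf in {name} at cells {bad}")
    if np.any(lateral[domain.land_mask] < 0):
        raise FreshwaterError("lateral inputs must be >= 0")

    reach_in, lake_in = partition_reach_lake(lateral, domain.lake_fraction)

    # lakes: inputs, kinetics, drain into own cell's reach
    lake = state.lake + lake_in
    lake, lake_denit = _transform(lake, hydro.lake_volume, hydro.lake_depth,
                                  temp, params, dt)
    a_lake = -np.expm1(-dt / hydro.tau_lake)
    lake_out = lake * a_lake
    lake = lake - lake_out

    river = state.river + reach_in + lake_out
    denit = lake_denit.copy()
    outlet_loads = np.zeros_like(river)
    a_reach = -np.expm1(-dt / hydro.tau_reach)

    if levels is None:
        levels = net.topo_levels(domain)
    for level in levels:
        sub, d = _transform(river[level], hydro.reach_volume[level],
                            hydro.reach_depth, temp[level], params, dt)
        denit[level] += d
        moved = sub * a_reach
        sub = sub - moved
        river[level] = sub
        ds = net.downstream[level]
        at_outlet = ds == OUTLET
        outlet_loads[level[at_outlet]] = moved[at_outlet]
        inland = ds >= 0
        np.add.at(river, ds[inland], moved[inland])

    return FreshwaterState(river, lake), outlet_loads, denit
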