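"""Synthetic scenario forcing generator and climate/CO2 perturbations.

The generator emulates the qualitative cross-scenario structure of the
SSP marker scenarios as they matter for nitrogen delivery to rivers:

* global fertilizer use is highest under middle-of-the-road development
  (SSP2-4.5), intermediate under sustainability (SSP1-2.6), and lowest
  under fossil-fueled development (SSP5-8.5), whose rapid agricultural
  productivity gains and absent biofuel demand curb fertilizer needs;
* atmospheric N deposition, warming, and precipitation increase with the
  emission level (SSP5-8.5 > SSP2-4.5 > SSP1-2.6);
* manure applications exist from 2002 onward for SSP2-4.5, SSP4-3.4 and
  SSP5-8.5 only; the SSP5-8.5 trajectory peaks in the 2040s and declines
  after the 2060s as grassland availability limits livestock expansion.
  Requesting manure under SSP1-2.6 is an error — those projections are
  not available — and a custom trajectory must be supplied instead.

Global trajectories are piecewise-linear anchor curves (TgN yr-1, ppm,
degC) distributed over cells by static or land-use-proportional spatial
patterns, plus optional AR(1) interannual noise on climate. Everything is
deterministic for a fixed (spec, domain, seed).

Three perturbation operators support the climate/CO2 uncertainty
experiments: a multiplicative precipitation ramp and an additive
temperature ramp, each solved per cell so that the realized change between
a base and an evaluation period equals the target exactly, and a CO2
freeze that holds concentration at its value in a chosen year.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import xarray as xr

from .domain import CROPLAND, GridDomain, N_TILES, PASTURE

SCENARIO_NAMES = ("SSP1-2.6", "SSP2-4.5", "SSP5-8.5")
PERTURBATIONS = ("none", "precip_high", "temp_high", "co2_frozen")

#: first year with manure application data; earlier years are reconstructed
#: by recycling simulated grazing and crop production (see terrestrial module)
MANURE_DATA_START = 2002
#: scenarios for which manure application projections exist
MANURE_SCENARIOS = ("SSP2-4.5", "SSP4-3.4", "SSP5-8.5")

# Perturbation contract (uncertainty experiments): base/eval periods and
# the year the ramp starts.
PRECIP_TARGET = 0.076          # +7.6 % global precipitation
TEMP_TARGET = 5.3              # +5.3 degC global air temperature
PERTURB_BASE = (1986, 2005)
PERTURB_EVAL = (2080, 2099)
CLIMATE_PERTURB_START = 2020
CO2_FREEZE_YEAR = 2014


class ScenarioError(ValueError):
    """Raised for unsupported scenario requests or invalid forcing."""


# ---------------------------------------------------------------------------
# global trajectory anchors (year, value); historical part shared by scenarios
# ---------------------------------------------------------------------------

_HIST = {
    "fertilizer": [(1861, 0.5), (1900, 2), (1950, 10), (1980, 60),
                   (2000, 88), (2014, 105)],
    "deposition": [(1861, 8), (1950, 25), (1980, 45), (2000, 58), (2014, 62)],
    "warming": [(1861, 0.0), (1950, 0.3), (2000, 0.8), (2014, 1.0)],
    "co2": [(1861, 286), (1900, 296), (1950, 311), (1980, 339),
            (2000, 370), (2014, 397)],
    "crop_index": [(1861, 0.25), (1950, 0.55), (2000, 0.95), (2014, 1.0)],
    "pasture_index": [(1861, 0.30), (1950, 0.70), (2014, 1.0)],
    "disturbance_index": [(1861, 0.10), (1950, 0.40), (2014, 1.0)],
}

_FUTURE = {
    "fertilizer": {
        "SSP1-2.6": [(2050, 132), (2080, 150), (2099, 158)],
        "SSP2-4.5": [(2050, 165), (2080, 200), (2099, 208)],
        "SSP5-8.5": [(2050, 112), (2080, 109), (2099, 107)],
        "SSP4-3.4": [(2050, 120), (2099, 118)],
    },
    "deposition": {
        "SSP1-2.6": [(2050, 48), (2099, 35)],
        "SSP2-4.5": [(2050, 58), (2099, 52)],
        "SSP5-8.5": [(2050, 68), (2099, 72)],
        "SSP4-3.4": [(2050, 55), (2099, 48)],
    },
    "warming": {
        "SSP1-2.6": [(2050, 1.5), (2099, 1.7)],
        "SSP2-4.5": [(2050, 2.0), (2099, 2.9)],
        "SSP5-8.5": [(2050, 2.6), (2099, 4.8)],
        "SSP4-3.4": [(2050, 1.8), (2099, 2.2)],
    },
    "co2": {
        "SSP1-2.6": [(2050, 440), (2099, 446)],
        "SSP2-4.5": [(2050, 510), (2099, 600)],
        "SSP5-8.5": [(2050, 640), (2099, 1100)],
        "SSP4-3.4": [(2050, 480), (2099, 510)],
    },
    "crop_index": {
        "SSP1-2.6": [(2099, 1.08)],
        "SSP2-4.5": [(2099, 1.12)],
        "SSP5-8.5": [(2099, 0.97)],
        "SSP4-3.4": [(2099, 1.0)],
    },
    "pasture_index": {
        "SSP1-2.6": [(2099, 0.95)],
        "SSP2-4.5": [(2099, 1.05)],
        "SSP5-8.5": [(2099, 1.10)],
        "SSP4-3.4": [(2099, 0.9)],
    },
    "disturbance_index": {
        "SSP1-2.6": [(2099, 1.2)],
        "SSP2-4.5": [(2099, 1.2)],
        "SSP5-8.5": [(2099, 1.2)],
        "SSP4-3.4": [(2099, 1.2)],
    },
}

#: manure applications, TgN yr-1, defined from MANURE_DATA_START onward
_MANURE = {
    "SSP2-4.5": [(2002, 100), (2030, 110), (2050, 118), (2099, 125)],
    "SSP5-8.5": [(2002, 100), (2030, 128), (2040, 136), (2045, 138),
                 (2050, 136), (2060, 128), (2080, 112), (2099, 104)],
    "SSP4-3.4": [(2002, 100), (2050, 104), (2099, 98)],
}

#: fraction of applied manure from managed lands (rest is from grasslands)
MANURE_MANAGED_FRACTION = 0.6
#: precipitation sensitivity to warming, fractional change per degC
PRECIP_PER_DEGC = 0.02


@dataclass
class ScenarioSpec:
    """One simulation experiment: scenario, toggles, perturbation, seed."""

    name: str = "SSP2-4.5"
    start_year: int = 1861
    end_year: int = 2099
    manure_on: bool = False
    co2_fertilization_on: bool = True
    perturbation: str = "none"
    seed: int = 0
    noise_amplitude: float = 0.02  # relative AR(1) climate noise
    trend_scale: float = 1.0       # 0 freezes every trajectory at start_year
    anchors_override: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.name not in SCENARIO_NAMES + ("SSP4-3.4", "custom"):
            raise ScenarioError(f"unknown scenario {self.name!r}")
        if self.perturbation not in PERTURBATIONS:
            raise ScenarioError(f"unknown perturbation {self.perturbation!r}")
        if self.start_year >= self.end_year:
            raise ScenarioError("start_year must be < end_year")
        if self.manure_on and self.name == "SSP1-2.6":
            raise ScenarioError(
                "manure applications requested under SSP1-2.6, but these "
                "projections are not available for SSP1-2.6; supply a custom "
                "manure trajectory via anchors_override['manure'] instead")

    def label(self) -> str:
        bits = [self.name,
                "manure" if self.manure_on else "nomanure",
                "co2fert" if self.co2_fertilization_on else "noco2fert"]
        if self.perturbation != "none":
            bits.append(self.perturbation)
        return "_".join(bits)


@dataclass
class ForcingSeries:
    """Annual gridded drivers on a flat cell axis.

    Shapes: global series (ny,), per-cell fields (ny, n_cells), land-use
    tiles (ny, n_cells, 4). N application rates are kgN per m2 of *cell*
    per year; the terrestrial stepper converts them to per-tile rates.
    """

    years: np.ndarray            # int years, strictly increasing
    co2: np.ndarray              # ppm
    precip: np.ndarray           # kg m-2 yr-1
    temp: np.ndarray             # degC
    runoff_fraction: np.ndarray  # fraction of precipitation becoming runoff
    fertilizer: np.ndarray       # kgN m-2(cell) yr-1, croplands
    deposition: np.ndarray       # kgN m-2(cell) yr-1, all tiles
    manure_managed: np.ndarray   # kgN m-2(cell) yr-1, cropland + pasture
    manure_grass: np.ndarray     # kgN m-2(cell) yr-1, pasture only
    tiles: np.ndarray            # fractions (ny, n_cells, 4)

    PER_CELL = ("precip", "temp", "runoff_fraction", "fertilizer",
                "deposition", "manure_managed", "manure_grass")

    @property
    def n_years(self) -> int:
        return self.years.size

    @property
    def n_cells(self) -> int:
        return self.precip.shape[1]

    def validate(self) -> None:
        if np.any(np.diff(self.years) <= 0):
            raise ScenarioError("time axis must be strictly increasing")
        if np.any(self.co2 <= 0):
            raise ScenarioError("CO2 must be > 0")
        if np.any(self.precip < 0):
            raise ScenarioError("precipitation must be >= 0")
        for name in ("fertilizer", "deposition", "manure_managed", "manure_grass"):
            if np.any(getattr(self, name) < 0):
                raise ScenarioError(f"{name} must be >= 0")
        for name in self.PER_CELL:
            if getattr(self, name).shape != (self.n_years, self.n_cells):
                raise ScenarioError(f"{name} has inconsistent shape")
        if self.tiles.shape != (self.n_years, self.n_cells, N_TILES):
            raise ScenarioError("tiles has inconsistent shape")

    def copy(self) -> "ForcingSeries":
        kw = {f.name: getattr(self, f.name).copy()
              for f in dataclasses.fields(self)}
        return ForcingSeries(**kw)

    def year_index(self, year: int) -> int:
        idx = int(np.searchsorted(self.years, year))
        if idx >= self.years.size or self.years[idx] != year:
            raise ScenarioError(f"year {year} not on the time axis")
        return idx

    def subset_cells(self, cells: np.ndarray) -> "ForcingSeries":
        kw = {"years": self.years.copy(), "co2": self.co2.copy(),
              "tiles": self.tiles[:, cells, :].copy()}
        for name in self.PER_CELL:
            kw[name] = getattr(self, name)[:, cells].copy()
        return ForcingSeries(**kw)

    def to_dataset(self) -> xr.Dataset:
        data = {"co2": (("time",), self.co2)}
        for name in self.PER_CELL:
            data[name] = (("time", "cell"), getattr(self, name))
        data["tiles"] = (("time", "cell", "tile"), self.tiles)
        ds = xr.Dataset(data, coords={"time": self.years,
                                      "cell": np.arange(self.n_cells),
                                      "tile": np.arange(N_TILES)})
        units = {"co2": "ppm", "precip": "kg m-2 yr-1", "temp": "degC",
                 "runoff_fraction": "1", "fertilizer": "kgN m-2 yr-1",
                 "deposition": "kgN m-2 yr-1", "manure_managed": "kgN m-2 yr-1",
                 "manure_grass": "kgN m-2 yr-1", "tiles": "1"}
        for k, u in units.items():
            ds[k].attrs["units"] = u
        return ds

    @classmethod
    def from_dataset(cls, ds: xr.Dataset) -> "ForcingSeries":
        kw = {"years": ds["time"].values.astype(np.int64),
              "co2": ds["co2"].values,
              "tiles": ds["tiles"].values}
        for name in cls.PER_CELL:
            kw[name] = ds[name].values
        f = cls(**kw)
        f.validate()
        return f


def _trajectory(key: str, scenario: str, years: np.ndarray,
                trend_scale: float, override: dict) -> np.ndarray:
    anchors = override.get(key)
    if anchors is None:
        anchors = list(_HIST.get(key, []))
        anchors += _FUTURE.get(key, {}).get(scenario, [])
    if not anchors:
        raise ScenarioError(f"no trajectory anchors for {key!r} / {scenario!r}")
    ax, ay = zip(*sorted(anchors))
    v = np.interp(years.astype(float), ax, ay)
    if trend_scale != 1.0:
        v = v[0] + trend_scale * (v - v[0])
    return v


def _manure_trajectory(spec: ScenarioSpec, years: np.ndarray) -> np.ndarray:
    anchors = spec.anchors_override.get("manure")
    if anchors is None:
        if spec.name not in MANURE_SCENARIOS:
            raise ScenarioError(
                f"manure projections are not available for {spec.name}")
        anchors = _MANURE[spec.name]
    ax, ay = zip(*sorted(anchors))
    v = np.interp(years.astype(float), ax, ay)
    if spec.trend_scale != 1.0:
        first = np.searchsorted(years, MANURE_DATA_START)
        first = min(first, years.size - 1)
        v = v[first] + spec.trend_scale * (v - v[first])
    v = np.where(years < MANURE_DATA_START, 0.0, v)  # reconstructed in-model
    return v


def _ar1(rng: np.random.Generator, n: int, rho: float = 0.5) -> np.ndarray:
    xi = rng.standard_normal(n)
    e = np.empty(n)
    e[0] = xi[0]
    s = np.sqrt(1 - rho ** 2)
    for t in range(1, n):
        e[t] = rho * e[t - 1] + s * xi[t]
    return e


def _distribute(global_total_tg: np.ndarray, weights: np.ndarray,
                cell_area: np.ndarray) -> np.ndarray:
    """Spread a global TgN yr-1 series over cells -> kgN m-2(cell) yr-1.

    ``weights`` is (ny, n_cells) or (n_cells,); rows with zero weight get
    zero flux (the mass is simply not applied that year).
    """
    w = np.atleast_2d(weights).astype(float)
    if w.shape[0] == 1:
        w = np.broadcast_to(w, (global_total_tg.size, w.shape[1]))
    tot = w.sum(axis=1, keepdims=True)
    share = np.divide(w, tot, out=np.zeros_like(w), where=tot > 0)
    mass = global_total_tg[:, None] * 1.0e9 * share  # kgN yr-1 per cell
    return mass / cell_area[None, :]


def generate_scenario_forcings(spec: ScenarioSpec,
                               domain: GridDomain) -> ForcingSeries:
    """Build the full forcing series for one scenario on one domain.

    Deterministic for fixed (spec, domain, seed). The historical portion
    (before 2015) is identical across scenarios for the same seed, so
    scenario runs diverge only through their projections.
    """
    spec.validate()
    years = np.arange(spec.start_year, spec.end_year + 1, dtype=np.int64)
    ny, n = years.size, domain.n_cells
    land = domain.land_mask.astype(float)

    # spatial patterns: domain-determined RNG stream (same across scenarios)
    prng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 11]))
    n_lat, n_lon = domain.n_lat, domain.n_lon
    lat_norm = (np.repeat(np.arange(n_lat), n_lon) - (n_lat - 1) / 2.0)
    lat_norm /= max((n_lat - 1) / 2.0, 1.0)
    base_temp = (28.0 - 20.0 * np.abs(lat_norm) ** 1.3
                 + 2.0 * prng.standard_normal(n)) * land
    base_precip = np.exp(prng.normal(np.log(900.0), 0.35, n)) * land
    crop_max = 0.30 * prng.beta(2.0, 3.0, n) * land
    pasture_max = 0.35 * prng.beta(2.0, 3.0, n) * land
    dep_pattern = (0.6 + 0.8 * prng.random(n)) * land * domain.cell_area

    ov = spec.anchors_override
    fert_tg = _trajectory("fertilizer", spec.name, years, spec.trend_scale, ov)
    dep_tg = _trajectory("deposition", spec.name, years, spec.trend_scale, ov)
    warming = _trajectory("warming", spec.name, years, spec.trend_scale, ov)
    co2 = _trajectory("co2", spec.name, years, spec.trend_scale, ov)
    crop_idx = _trajectory("crop_index", spec.name, years, spec.trend_scale, ov)
    past_idx = _trajectory("pasture_index", spec.name, years, spec.trend_scale, ov)
    dist_idx = _trajectory("disturbance_index", spec.name, years,
                           spec.trend_scale, ov)

    # land-use tiles: per-cell maxima scaled by global expansion indices,
    # remainder split primary/secondary by a disturbance index; the four
    # fractions sum to a constant 0.97 of the cell (residual barren/ice)
    crop = np.clip(crop_max[None, :] * crop_idx[:, None], 0.0, 0.5)
    past = np.clip(pasture_max[None, :] * past_idx[:, None], 0.0, 0.5)
    natural = 1.0 - crop - past
    secondary = natural * np.clip(0.25 * dist_idx[:, None], 0.0, 0.9)
    primary = natural - secondary
    tiles = 0.97 * np.stack([primary, secondary, crop, past], axis=-1)
    tiles *= land[None, :, None]

    # climate fields with optional AR(1) interannual noise
    nrng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 23]))
    noise = spec.noise_amplitude * _ar1(nrng, ny) if spec.noise_amplitude else 0.0
    temp = base_temp[None, :] + warming[:, None] + np.atleast_1d(
        noise * 2.0)[..., None] * (1.0 if spec.noise_amplitude else 0.0)
    temp = temp * land[None, :]
    precip = base_precip[None, :] * (1.0 + PRECIP_PER_DEGC * warming[:, None])
    if spec.noise_amplitude:
        precip = precip * (1.0 + np.atleast_1d(noise)[..., None])
    precip = np.maximum(precip, 0.0)
    runoff_fraction = np.full((ny, n), 0.3) * land[None, :]

    crop_area_w = tiles[:, :, CROPLAND] * domain.cell_area[None, :]
    agro_area_w = (tiles[:, :, CROPLAND] + tiles[:, :, PASTURE]) * \
        domain.cell_area[None, :]
    past_area_w = tiles[:, :, PASTURE] * domain.cell_area[None, :]

    fertilizer = _distribute(fert_tg, crop_area_w, domain.cell_area)
    deposition = _distribute(dep_tg, dep_pattern, domain.cell_area)

    if spec.manure_on:
        man_tg = _manure_trajectory(spec, years)
        manure_managed = _distribute(man_tg * MANURE_MANAGED_FRACTION,
                                     agro_area_w, domain.cell_area)
        manure_grass = _distribute(man_tg * (1 - MANURE_MANAGED_FRACTION),
                                   past_area_w, domain.cell_area)
    else:
        manure_managed = np.zeros((ny, n))
        manure_grass = np.zeros((ny, n))

    f = ForcingSeries(years=years, co2=co2, precip=precip, temp=temp,
                      runoff_fraction=runoff_fraction, fertilizer=fertilizer,
                      deposition=deposition, manure_managed=manure_managed,
                      manure_grass=manure_grass, tiles=tiles)
    f.validate()
    return f


# ---------------------------------------------------------------------------
# perturbation operators
# ---------------------------------------------------------------------------

def _period_slice(f: ForcingSeries, period: tuple[int, int]) -> slice:
    a = f.year_index(period[0])
    b = f.year_index(period[1])
    return slice(a, b + 1)


def _ramp(f: ForcingSeries, start_year: int, eval_period: tuple[int, int]
          ) -> np.ndarray:
    """Linear 0 -> 1 ramp from start_year to the end of the eval period."""
    t = f.years.astype(float)
    r = (t - start_year) / float(eval_period[1] - start_year)
    return np.clip(r, 0.0, 1.0)


def apply_precip_perturbation(
    f: ForcingSeries,
    target_increase: float = PRECIP_TARGET,
    base_period: tuple[int, int] = PERTURB_BASE,
    eval_period: tuple[int, int] = PERTURB_EVAL,
    start_year: int = CLIMATE_PERTURB_START,
) -> ForcingSeries:
    """Multiplicative, linearly ramped precipitation scaling.

    The final factor is solved per cell so that each cell's (and hence the
    area-weighted global) eval-period mean exceeds its base-period mean by
    exactly ``target_increase`` (fractional). The base period is left
    unmodified (the ramp is zero before ``start_year``).
    """
    if start_year > eval_period[0]:
        raise ScenarioError("start_year must be <= eval period start")
    out = f.copy()
    if target_increase == 0:
        return out
    b = _period_slice(f, base_period)
    e = _period_slice(f, eval_period)
    r = _ramp(f, start_year, eval_period)
    base_mean = f.precip[b].mean(axis=0)
    eval_mean = f.precip[e].mean(axis=0)
    weighted = (f.precip[e] * r[e, None]).mean(axis=0)
    active = eval_mean > 0
    if np.any((base_mean <= 0) & active):
        raise ScenarioError(
            "infeasible precipitation target: zero baseline precipitation in "
            f"cells {np.flatnonzero((base_mean <= 0) & active).tolist()}")
    # solve eval_mean + weighted*(F-1) = (1+target)*base_mean per cell
    fac = np.ones_like(base_mean)
    fac[active] = 1.0 + ((1.0 + target_increase) * base_mean[active]
                         - eval_mean[active]) / weighted[active]
    out.precip = f.precip * (1.0 + r[:, None] * (fac[None, :] - 1.0))
    out.precip = np.maximum(out.precip, 0.0)
    return out


def apply_temp_perturbation(
    f: ForcingSeries,
    target_increase: float = TEMP_TARGET,
    base_period: tuple[int, int] = PERTURB_BASE,
    eval_period: tuple[int, int] = PERTURB_EVAL,
    start_year: int = CLIMATE_PERTURB_START,
) -> ForcingSeries:
    """Additive, linearly ramped warming offset.

    Additive (degC) rather than proportional: a proportional factor on a
    Celsius field is ill-defined across the 0 degC crossing; the end-point
    contract — realized eval-minus-base change equals the target — is what
    is imposed, per cell.
    """
    if start_year > eval_period[0]:
        raise ScenarioError("start_year must be <= eval period start")
    out = f.copy()
    if target_increase == 0:
        return out
    b = _period_slice(f, base_period)
    e = _period_slice(f, eval_period)
    r = _ramp(f, start_year, eval_period)
    realized = f.temp[e].mean(axis=0) - f.temp[b].mean(axis=0)
    ramp_mean = r[e].mean()
    offset = (target_increase - realized) / ramp_mean
    out.temp = f.temp + r[:, None] * offset[None, :]
    return out


def freeze_co2(f: ForcingSeries, freeze_year: int = CO2_FREEZE_YEAR
               ) -> ForcingSeries:
    """Hold CO2 at its ``freeze_year`` level for all later years."""
    out = f.copy()
    idx = f.year_index(freeze_year)
    out.co2[idx + 1:] = f.co2[idx]
    return out


def apply_perturbation(f: ForcingSeries, spec: ScenarioSpec) -> ForcingSeries:
    """Dispatch the spec's perturbation (identity for 'none')."""
    if spec.perturbation == "none":
        return f
    if spec.perturbation == "precip_high":
        return apply_precip_perturbation(f)
    if spec.perturbation == "temp_high":
        return apply_temp_perturbation(f)
    if spec.perturbation == "co2_frozen":
        return freeze_co2(f)
    raise ScenarioError(f"unknown perturbation {spec.perturbation!r}")
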