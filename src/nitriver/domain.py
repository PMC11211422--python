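"""Land grid, river-network topology, land-use tiling, and world regions.

The simulator runs on a rectangular grid of cells (0-based, row-major,
latitude-first). Every land cell hosts one river reach and may additionally
host one lake (``lake_fraction`` > 0). Dissolved N moves between cells along
a single-downstream-neighbor drainage network that is acyclic by
construction and terminates at coastal outlet cells.

Land use within a cell is tiled into four types — primary land, secondary
land, cropland, and pasture — obtained by grouping the 12 LUH2 land-use
classes. Results are aggregated over 11 major world regions (NAM, PAO, WEU,
CPA, PAS, LAC, EEU, FSU, MEA, SAS, AFR).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import xarray as xr

#: downstream sentinel: cell discharges to the coastal ocean
OUTLET = -1
#: downstream sentinel: cell is not land (no routing defined)
NOT_LAND = -2

# Tile indices (order is part of the on-disk contract)
PRIMARY, SECONDARY, CROPLAND, PASTURE = 0, 1, 2, 3
TILE_NAMES = ("primary", "secondary", "cropland", "pasture")
N_TILES = 4

#: the 12 LUH2 state classes (standard short names)
LUH2_CLASSES = (
    "primf",  # forested primary land
    "primn",  # non-forested primary land
    "secdf",  # potentially forested secondary land
    "secdn",  # potentially non-forested secondary land
    "urban",  # urban land
    "c3ann",  # C3 annual cropland
    "c3per",  # C3 perennial cropland
    "c4ann",  # C4 annual cropland
    "c4per",  # C4 perennial cropland
    "c3nfx",  # C3 N-fixing cropland
    "pastr",  # managed pasture
    "range",  # rangeland
)

#: grouping of the 12 LUH2 classes into the 4 model tiles
LUH2_TO_TILE = {
    "primf": PRIMARY,
    "primn": PRIMARY,
    "secdf": SECONDARY,
    "secdn": SECONDARY,
    "urban": SECONDARY,  # urban is grouped into secondary land
    "c3ann": CROPLAND,
    "c3per": CROPLAND,
    "c4ann": CROPLAND,
    "c4per": CROPLAND,
    "c3nfx": CROPLAND,
    "pastr": PASTURE,
    "range": PASTURE,
}

REGION_CODES = (
    "NAM", "PAO", "WEU", "CPA", "PAS", "LAC", "EEU", "FSU", "MEA", "SAS", "AFR",
)
REGION_NAMES = {
    "NAM": "North America",
    "PAO": "Pacific OECD",
    "WEU": "Western Europe",
    "CPA": "Centrally Planned Asia and China",
    "PAS": "Other Pacific Asia",
    "LAC": "Latin America and the Caribbean",
    "EEU": "Central and Eastern Europe",
    "FSU": "Former Soviet Union",
    "MEA": "Middle East and North Africa",
    "SAS": "South Asia",
    "AFR": "Sub-Saharan Africa",
}
N_REGIONS = 11


class DomainError(ValueError):
    """Raised for impossible or inconsistent domain topology."""


@dataclass
class GridDomain:
    """Rectangular land grid.

    All per-cell arrays are flat, length ``n_lat * n_lon``, row-major
    (cell = ilat * n_lon + ilon).
    """

    n_lat: int
    n_lon: int
    cell_area: np.ndarray      # m2 per cell, > 0
    land_mask: np.ndarray      # bool per cell
    lake_fraction: np.ndarray  # [0, 1] per cell
    has_reach: np.ndarray      # bool per cell

    @property
    def n_cells(self) -> int:
        return self.n_lat * self.n_lon

    @property
    def land_cells(self) -> np.ndarray:
        return np.flatnonzero(self.land_mask)

    def validate(self) -> None:
        n = self.n_cells
        for name in ("cell_area", "land_mask", "lake_fraction", "has_reach"):
            if getattr(self, name).shape != (n,):
                raise DomainError(f"{name} must have shape ({n},)")
        if not np.all(self.cell_area > 0):
            raise DomainError("cell_area must be > 0 everywhere")
        if np.any((self.lake_fraction < 0) | (self.lake_fraction > 1)):
            raise DomainError("lake_fraction must lie in [0, 1]")
        bad = self.land_mask & ~self.has_reach & (self.lake_fraction <= 0)
        if np.any(bad):
            raise DomainError(
                f"land cells without reach or lake: {np.flatnonzero(bad).tolist()}"
            )

    def to_dataset(self, net: "FlowNetwork | None" = None,
                   regions: "RegionMap | None" = None) -> xr.Dataset:
        """Gridded (lat, lon) dataset following the NetCDF-style convention."""
        shape = (self.n_lat, self.n_lon)
        data = {
            "land_mask": (("lat", "lon"), self.land_mask.reshape(shape).astype("i1")),
            "cell_area": (("lat", "lon"), self.cell_area.reshape(shape)),
            "lake_fraction": (("lat", "lon"), self.lake_fraction.reshape(shape)),
            "has_reach": (("lat", "lon"), self.has_reach.reshape(shape).astype("i1")),
        }
        if net is not None:
            data["downstream_index"] = (
                ("lat", "lon"), net.downstream.reshape(shape).astype("i4"))
        if regions is not None:
            data["region_id"] = (
                ("lat", "lon"), regions.region_id.reshape(shape).astype("i4"))
        ds = xr.Dataset(data)
        ds["cell_area"].attrs["units"] = "m2"
        return ds


@dataclass
class FlowNetwork:
    """Single-downstream-neighbor drainage graph ending at coastal outlets."""

    downstream: np.ndarray  # per-cell receiving cell index, OUTLET, or NOT_LAND

    @property
    def outlet_set(self) -> np.ndarray:
        return np.flatnonzero(self.downstream == OUTLET)

    def topo_levels(self, domain: GridDomain) -> list[np.ndarray]:
        """Group land cells by longest path to an outlet, upstream first.

        An edge i -> j guarantees level(i) > level(j), so cells within one
        level never flow into each other and can be stepped vectorized.
        """
        n = domain.n_cells
        depth = np.full(n, -1, dtype=np.int64)

        def _depth(i: int) -> int:
            # iterative longest-chain walk (network is acyclic and validated)
            chain = []
            while depth[i] < 0:
                chain.append(i)
                j = self.downstream[i]
                if j == OUTLET:
                    depth[i] = 0
                    chain.pop()
                    break
                i = j
            base = depth[i]
            for k, c in enumerate(reversed(chain), start=1):
                depth[c] = base + k
            return depth[chain[0]] if chain else base

        for i in domain.land_cells:
            _depth(int(i))
        levels = []
        for d in range(int(depth.max()), -1, -1):
            levels.append(np.flatnonzero(depth == d))
        return levels


@dataclass
class LandTileSet:
    """Per-cell area fractions of the 4 land-use tiles, shape (n_cells, 4)."""

    fractions: np.ndarray

    def validate(self) -> None:
        f = self.fractions
        if f.ndim != 2 or f.shape[1] != N_TILES:
            raise DomainError("tile fractions must have shape (n_cells, 4)")
        if np.any((f < -1e-12) | (f > 1 + 1e-12)):
            raise DomainError("tile fractions must lie in [0, 1]")
        if np.any(f.sum(axis=1) > 1 + 1e-9):
            raise DomainError("per-cell tile fractions must sum to <= 1")


@dataclass
class RegionMap:
    """Assignment of land cells to the 11 aggregate world regions.

    ``region_id`` is 1..11 on land, 0 elsewhere. ``pcgdp`` (diagnostic
    metadata only; never feeds back into simulation) maps scenario name to a
    year x region DataFrame of per-capita GDP in 2010 USD.
    """

    region_id: np.ndarray
    codes: tuple[str, ...] = REGION_CODES
    names: dict[str, str] = field(default_factory=lambda: dict(REGION_NAMES))
    pcgdp: dict[str, pd.DataFrame] = field(default_factory=dict)

    def code_of(self, region_id: int) -> str:
        return self.codes[region_id - 1]

    def cells_in(self, code: str) -> np.ndarray:
        rid = self.codes.index(code) + 1
        return np.flatnonzero(self.region_id == rid)


@dataclass
class ValidationReport:
    """Outcome of flow-network validation; empty report <=> valid network."""

    cycles: list[list[int]]
    dead_ends: list[int]
    unreachable: list[int]

    @property
    def ok(self) -> bool:
        return not (self.cycles or self.dead_ends or self.unreachable)

    def __str__(self) -> str:
        if self.ok:
            return "flow network valid"
        return (f"cycles={self.cycles} dead_ends={self.dead_ends} "
                f"unreachable={self.unreachable}")


def _neighbors8(i: int, n_lat: int, n_lon: int):
    ilat, ilon = divmod(i, n_lon)
    for dlat in (-1, 0, 1):
        for dlon in (-1, 0, 1):
            if dlat == 0 and dlon == 0:
                continue
            a, b = ilat + dlat, ilon + dlon
            if 0 <= a < n_lat and 0 <= b < n_lon:
                yield a * n_lon + b
            else:
                yield -1  # off-grid: ocean


def build_synthetic_domain(
    n_lat: int,
    n_lon: int,
    land_fraction: float = 1.0,
    seed: int = 0,
    mean_cell_area: float = 3.6e12,
    lake_cell_fraction: float = 0.3,
) -> tuple[GridDomain, FlowNetwork, RegionMap]:
    """Generate a random but valid desk-scale domain.

    Routing is steepest-descent on a pseudo-elevation built from the
    breadth-first distance to the ocean (off-grid and non-land cells count
    as ocean), which makes the drainage network acyclic by construction:
    every hop strictly reduces the distance to an outlet.

    ``mean_cell_area`` defaults to ~3.6e6 km2 so that a handful of cells
    carries a global-scale land area (~1.3e14 m2 on a 6x6 land grid).
    """
    if n_lat < 1 or n_lon < 1:
        raise DomainError("grid must be at least 1x1")
    if not (0 < land_fraction <= 1):
        raise DomainError("land_fraction must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    n = n_lat * n_lon

    n_land = max(1, int(round(land_fraction * n)))
    land_mask = np.zeros(n, dtype=bool)
    # grow a single connected land blob from a random start so that the
    # land area is contiguous (regions stay contiguous blocks)
    start = int(rng.integers(n))
    frontier = [start]
    chosen: list[int] = []
    seen = {start}
    while frontier and len(chosen) < n_land:
        idx = int(rng.integers(len(frontier)))
        c = frontier.pop(idx)
        chosen.append(c)
        for nb in _neighbors8(c, n_lat, n_lon):
            if nb >= 0 and nb not in seen:
                seen.add(nb)
                frontier.append(nb)
    land_mask[np.array(chosen, dtype=np.int64)] = True

    cell_area = mean_cell_area * (0.8 + 0.4 * rng.random(n))
    lake_fraction = np.where(
        land_mask & (rng.random(n) < lake_cell_fraction),
        0.05 + 0.25 * rng.random(n), 0.0)
    has_reach = land_mask.copy()

    # BFS distance to ocean (off-grid or non-land neighbor => distance 1)
    dist = np.full(n, -1, dtype=np.int64)
    queue: list[int] = []
    for i in np.flatnonzero(land_mask):
        if any(nb < 0 or not land_mask[nb] for nb in _neighbors8(int(i), n_lat, n_lon)):
            dist[i] = 1
            queue.append(int(i))
    if not queue:
        raise DomainError("impossible topology: no ocean-adjacent land cell")
    head = 0
    while head < len(queue):
        c = queue[head]
        head += 1
        for nb in _neighbors8(c, n_lat, n_lon):
            if nb >= 0 and land_mask[nb] and dist[nb] < 0:
                dist[nb] = dist[c] + 1
                queue.append(nb)

    noise = rng.random(n)
    downstream = np.full(n, NOT_LAND, dtype=np.int64)
    for i in np.flatnonzero(land_mask):
        i = int(i)
        if dist[i] == 1:
            downstream[i] = OUTLET
            continue
        cands = [nb for nb in _neighbors8(i, n_lat, n_lon)
                 if nb >= 0 and land_mask[nb] and dist[nb] == dist[i] - 1]
        downstream[i] = min(cands, key=lambda j: noise[j])

    domain = GridDomain(n_lat, n_lon, cell_area, land_mask, lake_fraction, has_reach)
    domain.validate()
    net = FlowNetwork(downstream)

    # contiguous region blocks over land cells in row-major order
    region_id = np.zeros(n, dtype=np.int64)
    blocks = np.array_split(np.sort(domain.land_cells), N_REGIONS)
    for k, block in enumerate(blocks, start=1):
        region_id[block] = k
    regions = RegionMap(region_id=region_id)

    report = validate_flow_network(net, domain)
    if not report.ok:
        raise DomainError(f"generated network failed validation: {report}")
    return domain, net, regions


def validate_flow_network(net: FlowNetwork, domain: GridDomain) -> ValidationReport:
    """Check acyclicity, outlet reachability, and link sanity.

    Reporting operation: never raises for a bad network, only describes it.
    """
    n = domain.n_cells
    if net.downstream.shape != (n,):
        raise DomainError("network and domain shapes disagree")
    dead_ends = []
    g = nx.DiGraph()
    land = set(domain.land_cells.tolist())
    for i in land:
        j = int(net.downstream[i])
        if j == OUTLET:
            continue
        if j < 0 or j >= n or j not in land:
            dead_ends.append(i)
        else:
            g.add_edge(i, j)
    cycles = [sorted(c) for c in nx.simple_cycles(g)]
    in_cycle = {c for cyc in cycles for c in cyc}
    unreachable = []
    for i in sorted(land):
        c, steps = i, 0
        while steps <= n:
            j = int(net.downstream[c])
            if j == OUTLET:
                break
            if j < 0 or j >= n or j not in land:
                break  # dead end already reported
            c, steps = j, steps + 1
        else:
            if i not in in_cycle:
                unreachable.append(i)
    return ValidationReport(cycles=cycles, dead_ends=sorted(dead_ends),
                            unreachable=unreachable)


def map_luh2_states(luh2_fractions: dict[str, np.ndarray]) -> LandTileSet:
    """Group the 12 LUH2 class fractions into the 4 model tiles.

    primary = primf + primn; secondary = secdf + secdn + urban;
    cropland = c3ann + c3per + c4ann + c4per + c3nfx;
    pasture = pastr + range. Total area is conserved exactly.
    """
    missing = [c for c in LUH2_CLASSES if c not in luh2_fractions]
    if missing:
        raise DomainError(f"missing LUH2 classes: {missing}")
    arrays = {c: np.asarray(luh2_fractions[c], dtype=float) for c in LUH2_CLASSES}
    for c, a in arrays.items():
        if np.any((a < 0) | (a > 1)):
            raise DomainError(f"LUH2 class {c!r} has fractions outside [0, 1]")
    n = arrays["primf"].shape[0]
    fractions = np.zeros((n, N_TILES))
    for c, tile in LUH2_TO_TILE.items():
        fractions[:, tile] += arrays[c]
    tiles = LandTileSet(fractions)
    tiles.validate()
    return tiles


def synthesize_pcgdp(years: np.ndarray, scenarios: list[str],
                     seed: int = 0) -> dict[str, pd.DataFrame]:
    """Synthetic per-capita GDP series per region and scenario (metadata).

    Base 2010 levels follow the familiar income ordering of the 11 regions;
    growth rates differ by scenario (fastest under fossil-fueled
    development). Diagnostic only — used to order regions on cross-plots.
    """
    base = {"NAM": 45000, "PAO": 40000, "WEU": 42000, "CPA": 8000,
            "PAS": 7000, "LAC": 10000, "EEU": 15000, "FSU": 12000,
            "MEA": 9000, "SAS": 3000, "AFR": 2500}
    growth = {"SSP5-8.5": 0.030, "SSP2-4.5": 0.018, "SSP1-2.6": 0.022}
    rng = np.random.default_rng(seed)
    out = {}
    for scen in scenarios:
        g = growth.get(scen, 0.02)
        cols = {}
        for code in REGION_CODES:
            jitter = 1 + 0.1 * (rng.random() - 0.5)
            cols[code] = base[code] * np.exp(g * jitter * (years - 2010.0))
        out[scen] = pd.DataFrame(cols, index=pd.Index(years, name="year"))
    return out
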