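"""Post-processing: budget closure, smoothing, regional tables, correlations.

These operations reproduce the analysis surface behind the scenario
experiments: 21-year moving averages of load trajectories, the
input/output/storage budget ledger and its closure residual, annual
region x variable tables for the 11 world regions (plus GLOBAL), percent
changes between a present and an end-of-century period, and Pearson
correlations of load changes against driver changes across the
region x scenario matrix.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .domain import N_REGIONS, REGION_CODES, RegionMap
from .engine import FluxLedger, RunResult


class DiagnosticsError(ValueError):
    """Raised for invalid diagnostic requests."""


def moving_average(series: np.ndarray | pd.Series, window: int,
                   edge: str = "truncate") -> np.ndarray | pd.Series:
    """Centered moving average with an odd window.

    ``edge='truncate'`` averages whatever part of the window lies inside
    the series (endpoints stay defined); ``edge='valid'`` leaves NaN where
    the full window does not fit. ``window=1`` is the identity.
    """
    if window % 2 == 0 or window < 1:
        raise DiagnosticsError(f"window must be odd and >= 1, got {window}")
    if edge not in ("truncate", "valid"):
        raise DiagnosticsError(f"unknown edge policy {edge!r}")
    values = np.asarray(series, dtype=float)
    half = window // 2
    n = values.size
    out = np.full(n, np.nan)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        if edge == "valid" and hi - lo < window:
            continue
        out[i] = values[lo:hi].mean()
    if isinstance(series, pd.Series):
        return pd.Series(out, index=series.index, name=series.name)
    return out


def regional_aggregate(result: RunResult, regions: RegionMap) -> pd.DataFrame:
    """Aggregate outlet loads by the region of the river-mouth cell.

    Returns a tidy frame (year, region, DIN, DON, DN) in TgN yr-1 covering
    all 11 regions (zero where a region has no outlet) plus GLOBAL, which
    equals the sum over regions exactly.
    """
    loads = result.outlet_loads  # (ny, n_cells, 3), species (DON, NH4, NO3)
    rid = regions.region_id
    if loads.shape[1] != rid.size:
        raise DiagnosticsError("loads and region map are on different grids")
    if np.any((rid == 0) & (loads.sum(axis=(0, 2)) > 0)):
        raise DiagnosticsError("outlet load on a cell with no region assigned")
    rows = []
    don = loads[:, :, 0]
    din = loads[:, :, 1] + loads[:, :, 2]
    for r in range(1, N_REGIONS + 1):
        mask = rid == r
        rows.append(pd.DataFrame({
            "year": result.years, "region": REGION_CODES[r - 1],
            "DIN": din[:, mask].sum(axis=1), "DON": don[:, mask].sum(axis=1)}))
    table = pd.concat(rows, ignore_index=True)
    g = table.groupby("year", as_index=False)[["DIN", "DON"]].sum()
    g.insert(1, "region", "GLOBAL")
    table = pd.concat([table, g], ignore_index=True)
    table["DN"] = table["DIN"] + table["DON"]
    return table


def period_change(series: pd.Series, base_period: tuple[int, int],
                  eval_period: tuple[int, int]) -> float:
    """Percent change of period means; NaN (flagged) when the base mean is 0.

    ``series`` must be indexed by year and cover both periods.
    """
    for period in (base_period, eval_period):
        missing = [y for y in range(period[0], period[1] + 1)
                   if y not in series.index]
        if missing:
            raise DiagnosticsError(f"period {period} not fully in series")
    base = series.loc[base_period[0]:base_period[1]].mean()
    ev = series.loc[eval_period[0]:eval_period[1]].mean()
    if base == 0:
        return float("nan")
    return 100.0 * (ev - base) / base


def budget_closure(ledger: FluxLedger) -> pd.DataFrame:
    """Annual closure residual of the N budget, TgN yr-1.

    residual(t) = dStorage(t) - [inputs(t) - outputs(t)], with inputs
    fertilizer + deposition + BNF and outputs using net harvest. A closed
    budget has |residual| at machine-precision level relative to inputs.
    """
    t = ledger.table
    storage = t["storage_total"].values
    prev = np.concatenate([[ledger.initial_storage], storage[:-1]])
    residual = (storage - prev) - (ledger.inputs_total().values
                                   - ledger.outputs_total().values)
    return pd.DataFrame({"year": t["year"], "residual": residual,
                         "inputs": ledger.inputs_total().values})


def build_change_table(
    suite_runs: dict[str, RunResult],
    regions: RegionMap,
    base_period: tuple[int, int] = (2000, 2020),
    eval_period: tuple[int, int] = (2079, 2099),
    pcgdp_period: tuple[int, int] = (2080, 2099),
) -> pd.DataFrame:
    """Region x scenario change table for cross-plots and correlations.

    Per region and run: percent DN load change between the two periods,
    absolute driver changes (global ledger fluxes in TgN yr-1; regional
    mean temperature in degC, precipitation in %), and the mean per-capita
    GDP of the region over ``pcgdp_period`` where available.
    """
    rows = []
    for label, res in suite_runs.items():
        reg = regional_aggregate(res, regions).set_index("year")
        led = res.ledger.table.set_index("year")
        pc = regions.pcgdp.get(res.spec.name)
        for code in REGION_CODES:
            sub = reg[reg["region"] == code]
            row = {
                "run": label, "scenario": res.spec.name, "region": code,
                "dn_change_pct": period_change(sub["DN"], base_period,
                                               eval_period),
                "dn_change_abs": (sub["DN"].loc[eval_period[0]:eval_period[1]]
                                  .mean()
                                  - sub["DN"].loc[base_period[0]:
                                                  base_period[1]].mean()),
            }
            for col, name in (("in_fertilizer", "fertilizer"),
                              ("in_deposition", "deposition"),
                              ("in_manure", "manure"), ("in_bnf", "bnf")):
                row[f"d_{name}"] = (
                    led[col].loc[eval_period[0]:eval_period[1]].mean()
                    - led[col].loc[base_period[0]:base_period[1]].mean())
            if pc is not None and code in pc.columns:
                row["pcgdp"] = pc[code].loc[pcgdp_period[0]:
                                            pcgdp_period[1]].mean()
            else:
                row["pcgdp"] = np.nan
            rows.append(row)
    return pd.DataFrame(rows)


def add_climate_changes(table: pd.DataFrame, forcings_by_run: dict,
                        regions: RegionMap,
                        base_period: tuple[int, int] = (2000, 2020),
                        eval_period: tuple[int, int] = (2079, 2099)
                        ) -> pd.DataFrame:
    """Attach regional temperature (degC) and precipitation (%) changes."""
    out = table.copy()
    out["d_temperature"] = np.nan
    out["d_precipitation_pct"] = np.nan
    for label, f in forcings_by_run.items():
        b = slice(f.year_index(base_period[0]), f.year_index(base_period[1]) + 1)
        e = slice(f.year_index(eval_period[0]), f.year_index(eval_period[1]) + 1)
        for code in REGION_CODES:
            cells = regions.cells_in(code)
            if cells.size == 0:
                continue
            sel = (out["run"] == label) & (out["region"] == code)
            dt = (f.temp[e][:, cells].mean() - f.temp[b][:, cells].mean())
            pb = f.precip[b][:, cells].mean()
            dp = 100.0 * (f.precip[e][:, cells].mean() - pb) / pb if pb else np.nan
            out.loc[sel, "d_temperature"] = dt
            out.loc[sel, "d_precipitation_pct"] = dp
    return out


def correlate_changes(table: pd.DataFrame, x: str, y: str
                      ) -> tuple[float, float, int]:
    """Pearson correlation over region x scenario pairs.

    Drops incomplete pairs (count reported through ``n``); the two-sided
    p-value comes from the t-distribution. Raises if fewer than 3 pairs
    remain.
    """
    sub = table[[x, y]].dropna()
    n = len(sub)
    if n < 3:
        raise DiagnosticsError(f"need >= 3 paired observations, have {n}")
    r, p = stats.pearsonr(sub[x], sub[y])
    return float(r), float(p), n
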