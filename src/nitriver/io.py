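"""Output writing with checksummed manifests."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import xarray as xr

from .engine import RunResult
from .terrestrial import N_POOLS, POOL_NAMES


class OutputError(RuntimeError):
    """Raised on output failures (partial files are removed)."""


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def state_to_dataset(result: RunResult) -> xr.Dataset:
    """Final-state snapshot (pool x tile x cell, plus freshwater pools)."""
    t = result.final.terrestrial.pools
    f = result.final.freshwater
    ds = xr.Dataset(
        {
            "terrestrial_pools": (("cell", "tile", "pool"), t),
            "river_pools": (("cell", "species"), f.river),
            "lake_pools": (("cell", "species"), f.lake),
        },
        coords={"cell": np.arange(t.shape[0]),
                "tile": np.arange(t.shape[1]),
                "pool": list(POOL_NAMES[:N_POOLS]),
                "species": ["DON", "NH4", "NO3"]})
    ds["terrestrial_pools"].attrs["units"] = "kgN m-2"
    ds["river_pools"].attrs["units"] = "kgN"
    ds["lake_pools"].attrs["units"] = "kgN"
    return ds


def write_outputs(result: RunResult, out_dir: str | Path,
                  regional: "object | None" = None) -> dict:
    """Write ledger CSV, load CSVs, state snapshot, and provenance JSON.

    Returns a manifest listing every file with its sha256 checksum (also
    written as manifest.json). On failure all partial outputs are removed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    label = result.spec.label()
    written: list[Path] = []
    try:
        p = out / f"{label}_ledger.csv"
        result.ledger.table.to_csv(p, index=False)
        written.append(p)
        p = out / f"{label}_loads.csv"
        result.loads.to_csv(p, index=False)
        written.append(p)
        if regional is not None:
            p = out / f"{label}_regional.csv"
            regional.to_csv(p, index=False)
            written.append(p)
        p = out / f"{label}_state.nc"
        state_to_dataset(result).to_netcdf(p)
        written.append(p)
        p = out / f"{label}_provenance.json"
        prov = dict(result.provenance)
        prov["result_digest"] = result.digest()
        prov["spec"] = dataclasses.asdict(result.spec)
        with open(p, "w") as fh:
            json.dump(prov, fh, indent=2, default=str)
        written.append(p)
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise OutputError(f"failed writing outputs to {out}: {exc}") from exc
    manifest = {"files": {p.name: _sha256(p) for p in written}}
    with open(out / f"{label}_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
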