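import numpy as np
import pandas as pd
import pytest

from conftest import make_chain_domain
from nitriver.domain import build_synthetic_domain
from nitriver.engine import (EngineError, StatePack, run_experiment,
                             run_suite, spin_up)
from nitriver.forcing import ForcingSeries, ScenarioSpec, generate_scenario_forcings
from nitriver.freshwater import FreshwaterState
from nitriver.params import ModelParams
from nitriver.terrestrial import TerrestrialState


def zero_forcings(domain, years):
    ny, n = len(years), domain.n_cells
    tiles = np.tile(np.array([0.25, 0.25, 0.25, 0.22]), (ny, n, 1))
    tiles *= domain.land_mask[None, :, None]
    return ForcingSeries(
        years=np.asarray(years), co2=np.full(ny, 285.0),
        precip=np.zeros((ny, n)), temp=np.full((ny, n), 20.0),
        runoff_fraction=np.full((ny, n), 0.3),
        fertilizer=np.zeros((ny, n)), deposition=np.zeros((ny, n)),
        manure_managed=np.zeros((ny, n)), manure_grass=np.zeros((ny, n)),
        tiles=tiles)


def zero_pack(n):
    return StatePack(TerrestrialState.zeros(n), FreshwaterState.zeros(n),
                     np.zeros(n), np.zeros(n))


@pytest.fixture(scope="module")
def world():
    return build_synthetic_domain(3, 3, 1.0, seed=4)


def no_bnf_params():
    return ModelParams().with_overrides({
        "terrestrial.bnf_max": 0.0, "terrestrial.bnf_floor": 0.0,
        "terrestrial.bnf_cultivated": 0.0})


def test_one_year_zero_run_gives_zero_ledger(world):
    domain, net, regions = world
    f = zero_forcings(domain, [2000])
    spec = ScenarioSpec(name="custom", start_year=2000, end_year=2001)
    res = run_experiment(spec, domain, net, regions, params=no_bnf_params(),
                         initial=zero_pack(domain.n_cells), forcings=f,
                         year_range=(2000, 2000), spin_up_first=False)
    t = res.ledger.table
    flux_cols = [c for c in t.columns if c.startswith(("in_", "out_"))]
    assert not t[flux_cols].values.any()
    assert not t.filter(like="storage").values.any()


def test_identical_runs_have_identical_digests(world):
    domain, net, regions = world
    spec = ScenarioSpec(name="SSP2-4.5", start_year=2000, end_year=2099,
                        seed=7)
    f = generate_scenario_forcings(spec, domain)
    kw = dict(params=ModelParams(), initial=zero_pack(domain.n_cells),
              forcings=f, spin_up_first=False, dt_days=73.0)
    a = run_experiment(spec, domain, net, regions, **kw)
    b = run_experiment(spec, domain, net, regions, **kw)
    assert a.digest() == b.digest()


def test_restart_equivalence_is_bit_exact(world):
    domain, net, regions = world
    spec = ScenarioSpec(name="SSP2-4.5", start_year=1990, end_year=2030,
                        seed=7)
    f = generate_scenario_forcings(spec, domain)
    params = ModelParams()
    full = run_experiment(spec, domain, net, regions, params=params,
                          initial=zero_pack(domain.n_cells), forcings=f,
                          spin_up_first=False, dt_days=30.0)
    first = run_experiment(spec, domain, net, regions, params=params,
                           initial=zero_pack(domain.n_cells), forcings=f,
                           year_range=(1990, 2010), spin_up_first=False,
                           dt_days=30.0)
    second = run_experiment(spec, domain, net, regions, params=params,
                            initial=first.final, forcings=f,
                            year_range=(2011, 2030), spin_up_first=False,
                            dt_days=30.0)
    stitched = pd.concat([first.ledger.table, second.ledger.table],
                         ignore_index=True)
    pd.testing.assert_frame_equal(stitched, full.ledger.table)
    assert np.array_equal(second.final.terrestrial.pools,
                          full.final.terrestrial.pools)
    assert np.array_equal(second.final.freshwater.river,
                          full.final.freshwater.river)


def test_spin_up_zero_forcing_converges_immediately(world):
    domain, net, _ = world
    f = zero_forcings(domain, [2000])
    pack, drift = spin_up(domain, net, f, no_bnf_params(), spin_year=2000,
                          window=10, max_years=100)
    assert drift == 0.0
    assert not pack.terrestrial.pools.any()


def test_spin_up_equilibrium_balances_inputs_and_outputs():
    """At the spun-up fixed point, annual inputs equal annual outputs."""
    domain, net, regions = make_chain_domain(3)
    f = zero_forcings(domain, [2000])
    f.deposition[:] = 0.001
    f.precip[:] = 900.0
    params = no_bnf_params()
    pack, drift = spin_up(domain, net, f, params, spin_year=2000,
                          drift_tolerance=1e-6, window=50, max_years=4000)
    spec = ScenarioSpec(name="custom", start_year=2000, end_year=2001)
    res = run_experiment(spec, domain, net, regions, params=params,
                         initial=pack, forcings=f, year_range=(2000, 2000),
                         spin_up_first=False)
    t = res.ledger.table.iloc[0]
    inputs = res.ledger.inputs_total().iloc[0]
    outputs = res.ledger.outputs_total().iloc[0]
    assert inputs > 0
    assert outputs == pytest.approx(inputs, rel=5e-3)


def test_spin_up_is_idempotent_once_converged():
    domain, net, regions = make_chain_domain(2)
    f = zero_forcings(domain, [2000])
    f.deposition[:] = 0.001
    f.precip[:] = 900.0
    params = no_bnf_params()
    pack1, _ = spin_up(domain, net, f, params, spin_year=2000,
                       drift_tolerance=1e-7, window=50, max_years=6000)
    pack2, _ = spin_up(domain, net, f, params, spin_year=2000,
                       drift_tolerance=1e-7, window=50, max_years=6000,
                       initial=pack1)
    rel = np.abs(pack2.terrestrial.pools - pack1.terrestrial.pools) / \
        np.maximum(pack1.terrestrial.pools, 1e-9)
    assert rel.max() < 1e-4


def test_spin_up_nonconvergence_raises():
    domain, net, _ = make_chain_domain(2)
    f = zero_forcings(domain, [2000])
    f.deposition[:] = 0.001
    f.precip[:] = 900.0
    with pytest.raises(EngineError, match="did not converge"):
        spin_up(domain, net, f, no_bnf_params(), spin_year=2000,
                drift_tolerance=1e-12, window=10, max_years=30)


def test_suite_refuses_manure_under_ssp126(world):
    domain, net, regions = world
    specs = [ScenarioSpec(name="SSP1-2.6", start_year=2000, end_year=2010,
                          manure_on=True)]
    out = run_suite(specs, domain, net, regions, dt_days=73.0)
    assert not out.runs
    assert len(out.failures) == 1
    assert "not available for SSP1-2.6" in next(iter(out.failures.values()))


def test_suite_empty_scenario_list(world):
    domain, net, regions = world
    out = run_suite([], *world)
    assert out.runs == {} and out.failures == {} and out.summary is None


def test_perturbed_run_diverges_only_after_start_year(world):
    domain, net, regions = world
    base = ScenarioSpec(name="SSP5-8.5", start_year=1980, end_year=2099,
                        seed=2)
    pert = ScenarioSpec(name="SSP5-8.5", start_year=1980, end_year=2099,
                        seed=2, perturbation="temp_high")
    out = run_suite([base, pert], domain, net, regions, dt_days=73.0)
    a = out.runs[base.label()].loads.set_index("year")["DN"]
    b = out.runs[pert.label()].loads.set_index("year")["DN"]
    assert np.array_equal(a.loc[:2019].values, b.loc[:2019].values)
    assert not np.array_equal(a.loc[2020:].values, b.loc[2020:].values)


def test_manure_recycling_active_before_data_period(world):
    domain, net, regions = world
    spec = ScenarioSpec(name="SSP5-8.5", start_year=1995, end_year=2006,
                        seed=1, manure_on=True)
    f = generate_scenario_forcings(spec, domain)
    res = run_experiment(spec, domain, net, regions, params=ModelParams(),
                         initial=zero_pack(domain.n_cells), forcings=f,
                         spin_up_first=False, dt_days=30.0)
    t = res.ledger.table.set_index("year")
    # no production in the zero-state first year, recycling from the second
    assert t.loc[1996:2001, "in_manure"].min() > 0
    assert t.loc[2002:, "in_manure"].min() > 0
    # full-run ledger identity: net harvest = harvest - recycled manure
    np.testing.assert_allclose(
        t["out_net_harvest"], t["out_harvest"] - t["in_manure"], rtol=1e-12)
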