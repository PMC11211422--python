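import logging

import numpy as np
import pytest

from nitriver.params import ManureParams, ParamError, TerrestrialParams
from nitriver.terrestrial import (AMMONIUM, CROPLAND, FAST_LITTER, NITRATE,
                                  N_POOLS, N_TILES, PASSIVE_SOIL,
                                  TerrestrialError, TerrestrialForcing,
                                  TerrestrialState, apply_tile_transition,
                                  bnf, co2_multiplier, net_harvest,
                                  recycle_manure, step_terrestrial)


def make_forcing(n=1, fert=0.0, dep=0.0, man_m=0.0, man_g=0.0, precip=0.0,
                 temp=20.0, co2=285.0, crop=0.25):
    tiles = np.tile([0.25, 0.25, crop, 0.25], (n, 1))
    return TerrestrialForcing(
        fertilizer=np.full(n, fert), deposition=np.full(n, dep),
        manure_managed=np.full(n, man_m), manure_grass=np.full(n, man_g),
        precip=np.full(n, precip), temp=np.full(n, temp),
        runoff_fraction=np.full(n, 0.3), co2=co2, tiles=tiles)


def test_zero_state_zero_forcing_stays_zero_except_bnf():
    params = TerrestrialParams(bnf_max=0.0, bnf_floor=0.0, bnf_cultivated=0.0)
    state = TerrestrialState.zeros(2)
    new, fl = step_terrestrial(state, make_forcing(2), params, dt=1 / 12)
    assert not np.any(new.pools)
    assert not np.any(fl.inputs_total())
    assert not np.any(fl.outputs_total())


def test_single_pool_decay_matches_closed_form():
    """Passive soil with recycling paths off decays as exp(-k t) to 1e-8."""
    params = TerrestrialParams(bnf_max=0.0, bnf_floor=0.0, bnf_cultivated=0.0,
                               uptake_potential=0.0,
                               mineralization_fraction=1.0)
    state = TerrestrialState.zeros(1)
    p0 = 0.7
    state.pools[0, :, PASSIVE_SOIL] = p0
    dt, n = 1 / 12, 120
    for _ in range(n):
        state, _ = step_terrestrial(state, make_forcing(), params, dt)
    expected = p0 * np.exp(-params.k_passive_soil * n * dt)
    assert state.pools[0, 0, PASSIVE_SOIL] == pytest.approx(expected,
                                                            rel=1e-8)


def test_fertilizer_on_zero_cropland_not_registered(caplog):
    params = TerrestrialParams()
    state = TerrestrialState.zeros(1)
    with caplog.at_level(logging.WARNING, logger="nitriver.terrestrial"):
        new, fl = step_terrestrial(state, make_forcing(fert=0.01, crop=0.0),
                                   params, dt=1 / 12)
    assert not np.any(fl.fertilizer)
    assert "fertilizer" in caplog.text


def test_mass_balance_closes_per_tile():
    rng = np.random.default_rng(0)
    params = TerrestrialParams()
    for trial in range(5):
        n = 3
        state = TerrestrialState(rng.random((n, N_TILES, N_POOLS)) * 0.5)
        f = make_forcing(n, fert=0.02 * rng.random(), dep=0.001,
                         man_m=0.005, man_g=0.002, precip=900.0,
                         temp=15 + 10 * rng.random(), co2=400.0)
        new, fl = step_terrestrial(state, f, params, dt=1 / 12)
        delta = new.pools.sum(axis=2) - state.pools.sum(axis=2)
        balance = fl.inputs_total() - fl.outputs_total()
        scale = np.maximum(fl.inputs_total(), 1e-12)
        assert np.all(np.abs(delta - balance) / scale < 1e-10)
        assert np.all(new.pools >= 0)


def test_negative_forcing_rejected():
    params = TerrestrialParams()
    f = make_forcing()
    f.deposition[:] = -0.001
    with pytest.raises(TerrestrialError, match="deposition"):
        step_terrestrial(TerrestrialState.zeros(1), f, params, dt=1 / 12)


def test_too_large_dt_names_offending_rate():
    params = TerrestrialParams()
    with pytest.raises(TerrestrialError, match="uptake_avail_rate"):
        step_terrestrial(TerrestrialState.zeros(1), make_forcing(), params,
                         dt=10.0)


def test_co2_multiplier_contracts():
    params = TerrestrialParams()
    assert co2_multiplier(params.co2_ref, params) == 1.0
    doubled = co2_multiplier(2 * params.co2_ref, params)
    assert doubled == pytest.approx(1 + params.co2_beta * np.log(2.0))
    assert doubled > 1
    assert co2_multiplier(900.0, params, enabled=False) == 1.0
    with pytest.raises(TerrestrialError):
        co2_multiplier(-1.0, params)


def test_bnf_limits_and_monotonicity():
    params = TerrestrialParams()
    lo = TerrestrialState.zeros(1)
    hi = TerrestrialState.zeros(1)
    hi.pools[:, :, NITRATE] = 100.0  # mineral N -> infinity limit
    assert bnf(lo, params)[0, 0] == pytest.approx(params.bnf_max)
    assert bnf(hi, params)[0, 0] == pytest.approx(params.bnf_floor, rel=1e-3)
    mid = TerrestrialState.zeros(1)
    mid.pools[:, :, NITRATE] = 0.001
    assert np.all(bnf(mid, params) <= bnf(lo, params))
    assert np.all(bnf(hi, params) <= bnf(mid, params))
    # cultivation-induced component on cropland only
    assert bnf(lo, params)[0, CROPLAND] == pytest.approx(
        params.bnf_max + params.bnf_cultivated)


def test_recycle_manure_arithmetic_and_bounds():
    p = ManureParams(f_grazing=0.4, f_crop=0.2)
    managed, grass = recycle_manure(np.array([10.0]), np.array([5.0]), p)
    assert managed[0] + grass[0] == pytest.approx(5.0)  # 0.4*10 + 0.2*5
    z = recycle_manure(np.zeros(2), np.zeros(2), p)
    assert not np.any(z[0]) and not np.any(z[1])
    full = ManureParams(f_grazing=1.0, f_crop=1.0)
    m, g = recycle_manure(np.array([1.0]), np.array([1.0]), full)
    assert m[0] + g[0] == pytest.approx(2.0)
    with pytest.raises(ParamError):
        recycle_manure(np.array([1.0]), np.array([1.0]),
                       ManureParams(f_grazing=1.5))


def test_net_harvest_subtraction_and_clipping(caplog):
    assert net_harvest(np.array([10.0]), np.array([3.0]))[0] == 7.0
    assert net_harvest(np.array([0.0]), np.array([0.0]))[0] == 0.0
    with caplog.at_level(logging.WARNING, logger="nitriver.terrestrial"):
        clipped = net_harvest(np.array([1.0]), np.array([4.0]))
    assert clipped[0] == 0.0
    assert "clipping" in caplog.text
    assert net_harvest(np.array([1.0]), np.array([4.0]), clip=False)[0] == -3.0


def test_tile_transition_conserves_cell_totals():
    rng = np.random.default_rng(3)
    state = TerrestrialState(rng.random((4, N_TILES, N_POOLS)))
    old = rng.dirichlet(np.ones(N_TILES), size=4) * 0.97
    new = rng.dirichlet(np.ones(N_TILES), size=4) * 0.97
    moved = apply_tile_transition(state, old, new)
    before = (state.pools * old[:, :, None]).sum(axis=1)
    after = (moved.pools * new[:, :, None]).sum(axis=1)
    np.testing.assert_allclose(after, before, rtol=1e-12)
    assert np.all(moved.pools >= 0)


def test_fertilizer_enters_cropland_only():
    params = TerrestrialParams(bnf_max=0.0, bnf_floor=0.0, bnf_cultivated=0.0)
    state = TerrestrialState.zeros(1)
    new, fl = step_terrestrial(state, make_forcing(fert=0.01), params,
                               dt=1 / 365)
    assert np.all(fl.fertilizer[:, [0, 1, 3]] == 0)
    assert fl.fertilizer[0, CROPLAND] > 0
    mineral = new.pools[:, :, AMMONIUM] + new.pools[:, :, NITRATE]
    assert mineral[0, CROPLAND] > 0
    # other tiles only ever see deposition (zero here)
    assert np.all(new.pools[0, [0, 1, 3]][:, [AMMONIUM, NITRATE]]
                  <= mineral[0, CROPLAND])


def test_manure_streams_target_cropland_and_pasture():
    params = TerrestrialParams(bnf_max=0.0, bnf_floor=0.0, bnf_cultivated=0.0)
    state = TerrestrialState.zeros(1)
    _, fl = step_terrestrial(state, make_forcing(man_m=0.01, man_g=0.004),
                             params, dt=1 / 365)
    assert np.all(fl.manure_applied[:, [0, 1]] == 0)  # primary, secondary
    assert fl.manure_applied[0, CROPLAND] > 0
    assert fl.manure_applied[0, 3] > fl.manure_applied[0, CROPLAND]
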