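import numpy as np
import pytest

from conftest import make_chain_domain
from nitriver.domain import OUTLET, build_synthetic_domain
from nitriver.freshwater import (DON, FreshwaterError, FreshwaterState, NH4,
                                 NO3, build_hydrology,
                                 denitrification_coefficient,
                                 partition_reach_lake, step_freshwater,
                                 temperature_factor)
from nitriver.params import HydroParams, RateParams


def make_hydro(domain, net, precip=1000.0, **kw):
    hp = HydroParams(**kw)
    n = domain.n_cells
    return build_hydrology(domain, net, np.full(n, precip),
                           np.full(n, hp.runoff_fraction), hp)


def test_temperature_factor_reference_is_unity():
    p = RateParams()
    assert temperature_factor(p.t_ref, p) == 1.0


def test_temperature_factor_doubles_per_ten_degrees():
    p = RateParams()
    assert temperature_factor(p.t_ref + 10, p) / temperature_factor(
        p.t_ref, p) == pytest.approx(2.0, abs=1e-12)


def test_temperature_factor_constant_ratio_property():
    p = RateParams()
    r1 = temperature_factor(25.0, p) / temperature_factor(15.0, p)
    r2 = temperature_factor(35.0, p) / temperature_factor(25.0, p)
    assert r1 == pytest.approx(r2, abs=1e-12)
    assert temperature_factor(30.0, p) > temperature_factor(20.0, p)


def test_denitrification_coefficient_anchor_point():
    p = RateParams()
    assert denitrification_coefficient(1.0, 1.0, p.t_ref, p) == pytest.approx(
        p.vf_a)


def test_denitrification_coefficient_doubles_with_ten_degrees():
    p = RateParams()
    k0 = denitrification_coefficient(1.0, 1.0, p.t_ref, p)
    k1 = denitrification_coefficient(1.0, 1.0, p.t_ref + 10, p)
    assert k1 == pytest.approx(2 * k0, rel=1e-12)


def test_denitrification_efficiency_falls_with_concentration():
    p = RateParams(vf_b=-0.5)
    k1 = denitrification_coefficient(1.0, 1.0, p.t_ref, p)
    k4 = denitrification_coefficient(4.0, 1.0, p.t_ref, p)
    assert k4 == pytest.approx(k1 / 2, rel=1e-12)


def test_denitrification_rejects_nonpositive_depth():
    with pytest.raises(FreshwaterError, match="depth"):
        denitrification_coefficient(1.0, 0.0, 20.0, RateParams())


def test_partition_reach_lake():
    reach, lake = partition_reach_lake(np.array([[8.0, 8.0, 8.0]]),
                                       np.array([0.25]))
    assert reach[0].tolist() == [6.0, 6.0, 6.0]
    assert lake[0].tolist() == [2.0, 2.0, 2.0]
    r0, l0 = partition_reach_lake(np.array([[5.0, 0, 0]]), np.array([0.0]))
    assert r0[0, 0] == 5.0 and l0[0, 0] == 0.0
    r1, l1 = partition_reach_lake(np.array([[5.0, 0, 0]]), np.array([1.0]))
    assert r1[0, 0] == 0.0 and l1[0, 0] == 5.0


def test_zero_state_zero_input_gives_zero_loads():
    domain, net, _ = make_chain_domain(3)
    hydro = make_hydro(domain, net)
    state = FreshwaterState.zeros(3)
    new, loads, denit = step_freshwater(
        state, np.zeros((3, 3)), np.full(3, 20.0), domain, net, hydro,
        RateParams(), 1 / 12)
    assert not np.any(new.river) and not np.any(loads) and not np.any(denit)


def test_conservative_tracer_reaches_steady_outlet_equal_to_input():
    """All kinetics off: at steady state the outlet exports the input."""
    domain, net, _ = make_chain_domain(3)
    p = RateParams(k_min=0.0, k_nit=0.0, vf_a=0.0)
    hydro = make_hydro(domain, net)
    dt = 1 / 73  # 5-day steps
    lateral = np.zeros((3, 3))
    lateral[0, NO3] = 1.0e6 * dt  # constant headwater input, kgN per step
    state = FreshwaterState.zeros(3)
    for _ in range(3000):
        state, loads, denit = step_freshwater(
            state, lateral, np.full(3, 20.0), domain, net, hydro, p, dt)
    assert denit.sum() == 0
    assert loads[2, NO3] == pytest.approx(lateral[0, NO3], rel=1e-9)


def test_single_reach_steady_state_matches_closed_form():
    """Constant input I with outflow q and linear denit k -> N = I/(q+k)."""
    domain, net, _ = make_chain_domain(1)
    # vf_b = 0 makes denitrification linear: k = a / depth
    p = RateParams(k_min=0.0, k_nit=0.0, vf_a=20.0, vf_b=0.0)
    hydro = make_hydro(domain, net)
    k = p.vf_a / hydro.reach_depth          # yr-1
    q = 1.0 / hydro.tau_reach               # yr-1
    I = 5.0e7                               # kgN yr-1
    dt = 1e-3 / (k + q)                     # resolve the fastest timescale
    lateral = np.zeros((1, 3))
    lateral[0, NO3] = I * dt
    state = FreshwaterState.zeros(1)
    prev = -1.0
    for i in range(40000):
        state, loads, _ = step_freshwater(
            state, lateral, np.full(1, p.t_ref), domain, net, hydro, p, dt)
        if i % 1000 == 0:
            if abs(state.river[0, NO3] - prev) < 1e-13 * max(prev, 1.0):
                break
            prev = state.river[0, NO3]
    assert state.river[0, NO3] == pytest.approx(I / (q + k), rel=1e-3)


def test_step_mass_balance_closes():
    domain, net, _ = build_synthetic_domain(4, 4, 1.0, seed=8)
    rng = np.random.default_rng(1)
    hydro = make_hydro(domain, net)
    p = RateParams()
    state = FreshwaterState(rng.random((16, 3)) * 1e5,
                            rng.random((16, 3)) * 1e4)
    state.lake[domain.lake_fraction == 0] = 0.0
    lateral = rng.random((16, 3)) * 1e4
    total0 = state.total() + lateral.sum()
    new, loads, denit = step_freshwater(
        state, lateral, np.full(16, 18.0), domain, net, hydro, p, 1 / 12)
    total1 = new.total() + loads.sum() + denit.sum()
    assert total1 == pytest.approx(total0, rel=1e-10)


def test_routing_matches_direct_linear_solve():
    """Steady-state outlet loads equal the solution of the per-step linear
    system assembled independently from the closed-form split fractions."""
    domain, net, _ = build_synthetic_domain(4, 5, 1.0, seed=6)
    domain.lake_fraction[:] = 0.0  # reaches only: keeps the system per-cell
    n = domain.n_cells
    p = RateParams(vf_b=0.0, vf_a=10.0)  # b=0 -> linear kinetics
    hydro = make_hydro(domain, net)
    dt = hydro.tau_reach  # advect a healthy fraction per step
    rng = np.random.default_rng(3)
    temp = 10.0 + 15.0 * rng.random(n)
    lateral = rng.random((n, 3)) * 1e4

    # --- oracle: assemble the 3n x 3n steady-state system directly ---
    tf = p.q10 ** ((temp - p.t_ref) / 10.0)
    em = np.exp(-p.k_min * tf * dt)
    en = np.exp(-p.k_nit * tf * dt)
    ed = np.exp(-(p.vf_a / hydro.reach_depth) * tf * dt)
    a = 1.0 - np.exp(-dt / hydro.tau_reach)
    S = np.zeros((n, 3, 3))
    for i in range(n):
        M1 = np.array([[em[i], 0, 0], [1 - em[i], 1, 0], [0, 0, 1.0]])
        M2 = np.array([[1.0, 0, 0], [0, en[i], 0], [0, 1 - en[i], 1]])
        M3 = np.diag([1.0, 1.0, ed[i]])
        S[i] = M3 @ M2 @ M1
    # unknown w_i = mass vector entering cell i's kinetics each step:
    # w_i = (1-a) S_i w_i + lateral_i + sum_{j->i} a S_j w_j
    A = np.zeros((3 * n, 3 * n))
    b = np.zeros(3 * n)
    for i in range(n):
        sl = slice(3 * i, 3 * i + 3)
        A[sl, sl] = np.eye(3) - (1 - a) * S[i]
        b[sl] = lateral[i]
        j = int(net.downstream[i])
        if j >= 0:
            A[3 * j:3 * j + 3, sl] -= a * S[i]
    w = np.linalg.solve(A, b).reshape(n, 3)
    oracle_loads = np.zeros((n, 3))
    for i in np.flatnonzero(net.downstream == OUTLET):
        oracle_loads[i] = a * S[i] @ w[i]

    # --- implementation: iterate to steady state ---
    state = FreshwaterState.zeros(n)
    for _ in range(600):
        state, loads, _ = step_freshwater(
            state, lateral, temp, domain, net, hydro, p, dt)
    np.testing.assert_allclose(loads, oracle_loads, rtol=1e-9, atol=1e-12)


def test_more_nitrate_input_never_reduces_outlet_din():
    domain, net, _ = make_chain_domain(4)
    hydro = make_hydro(domain, net)
    p = RateParams()
    base = np.zeros((4, 3))
    base[0, NO3] = 100.0
    more = base.copy()
    more[0, NO3] = 200.0

    def run(lateral):
        state = FreshwaterState.zeros(4)
        total = 0.0
        for _ in range(240):
            state, loads, _ = step_freshwater(
                state, lateral, np.full(4, 20.0), domain, net, hydro, p,
                1 / 12)
            total += loads[:, [NH4, NO3]].sum()
        return total

    assert run(more) >= run(base)


def test_transformations_never_create_don():
    domain, net, _ = make_chain_domain(3, lake_fraction=0.2)
    hydro = make_hydro(domain, net)
    state = FreshwaterState.zeros(3)
    state.river[:, DON] = 50.0
    state.lake[:, DON] = 10.0
    don0 = state.river[:, DON].sum() + state.lake[:, DON].sum()
    for _ in range(24):
        state, loads, _ = step_freshwater(
            state, np.zeros((3, 3)), np.full(3, 20.0), domain, net, hydro,
            RateParams(), 1 / 12)
        don1 = state.river[:, DON].sum() + state.lake[:, DON].sum()
        assert don1 <= don0 + 1e-12
        don0 = don1


def test_nan_in_state_identifies_cell():
    domain, net, _ = make_chain_domain(3)
    hydro = make_hydro(domain, net)
    state = FreshwaterState.zeros(3)
    state.river[1, NO3] = np.nan
    with pytest.raises(FreshwaterError, match=r"state\.river at cells \[1\]"):
        step_freshwater(state, np.zeros((3, 3)), np.full(3, 20.0), domain,
                        net, hydro, RateParams(), 1 / 12)
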