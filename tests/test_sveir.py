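"""SVEIR right-hand side, integration accuracy and limiting behaviour."""

import numpy as np
import pytest

from epicalib import SVEIRParams, SVEIRState, default_init, predicted_incidence, rhs, solve


def _rk4_oracle(params, y0, horizon, dt):
    """Brute-force fixed-step RK4 written independently of the package's
    integration kernels (plain numpy, generic slope function)."""

    def f(y):
        s, sv, e, i, r, c = y
        foi = params.beta * i / params.N
        a = foi * s
        b = (1 - params.ve) * foi * sv
        return np.array([-a, -b, a + b - params.sigma * e,
                         params.sigma * e - params.gamma * i,
                         params.gamma * i, params.sigma * e])

    steps_per_day = int(round(1.0 / dt))
    y = np.asarray(y0, dtype=float)
    out = [y.copy()]
    for _ in range(horizon):
        for _ in range(steps_per_day):
            k1 = f(y)
            k2 = f(y + dt / 2 * k1)
            k3 = f(y + dt / 2 * k2)
            k4 = f(y + dt * k3)
            y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        out.append(y.copy())
    return np.array(out)


def test_rhs_hand_value():
    # dS/dt = -beta*S*I/N with S=N, I=1: -1.5
    p = SVEIRParams(beta=1.5, gamma=0.125, N=1000)
    d = rhs(SVEIRState(s=1000, sv=0, e=0, i=1, r=0), p)
    assert d[0] == pytest.approx(-1.5)


def test_rhs_conservation_and_dfe():
    p = SVEIRParams(beta=2.0, gamma=0.3, vr=0.4, N=500)
    d = rhs(SVEIRState(s=200, sv=150, e=30, i=20, r=100), p)
    assert d[:5].sum() == pytest.approx(0.0, abs=1e-12)
    # disease-free equilibrium: no I, no E -> nothing moves
    d0 = rhs(SVEIRState(s=300, sv=200, e=0, i=0, r=0), p)
    assert np.allclose(d0, 0.0)


def test_solve_matches_fine_rk4_oracle(sveir_base):
    traj = solve(sveir_base, horizon_days=120)
    oracle = _rk4_oracle(sveir_base, default_init(sveir_base).as_array(), 120, 0.001)
    scale = np.maximum(np.abs(oracle), 1.0)
    assert np.max(np.abs(traj.states - oracle) / scale) < 1e-4


def test_solve_conservation(sveir_base):
    traj = solve(sveir_base, horizon_days=150)
    total = traj.states[:, :5].sum(axis=1)
    assert np.max(np.abs(total - sveir_base.N)) < 1e-6 * sveir_base.N


def test_beta_zero_exponential_decay():
    p = SVEIRParams(beta=1e-12, gamma=0.2, sigma=0.1, N=1000)
    init = SVEIRState(s=900, sv=0, e=0, i=100, r=0)
    traj = solve(p, init, horizon_days=30)
    expected = 100 * np.exp(-0.2 * traj.days)
    assert np.max(np.abs(traj.column("i") - expected) / expected) < 1e-6
    assert np.allclose(traj.column("s"), 900, rtol=1e-9)


def test_vr_zero_reduces_to_seir(sveir_base):
    """With nobody vaccinated the Sv compartment is empty and the model is a
    plain SEIR regardless of ve; compare against a 4-compartment SEIR
    oracle (the ve=1 trajectory with identical split)."""
    p0 = SVEIRParams(beta=1.5, gamma=0.125, vr=0.0, ve=0.97, N=9547)
    p1 = SVEIRParams(beta=1.5, gamma=0.125, vr=0.0, ve=0.0, N=9547)
    t0 = solve(p0, horizon_days=100)
    t1 = solve(p1, horizon_days=100)
    assert np.allclose(t0.states, t1.states, rtol=1e-7, atol=1e-7)
    assert np.all(t0.column("sv") == 0)


def test_fast_incidence_matches_adaptive(sveir_base):
    fast = predicted_incidence(sveir_base, horizon_days=120, fast=True)
    slow = predicted_incidence(sveir_base, horizon_days=120, fast=False)
    assert np.max(np.abs(fast - slow) / (np.abs(slow) + 1e-9)) < 1e-4


def test_incidence_nonnegative_and_mass_balance(sveir_base):
    inc = predicted_incidence(sveir_base, horizon_days=400)
    assert np.all(inc >= -1e-9)
    traj = solve(sveir_base, horizon_days=400)
    # total incidence = C(T) - C(0) = change in E+I+R
    delta = (traj.states[-1, 2:5].sum()) - (traj.states[0, 2:5].sum())
    assert inc.sum() == pytest.approx(delta, rel=1e-4)


def test_incidence_zero_without_seed():
    p = SVEIRParams(beta=1e-12, gamma=0.2, N=1000)
    init = SVEIRState(s=1000, sv=0, e=0, i=0, r=0)
    inc = predicted_incidence(p, init, horizon_days=20)
    assert np.allclose(inc, 0.0, atol=1e-12)


def test_final_size_increasing_in_beta():
    sizes = []
    for beta in (0.5, 1.0, 1.5, 2.0):
        p = SVEIRParams(beta=beta, gamma=0.125, vr=0.0, N=9547)
        sizes.append(predicted_incidence(p, horizon_days=500).sum())
    assert all(b > a for a, b in zip(sizes, sizes[1:]))


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        SVEIRParams(beta=-1, gamma=0.1)
    with pytest.raises(ValueError):
        SVEIRParams(beta=1, gamma=0.1, vr=1.5)
    with pytest.raises(ValueError):
        solve(SVEIRParams(beta=1, gamma=0.1), horizon_days=0)
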