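"""Constrained Nelder-Mead fitting and the residual bootstrap."""

import numpy as np
import pytest

from epicalib import NMConfig, SVEIRParams, bootstrap_dataset, calibrate_bootstrap, fit_nm, predicted_incidence
from epicalib.metrics import sse
from epicalib.sveir import GAMMA_BOX


def test_noiseless_self_recovery(sveir_base, noiseless_incidence):
    """A series generated by the model itself is recovered essentially
    exactly."""
    fit = fit_nm(noiseless_incidence, sveir_base)
    assert fit.beta == pytest.approx(1.5, rel=1e-3)
    assert fit.gamma == pytest.approx(0.125, rel=1e-3)


def test_gamma_outside_box_pins_at_boundary(sveir_base):
    truth = predicted_incidence(
        sveir_base.with_rates(1.0, 0.05), horizon_days=200
    )  # gamma below the box
    fit = fit_nm(truth, sveir_base)
    assert fit.gamma <= GAMMA_BOX[0] * 1.05  # active constraint


def test_fit_descends_from_initial_point(sveir_base):
    rng = np.random.default_rng(10)
    y = rng.poisson(np.maximum(predicted_incidence(sveir_base, horizon_days=100), 0))
    cfg = NMConfig()
    start_pred = predicted_incidence(
        sveir_base.with_rates(cfg.beta0, cfg.gamma0), horizon_days=100
    )
    fit = fit_nm(y.astype(float), sveir_base, cfg)
    assert fit.sse <= sse(y, start_pred)


def test_nm_config_validation():
    with pytest.raises(ValueError):
        NMConfig(beta0=3.0)  # outside box
    with pytest.raises(ValueError):
        NMConfig(maxiter=0)


def test_bootstrap_dataset_properties(sveir_base, noiseless_incidence):
    rng = np.random.default_rng(0)
    fitted = noiseless_incidence
    observed = fitted + rng.normal(0, 2, size=len(fitted))
    residuals = observed - fitted
    new = bootstrap_dataset(observed, fitted, np.random.default_rng(1))
    assert new.shape == fitted.shape
    assert np.all(new >= 0)
    # every resampled residual comes from the empirical residual multiset
    implied = new - np.clip(fitted, None, None)
    pool = np.round(residuals, 9)
    clipped = np.isclose(new, 0.0)
    for v in np.round(implied[~clipped], 9):
        assert v in pool


def test_bootstrap_zero_residuals_reproduces_fit(noiseless_incidence):
    for seed in range(5):
        new = bootstrap_dataset(
            noiseless_incidence, noiseless_incidence, np.random.default_rng(seed)
        )
        assert np.allclose(new, noiseless_incidence)


def test_bootstrap_mean_converges_to_fitted_plus_mean_residual():
    """Law of large numbers: averaging many bootstrap series approaches
    fitted + mean(residuals)."""
    rng = np.random.default_rng(5)
    fitted = np.full(30, 50.0)
    observed = fitted + rng.normal(0, 5, 30)
    residuals = observed - fitted
    acc = np.zeros_like(fitted)
    n = 10_000
    g = np.random.default_rng(6)
    for _ in range(n):
        acc += bootstrap_dataset(observed, fitted, g)
    mc_err = 5 * residuals.std() / np.sqrt(n)
    assert np.allclose(acc / n, fitted + residuals.mean(), atol=mc_err + 0.1)


def test_calibrate_bootstrap_degenerate_noiseless(sveir_base, noiseless_incidence):
    """Zero residuals make every bootstrap dataset identical, so the 100
    refits collapse onto one point."""
    cfg = NMConfig(n_bootstrap=100, seed=3)
    s = calibrate_bootstrap(noiseless_incidence, sveir_base, cfg)
    assert s.n_draws == 100
    for par in ("beta", "infectious_period", "rc"):
        q = s.quantile_summary(par)
        assert q.values[-1] - q.values[0] < 1e-3
        assert all(b >= a for a, b in zip(q.values, q.values[1:]))
    assert 0.0 <= s.divergence_fraction <= 1.0


def test_calibrate_bootstrap_recovery_under_noise(sveir_base):
    """Median bootstrap estimates recover the generating parameters within
    10% on a pre-registered noisy dataset (seed 2025)."""
    truth = predicted_incidence(sveir_base, horizon_days=150)
    y = np.random.default_rng(2025).poisson(truth).astype(float)
    s = calibrate_bootstrap(y, sveir_base, NMConfig(n_bootstrap=60, seed=1))
    assert np.median(s.beta) == pytest.approx(1.5, rel=0.10)
    assert np.median(s.gamma) == pytest.approx(0.125, rel=0.10)
    # deterministic given seed
    s2 = calibrate_bootstrap(y, sveir_base, NMConfig(n_bootstrap=60, seed=1))
    assert np.array_equal(s.beta, s2.beta)
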