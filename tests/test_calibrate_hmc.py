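"""HMC sampler: leapfrog mechanics, known-distribution targets, prior
recovery and posterior parameter recovery."""

import numpy as np
import pytest
from scipy import stats

from epicalib import HMCConfig, SVEIRParams, diagnostics, log_joint, predicted_incidence, sample
from epicalib.calibrate_hmc import leapfrog, run_hmc
from epicalib.samples import CalibrationSamples
from epicalib.sveir import BETA_BOX, GAMMA_BOX


def _gaussian_target(theta):
    return -0.5 * float(theta @ theta), -theta


def test_leapfrog_reversibility():
    """Integrating L steps, flipping momentum, and integrating L steps
    returns the start point (time reversibility)."""
    rng = np.random.default_rng(0)
    theta0 = rng.normal(size=2)
    rho0 = rng.normal(size=2)
    t1, r1, _, _ = leapfrog(_gaussian_target, theta0, rho0, 0.1, 25)
    t2, r2, _, _ = leapfrog(_gaussian_target, t1, -r1, 0.1, 25)
    assert np.max(np.abs(t2 - theta0)) < 1e-8
    assert np.max(np.abs(-r2 - rho0)) < 1e-8


def test_gaussian_target_moments():
    """Standard-Gaussian validation: sample mean within +-0.05 and variance
    within [0.9, 1.1] at 4000 draws."""
    cfg = HMCConfig(chains=4, warmup=500, iterations=1000, seed=11,
                    init_step_size=0.5, leapfrog_steps=10)
    inits = np.random.default_rng(1).normal(size=(4, 2))
    out = run_hmc(_gaussian_target, inits, cfg)
    draws = out["draws"].reshape(-1, 2)
    assert draws.shape[0] == 4000
    assert np.all(np.abs(draws.mean(axis=0)) < 0.05)
    assert np.all((draws.var(axis=0) > 0.9) & (draws.var(axis=0) < 1.1))
    assert not out["divergent"].any()


def test_prior_recovery_flat_likelihood(sveir_base):
    """With the likelihood switched off the sampler must reproduce the
    truncated LogNormal(0,1) prior: quantiles of log(beta) match the
    truncated Normal within MCMC error."""
    cfg = HMCConfig(chains=4, warmup=400, iterations=1000, likelihood="none",
                    seed=5, init_step_size=0.5)
    y = np.zeros(10)  # ignored by the flat likelihood
    s = sample(y, sveir_base, cfg)
    a, b = np.log(BETA_BOX)
    tn = stats.truncnorm(a, b)
    logb = np.log(s.beta)
    for q in (0.25, 0.5, 0.75):
        assert np.quantile(logb, q) == pytest.approx(tn.ppf(q), abs=0.08)
    # gamma box too
    ag, bg = np.log(GAMMA_BOX)
    tng = stats.truncnorm(ag, bg)
    assert np.median(np.log(s.gamma)) == pytest.approx(tng.ppf(0.5), abs=0.08)


def test_log_joint_properties(sveir_base, noiseless_incidence):
    y = np.round(noiseless_incidence)
    lp_close = log_joint(1.5, 0.125, y, sveir_base)
    lp_far = log_joint(2.4, 0.9, y, sveir_base)
    assert lp_close > lp_far  # likelihood falls as series diverge
    assert log_joint(1.5, 0.125, y, sveir_base) == lp_close  # purity
    with pytest.raises(ValueError):
        log_joint(3.0, 0.125, y, sveir_base)


def test_posterior_recovery(sveir_base):
    """Posterior median within 10% of generating values and 95% interval
    covering the truth on the pre-registered noisy dataset (seed 2025)."""
    truth = predicted_incidence(sveir_base, horizon_days=150)
    y = np.random.default_rng(2025).poisson(truth).astype(float)
    cfg = HMCConfig(chains=4, warmup=300, iterations=300, seed=2026)
    s = sample(y, sveir_base, cfg, gt_id="recovery")
    assert np.median(s.beta) == pytest.approx(1.5, rel=0.10)
    assert np.median(s.gamma) == pytest.approx(0.125, rel=0.10)
    lo_b, hi_b = np.quantile(s.beta, [0.025, 0.975])
    lo_g, hi_g = np.quantile(s.gamma, [0.025, 0.975])
    assert lo_b <= 1.5 <= hi_b
    assert lo_g <= 0.125 <= hi_g
    # every draw respects the box
    assert np.all((s.beta >= BETA_BOX[0]) & (s.beta <= BETA_BOX[1]))
    assert np.all((s.gamma >= GAMMA_BOX[0]) & (s.gamma <= GAMMA_BOX[1]))
    assert 0.0 <= s.divergence_fraction <= 1.0
    d = diagnostics(s)
    assert d["rhat_beta"] < 1.1 and d["rhat_gamma"] < 1.1


def test_acceptance_rule_is_metropolis():
    """The transition rule is exactly min(1, exp(H - H*)), with non-finite
    energy drift never accepted; and step-size adaptation, which targets a
    configured mean of that acceptance probability, lands near its target
    on the Gaussian validation density."""
    from epicalib.calibrate_hmc import accept_probability

    assert accept_probability(-2.0) == 1.0  # energy fell: always accept
    assert accept_probability(0.0) == 1.0
    assert accept_probability(1.5) == pytest.approx(np.exp(-1.5))
    assert accept_probability(np.inf) == 0.0
    assert accept_probability(np.nan) == 0.0

    cfg = HMCConfig(chains=2, warmup=300, iterations=300, seed=4,
                    target_accept=0.95, init_step_size=0.5, leapfrog_steps=8)
    out = run_hmc(_gaussian_target, np.zeros((2, 2)), cfg)
    assert np.all(np.abs(out["accept_rate"] - 0.95) < 0.12)


def test_diagnostics_degenerate_chains_flagged():
    s = CalibrationSamples(
        gt_id="x", method="HMC",
        beta=np.full(40, 1.0), gamma=np.full(40, 0.5),
        divergent=np.zeros(40, bool), mase=np.full(40, 0.5),
        vr=0.0, ve=0.97, chain=np.repeat([0, 1], 20),
    )
    d = diagnostics(s)  # identical constant chains: R-hat undefined
    assert np.isnan(d["rhat_beta"]) or d["rhat_beta"] > 1.0


def test_hmc_config_validation():
    with pytest.raises(ValueError):
        HMCConfig(chains=1)
    with pytest.raises(ValueError):
        HMCConfig(likelihood="gamma")
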