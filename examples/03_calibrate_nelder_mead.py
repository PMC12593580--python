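"""Calibrate the SVEIR model to a noisy outbreak with Nelder-Mead and
quantify uncertainty with a residual bootstrap.

The 'observed' data here are a model-generated incidence curve with Poisson
noise, so the generating parameters (beta = 1.5, gamma = 0.125) are known
and recovery can be judged directly.
"""

import numpy as np

from epicalib import NMConfig, SVEIRParams, calibrate_bootstrap, predicted_incidence

base = SVEIRParams(beta=1.5, gamma=0.125, sigma=0.1, ve=0.97, vr=0.5, N=9547)
truth = predicted_incidence(base, horizon_days=150)
observed = np.random.default_rng(2025).poisson(truth).astype(float)

samples = calibrate_bootstrap(observed, base, NMConfig(n_bootstrap=100, seed=1))

q_beta = samples.quantile_summary("beta")
q_ip = samples.quantile_summary("infectious_period")
print(f"initial fit: beta={samples.meta['initial_beta']:.3f} "
      f"gamma={samples.meta['initial_gamma']:.4f}")
print(f"bootstrap beta quantiles (2.5/50/97.5%): "
      f"{q_beta.values[0]:.3f} / {q_beta.median:.3f} / {q_beta.values[-1]:.3f}")
print(f"infectious period median: {q_ip.median:.2f} days (truth: 8)")
print(f"mean MASE vs ground truth: {samples.mean_mase:.3f} "
      f"(<1 beats the naive one-step forecast)")
print(f"refits hitting the iteration cap: {100 * samples.divergence_fraction:.0f}%")
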