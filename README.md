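# epicalib

Evaluating epidemic-model calibration against a known generative truth.

When an SEIR-type compartmental model is calibrated to real outbreak data,
the recovered parameters are *effective* quantities: the fitted infectious
period absorbs isolation behaviour, the fitted transmission rate absorbs
the population's immunity and contact structure, and neither can be
checked because the truth is unknown. `epicalib` rebuilds the full
evaluation loop with a truth that *is* known: a stochastic agent-based
model (ABM) of a measles outbreak in a synthetic town generates daily
incidence under nine intervention scenarios — self-isolation rates of
0/50/100% crossed with vaccination coverage of 0/50/80% — and a
deterministic SVEIR model is calibrated to each replicate by two routes:

* **Nelder-Mead + residual bootstrap** — constrained least squares
  (SSE = Σ(Yᵢ−Fᵢ)²) over (β, γ) with β ∈ [0.125, 2.5], γ ∈ [0.1, 1],
  plus 100 bootstrap refits for uncertainty;
* **Hamiltonian Monte Carlo** — Poisson observation model on daily
  incidence, LogNormal(0, 1) priors truncated to the same box, leapfrog
  integration with exact ODE gradients from forward sensitivity equations.

The SVEIR model splits susceptibles into unvaccinated S and vaccinated Sv
(force of infection reduced by 1 − ve):

    dS/dt  = −βSI/N                 dSv/dt = −(1−ve)βSvI/N
    dE/dt  = βSI/N + (1−ve)βSvI/N − σE
    dI/dt  = σE − γI                dR/dt  = γI          dC/dt = σE

with σ = 1/10 d⁻¹, ve = 0.97 fixed to the generator's values and daily
incidence the first difference of the cumulative counter C. Methods are
compared on MASE, MAE and RRMSE, and on the recovered infectious period
1/γ, transmission rate β and control reproduction number

    R_c = (1 − vr)·R_u + vr·R_v,   R_u = β/γ,   R_v = (1 − ve)·R_u

(at R0 = 12, ve = 0.97: R_c = 6.18 for 50% coverage, 2.69 for 80%).
Per-replicate quantiles are aggregated across a scenario's ground truths
by a weighted median with weights ∝ 1/(mean MASE). See
`docs/methods.md` for the full model description and design choices.

## Worked example

`examples/04_calibrate_hmc.py` generates a noisy outbreak from the SVEIR
model itself (β = 1.5, γ = 0.125, 50% vaccination, N = 9547, Poisson
noise) and calibrates it back:

```
posterior median beta  = 1.477  (truth 1.5)
posterior median gamma = 0.1187 (truth 0.125)
implied infectious period: 8.43 days
control reproduction number R_c median: 6.40
divergent transitions: 0.00%
split R-hat: beta 1.016, gamma 1.018; bulk ESS: beta 146, gamma 134
```

Both parameters are recovered within ~5%, the implied infectious period
(8.4 days) brackets the 8-day truth, and R̂ ≈ 1 with zero divergences
indicates healthy sampling. The other examples cover the ABM generator
(`01`, printing the measured contact-derived infection probability,
outbreak length and final size), the deterministic model (`02`), the
Nelder-Mead bootstrap (`03`) and a miniature end-to-end scenario study
(`05`, emitting the accuracy and ensemble-quantile tables plus the
qualitative-findings report).

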