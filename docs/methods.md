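# Methods

## Overview

`epicalib` implements a closed experimental loop for evaluating epidemic
model calibration: a stochastic agent-based model (ABM) of a measles
outbreak in a synthetic town generates "ground truth" daily incidence under
nine intervention scenarios (self-isolation 0/50/100% crossed with
vaccination coverage 0/50/80%); a deterministic SVEIR compartmental model
is calibrated to each replicate by (i) constrained Nelder-Mead least
squares with a residual bootstrap and (ii) Hamiltonian Monte Carlo; the two
inference routes are compared on forecast accuracy (MASE, MAE, RRMSE) and
on the recovered effective parameters — the infectious period 1/γ, the
transmission rate β, and the control reproduction number R_c. Because the
generator's truth is fully known, any systematic drift in the recovered
parameters across scenarios measures how behavioural change (isolation,
immunity) is absorbed into the *effective* parameters of a homogeneous
process model.

## The agent-based generator

**Town.** A rectangular grid of cells is zoned residential, commercial/
industrial, community or empty by configured fractions (defaults 0.45 /
0.15 / 0.15). Households with sizes drawn from an Irish-like distribution
(mean ≈ 2.7) occupy residential cells and are grouped into contiguous
"small areas" of roughly 50–200 dwellings at the default population of
9547 agents. Schools sit on community cells, workplaces on commercial
cells. Each household is the first 1–2 members adult, the rest children;
children are primary- or secondary-level students attending the school of
their level nearest their home; adults are working / retired / unemployed
(0.6 / 0.2 / 0.2).

**Contact spaces.** "Sharing physical space" is the contact primitive.
Space is finer than the geographic grid: each dwelling is a private space
shared only by its household; each school is partitioned into classrooms
of 25 and each workplace into offices of 15; community and residential
street cells are public. This granularity matters: with whole buildings as
single spaces the measured contact rate `c` is inflated by two orders of
magnitude and the per-contact infectivity p = R0/(c·d) becomes so small
that the household secondary attack risk falls to ~45%, far below the
~90% reported for measles. With room-scale spaces the desk-scale town
measures c ≈ 2.7 pair-contacts per agent-tick and p ≈ 0.05, giving a
household secondary attack risk of ~95%.

**Schedule and movement.** Time advances in 2-hour ticks, 12 per day. On
weekdays students and workers are at their classroom/office from tick 4
(08:00) to tick 8 (16:00) and home otherwise, travelling the whole trip in
one tick. Everyone else — and everyone at weekends — picks a uniform
random community/residential street cell each daytime tick and is home at
night. Summer holidays are not modelled.

**Disease.** Measles natural history: exposed period ~ Normal(10, 0.5)
days, infectious period ~ Normal(8, 0.5) days, each converted to ticks,
rounded, floored at one tick. R0 = 12; the time-per-infection d is 96
ticks (8 days). `c` is measured on a 14-day disease-free rehearsal run
with isolation disabled, then p = R0/(c·d), clamped to [0, 1]. Each
co-located susceptible–infectious pair triggers an independent Bernoulli(p)
trial per tick; a vaccinated susceptible additionally escapes with
probability ve = 0.97 (two-dose MMR effectiveness). Exactly
round(vr·N) agents are vaccinated, uniformly at random regardless of age.
One unvaccinated index case starts infectious; the run ends at extinction
(E + I = 0) or a safety cap (730 days).

**Isolation.** An infectious agent stays home with the scenario's
isolation probability, drawn independently each tick; at rate 1.0 they
never leave. Because dwellings are private spaces, full isolation confines
transmission to the household. A consequence worth stating plainly: with
100% isolation an outbreak can only percolate within households and is
therefore subcritical at any vaccination level (≈ 0.35–1.6 expected
secondary cases depending on coverage), so the 100%-isolation scenarios
produce small outbreaks. A model that lets visitors share an isolating
agent's home space would instead sustain large epidemics under full
isolation; we deliberately exclude that leakage — isolation that isolates
is the cleaner experiment, and the disease-extinction contract for
singleton households requires it.

**Incidence.** "New cases per day" counts entries into the infectious
state (E→I), matching the process model's cumulative-case counter C with
dC/dt = σE. Daily compartment counts satisfy S + E + I + R = N exactly.

**First-peak truncation.** Multi-wave runs (the outbreak jumping between
contact pools) are restricted to their first wave before calibration: the
daily incidence is smoothed with a centred 7-day moving average; after the
global maximum, the first local minimum below 20% of the peak that is
followed (past any flat plateau) by three consecutive strict rises marks
the cut. Unimodal runs pass through unchanged; the rule is idempotent.

## The SVEIR process model

Unvaccinated susceptibles S, vaccinated susceptibles Sv (force of
infection multiplied by 1 − ve), exposed E, infectious I, recovered R, and
a cumulative-case counter C:

    S'  = −βSI/N        Sv' = −(1−ve)βSvI/N
    E'  = βSI/N + (1−ve)βSvI/N − σE
    I'  = σE − γI       R'  = γI        C' = σE

σ = 1/10 d⁻¹ and ve = 0.97 are fixed to the generator's values; vr and N
come from the scenario and trace; only β and γ are calibrated, boxed to
β ∈ [0.125, 2.5], γ ∈ [0.1, 1] (infectious period 1–10 days, implied R0
0.125–25). Initial condition mirrors the ABM: I0 = 1, E0 = R0 = C0 = 0,
Sv0 = vr(N−1), S0 = (1−vr)(N−1).

**Numerics.** `solve()` integrates with an adaptive Runge-Kutta (scipy
RK45, rtol 1e-8, atol 1e-10) sampled on integer days, clipping round-off
negatives. Calibration loops use a numba-compiled fixed-step RK4 at 20
substeps/day, which agrees with the adaptive solution to ~1e-7 relative
and evaluates in ~0.2 ms; its forward sensitivity equations (12 extra
states) supply exact likelihood gradients for HMC (verified against
central finite differences to 1e-9 relative).

## Calibration

**Nelder-Mead + residual bootstrap.** The simplex minimizes the sum of
squared errors between observed and predicted daily incidence, started
from (β, γ) = (1.5, 1/8), capped at 700 iterations; hitting the cap marks
the fit divergent. The box is enforced exactly by running the simplex on a
logit-rescaled parameterization. Uncertainty: 100 residual-bootstrap
datasets (fitted series plus residuals resampled with replacement, clipped
at zero since incidence is a count), each refitted starting from the
original optimum; every refit is scored by MASE against the original
ground truth.

**HMC.** Self-implemented sampler: leapfrog integration with identity
mass, dual-averaging step-size adaptation (target acceptance 0.8) during
warm-up, and a per-iteration path length jittered uniformly in [L/2, L]
(L = 20) to avoid periodic trajectories. Default runs use 4 chains of
1000 warm-up + 1000 sampling iterations. Parameters are sampled on the
logit-of-box scale with the Jacobian in the density, so draws respect the
box exactly. Priors: LogNormal(0, 1) truncated to the box, independently
for β and γ. The observation model — which the calibration problem leaves
open — is Poisson on daily incidence with rate max(prediction, 1e-6); a
negative-binomial alternative (dispersion φ, default 10) sits behind
`likelihood="negbin"` for sensitivity analysis. A transition is flagged
divergent when the Hamiltonian drifts by more than 1000 nats (the
conventional threshold) or turns non-finite; divergence fractions are
reported per run but depend on the (unstated-in-the-source) likelihood, so
only their order of magnitude is meaningful. Split-R̂ and bulk ESS come
from arviz.

**Metrics.** SSE, MAE, MASE (MAE over all n points divided by the
in-sample one-step naive forecast MAE over n−1 differences) and RRMSE
(RMSE divided by the observed mean). Per ground truth, each metric is the
arithmetic mean over all parameter draws; degenerate cases (constant
observed series for MASE, nonpositive mean for RRMSE) are excluded with a
warning rather than propagating infinities.

**Ensembles.** Per ground truth, parameter draws are summarized at the
2.5/5/25/50/75/95/97.5% quantiles (linear interpolation). Across the
replicates of a scenario, each quantile level is combined by a weighted
median with weights ∝ 1/(mean MASE), one shared weight per ground truth;
ties at cumulative weight 0.5 resolve to the lower value for determinism.
Per-level weighted medians can in principle break cross-level
monotonicity; that is detected and logged, never silently re-sorted.

**Reproduction numbers.** Ru = β/γ; the default vaccinated-branch
convention is Rv = (1 − ve)·Ru, giving the scenario ground truths
R_c = 6.18 (vr = 0.5) and 2.688 (vr = 0.8) at R0 = 12, ve = 0.97. An
alternative convention Rv = ve·Ru (`rv_formula="as_printed"`, exposed on
samples as `rc_literal`) makes R_c ≈ β/γ; the cross-scenario *stability*
analysis uses this quantity, because "β and the infectious period change
in tandem" is a statement about their product — under the (1 − ve)
convention R_c scales with coverage by construction and cannot be stable
across vaccination levels.

## Scenario study

`run_study` expands a master seed into per-(scenario, run, stage) seeds via
numpy SeedSequence spawn keys, caches traces and samples as CSV (resumable,
bit-identical on resume thanks to round-trip float parsing), and emits six
tables: Nelder-Mead divergence percentages, accuracy by scenario and
method, HMC divergence percentages, and ensemble quantiles for infectious
period, β and R_c. Every run with a non-degenerate incidence series is
calibrated — including the tiny household outbreaks of the
100%-isolation scenarios, whose short effective infectious periods are part
of the phenomenon under study; only all-zero series (index case infects
nobody) are excluded, since MASE is undefined for a constant series.

The qualitative findings report checks: (a) the median calibrated
infectious period at 80% vaccination strictly decreases as isolation goes
0 → 50 → 100%; (b) cross-scenario coefficient of variation of ensemble
R_c medians (literal convention) versus β medians; (c) all draws inside
the box; (d) mean final outbreak size decreasing in vaccination coverage.

## Problem sizes and what the tests show

Default configs are the full study conditions (9547 agents, 50
replicates, 100 bootstrap, 4×(1000+1000) HMC). The test suite and the
acceptance script run desk-scale versions — ~1000-agent towns, 4–6
replicates per scenario, 50–100 bootstrap refits, 2–4 chains of a few
hundred iterations — chosen so the full loop runs in minutes while keeping
every generator *condition* (R0, periods, ve, the scenario grid) at its
study value. Parameter-recovery checks use model-generated data with
Poisson noise, where truth is known exactly. One caveat quantified during
development: with σ = 0.1 < γ the latent period dominates the post-peak
decay, leaving γ weakly identified by a single realization (sampling
spread ≈ 13%); recovery assertions therefore sit at a fixed,
pre-registered dataset seed, and both estimators are unbiased in
expectation.

The synthetic generator emulates the *structure* of a census-built Irish
town (zones, households, schools, schedules) but not its geography, age
pyramid, or empirical contact matrix; passing tests demonstrate internal
consistency of the inference loop and reproduction of the study's
qualitative contrasts, not calibration of any real outbreak.

## Known limitations

- Effective infectious periods and transmission rates absorb all model
  mismatch between the heterogeneous generator and the homogeneous SVEIR
  model; they are not biological estimates.
- Under full isolation transmission is household-limited by design (see
  above), so 100%-isolation scenarios yield small outbreaks; analyses that
  depend on large epidemics under full isolation are sensitive to this
  modelling choice.
- The HMC divergence percentages are not comparable to any external
  implementation because the observation likelihood is a package choice.
- Age-structured mixing, reporting delay/under-reporting, inter-town
  travel, stochastic process models and forecasting are out of scope.
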