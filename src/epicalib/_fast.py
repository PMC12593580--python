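"""Numba kernels: fixed-step RK4 SVEIR integration with forward sensitivities.

Calibration needs on the order of 1e5 incidence evaluations (and their
gradients with respect to beta and gamma) per ground truth; these kernels
keep that affordable. State layout is ``[S, Sv, E, I, R, C]``; the augmented
system appends the 6 sensitivities to beta and the 6 to gamma (18 states).

The public adaptive solver lives in :mod:`epicalib.sveir`; tests pin these
kernels against it.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

#: substeps per day for the fixed-step RK4 used in calibration loops
DEFAULT_SUBSTEPS = 20


@njit(cache=True)
def _rhs(y, beta, gamma, sigma, ve, n_pop, out):
    s, sv, e, i = y[0], y[1], y[2], y[3]
    foi = beta * i / n_pop
    a = foi * s
    b = (1.0 - ve) * foi * sv
    out[0] = -a
    out[1] = -b
    out[2] = a + b - sigma * e
    out[3] = sigma * e - gamma * i
    out[4] = gamma * i
    out[5] = sigma * e


@njit(cache=True)
def _rhs_aug(y, beta, gamma, sigma, ve, n_pop, out):
    """Augmented RHS: state plus sensitivities d/dbeta (y[6:12]) and
    d/dgamma (y[12:18])."""
    s, sv, e, i = y[0], y[1], y[2], y[3]
    _rhs(y[:6], beta, gamma, sigma, ve, n_pop, out[:6])
    # Jacobian-vector products J @ u + df/dtheta
    k = beta / n_pop
    kv = (1.0 - ve) * k
    for block, extra in ((6, 0), (12, 1)):
        us, usv, ue, ui = y[block], y[block + 1], y[block + 2], y[block + 3]
        ja = -k * (i * us + s * ui)  # d(-beta S I/N)
        jb = -kv * (i * usv + sv * ui)
        out[block] = ja
        out[block + 1] = jb
        out[block + 2] = -ja - jb - sigma * ue
        out[block + 3] = sigma * ue - gamma * ui
        out[block + 4] = gamma * ui
        out[block + 5] = sigma * ue
        if extra == 0:  # df/dbeta
            pa = -s * i / n_pop
            pb = -(1.0 - ve) * sv * i / n_pop
            out[block] += pa
            out[block + 1] += pb
            out[block + 2] += -pa - pb
        else:  # df/dgamma
            out[block + 3] += -i
            out[block + 4] += i


@njit(cache=True)
def integrate_states(beta, gamma, sigma, ve, n_pop, y0, horizon, substeps):
    """Fixed-step RK4 over [0, horizon] days; returns (horizon+1, 6) states."""
    y = y0.copy()
    out = np.empty((horizon + 1, 6))
    out[0] = y
    h = 1.0 / substeps
    k1 = np.empty(6)
    k2 = np.empty(6)
    k3 = np.empty(6)
    k4 = np.empty(6)
    for d in range(horizon):
        for _ in range(substeps):
            _rhs(y, beta, gamma, sigma, ve, n_pop, k1)
            _rhs(y + 0.5 * h * k1, beta, gamma, sigma, ve, n_pop, k2)
            _rhs(y + 0.5 * h * k2, beta, gamma, sigma, ve, n_pop, k3)
            _rhs(y + h * k3, beta, gamma, sigma, ve, n_pop, k4)
            y = y + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        out[d + 1] = y
    return out


@njit(cache=True)
def incidence_and_sens(beta, gamma, sigma, ve, n_pop, y0, horizon, substeps):
    """Daily incidence (first differences of C) and its sensitivities.

    Returns ``(inc, dinc_dbeta, dinc_dgamma)``, each length ``horizon``.
    """
    y = np.zeros(18)
    y[:6] = y0
    h = 1.0 / substeps
    k1 = np.empty(18)
    k2 = np.empty(18)
    k3 = np.empty(18)
    k4 = np.empty(18)
    inc = np.empty(horizon)
    db = np.empty(horizon)
    dg = np.empty(horizon)
    c_prev, cb_prev, cg_prev = y[5], y[11], y[17]
    for d in range(horizon):
        for _ in range(substeps):
            _rhs_aug(y, beta, gamma, sigma, ve, n_pop, k1)
            _rhs_aug(y + 0.5 * h * k1, beta, gamma, sigma, ve, n_pop, k2)
            _rhs_aug(y + 0.5 * h * k2, beta, gamma, sigma, ve, n_pop, k3)
            _rhs_aug(y + h * k3, beta, gamma, sigma, ve, n_pop, k4)
            y = y + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        inc[d] = y[5] - c_prev
        db[d] = y[11] - cb_prev
        dg[d] = y[17] - cg_prev
        c_prev, cb_prev, cg_prev = y[5], y[11], y[17]
    return inc, db, dg


@njit(cache=True)
def predicted_incidence_fast(beta, gamma, sigma, ve, n_pop, y0, horizon, substeps):
    """Daily incidence only (no sensitivities)."""
    states = integrate_states(beta, gamma, sigma, ve, n_pop, y0, horizon, substeps)
    inc = np.empty(horizon)
    for d in range(horizon):
        v = states[d + 1, 5] - states[d, 5]
        inc[d] = v if v > 0.0 else 0.0
    return inc


@njit(cache=True)
def _sigmoid(t):
    if t >= 0.0:
        return 1.0 / (1.0 + math.exp(-t))
    z = math.exp(t)
    return z / (1.0 + z)


@njit(cache=True)
def logpost_and_grad(
    theta,
    y_obs,
    lo,
    hi,
    sigma,
    ve,
    n_pop,
    y0,
    substeps,
    likelihood_code,
    nb_phi,
):
    """Log posterior density and gradient in the unconstrained space.

    ``theta`` is the logit transform of box-scaled (beta, gamma). The prior
    on each natural parameter is LogNormal(0, 1) truncated to the box (the
    truncation constant is parameter-free and omitted); the log-Jacobian of
    the transform is included so the density is with respect to theta.

    ``likelihood_code``: 0 = Poisson on daily incidence, 1 = negative
    binomial with dispersion ``nb_phi``, 2 = none (prior-only).
    """
    x = np.empty(2)
    s01 = np.empty(2)
    lp = 0.0
    grad = np.empty(2)
    for k in range(2):
        s = _sigmoid(theta[k])
        s01[k] = s
        x[k] = lo[k] + (hi[k] - lo[k]) * s
        # truncated LogNormal(0,1) prior on x, plus transform Jacobian
        logx = math.log(x[k])
        lp += -logx - 0.5 * logx * logx
        lp += math.log(hi[k] - lo[k]) + math.log(s) + math.log(1.0 - s)
        dprior_dx = -(1.0 + logx) / x[k]
        dxdt = (hi[k] - lo[k]) * s * (1.0 - s)
        grad[k] = dprior_dx * dxdt + (1.0 - 2.0 * s)

    if likelihood_code != 2:
        horizon = y_obs.shape[0]
        inc, db, dg = incidence_and_sens(
            x[0], x[1], sigma, ve, n_pop, y0, horizon, substeps
        )
        dll_db = 0.0
        dll_dg = 0.0
        for t in range(horizon):
            lam = inc[t]
            if lam < 1e-6:
                lam = 1e-6
            y = y_obs[t]
            if likelihood_code == 0:  # Poisson (constants dropped)
                lp += y * math.log(lam) - lam
                w = y / lam - 1.0
            else:  # negative binomial, mean lam, dispersion phi
                lp += (
                    math.lgamma(y + nb_phi)
                    - math.lgamma(nb_phi)
                    - math.lgamma(y + 1.0)
                    + nb_phi * math.log(nb_phi / (nb_phi + lam))
                    + y * math.log(lam / (nb_phi + lam))
                )
                w = y / lam - (y + nb_phi) / (nb_phi + lam)
            if inc[t] >= 1e-6:  # clamped rate has zero sensitivity
                dll_db += w * db[t]
                dll_dg += w * dg[t]
        for k in range(2):
            dxdt = (hi[k] - lo[k]) * s01[k] * (1.0 - s01[k])
            grad[k] += (dll_db if k == 0 else dll_dg) * dxdt

    if not (math.isfinite(lp) and math.isfinite(grad[0]) and math.isfinite(grad[1])):
        return -np.inf, np.zeros(2)
    return lp, grad
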