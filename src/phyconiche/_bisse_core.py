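"""Numerical core for the BiSSE likelihood (numba-jitted).

Integrates the coupled BiSSE ordinary differential equations for the
extinction probabilities E₀, E₁ and data probabilities D₀, D₁ backward
along every branch with an adaptive Dormand–Prince RK5(4) scheme, and
prunes the tree in postorder, combining daughters at each node as
D_s = λ_s · D_left,s · D_right,s.  D is renormalised after every branch
and node (the log of the running normalisation is accumulated) so the
computation never underflows on large trees.

Status codes returned alongside the log-likelihood:
    0  ok
    1  ODE step-size underflow (integration failure)
    2  extinction probability left [0,1] by more than 1e-8
"""

from __future__ import annotations

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_ODE_FAILURE = 1
STATUS_E_OUT_OF_RANGE = 2

ROOT_OBS = 0
ROOT_FLAT = 1
ROOT_FIXED0 = 2
ROOT_FIXED1 = 3


@njit(cache=True)
def _deriv(y, p, out):
    lam0, lam1, mu0, mu1, q01, q10 = p[0], p[1], p[2], p[3], p[4], p[5]
    e0, e1, d0, d1 = y[0], y[1], y[2], y[3]
    out[0] = mu0 - (lam0 + mu0 + q01) * e0 + q01 * e1 + lam0 * e0 * e0
    out[1] = mu1 - (lam1 + mu1 + q10) * e1 + q10 * e0 + lam1 * e1 * e1
    out[2] = -(lam0 + mu0 + q01) * d0 + q01 * d1 + 2.0 * lam0 * e0 * d0
    out[3] = -(lam1 + mu1 + q10) * d1 + q10 * d0 + 2.0 * lam1 * e1 * d1


@njit(cache=True)
def _integrate(y, t_end, p, rtol, atol):
    """Advance y over [0, t_end] in place; returns a status code."""
    if t_end <= 0.0:
        return STATUS_OK
    t = 0.0
    rate_scale = p[0] + p[1] + p[2] + p[3] + p[4] + p[5] + 1e-12
    h = min(t_end, 0.1 / rate_scale)
    k = np.empty((7, 4))
    y4 = np.empty(4)
    y5 = np.empty(4)
    ytmp = np.empty(4)
    n_steps = 0
    while t < t_end:
        if n_steps > 100000:
            return STATUS_ODE_FAILURE
        if h < 1e-14 * max(t_end, 1.0):
            return STATUS_ODE_FAILURE
        if t + h > t_end:
            h = t_end - t
        _deriv(y, p, k[0])
        for i in range(4):
            ytmp[i] = y[i] + h * (0.2 * k[0, i])
        _deriv(ytmp, p, k[1])
        for i in range(4):
            ytmp[i] = y[i] + h * (3.0 / 40.0 * k[0, i] + 9.0 / 40.0 * k[1, i])
        _deriv(ytmp, p, k[2])
        for i in range(4):
            ytmp[i] = y[i] + h * (
                44.0 / 45.0 * k[0, i] - 56.0 / 15.0 * k[1, i] + 32.0 / 9.0 * k[2, i]
            )
        _deriv(ytmp, p, k[3])
        for i in range(4):
            ytmp[i] = y[i] + h * (
                19372.0 / 6561.0 * k[0, i]
                - 25360.0 / 2187.0 * k[1, i]
                + 64448.0 / 6561.0 * k[2, i]
                - 212.0 / 729.0 * k[3, i]
            )
        _deriv(ytmp, p, k[4])
        for i in range(4):
            ytmp[i] = y[i] + h * (
                9017.0 / 3168.0 * k[0, i]
                - 355.0 / 33.0 * k[1, i]
                + 46732.0 / 5247.0 * k[2, i]
                + 49.0 / 176.0 * k[3, i]
                - 5103.0 / 18656.0 * k[4, i]
            )
        _deriv(ytmp, p, k[5])
        for i in range(4):
            y5[i] = y[i] + h * (
                35.0 / 384.0 * k[0, i]
                + 500.0 / 1113.0 * k[2, i]
                + 125.0 / 192.0 * k[3, i]
                - 2187.0 / 6784.0 * k[4, i]
                + 11.0 / 84.0 * k[5, i]
            )
        _deriv(y5, p, k[6])
        for i in range(4):
            y4[i] = y[i] + h * (
                5179.0 / 57600.0 * k[0, i]
                + 7571.0 / 16695.0 * k[2, i]
                + 393.0 / 640.0 * k[3, i]
                - 92097.0 / 339200.0 * k[4, i]
                + 187.0 / 2100.0 * k[5, i]
                + 1.0 / 40.0 * k[6, i]
            )
        err = 0.0
        for i in range(4):
            sc = atol + rtol * max(abs(y[i]), abs(y5[i]))
            e = (y5[i] - y4[i]) / sc
            err += e * e
        err = np.sqrt(err / 4.0)
        if err <= 1.0:
            t += h
            for i in range(4):
                y[i] = y5[i]
            for i in range(2):
                if y[i] < -1e-8 or y[i] > 1.0 + 1e-8:
                    return STATUS_E_OUT_OF_RANGE
                if y[i] < 0.0:
                    y[i] = 0.0
                elif y[i] > 1.0:
                    y[i] = 1.0
            n_steps += 1
        factor = 0.9 * err ** (-0.2) if err > 1e-10 else 5.0
        if factor > 5.0:
            factor = 5.0
        elif factor < 0.2:
            factor = 0.2
        h *= factor
    return STATUS_OK


@njit(cache=True)
def bisse_loglik_core(
    child_left,
    child_right,
    blen,
    tip_state,
    postorder,
    n_tips,
    params,
    root_mode,
    condition_on_survival,
    rtol,
    atol,
):
    n_nodes = child_left.shape[0]
    vals = np.zeros((n_nodes, 4))
    log_comp = 0.0
    for i in range(n_tips):
        y = np.zeros(4)
        s = tip_state[i]
        if s == 0:
            y[2] = 1.0
        elif s == 1:
            y[3] = 1.0
        else:  # unknown state: both possible
            y[2] = 1.0
            y[3] = 1.0
        status = _integrate(y, blen[i], params, rtol, atol)
        if status != STATUS_OK:
            return np.nan, status, i
        norm = y[2] + y[3]
        if norm <= 0.0:
            return -np.inf, STATUS_OK, i
        y[2] /= norm
        y[3] /= norm
        log_comp += np.log(norm)
        for c in range(4):
            vals[i, c] = y[c]
    root = postorder[postorder.shape[0] - 1]
    for idx in range(postorder.shape[0]):
        i = postorder[idx]
        l = child_left[i]
        r = child_right[i]
        y = np.empty(4)
        y[0] = 0.5 * (vals[l, 0] + vals[r, 0])
        y[1] = 0.5 * (vals[l, 1] + vals[r, 1])
        y[2] = params[0] * vals[l, 2] * vals[r, 2]
        y[3] = params[1] * vals[l, 3] * vals[r, 3]
        norm = y[2] + y[3]
        if norm <= 0.0:
            return -np.inf, STATUS_OK, i
        y[2] /= norm
        y[3] /= norm
        log_comp += np.log(norm)
        if i != root:
            status = _integrate(y, blen[i], params, rtol, atol)
            if status != STATUS_OK:
                return np.nan, status, i
            norm = y[2] + y[3]
            if norm <= 0.0:
                return -np.inf, STATUS_OK, i
            y[2] /= norm
            y[3] /= norm
            log_comp += np.log(norm)
        for c in range(4):
            vals[i, c] = y[c]
    d0 = vals[root, 2]
    d1 = vals[root, 3]
    e0 = vals[root, 0]
    e1 = vals[root, 1]
    if root_mode == ROOT_OBS:
        w0 = d0 / (d0 + d1)
    elif root_mode == ROOT_FLAT:
        w0 = 0.5
    elif root_mode == ROOT_FIXED0:
        w0 = 1.0
    else:
        w0 = 0.0
    w1 = 1.0 - w0
    lik = w0 * d0 + w1 * d1
    if condition_on_survival:
        denom = w0 * params[0] * (1.0 - e0) ** 2 + w1 * params[1] * (1.0 - e1) ** 2
        if denom <= 0.0:
            return np.nan, STATUS_ODE_FAILURE, root
        lik /= denom
    if lik <= 0.0:
        return -np.inf, STATUS_OK, root
    return np.log(lik) + log_comp, STATUS_OK, root
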