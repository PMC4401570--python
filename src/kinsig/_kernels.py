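"""Compiled nested-sampling kernel for the signature models.

The generic sampler in :mod:`kinsig.nested` accepts arbitrary Python
callables and is the reference path; fitting five models to thousands of
clusters needs the whole loop (signature evaluation, L1 likelihood,
constrained walk, shell quadrature) fused into one nopython kernel.
The algorithm is the same shell construction with deterministic shrinkage
``ln X_i = -i/n_live``; agreement between the two paths is asserted in the
test suite.

Kind codes: 0 early_peak, 1 late_peak, 2 dip, 3 decay, 4 linear.
Replicates arrive as a rectangular (n_times, max_reps) array padded with
NaN where a time point has fewer replicates.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

LOG01 = math.log(0.1)
LN2 = math.log(2.0)

KIND_CODES = {"early_peak": 0, "late_peak": 1, "dip": 2, "decay": 3, "linear": 4}


@njit(cache=True)
def _loglike_kind(kind, p, times, reps, medians, eps_floor, t_end):
    """L1 log-likelihood of one parameter vector for one signature kind."""
    m = times.size
    total = 0.0
    for t in range(m):
        tt = times[t]
        if kind == 0 or kind == 1:  # peak (early/late share the form)
            ts = p[2]
            dlt = LOG01 / ts
            if tt <= ts:
                mu = p[0] + p[1] * (1.0 - math.exp(dlt * tt))
            else:
                mu = p[0] + 0.9 * p[1] - 0.9 * p[1] * (1.0 - math.exp(dlt * (tt - ts)))
        elif kind == 2:  # dip
            ts = p[2]
            dlt = LOG01 / ts
            if tt <= ts:
                mu = p[0] + p[1] * math.exp(dlt * tt)
            else:
                mu = p[0] + 0.1 * p[1] + 0.9 * p[1] * (1.0 - math.exp(dlt * (tt - ts)))
        elif kind == 3:  # decay
            mu = p[0] + p[1] * math.exp(-(LN2 / p[2]) * tt)
        else:  # linear
            mu = p[0] + p[1] * tt / t_end
        s = 0.0
        cnt = 0
        for j in range(reps.shape[1]):
            v = reps[t, j]
            if not np.isnan(v):
                s += abs(v - mu)
                cnt += 1
        eps = s / cnt
        if eps < eps_floor:
            eps = eps_floor
        total += -math.log(2.0 * eps) - abs(medians[t] - mu) / eps
    return total


@njit(cache=True)
def ns_signature_run(
    kind,
    lo,
    hi,
    times,
    reps,
    medians,
    eps_floor,
    t_end,
    n_live,
    max_iter,
    tol,
    n_steps,
    init_step,
    rng,
):
    """One nested-sampling run for one (time course, signature kind) pair.

    Returns ``(log_z, h, n_iter, dead_par, dead_logl, dead_logw, status)``;
    ``status`` is 1 if the likelihood produced NaN (dead arrays truncated),
    else 0. ``dead_par`` holds parameter-space coordinates.
    """
    d = lo.size
    width = hi - lo
    live_u = np.empty((n_live, d))
    live_logl = np.empty(n_live)
    p = np.empty(d)
    for i in range(n_live):
        for k in range(d):
            live_u[i, k] = rng.random()
            p[k] = lo[k] + live_u[i, k] * width[k]
        v = _loglike_kind(kind, p, times, reps, medians, eps_floor, t_end)
        if math.isnan(v):
            return (0.0, 0.0, 0, np.empty((0, d)), np.empty(0), np.empty(0), 1)
        live_logl[i] = v

    cap = max_iter + n_live
    dead_par = np.empty((cap, d))
    dead_logl = np.empty(cap)
    dead_logw = np.empty(cap)
    n_dead = 0

    log_z = -np.inf
    h = 0.0
    step = init_step
    log_width_factor = math.log(1.0 - math.exp(-1.0 / n_live))
    log_x = 0.0
    n_iter = 0
    status = 0

    for it in range(1, max_iter + 1):
        worst = 0
        for i in range(1, n_live):
            if live_logl[i] < live_logl[worst]:
                worst = i
        log_l_star = live_logl[worst]
        log_w = log_x + log_width_factor
        log_x = -it / n_live

        log_z_new = np.logaddexp(log_z, log_l_star + log_w)
        if np.isfinite(log_z_new):
            if np.isfinite(log_z):
                h = (
                    math.exp(log_l_star + log_w - log_z_new) * log_l_star
                    + math.exp(log_z - log_z_new) * (h + log_z)
                    - log_z_new
                )
            else:
                h = math.exp(log_l_star + log_w - log_z_new) * log_l_star - log_z_new
        log_z = log_z_new

        for k in range(d):
            dead_par[n_dead, k] = lo[k] + live_u[worst, k] * width[k]
        dead_logl[n_dead] = log_l_star
        dead_logw[n_dead] = log_w
        n_dead += 1

        # constrained Metropolis walk from a random live point
        start = int(rng.random() * n_live)
        if start == n_live:
            start = n_live - 1
        u = live_u[start].copy()
        cur_logl = live_logl[start]
        n_accept = 0
        n_reject = 0
        for _ in range(n_steps):
            ok = True
            prop = np.empty(d)
            for k in range(d):
                prop[k] = u[k] + step * rng.standard_normal()
                if prop[k] < 0.0 or prop[k] > 1.0:
                    ok = False
            if ok:
                for k in range(d):
                    p[k] = lo[k] + prop[k] * width[k]
                logl_prop = _loglike_kind(kind, p, times, reps, medians, eps_floor, t_end)
                if math.isnan(logl_prop):
                    status = 1
                    break
                if logl_prop >= log_l_star:
                    u = prop
                    cur_logl = logl_prop
                    n_accept += 1
                    continue
            n_reject += 1
        if status == 1:
            break
        if n_accept > n_reject:
            step *= math.exp(1.0 / max(n_accept, 1))
        elif n_reject > n_accept:
            step /= math.exp(1.0 / max(n_reject, 1))
        if step < 1e-6:
            step = 1e-6
        elif step > 1.0:
            step = 1.0

        live_u[worst] = u
        live_logl[worst] = cur_logl
        n_iter = it

        best = live_logl[0]
        for i in range(1, n_live):
            if live_logl[i] > best:
                best = live_logl[i]
        if best + log_x < math.log(tol) + log_z:
            break

    if status == 0:
        log_w_live = log_x - math.log(n_live)
        for j in range(n_live):
            log_z_new = np.logaddexp(log_z, live_logl[j] + log_w_live)
            h = (
                math.exp(live_logl[j] + log_w_live - log_z_new) * live_logl[j]
                + math.exp(log_z - log_z_new) * (h + log_z)
                - log_z_new
            )
            log_z = log_z_new
            for k in range(d):
                dead_par[n_dead, k] = lo[k] + live_u[j, k] * width[k]
            dead_logl[n_dead] = live_logl[j]
            dead_logw[n_dead] = log_w_live
            n_dead += 1

    return (
        log_z,
        h,
        n_iter,
        dead_par[:n_dead],
        dead_logl[:n_dead],
        dead_logw[:n_dead],
        status,
    )
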