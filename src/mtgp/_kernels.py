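"""Numba-compiled inner loop of the single-site Gibbs marker sweep.

The sweep mutates effects, indicators and residuals in place and draws from
the ``numpy.random.Generator`` passed in, so the random stream is shared
with (and interleaves correctly with) the pure-Python update steps that run
between sweeps.  :func:`mtgp.gibbs.update_indicator_and_effects` is the
reference implementation of one marker update; the two are kept in lockstep
(same arithmetic, same draw order) and cross-checked in the test suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["sweep_markers"]


@njit(cache=True)
def sweep_markers(
    X,          # (n_total, m) float64, Fortran order, stacked by effect group
    e,          # (n_total,) residuals, updated in place
    offsets,    # (c+1,) int64 row offsets of effect groups
    xtx,        # (c, m) precomputed x'x per group
    effects,    # (m, c) SNP effects, updated in place
    gamma,      # (m,) int8 inclusion indicators, updated in place
    w,          # exclusion probability, fixed during the sweep
    sigma2_a,   # (c,) slab variances
    sigma2_e,   # (c,) residual variances
    order,      # (m,) int64 marker visit order
    rng,        # np.random.Generator
):
    """One full sweep of joint (gamma_j, a_j.) updates over all markers.

    For each marker j the inclusion log-odds pool evidence over all effect
    groups; gamma_j is drawn Bernoulli(1/(1+q_j)), then each group's effect
    is drawn from its conditional normal (or set to zero), and residuals are
    updated incrementally.
    """
    m = effects.shape[0]
    c = offsets.shape[0] - 1
    logit_w = np.log(w) - np.log(1.0 - w)
    mu_hat = np.empty(c)
    s2_hat = np.empty(c)
    for t in range(m):
        j = order[t]
        logq = logit_w
        for k in range(c):
            lo = offsets[k]
            hi = offsets[k + 1]
            xx = xtx[k, j]
            xe = 0.0
            for i in range(lo, hi):
                xe += X[i, j] * e[i]
            xy = xe + xx * effects[j, k]
            denom = xx + sigma2_e[k] / sigma2_a[k]
            mh = xy / denom
            sh = sigma2_e[k] / denom
            mu_hat[k] = mh
            s2_hat[k] = sh
            logq += 0.5 * np.log(xx * sigma2_a[k] / sigma2_e[k] + 1.0)
            logq -= 0.5 * mh * mh / sh
        if logq >= 0.0:
            ex = np.exp(-logq)
            p_incl = ex / (1.0 + ex)
        else:
            p_incl = 1.0 / (1.0 + np.exp(logq))
        u = rng.random()
        if u < p_incl:
            gamma[j] = 1
            for k in range(c):
                a_new = mu_hat[k] + np.sqrt(s2_hat[k]) * rng.standard_normal()
                diff = a_new - effects[j, k]
                if diff != 0.0:
                    for i in range(offsets[k], offsets[k + 1]):
                        e[i] -= X[i, j] * diff
                effects[j, k] = a_new
        else:
            gamma[j] = 0
            for k in range(c):
                a_old = effects[j, k]
                if a_old != 0.0:
                    for i in range(offsets[k], offsets[k + 1]):
                        e[i] += X[i, j] * a_old
                    effects[j, k] = 0.0
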