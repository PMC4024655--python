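"""Independent brute-force references used by the test suite.

These deliberately avoid the package's own update formulas: the
enumeration oracle integrates SNP effects out of the exact multivariate
normal marginal likelihood per inclusion configuration, which is feasible
only for a handful of markers.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import stats


def enumeration_inclusion_probs(
    X_by_pop: dict[str, np.ndarray],
    y_by_pop: dict[str, np.ndarray],
    w: float,
    sigma2_a: dict[str, float],
    sigma2_e: dict[str, float],
    mu: dict[str, float],
) -> np.ndarray:
    """Exact marginal inclusion probabilities with variances, w and mu known.

    For each configuration gamma of the m indicators, effects are integrated
    analytically: y_k - mu_k ~ N(0, sigma2_ak X_gamma X_gamma' + I sigma2_ek),
    and the prior is prod_j w^(1-gamma_j) (1-w)^gamma_j.  Returns the
    posterior mean of each gamma_j over all 2^m configurations.
    """
    pops = list(X_by_pop)
    m = X_by_pop[pops[0]].shape[1]
    configs = list(itertools.product([0, 1], repeat=m))
    log_post = np.empty(len(configs))
    for c_idx, gamma in enumerate(configs):
        g = np.asarray(gamma, dtype=bool)
        lp = np.sum(np.where(g, np.log(1.0 - w), np.log(w)))
        for pop in pops:
            Xk = X_by_pop[pop]
            yk = y_by_pop[pop] - mu[pop]
            n_k = Xk.shape[0]
            cov = sigma2_e[pop] * np.eye(n_k)
            if g.any():
                Xg = Xk[:, g]
                cov = cov + sigma2_a[pop] * (Xg @ Xg.T)
            lp += stats.multivariate_normal.logpdf(yk, mean=np.zeros(n_k), cov=cov)
        log_post[c_idx] = lp
    post = np.exp(log_post - log_post.max())
    post /= post.sum()
    probs = np.zeros(m)
    for c_idx, gamma in enumerate(configs):
        probs += post[c_idx] * np.asarray(gamma)
    return probs


def scaled_inv_chi2_moments(df: float, scale: float) -> tuple[float, float]:
    """Mean and variance of a scaled-inverse-chi-square distribution."""
    mean = df * scale / (df - 2.0)
    var = 2.0 * df**2 * scale**2 / ((df - 2.0) ** 2 * (df - 4.0))
    return mean, var
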