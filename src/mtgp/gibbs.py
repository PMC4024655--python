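"""Spike-and-slab Gibbs samplers for multi-population genomic prediction.

Three whole-genome regression models share one sampling engine:

``run_multi_task``
    Each population k has its own intercept mu_k, SNP effects a_jk, slab
    variance sigma2_ak and residual variance sigma2_ek, but all populations
    share a single vector of latent SNP-inclusion indicators gamma_j.  The
    indicator update pools evidence across populations, which is how a
    small population borrows information from a large one.

``run_single_task``
    The classical one-population spike-and-slab regression (BayesC-pi style
    prior with an estimated exclusion probability w): the multi-task model
    with c = 1.

``run_pooled``
    All populations stacked into one training set with population origin as
    a fixed effect (per-population intercepts) and one shared effect vector,
    slab variance and residual variance.

Model, per population k::

    y_ik = mu_k + sum_j x_ijk a_jk + e_ik,      e_ik ~ N(0, sigma2_ek)
    a_jk | gamma_j ~ gamma_j N(0, sigma2_ak) + (1 - gamma_j) delta_0
    gamma_j | w ~ Bernoulli(1 - w),             w ~ Uniform(0, 1)
    sigma2_ak ~ ScaledInvChi2(v_a, s2_a),       sigma2_ek ~ ScaledInvChi2(v_e, s2_e)

The sampler is a systematic-scan Gibbs chain with joint (gamma_j, a_j.)
updates and incremental residual bookkeeping, so one sweep costs O(n m).
The marker loop is compiled with numba (:mod:`mtgp._kernels`); the
conditional-update operations below are the pure-Python reference versions
used for small problems and for verification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from ._kernels import sweep_markers

__all__ = [
    "PriorSpec",
    "GibbsConfig",
    "MCMCState",
    "PosteriorSummary",
    "derive_scale",
    "inclusion_log_odds",
    "update_indicator_and_effects",
    "sample_w",
    "sample_sigma2_a",
    "sample_sigma2_e",
    "sample_mu",
    "run_multi_task",
    "run_single_task",
    "run_pooled",
]

# state is declared divergent when a variance leaves this interval
_VAR_FLOOR = 1e-12
_VAR_CEIL = 1e12
_RESID_RTOL = 1e-8


def derive_scale(sigma2: float, v: float) -> float:
    """Scale of a scaled-inverse-chi-square with mean ``sigma2``.

    E[sigma2] = S2 v / (v - 2) for v > 2, hence S2 = sigma2 (v - 2) / v.
    Used to anchor the variance priors at known (true or REML-estimated)
    variances.
    """
    if v <= 2:
        raise ValueError("degrees of freedom must exceed 2 to have a finite mean")
    if sigma2 < 0:
        raise ValueError("variance must be non-negative")
    return sigma2 * (v - 2.0) / v


@dataclass(frozen=True)
class PriorSpec:
    """Hyper-parameters of the variance priors, per effect group.

    ``s2_a``/``s2_e`` may be scalars (broadcast) or one value per group:
    populations for the multi-task model, a single group for the
    single-task and pooled models.
    """

    v_a: float = 4.0
    s2_a: np.ndarray | float = 0.5
    v_e: float = 10.0
    s2_e: np.ndarray | float = 0.8

    def __post_init__(self) -> None:
        if self.v_a <= 2 or self.v_e <= 2:
            raise ValueError("prior degrees of freedom must exceed 2")
        for name in ("s2_a", "s2_e"):
            val = np.atleast_1d(np.asarray(getattr(self, name), dtype=float))
            if (val <= 0).any():
                raise ValueError(f"{name} must be positive")
            object.__setattr__(self, name, val)

    def broadcast(self, c: int) -> "PriorSpec":
        """Return a copy with per-group scale arrays of length ``c``."""
        for name in ("s2_a", "s2_e"):
            size = np.asarray(getattr(self, name)).size
            if size not in (1, c):
                raise ValueError(
                    f"prior {name} has {size} values but the model has {c} "
                    f"effect group(s)"
                )
        s2_a = np.broadcast_to(self.s2_a, (c,)).astype(float).copy()
        s2_e = np.broadcast_to(self.s2_e, (c,)).astype(float).copy()
        return PriorSpec(self.v_a, s2_a, self.v_e, s2_e)

    @classmethod
    def from_variances(
        cls,
        sigma2_a: Sequence[float] | float,
        sigma2_e: Sequence[float] | float,
        v_a: float = 4.0,
        v_e: float = 10.0,
    ) -> "PriorSpec":
        """Anchor the priors so their means equal the given variances."""
        s2_a = np.array([derive_scale(s, v_a) for s in np.atleast_1d(sigma2_a)])
        s2_e = np.array([derive_scale(s, v_e) for s in np.atleast_1d(sigma2_e)])
        return cls(v_a, s2_a, v_e, s2_e)


@dataclass(frozen=True)
class GibbsConfig:
    """Chain-length, seeding and update-control settings.

    ``w_posterior_form`` selects the Beta update for the exclusion
    probability: ``conjugate_plus_one`` (default) draws
    Beta(m - sum(gamma) + 1, sum(gamma) + 1), the exact conditional under
    the Uniform(0,1) prior; ``as_printed`` draws Beta(m - sum(gamma),
    sum(gamma)) with both parameters floored at 1e-8 so the density stays
    proper at the boundaries.

    The ``update_*`` switches freeze individual blocks at their initial
    values; they exist for calibration experiments (e.g. validating the
    indicator update against exhaustive enumeration with variances known).
    ``validate_every`` > 0 re-derives the residuals from scratch every that
    many sweeps and checks them against the incrementally maintained vector.
    """

    n_iter: int = 50_000
    burn_in: int = 10_000
    seed: int = 0
    thin: int = 1
    w_posterior_form: str = "conjugate_plus_one"
    shuffle_update_order: bool = False
    update_w: bool = True
    update_variances: bool = True
    update_mu: bool = True
    init_w: float = 0.5
    init_sigma2_a: Optional[Sequence[float]] = None
    init_sigma2_e: Optional[Sequence[float]] = None
    init_mu: Optional[Sequence[float]] = None
    record_trace: bool = False
    validate_every: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("need 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if not 0.0 < self.init_w < 1.0:
            raise ValueError("init_w must lie in (0, 1)")
        if self.w_posterior_form not in ("conjugate_plus_one", "as_printed"):
            raise ValueError(f"unknown w_posterior_form {self.w_posterior_form!r}")

    @property
    def n_recorded(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


@dataclass
class MCMCState:
    """All Gibbs unknowns plus the bookkeeping needed for O(n) updates.

    Rows of ``X`` are stacked by effect group (``offsets`` gives group
    boundaries); ``mu_offsets`` partitions the same rows into intercept
    groups, which differ from effect groups only in the pooled model (one
    shared effect group, per-population intercepts).  The residual identity
    e = y - mu - X a is maintained incrementally and can be re-checked via
    :meth:`residual_dev`.
    """

    X: np.ndarray            # (n_total, m), Fortran order
    y: np.ndarray            # (n_total,)
    offsets: np.ndarray      # (c_eff + 1,) effect-group row offsets
    mu_offsets: np.ndarray   # (c_mu + 1,) intercept-group row offsets
    mu_group_eff: np.ndarray  # (c_mu,) effect group owning each intercept group
    xtx: np.ndarray          # (c_eff, m)
    mu: np.ndarray           # (c_mu,)
    effects: np.ndarray      # (m, c_eff)
    gamma: np.ndarray        # (m,) int8
    w: float
    sigma2_a: np.ndarray     # (c_eff,)
    sigma2_e: np.ndarray     # (c_eff,)
    residuals: np.ndarray    # (n_total,)

    @property
    def n_groups(self) -> int:
        return len(self.offsets) - 1

    @property
    def n_markers(self) -> int:
        return self.effects.shape[0]

    def group_rows(self, k: int) -> slice:
        return slice(int(self.offsets[k]), int(self.offsets[k + 1]))

    def mu_rows(self, k: int) -> slice:
        return slice(int(self.mu_offsets[k]), int(self.mu_offsets[k + 1]))

    def fitted_residuals(self) -> np.ndarray:
        """Recompute y - mu - X a from scratch (no incremental bookkeeping)."""
        r = self.y.copy()
        for k in range(len(self.mu_offsets) - 1):
            r[self.mu_rows(k)] -= self.mu[k]
        for k in range(self.n_groups):
            rows = self.group_rows(k)
            r[rows] -= self.X[rows, :] @ self.effects[:, k]
        return r

    def residual_dev(self) -> float:
        """Max absolute deviation between stored and recomputed residuals."""
        return float(np.max(np.abs(self.fitted_residuals() - self.residuals), initial=0.0))


@dataclass
class PosteriorSummary:
    """Posterior means over recorded post-burn-in samples.

    ``effect_mean`` averages every recorded draw of a_jk including the
    zeros from excluded sweeps (unconditional posterior means), so GEBV can
    be formed by a plain dot product.  ``inclusion_prob`` is the posterior
    mean of gamma_j.
    """

    populations: list[str]          # effect-group labels
    mu_populations: list[str]       # intercept-group labels
    effect_mean: np.ndarray         # (m, c_eff)
    inclusion_prob: np.ndarray      # (m,)
    mu_mean: np.ndarray             # (c_mu,)
    w_mean: float
    sigma2_a_mean: np.ndarray
    sigma2_e_mean: np.ndarray
    n_samples_used: int
    max_residual_dev: float = 0.0
    marker_ids: Optional[list[str]] = None
    trace: Optional[pd.DataFrame] = None
    meta: dict = field(default_factory=dict)

    def effects_for(self, population: str) -> np.ndarray:
        """Effect column for a population (shared column for pooled fits)."""
        if population in self.populations:
            return self.effect_mean[:, self.populations.index(population)]
        if len(self.populations) == 1:
            return self.effect_mean[:, 0]
        raise KeyError(f"population {population!r} not in summary")

    def intercept_for(self, population: str) -> float:
        return float(self.mu_mean[self.mu_populations.index(population)])


# ---------------------------------------------------------------------------
# conditional-update operations (pure-Python reference implementations)
# ---------------------------------------------------------------------------

def _sigmoid_neg(logq: float) -> float:
    """1 / (1 + exp(logq)), branch-stable; mirrors the compiled kernel."""
    if logq >= 0.0:
        ex = np.exp(-logq)
        return ex / (1.0 + ex)
    return 1.0 / (1.0 + np.exp(logq))


def _marker_conditionals(j: int, state: MCMCState) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-group conditional mean/variance of a_jk plus the pooled log q_j.

    x'_jk y*_k is recovered from the maintained residuals as
    x' e + x'x a_jk(current), avoiding any O(nm) recomputation.
    """
    c = state.n_groups
    mu_hat = np.empty(c)
    s2_hat = np.empty(c)
    logq = np.log(state.w) - np.log(1.0 - state.w)
    for k in range(c):
        rows = state.group_rows(k)
        xx = state.xtx[k, j]
        # sequential accumulation, bit-identical to the compiled sweep
        # (BLAS dot products use a different summation order)
        xe = 0.0
        for xi, ei in zip(state.X[rows, j], state.residuals[rows]):
            xe += xi * ei
        xy = xe + xx * state.effects[j, k]
        denom = xx + state.sigma2_e[k] / state.sigma2_a[k]
        mu_hat[k] = xy / denom
        s2_hat[k] = state.sigma2_e[k] / denom
        logq += 0.5 * np.log(xx * state.sigma2_a[k] / state.sigma2_e[k] + 1.0)
        logq -= 0.5 * mu_hat[k] ** 2 / s2_hat[k]
    return mu_hat, s2_hat, logq


def inclusion_log_odds(j: int, state: MCMCState) -> float:
    """log q_j, the log odds of *excluding* marker j.

    q_j = w/(1-w) * prod_k sqrt(x'x sigma2_ak / sigma2_ek + 1)
          * exp(-1/2 sum_k mu_hat_jk^2 / s2_hat_jk),

    where mu_hat_jk and s2_hat_jk are the conditional posterior mean and
    variance of a_jk given inclusion.  gamma_j is then Bernoulli with
    success probability 1/(1+q_j).  Evidence from every group enters the
    product/sum, which is the information-sharing step of the multi-task
    model.  Computed entirely in log space.
    """
    if (state.sigma2_a <= 0).any() or (state.sigma2_e <= 0).any():
        raise ValueError("variances must be positive")
    return _marker_conditionals(j, state)[2]


def update_indicator_and_effects(j: int, state: MCMCState, rng: np.random.Generator) -> None:
    """Jointly draw gamma_j and then a_jk | gamma_j for every group.

    gamma_j = 0 zeroes all a_jk (the spike); gamma_j = 1 draws each a_jk
    from N(mu_hat_jk, s2_hat_jk) independently.  Residuals are shifted by
    -x_jk (a_new - a_old) for every group whose effect changed.
    """
    mu_hat, s2_hat, logq = _marker_conditionals(j, state)
    p_incl = _sigmoid_neg(logq)
    u = rng.random()
    if u < p_incl:
        state.gamma[j] = 1
        for k in range(state.n_groups):
            a_new = mu_hat[k] + np.sqrt(s2_hat[k]) * rng.standard_normal()
            diff = a_new - state.effects[j, k]
            if diff != 0.0:
                rows = state.group_rows(k)
                state.residuals[rows] -= state.X[rows, j] * diff
            state.effects[j, k] = a_new
    else:
        state.gamma[j] = 0
        for k in range(state.n_groups):
            a_old = state.effects[j, k]
            if a_old != 0.0:
                rows = state.group_rows(k)
                state.residuals[rows] += state.X[rows, j] * a_old
                state.effects[j, k] = 0.0


def sample_w(
    gamma: np.ndarray,
    m: int,
    form: str = "conjugate_plus_one",
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Draw the exclusion probability w from its Beta full conditional.

    ``conjugate_plus_one``: Beta(m - sum(gamma) + 1, sum(gamma) + 1), the
    exact posterior under the Uniform(0,1) prior.  ``as_printed``:
    Beta(m - sum(gamma), sum(gamma)) with parameters floored at 1e-8 so the
    density stays proper when sum(gamma) is 0 or m.
    """
    if rng is None:
        rng = np.random.default_rng()
    s = float(np.sum(gamma))
    if form == "conjugate_plus_one":
        alpha, beta = m - s + 1.0, s + 1.0
    elif form == "as_printed":
        alpha, beta = max(m - s, 1e-8), max(s, 1e-8)
    else:
        raise ValueError(f"unknown w posterior form {form!r}")
    # keep w strictly inside (0, 1): the indicator update needs log(w) and
    # log(1 - w), and boundary draws occur in as_printed mode
    return float(np.clip(rng.beta(alpha, beta), 1e-12, 1.0 - 1e-12))


def _scaled_inv_chi2(df: float, scale: float, rng: np.random.Generator) -> float:
    """Draw X ~ ScaledInvChi2(df, scale): X = df * scale / chi2(df)."""
    return df * scale / float(rng.chisquare(df))


def sample_sigma2_a(
    k: int, state: MCMCState, prior: PriorSpec, rng: np.random.Generator
) -> float:
    """Slab-variance draw for group k: ScaledInvChi2 with df v_a + sum(gamma)
    and scale (v_a s2_a + sum_j gamma_j a_jk^2) / (v_a + sum(gamma)).

    Excluded effects are zero by the spike constraint, so the plain sum of
    squared effects equals the sum over included markers.
    """
    s_gamma = float(np.sum(state.gamma))
    ssq = float(state.effects[:, k] @ state.effects[:, k])
    df = prior.v_a + s_gamma
    scale = (prior.v_a * float(np.asarray(prior.s2_a)[k]) + ssq) / df
    return _scaled_inv_chi2(df, scale, rng)


def sample_sigma2_e(
    k: int, state: MCMCState, prior: PriorSpec, rng: np.random.Generator
) -> float:
    """Residual-variance draw for group k: ScaledInvChi2 with df v_e + n_k
    and scale (v_e s2_e + e_k' e_k) / (v_e + n_k)."""
    rows = state.group_rows(k)
    n_k = rows.stop - rows.start
    ete = float(state.residuals[rows] @ state.residuals[rows])
    df = prior.v_e + n_k
    scale = (prior.v_e * float(np.asarray(prior.s2_e)[k]) + ete) / df
    return _scaled_inv_chi2(df, scale, rng)


def sample_mu(k: int, state: MCMCState, rng: np.random.Generator) -> float:
    """Intercept draw for intercept group k and residual shift.

    The full conditional is N(mean(y_k - X_k a_k), sigma2_ek / n_k); with
    maintained residuals this is N(mu_k + mean(e_k), sigma2_ek / n_k).
    Residuals are shifted by -(mu_new - mu_old).
    """
    rows = state.mu_rows(k)
    n_k = rows.stop - rows.start
    s2e = state.sigma2_e[int(state.mu_group_eff[k])]
    mean = state.mu[k] + float(np.mean(state.residuals[rows]))
    mu_new = mean + np.sqrt(s2e / n_k) * float(rng.standard_normal())
    state.residuals[rows] -= mu_new - state.mu[k]
    state.mu[k] = mu_new
    return mu_new


# ---------------------------------------------------------------------------
# chain driver
# ---------------------------------------------------------------------------

def _stack_groups(
    X_by: Mapping[str, np.ndarray], y_by: Mapping[str, np.ndarray]
) -> tuple[list[str], np.ndarray, np.ndarray, np.ndarray]:
    labels = list(X_by)
    if set(y_by) != set(labels):
        raise ValueError("genotype and phenotype groups must match")
    Xs, ys, offsets = [], [], [0]
    m = None
    for lab in labels:
        Xk = np.asarray(X_by[lab], dtype=float)
        yk = np.asarray(y_by[lab], dtype=float).ravel()
        if Xk.ndim != 2 or Xk.shape[0] != yk.shape[0]:
            raise ValueError(f"group {lab!r}: genotype/phenotype shapes disagree")
        if Xk.shape[0] == 0:
            raise ValueError(f"group {lab!r} has no samples")
        if m is None:
            m = Xk.shape[1]
        elif Xk.shape[1] != m:
            raise ValueError("all groups must share one marker set and order")
        if np.isnan(Xk).any():
            raise ValueError("genotypes entering the sampler must be complete")
        Xs.append(Xk)
        ys.append(yk)
        offsets.append(offsets[-1] + Xk.shape[0])
    if m is None or m == 0:
        raise ValueError("no markers")
    X = np.asfortranarray(np.vstack(Xs))
    return labels, X, np.concatenate(ys), np.asarray(offsets, dtype=np.int64)


def _init_state(
    X: np.ndarray,
    y: np.ndarray,
    offsets: np.ndarray,
    mu_offsets: np.ndarray,
    mu_group_eff: np.ndarray,
    prior: PriorSpec,
    cfg: GibbsConfig,
) -> MCMCState:
    """Prior-mean start: gamma = 0, a = 0, mu_k = group phenotype mean."""
    c_eff = len(offsets) - 1
    c_mu = len(mu_offsets) - 1
    m = X.shape[1]
    xtx = np.empty((c_eff, m))
    for k in range(c_eff):
        block = X[offsets[k]: offsets[k + 1], :]
        xtx[k] = np.einsum("ij,ij->j", block, block)
    if cfg.init_mu is not None:
        mu = np.asarray(cfg.init_mu, dtype=float).copy()
        if mu.shape != (c_mu,):
            raise ValueError("init_mu length must equal intercept-group count")
    else:
        mu = np.array(
            [float(np.mean(y[mu_offsets[k]: mu_offsets[k + 1]])) for k in range(c_mu)]
        )
    if cfg.init_sigma2_a is not None:
        sigma2_a = np.broadcast_to(
            np.asarray(cfg.init_sigma2_a, dtype=float), (c_eff,)
        ).copy()
    else:
        sigma2_a = np.asarray(prior.s2_a) * prior.v_a / (prior.v_a - 2.0)
    if cfg.init_sigma2_e is not None:
        sigma2_e = np.broadcast_to(
            np.asarray(cfg.init_sigma2_e, dtype=float), (c_eff,)
        ).copy()
    else:
        sigma2_e = np.asarray(prior.s2_e) * prior.v_e / (prior.v_e - 2.0)
    residuals = y.copy()
    for k in range(c_mu):
        residuals[mu_offsets[k]: mu_offsets[k + 1]] -= mu[k]
    return MCMCState(
        X=X,
        y=y,
        offsets=offsets,
        mu_offsets=mu_offsets,
        mu_group_eff=mu_group_eff,
        xtx=xtx,
        mu=mu,
        effects=np.zeros((m, c_eff)),
        gamma=np.zeros(m, dtype=np.int8),
        w=cfg.init_w,
        sigma2_a=sigma2_a.astype(float),
        sigma2_e=sigma2_e.astype(float),
        residuals=residuals,
    )


def _check_state(state: MCMCState, it: int) -> None:
    for name, arr in (("sigma2_a", state.sigma2_a), ("sigma2_e", state.sigma2_e)):
        if not np.isfinite(arr).all() or (arr < _VAR_FLOOR).any() or (arr > _VAR_CEIL).any():
            raise RuntimeError(
                f"divergent chain at iteration {it}: {name} = {arr}"
            )
    if not np.isfinite(state.w) or not 0.0 < state.w < 1.0:
        raise RuntimeError(f"divergent chain at iteration {it}: w = {state.w}")


def _validate_invariants(state: MCMCState, it: int) -> float:
    dev = state.residual_dev()
    tol = _RESID_RTOL * (1.0 + float(np.max(np.abs(state.y), initial=0.0)))
    if dev > tol:
        raise RuntimeError(
            f"residual bookkeeping drifted at iteration {it}: dev {dev:.3g} > {tol:.3g}"
        )
    excluded = state.gamma == 0
    if excluded.any() and np.any(state.effects[excluded, :] != 0.0):
        raise RuntimeError(f"spike constraint violated at iteration {it}")
    return dev


def _run_chain(
    labels_eff: list[str],
    labels_mu: list[str],
    X: np.ndarray,
    y: np.ndarray,
    offsets: np.ndarray,
    mu_offsets: np.ndarray,
    mu_group_eff: np.ndarray,
    prior: PriorSpec,
    cfg: GibbsConfig,
    marker_ids: Optional[list[str]],
) -> PosteriorSummary:
    c_eff = len(offsets) - 1
    c_mu = len(mu_offsets) - 1
    m = X.shape[1]
    prior = prior.broadcast(c_eff)
    state = _init_state(X, y, offsets, mu_offsets, mu_group_eff, prior, cfg)
    rng = np.random.default_rng(cfg.seed)

    eff_sum = np.zeros((m, c_eff))
    gamma_sum = np.zeros(m)
    mu_sum = np.zeros(c_mu)
    w_sum = 0.0
    s2a_sum = np.zeros(c_eff)
    s2e_sum = np.zeros(c_eff)
    n_rec = 0
    max_dev = 0.0
    trace_rows: list[dict] = []

    base_order = np.arange(m, dtype=np.int64)
    for it in range(1, cfg.n_iter + 1):
        order = rng.permutation(m).astype(np.int64) if cfg.shuffle_update_order else base_order
        sweep_markers(
            X,
            state.residuals,
            offsets,
            state.xtx,
            state.effects,
            state.gamma,
            state.w,
            state.sigma2_a,
            state.sigma2_e,
            order,
            rng,
        )
        if cfg.update_w:
            state.w = sample_w(state.gamma, m, cfg.w_posterior_form, rng)
        if cfg.update_variances:
            for k in range(c_eff):
                state.sigma2_a[k] = sample_sigma2_a(k, state, prior, rng)
            for k in range(c_eff):
                state.sigma2_e[k] = sample_sigma2_e(k, state, prior, rng)
        if cfg.update_mu:
            for k in range(c_mu):
                sample_mu(k, state, rng)
        _check_state(state, it)
        if cfg.validate_every and it % cfg.validate_every == 0:
            max_dev = max(max_dev, _validate_invariants(state, it))
        if it > cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0:
            eff_sum += state.effects
            gamma_sum += state.gamma
            mu_sum += state.mu
            w_sum += state.w
            s2a_sum += state.sigma2_a
            s2e_sum += state.sigma2_e
            n_rec += 1
            if cfg.record_trace:
                row = {
                    "iteration": it,
                    "w": state.w,
                    "n_included": int(state.gamma.sum()),
                }
                for k, lab in enumerate(labels_eff):
                    row[f"sigma2_a_{lab}"] = state.sigma2_a[k]
                    row[f"sigma2_e_{lab}"] = state.sigma2_e[k]
                for k, lab in enumerate(labels_mu):
                    row[f"mu_{lab}"] = state.mu[k]
                trace_rows.append(row)
    max_dev = max(max_dev, _validate_invariants(state, cfg.n_iter))

    return PosteriorSummary(
        populations=list(labels_eff),
        mu_populations=list(labels_mu),
        effect_mean=eff_sum / n_rec,
        inclusion_prob=gamma_sum / n_rec,
        mu_mean=mu_sum / n_rec,
        w_mean=w_sum / n_rec,
        sigma2_a_mean=s2a_sum / n_rec,
        sigma2_e_mean=s2e_sum / n_rec,
        n_samples_used=n_rec,
        max_residual_dev=max_dev,
        marker_ids=list(marker_ids) if marker_ids is not None else None,
        trace=pd.DataFrame(trace_rows) if cfg.record_trace else None,
        meta={"seed": cfg.seed, "n_iter": cfg.n_iter, "burn_in": cfg.burn_in,
              "thin": cfg.thin, "w_posterior_form": cfg.w_posterior_form},
    )


def run_multi_task(
    X_by_pop: Mapping[str, np.ndarray],
    y_by_pop: Mapping[str, np.ndarray],
    prior: PriorSpec,
    cfg: GibbsConfig,
    marker_ids: Optional[list[str]] = None,
) -> PosteriorSummary:
    """Fit the multi-task model: shared gamma, population-specific effects.

    ``X_by_pop``/``y_by_pop`` map population label to a complete ``(n_k, m)``
    genotype matrix (common marker order) and phenotype vector.  With one
    population the chain is identical draw-for-draw to
    :func:`run_single_task` under the same seed.
    """
    labels, X, y, offsets = _stack_groups(X_by_pop, y_by_pop)
    mu_group_eff = np.arange(len(labels), dtype=np.int64)
    return _run_chain(
        labels, labels, X, y, offsets, offsets, mu_group_eff, prior, cfg, marker_ids
    )


def run_single_task(
    X: np.ndarray,
    y: np.ndarray,
    prior: PriorSpec,
    cfg: GibbsConfig,
    marker_ids: Optional[list[str]] = None,
    label: str = "pop",
) -> PosteriorSummary:
    """Fit the one-population spike-and-slab regression."""
    return run_multi_task({label: X}, {label: y}, prior, cfg, marker_ids)


def run_pooled(
    X_by_pop: Mapping[str, np.ndarray],
    y_by_pop: Mapping[str, np.ndarray],
    prior: PriorSpec,
    cfg: GibbsConfig,
    marker_ids: Optional[list[str]] = None,
) -> PosteriorSummary:
    """Fit the data-pooling comparator.

    Populations are stacked into one training set; population origin enters
    as a fixed effect (per-population intercept) while a single effect
    vector, slab variance and residual variance are shared.  With one
    population this reduces exactly to :func:`run_single_task`.
    """
    labels, X, y, offsets = _stack_groups(X_by_pop, y_by_pop)
    eff_offsets = np.asarray([0, X.shape[0]], dtype=np.int64)
    mu_group_eff = np.zeros(len(labels), dtype=np.int64)
    return _run_chain(
        ["pooled"], labels, X, y, eff_offsets, offsets, mu_group_eff, prior, cfg, marker_ids
    )
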