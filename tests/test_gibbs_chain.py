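"""Chain-level behaviour: reductions, determinism, bookkeeping, kernels."""

import numpy as np
import pytest

from mtgp import (
    GibbsConfig,
    PriorSpec,
    run_multi_task,
    run_pooled,
    run_single_task,
)
from mtgp._kernels import sweep_markers
from mtgp.gibbs import (
    MCMCState,
    _check_state,
    _init_state,
    _stack_groups,
    update_indicator_and_effects,
)


def _summaries_equal(a, b) -> bool:
    return (
        np.array_equal(a.effect_mean, b.effect_mean)
        and np.array_equal(a.inclusion_prob, b.inclusion_prob)
        and np.array_equal(a.mu_mean, b.mu_mean)
        and a.w_mean == b.w_mean
        and np.array_equal(a.sigma2_a_mean, b.sigma2_a_mean)
        and np.array_equal(a.sigma2_e_mean, b.sigma2_e_mean)
        and a.n_samples_used == b.n_samples_used
    )


@pytest.fixture
def one_pop_problem(rng):
    X = rng.integers(0, 3, size=(35, 20)).astype(float)
    beta = np.zeros(20)
    beta[[2, 9]] = [1.2, -0.9]
    y = X @ beta + rng.normal(0, 1, 35)
    return X, y


CFG = GibbsConfig(n_iter=400, burn_in=100, seed=42, validate_every=50)
PRIOR = PriorSpec.from_variances(1.0, 1.0)


class TestReductions:
    def test_single_multi_pooled_identical_with_one_population(self, one_pop_problem):
        X, y = one_pop_problem
        s_single = run_single_task(X, y, PRIOR, CFG)
        s_multi = run_multi_task({"pop": X}, {"pop": y}, PRIOR, CFG)
        s_pooled = run_pooled({"pop": X}, {"pop": y}, PRIOR, CFG)
        assert _summaries_equal(s_single, s_multi)
        assert _summaries_equal(s_single, s_pooled)

    def test_pooled_has_one_effect_column(self, small_training_problem):
        X, y = small_training_problem
        s = run_pooled(X, y, PRIOR, CFG)
        assert s.effect_mean.shape[1] == 1
        assert s.populations == ["pooled"]
        assert s.mu_populations == ["A", "B"]


class TestDeterminism:
    def test_identical_seed_identical_summary(self, small_training_problem):
        X, y = small_training_problem
        prior = PriorSpec.from_variances([1.0, 1.0], [1.0, 1.0])
        assert _summaries_equal(
            run_multi_task(X, y, prior, CFG), run_multi_task(X, y, prior, CFG)
        )

    def test_different_seed_differs(self, one_pop_problem):
        X, y = one_pop_problem
        a = run_single_task(X, y, PRIOR, CFG)
        b = run_single_task(X, y, PRIOR, GibbsConfig(n_iter=400, burn_in=100, seed=43))
        assert not _summaries_equal(a, b)

    def test_shuffled_update_order_still_deterministic(self, one_pop_problem):
        X, y = one_pop_problem
        cfg = GibbsConfig(n_iter=200, burn_in=50, seed=7, shuffle_update_order=True)
        assert _summaries_equal(
            run_single_task(X, y, PRIOR, cfg), run_single_task(X, y, PRIOR, cfg)
        )


class TestKernelAgainstReference:
    def test_compiled_sweep_matches_python_updates(self, small_training_problem):
        """The numba sweep and the op-level reference produce the same chain."""
        X_by, y_by = small_training_problem
        labels, X, y, off = _stack_groups(X_by, y_by)
        prior = PriorSpec.from_variances([1.0, 1.0], [1.0, 1.0]).broadcast(2)
        cfg = GibbsConfig(n_iter=10, burn_in=1)
        mg = np.arange(2, dtype=np.int64)
        st_kernel = _init_state(X, y, off, off, mg, prior, cfg)
        st_python = _init_state(X, y, off, off, mg, prior, cfg)
        r1, r2 = np.random.default_rng(99), np.random.default_rng(99)
        order = np.arange(X.shape[1], dtype=np.int64)
        for _ in range(15):
            sweep_markers(
                st_kernel.X, st_kernel.residuals, off, st_kernel.xtx,
                st_kernel.effects, st_kernel.gamma, st_kernel.w,
                st_kernel.sigma2_a, st_kernel.sigma2_e, order, r1,
            )
            for j in range(X.shape[1]):
                update_indicator_and_effects(j, st_python, r2)
        np.testing.assert_array_equal(st_kernel.effects, st_python.effects)
        np.testing.assert_array_equal(st_kernel.gamma, st_python.gamma)
        np.testing.assert_array_equal(st_kernel.residuals, st_python.residuals)


class TestChainBehaviour:
    def test_all_noise_keeps_inclusion_low(self, rng):
        X = rng.integers(0, 3, size=(60, 50)).astype(float)
        y = rng.normal(size=60)
        s = run_single_task(X, y, PriorSpec.from_variances(0.5, 1.0), CFG)
        assert s.inclusion_prob.mean() < 0.5

    def test_opposite_effects_shrink_pooled_estimate(self):
        """With opposite-sign true effects, pooling shrinks the estimate
        toward zero relative to the per-population multi-task estimates."""
        wins = 0
        for rep in range(5):
            r = np.random.default_rng(100 + rep)
            X1 = r.integers(0, 3, size=(50, 10)).astype(float)
            X2 = r.integers(0, 3, size=(50, 10)).astype(float)
            y1 = 1.5 * X1[:, 4] + r.normal(0, 1, 50)
            y2 = -1.5 * X2[:, 4] + r.normal(0, 1, 50)
            X, y = {"A": X1, "B": X2}, {"A": y1, "B": y2}
            cfg = GibbsConfig(n_iter=400, burn_in=100, seed=rep)
            prior2 = PriorSpec.from_variances([1.0, 1.0], [1.0, 1.0])
            sm = run_multi_task(X, y, prior2, cfg)
            sp = run_pooled(X, y, PriorSpec.from_variances(1.0, 1.0), cfg)
            multi_mag = np.mean(np.abs(sm.effect_mean[4, :]))
            if abs(sp.effect_mean[4, 0]) < multi_mag:
                wins += 1
        assert wins >= 4

    def test_thinning_controls_recorded_samples(self, one_pop_problem):
        X, y = one_pop_problem
        cfg = GibbsConfig(n_iter=105, burn_in=20, thin=10, seed=0, record_trace=True)
        s = run_single_task(X, y, PRIOR, cfg)
        assert s.n_samples_used == (105 - 20) // 10 == 8
        assert len(s.trace) == 8

    def test_as_printed_w_form_runs(self, one_pop_problem):
        X, y = one_pop_problem
        cfg = GibbsConfig(n_iter=200, burn_in=50, seed=1, w_posterior_form="as_printed")
        s = run_single_task(X, y, PRIOR, cfg)
        assert 0.0 < s.w_mean < 1.0

    def test_zero_markers_is_an_error(self):
        with pytest.raises(ValueError, match="no markers"):
            run_single_task(np.empty((5, 0)), np.zeros(5), PRIOR, CFG)

    def test_incomplete_genotypes_rejected(self):
        X = np.array([[0.0, np.nan], [1.0, 2.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="complete"):
            run_single_task(X, np.zeros(3), PRIOR, CFG)

    def test_divergence_guard_triggers(self, one_pop_problem):
        X, y = one_pop_problem
        labels, Xs, ys, off = _stack_groups({"p": X}, {"p": y})
        st = _init_state(
            Xs, ys, off, off, np.zeros(1, dtype=np.int64),
            PRIOR.broadcast(1), GibbsConfig(n_iter=10, burn_in=1),
        )
        st.sigma2_e[0] = 1e13
        with pytest.raises(RuntimeError, match="divergent"):
            _check_state(st, it=1)


class TestConfigValidation:
    def test_burn_in_bounds(self):
        with pytest.raises(ValueError):
            GibbsConfig(n_iter=100, burn_in=100)

    def test_thin_bounds(self):
        with pytest.raises(ValueError):
            GibbsConfig(n_iter=100, burn_in=10, thin=0)

    def test_prior_degrees_of_freedom(self):
        with pytest.raises(ValueError):
            PriorSpec(v_a=2.0)
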