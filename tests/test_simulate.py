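"""Generator behaviour: divergence, LD, effect structure, heritability, panels."""

import numpy as np
import pytest

from mtgp import (
    SimConfig,
    build_panel,
    compute_genetic_variance,
    sample_qtl_effects,
    select_qtl,
    simulate_dataset,
    simulate_genotypes,
    split_train_validation,
)

SMALL = dict(
    n_per_population=(80, 120),
    m_markers=150,
    n_qtl=6,
    train_sizes=(60, 90),
    valid_sizes=(20, 30),
)


class TestGenotypeGeneration:
    def test_no_ld_gives_uncorrelated_neighbours(self):
        cfg = SimConfig(
            n_per_population=(2000, 100), m_markers=60, n_qtl=4, ld_phi=0.0,
            train_sizes=(1000, 50), valid_sizes=(100, 10), seed=5,
        )
        gs, _ = simulate_genotypes(cfg, np.random.default_rng(5))
        codes = gs[0].codes
        rs = [
            abs(np.corrcoef(codes[:, j], codes[:, j + 1])[0, 1])
            for j in range(0, 40, 2)
        ]
        assert np.mean(rs) < 0.05

    def test_strong_ld_correlates_neighbours(self):
        cfg = SimConfig(ld_phi=0.95, seed=2, **SMALL)
        gs, _ = simulate_genotypes(cfg, np.random.default_rng(2))
        codes = gs[1].codes
        rs = [np.corrcoef(codes[:, j], codes[:, j + 1])[0, 1] for j in range(30)]
        assert np.mean(rs) > 0.3

    def test_no_divergence_keeps_frequencies_close(self):
        cfg = SimConfig(
            n_per_population=(1500, 1500), m_markers=80, n_qtl=4, fst=0.0,
            train_sizes=(1000, 1000), valid_sizes=(100, 100), seed=7,
        )
        gs, freqs = simulate_genotypes(cfg, np.random.default_rng(7))
        assert np.allclose(freqs[0], freqs[1])  # identical targets at F=0
        f1 = gs[0].codes.mean(axis=0) / 2
        f2 = gs[1].codes.mean(axis=0) / 2
        se = np.sqrt(2 * freqs[0] * (1 - freqs[0]) / (2 * 1500))
        assert (np.abs(f1 - f2) < 6 * se).mean() > 0.95

    def test_realized_frequency_tracks_target(self):
        cfg = SimConfig(fst=0.1, seed=11, **SMALL)
        gs, freqs = simulate_genotypes(cfg, np.random.default_rng(11))
        for pop in range(2):
            n = cfg.n_per_population[pop]
            f = gs[pop].codes.mean(axis=0) / 2
            se = np.sqrt(freqs[pop] * (1 - freqs[pop]) / (2 * n))
            # LD correlates haplotypes within a sample but not across samples,
            # so the binomial SE is the right scale; allow rare 3-SE excursions
            assert (np.abs(f - freqs[pop]) < 3 * se).mean() > 0.9

    def test_maf_floor_enforced_in_both_populations(self):
        cfg = SimConfig(fst=0.3, seed=13, **SMALL)
        gs, _ = simulate_genotypes(cfg, np.random.default_rng(13))
        for g in gs:
            assert (g.maf() >= 0.05).all()
            assert not np.isnan(g.codes).any()


class TestQtlAndEffects:
    def test_select_qtl_respects_pool(self):
        cfg = SimConfig(qtl_pool_stride=8, seed=1, **SMALL)
        qtl = select_qtl(cfg, np.random.default_rng(1))
        assert len(qtl) == len(set(qtl.tolist())) == cfg.n_qtl
        assert (qtl % 8 == 0).all()

    def test_select_qtl_whole_pool(self):
        cfg = SimConfig(
            n_per_population=(20, 20), m_markers=40, n_qtl=5, qtl_pool_stride=8,
            train_sizes=(10, 10), valid_sizes=(5, 5),
        )
        qtl = select_qtl(cfg, np.random.default_rng(0))
        np.testing.assert_array_equal(qtl, [0, 8, 16, 24, 32])

    def test_select_qtl_seed_sensitivity(self):
        cfg = SimConfig(seed=0, **SMALL)
        draws = {
            tuple(select_qtl(cfg, np.random.default_rng(s))) for s in range(10)
        }
        assert len(draws) > 1

    def test_perfect_correlation_duplicates_effects(self, rng):
        alpha = sample_qtl_effects(50, 1.0, rng)
        np.testing.assert_array_equal(alpha[:, 0], alpha[:, 1])

    def test_moments_at_zero_correlation(self):
        alpha = sample_qtl_effects(10_000, 0.0, np.random.default_rng(3))
        r = np.corrcoef(alpha[:, 0], alpha[:, 1])[0, 1]
        assert abs(r) < 3.0 / np.sqrt(10_000) * 3
        assert np.var(alpha[:, 0]) == pytest.approx(1.0, abs=0.05)
        assert np.var(alpha[:, 1]) == pytest.approx(1.0, abs=0.05)

    def test_genetic_variance_formula(self, rng):
        assert compute_genetic_variance([0.5], [1.0]) == pytest.approx(0.5)
        assert compute_genetic_variance([0.0, 1.0], [2.0, 3.0]) == 0.0
        p = rng.uniform(0.05, 0.95, 20)
        a = rng.normal(size=20)
        manual = sum(2 * pj * (1 - pj) * aj**2 for pj, aj in zip(p, a))
        assert compute_genetic_variance(p, a) == pytest.approx(manual, rel=1e-12)


@pytest.fixture(scope="module")
def assembly_dataset():
    return simulate_dataset(SimConfig(seed=21, **SMALL))


@pytest.fixture(scope="module")
def panel_dataset():
    return simulate_dataset(SimConfig(seed=31, **SMALL))


class TestDatasetAssembly:
    @pytest.fixture
    def dataset(self, assembly_dataset):
        return assembly_dataset

    def test_tbv_matches_genotypes_exactly(self, dataset):
        truth = dataset.truth
        for pop, g in zip(("pop1", "pop2"), dataset.genotypes):
            Xq = g.codes[:, truth.qtl_indices]
            k = 0 if pop == "pop1" else 1
            np.testing.assert_array_equal(truth.tbv[pop], Xq @ truth.alpha[:, k])

    def test_heritability_exact_by_construction(self, dataset):
        truth = dataset.truth
        h2 = truth.sigma2_a / (truth.sigma2_a + truth.sigma2_e)
        np.testing.assert_allclose(h2, 0.5)
        np.testing.assert_array_equal(truth.sigma2_e, truth.sigma2_a)

    def test_phenotype_variance_scale(self):
        cfg = SimConfig(
            n_per_population=(3000, 100), m_markers=100, n_qtl=10,
            train_sizes=(2000, 50), valid_sizes=(500, 20), seed=3,
        )
        ds = simulate_dataset(cfg)
        y1 = ds.phenotypes.values[np.asarray(ds.phenotypes.population_labels) == "pop1"]
        total = ds.truth.sigma2_a[0] + ds.truth.sigma2_e[0]
        # var(TBV) can deviate from the linkage-equilibrium formula under LD;
        # check the phenotypic variance against realized TBV variance + sigma2_e
        realized = np.var(ds.truth.tbv["pop1"]) + ds.truth.sigma2_e[0]
        assert np.var(y1) == pytest.approx(realized, rel=0.15)
        assert total > 0

    def test_pure_function_of_config(self):
        cfg = SimConfig(seed=8, **SMALL)
        a, b = simulate_dataset(cfg), simulate_dataset(cfg)
        assert a.genotypes[0] == b.genotypes[0]
        np.testing.assert_array_equal(a.phenotypes.values, b.phenotypes.values)
        np.testing.assert_array_equal(a.truth.alpha, b.truth.alpha)
        assert a.splits == b.splits


class TestPanelsAndSplits:
    @pytest.fixture
    def dataset(self, panel_dataset):
        return panel_dataset

    def test_thinning_keeps_anchored_stride(self, dataset):
        cfg2 = SimConfig(seed=31, **{**SMALL, "thin_factor": 2})
        g = dataset.genotypes[0]
        panel = build_panel(g, dataset.truth, cfg2)
        expected = [
            g.marker_ids[j]
            for j in range(0, g.n_markers, 2)
            if j not in set(dataset.truth.qtl_indices.tolist())
        ]
        assert panel.marker_ids == expected

    def test_qtl_removed_by_default(self, dataset):
        cfg = dataset.config
        panel = build_panel(dataset.genotypes[0], dataset.truth, cfg)
        qtl_ids = {dataset.genotypes[0].marker_ids[j] for j in dataset.truth.qtl_indices}
        assert panel.n_markers == cfg.m_markers - cfg.n_qtl
        assert qtl_ids.isdisjoint(panel.marker_ids)

    def test_qtl_retained_when_requested(self, dataset):
        cfg = SimConfig(seed=31, **{**SMALL, "include_qtl_in_panel": True, "thin_factor": 4})
        panel = build_panel(dataset.genotypes[0], dataset.truth, cfg)
        qtl_ids = {dataset.genotypes[0].marker_ids[j] for j in dataset.truth.qtl_indices}
        assert qtl_ids.issubset(set(panel.marker_ids))

    def test_split_sizes_and_disjointness(self, dataset):
        cfg = dataset.config
        for k, pop in enumerate(("pop1", "pop2")):
            train, valid = dataset.splits[pop]
            assert len(train) == cfg.train_sizes[k]
            assert len(valid) == cfg.valid_sizes[k]
            assert set(train).isdisjoint(valid)

    def test_default_split_covers_everyone(self):
        cfg = SimConfig(seed=31, **SMALL)
        ds = simulate_dataset(cfg)
        for g in ds.genotypes:
            pop = g.populations[0]
            train, valid = ds.splits[pop]
            assert set(train) | set(valid) == set(g.sample_ids)

    def test_split_seeded(self, dataset):
        cfg = dataset.config
        r1 = split_train_validation(dataset.genotypes, cfg, np.random.default_rng(4))
        r2 = split_train_validation(dataset.genotypes, cfg, np.random.default_rng(4))
        assert r1 == r2

    def test_oversized_split_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            SimConfig(seed=1, **{**SMALL, "train_sizes": (100, 90)})


def test_config_validation():
    with pytest.raises(ValueError, match="h2"):
        SimConfig(h2=1.5, **SMALL)
    with pytest.raises(ValueError, match="thin_factor"):
        SimConfig(thin_factor=3, **SMALL)
    with pytest.raises(ValueError, match="pool"):
        SimConfig(
            n_per_population=(20, 20), m_markers=40, n_qtl=10, qtl_pool_stride=8,
            train_sizes=(10, 10), valid_sizes=(5, 5),
        )
    with pytest.raises(ValueError, match="exceed"):
        SimConfig(
            n_per_population=(20, 20), m_markers=40, n_qtl=2,
            train_sizes=(18, 10), valid_sizes=(5, 5),
        )
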