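"""Synthetic two-population genotype/trait generator.

Stands in for real multi-breed chip data with the same statistical skeleton
the models care about:

* between-population allele-frequency divergence via the Balding-Nichols
  model (``fst``),
* within-population linkage disequilibrium via a latent AR(1) Gaussian
  copula over haplotypes (``ld_phi``),
* a designated low-density marker subset (every ``qtl_pool_stride``-th
  marker, a "50k-like" panel) from which QTL are drawn,
* QTL allele-substitution effects correlated between populations
  (bivariate normal, unit variances, correlation ``rho``),
* phenotypes y = TBV + e with residual variance set from the realized
  genetic variance so the variance-parameter heritability equals ``h2``
  exactly (0.5 by default, where sigma2_e = sigma2_a).

Everything downstream of a :class:`SimConfig` is a pure function of the
config (including its seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .datatypes import GenotypeMatrix, PhenotypeTable

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimDataset",
    "simulate_genotypes",
    "select_qtl",
    "sample_qtl_effects",
    "compute_genetic_variance",
    "simulate_phenotypes",
    "build_panel",
    "split_train_validation",
    "simulate_dataset",
]

_MAF_FLOOR = 0.05
_RESAMPLE_CAP = 200


@dataclass(frozen=True)
class SimConfig:
    """Simulation design parameters.

    Defaults follow the two-breed dairy-cattle design the package targets:
    one small population of 458 animals (393 training / 65 validation) and
    one large population of 2,298 (2,084 / 214); 20 or 200 QTL with effect
    correlation 0.2 or 0.8; heritability 0.5.
    """

    n_per_population: tuple[int, int] = (458, 2298)
    m_markers: int = 2000
    n_qtl: int = 20
    rho: float = 0.2
    fst: float = 0.1
    ld_phi: float = 0.95
    include_qtl_in_panel: bool = False
    thin_factor: int = 1
    qtl_pool_stride: int = 8
    h2: float = 0.5
    seed: int = 0
    train_sizes: tuple[int, int] = (393, 2084)
    valid_sizes: tuple[int, int] = (65, 214)
    population_names: tuple[str, str] = ("pop1", "pop2")

    def __post_init__(self) -> None:
        if len(self.n_per_population) != 2:
            raise ValueError("exactly two populations are simulated")
        if not 0.0 < self.h2 < 1.0:
            raise ValueError("h2 must lie in (0, 1)")
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [-1, 1]")
        if not 0.0 <= self.fst < 1.0:
            raise ValueError("fst must lie in [0, 1)")
        if not 0.0 <= self.ld_phi < 1.0:
            raise ValueError("ld_phi must lie in [0, 1)")
        if self.thin_factor not in (1, 2, 4, 8):
            raise ValueError("thin_factor must be one of 1, 2, 4, 8")
        if self.n_qtl > self.pool_size:
            raise ValueError(
                f"n_qtl={self.n_qtl} exceeds the QTL pool "
                f"({self.pool_size} markers at stride {self.qtl_pool_stride})"
            )
        for nk, tr, va in zip(self.n_per_population, self.train_sizes, self.valid_sizes):
            if tr + va > nk:
                raise ValueError("train + validation sizes exceed population size")

    @property
    def pool_size(self) -> int:
        return len(range(0, self.m_markers, self.qtl_pool_stride))


@dataclass
class SimTruth:
    """Ground truth of one simulated replicate."""

    qtl_indices: np.ndarray          # sorted marker indices of the QTL
    alpha: np.ndarray                # (n_qtl, 2) effects per population
    tbv: dict[str, np.ndarray]       # per-population true breeding values
    sigma2_a: np.ndarray             # (2,) genetic variances
    sigma2_e: np.ndarray             # (2,) residual variances
    allele_freqs: np.ndarray         # (2, n_qtl) realized QTL frequencies


@dataclass
class SimDataset:
    """Bundle returned by :func:`simulate_dataset`."""

    config: SimConfig
    genotypes: list[GenotypeMatrix]      # full marker set, per population
    panel: list[GenotypeMatrix]          # prediction panel, per population
    phenotypes: PhenotypeTable
    truth: SimTruth
    splits: dict[str, tuple[list[str], list[str]]]  # pop -> (train, valid)
    target_freqs: np.ndarray             # (2, m) Balding-Nichols targets


def _haplotypes(n_hap: int, thresholds: np.ndarray, phi: float, rng: np.random.Generator) -> np.ndarray:
    """AR(1) latent Gaussian copula: allele = 1 iff z_j < Phi^-1(p_j)."""
    m = thresholds.shape[0]
    z = np.empty((n_hap, m))
    z[:, 0] = rng.standard_normal(n_hap)
    scale = np.sqrt(1.0 - phi * phi)
    for j in range(1, m):
        z[:, j] = phi * z[:, j - 1] + scale * rng.standard_normal(n_hap)
    return (z < thresholds[np.newaxis, :]).astype(float)


def _draw_pop_freqs(p_anc: np.ndarray, fst: float, rng: np.random.Generator) -> np.ndarray:
    """Balding-Nichols population frequencies given ancestral frequencies."""
    if fst == 0.0:
        return np.vstack([p_anc, p_anc])
    a = p_anc * (1.0 - fst) / fst
    b = (1.0 - p_anc) * (1.0 - fst) / fst
    return np.vstack([rng.beta(a, b), rng.beta(a, b)])


def simulate_genotypes(
    cfg: SimConfig, rng: np.random.Generator
) -> tuple[list[GenotypeMatrix], np.ndarray]:
    """Generate complete genotype matrices for both populations.

    Ancestral frequencies are Uniform(0.1, 0.9); population frequencies
    follow Balding-Nichols with F = ``cfg.fst``; haplotypes carry AR(1)
    linkage disequilibrium with coefficient ``cfg.ld_phi``.  Markers whose
    realized MAF falls below 0.05 in either population are resampled with
    fresh, LD-free columns until the whole panel passes, so generated
    panels need no MAF QC.  Returns the matrices and the ``(2, m)`` target
    frequencies.
    """
    m = cfg.m_markers
    p_anc = rng.uniform(0.1, 0.9, size=m)
    freqs = _draw_pop_freqs(p_anc, cfg.fst, rng)
    thresholds = stats.norm.ppf(freqs)  # (2, m)
    codes = []
    for pop in range(2):
        n = cfg.n_per_population[pop]
        hap = _haplotypes(2 * n, thresholds[pop], cfg.ld_phi, rng)
        codes.append(hap[0::2] + hap[1::2])
    for _ in range(_RESAMPLE_CAP):
        fail = np.zeros(m, dtype=bool)
        for pop in range(2):
            f = codes[pop].mean(axis=0) / 2.0
            fail |= np.minimum(f, 1.0 - f) < _MAF_FLOOR
        if not fail.any():
            break
        idx = np.nonzero(fail)[0]
        p_new = rng.uniform(0.1, 0.9, size=idx.size)
        f_new = _draw_pop_freqs(p_new, cfg.fst, rng)
        freqs[:, idx] = f_new
        thr = stats.norm.ppf(f_new)
        for pop in range(2):
            n = cfg.n_per_population[pop]
            hap = (rng.standard_normal((2 * n, idx.size)) < thr[pop]).astype(float)
            codes[pop][:, idx] = hap[0::2] + hap[1::2]
    else:
        raise RuntimeError("could not satisfy the MAF floor after resampling")
    marker_ids = [f"m{j:06d}" for j in range(m)]
    out = []
    for pop in range(2):
        name = cfg.population_names[pop]
        n = cfg.n_per_population[pop]
        sample_ids = [f"{name}_{i:05d}" for i in range(n)]
        out.append(
            GenotypeMatrix(sample_ids, marker_ids, codes[pop], np.repeat(name, n))
        )
    return out, freqs


def select_qtl(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Sample QTL uniformly without replacement from the low-density pool."""
    pool = np.arange(0, cfg.m_markers, cfg.qtl_pool_stride)
    if pool.size < cfg.n_qtl:
        raise ValueError("QTL pool smaller than requested QTL count")
    return np.sort(rng.choice(pool, size=cfg.n_qtl, replace=False))


def sample_qtl_effects(n_qtl: int, rho: float, rng: np.random.Generator) -> np.ndarray:
    """Bivariate-normal allele substitution effects, unit variances.

    Constructed as alpha2 = rho * alpha1 + sqrt(1 - rho^2) * z so that
    rho = 1 yields exactly identical effect vectors.
    """
    if not -1.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [-1, 1]")
    a1 = rng.standard_normal(n_qtl)
    z = rng.standard_normal(n_qtl)
    a2 = rho * a1 + np.sqrt(max(0.0, 1.0 - rho * rho)) * z
    return np.column_stack([a1, a2])


def compute_genetic_variance(freqs: np.ndarray, alpha: np.ndarray) -> float:
    """Additive genetic variance sum_j 2 p_j (1 - p_j) alpha_j^2.

    ``freqs`` and ``alpha`` are the QTL allele frequencies and effects of
    one population.  The formula assumes linkage equilibrium between QTL;
    it defines the heritability target, while var(TBV) may differ under LD.
    """
    freqs = np.asarray(freqs, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if ((freqs < 0) | (freqs > 1)).any():
        raise ValueError("allele frequencies must lie in [0, 1]")
    return float(np.sum(2.0 * freqs * (1.0 - freqs) * alpha**2))


def _build_truth(
    genotypes: Sequence[GenotypeMatrix],
    qtl_indices: np.ndarray,
    alpha: np.ndarray,
    h2: float,
) -> SimTruth:
    tbv: dict[str, np.ndarray] = {}
    sigma2_a = np.empty(2)
    freqs = np.empty((2, len(qtl_indices)))
    for pop in range(2):
        g = genotypes[pop]
        Xq = g.codes[:, qtl_indices]
        tbv[g.populations[0]] = Xq @ alpha[:, pop]
        freqs[pop] = Xq.mean(axis=0) / 2.0
        sigma2_a[pop] = compute_genetic_variance(freqs[pop], alpha[:, pop])
    sigma2_e = sigma2_a * (1.0 - h2) / h2
    return SimTruth(
        qtl_indices=qtl_indices,
        alpha=alpha,
        tbv=tbv,
        sigma2_a=sigma2_a,
        sigma2_e=sigma2_e,
        allele_freqs=freqs,
    )


def simulate_phenotypes(
    genotypes: Sequence[GenotypeMatrix],
    truth: SimTruth,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> PhenotypeTable:
    """y_i = TBV_i + e_i with e_i ~ N(0, sigma2_e) of the sample's population."""
    ids: list[str] = []
    pops: list[str] = []
    values: list[np.ndarray] = []
    for pop in range(2):
        g = genotypes[pop]
        name = g.populations[0]
        a = truth.tbv[name]
        e = rng.normal(0.0, np.sqrt(truth.sigma2_e[pop]), size=a.shape[0])
        ids.extend(g.sample_ids)
        pops.extend([name] * g.n_samples)
        values.append(a + e)
    return PhenotypeTable(ids, np.asarray(pops, dtype=object), np.concatenate(values))


def build_panel(g: GenotypeMatrix, truth: SimTruth, cfg: SimConfig) -> GenotypeMatrix:
    """Thin the marker set and handle QTL columns.

    Keeps indices 0, t, 2t, ... (anchored at the first marker); QTL columns
    are then removed, or — when ``include_qtl_in_panel`` — appended at the
    end if thinning dropped them, so every QTL is always present in that
    mode.
    """
    kept = list(range(0, g.n_markers, cfg.thin_factor))
    qtl = set(int(q) for q in truth.qtl_indices)
    if cfg.include_qtl_in_panel:
        kept = kept + [q for q in sorted(qtl) if q not in set(kept)]
    else:
        kept = [j for j in kept if j not in qtl]
    return g.select_markers([g.marker_ids[j] for j in kept])


def split_train_validation(
    genotypes: Sequence[GenotypeMatrix],
    cfg: SimConfig,
    rng: np.random.Generator,
) -> dict[str, tuple[list[str], list[str]]]:
    """Seeded random train/validation split per population.

    A random split replaces the birth-year criterion used with pedigreed
    real data; sizes come from ``cfg.train_sizes`` / ``cfg.valid_sizes``.
    """
    out: dict[str, tuple[list[str], list[str]]] = {}
    for pop in range(2):
        g = genotypes[pop]
        n_train, n_valid = cfg.train_sizes[pop], cfg.valid_sizes[pop]
        if n_train + n_valid > g.n_samples:
            raise ValueError("split sizes exceed population size")
        perm = rng.permutation(g.n_samples)
        train = [g.sample_ids[i] for i in perm[:n_train]]
        valid = [g.sample_ids[i] for i in perm[n_train: n_train + n_valid]]
        out[g.populations[0]] = (train, valid)
    return out


def simulate_dataset(cfg: SimConfig) -> SimDataset:
    """Run the full generator: genotypes, QTL, effects, phenotypes, panel, split."""
    rng = np.random.default_rng(cfg.seed)
    genotypes, target_freqs = simulate_genotypes(cfg, rng)
    qtl = select_qtl(cfg, rng)
    alpha = sample_qtl_effects(cfg.n_qtl, cfg.rho, rng)
    truth = _build_truth(genotypes, qtl, alpha, cfg.h2)
    phenotypes = simulate_phenotypes(genotypes, truth, cfg, rng)
    panel = [build_panel(g, truth, cfg) for g in genotypes]
    splits = split_train_validation(genotypes, cfg, rng)
    return SimDataset(
        config=cfg,
        genotypes=genotypes,
        panel=panel,
        phenotypes=phenotypes,
        truth=truth,
        splits=splits,
        target_freqs=target_freqs,
    )
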