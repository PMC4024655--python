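"""End-to-end simulation-study driver: simulate -> fit -> predict -> evaluate.

One :class:`ExperimentConfig` defines a scenario cell (QTL count, effect
correlation, panel density, QTL-in-panel flag) and the experiment loops
replicates x methods, producing one row of mean +/- SE accuracy and slope
per (method, population).  Replicate seeds are derived deterministically
from the master seed, so the whole table is a pure function of the config.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix
from .evaluate import accuracy_r, predict_gebv, replicate_summary, slope_b
from .gibbs import (
    GibbsConfig,
    PosteriorSummary,
    PriorSpec,
    run_multi_task,
    run_pooled,
    run_single_task,
)
from .simulate import SimConfig, SimDataset, simulate_dataset

__all__ = [
    "ExperimentConfig",
    "desk_scale_config",
    "run_replicate",
    "run_experiment",
]

logger = logging.getLogger(__name__)

_METHODS = ("single", "pooled", "multi")


@dataclass(frozen=True)
class ExperimentConfig:
    """One scenario cell of the simulation study.

    ``prior_source='true_variances'`` anchors the variance priors at the
    replicate's realized genetic/residual variances through the
    scaled-inverse-chi-square mean relation (see
    :func:`mtgp.gibbs.derive_scale`); ``'user_supplied'`` uses ``prior``
    as given.  The pooled model, which estimates one variance pair for the
    stacked data, receives training-size-weighted averages of the
    per-population variances.
    """

    sim: SimConfig = field(default_factory=SimConfig)
    chain: GibbsConfig = field(default_factory=GibbsConfig)
    methods: tuple[str, ...] = _METHODS
    replicates: int = 10
    master_seed: int = 0
    v_a: float = 4.0
    v_e: float = 10.0
    prior_source: str = "true_variances"
    prior: Optional[PriorSpec] = None

    def __post_init__(self) -> None:
        if not self.methods:
            raise ValueError("at least one method is required")
        unknown = set(self.methods) - set(_METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.prior_source not in ("true_variances", "user_supplied"):
            raise ValueError(f"unknown prior_source {self.prior_source!r}")
        if self.prior_source == "user_supplied" and self.prior is None:
            raise ValueError("prior_source='user_supplied' needs an explicit prior")


def desk_scale_config(
    master_seed: int = 0,
    n_qtl: int = 20,
    rho: float = 0.2,
    include_qtl_in_panel: bool = False,
    methods: tuple[str, ...] = _METHODS,
    replicates: int = 5,
) -> ExperimentConfig:
    """Desk-scale analogue of the full study, sized for a single CPU.

    2,000 markers, a small population of 520 (400 training / 120
    validation) and a large one of 1,400 (1,200 / 200), chains of 5,000
    cycles with 1,000 burn-in, 5 replicates.  Divergence and LD follow the
    generator defaults (F = 0.1, phi = 0.95).
    """
    sim = SimConfig(
        n_per_population=(520, 1400),
        m_markers=2000,
        n_qtl=n_qtl,
        rho=rho,
        include_qtl_in_panel=include_qtl_in_panel,
        train_sizes=(400, 1200),
        valid_sizes=(120, 200),
    )
    chain = GibbsConfig(n_iter=5000, burn_in=1000, validate_every=1)
    return ExperimentConfig(
        sim=sim,
        chain=chain,
        methods=methods,
        replicates=replicates,
        master_seed=master_seed,
    )


def _seed_from(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


def _training_arrays(
    ds: SimDataset,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray], list[str]]:
    X_by, y_by = {}, {}
    for g in ds.panel:
        pop = g.populations[0]
        train_ids, _ = ds.splits[pop]
        sub = g.select_samples(train_ids)
        X_by[pop] = sub.codes
        y_by[pop] = ds.phenotypes.values_for(train_ids)
    return X_by, y_by, list(ds.panel[0].marker_ids)


def _validation_panel(ds: SimDataset, pop_index: int) -> tuple[GenotypeMatrix, np.ndarray]:
    g = ds.panel[pop_index]
    pop = g.populations[0]
    _, valid_ids = ds.splits[pop]
    sub = g.select_samples(valid_ids)
    id_to_row = {s: i for i, s in enumerate(ds.genotypes[pop_index].sample_ids)}
    tbv = ds.truth.tbv[pop][[id_to_row[s] for s in valid_ids]]
    return sub, tbv


def _priors_for(ds: SimDataset, cfg: ExperimentConfig) -> dict[str, PriorSpec]:
    """Per-method priors (multi: per population; single/pooled: one group)."""
    if cfg.prior_source == "user_supplied":
        assert cfg.prior is not None
        return {m: cfg.prior for m in _METHODS}
    s2a, s2e = ds.truth.sigma2_a, ds.truth.sigma2_e
    n_train = np.asarray(cfg.sim.train_sizes, dtype=float)
    weights = n_train / n_train.sum()
    priors = {
        "multi": PriorSpec.from_variances(s2a, s2e, cfg.v_a, cfg.v_e),
        "pooled": PriorSpec.from_variances(
            float(weights @ s2a), float(weights @ s2e), cfg.v_a, cfg.v_e
        ),
    }
    # single-task fits use each population's own variances; keyed per pop
    for k, pop in enumerate(cfg.sim.population_names):
        priors[f"single:{pop}"] = PriorSpec.from_variances(
            float(s2a[k]), float(s2e[k]), cfg.v_a, cfg.v_e
        )
    return priors


def run_replicate(
    cfg: ExperimentConfig, replicate: int
) -> tuple[pd.DataFrame, dict[str, PosteriorSummary]]:
    """Simulate one replicate, fit the requested methods, evaluate both populations.

    Returns one (method, population) row per cell with accuracy r and slope
    b on the validation set, plus the fitted posterior summaries keyed by
    method (single-task: ``single:<pop>``).
    """
    ss = np.random.SeedSequence(entropy=(cfg.master_seed, replicate))
    ss_sim, ss_chain = ss.spawn(2)
    sim_cfg = replace(cfg.sim, seed=_seed_from(ss_sim))
    ds = simulate_dataset(sim_cfg)
    X_by, y_by, marker_ids = _training_arrays(ds)
    priors = _priors_for(ds, cfg)
    chain_seeds = {m: _seed_from(s) for m, s in zip(_METHODS, ss_chain.spawn(3))}

    summaries: dict[str, PosteriorSummary] = {}
    rows: list[dict] = []
    pops = list(cfg.sim.population_names)
    for method in cfg.methods:
        chain = replace(cfg.chain, seed=chain_seeds[method])
        if method == "single":
            for pop in pops:
                summaries[f"single:{pop}"] = run_single_task(
                    X_by[pop], y_by[pop], priors[f"single:{pop}"], chain,
                    marker_ids=marker_ids, label=pop,
                )
        elif method == "pooled":
            summaries["pooled"] = run_pooled(
                X_by, y_by, priors["pooled"], chain, marker_ids=marker_ids
            )
        else:
            summaries["multi"] = run_multi_task(
                X_by, y_by, priors["multi"], chain, marker_ids=marker_ids
            )
        for k, pop in enumerate(pops):
            g_valid, tbv = _validation_panel(ds, k)
            summary = summaries[f"single:{pop}"] if method == "single" else summaries[method]
            gebv = predict_gebv(summary, g_valid)["gebv"].to_numpy()
            rows.append(
                {
                    "replicate": replicate,
                    "method": method,
                    "population": pop,
                    "r": accuracy_r(gebv, tbv),
                    "b": slope_b(gebv, tbv),
                    "n_valid": len(tbv),
                }
            )
    return pd.DataFrame(rows), summaries


def run_experiment(cfg: ExperimentConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run all replicates of one scenario cell.

    Returns ``(summary, per_replicate)``: the summary has one row per
    (method, population) with ``r_mean``, ``r_se``, ``b_mean``, ``b_se``;
    the per-replicate frame holds the raw r and b values.
    """
    frames: list[pd.DataFrame] = []
    for rep in range(cfg.replicates):
        logger.info("replicate %d/%d", rep + 1, cfg.replicates)
        frame, _ = run_replicate(cfg, rep)
        frames.append(frame)
    per_replicate = pd.concat(frames, ignore_index=True)
    if cfg.replicates >= 2:
        summary = replicate_summary(per_replicate, by=["method", "population"])
    else:
        summary = per_replicate.rename(columns={"r": "r_mean", "b": "b_mean"})
    summary.insert(0, "n_qtl", cfg.sim.n_qtl)
    summary.insert(1, "rho", cfg.sim.rho)
    summary.insert(2, "thin_factor", cfg.sim.thin_factor)
    summary.insert(3, "qtl_in_panel", cfg.sim.include_qtl_in_panel)
    return summary, per_replicate
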