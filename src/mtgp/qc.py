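"""Marker quality control and cross-population panel harmonization.

The canonical pipeline order is MAF -> missingness -> near-duplicate ->
harmonize.  Thresholds are strict inequalities: a marker is dropped when its
MAF is *below* the threshold or its missing rate is *above* the cap, so
boundary values survive.  Filters operate on whatever matrix they are given;
running them per population before :func:`harmonize_panels` reproduces the
per-breed-then-intersect convention.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np

from .datatypes import GenotypeMatrix, MarkerMap, QCReport

__all__ = [
    "qc_filter_maf",
    "qc_filter_missing",
    "qc_filter_near_duplicates",
    "qc_filter_chromosomes",
    "harmonize_panels",
    "impute_missing_to_mean",
    "qc_pipeline",
]

logger = logging.getLogger(__name__)

#: marker pairs sharing fewer jointly observed samples than this are never
#: declared duplicates -- the agreement estimate is too unstable
MIN_JOINT_OBS = 10


def _keep(g: GenotypeMatrix, keep_mask: np.ndarray) -> GenotypeMatrix:
    kept_ids = [m for m, k in zip(g.marker_ids, keep_mask) if k]
    return GenotypeMatrix(
        g.sample_ids, kept_ids, g.codes[:, keep_mask].copy(), g.population_labels.copy()
    )


def qc_filter_maf(
    g: GenotypeMatrix, threshold: float = 0.05
) -> tuple[GenotypeMatrix, QCReport]:
    """Drop markers with minor allele frequency strictly below ``threshold``.

    MAF is computed over non-missing codes pooled across all samples of the
    matrix passed in.  A marker sitting exactly at the threshold is kept.
    """
    if not 0.0 < threshold <= 0.5:
        raise ValueError("MAF threshold must lie in (0, 0.5]")
    keep = g.maf() >= threshold
    report = QCReport(
        removed_maf=[m for m, k in zip(g.marker_ids, keep) if not k],
        kept=[m for m, k in zip(g.marker_ids, keep) if k],
    )
    if not keep.any():
        logger.warning("MAF filter removed every marker")
    return _keep(g, keep), report


def qc_filter_missing(
    g: GenotypeMatrix, max_rate: float = 0.10
) -> tuple[GenotypeMatrix, QCReport]:
    """Drop markers whose missing fraction strictly exceeds ``max_rate``."""
    if not 0.0 <= max_rate <= 1.0:
        raise ValueError("max_rate must lie in [0, 1]")
    keep = g.missing_rate() <= max_rate
    report = QCReport(
        removed_missing=[m for m, k in zip(g.marker_ids, keep) if not k],
        kept=[m for m, k in zip(g.marker_ids, keep) if k],
    )
    return _keep(g, keep), report


def _pair_agreement(a: np.ndarray, b: np.ndarray) -> float:
    """Largest of identity / complementarity fractions over joint calls.

    Returns ``nan`` when fewer than :data:`MIN_JOINT_OBS` samples are
    observed at both loci.
    """
    both = ~np.isnan(a) & ~np.isnan(b)
    n = int(both.sum())
    if n < MIN_JOINT_OBS:
        return float("nan")
    same = float(np.mean(a[both] == b[both]))
    comp = float(np.mean(a[both] == 2.0 - b[both]))
    return max(same, comp)


def qc_filter_near_duplicates(
    g: GenotypeMatrix,
    agreement: float = 0.95,
    window: int = 100,
    all_pairs: bool = False,
) -> tuple[GenotypeMatrix, QCReport]:
    """Drop later markers that nearly duplicate an earlier one.

    Two loci count as duplicates when, over samples observed at both, the
    larger of the identical fraction and the complementary fraction
    (``g1 == 2 - g2``) reaches ``agreement``.  By default each marker is
    compared against the ``window`` preceding surviving markers only;
    LD-driven duplicates are positional, and the all-pairs scan is
    quadratic in panel size (available via ``all_pairs=True``).
    """
    if not 0.0 < agreement <= 1.0:
        raise ValueError("agreement must lie in (0, 1]")
    m = g.n_markers
    keep = np.ones(m, dtype=bool)
    kept_cols: list[int] = []
    for j in range(m):
        candidates = kept_cols if all_pairs else kept_cols[-window:]
        for i in candidates:
            agr = _pair_agreement(g.codes[:, i], g.codes[:, j])
            if not np.isnan(agr) and agr >= agreement:
                keep[j] = False
                break
        if keep[j]:
            kept_cols.append(j)
    report = QCReport(
        removed_duplicate=[mk for mk, k in zip(g.marker_ids, keep) if not k],
        kept=[mk for mk, k in zip(g.marker_ids, keep) if k],
    )
    return _keep(g, keep), report


def qc_filter_chromosomes(
    g: GenotypeMatrix, marker_map: MarkerMap, exclude: Sequence[str] = ("X", "Y")
) -> tuple[GenotypeMatrix, list[str]]:
    """Optional map-based filter: drop unmapped markers and excluded chromosomes.

    Sits outside the canonical four-bucket pipeline, so it returns the list
    of dropped marker ids rather than a :class:`QCReport`.
    """
    chroms = marker_map.chromosomes_of(g.marker_ids)
    keep = (~chroms.isna() & ~chroms.isin(list(exclude))).to_numpy()
    dropped = [mk for mk, k in zip(g.marker_ids, keep) if not k]
    return _keep(g, keep), dropped


def harmonize_panels(
    gs: Sequence[GenotypeMatrix],
) -> tuple[list[GenotypeMatrix], list[QCReport]]:
    """Restrict every population's panel to the common surviving marker set.

    A marker filtered out in one population is removed from all others, so
    downstream models see one shared marker order (taken from the first
    matrix).  Raises ``ValueError`` when no marker survives everywhere.
    """
    if not gs:
        raise ValueError("no panels to harmonize")
    common = set(gs[0].marker_ids)
    for g in gs[1:]:
        common &= set(g.marker_ids)
    if not common:
        raise ValueError("harmonize_panels: no marker shared by all populations")
    order = [m for m in gs[0].marker_ids if m in common]
    out_g: list[GenotypeMatrix] = []
    out_r: list[QCReport] = []
    for g in gs:
        out_g.append(g.select_markers(order))
        out_r.append(
            QCReport(
                removed_cross_population=[m for m in g.marker_ids if m not in common],
                kept=list(order),
            )
        )
    return out_g, out_r


def impute_missing_to_mean(g: GenotypeMatrix) -> np.ndarray:
    """Fill missing cells with the within-population mean code of the marker.

    Returns a real-valued ``(n, m)`` array suitable for the samplers; it is
    never written back as integer genotype codes.  A marker with no observed
    call inside some population is an error.
    """
    out = g.codes.copy()
    for pop in g.populations:
        rows = g.population_labels == pop
        block = out[rows, :]
        obs = ~np.isnan(block)
        if not obs.all():
            n_obs = obs.sum(axis=0)
            empty = np.nonzero(n_obs == 0)[0]
            if empty.size:
                raise ValueError(
                    f"marker {g.marker_ids[empty[0]]!r} has no observed genotype "
                    f"in population {pop!r}"
                )
            means = np.nansum(block, axis=0) / n_obs
            block[~obs] = np.broadcast_to(means, block.shape)[~obs]
            out[rows, :] = block
    return out


def qc_pipeline(
    gs: Sequence[GenotypeMatrix],
    maf_threshold: float = 0.05,
    max_missing: float = 0.10,
    duplicate_agreement: float = 0.95,
    window: int = 100,
    all_pairs: bool = False,
) -> tuple[list[GenotypeMatrix], list[QCReport]]:
    """Per-population MAF -> missingness -> near-duplicate filters, then harmonize."""
    filtered: list[GenotypeMatrix] = []
    reports: list[QCReport] = []
    for g in gs:
        g1, r1 = qc_filter_maf(g, maf_threshold)
        g2, r2 = qc_filter_missing(g1, max_missing)
        g3, r3 = qc_filter_near_duplicates(
            g2, duplicate_agreement, window=window, all_pairs=all_pairs
        )
        report = r1.merged_with(r2).merged_with(r3)
        logger.info(
            "QC: %d -> %d markers (maf %d, missing %d, duplicate %d)",
            g.n_markers,
            g3.n_markers,
            len(report.removed_maf),
            len(report.removed_missing),
            len(report.removed_duplicate),
        )
        filtered.append(g3)
        reports.append(report)
    harmonized, cross = harmonize_panels(filtered)
    merged = [r.merged_with(c) for r, c in zip(reports, cross)]
    for rep, g in zip(merged, gs):
        rep.check_partition(g.marker_ids)
    return harmonized, merged
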