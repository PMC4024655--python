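"""Core domain containers for genotype, phenotype and marker-map data.

Genotypes are additive allele counts (0, 1, 2) with ``NaN`` marking missing
cells.  Each sample carries a population label; the models in
:mod:`mtgp.gibbs` treat populations as related prediction tasks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "MarkerMap",
    "PhenotypeTable",
    "QCReport",
]


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
        raise ValueError(f"duplicate {what} id: {dup!r}")


@dataclass
class GenotypeMatrix:
    """Samples x markers table of additive genotype codes.

    Parameters
    ----------
    sample_ids
        Unique sample identifiers, one per row of ``codes``.
    marker_ids
        Unique marker identifiers, one per column of ``codes``.
    codes
        ``(n, m)`` float array with entries in ``{0, 1, 2}`` or ``NaN``
        (missing).  Codes count copies of an arbitrarily chosen reference
        allele.
    population_labels
        Per-sample population label.  Any hashable string label is accepted;
        every label present names a non-empty subset by construction.
    """

    sample_ids: list[str]
    marker_ids: list[str]
    codes: np.ndarray
    population_labels: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.marker_ids = [str(m) for m in self.marker_ids]
        self.codes = np.asarray(self.codes, dtype=float)
        self.population_labels = np.asarray(
            [str(p) for p in np.asarray(self.population_labels).ravel()], dtype=object
        )
        if self.codes.ndim != 2:
            raise ValueError("codes must be a 2-D array")
        n, m = self.codes.shape
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(self.marker_ids) != m:
            raise ValueError(f"{len(self.marker_ids)} marker ids for {m} columns")
        if len(self.population_labels) != n:
            raise ValueError("population_labels length must equal sample count")
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.marker_ids, "marker")
        finite = self.codes[~np.isnan(self.codes)]
        if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
            bad = finite[~np.isin(finite, (0.0, 1.0, 2.0))][0]
            raise ValueError(f"genotype codes must be 0/1/2/missing, got {bad!r}")

    # -- basic shape -----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.codes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.codes.shape[1]

    @property
    def populations(self) -> list[str]:
        """Population labels in order of first appearance."""
        seen: dict[str, None] = {}
        for p in self.population_labels:
            seen.setdefault(p)
        return list(seen)

    # -- per-marker statistics -------------------------------------------
    def allele_freq(self) -> np.ndarray:
        """Reference-allele frequency per marker over non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.codes, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        """Minor allele frequency per marker over non-missing calls."""
        f = self.allele_freq()
        return np.minimum(f, 1.0 - f)

    def missing_rate(self) -> np.ndarray:
        return np.isnan(self.codes).mean(axis=0)

    # -- subsetting ------------------------------------------------------
    def select_markers(self, marker_ids: Iterable[str]) -> "GenotypeMatrix":
        """Return a copy restricted to ``marker_ids`` in the given order."""
        wanted = list(marker_ids)
        index = {m: j for j, m in enumerate(self.marker_ids)}
        missing = [m for m in wanted if m not in index]
        if missing:
            raise KeyError(f"unknown marker ids: {missing[:5]}")
        cols = [index[m] for m in wanted]
        return GenotypeMatrix(
            self.sample_ids, wanted, self.codes[:, cols].copy(), self.population_labels.copy()
        )

    def select_samples(self, sample_ids: Iterable[str]) -> "GenotypeMatrix":
        wanted = list(sample_ids)
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in wanted if s not in index]
        if missing:
            raise KeyError(f"unknown sample ids: {missing[:5]}")
        rows = [index[s] for s in wanted]
        return GenotypeMatrix(
            wanted, self.marker_ids, self.codes[rows, :].copy(), self.population_labels[rows].copy()
        )

    def split_by_population(self) -> dict[str, "GenotypeMatrix"]:
        """Partition samples into per-population matrices (marker order kept)."""
        out: dict[str, GenotypeMatrix] = {}
        for pop in self.populations:
            mask = self.population_labels == pop
            out[pop] = GenotypeMatrix(
                [s for s, keep in zip(self.sample_ids, mask) if keep],
                self.marker_ids,
                self.codes[mask, :].copy(),
                self.population_labels[mask].copy(),
            )
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.marker_ids == other.marker_ids
            and list(self.population_labels) == list(other.population_labels)
            and np.array_equal(self.codes, other.codes, equal_nan=True)
        )


@dataclass
class MarkerMap:
    """Optional physical map: marker -> (chromosome, base-pair position)."""

    table: pd.DataFrame  # columns: marker_id, chrom, pos

    def __post_init__(self) -> None:
        required = {"marker_id", "chrom", "pos"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"marker map needs columns {sorted(required)}")
        if self.table["marker_id"].duplicated().any():
            raise ValueError("duplicate marker ids in map")
        if (self.table["pos"] < 0).any():
            raise ValueError("positions must be non-negative")

    def chromosomes_of(self, marker_ids: Iterable[str]) -> pd.Series:
        lookup = self.table.set_index("marker_id")["chrom"]
        return lookup.reindex(list(marker_ids))


@dataclass
class PhenotypeTable:
    """One trait record per sample: (sample_id, population_label, value)."""

    sample_ids: list[str]
    population_labels: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.population_labels = np.asarray(
            [str(p) for p in np.asarray(self.population_labels).ravel()], dtype=object
        )
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not (len(self.sample_ids) == len(self.population_labels) == len(self.values)):
            raise ValueError("sample_ids, population_labels and values must align")
        _check_unique(self.sample_ids, "sample")
        if not np.isfinite(self.values).all():
            raise ValueError("phenotype values must be finite")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "population_label": self.population_labels,
                "value": self.values,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PhenotypeTable":
        return cls(
            list(df["sample_id"]),
            df["population_label"].to_numpy(),
            df["value"].to_numpy(),
        )

    def values_for(self, sample_ids: Sequence[str]) -> np.ndarray:
        lookup = dict(zip(self.sample_ids, self.values))
        return np.array([lookup[s] for s in sample_ids], dtype=float)


@dataclass
class QCReport:
    """Bookkeeping for marker QC: which markers each filter removed.

    ``kept`` together with the four removal lists partitions the input
    marker set of the filter run that produced the report.
    """

    removed_maf: list[str] = field(default_factory=list)
    removed_missing: list[str] = field(default_factory=list)
    removed_duplicate: list[str] = field(default_factory=list)
    removed_cross_population: list[str] = field(default_factory=list)
    kept: list[str] = field(default_factory=list)

    @property
    def removed(self) -> list[str]:
        return (
            self.removed_maf
            + self.removed_missing
            + self.removed_duplicate
            + self.removed_cross_population
        )

    def check_partition(self, input_markers: Sequence[str]) -> None:
        """Raise unless kept + removed exactly partition ``input_markers``."""
        all_ids = self.kept + self.removed
        if len(set(all_ids)) != len(all_ids):
            raise ValueError("QC report lists a marker more than once")
        if set(all_ids) != set(input_markers):
            raise ValueError("QC report does not partition the input marker set")

    def merged_with(self, other: "QCReport") -> "QCReport":
        """Sequential composition: this report's kept set was other's input."""
        return QCReport(
            removed_maf=self.removed_maf + other.removed_maf,
            removed_missing=self.removed_missing + other.removed_missing,
            removed_duplicate=self.removed_duplicate + other.removed_duplicate,
            removed_cross_population=self.removed_cross_population
            + other.removed_cross_population,
            kept=other.kept,
        )
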