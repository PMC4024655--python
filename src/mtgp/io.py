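"""Readers and writers for genotype, phenotype and map tables.

Two plain-text genotype dialects are supported:

``tsv``
    Header line: ``sample_id<TAB>population_label<TAB><marker ids...>``;
    one row per sample with codes 0/1/2 and ``NA`` for missing.

``plink_raw``
    The PLINK ``--recode A`` additive dialect: six leading columns
    (FID IID PAT MAT SEX PHENOTYPE) followed by one allele-count column per
    marker, ``NA`` for missing.  The FID column doubles as the population
    label; any other label source can be attached afterwards.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix, MarkerMap, PhenotypeTable
from .gibbs import PosteriorSummary

__all__ = [
    "read_genotypes",
    "write_genotypes",
    "read_phenotypes",
    "write_phenotypes",
    "read_marker_map",
    "write_posterior_summary",
    "read_posterior_summary",
]

PathLike = Union[str, Path]

_RAW_LEADING = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


class FormatError(ValueError):
    """Raised when a file does not parse in the declared dialect."""


def _parse_codes(block: pd.DataFrame, where: str) -> np.ndarray:
    codes = block.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    # distinguish true NA tokens from unparseable garbage
    raw_na = block.isna() | block.astype(str).isin(["NA", "nan"])
    bad = np.isnan(codes) & ~raw_na.to_numpy()
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise FormatError(f"{where}: unparseable genotype cell at row {i}, column {j}")
    return codes


def read_genotypes(path: PathLike, format: str = "tsv") -> GenotypeMatrix:
    """Read a genotype table in the ``tsv`` or ``plink_raw`` dialect.

    Returns a :class:`GenotypeMatrix`; ``NA`` cells become missing.  Raises
    :class:`FormatError` on malformed headers and ``ValueError`` on
    duplicate identifiers (via ``GenotypeMatrix`` validation).
    """
    path = Path(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", dtype=str, na_values=["NA"], keep_default_na=False)
        if df.shape[1] < 3 or list(df.columns[:2]) != ["sample_id", "population_label"]:
            raise FormatError(
                f"{path}: genotype TSV must start with sample_id, population_label columns"
            )
        marker_ids = list(df.columns[2:])
        codes = _parse_codes(df.iloc[:, 2:], str(path))
        return GenotypeMatrix(
            list(df["sample_id"]), marker_ids, codes, df["population_label"].to_numpy()
        )
    if format == "plink_raw":
        df = pd.read_csv(path, sep=r"\s+", dtype=str, na_values=["NA"], keep_default_na=False)
        if list(df.columns[:6]) != _RAW_LEADING:
            raise FormatError(f"{path}: PLINK RAW header must begin {' '.join(_RAW_LEADING)}")
        marker_ids = list(df.columns[6:])
        if not marker_ids:
            raise FormatError(f"{path}: PLINK RAW file has no genotype columns")
        codes = _parse_codes(df.iloc[:, 6:], str(path))
        return GenotypeMatrix(list(df["IID"]), marker_ids, codes, df["FID"].to_numpy())
    raise ValueError(f"unknown genotype format {format!r}")


def write_genotypes(g: GenotypeMatrix, path: PathLike, format: str = "tsv") -> None:
    """Write ``g`` in the named dialect; missing cells become ``NA``."""
    path = Path(path)

    def fmt(v: float) -> str:
        return "NA" if np.isnan(v) else str(int(v))

    buf = _io.StringIO()
    if format == "tsv":
        buf.write("sample_id\tpopulation_label\t" + "\t".join(g.marker_ids) + "\n")
        for i, sid in enumerate(g.sample_ids):
            row = "\t".join(fmt(v) for v in g.codes[i])
            buf.write(f"{sid}\t{g.population_labels[i]}\t{row}\n")
    elif format == "plink_raw":
        buf.write(" ".join(_RAW_LEADING + g.marker_ids) + "\n")
        for i, sid in enumerate(g.sample_ids):
            row = " ".join(fmt(v) for v in g.codes[i])
            buf.write(f"{g.population_labels[i]} {sid} 0 0 0 -9 {row}\n")
    else:
        raise ValueError(f"unknown genotype format {format!r}")
    path.write_text(buf.getvalue())


def read_phenotypes(path: PathLike) -> PhenotypeTable:
    """Read a phenotype TSV with columns sample_id, population_label, value."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "population_label": str})
    required = {"sample_id", "population_label", "value"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: phenotype TSV needs columns {sorted(required)}")
    return PhenotypeTable.from_frame(df)


def write_phenotypes(p: PhenotypeTable, path: PathLike) -> None:
    p.to_frame().to_csv(path, sep="\t", index=False)


def write_posterior_summary(summary: PosteriorSummary, path: PathLike) -> None:
    """Write a fitted summary as TSV: marker_id, population, effect_mean,
    inclusion_prob (long format), with scalar posterior means and run
    metadata in ``#`` header comments."""
    path = Path(path)
    lines = ["# mtgp posterior summary"]
    for key, val in summary.meta.items():
        lines.append(f"# meta {key} {val}")
    lines.append(f"# w_mean {float(summary.w_mean)!r}")
    lines.append(f"# n_samples_used {summary.n_samples_used}")
    lines.append(f"# max_residual_dev {float(summary.max_residual_dev)!r}")
    for k, lab in enumerate(summary.populations):
        lines.append(
            f"# variance {lab} sigma2_a_mean {float(summary.sigma2_a_mean[k])!r} "
            f"sigma2_e_mean {float(summary.sigma2_e_mean[k])!r}"
        )
    for k, lab in enumerate(summary.mu_populations):
        lines.append(f"# intercept {lab} {float(summary.mu_mean[k])!r}")
    lines.append("marker_id\tpopulation\teffect_mean\tinclusion_prob")
    m = summary.effect_mean.shape[0]
    ids = summary.marker_ids or [f"m{j:06d}" for j in range(m)]
    for k, lab in enumerate(summary.populations):
        for j in range(m):
            lines.append(
                f"{ids[j]}\t{lab}\t{float(summary.effect_mean[j, k])!r}\t"
                f"{float(summary.inclusion_prob[j])!r}"
            )
    path.write_text("\n".join(lines) + "\n")


def read_posterior_summary(path: PathLike) -> PosteriorSummary:
    """Reconstruct a :class:`PosteriorSummary` written by
    :func:`write_posterior_summary`."""
    path = Path(path)
    meta: dict = {}
    w_mean = np.nan
    n_used = 0
    max_dev = 0.0
    variances: dict[str, tuple[float, float]] = {}
    intercepts: dict[str, float] = {}
    body: list[str] = []
    for line in path.read_text().splitlines():
        if line.startswith("#"):
            parts = line[1:].split()
            if not parts:
                continue
            if parts[0] == "meta" and len(parts) >= 3:
                meta[parts[1]] = " ".join(parts[2:])
            elif parts[0] == "w_mean":
                w_mean = float(parts[1])
            elif parts[0] == "n_samples_used":
                n_used = int(parts[1])
            elif parts[0] == "max_residual_dev":
                max_dev = float(parts[1])
            elif parts[0] == "variance":
                variances[parts[1]] = (float(parts[3]), float(parts[5]))
            elif parts[0] == "intercept":
                intercepts[parts[1]] = float(parts[2])
        else:
            body.append(line)
    df = pd.read_csv(_io.StringIO("\n".join(body)), sep="\t", dtype={"marker_id": str})
    populations = list(dict.fromkeys(df["population"]))
    marker_ids = list(dict.fromkeys(df["marker_id"]))
    m = len(marker_ids)
    effect_mean = np.column_stack(
        [df.loc[df["population"] == lab, "effect_mean"].to_numpy() for lab in populations]
    )
    inclusion = df.loc[df["population"] == populations[0], "inclusion_prob"].to_numpy()
    mu_pops = list(intercepts)
    return PosteriorSummary(
        populations=populations,
        mu_populations=mu_pops,
        effect_mean=effect_mean.reshape(m, len(populations)),
        inclusion_prob=inclusion,
        mu_mean=np.array([intercepts[p] for p in mu_pops]),
        w_mean=w_mean,
        sigma2_a_mean=np.array([variances[p][0] for p in populations]),
        sigma2_e_mean=np.array([variances[p][1] for p in populations]),
        n_samples_used=n_used,
        max_residual_dev=max_dev,
        marker_ids=marker_ids,
        meta=meta,
    )


def read_marker_map(path: PathLike) -> MarkerMap:
    """Read a map TSV with columns marker_id, chrom, pos."""
    df = pd.read_csv(path, sep="\t", dtype={"marker_id": str, "chrom": str, "pos": int})
    required = {"marker_id", "chrom", "pos"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: marker map TSV needs columns {sorted(required)}")
    return MarkerMap(df)
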