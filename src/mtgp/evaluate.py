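"""GEBV prediction and the two validation metrics: accuracy and slope bias.

Accuracy is r(GEBV, TBV), the Pearson correlation in the validation set.
Bias is measured by b(TBV, GEBV), the coefficient from regressing TBV on
GEBV: b < 1 means the GEBV are over-dispersed (inflated), b > 1 deflated.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix
from .gibbs import PosteriorSummary

__all__ = [
    "predict_gebv",
    "accuracy_r",
    "slope_b",
    "replicate_summary",
]


def predict_gebv(summary: PosteriorSummary, g: GenotypeMatrix) -> pd.DataFrame:
    """Point-prediction GEBV for every sample of ``g``.

    gebv_i = mu_k(i) + sum_j x_ij * effect_mean[j, k(i)], using the
    sample's population column of the posterior effect means (the shared
    column for pooled fits) and its population intercept.  Marker sets must
    match; if the summary carries marker ids in a different order the
    genotypes are realigned to them.
    """
    if summary.marker_ids is not None:
        if set(summary.marker_ids) != set(g.marker_ids):
            raise ValueError("summary and genotype marker sets differ")
        if summary.marker_ids != g.marker_ids:
            g = g.select_markers(summary.marker_ids)
    elif summary.effect_mean.shape[0] != g.n_markers:
        raise ValueError("summary and genotype marker counts differ")
    X = g.codes
    if np.isnan(X).any():
        raise ValueError("validation genotypes must be complete")
    gebv = np.empty(g.n_samples)
    for pop in g.populations:
        rows = g.population_labels == pop
        beta = summary.effects_for(pop)
        gebv[rows] = summary.intercept_for(pop) + X[rows, :] @ beta
    return pd.DataFrame(
        {
            "sample_id": g.sample_ids,
            "population_label": g.population_labels,
            "gebv": gebv,
        }
    )


def _check_vectors(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    if a.size < 3:
        raise ValueError("need at least 3 observations")
    return a, b


def accuracy_r(gebv: np.ndarray, tbv: np.ndarray) -> float:
    """Pearson correlation r(GEBV, TBV)."""
    gebv, tbv = _check_vectors(gebv, tbv)
    if np.var(gebv) == 0.0 or np.var(tbv) == 0.0:
        raise ValueError("accuracy undefined for a zero-variance vector")
    return float(np.corrcoef(gebv, tbv)[0, 1])


def slope_b(gebv: np.ndarray, tbv: np.ndarray) -> float:
    """Regression coefficient of TBV on GEBV: cov(TBV, GEBV) / var(GEBV)."""
    gebv, tbv = _check_vectors(gebv, tbv)
    v = np.var(gebv, ddof=1)
    if v == 0.0:
        raise ValueError("slope undefined for zero-variance GEBV")
    cov = np.cov(tbv, gebv, ddof=1)[0, 1]
    return float(cov / v)


def replicate_summary(results: pd.DataFrame, by: list[str] | None = None) -> pd.DataFrame:
    """Mean and standard error of r and b across replicates.

    ``results`` holds one row per replicate with columns ``r`` and ``b``
    plus any grouping columns (method, population, scenario...).  The
    plus/minus reported alongside means is the standard error of the mean,
    sd / sqrt(n_replicates).
    """
    if not {"r", "b"}.issubset(results.columns):
        raise ValueError("results need columns 'r' and 'b'")

    def _agg(df: pd.DataFrame) -> pd.Series:
        n = len(df)
        if n < 2:
            raise ValueError("replicate_summary needs at least 2 replicates")
        return pd.Series(
            {
                "r_mean": df["r"].mean(),
                "r_se": df["r"].std(ddof=1) / np.sqrt(n),
                "b_mean": df["b"].mean(),
                "b_se": df["b"].std(ddof=1) / np.sqrt(n),
                "n_replicates": n,
            }
        )

    if by:
        out = results.groupby(by, sort=False).apply(_agg, include_groups=False).reset_index()
    else:
        out = _agg(results).to_frame().T
    out["n_replicates"] = out["n_replicates"].astype(int)
    return out
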