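"""Marker QC on genotype panels with missing data.

Builds two small panels with planted defects — a rare allele, a high
missing rate, a duplicated column — runs the canonical filter order
(MAF -> missingness -> near-duplicate -> cross-population harmonization)
and prints what each filter removed.  The harmonized panels share one
marker set: anything filtered in either population is dropped from both.
"""

import numpy as np

from mtgp import GenotypeMatrix, impute_missing_to_mean, qc_pipeline

rng = np.random.default_rng(11)
n, m = 50, 12
panels = []
for pop in ("A", "B"):
    codes = rng.integers(0, 3, size=(n, m)).astype(float)
    codes[:, 2] = 0.0                       # monomorphic -> MAF filter
    codes[: n // 4, 5] = np.nan             # 25% missing -> missingness filter
    codes[:, 8] = codes[:, 7]               # duplicate -> near-duplicate filter
    if pop == "B":
        codes[:, 11] = 0.0                  # fails MAF only in B -> harmonization
    panels.append(
        GenotypeMatrix(
            [f"{pop}{i}" for i in range(n)],
            [f"m{j}" for j in range(m)],
            codes,
            np.asarray([pop] * n, dtype=object),
        )
    )

harmonized, reports = qc_pipeline(panels)
for pop, rep in zip(("A", "B"), reports):
    print(
        f"population {pop}: kept {len(rep.kept)}, "
        f"maf-removed {rep.removed_maf}, missing-removed {rep.removed_missing}, "
        f"duplicate-removed {rep.removed_duplicate}, "
        f"cross-population {rep.removed_cross_population}"
    )
assert harmonized[0].marker_ids == harmonized[1].marker_ids
print(f"shared marker set: {harmonized[0].marker_ids}")

# remaining missing cells are mean-imputed within population before sampling
X = impute_missing_to_mean(harmonized[0])
print(f"missing cells after imputation: {int(np.isnan(X).sum())}")
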