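#!/usr/bin/env python
"""Multivariate screening of the simulated trial: PCA of the standardized
genotype-by-trait matrix of adjusted means (with the varimax variant),
the significance-masked trait correlation matrix, Ward clustering, and the
composite rank-sum classification into top / intermediate / low performers.

Reads results/sim/, writes results/multivariate/.
"""
from pathlib import Path

import pandas as pd

import wheatscreen as ws

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    out = ROOT / "multivariate"
    out.mkdir(parents=True, exist_ok=True)
    fb = ws.read_fieldbook(ROOT / "sim" / "fieldbook.tsv")
    adjusted = {t: ws.adjust_means(fb, t) for t in fb.trait_names}
    tm = ws.build_trait_matrix(adjusted)

    res = ws.pca(tm, n_components=2)
    load = res.loadings.copy()
    load.loc["Explained variance (eigenvalue)"] = res.eigenvalues[:2]
    load.loc["Proportion of total variance (%)"] = res.proportion
    load.loc["Cumulative percent of variance (%)"] = res.cumulative
    load.to_csv(out / "pca_loadings.tsv", sep="\t")
    res.scores.to_csv(out / "pca_scores.tsv", sep="\t")
    ws.pca(tm, n_components=2, rotation="varimax").loadings.to_csv(
        out / "pca_loadings_varimax.tsv", sep="\t")
    print(f"PC1+PC2 explain {res.cumulative[-1]:.1f}% of trait variance "
          f"(eigenvalues {res.eigenvalues[0]:.2f}, {res.eigenvalues[1]:.2f})")

    corr = ws.correlation_matrix(tm, alpha=0.05)
    corr.r.to_csv(out / "correlation_r.tsv", sep="\t")
    corr.p.to_csv(out / "correlation_p.tsv", sep="\t")
    n_sig = int(corr.significant.to_numpy().sum() // 2)
    print(f"{n_sig} of {len(tm.traits) * (len(tm.traits) - 1) // 2} trait pairs "
          f"significant at alpha = 0.05 (independent simulated effects, so few expected)")

    tree = ws.hierarchical_clusters(tm, method="ward", k=3)
    tree.assignments.rename("cluster").rename_axis("genotype").reset_index().to_csv(
        out / "clusters.tsv", sep="\t", index=False)
    sizes = tree.assignments.value_counts().sort_index()
    print("Ward clusters at k=3:", dict(sizes))

    ranking = ws.rank_genotypes(tm, ws.study_trait_registry(), top_n=10, bottom_n=5)
    ranking.table.rename_axis("genotype").reset_index().to_csv(
        out / "ranking.tsv", sep="\t", index=False)
    top = list(ranking.table.index[:10])
    low = list(ranking.table.index[-5:])
    print(f"top-10 composite performers: {top}")
    print(f"lowest five: {low}")


if __name__ == "__main__":
    main()
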