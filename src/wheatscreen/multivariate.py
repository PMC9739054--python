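"""Multivariate screening: genotype-by-trait matrix, PCA, correlations,
hierarchical clustering and composite ranking.

The screening layer works on the standardized genotypes-by-traits matrix of
adjusted means.  PCA is the eigen-decomposition of the trait correlation
matrix; loadings are scaled eigenvectors (trait-component correlations), so
eigenvalues sum to the number of traits and squared loadings per trait sum
to one over all components.  An optional varimax rotation of the retained
loadings is provided.  Ranking orients each trait by its registered
direction (rank 1 most favourable) and combines per-trait ranks into a
weighted mean rank.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from statsmodels.multivariate.factor_rotation import rotate_factors

from .augmented_design import AdjustedMeans
from .errors import AnalysisError, ParameterError
from .io_formats import TraitRegistry


@dataclass
class TraitMatrix:
    genotypes: list[str]
    traits: list[str]
    values: np.ndarray  # genotypes x traits
    standardized: bool = False
    raw_values: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genotypes), len(self.traits)):
            raise ParameterError("trait matrix shape mismatch")
        if np.isnan(self.values).any():
            raise ParameterError("trait matrix holds missing values")

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genotypes, columns=self.traits)


@dataclass
class PCAResult:
    eigenvalues: np.ndarray
    proportion: np.ndarray  # percent per retained component
    cumulative: np.ndarray
    loadings: pd.DataFrame  # traits x retained components
    scores: pd.DataFrame  # genotypes x retained components
    cos2_genotypes: pd.DataFrame
    cos2_traits: pd.DataFrame
    rotation_applied: str = "none"


@dataclass
class CorrelationResult:
    r: pd.DataFrame
    p: pd.DataFrame
    significant: pd.DataFrame  # True where p < alpha, off-diagonal
    alpha: float


@dataclass
class ClusterTree:
    linkage_matrix: np.ndarray
    genotypes: list[str]
    leaf_order: list[str]
    assignments: pd.Series  # genotype -> cluster id (1..k)
    k: int
    method: str


@dataclass
class RankingTable:
    table: pd.DataFrame  # per-trait ranks + composite + final_rank + class
    trait_ranks: pd.DataFrame


def standardize(values: np.ndarray) -> np.ndarray:
    """Column z-scores with the n-1 sd; zero-variance columns are an error."""
    values = np.asarray(values, dtype=float)
    sd = values.std(axis=0, ddof=1)
    if np.any(sd == 0):
        idx = int(np.argwhere(sd == 0)[0][0])
        raise AnalysisError(f"column {idx} has zero variance; cannot standardize")
    return (values - values.mean(axis=0)) / sd


def build_trait_matrix(
    adjusted: Mapping[str, AdjustedMeans],
    traits: Sequence[str] | None = None,
    impute: bool = False,
) -> TraitMatrix:
    """Assemble and z-standardize the genotypes-by-traits matrix.

    Every selected trait must supply an adjusted mean for every genotype;
    with ``impute=True`` missing cells take the trait's column mean instead
    of failing.
    """
    traits = list(traits) if traits is not None else list(adjusted.keys())
    if not traits:
        raise ParameterError("no traits selected")
    genotypes = sorted(adjusted[traits[0]].table["genotype"])
    frame = pd.DataFrame(index=genotypes, columns=traits, dtype=float)
    for trait in traits:
        if trait not in adjusted:
            raise ParameterError(f"no adjusted means supplied for trait {trait!r}")
        frame[trait] = adjusted[trait].series.reindex(genotypes)
    if frame.isna().any().any():
        if not impute:
            g = frame.isna().stack()
            g, t = g[g].index[0]
            raise AnalysisError(f"missing adjusted mean for genotype {g!r}, trait {t!r}")
        frame = frame.fillna(frame.mean())
    raw = frame.to_numpy()
    return TraitMatrix(
        genotypes=list(frame.index),
        traits=traits,
        values=standardize(raw),
        standardized=True,
        raw_values=raw,
    )


# -- PCA -------------------------------------------------------------------

def _fix_signs(loadings: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Make each component's largest-|loading| entry positive (deterministic)."""
    for j in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] = -loadings[:, j]
            scores[:, j] = -scores[:, j]
    return loadings, scores


def pca(matrix: TraitMatrix, n_components: int = 2, rotation: str = "none") -> PCAResult:
    """Correlation-matrix PCA with optional varimax rotation of the
    retained loadings.

    Loadings are eigenvectors scaled by sqrt(eigenvalue), i.e. the
    correlation of each trait with each component; varimax rotates the
    retained loading block while preserving its total sum of squares.
    """
    if not matrix.standardized:
        raise ParameterError("PCA expects a standardized trait matrix")
    n, p = matrix.values.shape
    if not 1 <= n_components <= p:
        raise ParameterError(f"n_components must lie in [1, {p}]")
    if rotation not in ("none", "varimax"):
        raise ParameterError(f"unknown rotation {rotation!r}")
    Z = matrix.values
    corr = Z.T @ Z / (n - 1)
    vals, vecs = np.linalg.eigh(corr)
    order = np.argsort(vals)[::-1]
    vals, vecs = np.maximum(vals[order], 0.0), vecs[:, order]
    rank = int(np.linalg.matrix_rank(corr))
    if n_components > rank:
        raise AnalysisError(f"n_components {n_components} exceeds matrix rank {rank}")
    scores_full = Z @ vecs
    load_full = vecs * np.sqrt(vals)
    load_full, scores_full = _fix_signs(load_full, scores_full)

    comp_names = [f"PC{j + 1}" for j in range(n_components)]
    loadings = load_full[:, :n_components].copy()
    scores = scores_full[:, :n_components].copy()
    explained = vals[:n_components].copy()
    if rotation == "varimax":
        loadings, rot = rotate_factors(loadings, "varimax")
        scores = scores_full[:, :n_components] @ rot
        loadings, scores = _fix_signs(loadings, scores)
        explained = (loadings ** 2).sum(axis=0)
        order2 = np.argsort(explained)[::-1]
        loadings, scores, explained = loadings[:, order2], scores[:, order2], explained[order2]

    proportion = 100.0 * explained / p
    cumulative = np.cumsum(proportion)

    # cos2: squared cosines over ALL components (sum to 1 per entity)
    row_sq = (scores_full ** 2).sum(axis=1, keepdims=True)
    cos2_g = (scores ** 2) / np.where(row_sq == 0, 1.0, row_sq)
    trait_sq = (load_full ** 2).sum(axis=1, keepdims=True)
    cos2_t = (loadings ** 2) / np.where(trait_sq == 0, 1.0, trait_sq)

    return PCAResult(
        eigenvalues=vals,
        proportion=proportion,
        cumulative=cumulative,
        loadings=pd.DataFrame(loadings, index=matrix.traits, columns=comp_names),
        scores=pd.DataFrame(scores, index=matrix.genotypes, columns=comp_names),
        cos2_genotypes=pd.DataFrame(cos2_g, index=matrix.genotypes, columns=comp_names),
        cos2_traits=pd.DataFrame(cos2_t, index=matrix.traits, columns=comp_names),
        rotation_applied=rotation,
    )


# -- correlations ----------------------------------------------------------

def correlation_matrix(
    matrix: TraitMatrix, alpha: float = 0.05, adjust: str | None = None
) -> CorrelationResult:
    """Pairwise Pearson r with two-sided p-values and a significance mask.

    No multiple-testing correction by default; ``adjust='holm'`` applies a
    Holm step-down over the off-diagonal p-values.
    """
    n, p = matrix.values.shape
    if n < 3:
        raise AnalysisError("correlations need at least 3 genotypes")
    r = np.eye(p)
    pv = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            rij, pij = stats.pearsonr(matrix.values[:, i], matrix.values[:, j])
            r[i, j] = r[j, i] = rij
            pv[i, j] = pv[j, i] = pij
    if adjust == "holm":
        iu = np.triu_indices(p, 1)
        adj = _holm(pv[iu])
        pv[iu] = adj
        pv[(iu[1], iu[0])] = adj
    elif adjust is not None:
        raise ParameterError(f"unknown p adjustment {adjust!r}")
    sig = (pv < alpha) & ~np.eye(p, dtype=bool)
    idx = matrix.traits
    return CorrelationResult(
        r=pd.DataFrame(r, index=idx, columns=idx),
        p=pd.DataFrame(pv, index=idx, columns=idx),
        significant=pd.DataFrame(sig, index=idx, columns=idx),
        alpha=alpha,
    )


def _holm(pvals: np.ndarray) -> np.ndarray:
    order = np.argsort(pvals)
    m = pvals.size
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * pvals[i])
        adj[i] = min(1.0, running)
    return adj


# -- clustering ------------------------------------------------------------

def hierarchical_clusters(
    matrix: TraitMatrix, method: str = "ward", k: int = 3
) -> ClusterTree:
    """Agglomerative clustering on Euclidean distances of standardized rows."""
    n = len(matrix.genotypes)
    if not 1 <= k <= n:
        raise ParameterError(f"k must lie in [1, {n}]")
    if n == 1:
        return ClusterTree(
            linkage_matrix=np.empty((0, 4)),
            genotypes=list(matrix.genotypes),
            leaf_order=list(matrix.genotypes),
            assignments=pd.Series([1], index=matrix.genotypes),
            k=1,
            method=method,
        )
    Z = linkage(matrix.values, method=method, metric="euclidean")
    labels = fcluster(Z, t=k, criterion="maxclust")
    order = [matrix.genotypes[i] for i in leaves_list(Z)]
    return ClusterTree(
        linkage_matrix=Z,
        genotypes=list(matrix.genotypes),
        leaf_order=order,
        assignments=pd.Series(labels, index=matrix.genotypes),
        k=k,
        method=method,
    )


# -- ranking ---------------------------------------------------------------

def rank_genotypes(
    matrix: TraitMatrix,
    registry: TraitRegistry,
    weights: Mapping[str, float] | None = None,
    top_n: int = 10,
    bottom_n: int = 5,
) -> RankingTable:
    """Composite rank-sum screening.

    Each trait is ranked with rank 1 most favourable per the registry
    direction (ties take the average rank); the composite score is the
    weighted mean of per-trait ranks (equal weights by default) and the
    final rank orders composites.  Tolerance classes mirror the screening
    tables: 'top' for the best ``top_n``, 'low' for the worst ``bottom_n``.
    """
    frame = pd.DataFrame(
        matrix.raw_values if matrix.raw_values is not None else matrix.values,
        index=matrix.genotypes,
        columns=matrix.traits,
    )
    w = pd.Series({t: 1.0 for t in matrix.traits} if weights is None else dict(weights))
    missing = [t for t in matrix.traits if t not in w.index]
    if missing:
        raise ParameterError(f"weights missing for traits {missing}")
    w = w.reindex(matrix.traits)
    ranks = pd.DataFrame(index=frame.index, columns=frame.columns, dtype=float)
    for trait in frame.columns:
        ascending = registry.direction(trait) == "lower_better"
        ranks[trait] = frame[trait].rank(ascending=ascending, method="average")
    composite = (ranks * w).sum(axis=1) / w.sum()
    final = composite.rank(method="average")
    n = len(frame)
    cls = pd.Series("intermediate", index=frame.index)
    cls[final <= top_n] = "top"
    cls[final > n - bottom_n] = "low"
    table = pd.DataFrame(
        {"composite_score": composite, "final_rank": final, "tolerance_class": cls}
    ).sort_values("final_rank")
    return RankingTable(table=table, trait_ranks=ranks)
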