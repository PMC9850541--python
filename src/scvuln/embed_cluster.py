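"""PCA with jackstraw PC significance, t-SNE embedding, KNN-Jaccard graph,
Louvain community detection and cluster-comparison utilities.

Clustering runs on the 2-D embedding coordinates by default (as in the
protocol this reimplements); pass PC scores to :func:`build_knn_jaccard`
to cluster in PC space instead.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass, field

import igraph as ig
import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

from .core_io import ExpressionMatrix, ValidationError, log_stage
from .preprocess import hvg_stats

__all__ = [
    "PCAModel",
    "JackstrawReport",
    "Embedding2D",
    "NeighborGraph",
    "ClusterAssignment",
    "ClusterSimilarityMatrix",
    "run_pca",
    "jackstraw",
    "embed_2d",
    "build_knn_jaccard",
    "louvain",
    "cluster_similarity",
    "cross_tabulate",
]


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass
class PCAModel:
    loadings: np.ndarray        # genes x PCs, orthonormal columns
    scores: np.ndarray          # cells x PCs
    variance_explained: np.ndarray
    gene_ids: list[str]
    mean_: np.ndarray
    scale_: np.ndarray

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


def _standardize_genes(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Center and unit-scale each gene (row) over cells; zero-var rows -> 0."""
    mean = x.mean(axis=1)
    sd = x.std(axis=1)
    safe = np.where(sd > 0, sd, 1.0)
    z = (x - mean[:, None]) / safe[:, None]
    return z, mean, sd


def run_pca(m: ExpressionMatrix, genes: list[str] | None = None,
            n_components: int = 20, seed: int = 0) -> PCAModel:
    """PCA of gene-standardized normalized expression restricted to ``genes``."""
    sub = m if genes is None else m.subset_genes(genes, note="pca_genes")
    z, mean, sd = _standardize_genes(sub.layer("norm"))
    n_max = min(sub.n_genes, sub.n_cells)
    if n_components > n_max:
        raise ValueError(f"n_components={n_components} > min(genes, cells)={n_max}")
    x = z.T  # cells x genes
    solver = "full" if max(x.shape) <= 500 else "randomized"
    pca = PCA(n_components=n_components, svd_solver=solver, random_state=seed)
    scores = pca.fit_transform(x)
    loadings = pca.components_.T
    # deterministic sign: largest-|loading| entry positive per PC
    for j in range(loadings.shape[1]):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    return PCAModel(loadings=loadings, scores=scores,
                    variance_explained=pca.explained_variance_ratio_,
                    gene_ids=list(sub.gene_ids), mean_=mean, scale_=sd)


# ---------------------------------------------------------------------------
# Jackstraw
# ---------------------------------------------------------------------------


@dataclass
class JackstrawReport:
    p_values: np.ndarray
    significant: np.ndarray
    n_iterations: int
    perm_fraction: float
    alpha: float

    @property
    def n_significant(self) -> int:
        return int(self.significant.sum())

    def significant_pcs(self) -> list[int]:
        return list(np.flatnonzero(self.significant))

    def to_dict(self) -> dict:
        return {
            "p_values": [float(p) for p in self.p_values],
            "significant": [bool(s) for s in self.significant],
            "n_iterations": self.n_iterations,
            "perm_fraction": self.perm_fraction,
            "alpha": self.alpha,
        }


def jackstraw(m: ExpressionMatrix, pca: PCAModel, n_iter: int = 100,
              perm_fraction: float = 0.01, alpha: float = 0.01,
              seed: int = 0) -> JackstrawReport:
    """Permutation test for PC significance.

    Each iteration row-permutes a random fraction of genes, refits the PCA
    and records the mean squared loading of the permuted genes on each PC as
    a null statistic.  The observed statistic is the mean squared loading
    over all genes of the original fit (1/n_genes, since loadings are unit
    vectors); per-PC p = (1 + #{null >= observed}) / (2 + n_iter).  Permuted
    genes lose any real structure, so structured PCs push the null below the
    observed value.  Smallest achievable p is 1/(n_iter+2); with the default
    alpha = 0.01 at least 99 iterations are required for any PC to reach
    significance.
    """
    if n_iter < 10:
        warnings.warn(f"jackstraw with n_iter={n_iter} < 10 is unreliable")
    genes = pca.gene_ids
    z, _, _ = _standardize_genes(m.subset_genes(genes).layer("norm"))
    n_genes, n_cells = z.shape
    n_perm = int(round(perm_fraction * n_genes))
    if n_perm < 1:
        raise ValueError("perm_fraction * n_genes < 1: nothing to permute")
    n_pc = pca.n_components
    rng = np.random.default_rng(seed)
    solver = "full" if max(n_genes, n_cells) <= 500 else "randomized"

    observed = 1.0 / n_genes  # mean squared loading over all genes, per PC
    null = np.empty((n_iter, n_pc))
    for it in range(n_iter):
        perm_idx = rng.choice(n_genes, size=n_perm, replace=False)
        zp = z.copy()
        for i in perm_idx:
            zp[i] = zp[i, rng.permutation(n_cells)]
        pca_p = PCA(n_components=n_pc, svd_solver=solver,
                    random_state=int(rng.integers(2**31)))
        pca_p.fit(zp.T)
        load = pca_p.components_.T[perm_idx]  # permuted genes x PCs
        null[it] = (load ** 2).mean(axis=0)

    # add-one shrinkage on both tails keeps p inside (0, 1) so that
    # significance at alpha=1 is attainable and p=0 never reported
    p = (1 + (null >= observed).sum(axis=0)) / (2 + n_iter)
    report = JackstrawReport(p_values=p, significant=p < alpha,
                             n_iterations=n_iter, perm_fraction=perm_fraction,
                             alpha=alpha)
    log_stage("jackstraw", n_iter=n_iter, n_significant=report.n_significant)
    return report


# ---------------------------------------------------------------------------
# 2-D embedding
# ---------------------------------------------------------------------------


@dataclass
class Embedding2D:
    coords: np.ndarray  # cells x 2
    method: str
    perplexity: float
    seed: int

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValidationError("embedding must be cells x 2")
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("embedding contains non-finite coordinates")

    def to_frame(self, cell_ids: list[str] | None = None) -> pd.DataFrame:
        idx = cell_ids if cell_ids is not None else range(len(self.coords))
        return pd.DataFrame(self.coords, index=idx, columns=["x", "y"])


def embed_2d(scores: np.ndarray, perplexity: float = 20.0,
             seed: int = 0) -> Embedding2D:
    """t-SNE of PC (or CC) scores; deterministic for a fixed seed."""
    scores = np.asarray(scores, dtype=float)
    if scores.ndim == 1:
        scores = scores[:, None]
    n = scores.shape[0]
    if perplexity >= (n - 1) / 3:
        raise ValueError(f"perplexity {perplexity} too large for {n} cells "
                         f"(must be < (n-1)/3)")
    tsne = TSNE(n_components=2, perplexity=perplexity, random_state=seed,
                init="pca", learning_rate="auto")
    coords = tsne.fit_transform(scores)
    return Embedding2D(coords=np.asarray(coords, dtype=float), method="tsne",
                       perplexity=perplexity, seed=seed)


# ---------------------------------------------------------------------------
# KNN-Jaccard graph + Louvain
# ---------------------------------------------------------------------------


@dataclass
class NeighborGraph:
    n_nodes: int
    edges: np.ndarray    # m x 2 int array, i < j
    weights: np.ndarray  # m floats in (0, 1]
    k: int

    def __post_init__(self) -> None:
        if len(self.edges) and (self.weights.min() <= 0 or self.weights.max() > 1):
            raise ValidationError("edge weights must lie in (0, 1]")

    def to_igraph(self) -> ig.Graph:
        g = ig.Graph(n=self.n_nodes, edges=[tuple(e) for e in self.edges])
        g.es["weight"] = list(self.weights)
        return g


def build_knn_jaccard(coords: np.ndarray, k: int = 30) -> NeighborGraph:
    """Jaccard-weighted graph of k-nearest-neighbour sets.

    Edge (i, j) exists iff j is in kNN(i) or i is in kNN(j); its weight is
    |kNN(i) & kNN(j)| / |kNN(i) | kNN(j)|.  Distance ties break on the
    stable cell index so the graph is deterministic.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of cells ({n})")
    d = cdist(coords, coords)
    np.fill_diagonal(d, np.inf)
    order = np.argsort(d, axis=1, kind="stable")
    knn_idx = order[:, :k]

    member = np.zeros((n, n), dtype=np.float32)
    rows = np.repeat(np.arange(n), k)
    member[rows, knn_idx.ravel()] = 1.0
    inter = member @ member.T  # |kNN(i) & kNN(j)|

    # candidate edges: j in kNN(i) or i in kNN(j), i < j
    adj = np.logical_or(member > 0, member.T > 0)
    iu, ju = np.where(np.triu(adj, 1))
    inter_e = inter[iu, ju]
    union_e = 2 * k - inter_e
    keep = inter_e > 0
    edges = np.stack([iu[keep], ju[keep]], axis=1)
    weights = (inter_e[keep] / union_e[keep]).astype(float)
    return NeighborGraph(n_nodes=n, edges=edges, weights=weights, k=k)


@dataclass
class ClusterAssignment:
    labels: list[str]
    resolution: float
    seed: int
    parent_class: str | None = None

    def __post_init__(self) -> None:
        if not self.labels:
            raise ValidationError("empty cluster assignment")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.labels, dtype=object)

    def sizes(self) -> pd.Series:
        return pd.Series(self.labels).value_counts()

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels))


def louvain(graph: NeighborGraph, resolution: float = 1.0, seed: int = 0,
            method: str = "louvain", parent_class: str | None = None
            ) -> ClusterAssignment:
    """Community detection on the Jaccard graph at the given resolution.

    ``louvain`` uses igraph's multilevel algorithm; ``leiden`` is available
    behind the flag.  Deterministic given the seed.  Community ids are
    renumbered contiguously in order of first appearance, optionally
    prefixed by the parent cardinal class.
    """
    if graph.n_nodes == 0:
        raise ValidationError("empty graph")
    g = graph.to_igraph()
    weights = g.es["weight"] if g.ecount() else None
    state = random.getstate()
    try:
        random.seed(seed)
        if method == "louvain":
            part = g.community_multilevel(weights=weights, resolution=resolution)
            membership = part.membership
        elif method == "leiden":
            import leidenalg

            part = leidenalg.find_partition(
                g, leidenalg.RBConfigurationVertexPartition,
                weights=weights, resolution_parameter=resolution, seed=seed)
            membership = part.membership
        else:
            raise ValueError(f"unknown clustering method {method!r}")
    finally:
        random.setstate(state)

    relabel: dict[int, int] = {}
    labels = []
    prefix = f"{parent_class}." if parent_class else ""
    for community in membership:
        if community not in relabel:
            relabel[community] = len(relabel)
        labels.append(f"{prefix}{relabel[community]}")
    assignment = ClusterAssignment(labels=labels, resolution=resolution,
                                   seed=seed, parent_class=parent_class)
    log_stage("louvain", resolution=resolution, n_clusters=assignment.n_clusters)
    return assignment


# ---------------------------------------------------------------------------
# Cluster comparison
# ---------------------------------------------------------------------------


@dataclass
class ClusterSimilarityMatrix:
    values: pd.DataFrame  # clusters of A x clusters of B, Pearson r
    n_hvg: int
    small_clusters: list[str] = field(default_factory=list)


def cluster_similarity(m: ExpressionMatrix, clusters_a, clusters_b,
                       top_n_hvg: int = 3000) -> ClusterSimilarityMatrix:
    """Pearson correlation of per-cluster mean log expression over top HVGs.

    Genes are ranked by linear-scale VMR; the top ``top_n_hvg`` are used.
    Clusters with fewer than 2 cells are computed but flagged.
    """
    labels_a = np.asarray(list(clusters_a), dtype=object)
    labels_b = np.asarray(list(clusters_b), dtype=object)
    if len(labels_a) != m.n_cells or len(labels_b) != m.n_cells:
        raise ValidationError("cluster assignments must cover all matrix cells")
    stats = hvg_stats(m)
    ranked = stats["vmr"].fillna(-np.inf).to_numpy()
    top = np.argsort(-ranked, kind="stable")[:min(top_n_hvg, m.n_genes)]
    norm = m.layer("norm")[top]

    def _means(labels: np.ndarray) -> pd.DataFrame:
        groups = pd.unique(labels)
        cols = {g: norm[:, labels == g].mean(axis=1) for g in groups}
        return pd.DataFrame(cols)

    mean_a, mean_b = _means(labels_a), _means(labels_b)
    small = sorted(
        {str(g) for g in pd.unique(labels_a) if (labels_a == g).sum() < 2}
        | {str(g) for g in pd.unique(labels_b) if (labels_b == g).sum() < 2})
    corr = pd.DataFrame(index=mean_a.columns, columns=mean_b.columns, dtype=float)
    for a in mean_a.columns:
        for b in mean_b.columns:
            va, vb = mean_a[a].to_numpy(), mean_b[b].to_numpy()
            corr.loc[a, b] = float(np.corrcoef(va, vb)[0, 1])
    return ClusterSimilarityMatrix(values=corr, n_hvg=len(top),
                                   small_clusters=small)


def cluster_workflow(m: ExpressionMatrix, hvg_table: pd.DataFrame,
                     n_pcs: int = 20, jackstraw_iterations: int = 100,
                     jackstraw_perm_fraction: float = 0.01,
                     jackstraw_alpha: float = 0.01,
                     max_significant_pcs: int | None = None,
                     perplexity: float = 20.0, knn_k: int = 30,
                     resolution: float = 1.0, cluster_on: str = "embedding",
                     cluster_method: str = "louvain", seed: int = 0,
                     parent_class: str | None = None) -> dict:
    """HVGs -> PCA -> jackstraw -> t-SNE -> KNN-Jaccard -> Louvain.

    Returns a dict with the intermediate artefacts (``pca``, ``jackstraw``,
    ``embedding``, ``graph``, ``clusters``).  All jackstraw-significant PCs
    feed the embedding, optionally capped at ``max_significant_pcs``.
    """
    hvgs = list(hvg_table.index[hvg_table["selected"]])
    n_pcs = min(n_pcs, len(hvgs), m.n_cells)
    pca = run_pca(m, genes=hvgs, n_components=n_pcs, seed=seed)
    js = jackstraw(m, pca, n_iter=jackstraw_iterations,
                   perm_fraction=jackstraw_perm_fraction,
                   alpha=jackstraw_alpha, seed=seed)
    sig = js.significant_pcs()
    if not sig:  # fall back to the leading PCs rather than aborting
        warnings.warn("no jackstraw-significant PC; using the first 2 PCs")
        sig = [0, 1][: pca.n_components]
    if max_significant_pcs is not None:
        sig = sig[:max_significant_pcs]
    scores = pca.scores[:, sig]
    embedding = embed_2d(scores, perplexity=perplexity, seed=seed)
    basis = embedding.coords if cluster_on == "embedding" else scores
    graph = build_knn_jaccard(basis, k=min(knn_k, m.n_cells - 1))
    clusters = louvain(graph, resolution=resolution, seed=seed,
                       method=cluster_method, parent_class=parent_class)
    return {"pca": pca, "jackstraw": js, "embedding": embedding,
            "graph": graph, "clusters": clusters, "significant_pcs": sig}


def cross_tabulate(clusters_a, clusters_b) -> pd.DataFrame:
    """Contingency table of two cluster assignments over the same cells."""
    a = pd.Series(list(clusters_a), name="A")
    b = pd.Series(list(clusters_b), name="B")
    if len(a) != len(b):
        raise ValidationError("assignments must cover the same cells")
    return pd.crosstab(a, b)
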