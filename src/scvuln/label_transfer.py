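"""Reference-based identity assignment across datasets.

Shared variable features -> diagonal CCA (SVD of the cross-product of the
two gene-standardized matrices) -> per-dimension quantile alignment of the
CC score distributions -> joint t-SNE -> KNN majority vote: a query cell is
assigned the identity of the unique plurality among its k closest
*reference* cells, provided the top count reaches ``min_votes``; ties and
weak pluralities stay UNASSIGNED.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import kruskal, rankdata
from sklearn.neighbors import NearestNeighbors

from .core_io import ExpressionMatrix, ValidationError, log_stage
from .embed_cluster import Embedding2D, _standardize_genes, embed_2d

__all__ = [
    "SharedFeatureSet",
    "CCAScores",
    "select_shared_features",
    "diagonal_cca",
    "align_cc_scores",
    "knn_assign",
    "composition_summary",
    "transfer_labels",
]

UNASSIGNED = "UNASSIGNED"


@dataclass
class SharedFeatureSet:
    genes: list[str]
    scores: pd.Series | None = None  # optional per-gene discriminability

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(
                "no shared variable features; relax the HVG thresholds")

    def __len__(self) -> int:
        return len(self.genes)


def discriminability_scores(m: ExpressionMatrix, labels,
                            genes: list[str]) -> pd.Series:
    """Kruskal-Wallis H per gene against the given type labels.

    Deterministic replacement for the under-specified random-forest feature
    ranking: a high H means the gene separates the reference types well.
    """
    labels = np.asarray(list(labels), dtype=object)
    x = m.subset_genes(genes).layer("norm")
    groups = [labels == g for g in pd.unique(labels)]
    scores = np.zeros(len(genes))
    for i in range(len(genes)):
        samples = [x[i, g] for g in groups]
        if all(np.all(s == s[0]) for s in samples if s.size) and \
           len({s[0] for s in samples if s.size}) <= 1:
            scores[i] = 0.0
            continue
        try:
            scores[i] = kruskal(*samples).statistic
        except ValueError:  # all values identical
            scores[i] = 0.0
    return pd.Series(scores, index=genes)


def select_shared_features(hvg_a: pd.DataFrame, hvg_b: pd.DataFrame,
                           ranking: pd.Series | None = None,
                           top_n: int | None = None) -> SharedFeatureSet:
    """Intersect the selected HVGs of two datasets (case-insensitive).

    ``ranking`` (e.g. from :func:`discriminability_scores`) optionally
    orders the intersection, with a ``top_n`` cap.
    """
    sel_a = {g.upper(): g for g in hvg_a.index[hvg_a["selected"]]}
    sel_b = {g.upper() for g in hvg_b.index[hvg_b["selected"]]}
    shared = [sel_a[u] for u in sel_a if u in sel_b]
    if not shared:
        raise ValidationError(
            "HVG intersection between datasets is empty; relax thresholds")
    scores = None
    if ranking is not None:
        rank_upper = {str(g).upper(): v for g, v in ranking.items()}
        shared.sort(key=lambda g: -rank_upper.get(g.upper(), -np.inf))
        scores = pd.Series([rank_upper.get(g.upper(), np.nan) for g in shared],
                           index=shared)
    if top_n is not None:
        shared = shared[:top_n]
        if scores is not None:
            scores = scores.iloc[:top_n]
    return SharedFeatureSet(genes=shared, scores=scores)


@dataclass
class CCAScores:
    scores_a: np.ndarray  # cells_a x n_cc
    scores_b: np.ndarray  # cells_b x n_cc
    correlations: np.ndarray  # per-CC canonical correlation in [0, 1]
    n_cc: int
    singular_values: np.ndarray | None = None  # non-increasing, SVD order


def diagonal_cca(m_a: ExpressionMatrix, m_b: ExpressionMatrix,
                 features: list[str], n_cc: int = 4) -> CCAScores:
    """Diagonalized CCA: SVD of the cross-product of standardized matrices.

    Both matrices are gene-standardized over their own cells on the shared
    features; the cells_a x cells_b cross-product is decomposed and the left
    and right singular vectors are the per-dataset CC scores.  The reported
    canonical correlation per dimension is the Pearson correlation over
    genes between the paired canonical variates (1.0 when B duplicates A).
    """
    upper = {g.upper() for g in features}
    genes_a = [g for g in m_a.gene_ids if g.upper() in upper]
    genes_b_map = m_b.gene_index_upper()
    genes_b = []
    for g in genes_a:
        if g.upper() not in genes_b_map:
            raise ValidationError(f"shared feature {g} absent from dataset B")
        genes_b.append(m_b.gene_ids[genes_b_map[g.upper()]])
    if len(genes_a) < n_cc:
        raise ValueError("fewer shared features than requested CCs")
    za, _, _ = _standardize_genes(m_a.subset_genes(genes_a).layer("norm"))
    zb, _, _ = _standardize_genes(m_b.subset_genes(genes_b).layer("norm"))
    if n_cc > min(za.shape[1], zb.shape[1]):
        raise ValueError(f"n_cc={n_cc} exceeds the smaller cell count")

    cross = za.T @ zb  # cells_a x cells_b
    u, s, vt = np.linalg.svd(cross, full_matrices=False)
    u, v = u[:, :n_cc], vt[:n_cc].T
    # deterministic sign: largest-|entry| element of each left vector positive
    for j in range(n_cc):
        i = np.argmax(np.abs(u[:, j]))
        if u[i, j] < 0:
            u[:, j] *= -1
            v[:, j] *= -1
    variate_a = za @ u  # genes x n_cc
    variate_b = zb @ v
    corrs = np.zeros(n_cc)
    for j in range(n_cc):
        sa, sb = variate_a[:, j].std(), variate_b[:, j].std()
        if sa > 0 and sb > 0:
            corrs[j] = abs(float(np.corrcoef(variate_a[:, j], variate_b[:, j])[0, 1]))
    return CCAScores(scores_a=u, scores_b=v, correlations=corrs, n_cc=n_cc,
                     singular_values=s[:n_cc])


def align_cc_scores(cca: CCAScores) -> CCAScores:
    """Quantile-align each CC dimension's score distributions across datasets.

    Every value is replaced by the pooled empirical quantile at its
    within-dataset rank (ties averaged), which is monotone within each
    dataset and equalizes the two per-CC distributions.
    """
    a = cca.scores_a.copy()
    b = cca.scores_b.copy()
    for j in range(cca.n_cc):
        pooled = np.sort(np.concatenate([a[:, j], b[:, j]]))
        for arr in (a, b):
            q = (rankdata(arr[:, j]) - 0.5) / arr.shape[0]
            arr[:, j] = np.quantile(pooled, q)
    return CCAScores(scores_a=a, scores_b=b,
                     correlations=cca.correlations.copy(), n_cc=cca.n_cc,
                     singular_values=cca.singular_values)


def knn_assign(query_coords: np.ndarray, ref_coords: np.ndarray,
               ref_labels, k: int = 30, min_votes: int = 5) -> pd.DataFrame:
    """Vote each query cell's identity from its k nearest reference cells.

    Returns one row per query cell with per-label vote counts, the assigned
    label (or UNASSIGNED) and a reason in {ok, below_min_votes, tie}.
    """
    query_coords = np.asarray(query_coords, dtype=float)
    ref_coords = np.asarray(ref_coords, dtype=float)
    ref_labels = np.asarray(list(ref_labels), dtype=object)
    if ref_coords.shape[0] != ref_labels.size:
        raise ValidationError("reference labels must cover reference cells")
    if ref_coords.shape[0] < k:
        raise ValidationError(
            f"fewer reference cells ({ref_coords.shape[0]}) than k={k}")
    nn = NearestNeighbors(n_neighbors=k, metric="euclidean")
    nn.fit(ref_coords)
    _, idx = nn.kneighbors(query_coords)
    label_names = sorted(set(ref_labels))
    rows = []
    for neigh in idx:
        votes = pd.Series(ref_labels[neigh]).value_counts()
        counts = {lbl: int(votes.get(lbl, 0)) for lbl in label_names}
        top = votes.iloc[0]
        winners = votes[votes == top].index.tolist()
        if len(winners) > 1:
            assigned, reason = UNASSIGNED, "tie"
        elif top < min_votes:
            assigned, reason = UNASSIGNED, "below_min_votes"
        else:
            assigned, reason = winners[0], "ok"
        rows.append({**counts, "assigned": assigned, "reason": reason})
    return pd.DataFrame(rows)


def composition_summary(transfer: pd.DataFrame, query_clusters) -> pd.DataFrame:
    """Per query cluster: count and proportion of each assigned type."""
    clusters = np.asarray(list(query_clusters), dtype=object)
    if clusters.size != len(transfer):
        raise ValidationError("clusters must cover every transfer row")
    df = pd.DataFrame({"cluster": clusters,
                       "assigned": transfer["assigned"].to_numpy()})
    counts = pd.crosstab(df["cluster"], df["assigned"])
    props = counts.div(counts.sum(axis=1), axis=0)
    counts.columns = [f"n_{c}" for c in counts.columns]
    props.columns = [f"frac_{c}" for c in props.columns]
    return counts.join(props)


def transfer_labels(m_ref: ExpressionMatrix, ref_labels,
                    m_query: ExpressionMatrix,
                    hvg_ref: pd.DataFrame, hvg_query: pd.DataFrame,
                    n_cc: int = 4, k: int = 30, min_votes: int = 5,
                    perplexity: float = 40.0, seed: int = 0,
                    rank_features: bool = True,
                    top_n_features: int | None = None
                    ) -> tuple[pd.DataFrame, Embedding2D, CCAScores]:
    """End-to-end transfer: features -> CCA -> alignment -> t-SNE -> KNN."""
    ranking = None
    if rank_features:
        shared0 = select_shared_features(hvg_ref, hvg_query)
        ranking = discriminability_scores(m_ref, ref_labels, shared0.genes)
    features = select_shared_features(hvg_ref, hvg_query, ranking=ranking,
                                      top_n=top_n_features)
    cca = diagonal_cca(m_ref, m_query, features.genes, n_cc=n_cc)
    aligned = align_cc_scores(cca)
    joint = np.vstack([aligned.scores_a, aligned.scores_b])
    embedding = embed_2d(joint, perplexity=perplexity, seed=seed)
    n_ref = m_ref.n_cells
    ref_coords = embedding.coords[:n_ref]
    query_coords = embedding.coords[n_ref:]
    table = knn_assign(query_coords, ref_coords, ref_labels,
                       k=k, min_votes=min_votes)
    table.insert(0, "cell_id", m_query.cell_ids)
    log_stage("transfer", n_features=len(features), n_cc=n_cc,
              n_assigned=int((table["assigned"] != UNASSIGNED).sum()),
              n_query=m_query.n_cells)
    return table, embedding, aligned
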