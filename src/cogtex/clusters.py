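"""Two-stage purification of tissue clusters.

Stage one works in PC space: PCA of standardized genes with a sequential
permutation test deciding how many components carry signal, then Louvain
clustering of Jaccard-weighted k-nearest-neighbour graphs over a sweep of k.
Each tissue is matched to its best (k, cluster) by the purity score
P = (I/T)(I/C) — the product of the cluster's recall and precision for the
tissue — and samples that sit in a cluster dominated by another tissue are
flagged DIVERGENT while samples in clusters with no dominant tissue are
flagged MIXED. Tissue pairs that share one cluster are merged.

Stage two embeds the retained samples with exact t-SNE and removes samples
whose majority vote among their k nearest embedded neighbours (k = size of the
nearest-medoid's cluster) disagrees with their assigned cluster.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass, field

import igraph
import numpy as np
import pandas as pd
from sklearn.manifold import TSNE
from sklearn.neighbors import NearestNeighbors
from sklearn.utils.extmath import randomized_svd

from ._errors import CogtexError

__all__ = [
    "PCEmbedding",
    "ClusterAssignment",
    "purity_score",
    "retain_significant_pcs",
    "louvain_sweep",
    "flag_mixed_and_divergent",
    "merge_mixed_tissue_pairs",
    "tsne_embed",
    "medoid_knn_outlier_removal",
    "apply_manual_exclusions",
    "purify_tissue_clusters",
]


@dataclass
class PCEmbedding:
    scores: pd.DataFrame  # samples x retained PCs
    explained_variance: np.ndarray  # variance fraction per retained PC
    n_retained: int
    n_permutations: int


@dataclass
class ClusterAssignment:
    """Per-sample tissue/cluster labels with removal status.

    ``status`` is one of KEPT, MIXED, DIVERGENT, TSNE_OUTLIER, MANUAL; KEPT
    samples carry a cluster label. ``tissue_best`` records each tissue's best
    (k, cluster id, P); ``merges`` lists merged tissue groups.
    """

    table: pd.DataFrame  # sample_id, tissue, cluster, status, P, k
    tissue_best: pd.DataFrame  # tissue, k, cluster_id, P
    merges: list[list[str]] = field(default_factory=list)

    @property
    def kept(self) -> pd.DataFrame:
        return self.table[self.table["status"] == "KEPT"]

    def cluster_of_kept(self) -> pd.Series:
        k = self.kept
        return pd.Series(k["cluster"].to_numpy(), index=k["sample_id"].to_numpy())

    def n_clusters(self) -> int:
        return self.kept["cluster"].nunique()

    def counts(self) -> dict[str, int]:
        c = self.table["status"].value_counts().to_dict()
        return {s: int(c.get(s, 0)) for s in ("KEPT", "MIXED", "DIVERGENT", "TSNE_OUTLIER", "MANUAL")}


def purity_score(tissue_samples: set, cluster_samples: set) -> float:
    """P = (I/T)(I/C); equals 1 exactly when the two sets coincide."""
    if not tissue_samples or not cluster_samples:
        return 0.0
    i = len(tissue_samples & cluster_samples)
    return (i / len(tissue_samples)) * (i / len(cluster_samples))


def _standardize_genes(values: pd.DataFrame) -> np.ndarray:
    """Standardize genes (rows) to mean 0, sd 1; constant genes are dropped."""
    arr = values.to_numpy(float)
    sd = arr.std(axis=1, ddof=0)
    const = sd == 0
    if const.any():
        warnings.warn(f"{int(const.sum())} constant gene(s) excluded from standardization")
        arr = arr[~const]
        sd = sd[~const]
    return (arr - arr.mean(axis=1, keepdims=True)) / sd[:, None]


def _leading_variance_fraction(X: np.ndarray, seed: int) -> tuple[float, np.ndarray, np.ndarray, float]:
    """First-PC explained-variance fraction of a centered samples x genes matrix."""
    total = (X**2).sum()
    if total == 0:
        return 0.0, np.zeros(X.shape[0]), np.zeros(X.shape[1]), 0.0
    U, S, Vt = randomized_svd(X, n_components=1, random_state=seed)
    return float(S[0] ** 2 / total), U[:, 0], Vt[0], float(S[0])


def retain_significant_pcs(
    values: pd.DataFrame,
    n_perm: int = 100,
    seed: int = 0,
    criterion: str = "max",
    max_pcs: int | None = None,
) -> PCEmbedding:
    """Sequential permutation test for the number of informative PCs.

    ``values`` is genes x samples. PC_i is retained when its explained-variance
    fraction (of the residual after removing the previously retained PCs)
    exceeds the ``criterion`` ("max" or "q95") of ``n_perm`` first-PC fractions
    computed after permuting every gene's values independently. Stops at the
    first failure.
    """
    if values.shape[1] < 2:
        raise CogtexError("need at least 2 samples for PCA")
    Z = _standardize_genes(values).T  # samples x genes, each column mean 0
    n, g = Z.shape
    limit = max_pcs if max_pcs is not None else min(n, g) - 1
    rng = np.random.default_rng(seed)
    R = Z.copy()
    total_var = (Z**2).sum()
    scores, evs = [], []
    while len(evs) < limit:
        frac, u, v, s = _leading_variance_fraction(R, seed + len(evs))
        null_max = []
        for p in range(n_perm):
            P = R.copy()
            for j in range(g):
                rng.shuffle(P[:, j])
            P -= P.mean(axis=0, keepdims=True)
            null_max.append(_leading_variance_fraction(P, seed + 7919 + p)[0])
        cutoff = max(null_max) if criterion == "max" else float(np.quantile(null_max, 0.95))
        if frac <= cutoff:
            break
        scores.append(u * s)
        evs.append(float(s**2 / total_var))
        R = R - np.outer(u * s, v)
    score_df = pd.DataFrame(
        np.column_stack(scores) if scores else np.empty((n, 0)),
        index=values.columns,
        columns=[f"PC{i + 1}" for i in range(len(scores))],
    )
    return PCEmbedding(score_df, np.asarray(evs), len(evs), n_perm)


def _jaccard_knn_graph(coords: np.ndarray, k: int) -> igraph.Graph:
    """Union-symmetrized kNN graph with Jaccard-of-neighbour-sets edge weights."""
    n = coords.shape[0]
    nn = NearestNeighbors(n_neighbors=min(k + 1, n)).fit(coords)
    _, idx = nn.kneighbors(coords)
    A = np.zeros((n, n), dtype=bool)
    for i in range(n):
        A[i, idx[i, 1 : k + 1]] = True  # self excluded
    inter = (A.astype(np.int32) @ A.T.astype(np.int32)).astype(float)
    sizes = A.sum(axis=1).astype(float)
    union = sizes[:, None] + sizes[None, :] - inter
    sym = A | A.T
    edges, weights = [], []
    ii, jj = np.where(np.triu(sym, k=1))
    for i, j in zip(ii, jj):
        u = union[i, j]
        w = inter[i, j] / u if u > 0 else 0.0
        edges.append((int(i), int(j)))
        weights.append(w)
    g = igraph.Graph(n=n, edges=edges)
    g.es["weight"] = weights
    return g


def louvain_sweep(
    pcs: PCEmbedding, k_values=range(1, 101), seed: int = 0
) -> dict[int, tuple[np.ndarray, float]]:
    """Louvain partitions of Jaccard-kNN graphs for each k; returns
    {k: (labels, modularity)}. Values of k >= n_samples are skipped."""
    coords = pcs.scores.to_numpy(float)
    n = coords.shape[0]
    if n < 2:
        raise CogtexError("need at least 2 samples to cluster")
    out: dict[int, tuple[np.ndarray, float]] = {}
    for k in k_values:
        if k >= n:
            warnings.warn(f"k={k} >= n_samples={n}; skipped")
            continue
        graph = _jaccard_knn_graph(coords, k)
        random.seed(seed + k)  # python-igraph draws from the stdlib RNG
        if sum(graph.es["weight"]) == 0:
            labels = np.zeros(n, dtype=int)
            out[k] = (labels, 0.0)
            continue
        part = graph.community_multilevel(weights="weight")
        out[k] = (np.asarray(part.membership), part.modularity)
    if not out:
        raise CogtexError("no usable k in the sweep")
    return out


def flag_mixed_and_divergent(
    partitions: dict[int, tuple[np.ndarray, float]],
    tissues: pd.Series,
    p_min: float = 0.5,
) -> ClusterAssignment:
    """Match each tissue to its best (k, cluster) by purity and flag samples.

    A sample is DIVERGENT when it falls outside its tissue's best cluster and
    the cluster it does fall in (at that k) is dominated by another tissue;
    MIXED when its cluster has no dominant tissue (max P < ``p_min``).
    """
    sample_ids = list(tissues.index)
    tissue_sets = {t: set(tissues.index[tissues == t]) for t in tissues.unique()}
    if not tissue_sets:
        raise CogtexError("no tissues")
    # purity of every (k, cluster) against every tissue
    cluster_members: dict[tuple[int, int], set] = {}
    for k, (labels, _) in partitions.items():
        for c in np.unique(labels):
            cluster_members[(k, int(c))] = {sample_ids[i] for i in np.where(labels == c)[0]}
    purity: dict[tuple[int, int], dict[str, float]] = {
        key: {t: purity_score(ts, members) for t, ts in tissue_sets.items()}
        for key, members in cluster_members.items()
    }
    best_rows = []
    for t in tissue_sets:
        scored = [(purity[key][t], key) for key in cluster_members]
        p_best, (k_best, c_best) = max(scored, key=lambda x: (x[0], -x[1][0]))
        best_rows.append(dict(tissue=t, k=k_best, cluster_id=c_best, P=p_best))
    tissue_best = pd.DataFrame(best_rows).set_index("tissue", drop=False)

    pos = {sid: i for i, sid in enumerate(sample_ids)}
    rows = []
    for sid in sample_ids:
        t = tissues.loc[sid]
        k_best = int(tissue_best.loc[t, "k"])
        c_best = int(tissue_best.loc[t, "cluster_id"])
        labels = partitions[k_best][0]
        own_cluster = int(labels[pos[sid]])
        p_by_tissue = purity[(k_best, own_cluster)]
        dominant = max(p_by_tissue, key=p_by_tissue.get)
        p_dom = p_by_tissue[dominant]
        if p_dom < p_min:
            status, cluster = "MIXED", None
        elif own_cluster != c_best and dominant != t:
            status, cluster = "DIVERGENT", None
        else:
            status, cluster = "KEPT", t
        rows.append(
            dict(sample_id=sid, tissue=t, cluster=cluster, status=status,
                 P=float(tissue_best.loc[t, "P"]), k=k_best)
        )
    table = pd.DataFrame(rows).set_index("sample_id", drop=False)
    return ClusterAssignment(table, tissue_best)


def merge_mixed_tissue_pairs(assignment: ClusterAssignment, mix_threshold: float = 0.25) -> ClusterAssignment:
    """Merge tissues whose samples co-occupy one cluster.

    Two tissues merge when their best clusters are the same (k, cluster) and
    both purities reach ``mix_threshold``; chains merge transitively with a
    warning. Merged clusters are named by joining the tissue names.
    """
    best = assignment.tissue_best
    groups: dict[tuple[int, int], list[str]] = {}
    for t, row in best.iterrows():
        if row["P"] >= mix_threshold:
            groups.setdefault((int(row["k"]), int(row["cluster_id"])), []).append(t)
    table = assignment.table.copy()
    merges = []
    for key, members in groups.items():
        if len(members) < 2:
            continue
        if len(members) > 2:
            warnings.warn(f"merging a chain of {len(members)} tissues: {members}")
        merged_name = "+".join(sorted(members))
        merges.append(sorted(members))
        mask = table["tissue"].isin(members) & (table["status"] == "KEPT")
        table.loc[mask, "cluster"] = merged_name
    return ClusterAssignment(table, best, merges=merges)


def tsne_embed(
    pcs: PCEmbedding,
    perplexity: float = 30.0,
    learning_rate: float = 200.0,
    max_iter: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Exact (theta = 0) 2-D t-SNE of the PC scores; no extra PCA, no rescaling."""
    coords = pcs.scores.to_numpy(float)
    n = coords.shape[0]
    if perplexity >= (n - 1) / 3:
        raise CogtexError(f"perplexity {perplexity} too large for {n} samples")
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        learning_rate=learning_rate,
        max_iter=max_iter,
        method="exact",
        init="random",
        random_state=seed,
    )
    emb = tsne.fit_transform(coords)
    return pd.DataFrame(emb, index=pcs.scores.index, columns=["tsne1", "tsne2"])


def _trimmed_medoid(points: np.ndarray) -> np.ndarray:
    """Coordinate-wise median after dropping boxplot outliers in either dim."""
    if len(points) < 4:
        warnings.warn("cluster smaller than 4: medoid computed without outlier trim")
        return np.median(points, axis=0)
    keep = np.ones(len(points), dtype=bool)
    for d in range(points.shape[1]):
        q1, q3 = np.percentile(points[:, d], [25, 75])
        iqr = q3 - q1
        keep &= (points[:, d] >= q1 - 1.5 * iqr) & (points[:, d] <= q3 + 1.5 * iqr)
    if not keep.any():
        keep[:] = True
    return np.median(points[keep], axis=0)


def medoid_knn_outlier_removal(embedding: pd.DataFrame, assignment: ClusterAssignment) -> ClusterAssignment:
    """Flag KEPT samples whose voted cluster in t-SNE space disagrees with their own.

    For each sample, k equals the size of the cluster whose trimmed medoid is
    nearest (ties toward the larger cluster); membership is predicted by
    majority vote among the k nearest retained samples, and vote ties keep the
    sample.
    """
    table = assignment.table.copy()
    kept = table[table["status"] == "KEPT"]
    ids = list(kept["sample_id"])
    coords = embedding.loc[ids].to_numpy(float)
    clusters = kept["cluster"].to_numpy()
    names = pd.unique(clusters)
    medoids = {c: _trimmed_medoid(coords[clusters == c]) for c in names}
    sizes = {c: int((clusters == c).sum()) for c in names}
    dists = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    order = np.argsort(dists, axis=1, kind="stable")
    flagged = []
    for i, sid in enumerate(ids):
        md = {c: float(np.linalg.norm(coords[i] - m)) for c, m in medoids.items()}
        nearest = min(names, key=lambda c: (md[c], -sizes[c]))
        k = min(sizes[nearest], len(ids) - 1)
        neigh = [j for j in order[i] if j != i][:k]
        votes = pd.Series(clusters[neigh]).value_counts()
        top = votes.max()
        winners = set(votes.index[votes == top])
        if clusters[i] in winners:
            continue  # ties (or wins) keep the sample
        if len(winners) > 1:
            continue
        flagged.append(sid)
    table.loc[flagged, "status"] = "TSNE_OUTLIER"
    table.loc[flagged, "cluster"] = None
    return ClusterAssignment(table, assignment.tissue_best, merges=list(assignment.merges))


def apply_manual_exclusions(assignment: ClusterAssignment, sample_ids) -> ClusterAssignment:
    """Mark listed samples MANUAL; unknown ids raise."""
    table = assignment.table.copy()
    unknown = set(sample_ids) - set(table.index)
    if unknown:
        raise CogtexError(f"unknown sample id(s) in exclusion list: {sorted(unknown)[:5]}")
    table.loc[list(sample_ids), "status"] = "MANUAL"
    table.loc[list(sample_ids), "cluster"] = None
    return ClusterAssignment(table, assignment.tissue_best, merges=list(assignment.merges))


def purify_tissue_clusters(
    values: pd.DataFrame,
    tissues: pd.Series,
    n_perm: int = 100,
    k_values=range(1, 101),
    p_min: float = 0.5,
    mix_threshold: float = 0.25,
    perplexity: float = 30.0,
    learning_rate: float = 200.0,
    tsne_max_iter: int = 1000,
    manual_exclusions=(),
    seed: int = 0,
    max_pcs: int | None = None,
) -> tuple[ClusterAssignment, PCEmbedding, pd.DataFrame]:
    """Run both purification stages; returns (assignment, PCs, t-SNE coords)."""
    pcs = retain_significant_pcs(values, n_perm=n_perm, seed=seed, max_pcs=max_pcs)
    if pcs.n_retained == 0:
        raise CogtexError("no significant PCs: data show no structure to cluster")
    partitions = louvain_sweep(pcs, k_values=k_values, seed=seed)
    assignment = flag_mixed_and_divergent(partitions, tissues, p_min=p_min)
    assignment = merge_mixed_tissue_pairs(assignment, mix_threshold=mix_threshold)
    embedding = tsne_embed(pcs, perplexity=perplexity, learning_rate=learning_rate,
                           max_iter=tsne_max_iter, seed=seed)
    assignment = medoid_knn_outlier_removal(embedding, assignment)
    if manual_exclusions:
        assignment = apply_manual_exclusions(assignment, manual_exclusions)
    return assignment, pcs, embedding
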