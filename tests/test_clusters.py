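import numpy as np
import pandas as pd
import pytest

from cogtex._errors import CogtexError
from cogtex.clusters import (
    ClusterAssignment,
    flag_mixed_and_divergent,
    louvain_sweep,
    medoid_knn_outlier_removal,
    merge_mixed_tissue_pairs,
    purify_tissue_clusters,
    purity_score,
    retain_significant_pcs,
    tsne_embed,
    PCEmbedding,
    apply_manual_exclusions,
)
from cogtex.preprocess import log_quantile_normalize
from cogtex.synthetic import CohortConfig, generate_cohort, inject_outliers


def _blobs(n_per=30, centers=((0, 0), (10, 10), (-10, 10)), sd=0.5, seed=0, n_noise_dims=0):
    rng = np.random.default_rng(seed)
    pts, labels = [], []
    for i, c in enumerate(centers):
        block = rng.normal(0, sd, (n_per, 2 + n_noise_dims))
        block[:, 0] += c[0]
        block[:, 1] += c[1]
        pts.append(block)
        labels += [f"T{i}"] * n_per
    coords = np.vstack(pts)
    ids = [f"s{i}" for i in range(len(coords))]
    scores = pd.DataFrame(coords, index=ids)
    return PCEmbedding(scores, np.ones(coords.shape[1]), coords.shape[1], 0), pd.Series(labels, index=ids)


class TestPurityScore:
    def test_exact_match_is_one(self):
        s = {"a", "b", "c"}
        assert purity_score(s, set(s)) == 1.0

    @pytest.mark.parametrize(
        "tissue, cluster",
        [({"a", "b"}, {"a", "b", "c"}), ({"a", "b", "c"}, {"a"}), ({"a"}, {"b"})],
    )
    def test_strictly_below_one_unless_identical(self, tissue, cluster):
        assert purity_score(tissue, cluster) < 1.0

    def test_product_of_recall_and_precision(self):
        p = purity_score({"a", "b", "c", "d"}, {"c", "d", "e"})
        assert p == pytest.approx((2 / 4) * (2 / 3))


class TestPcRetention:
    def test_iid_noise_retains_almost_nothing(self):
        retained = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            values = pd.DataFrame(rng.normal(size=(60, 80)))  # genes x samples
            emb = retain_significant_pcs(values, n_perm=30, seed=seed, max_pcs=5)
            retained.append(emb.n_retained)
        assert max(retained) <= 2

    def test_planted_factor_recovered_by_pc1(self):
        rng = np.random.default_rng(1)
        factor = rng.normal(size=100)  # per sample
        loadings = rng.normal(size=50)
        values = pd.DataFrame(
            np.outer(loadings, factor) * 2.0 + rng.normal(size=(50, 100))
        )
        emb = retain_significant_pcs(values, n_perm=30, seed=0, max_pcs=5)
        assert emb.n_retained >= 1
        r = np.corrcoef(emb.scores.iloc[:, 0], factor)[0, 1]
        assert abs(r) > 0.9
        assert (np.diff(emb.explained_variance) <= 1e-12).all()

    def test_constant_gene_excluded_with_warning(self):
        rng = np.random.default_rng(2)
        arr = rng.normal(size=(10, 20))
        arr[3] = 5.0
        with pytest.warns(UserWarning, match="constant"):
            retain_significant_pcs(pd.DataFrame(arr), n_perm=10, seed=0, max_pcs=2)

    def test_too_few_samples_rejected(self):
        with pytest.raises(CogtexError):
            retain_significant_pcs(pd.DataFrame(np.ones((5, 1))), n_perm=5, seed=0)


class TestLouvain:
    def test_separated_blobs_recovered_exactly(self):
        pcs, labels = _blobs(n_per=25)
        parts = louvain_sweep(pcs, k_values=[15], seed=0)
        membership, modularity = parts[15]
        assert modularity > 0.5
        # each true blob maps to exactly one cluster
        df = pd.DataFrame({"true": labels.to_numpy(), "found": membership})
        assert (df.groupby("true")["found"].nunique() == 1).all()
        assert df["found"].nunique() == 3

    def test_oversized_k_skipped_with_warning(self):
        pcs, _ = _blobs(n_per=3)
        with pytest.warns(UserWarning, match="skipped"):
            parts = louvain_sweep(pcs, k_values=[2, 500], seed=0)
        assert list(parts) == [2]

    def test_jaccard_weight_is_one_for_identical_neighbourhoods(self):
        from cogtex.clusters import _jaccard_knn_graph

        # four collinear points: the two middle points share both neighbours
        coords = np.array([[0.0, 0], [1, 0], [1.1, 0], [2.1, 0]])
        g = _jaccard_knn_graph(coords, k=3)  # all-to-all: identical sets minus self
        # neighbours of i are all others; Jaccard of (i, j) = |rest|/|union|
        w = dict(zip([(e.source, e.target) for e in g.es], g.es["weight"]))
        assert all(v > 0 for v in w.values())
        sym = _jaccard_knn_graph(np.array([[0.0, 0], [1, 0], [0, 1], [1, 1]]), k=2)
        assert max(sym.es["weight"]) <= 1.0


class TestFlagging:
    def test_perfect_tissues_all_kept_with_unit_purity(self):
        pcs, labels = _blobs(n_per=20)
        parts = louvain_sweep(pcs, k_values=[8, 12], seed=0)
        assignment = flag_mixed_and_divergent(parts, labels)
        assert (assignment.table["status"] == "KEPT").all()
        assert (assignment.tissue_best["P"] == 1.0).all()

    def test_relabelled_sample_flagged_divergent(self):
        pcs, labels = _blobs(n_per=20, seed=3)
        labels = labels.copy()
        labels.iloc[0] = "T1"  # point sits in T0's blob but is labelled T1
        parts = louvain_sweep(pcs, k_values=[8], seed=0)
        assignment = flag_mixed_and_divergent(parts, labels)
        assert assignment.table.loc["s0", "status"] == "DIVERGENT"

    def test_conservation_of_counts(self, small_cohort):
        cohort = inject_outliers(small_cohort, 3, 3, seed=4)
        norm = log_quantile_normalize(cohort.expr)
        assignment, _, _ = purify_tissue_clusters(
            norm.values, cohort.samples["tissue"], n_perm=20,
            k_values=range(5, 26, 5), perplexity=10, seed=0, max_pcs=8,
        )
        counts = assignment.counts()
        assert sum(counts.values()) == cohort.expr.n_samples


class TestMerging:
    def test_same_profile_tissues_merged(self):
        # two tissues drawn from one blob, one distinct tissue
        pcs, labels = _blobs(n_per=30, centers=((0, 0), (10, 10)), seed=5)
        labels = labels.copy()
        # split blob T0 arbitrarily into two "tissues"
        first_half = labels.index[:15]
        labels.loc[first_half] = "T0a"
        labels[labels == "T0"] = "T0b"
        parts = louvain_sweep(pcs, k_values=[15], seed=0)
        assignment = flag_mixed_and_divergent(parts, labels, p_min=0.4)
        merged = merge_mixed_tissue_pairs(assignment, mix_threshold=0.25)
        assert merged.merges == [["T0a", "T0b"]]
        kept = merged.kept
        assert set(kept.loc[kept["tissue"].isin(["T0a", "T0b"]), "cluster"]) == {"T0a+T0b"}

    def test_distinct_tissues_not_merged(self):
        pcs, labels = _blobs(n_per=20, seed=6)
        parts = louvain_sweep(pcs, k_values=[8], seed=0)
        assignment = flag_mixed_and_divergent(parts, labels)
        merged = merge_mixed_tissue_pairs(assignment)
        assert merged.merges == []


class TestTsneStage:
    def test_same_seed_identical_coordinates(self):
        pcs, _ = _blobs(n_per=15, sd=1.0, seed=7)
        a = tsne_embed(pcs, perplexity=10, seed=3)
        b = tsne_embed(pcs, perplexity=10, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_blobs_separate_in_embedding(self):
        from sklearn.metrics import silhouette_score

        pcs, labels = _blobs(n_per=25, sd=0.5, seed=8)
        emb = tsne_embed(pcs, perplexity=10, learning_rate=50, seed=0)
        assert silhouette_score(emb.to_numpy(), labels.to_numpy()) > 0.5

    def test_perplexity_too_large_rejected(self):
        pcs, _ = _blobs(n_per=3)
        with pytest.raises(CogtexError, match="perplexity"):
            tsne_embed(pcs, perplexity=30, seed=0)


class TestMedoidOutlierRemoval:
    def _assignment(self, labels):
        table = pd.DataFrame(
            {
                "sample_id": labels.index,
                "tissue": labels.to_numpy(),
                "cluster": labels.to_numpy(),
                "status": "KEPT",
                "P": 1.0,
                "k": 10,
            },
            index=labels.index,
        )
        return ClusterAssignment(table, pd.DataFrame())

    def test_relocated_point_flagged(self):
        pcs, labels = _blobs(n_per=20, seed=9)
        emb = pcs.scores.iloc[:, :2].copy()
        emb.columns = ["tsne1", "tsne2"]
        emb.iloc[0] = emb.loc[labels == "T1"].mean()  # drop a T0 point inside T1
        out = medoid_knn_outlier_removal(emb, self._assignment(labels))
        assert out.table.loc["s0", "status"] == "TSNE_OUTLIER"
        untouched = out.table.drop(index="s0")
        assert (untouched["status"] == "KEPT").all()

    def test_compact_clusters_untouched(self):
        pcs, labels = _blobs(n_per=15, seed=10)
        emb = pcs.scores.iloc[:, :2].copy()
        emb.columns = ["tsne1", "tsne2"]
        out = medoid_knn_outlier_removal(emb, self._assignment(labels))
        assert (out.table["status"] == "KEPT").all()

    def test_tiny_cluster_warns_but_processes(self):
        labels = pd.Series(
            ["A"] * 3 + ["B"] * 10,
            index=[f"s{i}" for i in range(13)],
        )
        rng = np.random.default_rng(11)
        emb = pd.DataFrame(
            np.vstack([rng.normal(0, 0.1, (3, 2)), rng.normal(8, 0.1, (10, 2))]),
            index=labels.index, columns=["tsne1", "tsne2"],
        )
        with pytest.warns(UserWarning, match="without outlier trim"):
            out = medoid_knn_outlier_removal(emb, self._assignment(labels))
        assert (out.table["status"] == "KEPT").all()


def test_manual_exclusions_applied_and_unknown_rejected(small_cohort):
    labels = small_cohort.samples["tissue"]
    table = pd.DataFrame(
        {"sample_id": labels.index, "tissue": labels.to_numpy(),
         "cluster": labels.to_numpy(), "status": "KEPT", "P": 1.0, "k": 5},
        index=labels.index,
    )
    assignment = ClusterAssignment(table, pd.DataFrame())
    sid = labels.index[0]
    out = apply_manual_exclusions(assignment, [sid])
    assert out.table.loc[sid, "status"] == "MANUAL"
    with pytest.raises(CogtexError, match="unknown"):
        apply_manual_exclusions(assignment, ["nope"])


def test_outlier_recovery_end_to_end():
    """Injected mixed/divergent samples are recovered with precision and
    recall >= 0.8 by the two-stage purification."""
    cohort = generate_cohort(
        CohortConfig(n_tissues=5, samples_per_tissue=40, n_genes=80, seed=17)
    )
    cohort = inject_outliers(cohort, 5, 5, seed=23)
    norm = log_quantile_normalize(cohort.expr)
    assignment, _, _ = purify_tissue_clusters(
        norm.values, cohort.samples["tissue"], n_perm=20,
        k_values=range(5, 31, 5), perplexity=15, seed=0, max_pcs=10,
    )
    truth = set(cohort.truth.mixed_samples) | set(cohort.truth.divergent_samples)
    flagged = set(
        assignment.table.index[
            assignment.table["status"].isin(["MIXED", "DIVERGENT", "TSNE_OUTLIER"])
        ]
    )
    recall = len(truth & flagged) / len(truth)
    precision = len(truth & flagged) / len(flagged)
    assert recall >= 0.8
    assert precision >= 0.8
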