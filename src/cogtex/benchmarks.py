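"""Property benchmarks on synthetic cohorts with known ground truth.

These harnesses exercise the full estimation chain (filter -> normalize ->
batch-correct -> estimate; purification where it is the object under test) on
seeded cohorts and score the outcome against what was planted: rank recovery
of the coexpression scenarios in the two modalities, recovery of injected
outlier samples, and tissue-pair merging. Problem sizes are chosen so each
benchmark finishes in minutes on one core while leaving the planted signals
at realistic strengths.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .clusters import (
    PCEmbedding,
    flag_mixed_and_divergent,
    louvain_sweep,
    merge_mixed_tissue_pairs,
    purify_tissue_clusters,
)
from .coexpression import CoexpressionModel
from .preprocess import combat_serial, filter_and_rescue, log_quantile_normalize
from .synthetic import CohortConfig, PlantedPair, generate_cohort, inject_outliers

__all__ = [
    "planted_scenario_benchmark",
    "outlier_recovery_benchmark",
    "tissue_merge_benchmark",
]


def _pair_ranks(matrix: pd.DataFrame, pairs) -> dict[str, list[int]]:
    """1-based rank of each planted pair among all unordered pairs, by |value|."""
    genes = list(matrix.index)
    pos = {g: i for i, g in enumerate(genes)}
    arr = matrix.to_numpy(float)
    iu = np.triu_indices(len(genes), k=1)
    vals = np.abs(arr[iu])
    order = np.argsort(-vals, kind="stable")
    rank = np.empty(len(vals))
    rank[order] = np.arange(1, len(vals) + 1)
    rank_of = dict(zip(zip(iu[0], iu[1]), rank))
    out: dict[str, list[int]] = {}
    for ga, gb, scenario in pairs:
        if ga in pos and gb in pos:
            i, j = sorted((pos[ga], pos[gb]))
            out.setdefault(scenario, []).append(int(rank_of[(i, j)]))
    return out


def planted_scenario_benchmark(
    seed: int,
    n_tissues: int = 12,
    samples_per_tissue: int = 60,
    n_genes: int = 100,
    n_pairs_per_scenario: int = 3,
    n_per: int = 50,
    n_reps: int = 10,
) -> dict:
    """Rank recovery of planted coexpression scenarios through the full chain.

    Returns per-scenario pair ranks for (pearson, tpm), (pearson, zscore) and
    (g, tpm), plus the total number of pairs, as
    ``{"n_pairs": N, "ranks": {(metric, modality): {scenario: [ranks]}}}``.
    """
    scenarios = ["SYS_ONLY", "TISSUE_ONLY", "XOR", "TISSUE_EXCEPTION", "NONLINEAR", "BOTH"]
    planted, idx = [], 0
    for s in scenarios:
        for _ in range(n_pairs_per_scenario):
            planted.append(PlantedPair(idx, idx + 1, s))
            idx += 2
    cfg = CohortConfig(
        n_tissues=n_tissues, samples_per_tissue=samples_per_tissue,
        n_genes=n_genes, seed=seed, planted_pairs=planted,
    )
    cohort = generate_cohort(cfg)
    report = filter_and_rescue(cohort.expr, cohort.samples["tissue"])
    expr = cohort.expr.subset_genes(report.retained)
    corrected = combat_serial(log_quantile_normalize(expr), cohort.samples)
    results = {}
    for modality in ("tpm", "zscore"):
        model = CoexpressionModel(
            corrected, cohort.samples["tissue"], metrics=("pearson", "g"),
            modality=modality, n_per=n_per, n_reps=n_reps, strict=False,
        )
        results[modality] = model.fit(seed=seed + 1)
    gid = lambda i: f"G{i:05d}"
    pair_keys = [(gid(p.gene_a), gid(p.gene_b), p.scenario) for p in planted]
    n_retained = results["tpm"].min_matrix("pearson").shape[0]
    ranks = {
        (metric, modality): _pair_ranks(results[modality].min_matrix(metric), pair_keys)
        for metric, modality in (("pearson", "tpm"), ("pearson", "zscore"), ("g", "tpm"))
    }
    return {"n_pairs": n_retained * (n_retained - 1) // 2, "ranks": ranks}


def outlier_recovery_benchmark(
    seed: int,
    n_tissues: int = 6,
    samples_per_tissue: int = 40,
    n_genes: int = 120,
    n_mixed: int = 5,
    n_divergent: int = 5,
    n_repeats: int = 3,
) -> dict:
    """Precision/recall of the two-stage purification on injected outliers.

    Counts are pooled over ``n_repeats`` independent cohorts (seeds derived
    from ``seed``) so single-cohort variance does not dominate the estimate.
    """
    tp = fp = fn = 0
    for r in range(n_repeats):
        s = seed + 1000 * r
        cohort = generate_cohort(
            CohortConfig(n_tissues=n_tissues, samples_per_tissue=samples_per_tissue,
                         n_genes=n_genes, seed=s)
        )
        cohort = inject_outliers(cohort, n_mixed, n_divergent, seed=s + 1)
        norm = log_quantile_normalize(cohort.expr)
        assignment, _, _ = purify_tissue_clusters(
            norm.values, cohort.samples["tissue"], n_perm=20,
            k_values=range(5, 31, 5), perplexity=15, seed=s, max_pcs=10,
        )
        truth = set(cohort.truth.mixed_samples) | set(cohort.truth.divergent_samples)
        flagged = set(
            assignment.table.index[
                assignment.table["status"].isin(["MIXED", "DIVERGENT", "TSNE_OUTLIER"])
            ]
        )
        tp += len(truth & flagged)
        fp += len(flagged - truth)
        fn += len(truth - flagged)
    return {
        "n_injected": tp + fn,
        "n_flagged": tp + fp,
        "recall": tp / (tp + fn) if tp + fn else float("nan"),
        "precision": tp / (tp + fp) if tp + fp else float("nan"),
    }


def tissue_merge_benchmark(
    n_tissues: int = 47,
    n_merged_pairs: int = 5,
    samples_per_tissue: int = 12,
    seed: int = 0,
) -> dict:
    """Cluster count after merging tissue pairs that share one expression state.

    ``n_tissues`` labels are laid over ``n_tissues - n_merged_pairs`` distinct
    expression states (blobs in a 2-D embedding); each of ``n_merged_pairs``
    states carries two interleaved tissue labels. The expected cluster count
    after purity matching and merging is ``n_tissues - n_merged_pairs``.
    """
    n_states = n_tissues - n_merged_pairs
    rng = np.random.default_rng(seed)
    side = int(np.ceil(np.sqrt(n_states)))
    centers = np.array([(30.0 * (i % side), 30.0 * (i // side)) for i in range(n_states)])
    coords, labels = [], []
    tissue_id = 0
    for state in range(n_states):
        double = state < n_merged_pairs
        n_here = samples_per_tissue * (2 if double else 1)
        pts = rng.normal(0, 0.8, (n_here, 2)) + centers[state]
        coords.append(pts)
        if double:
            half = rng.permutation(n_here) < samples_per_tissue
            labels += [f"tissue_{tissue_id:02d}" if h else f"tissue_{tissue_id + 1:02d}"
                       for h in half]
            tissue_id += 2
        else:
            labels += [f"tissue_{tissue_id:02d}"] * n_here
            tissue_id += 1
    coords = np.vstack(coords)
    ids = [f"s{i}" for i in range(len(coords))]
    pcs = PCEmbedding(pd.DataFrame(coords, index=ids), np.ones(2), 2, 0)
    tissues = pd.Series(labels, index=ids)
    partitions = louvain_sweep(pcs, k_values=[8, 16, 24], seed=seed)
    assignment = flag_mixed_and_divergent(partitions, tissues, p_min=0.4)
    merged = merge_mixed_tissue_pairs(assignment, mix_threshold=0.25)
    return {
        "n_tissues": n_tissues,
        "n_merges": len(merged.merges),
        "n_clusters": merged.n_clusters(),
    }
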