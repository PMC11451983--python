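"""Evaluation statistics for coexpression estimates.

Four checks: hypergeometric pathway-enrichment counts on the top/bottom tail
of a gene's coexpression ranking; AUROC against a probabilistic functional
network (high-probability edges as positives, a matched random draw of
near-zero-probability edges as negatives); top-n overlap and median-rank
comparisons between two rankings; and the D-score quantifying how strongly a
gene ordering concentrates ChIP-peak-carrying genes at its head.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._errors import CogtexError

__all__ = [
    "rank_genes",
    "top_fraction",
    "bottom_fraction",
    "enrichment_counts",
    "RocResult",
    "network_auroc",
    "topn_overlap",
    "median_rank_of_top",
    "DScoreResult",
    "d_score",
]


def rank_genes(values: pd.Series, anchor: str | None = None) -> list[str]:
    """Genes ordered by |value| descending, ties broken by gene id; the anchor
    (if given) is excluded from its own ranking."""
    s = values.drop(index=anchor) if anchor is not None and anchor in values.index else values
    return sorted(s.index, key=lambda g: (-abs(s[g]), g))


def top_fraction(ranked: list[str], frac: float = 0.05) -> list[str]:
    """The top `frac` of a ranking (strongest |coexpression|)."""
    return ranked[: top_set_size(len(ranked), frac)]


def bottom_fraction(ranked: list[str], frac: float = 0.05) -> list[str]:
    """The bottom `frac`: the genes with |coexpression| closest to zero."""
    return ranked[len(ranked) - top_set_size(len(ranked), frac):]


def top_set_size(n_genes: int, frac: float = 0.05) -> int:
    """5% of 33,445 genes -> 1,672 (round to nearest)."""
    return int(round(frac * n_genes))


def enrichment_counts(
    gene_set,
    universe,
    pathways: dict[str, list[str]],
    alpha: float = 0.05,
) -> int:
    """Number of pathways over-represented in ``gene_set`` at p < ``alpha``.

    The universe is the genes shared between the coexpression matrix and the
    pathway collection; the test is the hypergeometric upper tail
    P(X >= overlap).
    """
    universe = set(universe)
    if not universe:
        raise CogtexError("empty gene universe")
    gene_set = set(gene_set) & universe
    M = len(universe)
    n = len(gene_set)
    count = 0
    for genes in pathways.values():
        pw = set(genes) & universe
        if not pw:
            continue
        k = len(gene_set & pw)
        # P(X >= k) for drawing n from M with len(pw) successes
        p = stats.hypergeom.sf(k - 1, M, len(pw), n)
        if p < alpha:
            count += 1
    return count


@dataclass
class RocResult:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auroc: float
    n_positives: int
    n_negatives: int


def _roc_from_scores(pos_scores: np.ndarray, neg_scores: np.ndarray, n_points: int) -> RocResult:
    allscores = np.concatenate([pos_scores, neg_scores])
    lo, hi = allscores.min(), allscores.max()
    ts = np.linspace(hi, lo, n_points)  # descending: curve runs (0,0) -> (1,1)
    tpr = np.array([(pos_scores >= t).mean() for t in ts])
    fpr = np.array([(neg_scores >= t).mean() for t in ts])
    # exact AUROC via the rank statistic (Mann-Whitney), invariant to the grid
    ranks = stats.rankdata(allscores)
    n_pos, n_neg = len(pos_scores), len(neg_scores)
    auroc = (ranks[:n_pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    return RocResult(ts, tpr, fpr, float(auroc), n_pos, n_neg)


def network_auroc(
    pair_values: pd.DataFrame,
    edges: pd.DataFrame,
    pos_thresh: float = 0.8,
    neg_thresh: float = 0.005,
    n_points: int = 1000,
    seed: int = 0,
) -> RocResult:
    """AUROC of |coexpression| separating high- from low-probability edges.

    ``pair_values`` has columns (gene_a, gene_b, value); ``edges`` has columns
    (gene_a, gene_b, probability). Positives are edges with probability >
    ``pos_thresh``; negatives a same-sized seeded draw from edges with
    probability < ``neg_thresh``. Pairs are matched by unordered gene id;
    edges without a coexpression value are dropped with a warning.
    """
    def keyed(df):
        k = df.apply(lambda r: tuple(sorted((r["gene_a"], r["gene_b"]))), axis=1)
        return df.assign(_key=k)

    pv = keyed(pair_values).set_index("_key")["value"]
    if pv.index.duplicated().any():
        pv = pv[~pv.index.duplicated()]
    ed = keyed(edges)
    pos = ed[ed["probability"] > pos_thresh]
    neg_pool = ed[ed["probability"] < neg_thresh]
    if pos.empty:
        raise CogtexError(f"no positive edges at probability > {pos_thresh}")
    rng = np.random.default_rng(seed)
    n_take = min(len(pos), len(neg_pool))
    neg = neg_pool.iloc[rng.choice(len(neg_pool), size=n_take, replace=False)]

    def scores(df):
        keys = df["_key"]
        present = keys.isin(pv.index)
        if (~present).any():
            warnings.warn(f"{int((~present).sum())} edge(s) without a coexpression value dropped")
        return np.abs(pv.loc[keys[present]].to_numpy(float))

    pos_scores, neg_scores = scores(pos), scores(neg)
    if len(pos_scores) == 0 or len(neg_scores) == 0:
        raise CogtexError("no scored positives or negatives after matching")
    return _roc_from_scores(pos_scores, neg_scores, n_points)


def topn_overlap(rank_a: list[str], rank_b: list[str], n: int = 100) -> int:
    """|top_n(a) ∩ top_n(b)|."""
    if n > len(rank_a) or n > len(rank_b):
        raise CogtexError(f"n={n} exceeds the ranked universe")
    return len(set(rank_a[:n]) & set(rank_b[:n]))


def median_rank_of_top(rank_a: list[str], rank_b: list[str], n: int = 100) -> float:
    """Median position (1-based) in ranking b of the top n genes of ranking a."""
    if n > len(rank_a):
        raise CogtexError(f"n={n} exceeds the ranked universe")
    pos_b = {g: i + 1 for i, g in enumerate(rank_b)}
    missing = [g for g in rank_a[:n] if g not in pos_b]
    if missing:
        raise CogtexError(f"gene(s) absent from the second ranking: {missing[:5]}")
    return float(np.median([pos_b[g] for g in rank_a[:n]]))


@dataclass
class DScoreResult:
    """Normalized area between the cumulative peak count over a gene ordering
    and the uniform expectation line."""

    d: float
    observed: np.ndarray  # cumulative O_i
    expected: np.ndarray  # E_i = i * P / N
    n_genes: int
    n_peaks: int
    null_mean: float | None = None  # mean D over random orderings
    null_values: np.ndarray | None = None


def _d_of(flags: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    n = len(flags)
    p = int(flags.sum())
    obs = np.cumsum(flags.astype(float))
    exp = np.arange(1, n + 1) * (p / n)
    d = float(np.abs(obs - exp).sum() / (n * p / 2.0))
    return d, obs, exp


def d_score(
    ranked_genes: list[str],
    peaks: pd.Series,
    n_null: int = 100,
    seed: int = 0,
) -> DScoreResult:
    """D-score of a gene ordering against per-gene peak flags.

    D = sum_i |O_i - E_i| / (N * P / 2), the deviation area between cumulative
    observed peak counts and the uniform diagonal, as a fraction of the
    triangle area. Also returns the mean D of ``n_null`` seeded random
    orderings as the permutation null.
    """
    missing = [g for g in ranked_genes if g not in peaks.index]
    if missing:
        raise CogtexError(f"gene(s) without a peak flag: {missing[:5]}")
    flags = peaks.loc[ranked_genes].to_numpy(bool)
    if flags.sum() == 0:
        raise CogtexError("no gene carries a peak")
    d, obs, exp = _d_of(flags)
    null_vals = None
    null_mean = None
    if n_null:
        rng = np.random.default_rng(seed)
        null_vals = np.array([_d_of(rng.permutation(flags))[0] for _ in range(n_null)])
        null_mean = float(null_vals.mean())
    return DScoreResult(d, obs, exp, len(flags), int(flags.sum()), null_mean, null_vals)
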