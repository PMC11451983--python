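"""The coexpression estimator.

Associations between gene pairs are measured three ways — Pearson, Spearman,
and a modified G-statistic over a 3-level (low/mid/high) discretization of each
gene — in two modalities: the *system level* (quantile-normalized log TPM, so
between-tissue mean differences contribute) and the *tissue level* (z-scores
per tissue cluster, so only within-tissue covariation contributes).

Robustness comes from the subsample design: 70 samples are drawn without
replacement from every tissue cluster, the matrices are computed, and this is
repeated 20 times; the reported value per pair is the *minimum* across
repetitions — for signed correlations the value of smallest absolute magnitude
with its sign preserved, a pessimistic estimate biased toward zero.

The module is organised around :class:`CoexpressionModel` (data + design)
whose :meth:`~CoexpressionModel.fit` returns :class:`CoexpressionResults`
carrying the per-repetition matrices, the minimum-aggregated matrices,
diagnostic flags, and a ``summary()`` table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._errors import CogtexError, ConfigError
from .io import ExpressionMatrix, Scale

__all__ = [
    "SubsampleDesign",
    "make_subsample_design",
    "correlation_matrix",
    "DiscretizedGene",
    "discretize_three_levels",
    "ContingencyTable3x3",
    "g_statistic",
    "g_matrix",
    "zscore_by_cluster",
    "aggregate_minimum",
    "ischemia_two_means",
    "covariate_strata",
    "matrix_inventory",
    "CoexpressionModel",
    "CoexpressionResults",
]

METRICS = ("pearson", "spearman", "g")
TRIMMED, LOW, MID, HIGH = -1, 0, 1, 2


# ----------------------------------------------------------------- subsampling

@dataclass
class SubsampleDesign:
    """Per-repetition sample draws: ``indices[rep][cluster]`` -> list of sample ids."""

    n_per: int
    n_reps: int
    base_seed: int
    indices: list[dict[str, list[str]]]

    def samples_for_rep(self, rep: int) -> list[str]:
        out: list[str] = []
        for cluster in sorted(self.indices[rep]):
            out.extend(self.indices[rep][cluster])
        return out


def make_subsample_design(
    cluster_of_sample: pd.Series,
    n_per: int = 70,
    n_reps: int = 20,
    base_seed: int = 0,
    strict: bool = True,
) -> SubsampleDesign:
    """Draw ``n_per`` samples per cluster, without replacement, ``n_reps`` times.

    In strict mode a cluster smaller than ``n_per`` is an error; in lenient
    mode all its samples are used with a warning. Deterministic given
    ``base_seed``; repetition r uses the child stream (base_seed, r).
    """
    clusters = {c: list(cluster_of_sample.index[cluster_of_sample == c])
                for c in sorted(cluster_of_sample.unique())}
    for c, ids in clusters.items():
        if len(ids) < n_per:
            if strict:
                raise CogtexError(
                    f"cluster {c!r} has {len(ids)} samples, fewer than n_per={n_per}"
                )
            warnings.warn(f"cluster {c!r} has {len(ids)} < {n_per} samples; using all")
    reps = []
    for r in range(n_reps):
        rng = np.random.default_rng(np.random.SeedSequence(base_seed, spawn_key=(r,)))
        draw = {}
        for c, ids in clusters.items():
            take = min(n_per, len(ids))
            draw[c] = [ids[i] for i in rng.choice(len(ids), size=take, replace=False)]
        reps.append(draw)
    return SubsampleDesign(n_per, n_reps, base_seed, reps)


# ---------------------------------------------------------------- correlations

def correlation_matrix(values: pd.DataFrame, metric: str = "pearson") -> pd.DataFrame:
    """Symmetric gene x gene correlation over samples (columns).

    Spearman uses average ranks for ties. Constant genes get 0 rows/columns
    (flagged with a warning) and 1 on the diagonal.
    """
    if values.shape[1] < 3:
        raise CogtexError("need at least 3 samples for a correlation")
    arr = values.to_numpy(float)
    if metric == "spearman":
        arr = stats.rankdata(arr, axis=1)
    elif metric != "pearson":
        raise ConfigError(f"unknown correlation metric {metric!r}")
    sd = arr.std(axis=1)
    const = sd == 0
    if const.any():
        warnings.warn(f"{int(const.sum())} constant gene(s): correlations set to 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(arr)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)
    np.clip(corr, -1.0, 1.0, out=corr)
    return pd.DataFrame(corr, index=values.index, columns=values.index)


# -------------------------------------------------------------- discretization

@dataclass
class DiscretizedGene:
    """Per-sample codes in {LOW, MID, HIGH, TRIMMED} with the fitted centroids."""

    codes: np.ndarray  # int codes; TRIMMED = -1
    centroids: np.ndarray  # ascending
    trim_bounds: tuple[float, float]
    variant: str  # "HW" or "LLOYD"
    degenerate: bool = False


def _kmeans_1d_hw(x: np.ndarray, centers: np.ndarray, max_iter: int) -> tuple[np.ndarray, np.ndarray, bool]:
    """Hartigan-Wong k-means on a 1-D vector. Returns (labels, centers, converged)."""
    k = len(centers)
    labels = np.argmin(np.abs(x[:, None] - centers[None, :]), axis=1)
    centers = centers.copy()
    counts = np.bincount(labels, minlength=k).astype(float)
    sums = np.bincount(labels, weights=x, minlength=k)
    with np.errstate(invalid="ignore"):
        centers = np.where(counts > 0, sums / np.maximum(counts, 1), centers)
    for _ in range(max_iter):
        moved = False
        for i in range(len(x)):
            s = labels[i]
            if counts[s] <= 1:
                continue
            removal = counts[s] * (x[i] - centers[s]) ** 2 / (counts[s] - 1)
            gains = counts * (x[i] - centers) ** 2 / (counts + 1)
            gains[s] = np.inf
            t = int(np.argmin(gains))
            if gains[t] < removal:
                sums[s] -= x[i]; counts[s] -= 1
                centers[s] = sums[s] / counts[s]
                sums[t] += x[i]; counts[t] += 1
                centers[t] = sums[t] / counts[t]
                labels[i] = t
                moved = True
        if not moved:
            return labels, centers, True
    return labels, centers, False


def _kmeans_1d_lloyd(x: np.ndarray, centers: np.ndarray, max_iter: int) -> tuple[np.ndarray, np.ndarray, bool]:
    centers = centers.copy()
    labels = np.argmin(np.abs(x[:, None] - centers[None, :]), axis=1)
    for _ in range(max_iter):
        new = centers.copy()
        for c in range(len(centers)):
            members = x[labels == c]
            if len(members):
                new[c] = members.mean()
        new_labels = np.argmin(np.abs(x[:, None] - new[None, :]), axis=1)
        if np.array_equal(new_labels, labels) and np.allclose(new, centers):
            return labels, new, True
        labels, centers = new_labels, new
    return labels, centers, False


def discretize_three_levels(
    values: np.ndarray,
    trim_quantiles: tuple[float, float] = (0.002, 0.998),
    max_iter_hw: int = 1000,
    max_iter_lloyd: int = 10_000,
) -> DiscretizedGene:
    """Three-level (low/mid/high) discretization of one gene's expression.

    Values strictly below the 0.2 percentile or strictly above the 99.8
    percentile are TRIMMED. K-means (k=3) runs on the rest, initialized at the
    deterministic centroids [0.2-percentile, median, 99.8-percentile];
    Hartigan-Wong first, with a Lloyd fallback on non-convergence. Codes are
    ordered by centroid value.
    """
    x = np.asarray(values, float)
    lo, hi = np.quantile(x, trim_quantiles)
    keep = (x >= lo) & (x <= hi)  # trim is strict "below and above"
    codes = np.full(len(x), TRIMMED, dtype=int)
    xk = x[keep]
    if len(np.unique(xk)) < 3:
        codes[keep] = MID
        return DiscretizedGene(codes, np.array([np.nan, float(np.mean(xk)) if len(xk) else np.nan, np.nan]),
                               (float(lo), float(hi)), "HW", degenerate=True)
    init = np.array([np.quantile(xk, 0.002), np.median(xk), np.quantile(xk, 0.998)])
    if len(np.unique(init)) < 3:
        init = np.quantile(xk, [0.1, 0.5, 0.9])
    labels, centers, converged = _kmeans_1d_hw(xk, init, max_iter_hw)
    variant = "HW"
    if not converged:
        labels, centers, _ = _kmeans_1d_lloyd(xk, init, max_iter_lloyd)
        variant = "LLOYD"
    order = np.argsort(centers)
    remap = np.empty(3, dtype=int)
    remap[order] = [LOW, MID, HIGH]
    codes[keep] = remap[labels]
    return DiscretizedGene(codes, centers[order], (float(lo), float(hi)), variant)


# ----------------------------------------------------------------- G-statistic

@dataclass
class ContingencyTable3x3:
    observed: np.ndarray  # 3x3
    expected: np.ndarray  # raw E (product of marginals / total)
    expected_floored: np.ndarray
    g: float
    residual_p: np.ndarray  # two-sided normal p from standardized residuals


def _floor_expected(O: np.ndarray, E: np.ndarray, big_floor: float = 1.0, small_floor: float = 0.5) -> np.ndarray:
    """Floor tiny expected counts: cells with O > 4 floor at 1, else at 0.5."""
    floors = np.where(O > 4, big_floor, small_floor)
    return np.maximum(E, floors)


def g_statistic(codes_a: np.ndarray, codes_b: np.ndarray, floor: bool = True) -> ContingencyTable3x3:
    """Modified G-statistic between two discretized genes.

    Samples TRIMMED in either gene are excluded pairwise. G = 2 sum O ln(O/E)
    with E floored (O > 4 -> floor 1, else 0.5) and empty cells contributing 0.
    Cell-wise post-hoc p-values come from standardized residuals
    (O-E)/sqrt(E(1-rowfrac)(1-colfrac)) against a standard normal.
    """
    mask = (codes_a != TRIMMED) & (codes_b != TRIMMED)
    a, b = codes_a[mask], codes_b[mask]
    n = len(a)
    if n == 0:
        raise CogtexError("empty contingency table: no shared non-trimmed samples")
    O = np.zeros((3, 3))
    np.add.at(O, (a, b), 1.0)
    row = O.sum(axis=1)
    col = O.sum(axis=0)
    E = np.outer(row, col) / n
    Ef = _floor_expected(O, E) if floor else E.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(O > 0, O * np.log(O / Ef), 0.0)
    g = float(2.0 * terms.sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = np.sqrt(E * (1 - row[:, None] / n) * (1 - col[None, :] / n))
        resid = np.where(denom > 0, (O - E) / denom, 0.0)
    pvals = 2.0 * stats.norm.sf(np.abs(resid))
    return ContingencyTable3x3(O, E, Ef, g, pvals)


def g_matrix(values: pd.DataFrame, floor: bool = True) -> pd.DataFrame:
    """Symmetric gene x gene matrix of modified G-statistics (diagonal NaN)."""
    genes = list(values.index)
    disc = [discretize_three_levels(values.loc[g].to_numpy()) for g in genes]
    n = len(genes)
    out = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i + 1, n):
            g = g_statistic(disc[i].codes, disc[j].codes, floor=floor).g
            out[i, j] = out[j, i] = g
    return pd.DataFrame(out, index=genes, columns=genes)


# -------------------------------------------------------------------- z-scores

def zscore_by_cluster(values: pd.DataFrame, cluster_of_sample: pd.Series) -> pd.DataFrame:
    """z = (x - m) / s per gene within each tissue cluster (s: sample sd).

    Genes constant within a cluster (s = 0) get z = 0 there.
    """
    cluster_of_sample = cluster_of_sample.loc[values.columns]
    out = np.empty_like(values.to_numpy(float))
    arr = values.to_numpy(float)
    cols = np.asarray(cluster_of_sample)
    for c in pd.unique(cols):
        m = cols == c
        sub = arr[:, m]
        mu = sub.mean(axis=1, keepdims=True)
        sd = sub.std(axis=1, ddof=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (sub - mu) / sd
        out[:, m] = np.where(sd > 0, z, 0.0)
    return pd.DataFrame(out, index=values.index, columns=values.columns)


# ------------------------------------------------------------------ aggregation

def aggregate_minimum(per_rep: list[pd.DataFrame], metric: str, signed_min: bool = False):
    """Collapse per-repetition matrices to the pessimistic minimum.

    For correlations the retained value per pair is the repetition value of
    smallest absolute magnitude with its sign preserved (``signed_min=True``
    takes the raw signed minimum instead); for G, the smallest G. Returns
    (matrix, sign_disagreement) where the flag marks pairs whose sign differs
    across repetitions (correlations only).
    """
    if not per_rep:
        raise CogtexError("no repetitions to aggregate")
    stack = np.stack([m.to_numpy(float) for m in per_rep])
    if metric == "g":
        all_nan = np.isnan(stack).all(axis=0)  # the G diagonal is undefined
        agg = np.min(np.where(np.isnan(stack), np.inf, stack), axis=0)
        agg[all_nan] = np.nan
        flags = np.zeros(agg.shape, dtype=bool)
    elif signed_min:
        agg = stack.min(axis=0)
        flags = (np.sign(stack).max(axis=0) != np.sign(stack).min(axis=0)) & (
            np.abs(stack).min(axis=0) > 0
        )
    else:
        idx = np.abs(stack).argmin(axis=0)
        agg = np.take_along_axis(stack, idx[None], axis=0)[0]
        flags = (np.sign(stack).max(axis=0) != np.sign(stack).min(axis=0)) & (
            np.abs(stack).min(axis=0) > 0
        )
    template = per_rep[0]
    return (
        pd.DataFrame(agg, index=template.index, columns=template.columns),
        pd.DataFrame(flags, index=template.index, columns=template.columns),
    )


# ------------------------------------------------------------------- covariates

def ischemia_two_means(times: np.ndarray) -> tuple[np.ndarray, float]:
    """Split ischemia times by 2-means with centroids initialized at the
    minimum and maximum; returns (labels 0=low/1=high, boundary)."""
    x = np.asarray(times, float)
    x = x[np.isfinite(x)]
    if len(x) < 2:
        raise CogtexError("need at least 2 ischemia times")
    centers = np.array([x.min(), x.max()])
    labels, centers, _ = _kmeans_1d_lloyd(x, centers, 1000)
    boundary = float(centers.mean())
    full = np.asarray(times, float)
    return (full >= boundary).astype(int), boundary


def covariate_strata(sample_table: pd.DataFrame) -> dict[str, list[str]]:
    """The seven covariate strata: sex (2), age (<50, 50-59 inclusive, >59),
    ischemia (2-means low/high). Returns {stratum name: sample ids}."""
    t = sample_table
    strata: dict[str, list[str]] = {
        "sex_male": list(t.index[t["sex"] == "male"]),
        "sex_female": list(t.index[t["sex"] == "female"]),
        "age_lt50": list(t.index[t["age"] < 50]),
        "age_50_59": list(t.index[(t["age"] >= 50) & (t["age"] <= 59)]),
        "age_gt59": list(t.index[t["age"] > 59]),
    }
    isch = t["ischemia_time"]
    known = isch.notna()
    labels, _ = ischemia_two_means(isch[known].to_numpy())
    ids = t.index[known]
    strata["ischemia_low"] = list(ids[labels == 0])
    strata["ischemia_high"] = list(ids[labels == 1])
    return strata


def stratify_covariates(
    expr: ExpressionMatrix,
    sample_table: pd.DataFrame,
    cluster_of_sample: pd.Series,
    n_per: int = 70,
    seed: int = 0,
) -> tuple[dict[str, list[str]], dict[tuple[str, str], pd.DataFrame]]:
    """Per-stratum Pearson matrices in both modalities.

    For each of the seven covariate strata a single expression matrix is
    assembled by drawing up to ``n_per`` samples per cluster from the stratum
    (clusters with no samples in the stratum are dropped with a warning).
    Returns (strata, {(stratum, modality): matrix}).
    """
    strata = covariate_strata(sample_table.loc[cluster_of_sample.index])
    results: dict[tuple[str, str], pd.DataFrame] = {}
    for si, (name, ids) in enumerate(sorted(strata.items())):
        members = cluster_of_sample.loc[[i for i in ids if i in cluster_of_sample.index]]
        if members.empty:
            warnings.warn(f"stratum {name!r} has no retained samples; skipped")
            continue
        empty = set(cluster_of_sample.unique()) - set(members.unique())
        if empty:
            warnings.warn(f"stratum {name!r}: cluster(s) {sorted(empty)} empty, dropped")
        design = make_subsample_design(members, n_per, n_reps=1,
                                       base_seed=seed + 100 + si, strict=False)
        chosen = design.samples_for_rep(0)
        sub = expr.values[chosen]
        results[(name, "tpm")] = correlation_matrix(sub, "pearson")
        zsub = zscore_by_cluster(sub, members.loc[chosen])
        results[(name, "zscore")] = correlation_matrix(zsub, "pearson")
    return strata, results


def matrix_inventory(
    n_modalities: int = 2, n_reps: int = 20, n_metrics: int = 3, n_strata: int = 7
) -> dict:
    """Count the matrices one full run produces (per-rep + covariate + minima)."""
    per_rep = n_modalities * n_reps * n_metrics
    covariate = n_modalities * n_strata
    minima = n_metrics * n_modalities
    return {
        "per_rep": per_rep,
        "covariate": covariate,
        "minimum": minima,
        "total": per_rep + covariate + minima,
    }


# ------------------------------------------------------------------ the model

class CoexpressionModel:
    """Subsampled coexpression estimator for one modality.

    Parameters
    ----------
    expr : ExpressionMatrix
        LOG10P1-scale matrix (normalized, batch-corrected).
    cluster_of_sample : Series
        Tissue-cluster label per retained sample (purification output).
    metrics : sequence of {"pearson", "spearman", "g"}
    modality : {"tpm", "zscore"}
        "tpm" correlates the log-scale values as-is (system level); "zscore"
        standardizes each gene within each cluster first (tissue level).
    n_per, n_reps : int
        Subsample size per cluster and number of repetitions.
    """

    def __init__(
        self,
        expr: ExpressionMatrix,
        cluster_of_sample: pd.Series,
        metrics=("pearson", "spearman", "g"),
        modality: str = "tpm",
        n_per: int = 70,
        n_reps: int = 20,
        strict: bool = True,
        signed_min: bool = False,
    ) -> None:
        if expr.scale != Scale.LOG10P1:
            raise CogtexError(f"model expects LOG10P1 scale, got {expr.scale}")
        if modality not in ("tpm", "zscore"):
            raise ConfigError(f"unknown modality {modality!r}")
        for m in metrics:
            if m not in METRICS:
                raise ConfigError(f"unknown metric {m!r}")
        missing = set(cluster_of_sample.index) - set(expr.sample_ids)
        if missing:
            raise CogtexError(f"cluster table references unknown samples: {sorted(missing)[:5]}")
        self.expr = expr
        self.cluster_of_sample = cluster_of_sample
        self.metrics = tuple(metrics)
        self.modality = modality
        self.n_per = n_per
        self.n_reps = n_reps
        self.strict = strict
        self.signed_min = signed_min

    def fit(self, seed: int = 0) -> "CoexpressionResults":
        design = make_subsample_design(
            self.cluster_of_sample, self.n_per, self.n_reps, base_seed=seed, strict=self.strict
        )
        per_rep: dict[str, list[pd.DataFrame]] = {m: [] for m in self.metrics}
        for r in range(design.n_reps):
            ids = design.samples_for_rep(r)
            sub = self.expr.values[ids]
            if self.modality == "zscore":
                sub = zscore_by_cluster(sub, self.cluster_of_sample.loc[ids])
            for m in self.metrics:
                if m == "g":
                    per_rep[m].append(g_matrix(sub))
                else:
                    per_rep[m].append(correlation_matrix(sub, m))
        minimum, flags = {}, {}
        for m in self.metrics:
            minimum[m], flags[m] = aggregate_minimum(per_rep[m], m, signed_min=self.signed_min)
        return CoexpressionResults(self, design, per_rep, minimum, flags)


@dataclass
class CoexpressionResults:
    """Fitted per-repetition and minimum-aggregated coexpression matrices."""

    model: CoexpressionModel
    design: SubsampleDesign
    per_rep: dict[str, list[pd.DataFrame]]
    minimum: dict[str, pd.DataFrame]
    sign_disagreement: dict[str, pd.DataFrame]

    def min_matrix(self, metric: str) -> pd.DataFrame:
        return self.minimum[metric]

    def ranking(self, metric: str, anchor: str) -> pd.Series:
        """Genes ordered by |min coexpression| with ``anchor``, descending;
        ties broken by gene id. The anchor is excluded."""
        col = self.minimum[metric][anchor].drop(index=anchor)
        order = sorted(col.index, key=lambda g: (-abs(col[g]), g))
        return col.loc[order]

    def pair(self, metric: str, gene_a: str, gene_b: str) -> dict:
        """All repetition values plus the minimum for one pair."""
        reps = [float(m.loc[gene_a, gene_b]) for m in self.per_rep[metric]]
        return {
            "reps": reps,
            "min": float(self.minimum[metric].loc[gene_a, gene_b]),
            "sign_disagreement": bool(self.sign_disagreement[metric].loc[gene_a, gene_b]),
        }

    def summary(self) -> str:
        lines = [
            "Coexpression estimation results",
            "=" * 47,
            f"modality:        {self.model.modality}",
            f"genes:           {self.model.expr.n_genes}",
            f"clusters:        {self.model.cluster_of_sample.nunique()}",
            f"subsample size:  {self.design.n_per} per cluster",
            f"repetitions:     {self.design.n_reps}",
            "",
            f"{'metric':<10}{'mean |min|':>12}{'max |min|':>12}{'sign flags':>12}",
        ]
        for m in self.model.metrics:
            mat = self.minimum[m].to_numpy(float)
            iu = np.triu_indices(mat.shape[0], k=1)
            vals = np.abs(mat[iu])
            vals = vals[np.isfinite(vals)]
            nflag = int(self.sign_disagreement[m].to_numpy()[iu].sum())
            lines.append(f"{m:<10}{vals.mean():>12.4f}{vals.max():>12.4f}{nflag:>12d}")
        return "\n".join(lines)
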