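"""Seeded generator for GTEx-like multi-tissue cohorts with known ground truth.

The generator emulates the structure the estimator has to cope with: several
tissues with distinct per-gene mean-expression profiles, two nested batch
effects (extraction and sequencing), a fraction of tissue-specific genes,
donor covariates (sex, age, ischemia time), and planted gene pairs realizing
the canonical coexpression scenarios — coexpressed only at the system level
(shared tissue-mean profile, independent within-tissue residuals), only at the
tissue level (orthogonal mean profiles, correlated residuals), both, mutually
exclusive (XOR) on/off tissue sets, monotone-saturating non-linear links, and
linear links with one exceptional tissue.

Values are generated on the log10(TPM+1) scale — tissue mean + batch shifts +
Gaussian residual — and exponentiated back to TPM, i.e. log-normal TPM with
multiplicative batch effects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._errors import ConfigError
from .io import ExpressionMatrix, Scale, write_gct

__all__ = [
    "SCENARIOS",
    "PlantedPair",
    "CohortConfig",
    "GroundTruth",
    "SyntheticCohort",
    "generate_cohort",
    "inject_outliers",
    "write_cohort",
]

SCENARIOS = (
    "SYS_POS",
    "SYS_ONLY",
    "TISSUE_ONLY",
    "BOTH",
    "XOR",
    "NONLINEAR",
    "TISSUE_EXCEPTION",
    "NULL",
)


@dataclass
class PlantedPair:
    gene_a: int
    gene_b: int
    scenario: str
    effect_size: float = 0.9

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ConfigError(f"unknown scenario {self.scenario!r}; choose from {SCENARIOS}")
        if self.gene_a == self.gene_b:
            raise ConfigError("planted pair must involve two distinct genes")


@dataclass
class CohortConfig:
    """Study-design knobs for one synthetic cohort.

    All magnitudes are on the log10(TPM+1) scale. Defaults give tissue
    separation strong enough for purification to be non-trivial, batch shifts
    detectable but smaller than the tissue signal, and within-tissue noise
    typical of bulk RNA-seq replicates.
    """

    n_tissues: int = 8
    samples_per_tissue: int | list[int] = 90
    n_genes: int = 200
    n_batches_extraction: int = 3
    n_batches_sequencing: int = 2
    batch_shift_sd: float = 0.12
    within_tissue_sd: float = 0.25
    tissue_mean_sd: float = 0.6
    fraction_tissue_specific_genes: float = 0.1
    planted_pairs: list[PlantedPair] = field(default_factory=list)
    seed: int = 0

    def sizes(self) -> list[int]:
        if isinstance(self.samples_per_tissue, int):
            return [self.samples_per_tissue] * self.n_tissues
        if len(self.samples_per_tissue) != self.n_tissues:
            raise ConfigError("samples_per_tissue list must have n_tissues entries")
        return list(self.samples_per_tissue)

    def validate(self) -> None:
        if min(self.n_tissues, self.n_genes, self.n_batches_extraction,
               self.n_batches_sequencing) < 1 or min(self.sizes()) < 1:
            raise ConfigError("all counts must be positive")
        if not 0.0 <= self.fraction_tissue_specific_genes <= 1.0:
            raise ConfigError("fraction_tissue_specific_genes must lie in [0, 1]")
        for pair in self.planted_pairs:
            for g in (pair.gene_a, pair.gene_b):
                if not 0 <= g < self.n_genes:
                    raise ConfigError(f"planted gene index {g} out of range [0, {self.n_genes})")


@dataclass
class GroundTruth:
    """What the generator planted, for scoring recovery downstream."""

    tissue_of_sample: pd.Series
    tissue_specific_genes: list[str]
    planted_pairs: pd.DataFrame  # gene_a, gene_b, scenario, effect_size, r_system, r_tissue
    mixed_samples: list[str] = field(default_factory=list)
    divergent_samples: list[str] = field(default_factory=list)


@dataclass
class SyntheticCohort:
    expr: ExpressionMatrix
    samples: pd.DataFrame
    truth: GroundTruth
    config: CohortConfig
    log_values: pd.DataFrame = None  # noiseless-scale convenience copy (log10(TPM+1))
    tissue_means: pd.DataFrame = None  # genes x tissues mean profile on log scale


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def _raise_floor(profile: np.ndarray, floor: float = 0.75) -> np.ndarray:
    """Shift a mean profile so its minimum sits at ``floor``, preserving shape."""
    return profile + max(0.0, floor - profile.min())


def _pair_correlations(log_values: pd.DataFrame, tissues: pd.Series, ga: str, gb: str):
    """Realized Pearson of a pair at system level (log scale) and tissue level (per-tissue z)."""
    a = log_values.loc[ga].to_numpy()
    b = log_values.loc[gb].to_numpy()
    r_sys = float(np.corrcoef(a, b)[0, 1]) if a.std() > 0 and b.std() > 0 else 0.0
    za, zb = np.empty_like(a), np.empty_like(b)
    for t in tissues.unique():
        m = (tissues == t).to_numpy()
        for src, dst in ((a, za), (b, zb)):
            mu, sd = src[m].mean(), src[m].std(ddof=1)
            dst[m] = (src[m] - mu) / sd if sd > 0 else 0.0
    r_tis = float(np.corrcoef(za, zb)[0, 1]) if za.std() > 0 and zb.std() > 0 else 0.0
    return r_sys, r_tis


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate one cohort; deterministic given ``config.seed``."""
    config.validate()
    sizes = config.sizes()
    n_samples = sum(sizes)
    T, G = config.n_tissues, config.n_genes
    gene_ids = [f"G{i:05d}" for i in range(G)]
    tissue_names = [f"tissue_{t:02d}" for t in range(T)]

    rng_mu = _rng(config.seed, 1)
    base = rng_mu.normal(1.2, 0.4, size=G)
    mu = base[:, None] + rng_mu.normal(0.0, config.tissue_mean_sd, size=(G, T))
    n_specific = int(round(config.fraction_tissue_specific_genes * G))
    specific_idx = rng_mu.choice(G, size=n_specific, replace=False) if n_specific else np.array([], int)
    home = rng_mu.integers(0, T, size=n_specific)
    for gi, ti in zip(specific_idx, home):
        mu[gi, :] = rng_mu.normal(0.01, 0.005, size=T)
        mu[gi, ti] = rng_mu.normal(1.6, 0.2)
    np.clip(mu, 0.0, None, out=mu)

    # sample bookkeeping: donors contribute one sample per tissue
    tissue_of = np.concatenate([[t] * n for t, n in enumerate(sizes)])
    within_idx = np.concatenate([np.arange(n) for n in sizes])
    sample_ids = [
        f"SYN-{d:04d}-{t:02d}" for d, t in zip(within_idx, tissue_of)
    ]

    rng_eps = _rng(config.seed, 2)
    eps = rng_eps.normal(0.0, config.within_tissue_sd, size=(G, n_samples))

    # planted pairs overwrite the mean profiles / residuals of the genes involved
    rng_pair = _rng(config.seed, 3)
    for pair in config.planted_pairs:
        a, b, rho = pair.gene_a, pair.gene_b, float(pair.effect_size)
        eta = rng_pair.normal(0.0, config.within_tissue_sd, size=n_samples)
        if pair.scenario == "NULL":
            continue
        if pair.scenario == "SYS_ONLY":
            # shared between-tissue profile, independent residuals; shift the
            # profile well above the zero floor (3 residual sds) so joint
            # clipping cannot induce a spurious within-tissue correlation,
            # while preserving its between-tissue variation
            mu[a] = _raise_floor(mu[a])
            mu[b] = mu[a]
        elif pair.scenario == "SYS_POS":
            mu[a] = _raise_floor(mu[a])
            jitter = rng_pair.normal(0.0, (1.0 - rho) * config.tissue_mean_sd, size=T)
            mu[b] = _raise_floor(rho * mu[a] + (1.0 - rho) * mu[a].mean() + jitter)
        elif pair.scenario == "TISSUE_ONLY":
            # orthogonalize the two mean profiles so only the correlated
            # residuals carry signal; between-tissue variation then dilutes the
            # system-level correlation as in the canonical tissue-only scenario
            ca = mu[a] - mu[a].mean()
            cb = mu[b] - mu[b].mean()
            if (ca**2).sum() > 0:
                cb = cb - (cb @ ca) / (ca @ ca) * ca
            mu[b] = _raise_floor(cb + mu[b].mean())
            mu[a] = _raise_floor(mu[a])
            eps[b] = rho * eps[a] + np.sqrt(1.0 - rho**2) * eta
        elif pair.scenario == "BOTH":
            mu[a] = _raise_floor(mu[a])
            mu[b] = mu[a]
            eps[b] = rho * eps[a] + np.sqrt(1.0 - rho**2) * eta
        elif pair.scenario == "XOR":
            # mutually exclusive on/off tissue sets; the "on" level varies by
            # tissue so the scatter is L-shaped (high G, weak linear fit)
            on = rng_pair.permutation(T) < T // 2
            hi_a = rng_pair.normal(1.8, 0.5, size=T)
            hi_b = rng_pair.normal(1.8, 0.5, size=T)
            mu[a] = np.where(on, np.maximum(hi_a, 0.8), 0.02)
            mu[b] = np.where(on, 0.02, np.maximum(hi_b, 0.8))
        elif pair.scenario == "NONLINEAR":
            mu[a] = _raise_floor(mu[a])
            x = mu[a][tissue_of] + eps[a]
            y = 2.8 * x / (x + 1.0)  # monotone-saturating link
            mu[b] = 0.0
            eps[b] = y + np.sqrt(max(1.0 - rho, 0.0)) * 0.3 * eta
        elif pair.scenario == "TISSUE_EXCEPTION":
            exc = int(rng_pair.integers(0, T))
            mu[a] = _raise_floor(mu[a])
            mu[b] = mu[a].copy()
            mu[b][exc] = mu[a][exc] + 2.0
            eps[b] = rho * eps[a] + np.sqrt(1.0 - rho**2) * eta

    rng_batch = _rng(config.seed, 4)
    ext_of = rng_batch.integers(0, config.n_batches_extraction, size=n_samples)
    seq_of = rng_batch.integers(0, config.n_batches_sequencing, size=n_samples)
    ext_shift = rng_batch.normal(0.0, config.batch_shift_sd, size=(config.n_batches_extraction, G))
    seq_shift = rng_batch.normal(0.0, config.batch_shift_sd, size=(config.n_batches_sequencing, G))

    log_vals = mu[:, tissue_of] + eps + ext_shift[ext_of].T + seq_shift[seq_of].T
    np.clip(log_vals, 0.0, None, out=log_vals)
    tpm = np.power(10.0, log_vals) - 1.0
    np.clip(tpm, 0.0, None, out=tpm)

    # donor covariates: sex/age per donor, ischemia per sample and bimodal so a
    # two-cluster split is well defined
    rng_cov = _rng(config.seed, 5)
    n_donors = max(sizes)
    donor_sex = rng_cov.choice(["male", "female"], size=n_donors)
    donor_age = rng_cov.integers(25, 76, size=n_donors)
    low_isch = rng_cov.normal(120.0, 40.0, size=n_samples)
    high_isch = rng_cov.normal(800.0, 120.0, size=n_samples)
    ischemia = np.clip(np.where(rng_cov.random(n_samples) < 0.5, low_isch, high_isch), 1.0, None)

    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "subject_id": [f"SYN-{d:04d}" for d in within_idx],
            "tissue": [tissue_names[t] for t in tissue_of],
            "extraction_batch": [f"EXT{b}" for b in ext_of],
            "sequencing_batch": [f"SEQ{b}" for b in seq_of],
            "sex": donor_sex[within_idx],
            "age": donor_age[within_idx].astype(float),
            "ischemia_time": np.round(ischemia, 1),
        },
        index=sample_ids,
    )

    log_df = pd.DataFrame(log_vals, index=gene_ids, columns=sample_ids)
    tissue_series = samples["tissue"]
    pair_rows = []
    for pair in config.planted_pairs:
        ga, gb = gene_ids[pair.gene_a], gene_ids[pair.gene_b]
        r_sys, r_tis = _pair_correlations(log_df, tissue_series, ga, gb)
        pair_rows.append(
            dict(gene_a=ga, gene_b=gb, scenario=pair.scenario,
                 effect_size=pair.effect_size, r_system=r_sys, r_tissue=r_tis)
        )
    truth = GroundTruth(
        tissue_of_sample=tissue_series.copy(),
        tissue_specific_genes=[gene_ids[i] for i in specific_idx],
        planted_pairs=pd.DataFrame(
            pair_rows, columns=["gene_a", "gene_b", "scenario", "effect_size", "r_system", "r_tissue"]
        ),
    )
    expr = ExpressionMatrix(pd.DataFrame(tpm, index=gene_ids, columns=sample_ids), Scale.TPM)
    means = pd.DataFrame(mu, index=gene_ids, columns=tissue_names)
    return SyntheticCohort(expr, samples, truth, config, log_values=log_df, tissue_means=means)


def inject_outliers(cohort: SyntheticCohort, n_mixed: int, n_divergent: int, seed: int) -> SyntheticCohort:
    """Corrupt a cohort with the two artifact types purification must catch.

    Mixed samples are re-drawn as 50/50 mixtures of two tissues' mean profiles;
    divergent samples keep their expression but get a wrong tissue label.
    The returned cohort's ground truth records which samples were touched.
    """
    n_samples = cohort.expr.n_samples
    if n_mixed + n_divergent > n_samples:
        raise ConfigError("cannot inject more outliers than samples")
    rng = _rng(seed, 101)
    expr_vals = cohort.expr.values.copy()
    samples = cohort.samples.copy()
    tissue_names = sorted(samples["tissue"].unique())
    chosen = rng.choice(n_samples, size=n_mixed + n_divergent, replace=False)
    mixed_ids, divergent_ids = [], []
    cfg = cohort.config
    # all mixtures come from one tissue pair so they occupy a shared
    # intermediate expression state, as co-clustering mixed samples do
    if n_mixed:
        t1, t2 = rng.choice(tissue_names, size=2, replace=False)
        profile = (0.5 * cohort.tissue_means[t1] + 0.5 * cohort.tissue_means[t2]).to_numpy()
    for si in chosen[:n_mixed]:
        sid = expr_vals.columns[si]
        noise = rng.normal(0.0, cfg.within_tissue_sd, size=len(profile))
        logv = np.clip(profile + noise, 0.0, None)
        expr_vals[sid] = np.clip(np.power(10.0, logv) - 1.0, 0.0, None)
        mixed_ids.append(sid)
    for si in chosen[n_mixed:]:
        sid = expr_vals.columns[si]
        own = samples.loc[sid, "tissue"]
        wrong = str(rng.choice([t for t in tissue_names if t != own]))
        samples.loc[sid, "tissue"] = wrong
        divergent_ids.append(sid)
    truth = GroundTruth(
        tissue_of_sample=cohort.truth.tissue_of_sample.copy(),
        tissue_specific_genes=list(cohort.truth.tissue_specific_genes),
        planted_pairs=cohort.truth.planted_pairs.copy(),
        mixed_samples=mixed_ids,
        divergent_samples=divergent_ids,
    )
    expr = ExpressionMatrix(expr_vals, Scale.TPM)
    return SyntheticCohort(expr, samples, truth, cohort.config,
                           log_values=cohort.log_values, tissue_means=cohort.tissue_means)


def write_cohort(cohort: SyntheticCohort, outdir) -> dict[str, str]:
    """Write the cohort in the formats the readers consume (GCT + GTEx-style TSVs)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": str(outdir / "expression.gct"),
        "attributes": str(outdir / "sample_attributes.tsv"),
        "phenotypes": str(outdir / "subject_phenotypes.tsv"),
        "truth": str(outdir / "ground_truth.json"),
    }
    write_gct(cohort.expr, paths["expression"])
    s = cohort.samples
    attrs = pd.DataFrame(
        {
            "SAMPID": s["sample_id"],
            "SMTSD": s["tissue"],
            "SMNABTCH": s["extraction_batch"],
            "SMGEBTCH": s["sequencing_batch"],
            "SMTSISCH": s["ischemia_time"],
        }
    )
    attrs.to_csv(paths["attributes"], sep="\t", index=False)
    pheno = (
        s[["subject_id", "sex", "age"]]
        .drop_duplicates("subject_id")
        .rename(columns={"subject_id": "SUBJID", "sex": "SEX", "age": "AGE"})
    )
    pheno.to_csv(paths["phenotypes"], sep="\t", index=False)
    truth = {
        "tissue_of_sample": cohort.truth.tissue_of_sample.to_dict(),
        "tissue_specific_genes": cohort.truth.tissue_specific_genes,
        "planted_pairs": cohort.truth.planted_pairs.to_dict(orient="records"),
        "mixed_samples": cohort.truth.mixed_samples,
        "divergent_samples": cohort.truth.divergent_samples,
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=1)
    return paths
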