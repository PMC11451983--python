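"""End-to-end orchestration: filter -> normalize -> batch-correct -> purify
clusters -> estimate coexpression (-> covariate strata), from one config.

Every stage writes its report under the output directory and is recorded in a
manifest (JSON) that embeds the config hash, so re-running with identical
config and inputs is reproducible and individual stages can be resumed from
persisted artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from ._errors import CogtexError, ConfigError
from . import io as cio
from .preprocess import FilterThresholds, filter_and_rescue, log_quantile_normalize, combat_serial
from .clusters import purify_tissue_clusters
from .coexpression import (
    CoexpressionModel,
    matrix_inventory,
    stratify_covariates,
)

log = logging.getLogger("cogtex")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All thresholds and parameters of the pipeline; defaults are the
    published operating point."""

    # inputs
    expression_gct: str | None = None
    sample_attributes: str | None = None
    subject_phenotypes: str | None = None
    output_dir: str = "cogtex_out"
    # gene filter
    tpm_min: float = 0.1
    frac_samples: float = 0.20
    rescue_mean_tpm: float = 5.0
    rescue_frac: float = 0.66
    rescue_tpm: float = 1.0
    rescue_same_tissue: bool = False
    # purification
    n_permutations: int = 100
    max_pcs: int | None = None
    k_min: int = 1
    k_max: int = 100
    p_min: float = 0.5
    mix_threshold: float = 0.25
    perplexity: float = 30.0
    learning_rate: float = 200.0
    tsne_max_iter: int = 1000
    manual_exclusions: list[str] = field(default_factory=list)
    # estimation
    n_per_cluster: int = 70
    n_reps: int = 20
    metrics: list[str] = field(default_factory=lambda: ["pearson", "spearman", "g"])
    modalities: list[str] = field(default_factory=lambda: ["tpm", "zscore"])
    strict_subsampling: bool = False
    signed_min: bool = False
    compute_strata: bool = True
    # general
    seed: int = 0

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _stage(manifest: dict, name: str, t0: float, **info) -> None:
    manifest["stages"].append({"stage": name, "seconds": round(time.time() - t0, 2), **info})
    log.info("stage %s done in %.1fs: %s", name, time.time() - t0, info)


def run_pipeline(config: PipelineConfig, expr=None, samples=None) -> dict:
    """Run the pipeline; returns the manifest (also written to the output dir).

    ``expr``/``samples`` may be passed in-memory (e.g. a synthetic cohort);
    otherwise they are read from the configured input files.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": config.hash(), "stages": [], "artifacts": {}}
    config.to_yaml(out / "config.yaml")
    manifest["artifacts"]["config"] = str(out / "config.yaml")

    try:
        t0 = time.time()
        if expr is None:
            if not config.expression_gct:
                raise ConfigError("no expression input: set expression_gct or pass expr")
            expr = cio.read_gct(config.expression_gct)
        if samples is None:
            if not config.sample_attributes or not config.subject_phenotypes:
                raise ConfigError("no sample metadata: set sample_attributes/subject_phenotypes")
            samples = cio.read_sample_attributes(
                config.sample_attributes, config.subject_phenotypes, expr.sample_ids
            )
        samples = samples.loc[expr.sample_ids]
        _stage(manifest, "load", t0, n_genes=expr.n_genes, n_samples=expr.n_samples)

        t0 = time.time()
        thresholds = FilterThresholds(
            config.tpm_min, config.frac_samples, config.rescue_mean_tpm,
            config.rescue_frac, config.rescue_tpm,
        )
        report = filter_and_rescue(expr, samples["tissue"], thresholds,
                                   same_tissue=config.rescue_same_tissue)
        report.to_frame().to_csv(out / "gene_filter.tsv", sep="\t", index=False)
        manifest["artifacts"]["gene_filter"] = str(out / "gene_filter.tsv")
        expr = expr.subset_genes(report.retained)
        _stage(manifest, "gene_filter", t0, **report.counts())

        t0 = time.time()
        norm = log_quantile_normalize(expr)
        _stage(manifest, "normalize", t0)

        t0 = time.time()
        corrected = combat_serial(norm, samples)
        _stage(manifest, "batch_correction", t0)

        t0 = time.time()
        assignment, pcs, embedding = purify_tissue_clusters(
            corrected.values,
            samples["tissue"],
            n_perm=config.n_permutations,
            k_values=range(config.k_min, config.k_max + 1),
            p_min=config.p_min,
            mix_threshold=config.mix_threshold,
            perplexity=config.perplexity,
            learning_rate=config.learning_rate,
            tsne_max_iter=config.tsne_max_iter,
            manual_exclusions=config.manual_exclusions,
            seed=config.seed,
            max_pcs=config.max_pcs,
        )
        assignment.table.to_csv(out / "cluster_assignment.tsv", sep="\t", index=False)
        manifest["artifacts"]["cluster_assignment"] = str(out / "cluster_assignment.tsv")
        _stage(manifest, "purify_clusters", t0, n_clusters=assignment.n_clusters(),
               n_pcs=pcs.n_retained, **assignment.counts())

        t0 = time.time()
        cluster_of = assignment.cluster_of_kept()
        kept_expr = corrected.subset_samples(list(cluster_of.index))
        matrices = {}
        for modality in config.modalities:
            model = CoexpressionModel(
                kept_expr, cluster_of, metrics=config.metrics, modality=modality,
                n_per=config.n_per_cluster, n_reps=config.n_reps,
                strict=config.strict_subsampling, signed_min=config.signed_min,
            )
            res = model.fit(seed=config.seed)
            matrices[modality] = res
            for metric in config.metrics:
                prefix = out / f"min_{metric}_{modality}"
                cio.save_result_matrix(
                    res.min_matrix(metric), prefix,
                    {"metric": metric, "modality": modality, "aggregation": "MIN",
                     "n_per": config.n_per_cluster, "n_reps": config.n_reps,
                     "seed": config.seed, "config_hash": config.hash()},
                )
                manifest["artifacts"][f"min_{metric}_{modality}"] = str(prefix)
        _stage(manifest, "estimate", t0)

        n_strata = 0
        if config.compute_strata:
            t0 = time.time()
            strata, strat_results = stratify_covariates(
                kept_expr, samples, cluster_of, n_per=config.n_per_cluster, seed=config.seed
            )
            for (name, modality), mat in strat_results.items():
                prefix = out / f"stratum_{name}_{modality}"
                cio.save_result_matrix(mat, prefix, {"stratum": name, "modality": modality,
                                                     "metric": "pearson"})
                manifest["artifacts"][f"stratum_{name}_{modality}"] = str(prefix)
            n_strata = len(strata)
            _stage(manifest, "covariate_strata", t0, n_strata=n_strata)

        manifest["inventory"] = matrix_inventory(
            n_modalities=len(config.modalities), n_reps=config.n_reps,
            n_metrics=len(config.metrics), n_strata=n_strata,
        )
    except Exception as exc:
        manifest["failed_stage"] = manifest["stages"][-1]["stage"] if manifest["stages"] else "load"
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
        raise CogtexError(f"pipeline failed after stage {manifest['failed_stage']!r}: {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    manifest["results"] = matrices
    return manifest
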