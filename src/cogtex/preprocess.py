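"""Gene filtering, normalization, and batch correction.

The preprocessing chain for a TPM matrix is:

1. drop genes not reaching 0.1 TPM in at least 20% of samples, then *rescue*
   genes that failed only because they are tissue-specific (some tissue with
   mean > 5 TPM and > 66% of its samples at >= 1 TPM);
2. log10(TPM + 1);
3. quantile normalization across samples;
4. ComBat run serially for the extraction batch and then the sequencing batch,
   preserving tissue, sex, and age.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._errors import CogtexError
from .combat import combat
from .io import ExpressionMatrix, Scale

__all__ = [
    "FilterThresholds",
    "GeneFilterReport",
    "filter_low_expressed",
    "rescue_tissue_specific",
    "filter_and_rescue",
    "log_quantile_normalize",
    "quantile_normalize",
    "assign_placeholder_batches",
    "combat_serial",
]

PLACEHOLDER = "PLACEHOLDER_BATCH"


@dataclass
class FilterThresholds:
    tpm_min: float = 0.1
    frac_samples: float = 0.20
    rescue_mean_tpm: float = 5.0
    rescue_frac: float = 0.66
    rescue_tpm: float = 1.0


@dataclass
class GeneFilterReport:
    """Per-gene PASS / FAIL / RESCUED status plus the thresholds used."""

    status: pd.Series  # index: gene_id, values in {PASS, FAIL, RESCUED}
    thresholds: FilterThresholds
    required_count: int  # samples a gene must reach tpm_min in to PASS

    @property
    def retained(self) -> list[str]:
        return list(self.status.index[self.status.isin(["PASS", "RESCUED"])])

    def counts(self) -> dict[str, int]:
        c = self.status.value_counts().to_dict()
        return {k: int(c.get(k, 0)) for k in ("PASS", "FAIL", "RESCUED")}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene_id": self.status.index, "status": self.status.to_numpy()})


def required_sample_count(n_samples: int, frac: float = 0.20) -> int:
    """'At least 20% of samples', rounded up (16,651 samples -> 3,331)."""
    return math.ceil(frac * n_samples)


def filter_low_expressed(expr: ExpressionMatrix, thresholds: FilterThresholds | None = None) -> GeneFilterReport:
    """PASS a gene iff it reaches ``tpm_min`` in at least ``frac_samples`` of samples."""
    if expr.scale != Scale.TPM:
        raise CogtexError(f"low-expression filter expects TPM scale, got {expr.scale}")
    if expr.n_genes == 0 or expr.n_samples == 0:
        raise CogtexError("empty expression matrix")
    th = thresholds or FilterThresholds()
    required = required_sample_count(expr.n_samples, th.frac_samples)
    n_expressed = (expr.values.to_numpy() >= th.tpm_min).sum(axis=1)
    status = pd.Series(
        np.where(n_expressed >= required, "PASS", "FAIL"), index=expr.values.index
    )
    return GeneFilterReport(status=status, thresholds=th, required_count=required)


def rescue_tissue_specific(
    expr: ExpressionMatrix,
    tissues: pd.Series,
    failed_genes,
    thresholds: FilterThresholds | None = None,
    same_tissue: bool = False,
) -> set[str]:
    """Rescue FAILed genes that are clearly expressed in at least one tissue.

    A gene is rescued when its maximum per-tissue mean TPM exceeds
    ``rescue_mean_tpm`` and its maximum per-tissue fraction of samples at
    >= ``rescue_tpm`` exceeds ``rescue_frac``. By default the two maxima may
    come from different tissues; ``same_tissue=True`` requires one tissue to
    satisfy both.
    """
    th = thresholds or FilterThresholds()
    tissues = tissues.loc[expr.values.columns]
    failed = list(failed_genes)
    unknown = set(failed) - set(expr.values.index)
    if unknown:
        raise CogtexError(f"unknown gene id(s): {sorted(unknown)[:5]}")
    sub = expr.values.loc[failed]
    mean_by_tissue = sub.T.groupby(tissues).mean().T  # genes x tissues
    frac_by_tissue = (sub >= th.rescue_tpm).T.groupby(tissues).mean().T
    if same_tissue:
        ok = ((mean_by_tissue > th.rescue_mean_tpm) & (frac_by_tissue > th.rescue_frac)).any(axis=1)
    else:
        ok = (mean_by_tissue.max(axis=1) > th.rescue_mean_tpm) & (
            frac_by_tissue.max(axis=1) > th.rescue_frac
        )
    return set(ok.index[ok])


def filter_and_rescue(
    expr: ExpressionMatrix,
    tissues: pd.Series,
    thresholds: FilterThresholds | None = None,
    same_tissue: bool = False,
) -> GeneFilterReport:
    """Run the low-expression filter then the tissue-specific rescue; idempotent."""
    report = filter_low_expressed(expr, thresholds)
    failed = report.status.index[report.status == "FAIL"]
    rescued = rescue_tissue_specific(expr, tissues, failed, report.thresholds, same_tissue)
    report.status.loc[list(rescued)] = "RESCUED"
    return report


def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize columns: each sample's sorted values are replaced by
    the mean of the sorted values across samples; tied values receive the mean
    of the reference values their positions span."""
    arr = values.to_numpy(float)
    n, k = arr.shape
    if k == 1:
        return values.copy()
    order = np.argsort(arr, axis=0, kind="stable")
    ref = np.take_along_axis(arr, order, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(k):
        col_sorted = arr[order[:, j], j]
        # average the reference over runs of ties
        _, inv, counts = np.unique(col_sorted, return_inverse=True, return_counts=True)
        sums = np.bincount(inv, weights=ref)
        out[order[:, j], j] = (sums / counts)[inv]
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def log_quantile_normalize(expr: ExpressionMatrix) -> ExpressionMatrix:
    """log10(TPM + 1) followed by quantile normalization across samples."""
    if expr.scale != Scale.TPM:
        raise CogtexError(f"expected TPM scale, got {expr.scale}")
    if (expr.values.to_numpy() < 0).any():
        raise CogtexError("negative TPM values")
    logged = np.log10(expr.values + 1.0)
    return ExpressionMatrix(quantile_normalize(logged), Scale.LOG10P1)


def assign_placeholder_batches(batch: pd.Series) -> pd.Series:
    """Pool samples with a missing batch, or in a batch of size < 2, into one
    shared placeholder level."""
    batch = batch.copy().astype(object)
    batch[batch.isna()] = PLACEHOLDER
    counts = batch.value_counts()
    singletons = counts.index[counts < 2]
    batch[batch.isin(singletons)] = PLACEHOLDER
    # the placeholder itself may hold a single sample; ComBat requires >= 2
    if (batch == PLACEHOLDER).sum() == 1:
        batch[batch == PLACEHOLDER] = batch.value_counts().idxmax()
    return batch


def combat_serial(
    expr: ExpressionMatrix,
    sample_table: pd.DataFrame,
    batch_variables: tuple[str, ...] = ("extraction_batch", "sequencing_batch"),
    preserve: tuple[str, ...] = ("tissue", "sex", "age"),
) -> ExpressionMatrix:
    """Run ComBat once per batch variable, in order, preserving the covariates."""
    if expr.scale != Scale.LOG10P1:
        raise CogtexError(f"batch correction expects LOG10P1 scale, got {expr.scale}")
    table = sample_table.loc[expr.values.columns]
    covariates = table[list(preserve)] if preserve else None
    values = expr.values
    for var in batch_variables:
        batch = assign_placeholder_batches(table[var])
        if batch.nunique() < 2:
            continue
        values = combat(values, batch, covariates)
    return ExpressionMatrix(values, Scale.LOG10P1)
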