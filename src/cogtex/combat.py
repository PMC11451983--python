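"""Parametric empirical-Bayes batch correction (ComBat).

Location/scale adjustment of a genes x samples matrix for one categorical
batch variable while preserving the effects of biological covariates. Per-gene
batch means and variances are shrunk toward common priors (normal for the
location, inverse-gamma for the scale) whose hyperparameters are estimated by
the method of moments, then solved by fixed-point iteration.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._errors import CogtexError

__all__ = ["combat"]


def _design_matrix(batch: pd.Series, covariates: pd.DataFrame | None) -> tuple[np.ndarray, np.ndarray, list]:
    levels = list(pd.unique(batch))
    batch_onehot = np.column_stack([(batch == lv).to_numpy(float) for lv in levels])
    if covariates is not None and covariates.shape[1] > 0:
        cov = pd.get_dummies(covariates, drop_first=True, dtype=float)
        design = np.column_stack([batch_onehot, cov.to_numpy(float)])
    else:
        design = batch_onehot
    return design, batch_onehot, levels


def combat(
    values: pd.DataFrame,
    batch: pd.Series,
    covariates: pd.DataFrame | None = None,
    conv: float = 1e-4,
    max_iter: int = 5000,
) -> pd.DataFrame:
    """Adjust ``values`` (genes x samples) for ``batch``, preserving ``covariates``.

    Returns a DataFrame of the same shape. A single batch level is a no-op.
    Raises :class:`CogtexError` if the batch indicators are collinear with the
    covariate columns (perfect confounding).
    """
    batch = batch.loc[values.columns]
    if covariates is not None:
        covariates = covariates.loc[values.columns]
    design, batch_onehot, levels = _design_matrix(batch, covariates)
    n_batch = len(levels)
    if n_batch == 1:
        return values.copy()
    for lv, cnt in batch.value_counts().items():
        if cnt < 2:
            raise CogtexError(f"batch level {lv!r} has fewer than 2 samples; pool it first")
    if covariates is not None:
        for col in covariates.columns:
            if _partitions_equal(batch, covariates[col]):
                raise CogtexError(
                    f"batch variable is perfectly confounded with covariate {col!r}"
                )
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise CogtexError("design matrix is rank-deficient: batch confounded with covariates")

    Y = values.to_numpy(float)  # G x N
    G, N = Y.shape
    n_per = batch_onehot.sum(axis=0)

    B_hat, *_ = np.linalg.lstsq(design, Y.T, rcond=None)  # p x G
    grand_mean = (n_per / N) @ B_hat[:n_batch]  # G
    var_pooled = ((Y - (design @ B_hat).T) ** 2).mean(axis=1)  # G
    var_pooled = np.where(var_pooled <= 0, 1e-12, var_pooled)

    stand_mean = grand_mean[:, None] * np.ones((1, N))
    if design.shape[1] > n_batch:
        stand_mean = stand_mean + (design[:, n_batch:] @ B_hat[n_batch:]).T
    sd = np.sqrt(var_pooled)[:, None]
    Z = (Y - stand_mean) / sd

    adjusted = Z.copy()
    for b in range(n_batch):
        mask = batch_onehot[:, b].astype(bool)
        n_b = int(n_per[b])
        Zb = Z[:, mask]
        gamma_hat = Zb.mean(axis=1)
        delta_hat = Zb.var(axis=1, ddof=1)
        gamma_bar = gamma_hat.mean()
        t2 = gamma_hat.var(ddof=1)
        # inverse-gamma prior on the scale, moments matched to delta_hat
        m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
        a_prior = (2 * s2 + m**2) / s2 if s2 > 0 else np.inf
        b_prior = (m * s2 + m**3) / s2 if s2 > 0 else 0.0
        gamma_star, delta_star = _it_solve(
            Zb, gamma_hat, delta_hat, gamma_bar, t2, a_prior, b_prior, conv, max_iter
        )
        adjusted[:, mask] = (Zb - gamma_star[:, None]) / np.sqrt(delta_star)[:, None]

    out = adjusted * sd + stand_mean
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def _it_solve(Zb, g_hat, d_hat, g_bar, t2, a, b, conv, max_iter):
    n = Zb.shape[1]
    g_old, d_old = g_hat.copy(), d_hat.copy()
    if not np.isfinite(t2) or t2 <= 0 or not np.isfinite(a):
        # degenerate prior (e.g. a single gene): no shrinkage
        return g_hat, np.where(d_hat <= 0, 1e-12, d_hat)
    for _ in range(max_iter):
        g_new = (n * t2 * g_hat + d_old * g_bar) / (n * t2 + d_old)
        sum2 = ((Zb - g_new[:, None]) ** 2).sum(axis=1)
        d_new = (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)
        change = max(
            np.max(np.abs(g_new - g_old) / np.maximum(np.abs(g_old), 1e-12)),
            np.max(np.abs(d_new - d_old) / np.maximum(np.abs(d_old), 1e-12)),
        )
        g_old, d_old = g_new, d_new
        if change < conv:
            break
    return g_old, np.where(d_old <= 0, 1e-12, d_old)


def _partitions_equal(a: pd.Series, b: pd.Series) -> bool:
    """True when two label vectors induce the same partition of the samples."""
    if b.dtype.kind in "fc" and b.nunique() > max(20, a.nunique()):
        return False  # continuous covariate: never treated as a partition
    mapping_ab: dict = {}
    mapping_ba: dict = {}
    for x, y in zip(a, b):
        if mapping_ab.setdefault(x, y) != y or mapping_ba.setdefault(y, x) != x:
            return False
    return True
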