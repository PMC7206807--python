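"""Normalisation, filtering, log transform and batch correction.

The processing chain applied to a cohort before any downstream analysis:

1. drop the two mitochondrial rRNA genes (their library fraction is large
   and highly variable) and rescale every sample back to a TPM sum of 10^6;
2. drop genes whose mean TPM is below 1 in every (population x histology)
   subtype group;
3. move to ``log2(1 + TPM)``;
4. remove batch (flowcell) effects with a parametric empirical-Bayes
   location/scale adjustment, protecting biological covariates supplied in
   a design matrix.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import ExpressionCohort, LogExpression

#: mitochondrial rRNA genes excluded before per-sample renormalisation
DEFAULT_EXCLUDE = ("MT-RNR1", "MT-RNR2")

TPM_TOTAL = 1_000_000.0


def renormalize_tpm(cohort: ExpressionCohort, exclude=DEFAULT_EXCLUDE) -> ExpressionCohort:
    """Drop ``exclude`` genes and rescale each sample to sum to 10^6.

    Genes in ``exclude`` that are absent from the matrix are ignored.  The
    within-sample ranking of the remaining genes is unchanged.  Raises if a
    sample has zero total expression after the exclusion.
    """
    keep = ~cohort.tpm.index.isin(list(exclude))
    tpm = cohort.tpm.loc[keep]
    totals = tpm.sum(axis=0)
    dead = totals.index[totals.to_numpy() <= 0.0]
    if len(dead):
        raise ValueError(f"samples with zero expression after exclusion: {list(dead)}")
    return ExpressionCohort(tpm * (TPM_TOTAL / totals), cohort.sample_meta)


def filter_low_expression(cohort: ExpressionCohort, threshold: float = 1.0) -> ExpressionCohort:
    """Keep genes with mean TPM >= ``threshold`` in at least one subtype group.

    Groups are the observed (population x histology) combinations; means are
    computed in TPM space.  ``threshold = 0`` keeps every gene.
    """
    meta = cohort.sample_meta
    groups = meta.groupby(["population", "histology"], observed=True).groups
    if not groups:
        raise ValueError("cohort has no (population, histology) groups")
    keep = np.zeros(len(cohort.genes), dtype=bool)
    for _, samples in groups.items():
        keep |= cohort.tpm[list(samples)].mean(axis=1).to_numpy() >= threshold
    return ExpressionCohort(cohort.tpm.loc[keep], cohort.sample_meta)


def log_transform(cohort: ExpressionCohort) -> LogExpression:
    """Elementwise moderated log: ``log2(1 + TPM)``."""
    return LogExpression(np.log2(1.0 + cohort.tpm), cohort.sample_meta)


# ---------------------------------------------------------------------------
# parametric empirical-Bayes batch correction
# ---------------------------------------------------------------------------

def design_from_meta(sample_meta: pd.DataFrame, columns=("histology", "population")) -> pd.DataFrame:
    """Treatment-coded indicator design for categorical metadata columns.

    The first level of each column is absorbed into the intercept (which the
    batch indicators span), so the combined batch + covariate design stays
    full rank when batches and covariates are not confounded.
    """
    parts = [
        pd.get_dummies(sample_meta[c], prefix=c, drop_first=True, dtype=float)
        for c in columns
    ]
    if not parts:
        return pd.DataFrame(index=sample_meta.index)
    return pd.concat(parts, axis=1)


def batch_correct(
    log_expr: LogExpression,
    batch: pd.Series | None = None,
    covariate_design: pd.DataFrame | None = None,
    eps: float = 1e-12,
) -> LogExpression:
    """Remove per-batch location/scale effects, shrunk by empirical Bayes.

    Genes are standardised given the covariate design, per-batch additive
    and multiplicative effects are estimated gene-wise, shrunk toward their
    across-gene priors (normal for location, inverse-gamma for scale),
    removed, and the covariate structure restored.  Covariate effects
    encoded in ``covariate_design`` are preserved.

    Parameters
    ----------
    batch
        Batch label per sample; defaults to the ``batch`` metadata column.
    covariate_design
        Samples x covariates indicator/real matrix of biological effects to
        protect.  Columns that are constant are dropped (the intercept is
        implicit in the batch indicators).

    Raises
    ------
    ValueError
        If any batch has fewer than two samples, or batch and covariates are
        confounded (the combined design is rank deficient).
    """
    X = log_expr.values.to_numpy(dtype=float)  # genes x samples
    n_genes, n_samples = X.shape
    if batch is None:
        batch = log_expr.sample_meta["batch"]
    batch = pd.Series(batch, index=log_expr.samples).astype(str)
    levels = batch.unique().tolist()
    n_batch = len(levels)
    if n_batch == 1:
        # nothing to correct; avoid a no-op pass through the EB machinery,
        # whose variance rescaling would perturb values without a second batch
        return LogExpression(log_expr.values.copy(), log_expr.sample_meta)
    batch_onehot = np.column_stack([(batch == lv).to_numpy(float) for lv in levels])
    sizes = batch_onehot.sum(axis=0)
    small = [lv for lv, s in zip(levels, sizes) if s < 2]
    if small:
        raise ValueError(f"batches with a single sample cannot be corrected: {small}")

    if covariate_design is not None and covariate_design.shape[1] > 0:
        C = covariate_design.loc[log_expr.samples].to_numpy(dtype=float)
        # drop intercept-like (constant) columns; the batch block spans them
        varying = C.std(axis=0) > 0
        C = C[:, varying]
        cov_names = list(np.asarray(covariate_design.columns)[varying])
    else:
        C = np.empty((n_samples, 0))
        cov_names = []

    design = np.hstack([batch_onehot, C])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise ValueError(
            "batch and covariates are confounded: combined design of "
            f"{n_batch} batches + covariates {cov_names} is rank deficient "
            f"(rank {rank} < {design.shape[1]})"
        )

    # gene-wise least squares fit of the full design
    beta, *_ = np.linalg.lstsq(design, X.T, rcond=None)  # (n_batch + p) x genes
    grand_mean = (sizes / n_samples) @ beta[:n_batch]  # genes
    stand_mean = np.tile(grand_mean, (n_samples, 1))  # samples x genes
    if C.shape[1]:
        stand_mean = stand_mean + C @ beta[n_batch:]
    resid = X.T - design @ beta
    var_pooled = (resid ** 2).mean(axis=0)  # genes
    scale = np.sqrt(np.maximum(var_pooled, eps))
    Z = (X.T - stand_mean) / scale  # samples x genes

    corrected = Z.copy()
    gamma_hat = np.vstack([Z[batch_onehot[:, i] == 1].mean(axis=0) for i in range(n_batch)])
    delta_hat = np.vstack([Z[batch_onehot[:, i] == 1].var(axis=0, ddof=1) for i in range(n_batch)])
    delta_hat = np.maximum(delta_hat, eps)

    for i in range(n_batch):
        idx = batch_onehot[:, i] == 1
        n_i = int(sizes[i])
        g_hat, d_hat = gamma_hat[i], delta_hat[i]
        gamma_bar, tau2 = g_hat.mean(), g_hat.var(ddof=1)
        m, v = d_hat.mean(), d_hat.var(ddof=1)
        v = max(v, eps)
        a_prior = (2.0 * v + m ** 2) / v
        b_prior = (m * v + m ** 3) / v
        g_star, d_star = g_hat.copy(), d_hat.copy()
        Zi = Z[idx]
        for _ in range(200):
            g_new = (tau2 * n_i * g_hat + d_star * gamma_bar) / (tau2 * n_i + d_star)
            sum2 = ((Zi - g_new) ** 2).sum(axis=0)
            d_new = (0.5 * sum2 + b_prior) / (n_i / 2.0 + a_prior - 1.0)
            change = max(np.abs(g_new - g_star).max(), np.abs(d_new - d_star).max())
            g_star, d_star = g_new, d_new
            if change < 1e-8:
                break
        corrected[idx] = (Zi - g_star) / np.sqrt(np.maximum(d_star, eps))

    out = corrected * scale + stand_mean
    values = pd.DataFrame(out.T, index=log_expr.genes, columns=log_expr.samples)
    return LogExpression(values, log_expr.sample_meta)
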