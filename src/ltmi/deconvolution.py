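"""Signature matrices, bulk deconvolution and reconstruction.

The signature matrix holds mean TPM reference profiles of marker genes per
sorted cell type; bulk mixing fractions are inferred per sample by
nonnegative least squares over the marker genes, with the coefficient
vector renormalised to sum to one.  This NNLS fit is a transparent
surrogate for the nu-SVR used by CIBERSORT: it shares the linear mixture
model and marker-gene restriction but not the SVR loss, so absolute
agreement with CIBERSORT outputs is not expected.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .cohort import ExpressionCohort, LogExpression, SORTED_POPULATIONS, BULK
from .interactome import differential_expression
from .preprocess import TPM_TOTAL

logger = logging.getLogger(__name__)

DEFAULT_MARKER_GRID = (10, 15, 20, 25, 30, 40, 50)


@dataclass
class SignatureMatrix:
    """Marker-genes x cell-types reference profiles in TPM units."""

    values: pd.DataFrame
    markers_per_type: int
    condition_number: float

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene ids in signature matrix")
        if (self.values.to_numpy().sum(axis=0) == 0).any():
            raise ValueError("signature matrix has an all-zero cell-type column")
        if not np.isfinite(self.condition_number):
            raise ValueError("signature matrix condition number is not finite")

    @property
    def cell_types(self) -> list[str]:
        return list(self.values.columns)

    def write_tsv(self, path: str) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene")

    @classmethod
    def read_tsv(cls, path: str) -> "SignatureMatrix":
        values = pd.read_csv(path, sep="\t", index_col=0)
        return cls(values, markers_per_type=0, condition_number=float(np.linalg.cond(values.to_numpy())))


@dataclass
class FractionTable:
    """Inferred cell-type fractions per bulk sample plus fit diagnostics.

    ``fractions`` rows sum to one; ``diagnostics`` carries the NNLS residual
    norm and the Pearson correlation between the fitted and observed marker
    profiles.
    """

    fractions: pd.DataFrame  # samples x cell types
    diagnostics: pd.DataFrame  # samples x (residual_norm, fit_correlation)

    def __post_init__(self) -> None:
        f = self.fractions.to_numpy()
        if (f < -1e-12).any():
            raise ValueError("negative fraction")
        if np.abs(f.sum(axis=1) - 1.0).max() > 1e-9:
            raise ValueError("fractions do not sum to one")

    def write_tsv(self, path: str) -> None:
        self.fractions.join(self.diagnostics).to_csv(path, sep="\t", index_label="sample")


def build_signature_matrix(
    log_expr: LogExpression,
    populations=SORTED_POPULATIONS,
    markers_per_type_grid=DEFAULT_MARKER_GRID,
    fdr: float = 0.01,
) -> SignatureMatrix:
    """Select markers per cell type and pick the best-conditioned matrix.

    Candidate markers per population are genes passing one-vs-rest
    moderated-t FDR < ``fdr`` with positive fold-change, ordered by
    fold-change.  For each count ``g`` in the grid the matrix of mean TPM
    per type over the top ``g`` markers of every type is assembled; the
    matrix with the smallest condition number wins (ties go to the smaller
    marker count).  Differential expression runs on the log scale; the
    signature itself is in TPM space.
    """
    sample_sets = {}
    for pop in populations:
        cols = log_expr.samples_of(pop)
        if len(cols) < 2:
            raise ValueError(f"population {pop!r} has fewer than two samples")
        sample_sets[pop] = cols

    tpm = np.exp2(log_expr.values) - 1.0
    mean_tpm = pd.DataFrame({pop: tpm[cols].mean(axis=1) for pop, cols in sample_sets.items()})

    candidates = {}
    for pop in populations:
        rest = [c for p in populations if p != pop for c in sample_sets[p]]
        de = differential_expression(log_expr, sample_sets[pop], rest)
        hits = de[(de["fdr"] < fdr) & (de["log2_fc"] > 0)].sort_values(
            "log2_fc", ascending=False, kind="stable"
        )
        if hits.empty:
            raise ValueError(f"no gene passes FDR < {fdr} for population {pop!r}")
        candidates[pop] = hits.index

    best = None
    for g in sorted(set(int(v) for v in markers_per_type_grid)):
        genes: list[str] = []
        for pop in populations:
            for gene in candidates[pop][:g]:
                if gene not in genes:
                    genes.append(gene)
        mat = mean_tpm.loc[genes]
        cond = float(np.linalg.cond(mat.to_numpy()))
        if best is None or cond < best[0]:
            best = (cond, g, mat)
    cond, g, mat = best
    return SignatureMatrix(mat, markers_per_type=g, condition_number=cond)


def deconvolve(
    bulk: ExpressionCohort,
    signature: SignatureMatrix,
    gene_weights: str | None = "signature_mean",
) -> FractionTable:
    """Infer mixing fractions per sample by NNLS against the signature.

    At least half of the signature genes must be present in the bulk matrix.
    Coefficients are renormalised to sum to one; residual norm and fit
    correlation are reported per sample.

    With ``gene_weights="signature_mean"`` (default) each gene row of the
    system is divided by the gene's mean signature TPM before the fit, so
    the least squares operates on relative rather than absolute errors;
    TPM-scale measurement noise is roughly multiplicative, and without the
    scaling a handful of high-abundance genes dominate the fit.  Pass
    ``None`` for plain unweighted NNLS.  Exact mixtures are recovered
    identically either way.
    """
    genes = signature.values.index.intersection(bulk.genes)
    if len(genes) < 0.5 * len(signature.values):
        raise ValueError(
            f"only {len(genes)}/{len(signature.values)} signature genes present in bulk matrix"
        )
    S = signature.values.loc[genes].to_numpy(float)
    B = bulk.tpm.loc[genes].to_numpy(float)
    if gene_weights == "signature_mean":
        w = 1.0 / np.maximum(S.mean(axis=1), 1e-12)
    elif gene_weights is None:
        w = np.ones(len(genes))
    else:
        raise ValueError(f"unknown gene_weights {gene_weights!r}")
    Sw = S * w[:, None]
    fracs, diags = [], []
    for j, sample in enumerate(bulk.samples):
        b = B[:, j]
        coef, rnorm = nnls(Sw, b * w)
        total = coef.sum()
        if total <= 0:
            raise ValueError(f"all-zero deconvolution solution for sample {sample!r}")
        fit = S @ coef
        r = np.corrcoef(fit, b)[0, 1] if b.std() > 0 and fit.std() > 0 else np.nan
        fracs.append(coef / total)
        diags.append((rnorm, r))
    fractions = pd.DataFrame(fracs, index=bulk.samples, columns=signature.cell_types)
    diagnostics = pd.DataFrame(diags, index=bulk.samples, columns=["residual_norm", "fit_correlation"])
    return FractionTable(fractions, diagnostics)


def reconstruct_bulk(
    sorted_cohort: ExpressionCohort,
    fractions: FractionTable,
    populations=SORTED_POPULATIONS,
    patients: pd.Series | None = None,
) -> ExpressionCohort:
    """Rebuild bulk profiles as fraction-weighted sums of sorted profiles.

    ``fractions`` is indexed by bulk sample id; each bulk sample's patient
    must have every required sorted population profiled (replicates are
    averaged in TPM space), otherwise the patient is skipped with a warning.
    Reconstructions are renormalised to a TPM sum of 10^6.

    ``patients`` optionally maps bulk sample ids to patient ids; without it,
    a ``<patient>_bulk`` naming convention or a literal patient id is
    assumed.
    """
    meta = sorted_cohort.sample_meta

    def patient_of(sample: str) -> str:
        if patients is not None and sample in patients.index:
            return str(patients.loc[sample])
        suffix = f"_{BULK}"
        if sample.endswith(suffix):
            return sample[: -len(suffix)]
        return sample

    recon, kept = {}, []
    for sample in fractions.fractions.index:
        patient = patient_of(sample)
        profiles = {}
        for pop in populations:
            cols = sorted_cohort.samples[
                ((meta["patient"] == patient) & (meta["population"] == pop)).to_numpy()
            ]
            if len(cols) == 0:
                break
            profiles[pop] = sorted_cohort.tpm[cols].mean(axis=1)
        if len(profiles) < len(populations):
            logger.warning("patient %s lacks sorted profiles; skipping reconstruction", patient)
            continue
        w = fractions.fractions.loc[sample]
        vec = sum(w[pop] * profiles[pop] for pop in populations)
        total = vec.sum()
        recon[sample] = vec * (TPM_TOTAL / total) if total > 0 else vec
        kept.append(sample)
    if not recon:
        raise ValueError("no sample could be reconstructed")
    tpm = pd.DataFrame(recon)[kept]
    sm = pd.DataFrame(
        {
            "patient": [patient_of(s) for s in kept],
            "population": BULK,
            "histology": [
                meta.loc[meta["patient"] == patient_of(s), "histology"].iloc[0]
                for s in kept
            ],
            "batch": "reconstructed",
            "replicate": False,
        },
        index=pd.Index(kept),
    )
    return ExpressionCohort(tpm, sm)


def rank_bulk_minus_reconstructed(
    bulk: ExpressionCohort, reconstructed: ExpressionCohort
) -> pd.DataFrame:
    """Rank genes by mean log2(1+TPM) difference, bulk minus reconstructed.

    Positive scores mean higher in bulk (e.g. populations missed by the
    sorting scheme).  Both cohorts must share the same gene set.
    """
    if not bulk.genes.equals(reconstructed.genes):
        raise ValueError("gene sets differ between bulk and reconstructed cohorts")
    diff = np.log2(1.0 + bulk.tpm).mean(axis=1) - np.log2(1.0 + reconstructed.tpm).mean(axis=1)
    out = pd.DataFrame({"score": diff}).sort_values("score", ascending=False, kind="stable")
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def compare_fraction_tables(
    fractions_bulk: FractionTable, fractions_sorted: FractionTable
) -> pd.Series:
    """Mean percentage-point difference per type, sorted minus bulk.

    Both tables must cover the same samples.  Because every row of each
    table sums to one, the differences sum to ~0 across types.
    """
    fb, fs = fractions_bulk.fractions, fractions_sorted.fractions
    if set(fb.index) != set(fs.index):
        raise ValueError("fraction tables cover different samples")
    fs = fs.loc[fb.index]
    if list(fb.columns) != list(fs.columns):
        raise ValueError("fraction tables have different cell types")
    return (fs - fb).mean(axis=0) * 100.0
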