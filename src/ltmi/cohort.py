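"""Core containers for sorted-population expression cohorts.

An :class:`ExpressionCohort` holds a genes x samples TPM matrix together with
per-sample metadata (patient, sorted population or bulk, histology, batch,
replicate flag).  A :class:`LogExpression` holds the same layout on the
moderated log scale, ``log2(1 + TPM)``, which is the scale used for
clustering, differential expression, batch correction and correlation.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: the four sorted populations profiled in a cohort
SORTED_POPULATIONS = ("malignant", "endothelial", "immune", "fibroblast")
#: label used for unsorted bulk samples
BULK = "bulk"
#: valid values of the ``population`` metadata column
POPULATIONS = SORTED_POPULATIONS + (BULK,)
#: valid values of the ``histology`` metadata column
HISTOLOGIES = ("adenocarcinoma", "SCC", "other")

META_COLUMNS = ("patient", "population", "histology", "batch", "replicate")


def _validate_meta(index: pd.Index, sample_meta: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in META_COLUMNS if c not in sample_meta.columns]
    if missing:
        raise ValueError(f"sample_meta is missing required columns: {missing}")
    if not index.equals(sample_meta.index):
        if set(index) != set(sample_meta.index):
            raise ValueError("sample_meta index does not match matrix columns")
        sample_meta = sample_meta.loc[index]
    bad_pop = set(sample_meta["population"]) - set(POPULATIONS)
    if bad_pop:
        raise ValueError(f"unknown populations in metadata: {sorted(bad_pop)}")
    if sample_meta[list(META_COLUMNS)].isna().any().any():
        raise ValueError("sample_meta contains missing values")
    return sample_meta


@dataclass
class ExpressionCohort:
    """Genes x samples TPM matrix plus per-sample metadata.

    Parameters
    ----------
    tpm
        Nonnegative TPM values; rows are gene symbols (unique), columns are
        sample ids.
    sample_meta
        One row per sample (indexed by sample id) with columns
        ``patient``, ``population``, ``histology``, ``batch``, ``replicate``.
    """

    tpm: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.tpm.index.has_duplicates:
            dups = self.tpm.index[self.tpm.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        values = self.tpm.to_numpy()
        if not np.isfinite(values).all():
            raise ValueError("TPM matrix contains non-finite values")
        if (values < 0).any():
            raise ValueError("TPM matrix contains negative values")
        self.sample_meta = _validate_meta(self.tpm.columns, self.sample_meta)

    # -- accessors ---------------------------------------------------------
    @property
    def genes(self) -> pd.Index:
        return self.tpm.index

    @property
    def samples(self) -> pd.Index:
        return self.tpm.columns

    def subset_samples(self, samples) -> "ExpressionCohort":
        samples = pd.Index(samples)
        return ExpressionCohort(self.tpm[samples], self.sample_meta.loc[samples])

    def samples_of(self, population: str | None = None, histology: str | None = None) -> pd.Index:
        """Sample ids matching a population and/or histology."""
        keep = pd.Series(True, index=self.samples)
        if population is not None:
            keep &= self.sample_meta["population"] == population
        if histology is not None:
            keep &= self.sample_meta["histology"] == histology
        return self.samples[keep.to_numpy()]

    # -- IO ----------------------------------------------------------------
    def write_tsv(self, outdir: str | os.PathLike, prefix: str = "cohort") -> None:
        """Write ``<prefix>_tpm.tsv`` (genes x samples) and ``<prefix>_meta.tsv``."""
        os.makedirs(outdir, exist_ok=True)
        self.tpm.to_csv(os.path.join(outdir, f"{prefix}_tpm.tsv"), sep="\t", index_label="gene")
        self.sample_meta.to_csv(os.path.join(outdir, f"{prefix}_meta.tsv"), sep="\t", index_label="sample")

    @classmethod
    def read_tsv(cls, tpm_path: str, meta_path: str) -> "ExpressionCohort":
        tpm = pd.read_csv(tpm_path, sep="\t", index_col=0)
        meta = pd.read_csv(meta_path, sep="\t", index_col=0)
        if "replicate" in meta.columns:
            meta["replicate"] = meta["replicate"].astype(bool)
        return cls(tpm, meta)


@dataclass
class LogExpression:
    """Genes x samples matrix of ``log2(1 + TPM)`` values with metadata."""

    values: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.sample_meta = _validate_meta(self.values.columns, self.sample_meta)

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def subset_samples(self, samples) -> "LogExpression":
        samples = pd.Index(samples)
        return LogExpression(self.values[samples], self.sample_meta.loc[samples])

    def samples_of(self, population: str | None = None, histology: str | None = None) -> pd.Index:
        keep = pd.Series(True, index=self.samples)
        if population is not None:
            keep &= self.sample_meta["population"] == population
        if histology is not None:
            keep &= self.sample_meta["histology"] == histology
        return self.samples[keep.to_numpy()]

    def to_tpm(self) -> ExpressionCohort:
        """Invert the moderated log transform back to TPM units."""
        tpm = np.exp2(self.values) - 1.0
        return ExpressionCohort(tpm.clip(lower=0.0), self.sample_meta)

    def patient_means(self, population: str, histology: str | None = None) -> pd.DataFrame:
        """Per-patient mean log expression within one population.

        Replicate samples of a patient are averaged on the log scale; the
        result is a genes x patients frame.
        """
        cols = self.samples_of(population, histology)
        if len(cols) == 0:
            return pd.DataFrame(index=self.genes)
        sub = self.values[cols]
        patients = self.sample_meta.loc[cols, "patient"]
        return sub.T.groupby(patients.to_numpy()).mean().T
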