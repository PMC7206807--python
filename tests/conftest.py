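"""Shared fixtures: small hand-built cohorts and generated datasets."""

import numpy as np
import pandas as pd
import pytest

import ltmi


@pytest.fixture(scope="session")
def toy_cohort():
    """Four genes x eight samples, two populations x two patients x replicates.

    Values are exact round numbers so group means can be checked by hand.
    """
    genes = ["GA", "GB", "GC", "MT-RNR1"]
    samples = [f"S{i}" for i in range(8)]
    tpm = pd.DataFrame(
        [
            [100.0, 200.0, 100.0, 200.0, 50.0, 50.0, 400.0, 400.0],
            [300.0, 200.0, 300.0, 200.0, 150.0, 150.0, 100.0, 100.0],
            [ 40.0,  40.0,  40.0,  40.0,  20.0,  20.0,  10.0,  10.0],
            [ 60.0,  60.0,  60.0,  60.0,  80.0,  80.0,  90.0,  90.0],
        ],
        index=pd.Index(genes, name="gene"),
        columns=samples,
    )
    meta = pd.DataFrame(
        {
            "patient": ["P0", "P0", "P1", "P1", "P0", "P0", "P1", "P1"],
            "population": ["malignant"] * 4 + ["immune"] * 4,
            "histology": ["adenocarcinoma"] * 8,
            "batch": ["B0", "B1"] * 4,
            "replicate": [False, True] * 4,
        },
        index=pd.Index(samples, name="sample"),
    )
    return ltmi.ExpressionCohort(tpm, meta)


@pytest.fixture(scope="session")
def default_cohort():
    """A standard generated cohort plus its ground truth (seed 7)."""
    spec = ltmi.default_cohort_spec(seed=7)
    return ltmi.generate_cohort(spec)


@pytest.fixture(scope="session")
def clean_cohort():
    """Noise-free, single-batch, no-coupling cohort for exact recovery."""
    spec = ltmi.default_cohort_spec(
        seed=7, noise_sd=0.0, n_batches=1, batch_offset_sd=0.0, with_coupling=False
    )
    spec.include_mt_rrna = False
    return ltmi.generate_cohort(spec)


def split_sorted_bulk(cohort):
    """Return (sorted-population subset, bulk subset) of a cohort."""
    is_bulk = (cohort.sample_meta["population"] == ltmi.BULK).to_numpy()
    return (
        cohort.subset_samples(cohort.samples[~is_bulk]),
        cohort.subset_samples(cohort.samples[is_bulk]),
    )


@pytest.fixture(scope="session")
def toy_nuclei():
    """Three tumor + four stromal nuclei with hand-computable distances.

    Tumor nuclei at (0,0), (0,10), (10,0).  Stromal distances to the
    nearest tumor nucleus: s0 (0,5) -> 5, s1 (10,5) -> 5,
    s2 (5,12) -> sqrt(29), s3 (0,30) -> 20.  Positives are s0 and s1
    (the two nearest).
    """
    return pd.DataFrame(
        {
            "row": [0, 0, 10, 0, 10, 5, 0],
            "col": [0, 10, 0, 5, 5, 12, 30],
            "cell_class": ["tumor"] * 3 + ["stroma"] * 4,
            "marker_positive": [False] * 3 + [True, True, False, False],
        }
    )
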