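"""Differential expression, uDEG calling, breadth patterns, cross-talk."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import ltmi
from conftest import split_sorted_bulk


def _log_from_array(values, populations, histology="adenocarcinoma"):
    n_genes, n = values.shape
    samples = [f"S{i}" for i in range(n)]
    df = pd.DataFrame(
        values, index=pd.Index([f"G{i:03d}" for i in range(n_genes)], name="gene"), columns=samples
    )
    meta = pd.DataFrame(
        {
            "patient": [f"P{i}" for i in range(n)],
            "population": populations,
            "histology": [histology] * n,
            "batch": ["B0"] * n,
            "replicate": [False] * n,
        },
        index=samples,
    )
    return ltmi.LogExpression(df, meta)


# -- moderated t -------------------------------------------------------------

def test_de_null_pvalues_roughly_uniform():
    rng = np.random.default_rng(0)
    vals = rng.normal(5, 1, size=(2000, 12))
    log = _log_from_array(vals, ["malignant"] * 6 + ["immune"] * 6)
    de = ltmi.differential_expression(log, log.samples[:6], log.samples[6:])
    ks = stats.kstest(de["pval"], "uniform")
    assert ks.pvalue > 1e-3
    assert (de["fdr"] < 0.01).mean() < 0.01


def test_de_detects_planted_shift():
    rng = np.random.default_rng(1)
    vals = rng.normal(5, 0.25, size=(500, 12))
    vals[:50, :6] += 2.0
    log = _log_from_array(vals, ["malignant"] * 6 + ["immune"] * 6)
    de = ltmi.differential_expression(log, log.samples[:6], log.samples[6:])
    planted = de.iloc[:50]
    rest = de.iloc[50:]
    assert (planted["fdr"] < 0.01).all()
    assert np.abs(planted["log2_fc"] - 2.0).mean() < 0.2
    assert (rest["fdr"] < 0.01).mean() < 0.01


def test_de_zero_variance_gene_is_finite():
    rng = np.random.default_rng(2)
    vals = rng.normal(5, 0.5, size=(100, 8))
    vals[0] = 5.0  # identical in both groups
    log = _log_from_array(vals, ["malignant"] * 4 + ["immune"] * 4)
    de = ltmi.differential_expression(log, log.samples[:4], log.samples[4:])
    assert np.isfinite(de["t"]).all()
    assert de.iloc[0]["pval"] > 0.5


def test_de_requires_two_per_group(toy_cohort):
    log = ltmi.log_transform(toy_cohort)
    with pytest.raises(ValueError, match="two samples"):
        ltmi.differential_expression(log, log.samples[:1], log.samples[1:])


# -- uDEG calling ------------------------------------------------------------

@pytest.fixture(scope="module")
def udeg_cohort():
    spec = ltmi.default_cohort_spec(
        n_patients=8,
        histologies=("adenocarcinoma",) * 8,
        n_batches=1,
        batch_offset_sd=0.0,
        with_coupling=False,
        seed=7,
    )
    return ltmi.generate_cohort(spec)


def test_udeg_planted_recovery(udeg_cohort):
    cohort, truth = udeg_cohort
    sorted_c, _ = split_sorted_bulk(cohort)
    log = ltmi.log_transform(ltmi.renormalize_tpm(sorted_c))
    udegs = ltmi.call_udegs(log, "adenocarcinoma")
    planted_all = set().union(*truth.true_udegs.values())
    called_all = set(udegs.table["gene"])
    tp = sum(
        len(udegs.genes(ct, "adenocarcinoma") & truth.true_udegs[ct])
        for ct in ltmi.SORTED_POPULATIONS
    )
    assert tp / len(planted_all) >= 0.9
    false_calls = called_all - planted_all
    assert len(false_calls) / max(len(called_all), 1) <= 0.01


def test_udeg_sets_disjoint(udeg_cohort):
    cohort, _ = udeg_cohort
    sorted_c, _ = split_sorted_bulk(cohort)
    log = ltmi.log_transform(ltmi.renormalize_tpm(sorted_c))
    udegs = ltmi.call_udegs(log, "adenocarcinoma")
    sets = [udegs.genes(ct, "adenocarcinoma") for ct in ltmi.SORTED_POPULATIONS]
    for i in range(len(sets)):
        for j in range(i + 1, len(sets)):
            assert not (sets[i] & sets[j])


def test_udeg_two_type_high_gene_excluded():
    """A gene elevated in two types is differential but not unique."""
    rng = np.random.default_rng(3)
    n_per = 4
    pops = [p for p in ltmi.SORTED_POPULATIONS for _ in range(n_per)]
    vals = rng.normal(5, 0.2, size=(60, len(pops)))
    pop_arr = np.array(pops)
    # gene 0: up in malignant only; gene 1: up in malignant AND immune
    vals[0, pop_arr == "malignant"] += 2.0
    vals[1, pop_arr == "malignant"] += 2.0
    vals[1, pop_arr == "immune"] += 2.0
    log = _log_from_array(vals, pops)
    udegs = ltmi.call_udegs(log, "adenocarcinoma")
    assert "G000" in udegs.genes("malignant")
    for ct in ltmi.SORTED_POPULATIONS:
        assert "G001" not in udegs.genes(ct)


def test_udeg_monotone_under_stricter_thresholds(udeg_cohort):
    cohort, _ = udeg_cohort
    sorted_c, _ = split_sorted_bulk(cohort)
    log = ltmi.log_transform(ltmi.renormalize_tpm(sorted_c))
    loose = ltmi.call_udegs(log, "adenocarcinoma", fdr=0.05, min_fold=1.5)
    strict = ltmi.call_udegs(log, "adenocarcinoma", fdr=0.01, min_fold=2.0)
    assert set(strict.table["gene"]) <= set(loose.table["gene"])


def test_udeg_needs_two_samples_per_type(toy_cohort):
    log = ltmi.log_transform(toy_cohort)
    with pytest.raises(ValueError, match="<2 samples|fewer"):
        ltmi.call_udegs(log, "adenocarcinoma")


# -- expression breadth ------------------------------------------------------

def _breadth_toy():
    """Hand-designed TPM so breadth is readable from the table."""
    genes = ["L1", "L2", "R1", "R2", "Labs"]
    pops = list(ltmi.SORTED_POPULATIONS)
    # per-population mean TPM (one sample each)
    tpm = pd.DataFrame(
        {
            "S0": [50.0, 50.0, 50.0, 5.0, 0.0],   # malignant
            "S1": [50.0, 5.0, 50.0, 5.0, 0.0],    # endothelial
            "S2": [50.0, 5.0, 50.0, 5.0, 0.0],    # immune
            "S3": [50.0, 5.0, 50.0, 50.0, 0.0],   # fibroblast
        },
        index=pd.Index(genes, name="gene"),
    )
    meta = pd.DataFrame(
        {
            "patient": ["P0"] * 4,
            "population": pops,
            "histology": ["adenocarcinoma"] * 4,
            "batch": ["B0"] * 4,
            "replicate": [False] * 4,
        },
        index=tpm.columns,
    )
    return ltmi.ExpressionCohort(tpm, meta)


def test_breadth_brute_force_oracle():
    cohort = _breadth_toy()
    catalog = ltmi.LigandReceptorCatalog.from_pairs(
        [("L1", "R1"), ("L2", "R2"), ("L1", "R2"), ("MISSING", "R1")]
    )
    bp = ltmi.expression_breadth(cohort, catalog, threshold_tpm=10.0)
    # breadths: L1 -> 4, L2 -> 1, R1 -> 4, R2 -> 1; MISSING pair skipped
    expect = np.zeros((5, 5), dtype=int)
    expect[4, 4] += 1  # (L1, R1)
    expect[1, 1] += 1  # (L2, R2)
    expect[4, 1] += 1  # (L1, R2)
    np.testing.assert_array_equal(bp.counts.to_numpy(), expect)
    # chi-squared over the 16 inner cells, against uniformity
    inner = expect[1:, 1:].ravel()
    chi2, p = stats.chisquare(inner)
    assert bp.chi2 == pytest.approx(chi2)
    assert bp.pval == pytest.approx(p)


def test_breadth_row_zero_tally():
    cohort = _breadth_toy()
    catalog = ltmi.LigandReceptorCatalog.from_pairs([("Labs", "R1")])
    bp = ltmi.expression_breadth(cohort, catalog, threshold_tpm=10.0)
    assert bp.counts.iat[0, 4] == 1
    assert bp.counts.to_numpy().sum() == 1


def test_breadth_uniform_counts_give_p_one():
    """If every inner cell holds the same count, chi2 = 0 and p = 1."""
    counts = np.ones((5, 5), dtype=int)
    chi2, p = stats.chisquare(counts[1:, 1:].ravel())
    assert chi2 == 0.0 and p == 1.0


def test_breadth_no_usable_pairs_raises():
    cohort = _breadth_toy()
    catalog = ltmi.LigandReceptorCatalog.from_pairs([("NOPE1", "NOPE2")])
    with pytest.raises(ValueError, match="no catalog pair"):
        ltmi.expression_breadth(cohort, catalog)


# -- cross-talk graph --------------------------------------------------------

def _udeg_table(sets):
    rows = [
        {"histology": "adenocarcinoma", "cell_type": ct, "gene": g, "fdr": 0.001, "log2_fc": 2.0}
        for ct, genes in sets.items()
        for g in genes
    ]
    return ltmi.UDEGTable(
        pd.DataFrame(rows, columns=["histology", "cell_type", "gene", "fdr", "log2_fc"]),
        fdr_threshold=0.01,
        min_fold=2.0,
    )


def test_crosstalk_hand_enumeration():
    udegs = _udeg_table(
        {
            "malignant": ["L1", "R2"],
            "fibroblast": ["L2", "L3"],
            "immune": ["R1"],
        }
    )
    catalog = ltmi.LigandReceptorCatalog.from_pairs(
        [("L1", "R1"), ("L2", "R2"), ("L3", "R2"), ("L1", "R9"), ("L9", "R1")]
    )
    g = ltmi.build_crosstalk_graph(udegs, catalog, "adenocarcinoma")
    # hand enumeration: L1(malig)->R1(immune); L2,L3(fibro)->R2(malig)
    assert g.counts.at["malignant", "immune"] == 1
    assert g.counts.at["fibroblast", "malignant"] == 2
    assert g.counts.to_numpy().sum() == 3
    assert g.edges[("fibroblast", "malignant")] == [("L2", "R2"), ("L3", "R2")]


def test_crosstalk_autocrine_allowed():
    udegs = _udeg_table({"malignant": ["L1", "R1"]})
    catalog = ltmi.LigandReceptorCatalog.from_pairs([("L1", "R1")])
    g = ltmi.build_crosstalk_graph(udegs, catalog, "adenocarcinoma")
    assert g.counts.at["malignant", "malignant"] == 1


def test_crosstalk_filters_restrict_edges():
    udegs = _udeg_table({"malignant": ["L1"], "immune": ["R1", "R2"]})
    catalog = ltmi.LigandReceptorCatalog.from_pairs([("L1", "R1"), ("L1", "R2")])
    g = ltmi.build_crosstalk_graph(
        udegs, catalog, "adenocarcinoma", ligand_filter=["L1"], receptor_filter=["R2"]
    )
    assert g.counts.to_numpy().sum() == 1
    assert g.edges[("malignant", "immune")] == [("L1", "R2")]


def test_crosstalk_empty_udegs_zero_graph():
    udegs = _udeg_table({})
    catalog = ltmi.LigandReceptorCatalog.from_pairs([("L1", "R1")])
    g = ltmi.build_crosstalk_graph(udegs, catalog, "adenocarcinoma")
    assert g.counts.to_numpy().sum() == 0
    assert g.edges == {}


def test_crosstalk_write(tmp_path):
    udegs = _udeg_table({"malignant": ["L1"], "immune": ["R1"]})
    catalog = ltmi.LigandReceptorCatalog.from_pairs([("L1", "R1")])
    g = ltmi.build_crosstalk_graph(udegs, catalog, "adenocarcinoma")
    g.write(str(tmp_path))
    edges = pd.read_csv(tmp_path / "crosstalk_edges.tsv", sep="\t")
    assert edges.iloc[0].tolist() == ["malignant", "immune", "L1", "R1"]
    import json

    payload = json.loads((tmp_path / "crosstalk.json").read_text())
    assert payload["counts"]["malignant"]["immune"] == 1


# -- catalogs ----------------------------------------------------------------

def test_catalog_duplicate_rejected():
    with pytest.raises(ValueError, match="duplicate"):
        ltmi.LigandReceptorCatalog.from_pairs([("L1", "R1"), ("L1", "R1")])


def test_catalog_fantom5_reader(tmp_path):
    p = tmp_path / "f5.tsv"
    p.write_text("Ligand\tReceptor\nTGFB1\tTGFBR1\nVEGFA\tKDR\n")
    cat = ltmi.LigandReceptorCatalog.read_fantom5(str(p))
    assert len(cat) == 2
    assert cat.pairs["source"].unique().tolist() == ["FANTOM5"]
    # headerless variant
    q = tmp_path / "f5b.tsv"
    q.write_text("TGFB1\tTGFBR1\nVEGFA\tKDR\n")
    assert len(ltmi.LigandReceptorCatalog.read_fantom5(str(q))) == 2


def test_catalog_cellphonedb_flattens_complexes(tmp_path):
    p = tmp_path / "cpdb.tsv"
    p.write_text("partner_a\tpartner_b\nTGFB1\tTGFBR1_TGFBR2\nIL2\tIL2RA+IL2RB\n")
    cat = ltmi.LigandReceptorCatalog.read_cellphonedb(str(p))
    got = set(map(tuple, cat.pairs[["ligand", "receptor"]].to_numpy()))
    assert got == {
        ("TGFB1", "TGFBR1"),
        ("TGFB1", "TGFBR2"),
        ("IL2", "IL2RA"),
        ("IL2", "IL2RB"),
    }


def test_read_gene_list(tmp_path):
    p = tmp_path / "genes.txt"
    p.write_text("# secreted genes\nTGFB1\n\nVEGFA\n")
    assert ltmi.read_gene_list(str(p)) == ["TGFB1", "VEGFA"]
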