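"""Stain unmixing, nuclei detection, classification and proximity tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage, stats
from scipy.spatial import cKDTree

import ltmi


@pytest.fixture(scope="module")
def tissue():
    img, mask, truth = ltmi.generate_tissue(seed=7)
    return img, mask, truth


@pytest.fixture(scope="module")
def sparse_tissue():
    """Well-separated nuclei: resolvable at the detector's working scale,
    and far enough apart that the cytoplasmic marker halo of one cell does
    not reach its neighbours' nuclei."""
    img, mask, truth = ltmi.generate_tissue(
        seed=7, min_separation=26.0, n_tumor_per_nest=4, n_stroma=35
    )
    return img, mask, truth


def _match(det, true, tol=5.0):
    if len(det) == 0:
        return 0.0, 0.0
    d, _ = cKDTree(true).query(det)
    tp = int((d <= tol).sum())
    return tp / len(det), tp / len(true)


# -- stain unmixing ----------------------------------------------------------

def test_unmix_recovers_true_maps(tissue):
    img, _, truth = tissue
    ch = ltmi.separate_stains(img, seed=0)
    th, tm = truth.true_stain_maps
    assert np.corrcoef(ch.hematoxylin.ravel(), th.ravel())[0, 1] > 0.95
    assert np.corrcoef(ch.marker.ravel(), tm.ravel())[0, 1] > 0.95


def test_unmix_deterministic(tissue):
    img, _, _ = tissue
    a = ltmi.separate_stains(img, seed=0)
    b = ltmi.separate_stains(img, seed=0)
    np.testing.assert_array_equal(a.hematoxylin, b.hematoxylin)
    np.testing.assert_array_equal(a.marker, b.marker)


def test_unmix_single_stain_degenerate():
    """A one-stain image is rank-1: error by default, flag to proceed."""
    rng = np.random.default_rng(0)
    conc = np.zeros((64, 64))
    conc[20:40, 20:40] = rng.uniform(0.3, 0.8, size=(20, 20))
    img = np.clip(conc[:, :, None] * np.array([0.65, 0.70, 0.29]), 0, 1)
    with pytest.raises(ValueError, match="single stain"):
        ltmi.separate_stains(img, seed=0)
    ch = ltmi.separate_stains(img, seed=0, allow_single_stain=True)
    assert ch.marker.max() == 0.0
    assert np.corrcoef(ch.hematoxylin.ravel(), conc.ravel())[0, 1] > 0.99


# -- nuclei detection --------------------------------------------------------

def test_detect_blank_map_no_nuclei():
    out = ltmi.detect_nuclei(np.zeros((64, 64)))
    assert len(out) == 0
    assert list(out.columns) == ["row", "col", "response"]


def test_detect_isolated_blobs_exact():
    centers = [(20, 20), (20, 60), (60, 40)]
    pts = np.zeros((90, 90))
    for r, c in centers:
        pts[r, c] = 1.0
    conc = ndimage.gaussian_filter(pts, sigma=6.0) * (2 * np.pi * 36)
    det = ltmi.detect_nuclei(conc)
    precision, recall = _match(
        det[["row", "col"]].to_numpy(float), np.array(centers, float), tol=2.0
    )
    assert precision == 1.0 and recall == 1.0


def test_detect_colliding_blobs_merge():
    """Two centers 4 px apart are below the NMS radius: one detection."""
    pts = np.zeros((64, 64))
    pts[30, 30] = 1.0
    pts[30, 34] = 1.0
    conc = ndimage.gaussian_filter(pts, sigma=6.0) * (2 * np.pi * 36)
    det = ltmi.detect_nuclei(conc)
    assert len(det) == 1


def test_detect_response_floor_suppresses_noise():
    rng = np.random.default_rng(1)
    noise = np.abs(rng.normal(0, 0.003, size=(64, 64)))
    det = ltmi.detect_nuclei(ndimage.gaussian_filter(noise, 2))
    assert len(det) == 0


def test_detect_on_sparse_tissue(sparse_tissue):
    img, _, truth = sparse_tissue
    ch = ltmi.separate_stains(img, seed=0)
    det = ltmi.detect_nuclei(ch.hematoxylin)
    tn = truth.true_nuclei[["row", "col"]].to_numpy(float)
    precision, recall = _match(det[["row", "col"]].to_numpy(float), tn)
    assert precision >= 0.95 and recall >= 0.95


# -- marker classification and class assignment ------------------------------

def test_classify_marker_threshold_semantics():
    marker = np.zeros((64, 64))
    marker[10, 10] = 1.0
    marker = ndimage.gaussian_filter(marker, sigma=6.0) * (2 * np.pi * 36)
    nuclei = pd.DataFrame({"row": [10, 50], "col": [10, 50]})
    out = ltmi.classify_marker(marker, nuclei)
    assert out["marker_positive"].tolist() == [True, False]
    # threshold 1.0: the smoothed value can never strictly exceed it
    out_hi = ltmi.classify_marker(marker, nuclei, threshold=1.0)
    assert not out_hi["marker_positive"].any()


def test_assign_classes_boundary_and_errors():
    mask = np.zeros((32, 32), dtype=bool)
    mask[:16] = True
    nuclei = pd.DataFrame({"row": [0, 15, 16, 31], "col": [5, 5, 5, 5]})
    out = ltmi.assign_classes(nuclei, mask)
    assert out["cell_class"].tolist() == ["tumor", "tumor", "stroma", "stroma"]
    bad = pd.DataFrame({"row": [40], "col": [5]})
    with pytest.raises(ValueError, match="outside"):
        ltmi.assign_classes(bad, mask)


def test_assign_classes_empty():
    out = ltmi.assign_classes(pd.DataFrame({"row": [], "col": []}), np.zeros((8, 8), bool))
    assert len(out) == 0


# -- proximity statistics ----------------------------------------------------

def test_proximity_hand_oracle(toy_nuclei):
    res = ltmi.proximity_analysis(toy_nuclei)
    # hand distances: positives (5, 5); negatives (sqrt(29), 20)
    np.testing.assert_allclose(np.sort(res.distances[res.positive].to_numpy()), [5.0, 5.0])
    np.testing.assert_allclose(
        np.sort(res.distances[~res.positive].to_numpy()), [np.sqrt(29.0), 20.0]
    )
    # brute-force Mann-Whitney U for the positive sample
    pos = res.distances[res.positive].to_numpy()
    neg = res.distances[~res.positive].to_numpy()
    u_hand = sum(
        1.0 if a > b else (0.5 if a == b else 0.0) for a in pos for b in neg
    )
    assert res.mannwhitney_u == pytest.approx(u_hand)
    assert res.t_observed == pytest.approx(5.0)


def test_proximity_mannwhitney_exact_enumeration():
    """Exact p by enumerating all label assignments on a tiny example."""
    nuclei = pd.DataFrame(
        {
            "row": [0, 0, 0, 0, 0, 0, 0, 0],
            "col": [0, 3, 5, 9, 14, 20, 27, 35],
            "cell_class": ["tumor"] + ["stroma"] * 7,
            "marker_positive": [False, True, True, True, False, False, False, False],
        }
    )
    res = ltmi.proximity_analysis(nuclei, alternative="less")
    d = np.array([3, 5, 9, 14, 20, 27, 35], float)
    u_obs = res.mannwhitney_u
    us = []
    for pos_idx in itertools.combinations(range(7), 3):
        pos = d[list(pos_idx)]
        neg = np.delete(d, list(pos_idx))
        us.append(sum(1.0 if a > b else 0.0 for a in pos for b in neg))
    p_exact = np.mean([u <= u_obs for u in us])
    assert res.mannwhitney_p == pytest.approx(p_exact)


def test_proximity_requires_both_label_groups(toy_nuclei):
    allpos = toy_nuclei.copy()
    allpos.loc[allpos["cell_class"] == "stroma", "marker_positive"] = True
    with pytest.raises(ValueError, match="marker-negative"):
        ltmi.proximity_analysis(allpos)
    with pytest.raises(ValueError, match="no tumor"):
        ltmi.proximity_analysis(toy_nuclei[toy_nuclei["cell_class"] == "stroma"])


def test_proximity_distance_zero_for_coincident():
    nuclei = pd.DataFrame(
        {
            "row": [5, 5, 9],
            "col": [5, 5, 9],
            "cell_class": ["tumor", "stroma", "stroma"],
            "marker_positive": [False, True, False],
        }
    )
    res = ltmi.proximity_analysis(nuclei)
    assert res.distances.iloc[0] == 0.0


def test_proximity_invariant_to_rigid_motion(toy_nuclei):
    base = ltmi.proximity_analysis(toy_nuclei)
    shifted = toy_nuclei.copy()
    shifted["row"] += 100
    shifted["col"] += 50
    rotated = toy_nuclei.copy()
    rotated["row"], rotated["col"] = toy_nuclei["col"], 200 - toy_nuclei["row"]
    for variant in (shifted, rotated):
        res = ltmi.proximity_analysis(variant)
        assert res.mannwhitney_u == pytest.approx(base.mannwhitney_u)
        np.testing.assert_allclose(
            np.sort(res.distances.to_numpy()), np.sort(base.distances.to_numpy())
        )


def test_permutation_strict_separation_minimal_p(toy_nuclei):
    res = ltmi.proximity_permutation_test(toy_nuclei, n_perm=999, seed=0)
    # positives are strictly nearest; only permutations reselecting them tie
    n_same = sum(
        1
        for c in itertools.combinations(range(4), 2)
        if sorted(c) == [0, 1]
    )
    # C(4,2) = 6 assignments; exact exceedance = 1/6 of draws on average
    assert res.perm_p <= (999 / 6 * 1.5 + 1) / 1000
    assert res.t_observed == pytest.approx(5.0)
    assert res.n_perm == 999


def test_permutation_all_positive_raises_and_p_bounds(toy_nuclei):
    res = ltmi.proximity_permutation_test(toy_nuclei, n_perm=50, seed=1)
    assert 0 < res.perm_p <= 1.0
    none_pos = toy_nuclei.copy()
    none_pos["marker_positive"] = False
    with pytest.raises(ValueError, match="no marker-positive"):
        ltmi.proximity_permutation_test(none_pos, n_perm=10)
    with pytest.raises(ValueError, match="n_perm"):
        ltmi.proximity_permutation_test(toy_nuclei, n_perm=0)


def test_permutation_deterministic(toy_nuclei):
    a = ltmi.proximity_permutation_test(toy_nuclei, n_perm=200, seed=5)
    b = ltmi.proximity_permutation_test(toy_nuclei, n_perm=200, seed=5)
    assert a.perm_p == b.perm_p and a.n_exceed == b.n_exceed


def test_proximity_result_json(toy_nuclei, tmp_path):
    import json

    res = ltmi.proximity_permutation_test(toy_nuclei, n_perm=99, seed=0)
    p = tmp_path / "prox.json"
    res.to_json(str(p))
    payload = json.loads(p.read_text())
    assert payload["perm_p"] == pytest.approx(res.perm_p)
    assert payload["n_perm"] == 99


# -- end-to-end slide pipeline ----------------------------------------------

def test_full_slide_pipeline_recovers_positivity(sparse_tissue):
    img, mask, truth = sparse_tissue
    ch = ltmi.separate_stains(img, seed=0)
    det = ltmi.detect_nuclei(ch.hematoxylin)
    det = ltmi.classify_marker(ch.marker, det)
    det = ltmi.assign_classes(det, mask)
    tn = truth.true_nuclei
    tree = cKDTree(tn[["row", "col"]].to_numpy(float))
    d, idx = tree.query(det[["row", "col"]].to_numpy(float))
    matched = d <= 5
    agree_class = (
        det.loc[matched, "cell_class"].to_numpy()
        == tn.iloc[idx[matched]]["cell_class"].to_numpy()
    ).mean()
    agree_marker = (
        det.loc[matched, "marker_positive"].to_numpy()
        == tn.iloc[idx[matched]]["marker_positive"].to_numpy()
    ).mean()
    assert agree_class >= 0.95
    assert agree_marker >= 0.9
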