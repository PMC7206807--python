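"""Stained-slide image analysis and spatial proximity testing.

Pipeline for a two-stain brightfield slide (nuclear counterstain +
chromogenic marker):

1. unmix the RGB image into hematoxylin and marker concentration maps by
   rank-2 non-negative matrix factorization;
2. detect nuclei centers on the hematoxylin map with a
   Laplacian-of-Gaussian filter at scale 6 px followed by non-maximum
   suppression;
3. smooth the marker map (Gaussian, sd 6 px), evaluate at the nuclei
   centers and threshold at 0.1 to call marker-positive cells;
4. classify nuclei as tumor or stroma from a manually annotated region
   mask, compute every stromal nucleus's distance to the nearest tumor
   nucleus, and compare positive vs negative distance distributions with a
   Mann-Whitney U test and a label-permutation test on the median distance
   of the positive cells.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage, stats
from scipy.spatial import cKDTree
from sklearn.decomposition import NMF
from sklearn.exceptions import ConvergenceWarning

#: reference hematoxylin RGB direction used to label NMF components
REFERENCE_HEMATOXYLIN = np.array([0.65, 0.70, 0.29])

#: default |LoG response| floor for nucleus candidates; calibrated on the
#: synthetic slide generator (unit-amplitude sd-6 blobs respond at ~0.014,
#: background noise after LoG smoothing stays well below 0.004)
DEFAULT_RESPONSE_FLOOR = 0.004

SPATIAL_DEFAULTS = {
    "log_scale": 6.0,
    "nms_radius": 6.0,
    "response_floor": DEFAULT_RESPONSE_FLOOR,
    "marker_smooth": 6.0,
    "marker_threshold": 0.1,
}


@dataclass
class StainChannels:
    """Unmixed concentration maps plus the 2 x 3 stain basis."""

    hematoxylin: np.ndarray
    marker: np.ndarray
    basis: np.ndarray  # rows: hematoxylin, marker

    def __post_init__(self) -> None:
        if (self.hematoxylin < 0).any() or (self.marker < 0).any():
            raise ValueError("negative stain concentrations")


@dataclass
class ProximityResult:
    """Distances and test statistics for marker-positive vs negative stroma."""

    distances: pd.Series  # per stromal nucleus, nearest-tumor distance (px)
    positive: pd.Series  # matching marker_positive flags
    mannwhitney_u: float | None = None
    mannwhitney_p: float | None = None
    t_observed: float | None = None  # median nearest-tumor distance of positives
    n_perm: int | None = None
    n_exceed: int | None = None  # permuted T <= observed T
    perm_p: float | None = None

    def to_json(self, path: str) -> None:
        payload = {
            k: (None if v is None else float(v))
            for k, v in {
                "mannwhitney_u": self.mannwhitney_u,
                "mannwhitney_p": self.mannwhitney_p,
                "t_observed": self.t_observed,
                "n_perm": self.n_perm,
                "n_exceed": self.n_exceed,
                "perm_p": self.perm_p,
            }.items()
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


# ---------------------------------------------------------------------------
# image IO
# ---------------------------------------------------------------------------

def read_image(path: str) -> np.ndarray:
    """Read an RGB image as float intensities in [0, 1]."""
    return np.asarray(Image.open(path).convert("RGB"), dtype=float) / 255.0


def write_image(image: np.ndarray, path: str) -> None:
    arr = np.clip(image, 0.0, 1.0)
    Image.fromarray((arr * 255).round().astype(np.uint8)).save(path)


def read_mask(path: str) -> np.ndarray:
    """Read a single-channel mask; nonzero (255) pixels mark the tumor region."""
    return np.asarray(Image.open(path).convert("L")) > 0


def write_mask(mask: np.ndarray, path: str) -> None:
    Image.fromarray(np.where(mask, 255, 0).astype(np.uint8)).save(path)


# ---------------------------------------------------------------------------
# stain unmixing
# ---------------------------------------------------------------------------

def separate_stains(
    image: np.ndarray,
    seed: int = 0,
    reference_hematoxylin: np.ndarray = REFERENCE_HEMATOXYLIN,
    allow_single_stain: bool = False,
    rank_tol: float = 0.02,
    foreground_floor: float = 0.3,
) -> StainChannels:
    """Unmix an RGB slide into two stain concentration maps via rank-2 NMF.

    The stain basis is fitted on bright foreground pixels (max channel
    above ``foreground_floor``): dim pixels sit near the origin of color
    space where sensor noise dominates the chromatic signal, and including
    them drags the fitted basis vectors toward each other.  Concentrations
    for every pixel (bright or not) are then solved against the fitted
    basis and clipped at zero.  The component whose basis vector is
    closest in cosine to the reference hematoxylin color is labeled
    hematoxylin; the other is the marker.  Each concentration map is
    rescaled by its 99th percentile and clipped to [0, 1].

    A single-stain image is detected *before* factorization: if the second
    singular value of the foreground pixel matrix is below ``rank_tol``
    times the first, the pixels span a single color direction and a rank-2
    factorization is meaningless (NMF would split the one stain into two
    arbitrary non-negative parts).  This raises unless
    ``allow_single_stain`` is set, in which case the whole image is
    projected onto the reference hematoxylin direction and the marker map
    is returned as zeros.
    """
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an H x W x 3 image")
    h, w, _ = image.shape
    V = np.maximum(image.reshape(-1, 3), 0.0)
    fg = V.max(axis=1) > foreground_floor
    fit_pixels = V[fg] if fg.sum() >= 100 else V
    sv = np.linalg.svd(fit_pixels, compute_uv=False)
    degenerate = sv[0] <= 0 or sv[1] / sv[0] < rank_tol
    if degenerate:
        if not allow_single_stain:
            raise ValueError(
                "image is effectively rank-1 (single stain); pass allow_single_stain=True "
                "to treat it as hematoxylin only"
            )
        hema = V @ reference_hematoxylin / (reference_hematoxylin @ reference_hematoxylin)
        hema = hema.reshape(h, w)
        return StainChannels(_rescale(hema), np.zeros((h, w)), np.vstack([reference_hematoxylin, np.zeros(3)]))

    model = NMF(n_components=2, init="nndsvda", random_state=seed, max_iter=1000, tol=1e-6)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(fit_pixels)
    H = model.components_  # 2 x 3 basis
    W = np.clip(V @ np.linalg.pinv(H), 0.0, None)
    norms = np.linalg.norm(H, axis=1)
    ref = reference_hematoxylin / np.linalg.norm(reference_hematoxylin)
    cos_ref = (H / norms[:, None]) @ ref
    hema_idx = int(np.argmax(cos_ref))
    marker_idx = 1 - hema_idx
    hema = _rescale(W[:, hema_idx].reshape(h, w))
    marker = _rescale(W[:, marker_idx].reshape(h, w))
    basis = np.vstack([H[hema_idx], H[marker_idx]])
    return StainChannels(hema, marker, basis)


def _rescale(channel: np.ndarray) -> np.ndarray:
    hi = np.percentile(channel, 99)
    if hi <= 0:
        return np.zeros_like(channel)
    return np.clip(channel / hi, 0.0, 1.0)


# ---------------------------------------------------------------------------
# nuclei detection and marker classification
# ---------------------------------------------------------------------------

def detect_nuclei(
    hematoxylin: np.ndarray,
    scale: float = 6.0,
    nms_radius: float = 6.0,
    response_floor: float = DEFAULT_RESPONSE_FLOOR,
) -> pd.DataFrame:
    """Detect nucleus centers as LoG minima with non-maximum suppression.

    Bright blobs of the concentration map yield negative
    Laplacian-of-Gaussian responses; candidates are local minima within
    ``nms_radius`` with ``|response| >= response_floor``.  Ties between
    equal responses are broken in row-major order.  Returns a frame with
    columns ``row``, ``col``, ``response``.
    """
    # zero-pad the border: outside the field of view there is no stain, and
    # reflect-style padding mirrors near-edge blobs onto the boundary,
    # displacing their response minima
    response = ndimage.gaussian_laplace(
        hematoxylin.astype(float), sigma=scale, mode="constant", cval=0.0
    )
    rad = int(np.floor(nms_radius))
    yy, xx = np.mgrid[-rad : rad + 1, -rad : rad + 1]
    footprint = (yy ** 2 + xx ** 2) <= nms_radius ** 2
    local_min = ndimage.minimum_filter(response, footprint=footprint, mode="nearest")
    cand = np.argwhere((response <= local_min) & (response <= -response_floor))
    if len(cand) == 0:
        return pd.DataFrame(columns=["row", "col", "response"]).astype(
            {"row": int, "col": int, "response": float}
        )
    resp = response[cand[:, 0], cand[:, 1]]
    order = np.lexsort((cand[:, 1], cand[:, 0], resp))  # response, then row-major
    kept: list[int] = []
    kept_pts: list[np.ndarray] = []
    r2 = nms_radius ** 2
    for i in order:
        p = cand[i]
        if all(((p - q) ** 2).sum() > r2 for q in kept_pts):
            kept.append(i)
            kept_pts.append(p)
    kept_arr = cand[kept]
    out = pd.DataFrame(
        {"row": kept_arr[:, 0], "col": kept_arr[:, 1], "response": resp[kept]}
    )
    return out.sort_values(["row", "col"], kind="stable").reset_index(drop=True)


def classify_marker(
    marker: np.ndarray,
    nuclei: pd.DataFrame,
    smooth: float = 6.0,
    threshold: float = 0.1,
) -> pd.DataFrame:
    """Evaluate the smoothed marker map at nuclei and threshold positivity.

    The marker map (scaled to [0, 1]) is Gaussian-smoothed with sd
    ``smooth``; a nucleus is positive iff the smoothed value at its center
    strictly exceeds ``threshold``.  Adds ``marker_value`` and
    ``marker_positive`` columns.
    """
    rows = nuclei["row"].to_numpy(int)
    cols = nuclei["col"].to_numpy(int)
    h, w = marker.shape
    if len(rows) and (
        rows.min() < 0 or rows.max() >= h or cols.min() < 0 or cols.max() >= w
    ):
        raise ValueError("nucleus center out of image bounds")
    smoothed = ndimage.gaussian_filter(marker.astype(float), sigma=smooth)
    values = smoothed[rows, cols] if len(rows) else np.array([])
    out = nuclei.copy()
    out["marker_value"] = values
    out["marker_positive"] = values > threshold
    return out


def assign_classes(nuclei: pd.DataFrame, mask: np.ndarray) -> pd.DataFrame:
    """Label each nucleus tumor (center inside the mask) or stroma."""
    if len(nuclei):
        h, w = mask.shape
        rows = nuclei["row"].to_numpy(int)
        cols = nuclei["col"].to_numpy(int)
        if rows.max(initial=0) >= h or cols.max(initial=0) >= w:
            raise ValueError("nucleus center outside mask bounds")
        inside = mask[rows, cols] > 0
    else:
        inside = np.array([], dtype=bool)
    out = nuclei.copy()
    out["cell_class"] = np.where(inside, "tumor", "stroma")
    return out


def write_nucleus_table(nuclei: pd.DataFrame, path: str) -> None:
    nuclei.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# proximity statistics
# ---------------------------------------------------------------------------

def _stromal_distances(nuclei: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    tumor = nuclei[nuclei["cell_class"] == "tumor"]
    stroma = nuclei[nuclei["cell_class"] == "stroma"]
    if len(tumor) == 0:
        raise ValueError("no tumor nuclei: cannot compute nearest-tumor distances")
    tree = cKDTree(tumor[["row", "col"]].to_numpy(float))
    d, _ = tree.query(stroma[["row", "col"]].to_numpy(float))
    return pd.Series(d, index=stroma.index), stroma["marker_positive"].astype(bool)


def proximity_analysis(nuclei: pd.DataFrame, alternative: str = "two-sided") -> ProximityResult:
    """Nearest-tumor distances plus a Mann-Whitney U test, positive vs negative.

    Requires at least one tumor nucleus and at least one positive and one
    negative stromal nucleus.
    """
    distances, positive = _stromal_distances(nuclei)
    pos = distances[positive.to_numpy()]
    neg = distances[~positive.to_numpy()]
    if len(pos) == 0 or len(neg) == 0:
        which = "marker-positive" if len(pos) == 0 else "marker-negative"
        raise ValueError(f"no {which} stromal nuclei: Mann-Whitney test undefined")
    u, p = stats.mannwhitneyu(pos, neg, alternative=alternative)
    return ProximityResult(
        distances=distances,
        positive=positive,
        mannwhitney_u=float(u),
        mannwhitney_p=float(p),
        t_observed=float(np.median(pos)),
    )


def proximity_permutation_test(
    nuclei: pd.DataFrame,
    n_perm: int = 100_000,
    seed: int | None = None,
) -> ProximityResult:
    """Label-permutation test on T = median nearest-tumor distance of positives.

    Positivity labels are permuted over the stromal nuclei, preserving the
    positive count; the empirical p is ``(#{T_perm <= T_obs} + 1)/(B + 1)``,
    so it is never zero and never exceeds one.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    distances, positive = _stromal_distances(nuclei)
    d = distances.to_numpy(float)
    k = int(positive.sum())
    if k == 0:
        raise ValueError("no marker-positive stromal nuclei")
    t_obs = float(np.median(d[positive.to_numpy()]))
    rng = np.random.default_rng(seed)
    n = len(d)
    exceed = 0
    chunk = max(1, min(n_perm, int(5e6 // max(n, 1))))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        perm = rng.permuted(np.broadcast_to(d, (m, n)).copy(), axis=1)
        t_perm = np.median(perm[:, :k], axis=1)
        exceed += int(np.sum(t_perm <= t_obs))
        done += m
    p = (exceed + 1.0) / (n_perm + 1.0)
    return ProximityResult(
        distances=distances,
        positive=positive,
        t_observed=t_obs,
        n_perm=n_perm,
        n_exceed=exceed,
        perm_p=p,
    )
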