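"""Synthetic study-condition generator with known ground truth.

Emulates the full input surface of the pipeline for a multi-patient cohort
of four sorted populations plus bulk across two histologies:

* sorted-population TPM matrices with planted cell-type markers, a planted
  ligand -> target-program coupling across compartments, mitochondrial rRNA
  load, batch effects and log-normal measurement noise;
* bulk samples as convex Dirichlet mixtures of each patient's sorted
  profiles;
* two-stain synthetic slides with tumor nests, stromal nuclei and an
  optional proximity bias of marker-positive cells toward the nests;
* survival tables with covariate-dependent exponential hazards.

Every generator returns the matching :class:`GroundTruth` so recovery can
be scored exactly.  All outputs are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .cohort import ExpressionCohort, SORTED_POPULATIONS, BULK, HISTOLOGIES
from .preprocess import TPM_TOTAL
from .spatial import write_image, write_mask

DEFAULT_STAIN_VECTORS = np.array(
    [
        [0.65, 0.70, 0.29],  # hematoxylin-like
        [0.27, 0.57, 0.78],  # chromogenic marker-like
    ]
)


# ---------------------------------------------------------------------------
# specs and ground truth
# ---------------------------------------------------------------------------

@dataclass
class CouplingPlan:
    """A planted ligand -> target-program coupling across compartments.

    Per patient, the ligand's log2 expression in ``source_type`` deviates
    from baseline by ``ligand_sd`` x z_p; every ``target_genes`` member in
    ``target_type`` moves by ``slope`` x that deviation (before measurement
    noise).  ``ligand_log2fc`` additionally elevates the ligand itself in
    the source type so the ligand is a marker of its compartment.
    """

    ligand: str
    source_type: str
    target_genes: tuple[str, ...]
    target_type: str
    slope: float = 1.0
    ligand_sd: float = 1.0
    ligand_log2fc: float = 2.0


@dataclass
class BatchPlan:
    """Additive per-(batch, gene) log2 offsets and noise scale factors."""

    n_batches: int = 1
    offset_sd: float = 0.0
    scale_sd: float = 0.0


@dataclass
class CohortSpec:
    """Design of a synthetic sorted cohort.

    ``marker_plan`` maps each cell type to its planted (gene, log2
    fold-change >= 1) markers; a gene may be a marker of exactly one type.
    ``histologies`` assigns one histology per patient (defaults to an even
    adenocarcinoma/SCC split).
    """

    n_patients: int = 12
    cell_types: tuple[str, ...] = SORTED_POPULATIONS
    histologies: tuple[str, ...] | None = None
    n_genes: int = 2000
    marker_plan: dict[str, list[tuple[str, float]]] = field(default_factory=dict)
    coupling_plan: tuple[CouplingPlan, ...] = ()
    batch_plan: BatchPlan = field(default_factory=BatchPlan)
    noise_sd: float = 0.25
    dirichlet_alpha: float = 2.0
    include_mt_rrna: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.n_genes < 1 or self.batch_plan.n_batches < 1:
            raise ValueError("counts must be positive")
        if self.histologies is None:
            half = (self.n_patients + 1) // 2
            self.histologies = tuple(
                ["adenocarcinoma"] * half + ["SCC"] * (self.n_patients - half)
            )
        if len(self.histologies) != self.n_patients:
            raise ValueError("histologies must list one histology per patient")
        bad = set(self.histologies) - set(HISTOLOGIES)
        if bad:
            raise ValueError(f"unknown histologies: {sorted(bad)}")
        genes = set(self.gene_ids())
        seen: dict[str, str] = {}
        for ct, markers in self.marker_plan.items():
            if ct not in self.cell_types:
                raise ValueError(f"marker plan references unknown cell type {ct!r}")
            for gene, lfc in markers:
                if gene not in genes:
                    raise ValueError(f"marker gene {gene!r} is not in the gene list")
                if lfc < 1.0:
                    raise ValueError(f"marker log2 fold-change must be >= 1, got {lfc}")
                if gene in seen:
                    raise ValueError(f"gene {gene!r} planted as marker of both {seen[gene]!r} and {ct!r}")
                seen[gene] = ct
        for cp in self.coupling_plan:
            if cp.source_type not in self.cell_types or cp.target_type not in self.cell_types:
                raise ValueError("coupling plan references unknown cell type")
            for g in (cp.ligand, *cp.target_genes):
                if g not in genes:
                    raise ValueError(f"coupling gene {g!r} is not in the gene list")

    def gene_ids(self) -> list[str]:
        ids = [f"G{i:04d}" for i in range(self.n_genes)]
        if self.include_mt_rrna:
            ids += ["MT-RNR1", "MT-RNR2"]
        return ids


def default_cohort_spec(
    n_patients: int = 12,
    n_genes: int = 2000,
    markers_per_type: int = 25,
    marker_log2fc: float = 2.0,
    noise_sd: float = 0.25,
    n_batches: int = 2,
    batch_offset_sd: float = 0.4,
    histologies: tuple[str, ...] | None = None,
    with_coupling: bool = True,
    coupling_slope: float = 1.0,
    coupling_program_size: int = 30,
    seed: int = 0,
) -> CohortSpec:
    """The standard study-like design used throughout the tests.

    Four sorted populations, planted 4-fold markers (25 per type by
    default), a fibroblast-ligand -> malignant-program coupling, two
    batches and log-normal noise of sd 0.25.
    """
    types = SORTED_POPULATIONS
    marker_plan: dict[str, list[tuple[str, float]]] = {}
    g = 0
    for ct in types:
        marker_plan[ct] = [(f"G{g + j:04d}", marker_log2fc) for j in range(markers_per_type)]
        g += markers_per_type
    coupling: tuple[CouplingPlan, ...] = ()
    if with_coupling:
        ligand = f"G{g:04d}"
        program = tuple(f"G{g + 1 + j:04d}" for j in range(coupling_program_size))
        g += 1 + coupling_program_size
        coupling = (
            CouplingPlan(
                ligand=ligand,
                source_type="fibroblast",
                target_genes=program,
                target_type="malignant",
                slope=coupling_slope,
            ),
        )
    if g > n_genes:
        raise ValueError("n_genes too small for the requested marker/coupling plan")
    return CohortSpec(
        n_patients=n_patients,
        n_genes=n_genes,
        marker_plan=marker_plan,
        coupling_plan=coupling,
        batch_plan=BatchPlan(n_batches=n_batches, offset_sd=batch_offset_sd),
        noise_sd=noise_sd,
        histologies=histologies,
        seed=seed,
    )


@dataclass
class GroundTruth:
    """Planted truth backing a synthetic dataset (oracle for recovery tests)."""

    true_fractions: pd.DataFrame | None = None  # bulk samples x cell types
    true_udegs: dict[str, set[str]] | None = None
    true_coupling: list[dict] | None = None
    true_nuclei: pd.DataFrame | None = None  # row, col, cell_class, marker_positive
    true_stain_maps: tuple[np.ndarray, np.ndarray] | None = None  # hematoxylin, marker
    true_survival_effect: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.true_fractions is not None:
            sums = self.true_fractions.to_numpy().sum(axis=1)
            if np.abs(sums - 1.0).max() > 1e-9:
                raise ValueError("ground-truth fractions do not sum to one")


# ---------------------------------------------------------------------------
# cohort generator
# ---------------------------------------------------------------------------

def generate_cohort(spec: CohortSpec) -> tuple[ExpressionCohort, GroundTruth]:
    """Generate sorted + bulk TPM samples with planted structure.

    One sample per (patient, cell type) plus one bulk sample per patient.
    Bulk TPM is the convex Dirichlet(alpha) mixture of the patient's sorted
    TPM vectors.  Measurement noise is Gaussian on the log2(1+TPM) scale;
    batch offsets are additive on the same scale.  All final columns are
    renormalised to a TPM sum of 10^6.
    """
    rng = np.random.default_rng(spec.seed)
    genes = spec.gene_ids()
    gene_pos = {g: i for i, g in enumerate(genes)}
    n_genes = len(genes)
    types = list(spec.cell_types)

    base = rng.uniform(1.0, 9.0, size=n_genes)
    if spec.include_mt_rrna:
        base[gene_pos["MT-RNR1"]] = 16.0
        base[gene_pos["MT-RNR2"]] = 16.2

    # clean per-type log2 profiles (shared across patients except coupling)
    type_log = {ct: base.copy() for ct in types}
    true_udegs: dict[str, set[str]] = {ct: set() for ct in types}
    for ct, markers in spec.marker_plan.items():
        for gene, lfc in markers:
            type_log[ct][gene_pos[gene]] += lfc
            true_udegs[ct].add(gene)

    # per-patient coupling deviations
    coupling_truth: list[dict] = []
    patient_shift = {ct: np.zeros((spec.n_patients, n_genes)) for ct in types}
    for cp in spec.coupling_plan:
        z = rng.normal(0.0, cp.ligand_sd, size=spec.n_patients)
        li = gene_pos[cp.ligand]
        patient_shift[cp.source_type][:, li] += z
        type_log[cp.source_type][li] += cp.ligand_log2fc
        true_udegs[cp.source_type].add(cp.ligand)
        for g in cp.target_genes:
            patient_shift[cp.target_type][:, gene_pos[g]] += cp.slope * z
        coupling_truth.append(
            {
                "ligand": cp.ligand,
                "source_type": cp.source_type,
                "target_type": cp.target_type,
                "target_genes": list(cp.target_genes),
                "slope": cp.slope,
                "ligand_deviation": z.copy(),
            }
        )

    # clean TPM per (patient, type), columns normalised to 10^6
    clean_tpm: dict[tuple[int, str], np.ndarray] = {}
    for p in range(spec.n_patients):
        for ct in types:
            v = np.maximum(np.exp2(type_log[ct] + patient_shift[ct][p]) - 1.0, 0.0)
            clean_tpm[(p, ct)] = v * (TPM_TOTAL / v.sum())

    fractions = rng.dirichlet(np.full(len(types), spec.dirichlet_alpha), size=spec.n_patients)

    bp = spec.batch_plan
    batch_offsets = rng.normal(0.0, bp.offset_sd, size=(bp.n_batches, n_genes)) if bp.offset_sd > 0 else np.zeros((bp.n_batches, n_genes))
    batch_scales = np.exp(rng.normal(0.0, bp.scale_sd, size=bp.n_batches)) if bp.scale_sd > 0 else np.ones(bp.n_batches)

    columns, meta_rows, data = [], [], []
    sample_counter = 0

    def measure(clean: np.ndarray, batch_idx: int) -> np.ndarray:
        logv = np.log2(1.0 + clean) + batch_offsets[batch_idx]
        if spec.noise_sd > 0:
            logv = logv + rng.normal(0.0, spec.noise_sd * batch_scales[batch_idx], size=n_genes)
        tpm = np.maximum(np.exp2(logv) - 1.0, 0.0)
        return tpm * (TPM_TOTAL / tpm.sum())

    bulk_fraction_rows = {}
    for p in range(spec.n_patients):
        pid = f"P{p:02d}"
        hist = spec.histologies[p]
        for ct in types:
            batch_idx = sample_counter % bp.n_batches
            sid = f"{pid}_{ct}"
            columns.append(sid)
            data.append(measure(clean_tpm[(p, ct)], batch_idx))
            meta_rows.append((pid, ct, hist, f"B{batch_idx}", False))
            sample_counter += 1
        bulk_clean = sum(fractions[p, i] * clean_tpm[(p, ct)] for i, ct in enumerate(types))
        batch_idx = sample_counter % bp.n_batches
        sid = f"{pid}_{BULK}"
        columns.append(sid)
        data.append(measure(bulk_clean, batch_idx))
        meta_rows.append((pid, BULK, hist, f"B{batch_idx}", False))
        sample_counter += 1
        bulk_fraction_rows[sid] = fractions[p]

    tpm = pd.DataFrame(np.column_stack(data), index=pd.Index(genes, name="gene"), columns=columns)
    meta = pd.DataFrame(
        meta_rows,
        columns=["patient", "population", "histology", "batch", "replicate"],
        index=pd.Index(columns, name="sample"),
    )
    cohort = ExpressionCohort(tpm, meta)
    truth = GroundTruth(
        true_fractions=pd.DataFrame.from_dict(
            bulk_fraction_rows, orient="index", columns=types
        ),
        true_udegs=true_udegs,
        true_coupling=coupling_truth,
    )
    return cohort, truth


# ---------------------------------------------------------------------------
# tissue generator
# ---------------------------------------------------------------------------

def _place_points(
    rng: np.random.Generator,
    n: int,
    sampler,
    accept,
    existing: list[np.ndarray],
    min_sep: float,
    tries_per_point: int = 4000,
) -> list[np.ndarray]:
    pts: list[np.ndarray] = []
    sep2 = min_sep ** 2
    while len(pts) < n:
        for _ in range(tries_per_point):
            p = sampler()
            if not accept(p):
                continue
            if any(((p - q) ** 2).sum() < sep2 for q in existing) or any(
                ((p - q) ** 2).sum() < sep2 for q in pts
            ):
                continue
            pts.append(p)
            break
        else:
            raise ValueError(
                f"could not place {n} nuclei with separation {min_sep} in the available area"
            )
    return pts


def generate_tissue(
    n_tumor_nests: int = 4,
    n_stroma: int = 150,
    positive_fraction: float = 0.3,
    proximity_bias: float = 0.0,
    image_size: int = 256,
    stain_vectors: np.ndarray | None = None,
    seed: int = 0,
    n_tumor_per_nest: int = 12,
    nest_radius: float | None = None,
    min_separation: float = 14.0,
    blob_sd: float = 6.0,
    marker_blob_sd: float = 9.0,
    marker_offset: float = 8.0,
    noise_sd: float = 0.01,
    decay_scale: float = 25.0,
    render: bool = True,
    mode: str = "linear",
) -> tuple[np.ndarray | None, np.ndarray, GroundTruth]:
    """Simulate a two-stain slide with tumor nests and stromal nuclei.

    Tumor nuclei sit inside disk-shaped nests (which the returned mask
    covers); stromal nuclei sit outside.  ``positive_fraction`` of the
    stromal nuclei carry the marker; with ``proximity_bias > 0`` positives
    are drawn with probability decaying exponentially in the distance to
    the nearest tumor nucleus (scale ``decay_scale`` px), uniformly at 0.
    A very large bias makes the positives exactly the nearest stromal
    nuclei.

    With ``render=True`` the RGB image is the linear mixture of the two
    stain vectors over Gaussian nuclear blobs (sd ``blob_sd``), plus pixel
    noise, clipped to [0, 1]; ``mode="beer-lambert"`` instead renders
    transmitted light ``exp(-concentration x stain)`` on a white
    background for robustness experiments.
    """
    if not 0.0 <= positive_fraction <= 1.0:
        raise ValueError("positive_fraction must be in [0, 1]")
    if proximity_bias < 0:
        raise ValueError("proximity_bias must be nonnegative")
    if stain_vectors is None:
        stain_vectors = DEFAULT_STAIN_VECTORS
    stain_vectors = np.asarray(stain_vectors, dtype=float)
    if stain_vectors.shape != (2, 3) or (stain_vectors < 0).any():
        raise ValueError("stain_vectors must be a nonnegative 2 x 3 array")
    cross = np.linalg.norm(np.cross(stain_vectors[0], stain_vectors[1]))
    if cross < 1e-8 * np.linalg.norm(stain_vectors[0]) * np.linalg.norm(stain_vectors[1]):
        raise ValueError("stain vectors are collinear")

    rng = np.random.default_rng(seed)
    radius = nest_radius if nest_radius is not None else image_size / 7.0
    # packing feasibility: each nucleus excludes a disk of diameter min_separation
    nest_area = np.pi * radius ** 2
    if n_tumor_per_nest * np.pi * (min_separation / 2.0) ** 2 > 0.7 * nest_area:
        raise ValueError("nuclei count exceeds packable nest area")

    margin = radius + 2
    if 2 * margin >= image_size:
        raise ValueError("nest radius too large for the image")
    centers_list: list[np.ndarray] = []
    for _ in range(n_tumor_nests):
        # keep nests disjoint where the image allows it
        for _try in range(2000):
            c = rng.uniform(margin, image_size - margin, size=2)
            if all(np.linalg.norm(c - q) >= 2.1 * radius for q in centers_list):
                break
        centers_list.append(c)
    centers = np.array(centers_list).reshape(-1, 2)

    tumor_pts: list[np.ndarray] = []
    for c in centers:
        def in_disk_sampler(c=c):
            ang = rng.uniform(0, 2 * np.pi)
            rad = (radius - 2.0) * np.sqrt(rng.uniform())
            return c + rad * np.array([np.cos(ang), np.sin(ang)])

        tumor_pts += _place_points(
            rng, n_tumor_per_nest, in_disk_sampler, lambda p: True, tumor_pts, min_separation
        )

    def uniform_sampler():
        return rng.uniform(2, image_size - 2, size=2)

    def outside(p):
        return all(((p - c) ** 2).sum() > (radius + 3.0) ** 2 for c in centers)

    stroma_pts = _place_points(rng, n_stroma, uniform_sampler, outside, tumor_pts, min_separation)

    tumor = np.round(np.array(tumor_pts).reshape(-1, 2)).astype(int)
    stroma = np.round(np.array(stroma_pts).reshape(-1, 2)).astype(int)

    # marker positivity with optional proximity bias (Gumbel top-k trick)
    k = int(round(positive_fraction * len(stroma)))
    positive = np.zeros(len(stroma), dtype=bool)
    if len(stroma) and k > 0:
        d_nuc = np.array(
            [min(np.linalg.norm(p - t) for t in tumor) for p in stroma.astype(float)]
        )
        logw = -proximity_bias * d_nuc / decay_scale
        keys = logw + rng.gumbel(size=len(stroma))
        positive[np.argsort(-keys, kind="stable")[:k]] = True

    yy, xx = np.mgrid[0:image_size, 0:image_size]
    mask = np.zeros((image_size, image_size), dtype=bool)
    for c in centers:
        mask |= (yy - c[0]) ** 2 + (xx - c[1]) ** 2 <= radius ** 2

    nuclei = pd.DataFrame(
        {
            "row": np.concatenate([tumor[:, 0], stroma[:, 0]]) if len(tumor) + len(stroma) else np.array([], int),
            "col": np.concatenate([tumor[:, 1], stroma[:, 1]]) if len(tumor) + len(stroma) else np.array([], int),
            "cell_class": ["tumor"] * len(tumor) + ["stroma"] * len(stroma),
            "marker_positive": np.concatenate([np.zeros(len(tumor), bool), positive]) if len(tumor) + len(stroma) else np.array([], bool),
        }
    )
    truth = GroundTruth(true_nuclei=nuclei)

    image = None
    if render:
        hema_pts = np.zeros((image_size, image_size))
        marker_pts = np.zeros((image_size, image_size))
        for r, c in np.vstack([tumor, stroma]) if len(tumor) + len(stroma) else []:
            hema_pts[r, c] += 1.0
        for (r, c), pos in zip(stroma, positive):
            if not pos:
                continue
            # cytoplasmic marker: a wider blob displaced from the nucleus
            ang = rng.uniform(0, 2 * np.pi)
            rr = int(np.clip(round(r + marker_offset * np.cos(ang)), 0, image_size - 1))
            cc = int(np.clip(round(c + marker_offset * np.sin(ang)), 0, image_size - 1))
            marker_pts[rr, cc] += 1.0
        hema = ndimage.gaussian_filter(hema_pts, sigma=blob_sd) * (2.0 * np.pi * blob_sd ** 2)
        marker = ndimage.gaussian_filter(marker_pts, sigma=marker_blob_sd) * (
            2.0 * np.pi * marker_blob_sd ** 2
        )
        truth.true_stain_maps = (hema, marker)
        conc = hema[:, :, None] * stain_vectors[0] + marker[:, :, None] * stain_vectors[1]
        if mode == "linear":
            # keep the clean mixture inside [0, 1] so clipping only touches
            # noise at the boundaries and the rank-2 model stays exact
            peak = conc.max()
            if peak > 0:
                conc = conc * (0.95 / peak)
            image = conc + rng.normal(0.0, noise_sd, size=conc.shape)
        elif mode == "beer-lambert":
            image = np.exp(-conc) + rng.normal(0.0, noise_sd, size=conc.shape)
        else:
            raise ValueError(f"unknown rendering mode {mode!r}")
        image = np.clip(image, 0.0, 1.0)
    return image, mask, truth


def write_tissue(
    outdir: str,
    image: np.ndarray,
    mask: np.ndarray,
    truth: GroundTruth,
    prefix: str = "tissue",
) -> None:
    os.makedirs(outdir, exist_ok=True)
    write_image(image, os.path.join(outdir, f"{prefix}.png"))
    write_mask(mask, os.path.join(outdir, f"{prefix}_mask.png"))
    truth.true_nuclei.to_csv(os.path.join(outdir, f"{prefix}_nuclei.tsv"), sep="\t", index=False)


# ---------------------------------------------------------------------------
# survival generator
# ---------------------------------------------------------------------------

def generate_survival(
    n: int,
    covariate_effects: dict[str, float],
    censor_rate: float = 0.3,
    seed: int = 0,
    baseline_hazard: float = 0.1,
    covariate_types: dict[str, str] | None = None,
):
    """Exponential event times with covariate-dependent hazards.

    Hazard per subject is ``baseline_hazard * exp(sum(effect * covariate))``
    with covariates drawn N(0, 1) (``"normal"``, default) or Bernoulli(0.5)
    (``"bernoulli"``).  Censoring times are independent exponentials whose
    rate is set so that roughly ``censor_rate`` of baseline subjects are
    censored.
    """
    from .prognostics import SurvivalTable

    if n < 2:
        raise ValueError("need n >= 2 subjects")
    if not 0.0 <= censor_rate < 1.0:
        raise ValueError("censor_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    covariate_types = covariate_types or {}
    cols = {}
    eta = np.zeros(n)
    for name, beta in covariate_effects.items():
        kind = covariate_types.get(name, "normal")
        if kind == "normal":
            x = rng.normal(size=n)
        elif kind == "bernoulli":
            x = rng.integers(0, 2, size=n).astype(float)
        else:
            raise ValueError(f"unknown covariate type {kind!r}")
        cols[name] = x
        eta += beta * x
    hazard = baseline_hazard * np.exp(eta)
    t_event = rng.exponential(1.0 / hazard)
    if censor_rate > 0:
        c_rate = baseline_hazard * censor_rate / (1.0 - censor_rate)
        t_cens = rng.exponential(1.0 / c_rate, size=n)
    else:
        t_cens = np.full(n, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    data = pd.DataFrame({"time": time, "event": event, **cols})
    return SurvivalTable(data), GroundTruth(true_survival_effect=dict(covariate_effects))
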