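"""Cross-population correlation and pre-ranked gene-set enrichment.

To ask whether a ligand produced by one compartment couples to a
transcriptional program in another, the expression of a source gene in the
source compartment is correlated, across matched patients, with every gene
in the target compartment.  The resulting ranked correlation list feeds a
pre-ranked gene-set enrichment analysis based on the weighted
Kolmogorov-Smirnov running sum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import LogExpression

logger = logging.getLogger(__name__)


def cross_population_correlation(
    log_expr: LogExpression,
    source_gene: str,
    source_type: str,
    target_type: str,
    histology: str | None = None,
    method: str = "pearson",
) -> pd.DataFrame:
    """Correlate a source-compartment gene with every target-compartment gene.

    Patients are matched by id; replicate samples are averaged on the log
    scale; patients lacking either compartment are excluded (logged).  Genes
    with zero variance across the matched patients are dropped.  Returns a
    frame sorted by descending correlation with columns ``r`` and ``n``.

    ``method`` is ``"pearson"`` (default, on log2(1+TPM)) or ``"spearman"``.
    """
    if source_gene not in log_expr.genes:
        raise KeyError(f"source gene {source_gene!r} not in expression matrix")
    src = log_expr.patient_means(source_type, histology)
    tgt = log_expr.patient_means(target_type, histology)
    matched = src.columns.intersection(tgt.columns)
    dropped = set(src.columns).symmetric_difference(tgt.columns)
    if dropped:
        logger.info("excluding %d patients lacking one compartment: %s", len(dropped), sorted(dropped))
    if len(matched) < 3:
        raise ValueError(f"only {len(matched)} patients with both compartments; need >= 3")
    x = src.loc[source_gene, matched].to_numpy(float)
    Y = tgt[matched].to_numpy(float)
    if method == "spearman":
        x = stats.rankdata(x)
        Y = stats.rankdata(Y, axis=1)
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")
    if x.std() == 0:
        raise ValueError(f"source gene {source_gene!r} has zero variance across patients")
    keep = Y.std(axis=1) > 0
    Y = Y[keep]
    genes = tgt.index[keep]
    xc = x - x.mean()
    Yc = Y - Y.mean(axis=1, keepdims=True)
    r = (Yc @ xc) / (np.linalg.norm(Yc, axis=1) * np.linalg.norm(xc))
    out = pd.DataFrame({"r": np.clip(r, -1.0, 1.0), "n": len(matched)}, index=genes)
    return out.sort_values("r", ascending=False, kind="stable")


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str) -> dict[str, list[str]]:
    """Read a GMT file: name <tab> description <tab> gene1 <tab> ..."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path: str) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, name] + list(genes)) + "\n")


# ---------------------------------------------------------------------------
# pre-ranked GSEA
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    """Per-set enrichment statistics.

    ``table`` columns: ``es``, ``nes``, ``pval`` (same-sign permutation p
    from the set's own null), ``fdr`` (pooled-null NES ratio estimator),
    ``size``, ``leading_edge`` (comma-joined genes).
    """

    table: pd.DataFrame
    n_perm: int
    weight: float


def _es_from_hits(weights: np.ndarray, hit_mask: np.ndarray) -> np.ndarray:
    """Signed extremum of the running sum for each row of ``hit_mask``.

    ``weights`` is |r|^p over the ranked list (length N); ``hit_mask`` is a
    boolean (m x N) matrix of hit indicators.  Hit increments are
    proportional to the weights, miss decrements uniform.
    """
    w = np.where(hit_mask, weights[None, :], 0.0)
    wsum = w.sum(axis=1, keepdims=True)
    wsum[wsum == 0] = 1.0
    n = hit_mask.shape[1]
    k = hit_mask.sum(axis=1, keepdims=True)
    miss = np.where(hit_mask, 0.0, 1.0) / np.maximum(n - k, 1)
    run = np.cumsum(w / wsum - miss, axis=1)
    imax = np.argmax(run, axis=1)
    imin = np.argmin(run, axis=1)
    top = run[np.arange(len(run)), imax]
    bot = run[np.arange(len(run)), imin]
    return np.where(top >= -bot, top, bot)


def enrichment_score(
    ranked: pd.DataFrame, gene_set, weight: float = 1.0
) -> tuple[float, list[str]]:
    """ES of one gene set on a ranked list, plus its leading-edge genes.

    The running sum increments by ``|r|^weight`` (normalised) at set members
    and decrements uniformly elsewhere; ES is the signed extremum.  The
    leading edge is the set members at or before a positive extremum (or at
    or after a negative one).
    """
    genes = ranked.index.to_numpy()
    r = ranked["r"].to_numpy(float)
    hit = np.isin(genes, list(gene_set))
    if hit.sum() == 0:
        raise ValueError("gene set does not overlap the ranked list")
    w = np.abs(r) ** weight
    es = float(_es_from_hits(w, hit[None, :])[0])
    wh = np.where(hit, w, 0.0)
    run = np.cumsum(wh / max(wh.sum(), 1e-300) - np.where(hit, 0.0, 1.0) / max(len(genes) - hit.sum(), 1))
    if es >= 0:
        pos = int(np.argmax(run))
        leading = genes[: pos + 1][hit[: pos + 1]]
    else:
        pos = int(np.argmin(run))
        leading = genes[pos:][hit[pos:]]
    return es, list(leading)


def preranked_gsea(
    ranked: pd.DataFrame,
    gene_sets: dict[str, list[str]],
    n_perm: int = 1000,
    weight: float = 1.0,
    min_size: int = 5,
    seed: int | None = None,
) -> EnrichmentResult:
    """Weighted-KS pre-ranked enrichment with a gene-label permutation null.

    For every qualifying set (overlap >= ``min_size``) the null is built by
    drawing ``n_perm`` random gene sets of the same size from the ranked
    list.  NES divides each ES by the mean |null ES| of matching sign.
    ``pval`` is the same-sign exceedance probability against the set's own
    null, with the +1 correction.  ``fdr`` follows the standard pre-ranked
    GSEA estimator: the fraction of pooled null NES at least as extreme,
    divided by the fraction of observed NES at least as extreme, capped at 1
    and made monotone.
    """
    rng = np.random.default_rng(seed)
    genes = ranked.index.to_numpy()
    n = len(genes)
    w = np.abs(ranked["r"].to_numpy(float)) ** weight

    names, ess, sizes, leads = [], [], [], []
    null_es: dict[str, np.ndarray] = {}
    for name, members in gene_sets.items():
        overlap = [g for g in set(members) if g in ranked.index]
        if len(overlap) < min_size:
            continue
        es, lead = enrichment_score(ranked, overlap, weight)
        k = len(overlap)
        null_hits = np.zeros((n_perm, n), dtype=bool)
        draws = np.argsort(rng.random((n_perm, n)), axis=1)[:, :k]
        np.put_along_axis(null_hits, draws, True, axis=1)
        null_es[name] = _es_from_hits(w, null_hits)
        names.append(name)
        ess.append(es)
        sizes.append(k)
        leads.append(",".join(lead))
    if not names:
        raise ValueError(f"no gene set overlaps the ranked list by >= {min_size} genes")

    es_arr = np.array(ess)
    nes = np.empty_like(es_arr)
    pvals = np.empty_like(es_arr)
    null_nes_all = []
    for i, name in enumerate(names):
        null = null_es[name]
        pos_mean = np.abs(null[null > 0]).mean() if (null > 0).any() else np.nan
        neg_mean = np.abs(null[null < 0]).mean() if (null < 0).any() else np.nan
        es = es_arr[i]
        same = null[null >= 0] if es >= 0 else null[null < 0]
        pvals[i] = (np.sum(np.abs(same) >= abs(es)) + 1.0) / (len(same) + 1.0)
        denom = pos_mean if es >= 0 else neg_mean
        nes[i] = es / denom if np.isfinite(denom) and denom > 0 else np.nan
        nn = np.where(
            null >= 0,
            null / pos_mean if np.isfinite(pos_mean) else np.nan,
            null / neg_mean if np.isfinite(neg_mean) else np.nan,
        )
        null_nes_all.append(nn[np.isfinite(nn)])
    pooled = np.concatenate(null_nes_all)

    fdr = np.ones_like(es_arr)
    finite = np.isfinite(nes)
    for sign in (1, -1):
        obs = nes[finite & ((nes >= 0) if sign > 0 else (nes < 0))]
        nullpool = pooled[(pooled >= 0) if sign > 0 else (pooled < 0)]
        for i in np.where(finite)[0]:
            v = nes[i]
            if (v >= 0) != (sign > 0):
                continue
            if len(nullpool) == 0 or len(obs) == 0:
                fdr[i] = 1.0
                continue
            frac_null = np.mean(np.abs(nullpool) >= abs(v))
            frac_obs = np.mean(np.abs(obs) >= abs(v))
            fdr[i] = min(1.0, frac_null / max(frac_obs, 1e-300))
    # enforce monotonicity of q along |NES| within each sign
    for sign in (1, -1):
        idx = np.where(finite & ((nes >= 0) if sign > 0 else (nes < 0)))[0]
        order = idx[np.argsort(-np.abs(nes[idx]))]
        best = 0.0
        for i in order:
            best = max(best, fdr[i])
            fdr[i] = best

    table = pd.DataFrame(
        {"es": es_arr, "nes": nes, "pval": pvals, "fdr": fdr, "size": sizes, "leading_edge": leads},
        index=pd.Index(names, name="gene_set"),
    ).sort_values("nes", ascending=False, kind="stable")
    return EnrichmentResult(table, n_perm=n_perm, weight=weight)
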