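"""uDEG calling and ligand-receptor cross-talk graphs.

A gene is *uniquely differentially expressed* (uDEG) in a cell type if, within
one histology, it is over-expressed in that type relative to the pooled other
sorted types (moderated-t FDR below threshold, at least a minimum fold
difference) and its mean log expression is strictly maximal in that type.
Intersecting uDEGs with a ligand-receptor catalog yields a directed cell-type
x cell-type cross-talk graph: an edge X -> Y counts catalog pairs whose
ligand is a uDEG of X and whose receptor is a uDEG of Y.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .cohort import LogExpression, ExpressionCohort, SORTED_POPULATIONS


# ---------------------------------------------------------------------------
# moderated two-sample t statistics
# ---------------------------------------------------------------------------

def _trigamma_inverse(y: float) -> float:
    # Newton iteration on x -> trigamma(x) = y (y > 0)
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def _squeeze_variances(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled inverse-chi-square prior to gene-wise variances.

    Returns (prior df d0, prior variance s0^2); d0 = inf means all gene
    variances are shrunk completely to s0^2.
    """
    ok = s2 > 0
    if ok.sum() < 2:
        return np.inf, float(max(s2.mean(), 1e-12))
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    e_var = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    if e_var <= 0:
        return np.inf, float(np.exp(e_mean))
    d0 = 2.0 * _trigamma_inverse(e_var)
    s0_2 = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_2


def differential_expression(
    log_expr: LogExpression, group_a, group_b
) -> pd.DataFrame:
    """Moderated two-sample t-test per gene, group A vs group B.

    Gene-wise variances are shrunk toward a common prior fitted across genes
    (empirical Bayes), so zero-variance genes do not blow up the statistic.
    Fold-change is the difference of group means on the ``log2(1+TPM)``
    scale (positive = higher in A).  Returns a frame with columns
    ``t``, ``log2_fc``, ``mean_a``, ``mean_b``, ``pval``, ``fdr``.
    """
    group_a, group_b = pd.Index(group_a), pd.Index(group_b)
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least two samples")
    A = log_expr.values[group_a].to_numpy(float)
    B = log_expr.values[group_b].to_numpy(float)
    na, nb = A.shape[1], B.shape[1]
    ma, mb = A.mean(axis=1), B.mean(axis=1)
    df = na + nb - 2
    ss = ((A - ma[:, None]) ** 2).sum(axis=1) + ((B - mb[:, None]) ** 2).sum(axis=1)
    s2 = ss / df
    d0, s0_2 = _squeeze_variances(s2, df)
    if np.isinf(d0):
        s2_post, df_total = np.full_like(s2, s0_2), 1e12
    else:
        s2_post = (d0 * s0_2 + df * s2) / (d0 + df)
        df_total = df + d0
    se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, (ma - mb) / se, 0.0)
    pval = 2.0 * stats.t.sf(np.abs(t), df_total)
    fdr = multipletests(pval, method="fdr_bh")[1]
    return pd.DataFrame(
        {"t": t, "log2_fc": ma - mb, "mean_a": ma, "mean_b": mb, "pval": pval, "fdr": fdr},
        index=log_expr.genes,
    )


# ---------------------------------------------------------------------------
# ligand-receptor catalogs
# ---------------------------------------------------------------------------

@dataclass
class LigandReceptorCatalog:
    """Curated (ligand, receptor) gene pairs with optional annotations.

    ``pairs`` has columns ``ligand``, ``receptor``, ``source``; duplicate
    (ligand, receptor) pairs are rejected.  ``gene_annotations`` may carry
    per-gene secreted/surface flags and prognostic meta-Z scores, and is
    passed through to outputs untouched.
    """

    pairs: pd.DataFrame
    gene_annotations: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        required = {"ligand", "receptor"}
        if not required.issubset(self.pairs.columns):
            raise ValueError("catalog pairs need 'ligand' and 'receptor' columns")
        if "source" not in self.pairs.columns:
            self.pairs = self.pairs.assign(source="custom")
        if (self.pairs["ligand"].str.len() == 0).any() or (self.pairs["receptor"].str.len() == 0).any():
            raise ValueError("empty gene symbol in catalog")
        if self.pairs.duplicated(["ligand", "receptor"]).any():
            raise ValueError("duplicate (ligand, receptor) pairs in catalog")
        self.pairs = self.pairs.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.pairs)

    @classmethod
    def from_pairs(cls, pairs, source: str = "custom") -> "LigandReceptorCatalog":
        df = pd.DataFrame(pairs, columns=["ligand", "receptor"]).astype(str)
        return cls(df.assign(source=source))

    @classmethod
    def read_fantom5(cls, path: str) -> "LigandReceptorCatalog":
        """Two-column TSV (ligand, receptor), optional header detected."""
        df = pd.read_csv(path, sep="\t", dtype=str)
        if df.columns[0].lower() not in {"ligand", "from", "ligand.approvedsymbol"}:
            df = pd.read_csv(path, sep="\t", header=None, dtype=str)
        df = df.iloc[:, :2]
        df.columns = ["ligand", "receptor"]
        df = df.drop_duplicates(["ligand", "receptor"])
        return cls(df.assign(source="FANTOM5"))

    @classmethod
    def read_cellphonedb(cls, path: str) -> "LigandReceptorCatalog":
        """CellphoneDB-style TSV; complexes are flattened to member-gene pairs.

        Expects columns ``partner_a``/``partner_b`` (or first two columns)
        whose entries may be single symbols or complexes joined by ``_`` or
        ``+``; each member combination becomes one gene-level pair tagged
        with source ``CellphoneDB``.
        """
        df = pd.read_csv(path, sep="\t", dtype=str)
        cols = [c for c in ("partner_a", "partner_b") if c in df.columns] or list(df.columns[:2])
        rows = []
        for a, b in df[cols].itertuples(index=False):
            for ga in str(a).replace("+", "_").split("_"):
                for gb in str(b).replace("+", "_").split("_"):
                    if ga and gb:
                        rows.append((ga, gb))
        out = pd.DataFrame(sorted(set(rows)), columns=["ligand", "receptor"])
        return cls(out.assign(source="CellphoneDB"))

    def write_tsv(self, path: str) -> None:
        self.pairs.to_csv(path, sep="\t", index=False)


def read_gene_list(path: str) -> list[str]:
    """One gene symbol per line; blank lines and '#' comments ignored."""
    with open(path) as fh:
        return [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]


# ---------------------------------------------------------------------------
# uDEG calling
# ---------------------------------------------------------------------------

@dataclass
class UDEGTable:
    """Per (histology, cell type) uDEG sets with statistics.

    ``table`` columns: ``histology``, ``cell_type``, ``gene``, ``fdr``,
    ``log2_fc``, plus ``mean_<type>`` log-expression columns.
    """

    table: pd.DataFrame
    fdr_threshold: float
    min_fold: float

    def genes(self, cell_type: str, histology: str | None = None) -> set[str]:
        t = self.table
        sel = t["cell_type"] == cell_type
        if histology is not None:
            sel &= t["histology"] == histology
        return set(t.loc[sel, "gene"])


def call_udegs(
    log_expr: LogExpression,
    histology: str,
    fdr: float = 0.01,
    min_fold: float = 2.0,
    populations=SORTED_POPULATIONS,
) -> UDEGTable:
    """Call uniquely differentially expressed genes within one histology.

    For each sorted cell type the test is one-vs-rest (rest = pooled other
    sorted populations; bulk excluded).  A gene qualifies when FDR < ``fdr``,
    log2 fold-change >= log2(``min_fold``), and its mean log expression in
    the type strictly exceeds the mean in every other type — the strict
    maximum enforces uniqueness, so uDEG sets of different types within a
    histology are disjoint.
    """
    sample_sets = {}
    for pop in populations:
        cols = log_expr.samples_of(pop, histology)
        if len(cols) < 2:
            raise ValueError(f"population {pop!r} has <2 samples in histology {histology!r}")
        sample_sets[pop] = cols

    type_means = pd.DataFrame(
        {pop: log_expr.values[cols].mean(axis=1) for pop, cols in sample_sets.items()}
    )
    rows = []
    lfc_min = np.log2(min_fold)
    for pop in populations:
        rest = [c for p in populations if p != pop for c in sample_sets[p]]
        de = differential_expression(log_expr, sample_sets[pop], rest)
        others = [p for p in populations if p != pop]
        strict_max = (type_means[pop].to_numpy()[:, None] > type_means[others].to_numpy()).all(axis=1)
        hit = (de["fdr"].to_numpy() < fdr) & (de["log2_fc"].to_numpy() >= lfc_min) & strict_max
        for g in log_expr.genes[hit]:
            row = {
                "histology": histology,
                "cell_type": pop,
                "gene": g,
                "fdr": de.at[g, "fdr"],
                "log2_fc": de.at[g, "log2_fc"],
            }
            row.update({f"mean_{p}": type_means.at[g, p] for p in populations})
            rows.append(row)
    cols = ["histology", "cell_type", "gene", "fdr", "log2_fc"] + [f"mean_{p}" for p in populations]
    table = pd.DataFrame(rows, columns=cols)
    return UDEGTable(table, fdr_threshold=fdr, min_fold=min_fold)


# ---------------------------------------------------------------------------
# expression breadth patterns
# ---------------------------------------------------------------------------

@dataclass
class BreadthPatternMatrix:
    """5x5 tally of (populations expressing ligand) x (expressing receptor).

    Breadth runs 0..4 over the sorted populations; ``chi2``/``pval`` test
    the 16 cells with both breadths in 1..4 against uniformity.
    """

    counts: pd.DataFrame  # 5x5, rows = ligand breadth, cols = receptor breadth
    threshold_tpm: float
    chi2: float
    pval: float


def expression_breadth(
    cohort: ExpressionCohort,
    catalog: LigandReceptorCatalog,
    histology: str | None = None,
    threshold_tpm: float = 10.0,
    populations=SORTED_POPULATIONS,
) -> BreadthPatternMatrix:
    """Tally how many populations express each catalog ligand and receptor.

    A population "expresses" a gene when its mean TPM (over samples of the
    population, within ``histology`` if given) exceeds ``threshold_tpm``.
    Pairs with either gene absent from the matrix are skipped; the
    goodness-of-fit test covers only pairs expressed somewhere on both axes
    (breadths 1..4).
    """
    means = {}
    for pop in populations:
        cols = cohort.samples_of(pop, histology)
        if len(cols) == 0:
            raise ValueError(f"no samples for population {pop!r}")
        means[pop] = cohort.tpm[cols].mean(axis=1)
    expressed = pd.DataFrame(means) > threshold_tpm  # genes x populations

    present = set(cohort.genes)
    pairs = catalog.pairs
    usable = pairs["ligand"].isin(present) & pairs["receptor"].isin(present)
    if not usable.any():
        raise ValueError("no catalog pair has both genes in the expression matrix")
    breadth = expressed.sum(axis=1)
    lig_b = breadth[pairs.loc[usable, "ligand"]].to_numpy()
    rec_b = breadth[pairs.loc[usable, "receptor"]].to_numpy()
    n_pop = len(populations)
    counts = np.zeros((n_pop + 1, n_pop + 1), dtype=int)
    np.add.at(counts, (lig_b, rec_b), 1)
    inner = counts[1:, 1:].ravel()
    if inner.sum() > 0:
        chi2, pval = stats.chisquare(inner)
    else:
        chi2, pval = 0.0, 1.0
    idx = pd.RangeIndex(n_pop + 1, name="ligand_breadth")
    cols = pd.RangeIndex(n_pop + 1, name="receptor_breadth")
    return BreadthPatternMatrix(
        pd.DataFrame(counts, index=idx, columns=cols),
        threshold_tpm=threshold_tpm,
        chi2=float(chi2),
        pval=float(pval),
    )


# ---------------------------------------------------------------------------
# cross-talk graph
# ---------------------------------------------------------------------------

@dataclass
class CrossTalkGraph:
    """Directed cell-type x cell-type counts of uDEG ligand-receptor pairs."""

    counts: pd.DataFrame  # source type x target type
    edges: dict = field(default_factory=dict)  # (X, Y) -> list of (ligand, receptor)

    def __post_init__(self) -> None:
        for (x, y), pairs in self.edges.items():
            if self.counts.at[x, y] != len(pairs):
                raise ValueError(f"edge count mismatch for {x}->{y}")

    def write(self, outdir: str, prefix: str = "crosstalk") -> None:
        os.makedirs(outdir, exist_ok=True)
        rows = [
            {"source": x, "target": y, "ligand": l, "receptor": r}
            for (x, y), pairs in self.edges.items()
            for l, r in pairs
        ]
        pd.DataFrame(rows, columns=["source", "target", "ligand", "receptor"]).to_csv(
            os.path.join(outdir, f"{prefix}_edges.tsv"), sep="\t", index=False
        )
        payload = {
            "counts": {x: self.counts.loc[x].to_dict() for x in self.counts.index},
        }
        with open(os.path.join(outdir, f"{prefix}.json"), "w") as fh:
            json.dump(payload, fh, indent=1)


def build_crosstalk_graph(
    udegs: UDEGTable,
    catalog: LigandReceptorCatalog,
    histology: str,
    ligand_filter=None,
    receptor_filter=None,
    populations=SORTED_POPULATIONS,
) -> CrossTalkGraph:
    """Count catalog pairs whose ligand/receptor are uDEGs of types X/Y.

    ``ligand_filter`` (e.g. secreted genes) and ``receptor_filter`` (e.g.
    surface genes) restrict which uDEGs may act as ligand or receptor; pass
    ``None`` for no restriction.  Autocrine edges (X = Y) are allowed.
    """
    lig_ok = (lambda g: True) if ligand_filter is None else set(ligand_filter).__contains__
    rec_ok = (lambda g: True) if receptor_filter is None else set(receptor_filter).__contains__
    udeg_of = {pop: udegs.genes(pop, histology) for pop in populations}

    counts = pd.DataFrame(0, index=list(populations), columns=list(populations))
    edges: dict[tuple[str, str], list[tuple[str, str]]] = {}
    for lig, rec in catalog.pairs[["ligand", "receptor"]].itertuples(index=False):
        if not (lig_ok(lig) and rec_ok(rec)):
            continue
        src = [p for p in populations if lig in udeg_of[p]]
        dst = [p for p in populations if rec in udeg_of[p]]
        for x in src:
            for y in dst:
                counts.at[x, y] += 1
                edges.setdefault((x, y), []).append((lig, rec))
    return CrossTalkGraph(counts, edges)
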