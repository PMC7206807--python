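# ltmi

Cell-type cross-talk analysis for sorted tumor expression cohorts.

`ltmi` reconstructs a tumor-microenvironment interactome from RNA-seq of
flow-sorted cell populations — malignant, endothelial, immune and
fibroblast — plus matched bulk tissue. Sorting resolves which cell type
expresses which gene, something bulk profiles average away; `ltmi` turns
that resolution into:

- **Expression processing** — TPM renormalization (mitochondrial rRNA
  removal), low-expression filtering, log transform, and empirical-Bayes
  batch correction.
- **Deconvolution** — signature matrices of cell-type marker genes and
  nonnegative-least-squares inference of bulk mixing fractions, plus
  bulk reconstruction to reveal populations the sorting scheme misses.
- **Interactome building** — uniquely differentially expressed genes
  (uDEGs: over-expressed in exactly one population), ligand/receptor
  expression-breadth patterns, and directed cell-type cross-talk graphs
  from ligand-receptor catalogs (FANTOM5 and CellphoneDB formats
  supported).
- **Cross-population coupling** — correlating a ligand in one
  compartment against every gene of another compartment across patients,
  with pre-ranked gene-set enrichment to detect coordinated target
  programs.
- **Slide analysis** — NMF stain unmixing, Laplacian-of-Gaussian nuclei
  detection, marker-positivity calling, and permutation tests for
  spatial proximity of marker-positive stroma to tumor nests.
- **Prognostics** — Kaplan-Meier curves, multi-group log-rank tests,
  optimal-cutpoint scans (flagged for multiple testing), Cox
  proportional-hazards fits, and ordinal mast-cell infiltration scoring.

Every stage is paired with a synthetic-data generator that plants the
structure the stage is supposed to find (markers, couplings, mixing
fractions, spatially biased marker-positive cells, survival effects) and
returns the ground truth, so the whole pipeline is testable end to end
without any external data.

## Worked example

Detect a planted fibroblast-ligand → malignant-program coupling
(`examples/04_coupling_gsea.py`):

```python
import numpy as np
import ltmi

spec = ltmi.default_cohort_spec(seed=7)
cohort, truth = ltmi.generate_cohort(spec)
coupling = truth.true_coupling[0]

log = ltmi.log_transform(cohort)
ranked = ltmi.cross_population_correlation(
    log, coupling["ligand"], coupling["source_type"], coupling["target_type"]
)

rng = np.random.default_rng(0)
eligible = ranked.index.difference(list(coupling["target_genes"]) + [coupling["ligand"]])
sets = {"planted_program": list(coupling["target_genes"])}
for j in range(50):
    sets[f"decoy{j:02d}"] = list(rng.choice(eligible.to_numpy(), 30, replace=False))

res = ltmi.preranked_gsea(ranked, sets, n_perm=1000, seed=0)
print(res.table.sort_values("fdr").head(3)[["es", "nes", "pval", "fdr"]])
```

Output:

```
planted coupling: G0100 (fibroblast) -> 30-gene program (malignant)
mean correlation of program genes: 0.725
mean correlation of other genes:   -0.107

top enrichment results:
                       es       nes      pval       fdr
gene_set
planted_program  0.960207  4.084751  0.004566  0.000000
decoy39          0.297267  1.219427  0.163793  0.789354
decoy33         -0.454912 -1.559766  0.022585  0.813074

decoy sets with FDR < 0.05: 0/50
```

And the slide pipeline (`examples/05_slide_analysis.py`), on a rendered
two-stain image with proximity-biased marker-positive stroma:

```
slide: 256x256 px, 51 planted nuclei
stain recovery r: hematoxylin 0.990, marker 0.986
nuclei: 51 detected, precision 1.000, recall 1.000
median nearest-tumor distance, positive vs negative: 30.7 vs 47.9 px
Mann-Whitney p = 0.0002
permutation test (B = 100000): p = 0.00021
```

## Examples

Narrative scripts in `examples/`, each runnable standalone:

| script | covers |
| --- | --- |
| `01_cohort_preprocessing.py` | generation, renormalization, filtering, batch correction |
| `02_deconvolution.py` | signature matrix, NNLS fractions, bulk reconstruction |
| `03_interactome.py` | uDEG calling, expression breadth, cross-talk graph |
| `04_coupling_gsea.py` | cross-population correlation, pre-ranked GSEA |
| `05_slide_analysis.py` | stain unmixing, nuclei detection, proximity testing |
| `06_survival.py` | mast-cell bins, KM, log-rank, cutpoint scan, Cox |

Methods, model assumptions and numerical choices are documented in
`docs/methods.md`.

## Testing and reproduction

Run the full test suite (unit tests, hand-worked oracles, statistical
calibration checks, and the end-to-end acceptance criteria in
`tests/test_acceptance.py`):

```bash
pytest -q
```

Recompute the headline planted-truth recovery and calibration numbers on
freshly generated data:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

This reports, among others: the permutation proximity p on a
strictly-separated slide (≤ 1e-5 at 10^5 resamples), noiseless and noisy
deconvolution errors (max error ~2e-16; fraction RMSE ~0.016 at log-sd
0.25 over 100 samples), uDEG sensitivity and false-call rate (1.0 and 0.0
at FDR 1%), the planted coupling's NES/FDR against 50 decoys, nuclei
detection precision/recall at SNR 5 (1.0/1.0), and permutation/log-rank
type-I error over 200 null replicates (0.05 and 0.07 at seed 1). All
sub-seeds derive from `--seed`, so a run is reproducible from one
integer.
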