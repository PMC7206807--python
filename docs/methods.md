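# Methods

This document records the statistical models, default parameters and
numerical choices behind `ltmi`, along with the scope of the synthetic
generators and known limitations.

## Data model

An `ExpressionCohort` is a genes × samples TPM matrix (columns sum to
10^6) with per-sample metadata: `patient`, `population` (one of
`malignant`, `endothelial`, `immune`, `fibroblast`, or `bulk`),
`histology` (`adenocarcinoma` or `SCC`), `batch`, and a `replicate` flag.
`LogExpression` holds the same layout on the log2(1+TPM) scale; all
differential and correlation statistics operate there.

## Synthetic generators

The generators exist so every analysis stage can be validated against a
known ground truth; they are not calibrated to any particular real
dataset.

**Cohort generator** (`generate_cohort`). Baseline log2 expression per
gene is uniform on [1, 9] (TPM ≈ 2–512), shared across cell types.
Structure is planted on top:

- *Markers*: per cell type, a disjoint set of genes elevated by a log2
  fold-change ≥ 1 (default 2, i.e. 4-fold). These are the true uDEGs.
- *Coupling*: a ligand gene in a source compartment receives a per-patient
  N(0, 1) log2 deviation; each gene of a target program in another
  compartment moves by `slope` times that deviation. The ligand is also
  elevated 4-fold in its own compartment so it doubles as a marker.
- *Mitochondrial rRNA*: `MT-RNR1`/`MT-RNR2` at log2 ≈ 16, reproducing the
  large library-mass share these genes take in tissue RNA-seq.

Bulk TPM per patient is a convex mixture of that patient's clean sorted
TPM vectors with Dirichlet(α = 2) weights (the recorded true fractions).
Measurement noise is Gaussian on the log2(1+TPM) scale (default sd 0.25,
log-normal in TPM space); batch effects are additive per-(batch, gene)
N(0, `offset_sd`) shifts on the same scale, with samples assigned to
batches round-robin. Every final column is renormalised to 10^6.

**Tissue generator** (`generate_tissue`). Tumor nuclei are packed into
disk-shaped nests (rejection sampling with a minimum center separation
and an area-based packing feasibility check); stromal nuclei are uniform
outside the nests. A fraction of stromal nuclei carry the marker; with
`proximity_bias > 0`, positives are drawn by the Gumbel top-k trick with
log-weights proportional to −bias · d/`decay_scale`, where d is the
distance to the nearest tumor *nucleus* — a very large bias selects
exactly the nearest stromal nuclei. Nuclei render as Gaussian blobs
(sd 6) in a hematoxylin-like stain; marker-positive cells additionally
get a cytoplasmic marker blob (sd 9) displaced 8 px from the nucleus.
The default rendering is a linear mixture of the two stain RGB vectors
scaled to peak 0.95 plus N(0, 0.01) pixel noise; `mode="beer-lambert"`
renders transmitted light exp(−concentration × stain) on a white
background for robustness experiments. The ground truth records the
nucleus table and both true concentration maps.

**Survival generator** (`generate_survival`). Exponential event times
with hazard `baseline_hazard · exp(Σ β·x)`, covariates N(0, 1) or
Bernoulli(0.5), independent exponential censoring tuned to a target
baseline censoring rate.

## Preprocessing

- `renormalize_tpm` drops an exclusion list (default `MT-RNR1`,
  `MT-RNR2`) and rescales every column to 10^6.
- `filter_low_expression` keeps genes whose mean TPM reaches a threshold
  in at least one (population × histology) group.
- `batch_correct` removes per-batch location/scale effects with an
  empirical-Bayes adjustment in the ComBat family: genes are standardised
  given a covariate design (default: population and histology
  indicators), per-batch additive and multiplicative effects are shrunk
  toward their across-gene means (normal prior on locations,
  inverse-gamma on scales fitted by moments), and the data are
  reassembled. With a single batch the input is returned unchanged —
  there is nothing to correct, and a no-op pass through the variance
  rescaling would still perturb values. Designs in which batch is
  confounded with a covariate column, or a batch has fewer than two
  samples, raise.

## Deconvolution

`build_signature_matrix` selects one-vs-rest marker genes per sorted
population by moderated t (see below) at FDR < 0.01 with positive
fold-change, ordered by fold-change, and assembles mean-TPM profiles for
each candidate marker count in a grid, keeping the matrix with the
smallest condition number.

`deconvolve` solves nonnegative least squares per bulk sample against the
signature and renormalises the coefficients to sum to one. By default
each gene row is weighted by 1/(mean signature TPM) so the fit works on
relative errors; TPM-scale noise is roughly multiplicative, and without
the weighting a handful of high-abundance genes dominates the objective.
Exact mixtures are recovered identically with and without weighting.
This NNLS fit is a transparent surrogate for SVR-based tools such as
CIBERSORT: same linear mixture model and marker restriction, different
loss, so absolute agreement with those tools is not expected.

`reconstruct_bulk` mixes replicate-averaged sorted TPM profiles by the
inferred fractions and renormalises; `rank_bulk_minus_reconstructed`
ranks genes by mean log2(1+TPM) bulk-minus-reconstruction difference,
which surfaces populations missed by the sorting scheme.

## Differential expression and the interactome

`differential_expression` is a moderated t-test: per-gene pooled
variances are shrunk toward a global prior fitted by matching the first
two moments of the log variances to a scaled F distribution (trigamma
inversion), and p-values use the t distribution with augmented degrees of
freedom. FDR is Benjamini-Hochberg.

`call_udegs` runs one-vs-rest per population within one histology and
requires FDR < 0.01, log2 fold-change ≥ 1, and the population's mean
strictly exceeding every other population's mean. The strict maximum
makes uDEG sets disjoint by construction.

`expression_breadth` counts, for each catalog ligand and receptor, how
many of the four sorted populations express the gene (mean TPM above a
threshold), tallies a 5×5 pattern matrix, and tests the 16 cells with
both breadths ≥ 1 against uniformity with a chi-square goodness-of-fit.

`build_crosstalk_graph` counts catalog pairs whose ligand is a uDEG of
type X and receptor a uDEG of type Y (optionally restricted to
secreted/surface gene lists), yielding a directed cell-type graph
including autocrine edges.

## Cross-population correlation and enrichment

`cross_population_correlation` averages replicate samples per patient on
the log scale, matches patients present in both compartments, and
correlates one source-compartment gene against every target-compartment
gene (Pearson on log2(1+TPM), or Spearman via ranks).

`preranked_gsea` computes the weighted Kolmogorov-Smirnov running-sum
enrichment score (hit increments proportional to |r|^weight, default
weight 1) and builds each set's null by re-drawing random gene sets of
the same size from the ranked list (gene-label permutation). NES divides
ES by the mean |null ES| of matching sign; the p-value is the same-sign
exceedance with the +1 correction. FDR follows the standard pre-ranked
GSEA estimator — fraction of pooled null NES at least as extreme divided
by the fraction of observed NES at least as extreme, capped at 1 and made
monotone in |NES| within each sign. A Benjamini-Hochberg adjustment is
deliberately *not* used here: with K sets and B permutations the smallest
attainable permutation p is 1/(B+1), so BH's smallest adjusted value is
K/(B+1), which for realistic K cannot certify small FDRs; the pooled-null
estimator can.

## Slide analysis

`separate_stains` fits a rank-2 non-negative matrix factorization to the
pixels × 3 RGB matrix. The basis is fitted on bright foreground pixels
only (max channel > 0.3 by default): dim pixels sit near the color-space
origin where sensor noise dominates the chromatic signal, and including
them drags the two basis vectors toward each other, bleeding one stain
into the other's concentration map. Concentrations for *all* pixels are
then solved against the fitted basis by pseudo-inverse and clipped at
zero; channels are labeled by cosine similarity to a reference
hematoxylin RGB direction and rescaled by their 99th percentile.
Single-stain images are detected before factorization: if the second
singular value of the foreground pixel matrix is below 0.02 times the
first, the pixels span one color direction and a rank-2 factorization
would split that stain arbitrarily; this raises unless
`allow_single_stain` is set (measured ratios: ~1e-16 for a pure
single-stain image vs ~0.19 for two-stain tissue, so the threshold sits
in a wide gap).

`detect_nuclei` runs a Laplacian-of-Gaussian filter at scale 6 px and
keeps local minima within a 6 px non-maximum-suppression radius whose
|response| exceeds a floor (default 0.004, calibrated so unit-amplitude
sd-6 blobs at ~0.0147 clear it while smoothed background noise does not).
The LoG uses zero padding at the image border: outside the field of view
there is no stain, and reflect-style padding mirrors near-edge blobs onto
the boundary, displacing their response minima.

`classify_marker` Gaussian-smooths the marker map (sd 6) and calls a
nucleus positive when the smoothed value at its center strictly exceeds
0.1. `assign_classes` labels nuclei tumor/stroma by a region mask.

`proximity_analysis` computes each stromal nucleus's distance to the
nearest tumor nucleus and compares positive vs negative distances with a
Mann-Whitney U test. `proximity_permutation_test` permutes positivity
labels over the stromal nuclei (preserving the positive count) and uses
T = median nearest-tumor distance of the positives; the empirical p is
(#{T_perm ≤ T_obs} + 1)/(B + 1), which is never zero and never exceeds 1.

## Prognostics

`bin_mast_cell_counts` maps pathologist counts to ordinal categories:
0 → none, 1–9 → low, 10–30 → medium, ≥ 31 → high; 31 goes to "high" so
the bins partition the nonnegative integers exactly.

`kaplan_meier` wraps the product-limit estimator (lifelines).
`logrank_test` implements the multi-group observed-minus-expected
statistic with aggregated risk sets at tied event times and a chi-square
reference on (groups − 1) degrees of freedom; it matches lifelines'
`multivariate_logrank_test` to numerical precision (cross-checked in the
tests). `optimal_cutpoint` scans unique covariate values inside an inner
quantile range for the dichotomization minimizing the log-rank p; the
result always carries `multiple_testing_caution=True` and the number of
cutpoints scanned, because a scan-minimized p is optimistically biased.
`cox_likelihood_ratio` fits a single-covariate proportional-hazards model
by Newton iteration on the Breslow partial likelihood (covariate
standardized internally, coefficient reported in original units) and
reports the likelihood-ratio test; divergence (e.g. complete separation)
raises with diagnostics rather than returning a huge coefficient.

## Limitations

- The generators use idealized noise (Gaussian on the log scale,
  independent across genes) and uniform baseline expression; they do not
  model count overdispersion, gene-gene correlation beyond the planted
  coupling, or realistic marker co-expression structure.
- The NNLS deconvolution assumes the sorted populations span the bulk
  mixture; populations absent from the signature are absorbed into the
  others' fractions.
- Stain unmixing assumes a linear two-stain mixing model; strongly
  saturated or optically dense slides violate it (the Beer-Lambert
  rendering mode exists to probe this).
- The marker-positivity threshold operates on smoothed cytoplasmic
  signal; at nucleus separations below roughly three blob sd, a
  positive cell's halo can genuinely exceed the threshold at a
  neighboring negative nucleus, a physical resolution limit rather than
  an unmixing artifact.
- The cutpoint scan reports a naive minimal p by design; any downstream
  use needs permutation or split-sample correction.
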