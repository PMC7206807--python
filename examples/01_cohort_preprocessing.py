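"""Generate a sorted + bulk cohort and walk it through preprocessing.

The generator plants per-cell-type marker genes, a ligand -> program
coupling, batch offsets and log-normal measurement noise, and returns the
ground truth alongside the data.  Preprocessing renormalizes TPM after
dropping mitochondrial rRNA, filters weakly expressed genes, moves to
log2(1+TPM), and removes the batch structure with an empirical-Bayes
location/scale adjustment.
"""

import numpy as np

import ltmi

spec = ltmi.default_cohort_spec(seed=7)
cohort, truth = ltmi.generate_cohort(spec)
print(f"cohort: {len(cohort.genes)} genes x {len(cohort.samples)} samples")
print(cohort.sample_meta["population"].value_counts().to_string())

# MT-RNR1/2 dominate library mass in tissue RNA-seq; drop and renormalize
renorm = ltmi.renormalize_tpm(cohort)
share = cohort.tpm.loc[["MT-RNR1", "MT-RNR2"]].sum(axis=0).mean() / 1e6
print(f"\nmitochondrial rRNA share before renormalization: {share:.1%}")

kept = ltmi.filter_low_expression(renorm, threshold=10.0)
print(f"expressed genes (mean TPM > 10 in some population): {len(kept.genes)}/{len(renorm.genes)}")

log = ltmi.log_transform(kept)
corrected = ltmi.batch_correct(log)

# the planted batch offset shows up as a per-gene mean gap between batches
meta = log.sample_meta
b0 = log.values.loc[:, (meta["batch"] == "B0").to_numpy()].mean(axis=1)
b1 = log.values.loc[:, (meta["batch"] == "B1").to_numpy()].mean(axis=1)
c0 = corrected.values.loc[:, (meta["batch"] == "B0").to_numpy()].mean(axis=1)
c1 = corrected.values.loc[:, (meta["batch"] == "B1").to_numpy()].mean(axis=1)
print(f"mean |batch gap| before correction: {np.abs(b0 - b1).mean():.3f} log2 units")
print(f"mean |batch gap| after  correction: {np.abs(c0 - c1).mean():.3f} log2 units")
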