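"""Simulate a pooled-GBS trial and estimate allele frequencies.

Builds a small synthetic trial (two ryegrass cultivars, 7 seed compositions
x 2 replicates x 4 years, 40-plant pools), estimates per-sample alternative-
allele frequencies with the grid posterior, applies the filter cascade, and
reports how well the estimates track the true pool frequencies.
"""

import swardpop as sp

design = sp.full_design()
cfg = sp.SimulationConfig(n_loci=5000, seed=7, depth_mean=100)
trial = sp.simulate_trial(cfg)
print(f"simulated {trial.counts.n_loci} loci x {trial.counts.n_samples} "
      "population samples")

aaf, thetas = sp.estimate_aaf_matrix(trial.counts)
print(f"theta (sample c1A_y1): {thetas['c1A_y1'].theta:.4f} "
      "(Watterson-style prior scale for that pool)")

filt, report = sp.filter_cascade(trial.counts, aaf,
                                 sp.FilterConfig.pool_preset())
print("filter cascade:", " -> ".join(f"{s}:{n}" for s, n in report.steps))

agree = sp.compare_aaf(filt.aaf.ravel(),
                       trial.truth.sample_aaf[report.kept_indices].ravel())
print(f"estimated vs true pool AAF over {agree.n_snps} locus-samples: "
      f"r = {agree.pearson_r:.3f}, median |dev| = {agree.median_deviation:.3f}")
print("r near 1 and median deviation of a few percent mean the pooled "
      "read counts recover the 40-plant allele frequencies accurately.")
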