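"""Track genetic diversity and cultivar abundance across four years.

Computes mean expected heterozygosity per sample, tests its structure with
the sequential ANOVA, and tracks the two cultivars' proportions in mixed
plots through cultivar-private SNPs.
"""

import swardpop as sp

design = sp.full_design()
traj = sp.TrajectoryModel(year_logit_offsets=(0.4, -0.4, -0.4, 0.4))
cfg = sp.SimulationConfig(n_loci=5000, seed=11, trajectory=traj)
trial = sp.simulate_trial(cfg)
aaf, _ = sp.estimate_aaf_matrix(trial.counts)
filt, _ = sp.filter_cascade(trial.counts, aaf, sp.FilterConfig.pool_preset())

div = sp.heterozygosity(filt)
by = {c: div.mean_he[[s.sample_id for s in design
                      if s.ryegrass_content == c]].mean()
      for c in ("Merks", "Meloni", "both")}
print("mean He by ryegrass content:",
      {k: round(v, 3) for k, v in by.items()})
print("mixture plots are the most diverse: mixing differentiated cultivars "
      "adds heterozygosity at every locus where they differ.")

print(sp.anova_mean_he(div, design).round(5).to_string(index=False))
print("the composition term dominates; comp x year captures temporal "
      "diversity change consistent across replicate plots.")

pca = sp.pca_aaf(filt, design)
print(f"PC1 explains {100 * pca.variance_explained[0]:.1f}% of AAF variance "
      "(cultivar differentiation).")

pm = sp.private_snps(filt, design, "Merks")
po = sp.private_snps(filt, design, "Meloni")
ab = sp.cultivar_abundance(filt, pm, po, design)
mixed = ab[ab.seed_composition.isin([5, 6, 7])]
print("estimated Merks proportion in mixed plots by year:")
print(mixed.groupby("year")["w_merks"].mean().round(3).to_string())
print("the non-monotone trajectory (high years 1 and 4) matches the "
      "simulated cultivar dynamics.")
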