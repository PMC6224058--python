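# swardpop

Population-genetic and yield analysis of sown grassland swards genotyped by
pooled GBS (genotyping-by-sequencing of pooled tissue), built around a
multi-year field-trial design: perennial ryegrass cultivars sown alone or
with red clover, seven seed compositions in two replicate plots, sampled
once a year for four years (40 plants per plot-year, pooled).

The package is a library for people who study temporal genetic dynamics in
cultivated populations from pooled sequencing: breeders and population
geneticists asking *which cultivar is winning in a mixture, is diversity
being lost, and is any locus under selection* — plus the agronomic side:
*does the species/cultivar composition affect yield?*

## What it computes

**Pooled allele frequencies.** For each locus and pooled sample with `r`
reference and `a` alternative reads, a discrete posterior over the frequency
grid `f_k = k/n` (`n = 2 × pool size` chromosomes) with likelihood
`a ~ Binomial(r + a, f(1−ε) + (1−f)ε)` and a folded informative prior whose
interior mass is `min(1, θ·a_n)` (shape `1/f + 1/(1−f)`), the remainder on
the fixed boundaries. `θ` is a simplified Watterson estimator per sample
(segregating fraction over the harmonic number `a_n = Σ_{i<n} 1/i`, minor
allele count ≥ 3 at depth ≥ 30). Estimates are snapped to 0 when
`1 − p(0) < 0.9` and to 1 when `p(1) > 0.9`.

**SNP filtering.** An auditable cascade: per-cell depth ≥ 30; per-locus
total-depth ceiling (repeat guard); missing-data ceiling; multi-allelic
removal; mean-AAF band `[0.10, 0.90]` across samples (removes
non-reproducible low-frequency error calls).

**Diversity and cultivar dynamics.** Expected heterozygosity
`He = 2·AAF·(1−AAF)` per locus and sample, mean He per sample, and its
sequential ANOVA over seed composition `S`, `S×replicate` and `S×year`
(df 6/7/21 with 21 residual on the full design). PCA of the centered,
unscaled AAF matrix separates cultivars; cultivar-private SNPs (polymorphic
only where a cultivar was sown) give per-sample abundance estimates
`ŵ = mean private AAF / pure-plot mean`.

**Selection scan.** Per SNP, sequential variance decomposition
`AAF ~ PC1 + S + S×R + S×Y + ε`; the statistic is
`MSS(S×Y) / MSS(residual)` — temporal change consistent across replicate
plots relative to plot-specific change. The null is fitted empirically by
ML (log-normal, chi-square, F, gamma; AIC selection), p-values are
upper-tail probabilities, outliers are Benjamini–Hochberg calls, and a KS
uniformity diagnostic reports fit adequacy.

**Yield models.** DMW (t/ha) arithmetic, botanical fractions, and three
likelihood-ratio hypothesis tests on ML mixed models with random replicate
and year intercepts (ryegrass cultivar × clover presence; ryegrass
component; clover component).

**Synthetic trials.** `simulate` generates the whole study with ground
truth: founder cultivars on allele-frequency grids (3 vs 2 founders),
designated private loci, logistic cultivar-proportion trajectories, optional
selected loci (additive per-year AF shifts), Hardy–Weinberg plant sampling,
negative-binomial depths and error-prone reads — so every stage can be
tested against what was actually simulated.

## Worked example

```python
import swardpop as sp

design = sp.full_design()                  # 56 samples, 14 plots x 4 years
cfg = sp.SimulationConfig(n_loci=5000, seed=7, depth_mean=100)
trial = sp.simulate_trial(cfg)
aaf, thetas = sp.estimate_aaf_matrix(trial.counts)
filt, report = sp.filter_cascade(trial.counts, aaf, sp.FilterConfig.pool_preset())
agree = sp.compare_aaf(filt.aaf.ravel(),
                       trial.truth.sample_aaf[report.kept_indices].ravel())
print(agree.pearson_r, agree.median_deviation)
```

prints (seed 7):

```
0.9802590881192711 0.029130792892932966
```

i.e. over the 236,880 locus-sample cells surviving the filters, the pooled
estimates correlate with the true 40-plant pool frequencies at r ≈ 0.98
with a median absolute deviation of ≈ 0.03 — pooled GBS at depth 100 reads
population allele frequencies to within a few percent. The
`examples/` scripts walk each capability the same way (diversity dynamics,
the selection scan, the yield tests, the validation metrics) and print what
their numbers mean.

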