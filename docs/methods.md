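# Methods

This note documents the models behind `swardpop`, the choices made where the
design was genuinely open, what the synthetic-data generator does and does
not emulate, and the package's known limitations.

## Study design assumed throughout

Seven seed compositions (two perennial ryegrass cultivars — "Merks-like",
high-diversity, 3 founder components; "Meloni-like", 2 founder components —
alone or mixed, with or without red clover) sown in two replicate plots,
14 plots in all, each sampled once a year for four years: 56 population
samples of 40 plants. Each sample is pooled in two replicate tissue pools
(112 pools) whose reads are merged before estimation, so all matrices carry
56 columns. The design table is the single source of truth for composition,
replicate and year; all stages join on `sample_id`.

## Pooled allele-frequency estimation

For one locus in one pool, with `r` reference and `a` alternative reads and
`n = 2 × pool size` chromosomes, the latent pool frequency is modelled on
the grid `f_k = k/n`, `k = 0..n` (81 points for 40 diploids; a finer grid is
a config option but adds nothing at GBS depths):

* **Likelihood** `a ~ Binomial(r + a, f(1−ε) + (1−f)ε)`, with a single
  symmetric per-read error rate ε (default 0.001, a typical short-read
  substitution rate; no per-read base qualities are modelled).
* **Prior**: folded neutral-diversity shape `∝ 1/f + 1/(1−f)` on the
  interior, normalised so total interior mass is `min(1, θ·a_n)`; the
  remaining mass splits equally between the fixed boundaries `f = 0` and
  `f = 1`. A floor of 1e−12 keeps the posterior proper when θ = 0.
* **θ** is estimated per pooled sample as `S/(L·a_n)`: the fraction of
  assessable sites (depth ≥ 30) that segregate (minor-allele read count
  ≥ 3), over the harmonic number `a_n = Σ_{i=1}^{n−1} 1/i` (4.952979 for
  n = 80). This is a simplified Watterson estimator: it ignores the
  depth-dependent probability of observing a segregating site and is used
  only as a prior scale, not as a diversity estimate in its own right.
* **Summary**: the estimate is the posterior mean; `p0`/`p1` are the
  boundary masses. **Fixation rules** snap the estimate to 0 whenever
  `1 − p0 < 0.9` and to 1 whenever `p1 > 0.9`, zero rule first. The zero
  rule is deliberately asymmetric — it zeroes a site whenever more than 10%
  posterior mass sits on the fixed-reference boundary — which suppresses
  error-driven low-frequency calls at the cost of some true rare alleles.
  The symmetric alternative (`p0 > 0.9`) can be obtained by thresholding
  `p0` directly on the returned summaries.

Frequencies from individual genotypes (`AAF_ind`) are the summed
alternative-allele dose over called individuals divided by the called
chromosomes; missing calls leave both numerator and denominator.

## Filter cascade

Applied in a fixed order, each step auditable in the report: (1) cells with
depth < 30 become missing; (2) loci whose total depth across samples exceeds
a dataset-specific ceiling are dropped (repeat-region guard; presets: 6k for
40 individuals, 3.5k for three validation pools, 7k for merged pools, 150k
for the 56 field pools); (3) loci with more missing cells than allowed are
dropped (0 for pools; 1/5/10 presets for individuals); (4) loci with a third
allele observed in *any* sample are dropped; (5) loci whose mean AAF across
samples falls outside [0.10, 0.90] are dropped, bounds inclusive. Inclusive
bounds and the mean-across-samples scope are defaults with config switches
(`band_inclusive`, `band_scope="any-sample"`), since both readings are
defensible. The cascade is idempotent and monotone in its thresholds.

## Diversity, PCA, private SNPs

`He = 2p(1−p)` per locus and sample; mean He per sample uses the loci
non-missing in that sample (all loci, after the complete-data filter). The
mean-He ANOVA is a *sequential* (Type-I) decomposition in the order
composition → composition×replicate → composition×year, computed by
projecting the response onto nested orthonormal bases, so the term SS plus
residual SS equal the total SS exactly; on the full design the df are
6, 7, 21 with 21 residual.

PCA runs on the column-centered, unscaled AAF matrix with samples as rows
(SVD). Sign convention: PC1 is oriented so pure-Merks samples score
negative on average (stable plots, stable covariate); other components get
the largest-magnitude loading positive.

A locus is private to a cultivar when its post-fixation AAF is exactly 0 in
every sample of plots containing only the other cultivar and positive
(> `min_aaf`, default 0) in at least one plot containing the focal cultivar
— mixed plots count by default (`include_mixtures=False` restricts to pure
plots). The abundance estimate normalises each sample's mean private AAF by
the pure-plot average, so pure plots sit at ŵ = 1 by construction.

## Selection scan

Per SNP, the 56-sample AAF vector is decomposed sequentially over
PC1 → composition → composition×replicate → composition×year → residual
(df 1, 6, 7, 21, 20 on the full design). PC1 enters first to absorb
cultivar differentiation and mixture dynamics. The statistic is
`MSS(S×Y)/MSS(residual)`; the wording "mean square over residual sum of
squares" mixes scales, so the mean-square ratio (an F-like quantity, ≈ 1
under the null) is the default and the literal `MSS/RSS` is emitted
alongside — the two differ by the constant residual df, so the empirically
fitted p-values are identical.

The null is fitted to all finite positive statistics by ML in four families
(log-normal — parameterised by the mean and SD of the log statistics, its
exact MLE — chi-square, F and gamma, the last three with location fixed at
0), selected by AIC. Under the generator's null the statistic is close to
F(21, 20), so the F family often edges out the log-normal by a few AIC
points; the log-normal remains adequate (its p-values pass KS uniformity),
which is what matters for an empirically calibrated scan. P-values are
upper-tail probabilities of the selected fit; outliers are
Benjamini–Hochberg calls at FDR 0.05 (the calling rule is a package choice;
any FDR can be configured); a KS statistic of the p-values against
Uniform(0,1) is reported as a fit diagnostic. SNPs with zero total or
residual variance are flagged and excluded from fitting.

**Power.** With 40-plant pools the binomial sampling noise of a pool
frequency is ≈ 0.056 SD at p = 0.5 — irreducible at any depth. A shared
shift of 0.08/year (0.24 cumulative) spread over the 21-df interaction term
yields statistics that rank at the extreme top of the genome but p-values
around 1e−5, short of the BH threshold over 20k tests; recall at FDR 0.05
is therefore low (≈ 0–40% depending on depth) even though the loci are
cleanly separated by rank. Larger pools, more replicates or rank-based
candidate selection are the remedies; the package reports ranks alongside
calls for this reason.

## Yield models

DMW (t/ha) = fresh weight × dried-subsample dry fraction / area. Botanical
fractions are per-subsample dry-weight shares averaged unweighted over
subsamples (zero-total subsamples excluded with a warning). The response in
all models is the annual total (or grass/clover) DMW per plot; per-cut
dynamics are out of scope.

The three hypothesis tests use linear mixed models with the stated fixed
effects and independent random intercepts for replicate and year — the
minimal structure consistent with the design — fitted by **ML, not REML**,
because likelihood-ratio tests on fixed effects are invalid under REML.
LRT statistics are `2Δll` against chi-square with the fixed-parameter
difference as df; negative values from optimizer noise are clipped at 0
after multi-start refits. Main effects are tested in the additive model;
the interaction against the additive model. Singular variance-component
fits (boundary) are accepted — the likelihood is still valid.

With only 32 plot-year rows (compositions 1–4) the fixed-effect ML LRT is
mildly anticonservative: ≈ 0.08 rejection at nominal 0.05 in a 300-trial
null calibration under the generator. This is the familiar small-sample
behaviour of the procedure itself, shared by any analysis that uses ML
mixed fits with `anova`-style LRTs at this size; p-values near 0.05 should
be read accordingly.

## Synthetic-data generator

What it emulates: two founder cultivars whose allele frequencies sit on
grids `k/(2·founders)` (3 founders vs 2, so the Merks-like cultivar is the
more diverse), drawn against a Beta(3,3) base spectrum (mass at
intermediate frequencies, as in an ascertained SNP panel; this also keeps
expected He ordered by founder count under the ≥1-allele clamp); designated
private loci at rates 1.1%/2.8% (the shares observed in the trial's SNP
panel); logistic Merks-proportion trajectories in mixed plots with a
composition-level trend, shared per-year offsets (for non-monotone dynamics
such as Merks prominent in years 1 and 4) and independent plot-year noise
(SD 0.3 on the logit scale); optional selected loci as deterministic
additive per-year AF shifts shared by replicates — exactly the alternative
the S×Y term detects; 40 Hardy–Weinberg diploids per plot-year, equal-tissue
pooling (pool AAF = mean dose/2); per-cell negative-binomial depth (mean
100, dispersion 10 — overdispersed, as GBS depths are; Poisson is the
dispersion→∞ limit) and binomial reads with symmetric error.

What it does not emulate: linkage (loci are independent), family structure
within cultivars, PCR duplicates and allele-specific amplification bias,
reference-mapping bias, locus dropout (restriction-site polymorphism),
spatial field structure, and genotype-by-environment interaction in the
trajectories. Passing tests therefore show the *statistical machinery* is
correct and calibrated under the design's sampling structure, not that real
GBS data meet these assumptions — in real data the filter cascade and the
empirical (rather than theoretical) null carry that weight.

Yield generation is additive in cultivar-content effects with random
replicate/year intercepts and a logistic grass/clover split; defaults
(clover presence +2 t/ha on μ = 12, Meloni +1, erect clover cultivar
shifting the split toward clover) reproduce the trial's qualitative
pattern. All randomness flows from one seed through three documented
substreams (cultivars, trajectories, reads), so runs are bit-for-bit
reproducible and cultivar profiles are stable whether or not reads are
simulated.

## Numerical choices

Posterior computed in log space without the constant binomial coefficient;
cells with zero depth are missing. Sequential SS via orthonormal-basis
projection with an SVD rank tolerance of 1e−8 relative; tiny negative
residual SS from cancellation are clipped at 0; the decomposition is tested
against an independent nested-OLS oracle at 1e−9 relative tolerance.
Degenerate SNPs (constant rows) are flagged, not dropped silently. Locus
order is always (chrom lexicographic, position ascending); positions are
1-based (VCF convention). Missing AAF is an explicit mask; `NaN` is stored
under the mask so unmasked arithmetic fails loudly rather than silently.

## Problem sizes used by the test suite and acceptance script

The suite exercises the pipeline at 2,000–4,000 loci for unit-level checks
and at the study scale of 20,000 loci (once null, once with 20 selected
loci) for calibration, power and recovery; the acceptance script uses the
same 20,000-locus scale. These sizes give Monte-Carlo error comfortably
below every asserted tolerance.

## Known limitations

* The grid posterior is a transparent reimplementation of the pooled
  SNP-calling idea (informative folded Watterson prior, boundary fixation
  probabilities); it is not a line-by-line reproduction of any external
  caller, so per-SNP numbers from such tools will differ in detail.
* The literal zero-fixation rule discards true alleles below roughly 10%
  posterior support; analyses of rare variants should relax it.
* The scan assumes replicate plots of a composition experience similar
  selection pressure; plot-specific selection lands in the residual and is
  invisible by construction.
* Mixed-model LRT p-values inherit the small-sample anticonservativeness
  described above.
* The abundance estimator assumes private-SNP frequencies within a cultivar
  are stable over time; genuine selection on private loci would bias ŵ.
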