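# Methods

This note documents the statistical models implemented in `xcc`, the
assumptions they make, the defaults and why, the synthetic-data generators
that stand in for the unreleased individual-level genotypes, and the
numerical choices and known limitations. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Data model

All association statistics reduce to a 2×2 exposure×group count table
(a, b; c, d). Genotype counts are stored per (population, group, SNP) as
(hom-major, het, hom-minor) triples with an explicit major/minor orientation;
allele counts follow by 2·hom + het, conserving 2N chromosomes. Cohorts are
per-individual unphased diploid genotype matrices over an ordered biallelic
SNP panel with case/control labels; allele pairs are order-normalized (major
first) since phase is not observed. The panel is X-linked but all cohorts are
female, so the diploid (autosomal-style) treatment is exact; no haploid male
mode is provided. When major/minor must be inferred from data, the
control-group allele frequencies decide (association convention), with
lexicographic tie-breaking for determinism. Missing genotypes are retained in
the containers and excluded per analysis: pairwise deletion for single-SNP
statistics, complete-case over the panel for EM runs. The source data do not
state a missingness policy; this is the package's choice and is the standard
PLINK-style behaviour.

## Classical association

Odds ratios are ad/bc with the Woolf log-scale 95% interval,
exp(ln OR ± 1.96·√(1/a+1/b+1/c+1/d)). Tables with a zero cell report the
point estimate as 0 or ∞ — matching the display convention of the published
tables this package reproduces — while the interval is computed from the
Haldane–Anscombe +0.5 table and flagged `continuity_applied`. Genetic-model
collapsing offers allelic (chromosome counts), dominant (minor-allele
carriers vs major homozygotes) and recessive (minor homozygotes vs the rest);
an `exposure="major"` switch flips the exposed column, which is how the
published genotype-model rows (major-homozygote as exposure, OR < 1 for
protective major alleles) are reproduced. p-values use Pearson chi-square
with Yates correction when all expected cells are ≥ 5 and Fisher's exact
two-sided test otherwise; the rule actually applied is recorded per result,
since the source describes using both tests without stating the switch.
Hardy-Weinberg equilibrium is the 1-df chi-square of the three genotype
classes against N·(p², 2pq, q²) at the observed allele frequency; the
conventional χ² < 3.84 flag is reported. Bonferroni correction is min(1, m·p)
with m taken from the submitted batch size (22 for the packaged HLA scan),
never hard-coded.

## Bayesian Monte-Carlo odds ratio

Each group's exposure proportion gets an independent Uniform(0,1) prior, so
after n exposed / n′ unexposed observations the posterior is Beta(n+1, n′+1).
The posterior OR distribution is summarized from simulated draws (default
10⁶, PCG64 generator, seed recorded in every result): the point estimate is
the posterior **median** — chosen because it is equivariant under the
group-swap reciprocal symmetry OR → 1/OR, which the mean is not; the
credible bounds are empirical percentiles (one-sided 5th/95th oriented by the
effect direction by default, mirroring the published "[2.48–+∞]" style;
equal-tailed 2.5/97.5 behind `sided="two"`); and the reported p is the
smaller posterior tail mass min{P(OR<1), P(OR>1)}, so 0 ≤ p ≤ 0.5. Tables
whose sample OR is 0 or ∞ (a zero cell on one diagonal only) display the
point and outer bound as 0/∞ while the inner bound and the tail masses remain
finite — the uniform prior regularizes them. `bayes_or_exact` evaluates
P(OR < m) = ∫ f₂(y)·F₁(m·y/(1−y)/(1+m·y/(1−y))) dy on a Gauss-Legendre rule
(default 4096 nodes) and inverts it by Brent root-finding for the median and
percentiles; it is deterministic and serves as the independent oracle for the
Monte-Carlo path. In deep tails the Monte-Carlo exceedance count is Poisson,
so test comparisons use 3 binomial SEs plus an absolute 10-count floor;
the normal SE alone understates the probability of small-count fluctuations.

## EM haplotype frequencies, LD, haplotype association

For L biallelic SNPs the 2^L haplotypes are estimated from unphased diploid
genotypes by the classical EM: an individual heterozygous at k sites is
compatible with 2^(k−1) unordered haplotype pairs; the E-step distributes her
unit mass over those pairs proportionally to 2^[h≠h′]·f_h·f_h′ (random
pairing of haplotypes within group — the HWE assumption), the M-step
re-estimates frequencies from expected chromosome counts. Iteration stops
when the largest frequency change or the log-likelihood change drops below
`tol` (default 1e-8) or at `max_iter` (1000). The log-likelihood trace is
retained and asserted non-decreasing in tests. Initialization is uniform by
default; with many double heterozygotes the likelihood can be multimodal, so
seeded Dirichlet random restarts are available and the best final
log-likelihood wins, earliest restart on ties. Frequencies are renormalized
at exit to remove float drift.

Pairwise LD comes from a two-SNP haplotype table: D = p_AB − p_A·p_B on the
major-major haplotype, D′ = |D|/D_max with D_max the tightest one-sided
frequency bound, r² = D²/(p_A q_A p_B q_B).

Per-haplotype association runs EM on the pooled sample (defining the
haplotype set), then per group; haplotypes below `min_freq` (default 0.05)
in **both** groups are dropped — the published analyses state a 5% filter
without the group scoping, so the scoping here is explicit and configurable.
Each retained haplotype is tested haplotype-vs-all-others on a 2×2 of
expected chromosome counts (2n·freq rounded to integers) with a Woolf OR and
a plain chi-square p (Fisher fallback at small expected counts). This is a
deliberately transparent estimator rather than a score/regression test: the
exact test variant used by the original PLINK-based analyses is not
recoverable, and printed haplotype ORs cannot be reconstructed from rounded
published frequencies either, so validation is by simulation recovery, not
digit matching. Labels: Risk if p < 0.05 and OR > 1, Protector if p < 0.05
and OR < 1, else NA. Note the labels control the per-test level only; with
four common haplotypes the family-wise null rejection rate is necessarily
higher than 5%.

## Meta-analysis

Per study, the effect is ln OR on the allele-level 2×2 with Woolf variance
1/a+1/b+1/c+1/d; a zero cell adds +0.5 to all four cells of that study only
(flagged). Heterogeneity: Q = Σwᵢ(lnORᵢ − lnOR_fixed)², df = k−1, p from
chi-square, I² = max(0, (Q−df)/Q); DerSimonian-Laird
τ² = max(0, (Q−df)/C) with C = Σw − Σw²/Σw. Fixed-effect pooling is
inverse-variance (wᵢ = 1/vᵢ); random-effects uses wᵢ* = 1/(vᵢ+τ²); the CI is
exp(pooled ± 1.96/√Σw) and significance is the two-sided normal Z test. When
Q ≤ df, τ² truncates to 0 and the random-effects result coincides exactly
with fixed. Model auto-selection applies the standard rule — random effects
when I² > 50% (threshold configurable) — which is the rule that reproduces
the published pooled values: they correspond to fixed pooling at I² ≈ 23%
and to DL pooling at I² ≈ 75% and 64%. Pooling is done at the allele (chromosome) scale
with the exposed allele named per SNP (A for rs13397, T for rs1059703 and
rs1059702): this is the scale that reproduces the published pooled values.
The rs3027898 panel is computable but flagged: the Chinese study's published
control allele row contradicts its own genotype row (it appears transposed),
so the packaged fixture carries the genotype-derived counts and no published
pooled value is treated as reproducible for that SNP.

## Synthetic-data generators

`simulate_cohort` draws, per individual, two independent haplotypes from her
group's frequency vector (HWE within group), stores the unordered per-SNP
allele pairs (phase discarded), and masks genotypes MCAR at `missing_rate`.
Case frequencies are the control frequencies tilted multiplicatively by
exp(log OR) per haplotype and renormalized — each haplotype copy multiplies
the disease odds, the implicit model of chromosome-level 2×2 haplotype tests.
Default configurations used in the analysis scripts and tests mirror the
published cohorts: a French-like structure (GTC 0.68, ATC 0.09, GCC 0.06,
GTT 0.04, remainder split over the other four haplotypes; n = 289 cases /
340 controls; ATC odds tilt 4) and a Tunisian-like null structure
(GTC 0.56, ATC 0.15, GCC 0.14, GTT 0.15; n = 119/131). `simulate_meta_studies`
draws per-study effects from Normal(true lnOR, τ²), sets the control exposure
probability to `base_allele_freq` (default 0.3, a typical minor-allele
frequency) and fills the four cells binomially. Both generators are fully
reproducible from their seeds.

What the generators deliberately do not model: ascertainment bias, population
stratification or admixture, genotyping error, non-random missingness,
male (haploid X) carriers, and LD with unmeasured causal variants. Passing
recovery and calibration tests on these generators therefore shows the
estimators are correct under their own assumptions — not that those
assumptions hold in any particular real cohort.

## Problem sizes and test design

The simulation batteries run at sizes chosen to make sampling noise small
relative to the asserted tolerances while keeping the default suite fast:
EM recovery at n = 1000 individuals per cohort over a grid of generating
frequency vectors (asserted MAE < 0.02); haplotype-association null
calibration over 200 replicates at n = 500/500 (pooled per-test rejection
rate asserted ≤ 7% at the nominal 5%, and each haplotype NA in ≥ 90% of
runs); DL recovery over 200 replicate collections of k = 20 studies; and the
Monte-Carlo/quadrature cross-check on 50 random tables at 10⁶ draws each.
The published count-table reproductions are exact-arithmetic checks at the
precision at which each value was printed — the genotype-model and pooled
tables round to 2 decimals, while the HLA allele-scan table truncates its
third decimal, and the tests encode each table's own convention.

## Known limitations

- Haplotype EM is exponential in L (the 2^L universe is materialized); it is
  intended for small panels (L ≲ 10), not chromosome-scale phasing.
- The haplotype association test uses rounded expected counts, discarding
  phase uncertainty in the test statistic; p-values very close to the
  nominal level should not be over-read.
- One published genotype-model OR (Tunisian rs13397, printed 0.48) matches
  no standard collapse of its printed genotype counts (dominant 0.53,
  recessive 0.45) and is excluded from the reproduction targets; the scan
  emits all models with labels rather than silently choosing one.
- The published claim that all genotype distributions satisfy HWE (χ² < 3.84)
  is not reproducible from the published counts themselves (e.g. the Tunisian
  control rs13397 triple gives χ² ≈ 29); the package computes and reports
  HWE rather than asserting the claim.
- VCF support is deliberately minimal: biallelic SNP records, GT only,
  diploid calls; phase separators are accepted but ignored.
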