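# Methods

This note documents the statistical models behind `crossmeta`, the design
choices made where the design was genuinely open, what the synthetic data
do and do not emulate, and the numerical conventions that matter for
reproducing results.

## Overlap-corrected weighted-Z meta-analysis

Association Z-scores from studies that share participants are correlated
under the null. For two studies of one trait sharing `n_s` of `n_1`, `n_2`
participants the null correlation is `n_s / sqrt(n_1 n_2)`; for studies of
different traits it is scaled further by the phenotypic correlation. The
meta-analysis therefore combines studies as

    Z_meta = sum_i w_i Z_i / sqrt(sum_ij w_i w_j c_ij),  w_i = sqrt(N_i),

with `C = (c_ij)` estimated from the data. Per variant, only the studies in
which the variant is present enter the sums, with per-variant `N`. The
per-variant effective sample size is `(sum N_i)^2 / sum_ij sqrt(N_i N_j) c_ij`.

**Estimating C.** `c_ij` is the Pearson correlation of Z over shared
variants with `|Z| < 1.96` in both studies, so genuine shared signal does
not masquerade as overlap. Restricting a bivariate normal sample to the box
`|x|, |y| < 1.96` shrinks its correlation substantially (a true 0.5 is
observed as ≈ 0.41), so the estimator inverts the shrinkage through a
numerically integrated table of true-vs-truncated correlation; the
truncation threshold is configurable. Negative estimates are truncated at
zero by default (participant overlap cannot be negative), pairs with fewer
than 1000 usable variants get `c = 0` with a warning, and the matrix is
repaired to positive semi-definiteness by flooring eigenvalues at 1e-6 and
rescaling to unit diagonal.

**Nested plans.** Duplicated traits (e.g. two opioid-use-disorder studies in
one population) are meta-analyzed first; internal nodes re-estimate their
overlap model over their direct inputs and re-enter parent analyses with
`N` set to their effective sample size. When all correlations are zero this
composes exactly with a flat analysis.

**Concordance.** A variant is retained when it is present in at least two
contributing studies and all present nonzero signs agree; a Z of exactly 0
neither confirms nor breaks agreement, and a variant with no nonzero sign
carries no direction and is dropped. Requiring presence in *all* studies
was the plausible alternative; the ≥ 2 policy was chosen because published
locus tables report concordant loci with entries missing for some traits.
In cross-population analyses the filter sees the per-trait sign columns of
every population together with the per-population meta signs, which
enforces agreement both across disorders and across populations. Under
four independent null traits the filter retains 2^-3 = 12.5% of variants.

## Loci

Lead variants are genome-wide significant (P < 5e-8, configurable) variants
accepted greedily in ascending-P order subject to pairwise LD r² < 0.1;
ties are broken by (chromosome, position, id) for determinism. Each lead's
locus spans the positions of its r² > 0.6 partners; a locus containing
fewer than two GWS variants is flagged as lacking LD support (a likely
false positive). Same-chromosome loci with a gap under 250 kb merge
transitively; "gap" means end-to-start distance, and a gap of exactly
250 kb does not merge. The same rule is applied once more to the pooled
locus list when several meta-analyses are combined. Coordinates are
1-based inclusive; BED export converts to 0-based half-open. LD is
computed from a reference genotype panel as squared Pearson correlation of
dosages within a 1-Mb window (FUMA-like convention, configurable);
monomorphic panel variants get r² = 0 with a warning.

## Gene-based test

The gene statistic is the maximum squared Z over the variants mapped to the
gene body ± 10 kb. Its null distribution under LD is the maximum of squared
components of a zero-mean multivariate normal with the variants' reference
correlation, shrunk toward the identity with weight 0.05 because
panel-estimated matrices are noisy and can be indefinite. The gene P is the
Monte-Carlo tail probability with the add-one correction
`P = (1 + #exceed)/(n_mc + 1)`; the default 1e5 draws escalate tenfold when
the first pass lands below 1e-3. Against closed forms the sampler is exact:
a single-variant gene reproduces the variant's two-sided P, independent
variants reproduce the Šidák bound, and perfectly correlated variants
collapse to a single test. Gene P converts to Z by the probit
`Z = Phi^{-1}(1 - P)`; cross-population combination is a sqrt-N-weighted
Stouffer sum using the populations' effective sample sizes, and genes
present in only one population are excluded from the cross-population
table. Only genes expressed (value > 0) in at least one brain-tissue
column of the supplied expression matrix are tested.

## Mapping and prioritization

Significant concordant variants inside LD-supported loci map to genes three
ways: positionally (gene ± 10 kb), by cis-eQTL lookup, and by chromatin
loops (variant in one anchor, gene overlapping the other, anchor span
≤ 2 Mb). All evidence is consumed from offline flat tables — pathway gene
sets, gene families, interaction scores with evidence classes, and a
trait-class column — because what counts as a "psychiatric or brain
related" trait is a curation decision, not something the package infers.
The candidate set is the union of brain-expressed mapped genes and
significant gene-based genes (Bonferroni within the gene table); a
candidate is prioritized when it is a pathway member, shares a family with
a pathway member, interacts with one at confidence ≥ 0.7 or with
experimental/database evidence, or carries a psychiatric/brain trait
class. All firing reasons are recorded.

## Enrichment

For each gene, a column (brain dissection or cell type) is labeled highly
expressed when the value exceeds `mean + 1.645·SE` of the gene's own row
and lowly expressed below `mean − 1.645·SE`. SE is interpreted as the
standard error of the row mean (sd/√D over D columns); the source
convention does not spell the formula out, so plain sd is available as a
switch. Expression values are used as provided, with no internal log
transform. Per column, a one-sided (greater) Fisher's exact test compares
labeling rates of prioritized versus remaining genes, and
Benjamini–Hochberg correction is applied across columns within each of the
four analyses separately. The Fisher P equals the exact hypergeometric
tail sum to machine precision.

## Heritability

LD scores are `l_j = sum_k r2_adj(j,k)` within a 1-Mb window including the
self term, with the small-sample adjustment `r2_adj = r2 − (1−r2)/(n−2)`.
The regression `E[chi2_j] = 1 + a + N h2 l_j / M` is fitted by weighted
least squares with the standard heteroskedasticity weights
`1/(l_j (1 + N h0 l_j/M)^2)` and one reweighting iteration from an OLS
pilot; standard errors come from a 20-block jackknife over
position-ordered variants. Negative fitted slopes are reported as is,
never clipped. The cross-trait regression of `Z1·Z2` on the scores
estimates genetic covariance, and `rg = gencov/sqrt(h2_1 h2_2)`. By
default both fits keep a free intercept (it absorbs confounding and sample
overlap); when cohorts are known to be disjoint and unconfounded — as in
the package's own simulation studies — `intercept_free=False` /
`overlap_intercept_free=False` pin the intercepts at their theoretical
values, which leaves the estimators unbiased while shrinking their
seed-to-seed spread roughly threefold.

**Concordant fraction.** The share of SNP-heritability carried by the
concordant set is estimated with a two-category *stratified* fit: each
category (concordant, remainder) supplies partial LD scores — the sum of
r² to that category's variants only — and its own M, and the joint model
`E[chi2] = 1 + N (h2_c l_c/M_c + h2_r l_r/M_r)` attributes signal to the
category that tags it. A single-category fit restricted to the subset
credits the subset with signal from outside causal variants in LD with it
and overestimates the fraction badly; and dividing two independently
fitted estimates makes the ratio hostage to denominator noise at desk
scale. The reported fraction is therefore the concordant share of the
joint fit's total, preserving the ratio-of-estimates design (numerator
restricted to concordant variants, denominator all variants). A fixed-M
switch reproduces the alternative convention.

## Polygenic scores

Scores are dosage-weighted sums of per-allele effects; weights in swapped
allele orientation are sign-flipped, missing dosages are imputed as twice
the effect-allele frequency, and weight variants absent from the cohort
contribute a constant logged shift that cannot change ranks. Risk
stratification compares individuals at or above the stratum's 90th
percentile (ties go to the top group; strata are restricted *before* the
percentile is taken) to the remainder by logistic regression with sex,
age, principal components and any array indicator as covariates (sex
omitted in sex-stratified runs); without covariates the estimate equals
the closed-form 2×2 odds ratio. Complete separation is flagged as
non-estimable rather than reported. Cohort results combine by
fixed-effect inverse-variance (1/SE²) meta-analysis on the log-OR scale —
the phrase "weighted by the inverse of standard error" is ambiguous
between 1/SE and 1/SE², so 1/SE weighting is available as a switch. A
clump-and-threshold fallback (leads at r² < 0.1 within each P threshold,
weight `Z/sqrt(N_eff)`, threshold chosen on a tuning cohort when given,
else the strictest) stands in where posterior-effect weight files are not
supplied; externally estimated weights are accepted as input everywhere.

## The simulator

Haplotypes follow a first-order Markov chain within each LD block: allele
`j+1` copies allele `j` with probability rho and is otherwise a fresh
Bernoulli draw at the block's frequency. This yields haplotype and
genotype correlation exactly `rho^d` at distance `d` while preserving
marginal frequencies — a Gaussian copula would attenuate binary
correlations and fail the moment checks. One frequency is drawn per block
(the copy step requires it); block frequencies and rhos are *population
parameters* derived from the configuration seed alone, so GWAS cohorts,
LD reference panels and target cohorts drawn with different generators
share one LD structure. An optional per-block rho range emulates the
heterogeneous LD of real genomes, which the LD-score regression needs for
identification. Variants sit every 10 kb on one pseudo-chromosome.

Phenotypes follow a liability-threshold model: liability is the centered
genetic score plus Gaussian noise scaled to unit total variance, and cases
exceed the standard-normal `1 − prevalence` quantile. Causal variants are
planted as shared (identical effect across traits), discordant (sign
flipped in a random nonempty proper subset of traits) or trait-specific;
`scale_heritability` rescales each role to an exact per-trait variance
contribution. Summary statistics are score tests
(`Z = g_c·y_c / sqrt(mean(y_c²) sum g_c²)`), valid for binary and
quantitative phenotypes alike — fast, with an analytic null, at the price
of not modeling covariates or case-control ascertainment beyond the
threshold model. Sample overlap is realized by allocating pair-specific
index sets of shared individuals, which reproduces any feasible pairwise
overlap matrix exactly (triple overlaps are not generated).

What the simulation does **not** emulate: realistic human LD maps and
recombination, imputation uncertainty, allele-frequency differences
between populations, X/Y chromosomes, admixture, covariate confounding and
relatedness. Passing recovery tests therefore demonstrates correctness of
the estimators under their stated assumptions, not robustness to
real-data artifacts.

## Reference problem sizes

The bundled study sizes were chosen once, by power analysis, as the
smallest configurations in which each effect is identifiable: calibration
uses two cohorts of 2000 sharing 1000 participants over 20,000 independent
null variants; the concordance null uses four disjoint cohorts of 1500;
heritability recovery uses M = N = 5000 with a fully polygenic
architecture (h² = 0.3) and a 1000-haplotype panel, averaged over five
seeds; the 50/50 concordant/discordant split plants 120 + 120 causal
variants carrying 0.15 heritability each so per-study signs are recovered
with high probability; sign-recovery of shared causals with liability
effect 0.05 uses four cohorts of 40,000; and polygenic-score evaluation
scores a fresh 10,000-person target cohort at 10% prevalence. The
end-to-end demo (four traits, five studies with two overlapping cohorts of
a duplicated trait, 1200 variants) completes in well under a minute and
writes a manifest whose content hashes are bit-identical across runs.

## Known limitations

- The weighted-Z framework carries no effect sizes; inverse-variance
  (beta/SE) meta-analysis, random-effects models and genomic control are
  out of scope.
- The Monte-Carlo gene null is exact but stochastic; P-values below
  ~1/n_mc saturate at the add-one floor.
- LD score regression at M = 5000 has seed-to-seed spread of a few
  hundredths in h²; uncertainty statements rely on the block jackknife.
- The concordant-fraction estimate inherits the concordance filter's
  imperfect recall: shared causal variants whose sign is mis-estimated in
  any study leave the numerator, so planted 50/50 architectures recover
  fractions slightly below one half at desk-scale power.
- Liability-scale conversion of heritability and annotation-stratified
  partitions beyond the concordant/remainder split are not implemented.
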