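# Methods

## Model

`lbr` fits, per chromosome segment, the SNP-by-sex interaction regression

    y_m = 1 mu_m + X_m b0 + X_m b_m + e_m,   e_m ~ N(0, s2e_m I)
    y_f = 1 mu_f + X_f b0 + X_f b_f + e_f,   e_f ~ N(0, s2e_f I)

on dosages centered on the pooled (both-sex) mean and a phenotype scaled to
unit pooled variance. Sex-specific effects are beta_m = b0 + b_m and
beta_f = b0 + b_f: b0 is the component shared between sexes, b_m and b_f
are sex deviations. Pooled centering (rather than per-sex) preserves this
interpretation; the sex-specific intercepts absorb sex mean differences, so
the phenotype is deliberately *not* centered.

Each effect class k in {0, m, f} has an independent spike-slab prior,
pi_k N(0, s2b_k) + (1-pi_k) delta_0, with conjugate hyperpriors:
scaled-inverse-chi-square on the slab variances s2b_k and the per-sex
residual variances, Beta on the inclusion proportions pi_k. The model
assumes unrelated individuals, a phenotype precorrected for covariates,
autosomal biallelic dosages, and equal allele frequencies/LD across sexes
(true by design in the simulator and essentially true for autosomes in
random-mating populations).

## Sampler

A single-site Gibbs sweep per iteration: (a) intercepts from their Gaussian
full conditionals (flat prior); (b) for each SNP in genomic order and class
in order 0, m, f: the inclusion indicator from its effect-integrated
Bernoulli conditional, then the effect from its Gaussian conditional (or an
exact stored zero) — the shared-class cross-products are weighted by the
inverse sex-specific residual variances because the errors are
heteroskedastic across sexes; the residual vector is updated incrementally
after every accepted change; (c) slab variances and (d) inclusion
proportions from their conjugate conditionals; (e) per-sex residual
variances from scaled-inverse-chi-square. The sweep runs in a
numba-compiled kernel; chains are bit-reproducible given the seed, and the
fixed deterministic update order is chosen for reproducibility.

Validation rests on two independent oracles (exercised in the test suite):
with all indicators forced on and variances fixed the sampler must
reproduce the closed-form heteroskedastic ridge posterior mean, and on
two-SNP problems with fixed hyperparameters the indicator posterior must
match exhaustive enumeration of all 64 configurations under the exact
Gaussian marginal likelihood.

Hyperprior defaults (all overridable, recorded in output metadata):
slab_df = 5; the slab scale is set so each class's prior-expected genetic
variance equals one third of a whole-trait R² guess (default 0.5),
apportioned to a segment by its SNP fraction, given the Beta(1, p/50) prior
mean of pi_k and the segment's summed dosage variance; residual_df = 5 with
scale equal to the phenotype variance. Chain defaults are
n_iter = 12000 / burn_in = 2000 / thin = 5 (2000 stored draws: binomial SE
of a posterior probability near 0.5 is about 0.011 before autocorrelation).
Tests and the desk-scale benchmark use shorter chains (500 stored draws),
sized so that Monte Carlo error remains a small fraction of the
probability differences they assess.

## Tiling

Each chromosome is cut into consecutive cores (default 1500 SNPs, the last
core holding the remainder) extended by buffers (default 250 SNPs, roughly
1 Mb at biobank SNP density) that never cross chromosome ends. Segments
are fit independently — per-segment seeds derive deterministically from
(global seed, segment index) so results are order-independent — and only
core samples are kept, aligned positionally across segments (draw t of
every segment is draw t of the stitched chain). This treats cross-segment
posterior dependence beyond the buffer span as negligible, which is the
same assumption that justifies local fitting in the first place: dosage R²
decays to ~0 within 1–2 Mb in unstructured human populations. Window
variances for windows straddling a core boundary are computed from the
stitched samples.

## Posterior summaries

Spiked-out effects are stored as exact zeros, so all probabilities are
indicator averages with no epsilon tolerances: PPM_j averages
{b0j included or bmj included}; PPDiff_j averages {bmj or bfj included}
(equal to beta_m != beta_f up to measure-zero cancellations of continuous
draws); window-variance probabilities use the same bookkeeping, since the
male and female window variances of a draw coincide exactly when every
interaction effect in the window is spiked out.

Windows are defined per focal SNP by contiguous extension while dosage R²
with the focal SNP stays >= 0.05, stopping at the first sub-threshold SNP
(a configurable gap tolerance exists, default 0), at 1 Mb, or at the
chromosome end. This yields heavily overlapping, dynamically sized
windows; threshold, distance cap and gap tolerance are exposed in
configuration. Window variances use the pooled-sex dosage covariance (all
individuals), so with the unit-variance phenotype they are proportions of
total phenotypic variance; a per-sex genotype matrix is a documented
alternative but pooled is the default because the quantities are
interpreted against the pooled phenotypic variance. They are computed as
quadratic forms beta' C beta in the window's dosage covariance, which is
algebraically the sample variance of X_w beta and preserves exact zeros.

## Single-marker baseline

Per sex, simple OLS of the phenotype on dosage with intercept. The
sex-difference test is z = (beta_f_hat - beta_m_hat) / sqrt(se_f² + se_m²)
against the standard normal (valid because the sexes are disjoint
samples); the any-effect test sums the two squared per-sex z statistics
against chi-square(2). At GWAS sample sizes the difference between this
2-df chi-square and an F-test is negligible. SNPs monomorphic within a sex
are flagged with p-values of 1.

## Synthetic data

The genotype generator emulates the statistical features the method
exploits, not human genealogy. Per chromosome, SNP positions follow
exponential spacings (default mean 5 kb); each of the 2n haplotypes is a
stationary first-order latent-Gaussian process with inter-SNP correlation
exp(-d/phi), and the allele is the indicator that the latent value exceeds
the quantile of a per-SNP MAF drawn uniformly from [0.05, 0.5]. phi is set
to 2·L/ln(100) so that dosage R² is below 0.01 by the decay distance L
(default 1.5 Mb, within the 1–2 Mb range over which LD empirically
vanishes). Both sexes draw from the identical genotype distribution, so
sex is never confounded with allele frequency. Not emulated: population
structure, relatedness, recombination hotspots, rare variants, and
realistic site-frequency spectra — so passing tests demonstrate the
machinery under calibrated LD decay, not robustness to human demographic
structure.

The trait generator places one causal variant per ~2 Mb stratum (defaults:
150 causal variants, each expected to explain 3.3e-4 of phenotypic
variance, i.e. ~5% genetic variance on the simulated genome fraction,
corresponding to heritability 0.5 at whole-genome scale). A fraction
prop_gxs (default 40%) gets sex-differing effects under one of three
schemes; the default `mixed` uses half one-sex-only effects (alternating
sex; active-sex beta² var(x) = 2 × the per-variant target so the pooled
contribution matches shared variants) and half independent per-sex normal
draws with equal expected per-sex variance. Effects act on pooled-centered
dosages (a one-sex effect on raw dosages would also shift that sex's
phenotype mean, which is an intercept, not genetic variance). Residual
noise tops pooled variance up to 1 before final rescaling; the truth
object records per-variant realized variance fractions and the exact
variance decomposition. A masked-causal mode removes causal columns so
discovery must proceed through LD tagging.

Two presets bundle the study conditions. The full-scale preset (119,190
males, 139,738 females, 10 chromosomes × 6000 SNPs, 150 causal) is
cluster-sized. The desk preset uses 3000 individuals per sex,
2 chromosomes × 1000 SNPs, 10 causal variants (4 G×S) with per-variant R²
inflated to 2e-3 so power is estimable at that sample size; its SNP
spacing is 20 kb so that each 20 Mb chromosome spans ~13 LD-decay lengths
and can hold 10 causal strata of 2 Mb — at the 5 kb default spacing a
1000-SNP chromosome would be a single LD block and could not host the
stated architecture.

## Evaluation conventions

Observed-causal evaluation counts a selection as true only if it is itself
a causal variant of the relevant class. Masked-causal evaluation uses
target areas (1 Mb / 500 kb / 250 kb, i.e. half-widths 500/250/125 kb): a
causal variant is tagged if any selected SNP, or any SNP of a selected
window, lies within the half-width; power counts each variant once however
often it is tagged, and every selection tagging it is true. FDR with zero
selections is defined as 0 (avoiding 0/0); overlapping selected windows
are merged into distinct regions before counting. Monte Carlo aggregation
reports mean ± 1.96·SE across replicates. Enrichment of a selected SNP set
in an annotated set is the upper-tail hypergeometric probability of the
observed overlap.

## Numerical and degenerate-input choices

Missing dosages are mean-imputed per SNP, pooled across sexes (preserves
allele frequency; an all-missing SNP is an error). Monomorphic SNPs get
zero cross-products in the sampler (their effects are drawn from the
prior and are harmless); monomorphic focal SNPs get single-SNP windows
with a warning; SNPs monomorphic within a sex get flagged p-values of 1 in
the single-marker scan. Spike/slab log-odds beyond ±35 short-circuit to
avoid overflow; quadratic-form window variances are clipped at 0 against
roundoff; p-values are clipped into (0, 1] (underflow only). Constant
phenotypes cannot be scaled and are an error. Chain sanity is monitored by
a finiteness check each iteration (aborting with the iteration index) and
split-chain scale-reduction / batch-means MC errors in `log_diagnostics`.

## Known limitations

Window variances lose the sign of effects, so a window-level sex
difference cannot distinguish opposite-sign from different-magnitude
effects. Indicator-based PPDiff treats "both spiked out" as "equal", which
is exact under the point-mass prior but means PPDiff is bounded above by
the inclusion probability of the interaction classes. Cross-segment draw
alignment is positional, not joint sampling. The desk-scale benchmark
operates at a much lower per-variant non-centrality than a biobank-scale
study; threshold-based operating points (PPDiff >= 0.95, p <= 5e-8) select
very few SNPs there, and the power comparison against single-marker
regression is therefore made on ranking curves at matched selection sizes.
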