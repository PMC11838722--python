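# Methods

This note documents the statistical procedures, the synthetic-data
generator, the numerical choices, and the design decisions made where the
design was genuinely open. Notation: k traits, M regression SNPs, ℓⱼ the
LD score of SNP j, S the k×k genetic covariance matrix, V the sampling
covariance of vech(S) (lower triangle, column-major, a convention used
consistently across the package).

## Summary-statistic ingestion and harmonization

Sumstats tables are read from whitespace-delimited text with configurable
header mapping, and carry the canonical columns
`snp, chr, bp, a1, a2, freq, beta, se, z, p, n` (1-based coordinates). z is
derived as beta/se when absent, p from the two-sided normal tail of z, and
case-control designs are converted to effective N (below) when only
case/control counts are given.

Harmonization aligns each table to a reference allele frame: exact-match
SNPs pass through; swapped alleles flip the sign of beta/z and mirror the
frequency; strand-ambiguous SNPs (A/T, C/G) with effect-allele frequency
in [0.40, 0.60] are removed (frequency alone cannot resolve the strand);
any other allele configuration is removed as a mismatch. No strand
flipping is attempted — a conservative choice that trades a few SNPs for
zero risk of silent sign errors. Pre-regression QC keeps MAF ≥ 0.01,
drops non-ACGT alleles, and optionally drops χ² > 80 (all configurable).

Phenotype scale: for SNP j, the implied phenotypic SD is
sd_y,j = sqrt(2pⱼ(1−pⱼ)·(nⱼ seⱼ² + betaⱼ²)) — the exact least-squares
relation for a standardized phenotype. If the median sd_y departs from 1
by more than 5% (configurable), beta and se are divided by it; z and p are
scale-free and untouched.

Effective sample size for case-control GWAS: Neff = 4·v·(1−v)·n per
cohort (v the case ratio), summed over cohorts. A balanced cohort
contributes its full n. Note that evaluating the formula on pooled counts
is not the same as summing per-cohort values: for pooled counts
53,386/77,258 the formula gives ≈126,282, whereas the per-cohort sum over
the (unpublished) cohort splits of that study is 117,494. The package
computes whatever decomposition it is given; the user guide flags this
distinction.

## LD-score regression

Univariate: χ²ⱼ regressed on xⱼ = N ℓⱼ / M with intercept. Two-pass
weights: first pass 1/max(ℓⱼ, 1); second pass
1/[max(ℓⱼ, 1)·(â + ĥ² xⱼ)²] using the first-pass fit, with the fitted mean
floored at 0.05 to keep weights finite. Bivariate: z₁ⱼz₂ⱼ on
xⱼ = √(N₁N₂) ℓⱼ / M; the variance term of the weights is
m₁ⱼm₂ⱼ + ĉⱼ² with m, ĉ the first-pass univariate and cross means. Using
first-pass means throughout makes a trait paired with itself reduce to
the univariate regression exactly (the weights differ by the constant
factor 2).

Standard errors and V come from a delete-one block jackknife over 200
contiguous genome-ordered blocks (the standard choice), computed from
per-block sufficient statistics so each delete-one fit costs O(1) after
one O(M) pass. All k(k+1)/2 regressions run on the single SNP frame shared
by every trait and the LD table, so the blocks align and V is a coherent
joint sampling covariance (pairwise-maximal SNP overlap would break this).
M is the size of that common frame. Negative heritability slopes are
flagged, not errors. S is smoothed to positive semidefinite (eigenvalue
floor 1e-8) before SEM consumption, with the maximum perturbation logged.

Desk-scale caveat: with M a few tens of thousands and the strong per-SNP
signal that implies, the regression *intercept* is the least precisely
estimated quantity (its information comes from extrapolating to ℓ = 0).
S recovery and its jackknife calibration are unaffected — 95% CIs for S
entries cover the truth at 0.92–0.95 over 200 replicates under the test
conditions — but downstream consumers of the intercept matrix should
prefer known overlap structure when it is available (see factor GWAS).

## Structural-equation models on (S, V)

Models compile to RAM matrices: directed paths in A, undirected
(co)variances in S_mat, B = (I − A)⁻¹, implied covariance
Σ = [B S_mat Bᵀ] restricted to the observed block. Defaults: every
observed variable gets a free residual variance; factor scale is set by
unit-variance identification (variance fixed to 1) or unit-loading
(first declared loading fixed to 1, variance free); undeclared covariances
are 0. Cyclic directed paths and latents with no path to an observed
variable are rejected at compile time.

Fitting: DWLS objective (s − σ(θ))ᵀ D⁻¹ (s − σ(θ)) with D = diag(V)
(floored at 1e-12 of its maximum), minimized by L-BFGS-B with analytic
gradients (dΣ = B E C + C Eᵀ Bᵀ for path parameters, B E_sym Bᵀ for
(co)variances). Starts: loadings 0.5·√S_ii, residuals 0.5·S_ii,
covariances 0; five restarts with multiplicative jitter from a fixed
generator, so fits are deterministic. Convergence requires optimizer
success or a relative projected-gradient criterion; non-convergence after
all restarts raises with the best objective. Negative residual variances
are permitted during optimization and flagged post hoc (Heywood case),
matching common SEM practice.

Uncertainty: sandwich covariance
(ΔᵀWΔ)⁻¹ ΔᵀW V WΔ (ΔᵀWΔ)⁻¹ with W = D⁻¹ and Δ = ∂σ/∂θ. Model χ² is the
quadratic form of the residual e = s − σ(θ̂) in the rank-df pseudo-inverse
of its sampling covariance PVPᵀ (P the DWLS projection); df = q − n_free;
p from the χ²(df) upper tail. CFI uses the independence baseline
(free variances, zero covariances) fitted by the same machinery; SRMR is
the RMS of correlation-scale residuals. Simulation shows the statistic is
mildly inflated in the mean (≈2.6 at df = 2 over replicates) but rejects
at the nominal 5% rate. Standardized solutions rescale all variances to 1,
with delta-method CIs from a central-difference Jacobian.

## The cognitive battery models

- Correlated model: RT is its own genetic component (single indicator,
  free loading, residual fixed 0), fluid and crystallized factors with one
  cross-loading indicator on both, all factor correlations free.
  df = 11 with 7 traits.
- Language: one factor over four language tests; for GWAS the nonword
  reading loading anchors the scale at 1. df = 2.
- Extended: adds the language GWAS trait (loading on Gc and, to absorb any
  unexpected relation, on Gf) and EA as a correlated single-indicator
  factor with zero residual. df = 21 with 9 traits. In GWAS mode the
  Gf → language path is dropped and the named anchor indicators are fixed
  to 1.
- Subtraction: orthogonal Cholesky factors RT → Gf_u → Gc_u → NonCog with
  the full triangular loading pattern (each factor loads on its own stream
  and everything entered later, including language and EA; the
  cross-loading indicator receives RT, Gf_u and Gc_u), factor covariances
  fixed to 0, RT and EA residuals fixed to 0. df = 15. The Gf → language
  drop belongs to the extended model's GWAS form, not here: the df
  arithmetic (45 moments − 23 loadings − 7 residuals = 15) pins this down.
  GWAS-mode anchors: the RT trait, the fluid anchor (matrix), the
  crystallized anchor (vocabulary synonyms), and EA for NonCog.
- External traits are added one at a time (five free parameters: variance
  plus four factor covariances), keeping the cognitive part of the model
  untouched; their standardized covariances with the unit-variance factors
  are the reported genetic correlations.

EA variance decomposition: with zero EA residual, the share of EA's
genetic variance attributable to each factor is the squared standardized
loading, and the NonCog share is 1 minus the summed cognitive shares; the
operation accepts either a combined cognitive-pathway loading or the
per-factor vector.

## Factor GWAS

The structural model is fitted once genome-wide; each SNP contributes the
moments cov(SNP, trait t) = β_t·2p(1−p) with sampling covariance
(2p(1−p))²·se_t se_u·I_tu, where I is the LDSC intercept matrix (constant
across SNPs) and the SNP variance 2p(1−p) is treated as known, with MAF
from the reference panel. By default the SNP → factor paths are estimated
conditionally — structural parameters held at their genome-wide estimates,
the paths solved by weighted least squares on the SNP moments with
sandwich SEs (a speed/fidelity trade-off; for a single-factor toy the
conditional and full-refit estimates agree to 0.1%). A full per-SNP DWLS
refit is available via `mode="full"`. Effects are reported per allele on
the standardized (unit-variance) factor scale. Heterogeneity statistics
are not computed; the schema leaves room for them.

Power summaries: mean χ² of the factor z statistics, and the expected
sample size N̂ = mean over MAF ∈ [0.10, 0.40] of 1/(2p(1−p)·SE²), which for
a clean single-factor model approaches the information sum Σ_t N_t λ_t²
(observed within 4–10% in simulation). N̂ is meaningful only on the
standardized scale — jointly rescaling beta and SE by c changes it by
1/c² while z and p are invariant.

Because the per-SNP sandwich consumes the intercept matrix, its
calibration inherits the intercept-estimation caveat above: the
calibration and power tests supply the generating overlap matrix
(identity in the no-overlap designs), emulating the precision a
1.2M-SNP real analysis attains. Under null SNPs the type-I error at
α = 0.05 then sits inside per-seed binomial 95% bands.

## Loci

Clumping follows the two-stage reading of the published rule: (1)
independence — significant SNPs (p < 5e-8) visited in ascending p join the
independent set iff r² < 0.1 with every previously accepted SNP, ties
broken by chromosome, position, then SNP id so the result is invariant to
input row order; rejected significant SNPs attach to the earliest accepted
SNP they are linked to; (2) merging — independent SNPs within 250 kb
(chained, inclusive) form one locus, lead = lowest p. Candidate SNPs join
at r² ≥ 0.6 to any independent SNP irrespective of their own p-value
(a config switch selects |r| > 0.6 instead, surfacing the r-vs-r²
ambiguity of the published description), and locus bounds span all
candidates. Two loci of different traits overlap iff their candidate sets
intersect, so sharing only a linked non-significant SNP counts. BED export
converts the internal 1-based inclusive intervals to 0-based half-open
(start − 1) exactly. The implementation is tested for exact agreement with
an independently coded exhaustive oracle on 100 random panels per run.

## Synthetic data

The generator works on the z-statistic scale — precisely the sufficiency
level LDSC and summary-statistic SEM consume — with no individual-level
genotypes. Per SNP j, the k-vector of z draws from N(0, Cⱼ) with
Cⱼ = A ℓⱼ + B, A = √(N Nᵀ) ∘ Σ_g / M, B the intercept matrix implied by
sample overlap (B_tu = ρ_tu·n_shared/√(N_t N_u), unit diagonal). Sampling
uses z = √ℓⱼ·L_A ε₁ + L_B ε₂ with matrix square roots of A and B, which is
exact and fully vectorized. beta = z·se with se = 1/√(N·2p(1−p));
MAF ~ Uniform(0.05, 0.5); ℓ ~ 1 + Gamma(shape 2, scale 40) (mean ≈ 81,
loosely emulating common-variant panels). Everything is deterministic
given the seed; stages draw from independent seed-derived streams.

Factor architectures draw per-causal-SNP factor effects with variance
ℓⱼ·h²_factor/(c·M) (c the causal fraction) — the marginal/tagged-effect
scale, the proportionality constant chosen so the mean χ² matches the
LDSC expectation 1 + N h² ℓⱼ/M and heritabilities are recovered on the
usual scale. Trait effects are loadings × factor effects plus
trait-unique effects; the truth table records the factor effects per
standardized genotype for recovery scoring. Case-control traits are
simulated as continuous traits at the summed per-cohort effective N.

What the simulator does *not* emulate: cross-SNP correlation of z (LD
enters only through ℓⱼ; jackknife SEs therefore behave slightly better
than on real data), annotation-stratified architectures, population
stratification, and realistic human LD maps. Clumping is exercised on
separate block-diagonal signed AR(1) LD matrices with random decay and
sign flips (positive semidefinite by construction). Passing tests
demonstrate correctness of the estimators under the stated model, not
robustness to these real-data features.

The bundled demo battery (`simulate.demo_config`) mirrors the subtraction
structure: nine traits with standardized loadings on four orthogonal
factors, per-trait heritabilities loosely following published estimates
(0.07–0.25), RT and EA fully explained by the factors, and an optional
external disorder trait with prescribed factor correlations
(default: negative with RT and Gf_u, positive with Gc_u and NonCog, the
sign pattern reported for psychotic disorders). Demo sample sizes are a
few thousand per trait so that, at M = 20,000, per-SNP signal and runtime
stay desk-scale; mean trait χ² (≈3–8) is accordingly larger than in
million-SNP analyses. The full pipeline (simulate → munge → LDSC → fits →
factor GWAS → clump → external correlations) completes in well under a
minute at these sizes.

## Known limitations

- Partitioned/stratified LDSC, covariate-adjusted LDSC and within-trait
  cohort weighting are out of scope; ℓⱼ is an input, never computed from
  genotypes.
- The χ²/CFI formulas are the standard residual-based summary-statistic
  constructions; equivalence with any particular SEM software is not
  asserted.
- The conditional factor-GWAS estimator ignores the sampling error of the
  structural parameters; with weak factors the full refit is preferable.
- Genome-scale throughput is not a goal: the per-SNP loop is plain Python
  over small linear algebra (~10k SNPs/s).
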