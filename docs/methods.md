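# Methods

## Summary-statistics model

All locus-level inference starts from the RSS likelihood: for m variants
with LD correlation matrix R and standardized joint effects b, the
marginal association z-scores satisfy z ~ MVN(√n·R·b, R). This is also the
generative model of the synthetic-data module, so planted truth and the
fine-mapping likelihood agree by construction.

### Wakefield approximate Bayes factor

log ABF = ½·log(V/(V+W)) + ½·z²·W/(V+W), with W the prior effect variance
and V the sampling variance. For z-score-only input we parameterize on the
standardized-effect scale: V = 1/n and W = sd² with sd = 0.15 by default
(`ABFPrior.from_sample_size`), the conventional quantitative-trait prior.
Only the ratio W/V (= n·sd², the prior variance on the z scale) affects
variant ranking, so the same scalar drives the SuSiE prior.

### Sum-of-single-effects fine-mapping (`susie_rss`)

We fit L (default 5) single effects to the RSS likelihood by block
coordinate ascent: effect l is refit to the residual z-scores
zr = z − R·Σ_{k≠l} ᾱ_k μ̄_k, where the single-effect posterior is available
in closed form (s² = V_l/(1+V_l), μ_j = s²·zr_j,
α_j ∝ π_j·exp(lbf_j)). Because the single-effect family contains the exact
posterior, each block update maximizes its ELBO contribution exactly, so
the variational objective is non-decreasing; the implementation asserts
this at every sweep and raises if violated. Convergence: ELBO change
< 1e-4 (default) or 100 sweeps.

Per-effect prior variances are re-optimized each sweep by empirical Bayes
(bounded scalar maximization of the effect's marginal likelihood over V,
compared against V = 0). Effects whose optimized prior variance collapses
to zero carry no signal and are excluded from PIP computation and
credible-set reporting. This is deliberate: with a fixed prior, the
surplus effects (L larger than the number of true signals) produce
near-uniform inclusion vectors whose 95% credible sets always pass any
cumulative-probability retention filter, flooding the output with
uninformative sets. The empirical-Bayes switch-off mirrors how the
reference sum-of-single-effects implementations behave at their defaults.
A fixed-prior mode (`estimate_prior_variance=False`) remains available and
is the mode under which the L=1 fit is provably identical to exhaustive
single-causal enumeration.

Credible sets are the smallest per-effect sets reaching 95% coverage by
descending inclusion probability (ties broken by ascending variant index
for determinism). Purity (min |r| over member pairs, subsampled above 200
members) is reported; the purity filter defaults to 0, i.e. no set is
dropped for purity. The retention rule is applied post hoc, not as the
coverage parameter: sets with cumulative inclusion probability ≤ 0.85 are
dropped, and members with overall PIP ≤ 0.005 are pruned from surviving
sets.

Non-PSD LD matrices are regularized by an additive diagonal (logged via a
warning) or rejected, per configuration.

### LLR selection and LD supplementation

The likelihood-ratio rule is implemented under the normal approximation as
LLR_i = (z_i² − z_lead²)/2, retaining variants with LLR ≥ −ln(ratio),
ratio 1000 by default; the underlying likelihood is not uniquely pinned
down by a "1:1000" phrasing, and the quadratic z form is our documented
choice. LD supplementation admits proxies with r² strictly > 0.8 to the
lead that are absent from the assessed summary statistics (e.g. indels
missing from an imputation panel). The CCV union preserves per-source
provenance flags (bayesian / llr / ld_proxy) and orders deterministically
by position then id. External engines' results enter through a documented
TSV schema (`io.read_finemap`); no engine internals are re-implemented.

### Conditional association

On the standardized scale, for conditioning set C:
z_cond,j = (z_j − R_jC (R_CC+λI)⁻¹ z_C) / √(1 − R_jC (R_CC+λI)⁻¹ R_Cj),
with ridge λ = 1e-8 by default and conditional variances below 1e-10
flagged collinear and excluded. An empty conditioning set is the identity.

## Colocalization

Five-hypothesis single-causal enumeration from per-variant log-ABFs,
computed entirely in log space (log-sum-exp; the i≠j sum for H3 uses a
stable log-difference). Priors default to p1 = p2 = 1e-4, p12 = 1e-5, with
presets 1e-5/1e-4/1e-3 for the shared-causal prior reflecting a
stringent-to-lenient sweep; the decision band is PP4 > 0.8 (support) and
PP4 < 0.2 (against). Per-signal colocalization pairs the retained effects
of two fine-mapping fits and enumerates on their per-effect log Bayes
factors, reporting the full matrix and the maximum PP4 (0 when either fit
retains no effect).

## TWAS and conditioning on predicted expression

Weights are trained from eQTL summary statistics (top1 indicator, top-k
marginal z, or ridge (R+λI)⁻¹z); FUSION-style individual-level training is
out of reach of summary input, and the training scheme is recorded in the
output. The gene statistic is Z = w'z/√(w'Rw) with two-sided normal p (no
multiple-testing correction inside the module). Conditioning appends one
pseudo-variant per gene with SNP–gene correlation Rw/√(w'Rw), gene–gene
correlations of predicted expression, and pseudo-z equal to the marginal
TWAS Z, then applies the conditional formula. A SNP perfectly captured by
a gene model (conditional variance at the ridge floor) is reported with
conditional z = 0 rather than dropped — conditioning on the gene explains
it entirely. The joint model standardizes G⁻¹Z_marg by the joint precision
so uncorrelated genes keep their marginal Z; gene–gene correlation above
1−1e-8 (or a singular G) is an error.

## Variant annotation and gene nomination

All interval logic is 0-based half-open; adjacency never crosses
chromosomes. The enhancer/promoter vocabularies for melanocyte and
melanoma chromHMM tracks are shipped as defaults and overridable; unknown
states classify as "other" with a warning. A variant is cis-regulatory if
it overlaps an enhancer or promoter state or an ATAC peak in either cell
class. Windows are ±500 bp around the 1-bp variant position, clamped at
position 0. Fragment lookup returns the overlapping run plus one fragment
on each side ("adjacent" is not defined more precisely by the upstream
assay convention; ±1 fragment is our configurable choice). Interactions
are unordered pairs, deduplicated keeping the maximum score; nomination
requires score strictly > 5 linking any variant fragment to a promoter
fragment. Refinement upgrades a candidate to enhancer_promoter evidence
when at least one supporting variant is cis-regulatory. A four-fragment
aggregated resolution is available as an optional pre-merge
(`FragmentMap.merged(4)`), off by default. CpG probes assign to a gene
when within 1.5 kb of the TSS or inside a listed feature interval; strand
is ignored (promoters and features are supplied as intervals).

## Tumor cohorts

Model 1 calls a sample mutant on any mutation at BRAF codon 600/601 or
NRAS codon 61/12/13, matching by codon position regardless of the
alternate residue; unparseable protein changes on hotspot genes warn and
count as non-hotspot. Models 2–5 require a driver-flagged mutation in the
model's gene panel intersected with the cohort's assessed genes; samples
without mutations are WT over the assessed genes. The Model 5 panel ships
as a 10-gene stand-in for the full 44-gene pan-cancer MAPK list and is
configurable.

Expression association is OLS of expression on the WT indicator plus
age/sex/purity/stage where available (stage encoded ordinally I<II<III<IV;
covariates missing for a whole cohort are dropped, samples with remaining
missingness are dropped). Positive coefficients mean higher expression in
wild-type tumors.

Survival: stage-I samples are excluded (they are profiled almost
exclusively in early-stage cohorts and would distort comparability);
expression is dichotomized at the median of the full (stage-filtered)
cohort with ties assigned to "low" (a deterministic convention); the Cox
model for the high-expression indicator runs within the hotspot-WT
subgroup. The Firth-penalized partial likelihood
l*(β) = l(β) + ½·log det I(β) (Efron ties) is maximized by Newton steps
using the observed information as curvature with step-halving, which
guarantees the penalized objective never decreases across accepted steps.
The penalty gradient and the standard errors (curvature of l* at the
optimum) are computed by central finite differences — with ≤5 covariates
this costs a handful of O(n) likelihood evaluations and avoids
third-derivative tensors. Under complete separation the penalized estimate
is finite while the unpenalized likelihood is monotone in β.

Meta-analysis: n_eff = n⁺n⁻/(n⁺+n⁻) (any constant factor cancels in the
normalized weights w_i = √(n_eff,i/Σn_eff), which satisfy Σw_i² = 1
exactly), Z_meta = Σw_i z_i ~ N(0,1) under the null. For expression the
group sizes are mutant/WT counts; for survival the high/low expression
counts within the analyzed WT subgroup (the alternative WT-subset totals
are available to callers via the per-cohort results).

## Synthetic data: what it emulates and what it does not

LD is block-diagonal AR(1) (entry ρ^|i−j| within a block, zero across) —
the simplest structure with tunable decay and closed-form entries for
tests. Genotypes come from a Gaussian copula (latent MVN thresholded at
Hardy–Weinberg quantiles), preserving the target correlation
monotonically. Tumor cohorts plant a WT-group expression shift δ, linear
covariate effects, and exponential survival with hazard
h0·exp(β·1[high expression]) under independent exponential censoring,
times in days. Defaults: baseline hazard 1/1500 per day (median survival
≈ 2.8 years, typical of advanced melanoma cohorts), censoring 1/3000 per
day, expression noise SD 1. Every generator draws from a single seeded
NumPy generator per call; identical spec + seed is bit-for-bit
reproducible, and all planted truth (causal indices, effects,
enhancer–promoter pairs, δ, β) round-trips through the output objects.

Real data differ in ways these simulations do not capture: empirical LD is
not AR(1) and is estimated from a finite reference panel (panel mismatch
is not simulated); effect sizes and allele frequencies are coupled;
chromatin tracks have correlated, biased coverage rather than planted
intervals; cohort expression is normalized per-cohort by heterogeneous
pipelines; survival hazards are not exponential and censoring is
informative in practice. Passing the recovery/calibration benchmarks
therefore demonstrates correctness of the statistical machinery under its
own assumptions, not robustness to these real-data pathologies (LD
mismatch robustness in particular is delegated to external engines whose
results the union step accepts).

## Benchmark problem sizes

The simulation benchmarks use loci of 100–200 variants, n = 50,000 with
standardized effects 0.05 (|z| ≈ 11 at the causal), 100 seeds for
recovery/attenuation rates, 5,000 draws for calibration rates, 200
replicates at n = 500 (≥150 events) for Cox parameter recovery, and 10,000
panels for the meta-analysis null — sizes at which the Monte-Carlo error
of each checked rate is well below the asserted margins.
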