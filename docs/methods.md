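# Methods

This note documents the statistical procedures implemented in `transmr`,
the defaults chosen where the underlying methods admit variants, what the
synthetic-data generator does and does not emulate, and known limitations.

## Data model and harmonization

Summary statistics are per-SNP records (id, chromosome, position, effect
and other allele, effect-allele frequency, beta, SE, P, N). Quantitative
traits carry effects in trait-SD units; binary traits on the natural-log
odds scale. Validation drops records with non-positive SE or N, equal
alleles, or allele frequency outside [0,1], and counts the drops; missing
P-values are recomputed from the two-sided normal z = beta/se, and a
reported P disagreeing with z by more than a factor of 10 is logged but
kept.

Harmonization aligns the outcome cohort to the exposure's effect alleles,
flipping the outcome beta where alleles are swapped (directly or on the
complementary strand) and excluding irreconcilable pairs. Palindromic
(A/T, C/G) SNPs are dropped by default, because strand cannot be resolved
from alleles alone; under the `keep_with_eaf` policy they are retained
when both cohorts report a frequency clearly away from 0.5
(min(eaf, 1−eaf) < 0.42) and are oriented purely by frequency. The 0.42
cut-off is the conventional ambiguity threshold; it trades a small loss of
instruments for protection against silent sign errors.

Cross-cohort SD rescaling multiplies beta and SE by SD_target/SD_source so
both cohorts' effects are per the same SD; z-scores and P-values are
unchanged. Case-control sample sizes enter as the effective
N = 4/(1/n_cases + 1/n_controls).

## Instrument-selection cascade

The cascade order is fixed: discovery meta-analysis → consistency filter →
LD clumping → cross-trait pleiotropy screen → MR-PRESSO. Every SNP ends in
exactly one state with a recorded drop reason, so the audit table
partitions the candidates and filter counts always sum to the input size.

- **Discovery meta-analysis.** Per-SNP fixed-effect inverse-variance
  combination of the two cohorts; SNPs absent from either cohort are
  excluded rather than imputed.
- **Consistency filter.** Drops SNPs with P ≥ 0.05 in either cohort or
  discordant effect signs; this enforces that instruments reflect shared
  rather than cohort-private associations.
- **Clumping.** Greedy: repeatedly take the remaining SNP with the
  smallest discovery P (below 5×10⁻⁸), drop SNPs on the same chromosome
  within ±1 Mb with r² ≥ 0.01 against it. Ties on P break by (chromosome,
  position, id) for determinism. The ±1 Mb radius follows the PLINK
  clump-kb convention. Clumping runs once per population LD panel and the
  survivors are intersected by default (union available), since
  instruments must be index SNPs in both ancestries. SNP pairs absent from
  a (possibly sparse) LD input count as unlinked, with a warning.
- **Pleiotropy screen.** A candidate significant (P_meta < 5×10⁻⁸) for any
  non-exposure trait is dropped unless the (SNP, trait) pair is on a
  configured allow-list; absent lookups count as non-significant. The
  allow-list is configuration, not code.
- **MR-PRESSO.** For each instrument j, an IVW slope is fitted without j
  and the weighted squared residual of Γ̂ⱼ about its prediction recorded;
  the global statistic is the residual sum, referred to an empirical null
  of n_sim = 1000 parametric draws in which outcome effects are redrawn
  about their leave-one-out predictions and exposure effects about their
  observed values. Per-SNP outlier P-values are empirical tail
  probabilities with Bonferroni adjustment over instruments; SNPs are
  removed only when the global test itself rejects at α = 0.05. The test
  runs per population; a SNP flagged in either population is dropped.
  Note the resolution floor: the smallest attainable adjusted outlier P is
  k/(n_sim+1), so detecting outliers among k = 30 instruments at α = 0.05
  needs n_sim ≳ 600 — hence the default of 1000. At least 4 instruments
  are required.

## Estimators

**IVW (multiplicative random effects).** Weighted regression of outcome on
exposure effects through the origin, weights 1/σ_yj². The fixed-effect SE
is inflated by max(1, √(Q/(k−1))); the inflation is one-sided, so the MRE
SE never falls below the fixed-effect SE and equals it when Q ≤ k−1. A
single instrument falls back to the Wald ratio with a log note.

**RAPS.** The estimating equation Σ ψ(tⱼ) γ̂ⱼ/sⱼ = 0 is solved by scanning
a bounded bracket ([−10, 10], 20 intervals) for sign changes and refining
each by Brent's method; with multiple roots the one nearest the IVW
estimate is taken (the score can change sign spuriously where |β| is large
and all weights collapse). If no root exists in the bracket, a
non-convergence error carrying the bracket is raised rather than returning
a boundary value. Overdispersion τ² ≥ 0 is profiled at each β so that
mean(ψ(t)·t) matches its standard-normal expectation (1 for l2,
2Φ(c)−1 for Huber with c = 1.345). The SE is the sandwich
√(Σψ(t)²u²)/Σψ′(t)u², u = γ̂/s. Defaults are Huber loss with
overdispersion, the robust configuration recommended for the method;
`loss="l2"` without overdispersion reproduces fixed-effect IVW exactly in
the no-measurement-error limit, which the tests use as an oracle.

**Steiger directionality.** Summed per-IV PVE on the exposure and outcome
sides is converted to correlations (√ of the sums) and compared by the
z-test on Fisher transforms with variances 1/(N−3). For a binary outcome
the same z-score PVE approximation is applied to log-odds effects
(liability-scale refinements are out of scope); directions are called only
when the test rejects.

**Multivariable MR.** The outcome effects are regressed on the k×m matrix
of exposure effects without intercept, rows pre-scaled by 1/σ_yj, using
Huber M-estimation (tuning 1.345, IRLS to tolerance 1e−8, max 200
iterations) via statsmodels' RLM with sandwich SEs. An exact-fit guard
returns the weighted least-squares solution when residuals vanish (the MAD
scale would otherwise be zero). The instrument union is pruned to pairwise
r² < 0.01, preferring the priority trait's instruments, then smaller
discovery P, then position; instruments significant for any non-exposure
trait are removed. k ≤ m raises an under-identification error.

**Conditional F.** For exposure i, its instrument effects are regressed on
the other exposures' effects with weights iterated from the implied
residual variance σ_i² − 2δ′c + δ′Vδ, where the cross-covariances come
from the SEs and the phenotypic correlation matrix (full-overlap
approximation); F = Q/(k−m+1) from the weighted residual sum of squares.
With m = 1 this reduces exactly to the mean per-IV F (mean z², consistent
with PVE = z²/(z²+N−2), under which F and z² coincide). The construction
has variants in the literature; this one is validated by its m = 1
reduction and its collinear limit (F → 0), not claimed to replicate any
particular implementation.

**Meta-analysis.** Fixed-effect inverse-variance weighting; Cochran's Q at
k−1 df; for two populations Q = (β₁−β₂)²/(se₁²+se₂²). Combined P-values
are two-sided normal (equivalent to chi-square at 1 df). CI conversion
uses the exact normal quantile 1.959964 at 95%; comparisons against
printed tables round to the published precision (2 dp for ORs, 3 dp for
heterogeneity P). Population heterogeneity is flagged at P_het < 0.01.

## Multiple testing

Bonferroni only: 0.05/m with m = 37 forward and m = 4 reverse by default
(configurable). No FDR option.

## Synthetic-data generator

The generator works directly on the estimate scale — no individual-level
genotypes — drawing observed effects as truth plus noise with the analytic
SE 1/√(2·eaf·(1−eaf)·N) (effective N for the binary outcome). Causal
exposure effects are spike-and-slab (polygenicity 0.02, slab SD 0.015 per
SD of exposure by default), correlated 0.8 between populations on the
slab, emulating largely shared causal variants. True outcome effects are
Γⱼ = Σ_t β_t γⱼt + αⱼ with direct effects αⱼ (SD 0.05 on the log-odds
scale) for 5% of causal SNPs by default. LD is block-diagonal (blocks of
5, within-block r² = 0.4); the signed correlation both propagates causal
effects to tagging SNPs (marginal = R·causal) and correlates sampling
noise within blocks, so clumping is exercised realistically. Sample
overlap is emulated as correlation ρ = r·(phenotypic correlation) between
exposure and outcome noise. Default sample sizes emulate a Japanese
biobank (N ≈ 150k exposure; 29k/170k cases/controls) and a UK biobank
(360k; 60k/123k).

What it does not emulate: realistic human LD maps and allele-frequency
spectra, liability-threshold disease architecture, population
stratification, cryptic relatedness, or winner's-curse selection into the
discovery set. Passing calibration tests therefore demonstrates the
pipeline's internal correctness and statistical calibration under the
stated generating model, not robustness to every artefact of real data.

## Calibration experiments and problem sizes

The validation battery (module `transmr.calibration`) runs: full-pipeline
type-I error under the null over 500 replicates of a compact genome (240
SNPs, blocks of 4, polygenicity 0.1, MR-PRESSO n_sim 200 per replicate —
sizes chosen so the battery completes in minutes on one CPU while leaving
enough instruments per replicate); IVW 95% CI coverage over 500 replicates
at 50 instruments; RAPS bias over 200 replicates at β = 0.3; MR-PRESSO
planted-outlier (10 SE) detection and null false-removal over 50 seeds;
MVMR recovery of direct effects (0.3, −0.2, 0) over 200 replicates of 60
instruments; and the power of the between-population Q test for a planted
population-specific effect at published-study scale (β 0.239 vs 0.020,
57/56 instruments, per-population MR SEs 0.058/0.045).

On that last experiment: with those SEs the heterogeneity Q is noncentral
χ²₁ with ncp ≈ (0.219/0.0734)² ≈ 8.9, whose analytic power at P < 0.01 is
≈ 0.66 (measured ≈ 0.62, slightly lower because the one-sided MRE SE
inflation widens some intervals). A detection power of 80% at that effect
difference would require per-population SEs of about 0.045 or less. The
experiment is reported at the published scale rather than at a scale
chosen to flatter the test.

## Numerical choices and degenerate inputs

Exact normal quantiles throughout (no 1.96 rounding); empirical P-values
use the (hits+1)/(n+1) estimator so they are never zero; clump ties break
lexicographically; missing LD entries count as r² = 0 with a warning;
RAPS brackets and multi-starts are fixed for determinism; all simulation
entry points take a mandatory seed, and identical seeds give byte-identical
rendered reports. Degenerate cases raise typed errors: zero exposure
effect (Wald), < 3 instruments (RAPS), < 4 (MR-PRESSO), k ≤ m (MVMR),
empty harmonization intersection.

## Limitations

Estimator slots are filled by IVW-MRE and RAPS; Bayesian estimators
(MR-Corr, BWMR) and MR-Egger/median/mode are out of scope, as are LD-score
regression heritability, genetic correlation, liability-scale conversion,
nonlinear causal effects, and real-biobank ingestion. The overlap-bias
formula βr/F is a first-order approximation. The conditional-F phenotypic
correlation enters under a full-overlap approximation of estimate
covariance.
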