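# Methods

## Setting and assumptions

`ivmr` implements two-sample summary-level Mendelian randomization.  The
exposure association β̂X_j (SD units per effect allele, SE σX_j) and outcome
association β̂Y_j (log-odds per allele, SE σY_j) of each SNP come from
non-overlapping GWAS samples, so their estimation errors are independent.
The identifying assumptions are the usual instrumental-variable triple:
relevance (γ_j ≠ 0, enforced operationally by the genome-wide significance
screen), independence from exposure–outcome confounders, and exclusion
restriction (no direct SNP → outcome path).  All estimators take the
summary pairs at face value; allele-level harmonization (strand flips,
palindromic SNPs, allele-frequency matching) is assumed done upstream and is
out of scope.

Per-SNP effects on a binary outcome may be reconstructed from a 2×2 table of
effective/non-effective allele counts in cases (a, b) and controls (c, d):
OR = ad/bc, β = ln OR, se(ln OR) = √(1/a + 1/b + 1/c + 1/d).  Tables with a
zero cell raise an error; no continuity correction is applied, because a
silent +0.5 would change estimates without the analyst's knowledge.

## Instrument selection

1. **Significance screen** — keep SNPs with exposure p ≤ 5×10⁻⁸
   (inclusive boundary).
2. **Outcome-association exclusion** — delete SNPs with outcome p < 0.05
   (strict boundary).  A conservative guard against variants whose primary
   association is with the outcome; a SNP with no outcome record is kept by
   default (configurable), since absence of a record is not evidence of
   association.
3. **LD pruning** — greedy: visit SNPs in ascending exposure p-value
   (lexicographic rsID tie-break); keep a SNP iff its r² with every
   already-kept SNP is below 0.01.  The visit order is a declared
   convention: it retains the strongest exposure signal of each correlated
   cluster and makes the output deterministic and invariant to input
   permutation.  The kept set is always mutually below threshold and
   maximal (every pruned SNP conflicts with a kept one), but it is *not*
   monotone in the r² threshold — greedy keep-decisions depend on the
   evolving kept set, so loosening the threshold can exchange which member
   of a cluster survives.

Every removal is recorded with its stage and triggering value, so the three
set sizes are fully auditable.

## Estimators

**IVW.** Closed-form weighted least squares of β̂Y on β̂X through the origin
with weights σY⁻².  The fixed-effect SE is (Σ β̂X² σY⁻²)^(−1/2); a
multiplicative random-effects model is available that inflates the SE by
max(1, √(Q/(J−1))), Q the weighted residual sum of squares.  The default is
fixed-effect.  J = 1 is allowed and reduces exactly to the Wald ratio.  The
Wald-ratio SE is first-order (σY/|β̂X|), ignoring exposure-side noise — the
standard convention when instruments pass a genome-wide screen; its residual
effect is a small attenuation visible in the recovery experiment below.

**MR-Egger.** The same weighted regression with an intercept, after
orienting every instrument to β̂X > 0 (the intercept's sign is meaningless
without a fixed orientation; orientation makes the fit invariant to allele
flips).  Requires J ≥ 3 and non-constant β̂X.  The intercept block is
reported with its own SE/CI/p as the directional-pleiotropy test.

**Penalized variants.** With reference estimate θ_ref (the corresponding
unpenalized fit — robust if the robust variant is requested; for Egger
variants, the unpenalized Egger *slope*), each instrument's heterogeneity
contribution q_j = w_j (θ̂_j − θ_ref)², w_j = β̂X_j²/σY_j², is referred to a
χ²₁ law and the weight multiplied by min(1, 20·P(χ²₁ > q_j)).  Instruments
consistent with θ_ref (upper-tail p > 0.05) are untouched; outliers are
downweighted smoothly to zero.  The scale 20 and the χ²₁ form are declared
conventions following the penalized-weights literature the robust/penalized
IVW family comes from.

**Robust variants.** Tukey-biweight M-estimation (tuning 4.685, 95%
Gaussian efficiency) by iteratively reweighted least squares on
standardized residuals u_j = √w_j (y_j − X_j b).  Initialization: weighted
median of per-point slopes for the through-origin model, ordinary WLS with
an intercept.  The scale is fixed at 1.4826×MAD of the initial residuals
(not re-estimated per iteration), which keeps the fit deterministic and the
breakdown behaviour simple.  If that MAD is zero, a majority of points lie
exactly on the initial line; the biweight's scale→0 limit is used — a WLS
restricted to the exact-fit subset — rather than a full-sample fallback,
which a single gross outlier would ruin.  Convergence is a coefficient step
below 1e-8 within 100 iterations; the flag is carried on the estimate.
Robust-variant SEs come from the converged weighted design,
(Xᵀ W_eff X)⁻¹ with W_eff = σY⁻² × penalty × biweight ψ-weight.  This is a
declared convention; it is exact for the limiting WLS fit and slightly
anti-conservative relative to a full sandwich estimator, which matters
little at the heterogeneity levels the penalty leaves behind.

All CIs are β ± z·se with z = 1.96 by default (configurable, e.g.
Φ⁻¹(0.975) = 1.959964); p-values are two-sided normal.  Reports round
β/SE/CI/p to 3 decimals, recomputing CI bounds from unrounded values first;
all internal computation is full precision.

## Zero outcome SEs

The packaged 23-instrument LDL-C → T2DM table contains four rows whose
outcome SE is printed as exactly zero — physically impossible and implying
infinite IVW weight.  The package never guesses: `strict` (default) raises
an error naming the SNPs; `floor` substitutes the smallest positive outcome
SE in the table (or a user value) with a warning; `drop` excludes the rows
with a warning.  More generally the shipped table's outcome columns appear
internally transformed relative to their headers (the SE column contains
values equal to ln(1.00)…ln(1.03) including exact zeros), so published
full-sample estimates are not reproducible from it and are not used as
numerical oracles anywhere; the table is preserved verbatim as input data.

## Sensitivity analysis and reporting

Leave-one-out re-estimates the causal effect J times, excluding one
instrument each time (J ≥ 2, or ≥ 4 for Egger variants).  The default LOO
estimator is the penalized robust IVW — the variant whose stability the
single-SNP influence question is typically asked about — and is
configurable.  `influence_ranking` orders SNPs by |Δβ| from the full-sample
estimate (lexicographic tie-break).  For fixed-effect IVW every LOO SE is ≥
the full-sample SE, a useful internal consistency check.  Forest data are
per-SNP Wald ratios exponentiated to the OR scale; a combined row appears
only when an overall estimate is explicitly supplied.

## Synthetic data generator

`simulate_two_sample` draws, per instrument: true strength
βX_j ~ Uniform(0.02, 0.12) (the magnitude range of published per-allele
LDL-C effects), σX_j ~ Uniform(0.0036, 0.0121) and
σY_j ~ Uniform(0.00995, 0.0296) (the SE ranges of the shipped table), and
sets βY_j = θ·βX_j + α_j·1[invalid] + c·u_j with u_j a shared standard
normal confounder term added to both traits (c = 0 by default).  Observed
effects add independent N(0, σ²) noise on each side; Wald p-values are
attached; null SNPs (βX = 0) and exchangeable constant-r² LD blocks are
optional.  Defaults describe a valid-instrument panel of J = 23 with
θ = 0.25 log-odds per SD.  The generator emulates the *product* of two
GWAS — effect/SE/p tables — not the process producing them: no allele
frequencies, winner's curse, sample overlap, or LD-induced correlation of
estimation errors.  Passing recovery tests therefore demonstrates estimator
correctness under the stated model, not robustness to those real-data
complications.

The contamination scenario used for validation sets 30% of instruments
invalid with directional pleiotropy α_j ~ N(0.05, 0.02²) — direct outcome
effects comparable to or exceeding the mediated effect θ·βX_j, the regime
the robust variants exist for.  `make_paper_like_catalog` instead constructs
a 35-SNP catalog whose selection counts are fixed by construction
(29 genome-wide significant → 6 outcome-associated deleted → 23 mutually
independent), with betas kept Wald-consistent with the assigned p-values;
the seed only perturbs values within their bands.

## Validation experiments (computed by tests and `scripts/acceptance.py`)

Problem sizes were chosen so the full suite runs in seconds on one CPU:
1000 random instances for the least-squares oracle equivalence of IVW and
MR-Egger (agreement to 1e-10); 500 replicates of J = 100 valid instruments
for recovery of θ = 0.25 (mean within ±0.01, 95% CI coverage in
[0.93, 0.97] — the residual bias is the Wald-ratio attenuation noted above,
about −0.004 at these instrument strengths); 1000 no-pleiotropy replicates
for the MR-Egger intercept test's size at α = 0.05; 500 contaminated
replicates comparing median absolute errors of standard vs robust IVW; and
200 seeded instances (≤ 12 SNPs) for brute-force agreement of the LD pruner.

## Known limitations

- No allele-level harmonization or palindromic-SNP handling.
- No weighted-median/mode estimators, multivariable MR, or correlated-
  instrument (GLS) estimation; LD enters only through pruning.
- The robust SE convention above; no bootstrap or sandwich option.
- The multiplicative variance model truncates the dispersion at 1 (never
  deflates), matching common practice but not a likelihood.
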