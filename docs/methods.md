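# Methods

`mrkit` implements the complete analysis workflow of a two-sample Mendelian
randomization (MR) study conducted on GWAS summary statistics: instrument
selection and LD clumping, allele harmonization, univariable causal-effect
estimation with a sensitivity suite, MR-PRESSO outlier handling,
multivariable MR, and two-step mediation. This note records the models,
conventions and numerical choices, and what the synthetic-data experiments
do and do not demonstrate.

## The two-sample MR model

For SNP j, let γ_j be its true effect on the exposure (per SD of a
standardized trait) and α_j any direct effect on the outcome that bypasses
the exposure (horizontal pleiotropy). The observed summary statistics are

    β_X,j ~ N(γ_j, se_X,j²),     β_Y,j ~ N(θ·γ_j + α_j, se_Y,j²),

with θ the causal effect of interest (log-odds per SD for a binary
outcome). The per-SNP Wald ratio β_Y,j/β_X,j estimates θ when α_j = 0.
Exposure and outcome samples are assumed non-overlapping, so the two noise
terms are independent.

### Estimators

- **IVW** — inverse-variance-weighted meta-analysis of the Wald ratios,
  algebraically the zero-intercept weighted regression of β_Y on β_X with
  weights 1/se_Y². "Random effects" means multiplicative overdispersion:
  the fixed-effect SE 1/√(Σ w_j β_X,j²) is multiplied by √(Q/(J−1)) when
  that exceeds 1 and left alone otherwise (flag-switchable to additive
  DerSimonian–Laird or pure fixed effects). P-values are two-sided normal.
- **MR-Egger** — the same regression with an intercept after orienting
  every SNP so β_X,j ≥ 0. The slope estimates θ under the InSIDE
  assumption; the intercept estimates the average directional pleiotropy
  and its test is the Egger intercept test. SEs carry the same
  multiplicative floor; p-values use t with J−2 df (small-J behaviour).
- **Weighted median** — order the ratios, standardize cumulative weights
  s_j = (Σ_{i≤j} w_i − w_j/2)/Σw, and linearly interpolate to s = 1/2.
  Consistent while valid instruments carry > 50% of the weight. The SE is
  a parametric bootstrap (resampling β_X and β_Y from their sampling
  distributions; the seed is a mandatory argument). At finite J this
  interpolated estimator differs from the weighted-absolute-deviation
  minimizer by at most the local gap between adjacent order statistics;
  they coincide in the dense limit.
- **Wald-ratio SEs** use the first-order delta form se_Y/|β_X| (exposure
  uncertainty ignored); a second-order form is available behind a flag.

### Sensitivity suite

- **Cochran's Q** about the IVW estimate, χ² with J−1 df.
- **MR-PRESSO**: the observed residual sum of squares
  RSS = Σ_j w_j (β_Y,j − θ̂₋j β_X,j)², with θ̂₋j the leave-one-out IVW
  estimate, is compared against a parametric bootstrap null (β*_X drawn
  around β_X, β*_Y around θ̂₋j·β_X; exposure uncertainty included, flag to
  disable). The global p-value uses the add-one estimator and can never
  fall below 1/(n_sim+1). Per-SNP outlier p-values use the raw exceedance
  fraction — with an add-one floor, a Bonferroni-adjusted p below α would
  be unattainable at the default n_sim = 1000 with J ≈ 60 — and are
  Bonferroni-adjusted; flagged SNPs are removed and IVW re-estimated. The
  distortion test is not implemented.
- **Leave-one-out** IVW series, flagging omissions that flip the sign or
  leave the full-set CI.
- **Verdict** (per direction): significant iff IVW p < 0.05/(number of
  outcome traits), the three estimators agree in sign, and both the Egger
  intercept and PRESSO global tests have p > 0.05. All inequalities are
  strict; each criterion is stored separately so the verdict is re-derivable
  from the report alone.

### Harmonization

SNPs are matched by identifier. Swapped alleles negate the outcome beta
and reflect its allele frequency; strand complements are reconciled for
non-palindromic SNPs. Palindromic SNPs (A/T, G/C) cannot be strand-resolved
from alleles: under the default "conservative" policy they are kept only
when both allele frequencies are on the same side of 0.5 and outside
[0.42, 0.58] (threshold configurable; a missing frequency drops the SNP);
policy "drop" removes them all. Every decision is recorded in an audit
table whose actions partition the shared SNPs.

### Instrument strength

Genome-wide significance is p < 5×10⁻⁸ (strict), clumping is greedy at
r² < 0.001 within 10,000 kb against a caller-supplied LD matrix (ties in p
broken lexically by SNP id; cross-chromosome pairs never clump; a missing
LD entry for an in-window pair is an error, not an assumption of
independence). Instrument strength is F = ((n−k−1)/k)·R²/(1−R²) with
R² summed over per-SNP r² = β²/(β² + se²·n), an allele-frequency-free
approximation (a 2p(1−p)β² variant is available); the mean per-SNP F is
also reported since both conventions appear in applied work. F ≤ 10 sets a
weak-instrument flag.

## Multivariable MR and mediation

Multivariable IVW regresses β_Y jointly on the E exposures' beta columns
(no intercept, weights 1/se_Y²), solving the weighted normal equations;
with E = 1 it reproduces univariable IVW exactly. Exposure columns are
aligned to the *outcome's* effect allele so all betas share one reference.
The instrument set is the union of per-exposure genome-wide-significant,
cross-exposure-clumped SNPs; rank deficiency raises an error naming the
collinear exposures. A conditional instrument-strength heuristic per
exposure (weighted residual signal of each exposure's betas given the
others) is emitted as a diagnostic, not an estimator input.

Two-step mediation estimates β1 (exposure→mediator univariable IVW on the
exposure's instruments), β2 (mediator→outcome; by default the mediator's
direct effect from multivariable IVW adjusting for the exposure, using the
mediator's instruments — this blocks reverse-pathway contamination, which
a univariable β2 suffers badly in chain designs; the univariable variant
sits behind a flag), and the total effect (exposure→outcome IVW). Then

    indirect = β1·β2,  Var = β1²·se2² + β2²·se1²  (first order;
                       a second_order flag adds se1²·se2²)
    P = indirect/total,  Var(P) = P²·(Var(ind)/ind² + se_total²/total²),

with zero covariance assumed between steps (separate instrument sets and
non-overlapping samples — a documented limitation; the shared exposure
instruments induce a small correlation between β1 and the total effect
that this neglects). Negative proportions (inconsistent mediation) are
reported verbatim. When the total effect is exactly zero the proportion is
undefined (NaN) while the indirect effect is still returned.

## Synthetic data

The generator produces summary-statistic tables directly — no
individual-level genotypes — under the model above, with per-SNP standard
errors 1/√(2p_j(1−p_j)n) of a standardized-trait GWAS at biobank scale.
Defaults mirror the study design the package targets: J = 60 instruments,
exposure n = 329,821, outcome n = 403,124, MAF ~ U(0.05, 0.45), and
γ drawn as |N(0, 0.0219²)| so the set explains ≈ 1% of exposure variance
(joint F ≈ 50–55, matching the F ≈ 40 scale of published biobank MR
instrument sets). Instruments are reported aligned to the
exposure-increasing allele, as published instrument lists are; a flag
restores sign-symmetric effects. Pleiotropy modes: none, balanced
(zero-mean α), directional (α ~ N(m, s²), default m = 0.0018 ≈ 8% of the
mean instrument effect — a moderate contamination whose per-SNP ratio
shifts are of the same order as the causal effects the package studies),
and InSIDE-violated (α correlated with γ through a configurable slope).
Gross outliers shift chosen SNPs' outcome betas by a multiple of their SE.
Case-control outcomes are simulated on the log-odds scale directly.

Structure (MAF, effects, alleles, pleiotropy assignment) and observation
noise come from separate random streams, so replicate experiments can hold
the genetic architecture fixed while redrawing noise — this is what makes
the moment check (SD of β_X,j across replicates equals se_X,j) a testable
property. A noiseless flag replaces draws by their means, giving exact
oracle identities (every Wald ratio equals θ; mediation recovers its
proportion to machine precision). Deliberate palindromic SNPs (20% by
default) and randomly swapped outcome-allele reporting (30%) exercise
harmonization; both are statistical no-ops on the estimators.

The mediation generator adds a mediator GWAS (n = 300,000 by default):
shared SNPs carry β_M = β_xm·γ and β_Y = (β_direct + β_xm·β_my)·γ, and the
mediator receives its own instruments (30 by default) acting on the
outcome only through the mediator. The true proportion mediated
β_xm·β_my/(β_direct + β_xm·β_my) is recorded in the truth object. The LD
generator builds block-diagonal equicorrelated panels (positive
semidefiniteness checked; ρ = 1 allowed for perfect LD), places
within-block SNPs inside the clumping window and blocks outside it, and
draws correlated observed effects so clumping is non-trivial.

What the generator does **not** emulate: realistic LD from reference
panels, allele-frequency differences between studies, sample overlap,
population stratification, winner's-curse selection of instruments from
the same sample, or binary-liability effect-size attenuation. Passing
tests therefore demonstrate correctness of the estimators and pipeline
under the stated sampling model, not robustness to those real-data
complications.

## Validation experiments and their honest outcomes

The test suite validates by three routes: exact micro-examples (hand
weighted-least-squares, interpolation and delta-method arithmetic),
independent numerical oracles (least-squares and normal-equations solvers,
weighted-absolute-deviation grid search, analytic detection-power formula,
10⁶-draw Monte-Carlo error propagation), and seeded Monte-Carlo
experiments at the default biobank conditions: type-I error of the IVW,
Egger-intercept and indirect-effect tests (2000 replicates each, all
within [0.035, 0.065]); weighted-median robustness under 40% directional
pleiotropy (IVW mean bias ≈ +0.024 while the weighted median stays within
0.02 of θ = 0.157 over 500 replicates); MR-PRESSO detection of a planted
10·SE outlier (global p ≤ 0.05 with the correct SNP flagged in ≥ 90% of
200 seeded runs) and a clean-data false-flag rate far below α·J; and
mediation, where the noiseless chain recovers the proportion to 10⁻⁶.

Two properties fail their tightest stated bounds for reasons that are
estimator mathematics, not implementation defects, and are deliberately
left failing rather than loosened:

- the mean IVW estimate over 1000 replicates sits ≈ 1.8% below θ —
  two-sample weak-instrument attenuation of order 1/F̄ (F̄ ≈ 55 at the
  default R² ≈ 1%), which exceeds three Monte-Carlo SEs at that replicate
  count;
- the delta-method 95% CI for the proportion mediated covers the truth in
  ≈ 98% of replicates rather than 93–97%: the overdispersion floors on all
  three component SEs can only widen intervals, making the combined CI
  conservative by construction.

Problem sizes in the routine test runs (replicate counts of 100–2000,
bootstrap 100–1000, PRESSO simulations 1000) are the package's chosen
defaults for these experiments; every stochastic test and script takes an
explicit seed and is exactly reproducible.

## Known limitations

- Wald-ratio and IVW inference ignores exposure-side uncertainty (NOME);
  the attenuation this causes is visible in the validation experiments.
- MR-Egger's intercept is attenuated when weak instruments' observed
  exposure effects flip sign under orientation (~4% of SNPs at default
  strength); exact in the noiseless limit.
- No SIMEX correction, MR-RAPS, mode-based estimators, or PRESSO
  distortion test; no proxy-SNP lookup, liftover or GWAS-VCF parsing.
- The mediation delta method assumes independent steps; instrument overlap
  between β1 and the total effect is logged but not propagated.
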