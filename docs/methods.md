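# Methods

## The estimand and the model

The package quantifies *gene-by-environment effect modification* on the
relative-risk scale: how much the effect of LDL cholesterol on cardiovascular
event risk differs between carriers and non-carriers of a variant allele.
The working model is log-linear in LDL:

    risk(G, L) = r₀ · exp[ β_L (L − L_ref) + G·(β_G + β_GL (L − L_ref)) ]

with G ∈ {0,1} carrier status, L the study-mean LDL in mmol/L, β_L the ln RR
per mmol/L among non-carriers and β_GL the interaction (ln ratio of RRs per
mmol/L). The main genotype effect is not a free parameter: it is pinned by
the *null-crossing* LDL L₀ at which carriers and non-carriers have equal
risk, β_G = −β_GL(L₀ − L_ref). Log-linearity makes two quantities equal by
construction, which is the package's central identity:

* the effect modification of LDL on the genotype→CVD association
  (the meta-regression slope of per-study carrier ln RRs on study LDL), and
* the effect modification of genotype on the LDL→CVD association
  (the carrier-minus-non-carrier difference of per-mmol/L treatment
  effects in stratified trials).

Both estimate β_GL, and exp(−β_GL) is the *expected differential clinical
benefit*: the carrier/non-carrier ratio of RRs per mmol/L of LDL lowering.
The log-linearity (constant ratio of slopes) is an assumption, not a finding;
if the true dose-response were convex on the log scale the two routes would
diverge and the per-mmol/L standardization below would be biased for trials
with large Y.

## Study-level effect estimates

Prospective designs (cohorts and trial arms) contribute unadjusted relative
risks with the delta-method log-scale SE; case-control designs contribute
Woolf odds ratios used as RR approximations and pooled on the same log scale
— adequate in the rare-event regime and checked by simulation (mean |ln OR −
ln RR| < 0.02 at baseline risk ≤ 1%). Zero cells receive the
Haldane–Anscombe +0.5 added to all four cells, applied per table and only
when a zero is present; disabling the correction turns such tables into
errors rather than infinities. Confidence intervals use the exact normal
quantile (1.959964… at 95%) throughout, and published ratio/CI triplets are
converted back to log-scale estimates via se = (ln hi − ln lo)/(2z), which is
exact for intervals built symmetrically on the log scale. Genotype quality
is screened with the 1-df Pearson χ² test of Hardy–Weinberg proportions
(undefined, by design, for monomorphic samples).

## Pooling and heterogeneity

Pooling is inverse-variance with the DerSimonian–Laird moment estimator of
between-study variance; heterogeneity is reported as Cochran's Q, I² =
max(0, (Q − df)/Q)·100, and τ². The pooled CI uses the normal approximation
without the Knapp–Hartung adjustment, matching the software generation this
methodology comes from. A single study passes through unchanged with τ²
flagged not-estimable, so subset analyses can isolate one study without
erroring.

## Meta-regression

The moderated model yᵢ = β₀ + β₁xᵢ + uᵢ + εᵢ (Var εᵢ = seᵢ², Var uᵢ = τ²) is
fit by REML by default: Fisher scoring on τ² with score ½(yᵀP²y − tr P) and
expected information ½tr(P²), P the REML projection at the current weights,
started from the method-of-moments value, tolerance 1e-8, at most 100
iterations. Overshoots past τ² = 0 halve toward the boundary (the score at 0
is checked first, so a boundary solution is exact), and a bracketing/brentq
fallback guards against scoring oscillation; convergence failures raise an
error carrying the last iterate. The non-iterative method-of-moments
generalization of DerSimonian–Laird is available as `method="mom"`.
Coefficients and their covariance come from weighted least squares at the
converged τ², with weights 1/(seᵢ² + τ²). The implementation was verified
against R's metafor on frozen fixtures (method-of-moments to 1e-10; REML to
metafor's looser internal convergence, with our iterate sitting closer to
the score-equation root).

R², the share of between-study variance explained by the moderator, is
100·(τ²_null − τ²_resid)/τ²_null truncated to [0, 100]; τ²_null is refit
under the *same* estimator on the intercept-only design so the comparison is
like-with-like, and negative raw values (τ² estimation noise) truncate to
zero. Only a single moderator (study mean LDL, with a binary carrier
indicator reused for the trial-route estimator) is supported; requests with
fewer than three studies or a constant moderator are rejected.

## Trial standardization and the benefit comparison

Stratified trials contribute intent-to-treat RRs (active vs control within a
genotype stratum). Because trials achieve different LDL reductions, each log
effect and SE is multiplied by 1/Y (Y = between-arm LDL difference in
mmol/L) before pooling, putting placebo-controlled and intensity-comparison
trials on one per-mmol/L scale (for intensity trials, "active" is the more
intensive arm and Y the between-intensity difference). The observed
differential benefit is the Z-comparison of the pooled carrier and
non-carrier effects; an alternate estimator regresses all stratum effects on
a carrier indicator through the same meta-regression machinery. The expected
benefit treats the slope per mmol/L increase as exactly reciprocal per
mmol/L decrease — an explicit consequence of log-linearity, with no
small-sample correction. The expected-vs-observed agreement z treats the two
log-ratios as independent; in practice trial arms also enter the
meta-regression, the resulting positive correlation makes this agreement
check conservative.

## Synthetic study collections

The generator exists because the original study-level dataset is not
published at the 2×2 level. It samples genotypes in Hardy–Weinberg
proportions at allele frequency 0.37 (the common-variant regime), then
binomial events at the study-mean LDL; each study has exactly one LDL value
(the analysis consumes study-level means, so within-study LDL variation,
follow-up time and censoring are deliberately not modeled). Case-control
studies draw genotype mixtures among cases and controls by Bayes inversion
of the population mixture, making the OR estimate the model RR when events
are rare. Trials draw both arms from one genotype mixture, with the active
arm shifted down by Y. Risks are never clamped: any parameterization whose
risk leaves (0,1) over the collection's LDL range is rejected.

Default parameterization (plumbing for demonstrations, not estimates):
baseline risk 0.05 at L_ref = 3.0 mmol/L, β_L = ln 1.25, β_GL = ln 1.15,
L₀ = 3.5 mmol/L. The default collection mirrors the structure of the real
evidence base: 3 cohorts of 12,825 persons (LDL 2.6/3.5/4.4), 18
case-control studies of 987 cases/2,146 controls (LDL 2.5–4.5), and 8
two-arm trials of 3,129 per arm — 5 placebo-controlled with Y ≈ 1.0–1.25 and
3 intensity-comparison with Y ≈ 0.55–0.65, baselines 2.5–5.0 — so that the
37 association units, 19 meta-regression units and the sensitivity-subset
sizes (3/5/8/8/11/11) match the real collection's shape. A master seed fans
out to per-study streams keyed by a CRC-32 hash of the study id, so adding a
study never perturbs another's draws.

What passing simulation tests shows — and does not. The harnesses certify
internal calibration: when data truly come from the log-linear vulnerability
model with study-level LDL means, the chain recovers β_GL with near-nominal
CI coverage, the two estimation routes agree, the expected and observed
benefit ratios concord within two joint SEs in ≥95% of replicates, and
null-centered collections show marginal RR ≈ 1 despite the interaction.
They cannot certify robustness to what real studies add: outcome-definition
heterogeneity, covariate confounding, LDL measurement error, non-collapsible
alternatives to the RR scale, or selective publication.

## Monte-Carlo study sizes

Replicated harnesses (tests and the acceptance script) run the default
collection at half-size with case-control studies dropped — they enter
neither the meta-regression nor the trial stages being measured — which puts
200-replicate runs in seconds while keeping per-stratum event counts in the
dozens-to-hundreds range where the normal theory is sound. The estimator
symmetry harness instead uses 15,000 per arm: the stratum-difference route
carries a small O(1/events) bias from the correlation between log-RR
estimates and their estimated inverse-variance weights, and the harness
compares Monte-Carlo *means* at a 0.01 tolerance, so it needs that bias well
below the tolerance. Single-shot recovery tests use arms of 2–4·10⁵ with
3-SE bands.

## Numerical and interface choices

* Estimates are immutable dataclasses on the natural-log scale; ratio-scale
  values are derived views. Standardized (per-mmol/L) and unstandardized
  estimates never meet in one pool — pooling happens per stage, and measure
  labels travel with the estimates.
* The CSV schema is one row per study-stratum(-arm): `study_id, design, arm,
  stratum, events, total, mean_ldl, delta_ldl, trial_type`. Case-control
  rows store cases in `events` and cases+controls in `total`; `trial_type`
  distinguishes placebo-controlled from intensity-comparison trials, which
  the sensitivity subsets (placebo arms vs all control arms) require.
  Malformed rows are reported with 1-based line numbers, all problems at
  once.
* Reports serialize to sorted-key JSON, so identical inputs and settings
  give byte-identical reports; forest output is a fixed-width text table
  rather than graphics.
* The sensitivity analysis refits the meta-regression on design subsets
  (cohorts only; placebo arms; cohorts+placebo arms; control arms;
  cohorts+control arms; cohorts+active arms), flagging subsets with k < 3 as
  not-estimable rather than failing the run.

## Known limitations

Unadjusted effects only (no covariate conditioning, no genotype imputation);
single-moderator meta-regression; no permutation p-values, Knapp–Hartung
adjustment, prediction intervals, or publication-bias diagnostics; events
are exchangeable counts, so outcome-definition heterogeneity across studies
is invisible to the model.
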