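# vulnmeta

Meta-analysis toolkit for **genetic vulnerability to LDL cholesterol**: does a
common polymorphism change how strongly LDL cholesterol drives cardiovascular
risk — and therefore how much benefit a carrier gets from each mmol/L of LDL
lowering?

The motivating case is the KIF6 Trp719Arg polymorphism (rs20455). Genetic
sub-studies of statin trials reported that 719Arg carriers gained more
clinical benefit from statins than non-carriers despite identical LDL
lowering, while the variant showed no average association with cardiovascular
disease — an apparent contradiction. Both observations are consistent with a
*vulnerability* model: if carriers' risk rises faster with LDL, the
carrier-vs-non-carrier relative risk depends on a population's mean LDL
(positive at high LDL, inverse at low LDL, null in between), averaging out to
nothing across populations, while carriers still gain more per mmol/L of LDL
reduction.

## What the package computes

For a study collection (cohorts, case-control studies, and statin trials whose
allocation arms double as cohorts), the chain is:

1. **Study effects** — unadjusted RR (prospective) or OR (case-control, as an
   RR approximation) from 2×2 tables:
   `ln RR = ln[(a/(a+b))/(c/(c+d))]`, `se = √(1/a − 1/(a+b) + 1/c − 1/(c+d))`,
   with Haldane–Anscombe +0.5 correction for zero cells, plus a Hardy–Weinberg
   χ² check on genotype counts.
2. **Random-effects pooling** — inverse-variance with DerSimonian–Laird
   `τ² = max(0, (Q − df)/(Σw − Σw²/Σw))`, Cochran's Q and I².
3. **Meta-regression** — `yᵢ = β₀ + β₁·LDLᵢ + uᵢ + εᵢ`, `Var(uᵢ) = τ²` by REML
   (Fisher scoring; method-of-moments available). `exp(β₁)` is the ratio of
   RRs per mmol/L — the gene-by-environment interaction. R² is the percent
   reduction in τ² relative to the intercept-only model.
4. **Trial standardization** — each stratified trial's intent-to-treat log RR
   (and SE) is multiplied by 1/Y, Y being the between-arm LDL difference, so
   trials pool on a per-mmol/L scale, separately among carriers and
   non-carriers.
5. **Predicted vs observed benefit** — the slope re-expressed per mmol/L
   *decrease* (`exp(−β₁)`, the expected carrier/non-carrier benefit ratio) is
   compared with the observed ratio of the pooled stratum effects via a
   Z-test, `z = (ln r₁ − ln r₂)/√(se₁² + se₂²)`.

Because the original 37-study dataset is not published at the 2×2 level, the
package ships a first-class synthetic-data generator that samples study
collections from the log-linear vulnerability model
`risk(G, L) = r₀·exp[β_L(L − L_ref) + G(β_G + β_GL(L − L_ref))]`
(Hardy–Weinberg genotypes, binomial events, Bayes-inverted case-control
sampling), so every stage is testable end to end against known truth.

## Worked example

```python
from vulnmeta import run_simulated_analysis

report = run_simulated_analysis(seed=1)   # default 37-unit collection
meta = report.metareg
exp, obs = report.benefit.expected, report.benefit.observed
print(f"pooled carrier RR (37 units): {report.association.pooled}")
print(f"meta-regression slope: ratio of RRs {meta.slope.point:.3f} per mmol/L "
      f"(R^2 = {meta.r_squared:.1f}%)")
print(f"expected benefit ratio per mmol/L decrease: {exp.point:.3f} "
      f"(95% CI {exp.ci[0]:.3f}-{exp.ci[1]:.3f})")
print(f"observed benefit ratio in trials: {obs.ratio.point:.3f} "
      f"(95% CI {obs.ratio.ci[0]:.3f}-{obs.ratio.ci[1]:.3f}), p = {obs.p:.4f}")
```

prints

```
pooled carrier RR (37 units): RR 0.974 (95% CI 0.924-1.028)
meta-regression slope: ratio of RRs 1.238 per mmol/L (R^2 = 87.2%)
expected benefit ratio per mmol/L decrease: 0.808 (95% CI 0.746-0.875)
observed benefit ratio in trials: 0.871 (95% CI 0.723-1.050), p = 0.1478
```

Reading it: across 37 simulated units the carrier genotype shows no average
association with events (RR ≈ 0.97, CI spanning 1) even though the generating
model has a true interaction of 1.15 per mmol/L — the vulnerability structure
hides from marginal analysis. The meta-regression recovers a positive slope
(1.24 in this realization, its CI covering the truth), predicting that
carriers should do better per mmol/L of LDL lowering (expected ratio 0.81);
the stratified trials independently observe 0.87, and the two agree (|z| < 2).

The same chain is scriptable from the shell:

```bash
vulnmeta simulate --seed 1 --out studies.csv
vulnmeta metareg studies.csv
vulnmeta trials studies.csv --forest
vulnmeta report studies.csv --out report.json
```

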