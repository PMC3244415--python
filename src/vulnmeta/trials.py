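"""Statin-trial effects standardized per mmol/L of LDL lowering.

A trial's intent-to-treat relative risk compares the active arm to the
control arm within a genotype stratum.  Because trials differ in how much
LDL cholesterol they actually lowered, log effects (and their SEs) are
rescaled by 1/Y, where Y is the between-arm LDL difference in mmol/L, so
that every trial contributes an effect *per mmol/L of LDL reduction*.
Standardized stratum effects are pooled by random effects separately among
carriers and non-carriers, and the two pooled effects are compared with a
Z-test whose exponentiated difference is the observed ratio of RRs — the
quantity the vulnerability model predicts from the meta-regression slope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from scipy.stats import norm as _norm

from .effects import EffectEstimate, TwoByTwo, relative_risk
from .exceptions import NoDataError
from .metareg import MetaRegression, MetaRegressionResults
from .pooling import MetaAnalysisResults, RandomEffectsMeta

__all__ = [
    "ArmCounts",
    "StratifiedTrialRecord",
    "ComparisonResult",
    "BenefitComparison",
    "standardize_per_mmol",
    "trial_stratum_effect",
    "pool_stratified_trials",
    "compare_estimates_z",
    "invert_ratio",
    "predicted_vs_observed",
    "ratio_via_metaregression",
]

CARRIER_STRATA = ("argarg", "argtrp", "carrier")
NONCARRIER_STRATA = ("trptrp", "noncarrier")


@dataclass(frozen=True)
class ArmCounts:
    """Events and persons randomized in one arm-stratum cell."""

    events: int
    total: int

    def __post_init__(self):
        if not 0 <= self.events <= self.total:
            raise ValueError(
                f"need 0 <= events <= total, got {self.events}/{self.total}"
            )


def _stratum_counts(strata: Mapping[str, tuple[int, int]], carrier: bool) -> ArmCounts:
    keys = CARRIER_STRATA if carrier else NONCARRIER_STRATA
    events = n = 0
    found = False
    for key in keys:
        if key in strata:
            e, t = strata[key]
            events += e
            n += t
            found = True
    if not found:
        raise KeyError(f"no {'carrier' if carrier else 'non-carrier'} stratum present")
    return ArmCounts(events, n)


@dataclass(frozen=True)
class StratifiedTrialRecord:
    """One randomized trial with genotype-stratified per-arm counts.

    ``control`` and ``active`` map stratum name → (events, persons); strata
    may be genotype-level (argarg/argtrp/trptrp) or carrier-level
    (carrier/noncarrier).  ``delta_ldl`` is Y, the between-arm difference in
    average LDL cholesterol (mmol/L) during follow-up.  For trials comparing
    two statin intensities, "active" is the more intensive arm and
    ``placebo_controlled`` is False.
    """

    id: str
    control: Mapping[str, tuple[int, int]]
    active: Mapping[str, tuple[int, int]]
    delta_ldl: float
    control_ldl: float | None = None
    active_ldl: float | None = None
    placebo_controlled: bool = True

    def __post_init__(self):
        if not self.delta_ldl > 0:
            raise ValueError(f"delta_ldl (Y) must be > 0, got {self.delta_ldl}")
        for arm_name, arm in (("control", self.control), ("active", self.active)):
            if not arm:
                raise ValueError(f"trial {self.id}: empty {arm_name} arm")
            for stratum, (e, t) in arm.items():
                if not 0 <= e <= t:
                    raise ValueError(
                        f"trial {self.id} {arm_name}/{stratum}: "
                        f"need 0 <= events <= total, got {e}/{t}"
                    )

    def arm_counts(self, stratum: str, arm: str) -> ArmCounts:
        carrier = stratum == "carrier"
        table = self.control if arm == "control" else self.active
        return _stratum_counts(table, carrier)


@dataclass(frozen=True)
class ComparisonResult:
    """Z-test comparison of two independent log-scale estimates."""

    log_ratio: float
    se: float
    z: float
    p: float
    ratio: EffectEstimate

    @classmethod
    def from_log(
        cls, log_ratio: float, se: float, ci_level: float = 0.95
    ) -> "ComparisonResult":
        z = log_ratio / se
        return cls(
            log_ratio=log_ratio,
            se=se,
            z=z,
            p=2.0 * float(_norm.sf(abs(z))),
            ratio=EffectEstimate(log_ratio, se, ci_level, "ratio_of_RR"),
        )

    def to_dict(self) -> dict:
        lo, hi = self.ratio.ci
        return {
            "ratio": self.ratio.point,
            "ci": [lo, hi],
            "log_ratio": self.log_ratio,
            "se": self.se,
            "z": self.z,
            "p": self.p,
        }


def standardize_per_mmol(e: EffectEstimate, Y: float) -> EffectEstimate:
    """Rescale a trial effect to a per-mmol/L-of-LDL-reduction effect.

    Both the log point estimate and its SE are multiplied by 1/Y.  Identity
    when Y = 1; composes multiplicatively in Y.
    """
    if not Y > 0:
        raise ValueError(f"LDL difference Y must be > 0, got {Y}")
    return EffectEstimate(e.log_point / Y, e.se / Y, e.ci_level, e.measure_label)


def trial_stratum_effect(
    t: StratifiedTrialRecord,
    stratum: str,
    correction: bool = True,
    ci_level: float = 0.95,
    standardized: bool = True,
) -> EffectEstimate:
    """Intent-to-treat RR (active vs control) in one genotype stratum.

    ``stratum`` is ``"carrier"`` or ``"noncarrier"``; genotype-level strata
    are aggregated to carrier status.  The RR is standardized by 1/Y unless
    ``standardized=False``.
    """
    if stratum not in {"carrier", "noncarrier"}:
        raise ValueError(f"stratum must be carrier|noncarrier, got {stratum!r}")
    act = t.arm_counts(stratum, "active")
    ctl = t.arm_counts(stratum, "control")
    table = TwoByTwo(
        act.events, act.total - act.events, ctl.events, ctl.total - ctl.events
    )
    rr = relative_risk(table, correction=correction, ci_level=ci_level)
    return standardize_per_mmol(rr, t.delta_ldl) if standardized else rr


def pool_stratified_trials(
    trials: Sequence[StratifiedTrialRecord],
    correction: bool = True,
    ci_level: float = 0.95,
) -> tuple[MetaAnalysisResults, MetaAnalysisResults]:
    """Random-effects pools of standardized effects, per genotype stratum.

    Returns ``(carriers, non_carriers)``, each pooling one standardized
    per-mmol/L estimate per trial.
    """
    if len(trials) == 0:
        raise NoDataError("no trials to pool")
    labels = [t.id for t in trials]
    results = []
    for stratum in ("carrier", "noncarrier"):
        ests = [
            trial_stratum_effect(t, stratum, correction, ci_level) for t in trials
        ]
        results.append(RandomEffectsMeta.from_estimates(ests, labels).fit("dl"))
    return results[0], results[1]


def compare_estimates_z(
    e1: EffectEstimate, e2: EffectEstimate, ci_level: float = 0.95
) -> ComparisonResult:
    """Z-test of two independent log-scale estimates.

    The exponentiated difference is the ratio of the two effect measures
    (e.g. carrier RR over non-carrier RR) with joint SE
    sqrt(se₁² + se₂²).
    """
    log_ratio = e1.log_point - e2.log_point
    se = math.hypot(e1.se, e2.se)
    return ComparisonResult.from_log(log_ratio, se, ci_level)


def invert_ratio(e: EffectEstimate) -> EffectEstimate:
    """Re-express a ratio for the opposite direction of exposure change.

    A ratio of RRs per mmol/L *increase* in LDL becomes the ratio per
    mmol/L *decrease* by negating the log estimate; the SE is unchanged and
    the CI bounds swap and invert.  Involution: invert(invert(e)) = e.
    """
    return EffectEstimate(-e.log_point, e.se, e.ci_level, e.measure_label)


def ratio_via_metaregression(
    trials: Sequence[StratifiedTrialRecord],
    method: str = "reml",
    correction: bool = True,
    ci_level: float = 0.95,
) -> MetaRegressionResults:
    """Observed carrier/non-carrier ratio via a binary-moderator regression.

    Stacks both strata's standardized estimates (two per trial) and
    regresses on a carrier indicator; exp(slope) is the alternate estimator
    of the observed ratio of RRs, cross-checking the Z-method.
    """
    y, se, x, labels = [], [], [], []
    for t in trials:
        for stratum, ind in (("noncarrier", 0.0), ("carrier", 1.0)):
            e = trial_stratum_effect(t, stratum, correction, ci_level)
            y.append(e.log_point)
            se.append(e.se)
            x.append(ind)
            labels.append(f"{t.id}:{stratum}")
    return MetaRegression(y, se, x, labels=labels, ci_level=ci_level).fit(method)


@dataclass(frozen=True)
class BenefitComparison:
    """Expected vs observed differential benefit per mmol/L LDL decrease.

    ``expected`` re-expresses the meta-regression slope (a ratio of RRs per
    mmol/L increase) for a one mmol/L decrease; ``observed`` compares the
    pooled standardized carrier and non-carrier trial effects; ``agreement``
    is the Z-comparison of the two log-ratios (independence approximation).
    """

    expected: EffectEstimate
    observed: ComparisonResult
    agreement: ComparisonResult

    def to_dict(self) -> dict:
        lo, hi = self.expected.ci
        return {
            "expected": {
                "ratio": self.expected.point,
                "ci": [lo, hi],
                "p": self.expected.p_value,
            },
            "observed": self.observed.to_dict(),
            "agreement": self.agreement.to_dict(),
        }


def predicted_vs_observed(
    fit: MetaRegressionResults,
    carriers: MetaAnalysisResults,
    non_carriers: MetaAnalysisResults,
    ci_level: float = 0.95,
) -> BenefitComparison:
    """Compare the vulnerability prediction with the trial observation.

    The expected differential benefit is invert(exp(slope)): under a
    log-linear vulnerability model the ratio of RRs per mmol/L decrease is
    exactly the reciprocal of the ratio per mmol/L increase.  The observed
    counterpart is the Z-comparison of the pooled per-mmol/L stratum
    effects.
    """
    expected = invert_ratio(
        EffectEstimate(
            fit.slope.log_point, fit.slope.se, ci_level, "ratio_of_RR"
        )
    )
    observed = compare_estimates_z(carriers.pooled, non_carriers.pooled, ci_level)
    agreement = ComparisonResult.from_log(
        expected.log_point - observed.log_ratio,
        math.hypot(expected.se, observed.se),
        ci_level,
    )
    return BenefitComparison(expected=expected, observed=observed, agreement=agreement)
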