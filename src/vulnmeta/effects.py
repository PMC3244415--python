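"""Unadjusted effect estimates from 2x2 tables and genotype-quality checks.

This module is the computational atom of the package: every downstream
analysis (pooling, meta-regression, trial standardization) consumes the
:class:`EffectEstimate` objects built here.  Estimates live on the natural-log
scale with a normal-theory standard error, which is the common currency that
makes relative risks (prospective designs), odds ratios (case-control
designs, used as an approximation to the RR) and ratios of relative risks
interchangeable in inverse-variance machinery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from scipy.stats import chi2 as _chi2
from scipy.stats import norm as _norm

from .exceptions import (
    DegenerateEstimateError,
    InvalidTableError,
    UndefinedTestError,
)

__all__ = [
    "TwoByTwo",
    "GenotypeCounts",
    "EffectEstimate",
    "relative_risk",
    "odds_ratio",
    "hwe_chisq",
    "estimate_from_ci",
    "z_critical",
]


def z_critical(ci_level: float = 0.95) -> float:
    """Exact two-sided normal critical value for a confidence level.

    Uses the exact quantile (1.959964... for 95%) rather than the rounded
    1.96, matching conventional statistical software.
    """
    if not 0.0 < ci_level < 1.0:
        raise ValueError(f"ci_level must be in (0, 1), got {ci_level}")
    return float(_norm.ppf(0.5 + ci_level / 2.0))


@dataclass(frozen=True)
class TwoByTwo:
    """Event/non-event counts for exposed vs unexposed groups.

    "Exposed" means 719Arg carrier in the genotype-association analyses and
    the active treatment arm in the trial analyses.  Cells follow the usual
    a/b/c/d layout: (a) events among exposed, (b) non-events among exposed,
    (c) events among unexposed, (d) non-events among unexposed.  For
    case-control designs the same container holds case/control counts per
    exposure row (a=cases exposed, b=controls exposed, ...).
    """

    events_exposed: int
    nonevents_exposed: int
    events_unexposed: int
    nonevents_unexposed: int

    def __post_init__(self):
        for name, v in self.cells_dict().items():
            if v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")
        if self.n_exposed == 0 and self.n_unexposed == 0:
            raise ValueError("at least one row total must be positive")

    def cells_dict(self) -> dict[str, int]:
        return {
            "events_exposed": self.events_exposed,
            "nonevents_exposed": self.nonevents_exposed,
            "events_unexposed": self.events_unexposed,
            "nonevents_unexposed": self.nonevents_unexposed,
        }

    @property
    def cells(self) -> tuple[int, int, int, int]:
        return (
            self.events_exposed,
            self.nonevents_exposed,
            self.events_unexposed,
            self.nonevents_unexposed,
        )

    @property
    def n_exposed(self) -> int:
        return self.events_exposed + self.nonevents_exposed

    @property
    def n_unexposed(self) -> int:
        return self.events_unexposed + self.nonevents_unexposed

    @property
    def has_zero_cell(self) -> bool:
        return min(self.cells) == 0

    def swapped(self) -> "TwoByTwo":
        """Exchange the exposed and unexposed rows."""
        return TwoByTwo(
            self.events_unexposed,
            self.nonevents_unexposed,
            self.events_exposed,
            self.nonevents_exposed,
        )


@dataclass(frozen=True)
class GenotypeCounts:
    """Counts of the three genotypes at a biallelic site.

    For KIF6 Trp719Arg, ``n_homozygous_variant`` is Arg/Arg,
    ``n_heterozygous`` is Arg/Trp and ``n_homozygous_reference`` is Trp/Trp;
    carriers are the first two classes combined.
    """

    n_homozygous_variant: int
    n_heterozygous: int
    n_homozygous_reference: int

    def __post_init__(self):
        if min(self.counts) < 0:
            raise ValueError("genotype counts must be non-negative")

    @property
    def counts(self) -> tuple[int, int, int]:
        return (
            self.n_homozygous_variant,
            self.n_heterozygous,
            self.n_homozygous_reference,
        )

    @property
    def total(self) -> int:
        return sum(self.counts)

    @property
    def n_carriers(self) -> int:
        return self.n_homozygous_variant + self.n_heterozygous

    @property
    def variant_allele_freq(self) -> float:
        if self.total == 0:
            raise UndefinedTestError("no genotyped individuals")
        return (2 * self.n_homozygous_variant + self.n_heterozygous) / (
            2 * self.total
        )


@dataclass(frozen=True)
class EffectEstimate:
    """A ratio effect measure on the natural-log scale.

    ``log_point`` is ln(RR), ln(OR) or ln(ratio of RRs) depending on
    ``measure_label``; ``se`` is its normal-theory standard error.  Confidence
    intervals are symmetric around ``log_point`` on the log scale.
    """

    log_point: float
    se: float
    ci_level: float = 0.95
    measure_label: str = "RR"

    _LABELS = frozenset({"RR", "OR", "ratio_of_RR"})

    def __post_init__(self):
        if not math.isfinite(self.log_point):
            raise ValueError(f"log_point must be finite, got {self.log_point}")
        if not (math.isfinite(self.se) and self.se > 0):
            raise ValueError(f"se must be finite and positive, got {self.se}")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError(f"ci_level must be in (0, 1), got {self.ci_level}")
        if self.measure_label not in self._LABELS:
            raise ValueError(f"unknown measure_label {self.measure_label!r}")

    @property
    def point(self) -> float:
        """The estimate on the ratio scale, exp(log_point)."""
        return math.exp(self.log_point)

    @property
    def ci(self) -> tuple[float, float]:
        """Confidence bounds on the ratio scale."""
        z = z_critical(self.ci_level)
        return (
            math.exp(self.log_point - z * self.se),
            math.exp(self.log_point + z * self.se),
        )

    @property
    def z_value(self) -> float:
        return self.log_point / self.se

    @property
    def p_value(self) -> float:
        """Two-sided p against the null log ratio = 0."""
        return 2.0 * float(_norm.sf(abs(self.z_value)))

    def with_label(self, measure_label: str) -> "EffectEstimate":
        return replace(self, measure_label=measure_label)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        lo, hi = self.ci
        return (
            f"{self.measure_label} {self.point:.3f} "
            f"({100 * self.ci_level:.0f}% CI {lo:.3f}-{hi:.3f})"
        )


def _corrected_cells(
    table: TwoByTwo, correction: bool
) -> tuple[float, float, float, float]:
    """Apply the Haldane-Anscombe +0.5 correction when any cell is zero."""
    if table.has_zero_cell:
        if not correction:
            raise DegenerateEstimateError(
                f"zero cell in {table.cells} with continuity correction disabled"
            )
        return tuple(c + 0.5 for c in table.cells)
    return tuple(float(c) for c in table.cells)


def relative_risk(
    table: TwoByTwo, correction: bool = True, ci_level: float = 0.95
) -> EffectEstimate:
    """Unadjusted relative risk from a prospective 2x2 table.

    RR = [a/(a+b)] / [c/(c+d)] with the usual delta-method standard error on
    the log scale, se = sqrt(1/a - 1/(a+b) + 1/c - 1/(c+d)).  When any cell
    is zero and ``correction`` is enabled, 0.5 is added to all four cells
    before estimation.
    """
    if table.n_exposed == 0 or table.n_unexposed == 0:
        raise InvalidTableError(f"zero row total in {table.cells}")
    a, b, c, d = _corrected_cells(table, correction)
    n1, n0 = a + b, c + d
    log_point = math.log((a / n1) / (c / n0))
    se = math.sqrt(1 / a - 1 / n1 + 1 / c - 1 / n0)
    return EffectEstimate(log_point, se, ci_level, "RR")


def odds_ratio(
    table: TwoByTwo, correction: bool = True, ci_level: float = 0.95
) -> EffectEstimate:
    """Unadjusted odds ratio with the Woolf standard error.

    OR = ad/bc, se = sqrt(1/a + 1/b + 1/c + 1/d).  Used for case-control
    designs as an approximation of the relative risk, and treated as
    interchangeable with the RR on the log scale downstream.
    """
    if table.n_exposed == 0 or table.n_unexposed == 0:
        raise InvalidTableError(f"zero row total in {table.cells}")
    a, b, c, d = _corrected_cells(table, correction)
    log_point = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return EffectEstimate(log_point, se, ci_level, "OR")


def hwe_chisq(g: GenotypeCounts) -> tuple[float, float]:
    """Pearson chi-square test of Hardy-Weinberg equilibrium (df = 1).

    Expected genotype counts are computed from the observed allele
    frequency; the statistic is the usual sum of (obs - exp)^2 / exp over
    the three genotype classes, referred to a chi-square with one degree of
    freedom (three classes minus one constraint minus one estimated allele
    frequency).

    Returns ``(statistic, p_value)``.  Raises :class:`UndefinedTestError`
    for an empty or monomorphic sample, where the test is undefined.
    """
    n = g.total
    if n == 0:
        raise UndefinedTestError("no genotyped individuals")
    q = g.variant_allele_freq
    if q <= 0.0 or q >= 1.0:
        raise UndefinedTestError(f"monomorphic sample (allele freq {q})")
    expected = (n * q * q, 2 * n * q * (1 - q), n * (1 - q) * (1 - q))
    stat = sum((o - e) ** 2 / e for o, e in zip(g.counts, expected))
    return float(stat), float(_chi2.sf(stat, df=1))


def estimate_from_ci(
    point: float,
    lo: float,
    hi: float,
    ci_level: float = 0.95,
    measure_label: str = "RR",
) -> EffectEstimate:
    """Recover a log-scale estimate from a published ratio and CI.

    The standard error is back-calculated as (ln hi - ln lo) / (2 z), which
    assumes the interval was built symmetrically on the log scale — true for
    every normal-theory ratio CI this package produces or consumes.
    """
    if point <= 0 or lo <= 0 or hi <= 0:
        raise ValueError("point and CI bounds must be positive")
    if not lo <= point <= hi:
        raise ValueError(f"point {point} outside CI [{lo}, {hi}]")
    if lo == hi:
        raise DegenerateEstimateError("degenerate CI with lo == hi (zero SE)")
    z = z_critical(ci_level)
    se = (math.log(hi) - math.log(lo)) / (2.0 * z)
    return EffectEstimate(math.log(point), se, ci_level, measure_label)
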