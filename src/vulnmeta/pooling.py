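"""Inverse-variance meta-analysis with DerSimonian-Laird heterogeneity.

The model class :class:`RandomEffectsMeta` follows the familiar pattern of a
model object constructed from data whose :meth:`~RandomEffectsMeta.fit`
returns a results object (:class:`MetaAnalysisResults`) carrying the pooled
estimate, its uncertainty, the heterogeneity statistics (Cochran's Q, I²,
τ²) and the per-study weights.

Between-study variance is estimated by the DerSimonian-Laird method of
moments: a fixed-effect pass yields Q, then

    τ² = max(0, (Q - df) / (Σwᵢ - Σwᵢ²/Σwᵢ)),   wᵢ = 1/seᵢ²,

and the pool is re-weighted with wᵢ* = 1/(seᵢ² + τ²).  Confidence intervals
for the pooled estimate use the normal approximation (no Knapp-Hartung
adjustment), matching the meta-analytic software of the era this package's
methodology derives from.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .effects import EffectEstimate
from .exceptions import NoDataError

__all__ = [
    "RandomEffectsMeta",
    "MetaAnalysisResults",
    "pool_fixed",
    "pool_random_effects",
]


@dataclass(frozen=True)
class MetaAnalysisResults:
    """Pooled estimate plus heterogeneity diagnostics.

    ``tau_squared`` is NaN when not estimable (a single study); it is exactly
    0.0 whenever Q ≤ df, in which case the random-effects pool coincides with
    the fixed-effect pool.  ``weights`` are the weights actually used for the
    pooled estimate, so they sum to the inverse of the pooled variance.
    """

    pooled: EffectEstimate
    k: int
    Q: float
    df: int
    i_squared: float
    tau_squared: float
    weights: np.ndarray
    method: str
    labels: tuple[str, ...]
    y: np.ndarray
    se: np.ndarray

    @property
    def tau2_estimable(self) -> bool:
        return not math.isnan(self.tau_squared)

    def summary(self) -> str:
        lo, hi = self.pooled.ci
        tau2 = "n/e" if not self.tau2_estimable else f"{self.tau_squared:.4f}"
        lines = [
            f"Meta-analysis ({self.method}), k = {self.k}",
            f"  pooled {self.pooled.measure_label}: {self.pooled.point:.3f} "
            f"({100 * self.pooled.ci_level:.0f}% CI {lo:.3f}-{hi:.3f})  "
            f"z = {self.pooled.z_value:.3f}, p = {self.pooled.p_value:.4f}",
            f"  Q = {self.Q:.3f} on {self.df} df, I^2 = {self.i_squared:.1f}%, "
            f"tau^2 = {tau2}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        lo, hi = self.pooled.ci
        return {
            "method": self.method,
            "k": self.k,
            "pooled": self.pooled.point,
            "ci": [lo, hi],
            "log_point": self.pooled.log_point,
            "se": self.pooled.se,
            "p": self.pooled.p_value,
            "Q": self.Q,
            "df": self.df,
            "i_squared": self.i_squared,
            "tau_squared": None if not self.tau2_estimable else self.tau_squared,
            "weights": dict(zip(self.labels, self.weights.tolist())),
        }


class RandomEffectsMeta:
    """Inverse-variance meta-analysis model over log-scale effect estimates.

    Parameters
    ----------
    y : array-like
        Per-study effects on the natural-log scale (ln RR / ln OR).
    se : array-like
        Per-study standard errors of ``y`` (all strictly positive).
    labels : sequence of str, optional
        Study identifiers; defaults to ``study_1`` ... ``study_k``.
    measure_label, ci_level :
        Metadata propagated to the pooled :class:`EffectEstimate`.
    """

    def __init__(
        self,
        y,
        se,
        labels: Sequence[str] | None = None,
        measure_label: str = "RR",
        ci_level: float = 0.95,
    ):
        self.y = np.asarray(y, dtype=float)
        self.se = np.asarray(se, dtype=float)
        if self.y.ndim != 1 or self.y.shape != self.se.shape:
            raise ValueError("y and se must be 1-d arrays of equal length")
        if self.y.size == 0:
            raise NoDataError("no estimates to pool")
        if not np.all(np.isfinite(self.y)) or not np.all(self.se > 0):
            raise ValueError("y must be finite and se strictly positive")
        self.labels = (
            tuple(labels)
            if labels is not None
            else tuple(f"study_{i + 1}" for i in range(self.y.size))
        )
        if len(self.labels) != self.y.size:
            raise ValueError("labels length does not match estimates")
        self.measure_label = measure_label
        self.ci_level = ci_level

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_estimates(
        cls,
        estimates: Sequence[EffectEstimate],
        labels: Sequence[str] | None = None,
    ) -> "RandomEffectsMeta":
        if len(estimates) == 0:
            raise NoDataError("no estimates to pool")
        labels_set = {e.measure_label for e in estimates}
        # mixed RR/OR pools are allowed (the OR-as-RR approximation); a
        # standardized ratio never pools with an unstandardized one upstream.
        measure = "RR" if labels_set <= {"RR", "OR"} else estimates[0].measure_label
        ci = estimates[0].ci_level
        return cls(
            [e.log_point for e in estimates],
            [e.se for e in estimates],
            labels=labels,
            measure_label=measure,
            ci_level=ci,
        )

    @classmethod
    def from_dataframe(
        cls, df, y: str = "log_point", se: str = "se", label: str = "study_id"
    ) -> "RandomEffectsMeta":
        labels = df[label].astype(str).tolist() if label in df else None
        return cls(df[y].to_numpy(), df[se].to_numpy(), labels=labels)

    # -- fitting ----------------------------------------------------------
    def fit(self, method: str = "dl") -> MetaAnalysisResults:
        """Pool the estimates.

        ``method="dl"`` (default) is DerSimonian-Laird random effects;
        ``method="fixed"`` is the plain inverse-variance fixed-effect pool.
        A single study passes through unchanged with τ² not estimable.
        """
        if method not in {"dl", "fixed"}:
            raise ValueError(f"unknown pooling method {method!r}")
        y, v = self.y, self.se**2
        k = y.size
        w = 1.0 / v
        sw = w.sum()
        yhat = float(w @ y / sw)
        Q = float(w @ (y - yhat) ** 2)
        df = k - 1

        if method == "fixed":
            tau2 = 0.0 if k > 1 else math.nan
            wstar = w
        elif k == 1:
            tau2 = math.nan
            wstar = w
        else:
            denom = sw - float(w @ w) / sw
            tau2 = max(0.0, (Q - df) / denom) if denom > 0 else 0.0
            wstar = 1.0 / (v + tau2)

        pooled_log = float(wstar @ y / wstar.sum())
        pooled_se = 1.0 / math.sqrt(wstar.sum())
        i2 = 100.0 * max(0.0, (Q - df) / Q) if Q > 0 else 0.0
        pooled = EffectEstimate(
            pooled_log, pooled_se, self.ci_level, self.measure_label
        )
        return MetaAnalysisResults(
            pooled=pooled,
            k=k,
            Q=Q,
            df=df,
            i_squared=i2,
            tau_squared=tau2,
            weights=wstar,
            method=method,
            labels=self.labels,
            y=self.y,
            se=self.se,
        )


def pool_fixed(
    estimates: Sequence[EffectEstimate], labels: Sequence[str] | None = None
) -> MetaAnalysisResults:
    """Fixed-effect inverse-variance pool (the internal step of DL)."""
    return RandomEffectsMeta.from_estimates(estimates, labels).fit("fixed")


def pool_random_effects(
    estimates: Sequence[EffectEstimate], labels: Sequence[str] | None = None
) -> MetaAnalysisResults:
    """DerSimonian-Laird random-effects pool."""
    return RandomEffectsMeta.from_estimates(estimates, labels).fit("dl")
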