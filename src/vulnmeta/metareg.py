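"""Random-effects meta-regression of study log-effects on a moderator.

The scientific use case is effect modification: each study contributes an
effect estimate yᵢ (here ln RR for the carrier vs non-carrier genotype
contrast) with within-study variance vᵢ = seᵢ², and a study-level moderator
xᵢ (here the study mean LDL cholesterol in mmol/L).  The model is

    yᵢ = β₀ + β₁ xᵢ + uᵢ + εᵢ,   εᵢ ~ N(0, vᵢ),   uᵢ ~ N(0, τ²),

so exp(β₁) is a ratio of relative risks per mmol/L — the measure of
gene-by-environment interaction.  τ² is the residual between-study variance;
comparing it to the τ² of the intercept-only model gives the proportion of
between-study heterogeneity explained by the moderator (the meta-analytic
R², reported as a percentage and truncated to [0, 100]).

τ² estimators
-------------
``reml`` (default) maximizes the restricted likelihood by Fisher scoring on
τ² with non-negativity truncation; ``mom`` is the non-iterative
method-of-moments extension of DerSimonian-Laird to a regression design.
Coefficients are weighted least squares at the converged τ² with weights
1/(vᵢ + τ²).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .effects import EffectEstimate, z_critical
from .exceptions import (
    ConvergenceError,
    InsufficientStudiesError,
    NoDataError,
    RankDeficientError,
)

__all__ = [
    "MetaRegression",
    "MetaRegressionResults",
    "ModeratedEstimate",
    "fit_meta_regression",
    "r_squared_explained",
]


@dataclass(frozen=True)
class ModeratedEstimate:
    """An effect estimate paired with its study-level moderator value."""

    estimate: EffectEstimate
    moderator: float

    def __post_init__(self):
        if not math.isfinite(self.moderator):
            raise ValueError("moderator must be finite")


def r_squared_explained(tau_null: float, tau_resid: float) -> float:
    """Percent of between-study variance explained by the moderator.

    100·(τ²_null − τ²_resid)/τ²_null, truncated to [0, 100]; defined as 0
    when the intercept-only model already has τ² = 0.  Negative raw values
    (τ² noise) truncate to 0.
    """
    if tau_null < 0 or tau_resid < 0:
        raise ValueError("tau-squared values must be non-negative")
    if tau_null == 0:
        return 0.0
    return float(np.clip(100.0 * (tau_null - tau_resid) / tau_null, 0.0, 100.0))


def _wls(X: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Weighted least squares; returns (beta, cov) at the given weights."""
    xtw = X.T * w
    cov = np.linalg.inv(xtw @ X)
    beta = cov @ (xtw @ y)
    return beta, cov


def _tau2_mom(X: np.ndarray, y: np.ndarray, v: np.ndarray) -> float:
    """Method-of-moments τ² for a regression design (DL generalization)."""
    k, p = X.shape
    w = 1.0 / v
    beta, cov = _wls(X, y, w)
    resid = y - X @ beta
    qe = float(w @ resid**2)
    xtww = (X.T * w**2) @ X
    trace_p = w.sum() - float(np.trace(cov @ xtww))
    if trace_p <= 0:
        return 0.0
    return max(0.0, (qe - (k - p)) / trace_p)


def _reml_score_info(
    X: np.ndarray, y: np.ndarray, v: np.ndarray, tau2: float
) -> tuple[float, float]:
    """REML score and expected information for τ².

    With W = diag(1/(vᵢ+τ²)) and P = W − WX(XᵀWX)⁻¹XᵀW, the restricted
    log-likelihood has ∂l/∂τ² = ½(yᵀP²y − tr P) and expected information
    ½ tr(P²).  Study counts here are small, so forming P explicitly is fine.
    """
    w = 1.0 / (v + tau2)
    wx = X * w[:, None]
    P = np.diag(w) - wx @ np.linalg.inv(X.T @ wx) @ wx.T
    py = P @ y
    score = 0.5 * (float(py @ py) - float(np.trace(P)))
    info = 0.5 * float(np.sum(P * P))
    return score, info


def _tau2_reml(
    X: np.ndarray,
    y: np.ndarray,
    v: np.ndarray,
    tol: float = 1e-8,
    maxiter: int = 100,
) -> tuple[float, int]:
    """Fisher-scoring REML estimate of τ², truncated at 0.

    Starts from the method-of-moments value.  Convergence is declared when
    the scoring step falls below ``tol``; sitting at the τ² = 0 boundary
    with a negative score also counts as converged.
    """
    score0, _ = _reml_score_info(X, y, v, 0.0)
    if score0 <= 0.0:
        # likelihood decreasing at the boundary: truncated estimate is 0
        return 0.0, 0
    tau2 = max(_tau2_mom(X, y, v), tol)
    for it in range(1, maxiter + 1):
        score, info = _reml_score_info(X, y, v, tau2)
        if info <= 0:
            break
        new = tau2 + score / info
        if new <= 0.0:
            # overshoot past the boundary: halve toward 0 instead, since the
            # root is interior (score at 0 is positive)
            new = tau2 / 2.0
        if abs(new - tau2) < tol:
            return new, it
        tau2 = new
    # scoring stalled or oscillated: fall back to bracketing the score root
    from scipy.optimize import brentq

    hi = max(tau2, tol)
    for _ in range(200):
        if _reml_score_info(X, y, v, hi)[0] < 0.0:
            return (
                float(
                    brentq(
                        lambda t: _reml_score_info(X, y, v, t)[0],
                        0.0,
                        hi,
                        xtol=tol,
                    )
                ),
                maxiter,
            )
        hi *= 2.0
    raise ConvergenceError(
        f"REML did not converge in {maxiter} iterations (last tau^2 = {tau2})",
        tau2_last=tau2,
    )


@dataclass(frozen=True)
class MetaRegressionResults:
    """Coefficients, τ² with and without the moderator, and R².

    ``params`` is (intercept, slope) on the log scale; ``cov_params`` the
    coefficient covariance at the converged τ².  ``slope`` is exposed as an
    :class:`EffectEstimate` labelled ``ratio_of_RR`` — exp(slope) is the
    ratio of RRs per unit moderator.
    """

    params: np.ndarray
    cov_params: np.ndarray
    tau_squared_residual: float
    tau_squared_null: float
    k: int
    method: str
    n_iter: int
    ci_level: float
    x: np.ndarray
    y: np.ndarray
    se: np.ndarray
    labels: tuple[str, ...]

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_params))

    @property
    def intercept(self) -> EffectEstimate:
        return EffectEstimate(
            float(self.params[0]), float(self.bse[0]), self.ci_level, "RR"
        )

    @property
    def slope(self) -> EffectEstimate:
        return EffectEstimate(
            float(self.params[1]), float(self.bse[1]), self.ci_level, "ratio_of_RR"
        )

    @property
    def r_squared(self) -> float:
        return r_squared_explained(
            self.tau_squared_null, self.tau_squared_residual
        )

    def predict(self, x: float) -> EffectEstimate:
        """Fitted log-effect at moderator value ``x`` with its SE.

        The SE comes from the full coefficient covariance, including the
        intercept-slope covariance term, so it is minimized near the
        weighted mean moderator.
        """
        xv = np.array([1.0, float(x)])
        var = float(xv @ self.cov_params @ xv)
        return EffectEstimate(
            float(xv @ self.params), math.sqrt(var), self.ci_level, "RR"
        )

    def summary(self) -> str:
        z = z_critical(self.ci_level)
        rows = []
        for name, b, s in zip(("intercept", "slope"), self.params, self.bse):
            rows.append(
                f"  {name:<10} {b:+.4f} (se {s:.4f}) "
                f"[{b - z * s:+.4f}, {b + z * s:+.4f}]"
            )
        return "\n".join(
            [
                f"Meta-regression ({self.method}), k = {self.k}",
                *rows,
                f"  exp(slope) = {self.slope.point:.4f} per unit moderator",
                f"  tau^2 residual = {self.tau_squared_residual:.5f}, "
                f"null = {self.tau_squared_null:.5f}, "
                f"R^2 = {self.r_squared:.1f}%",
            ]
        )

    def to_dict(self) -> dict:
        lo, hi = self.slope.ci
        return {
            "method": self.method,
            "k": self.k,
            "intercept": float(self.params[0]),
            "slope": float(self.params[1]),
            "slope_se": float(self.bse[1]),
            "ratio_of_rr_per_unit": self.slope.point,
            "ratio_ci": [lo, hi],
            "slope_p": self.slope.p_value,
            "tau2_residual": self.tau_squared_residual,
            "tau2_null": self.tau_squared_null,
            "r_squared_pct": self.r_squared,
        }


class MetaRegression:
    """Random-effects meta-regression model with a single moderator.

    Parameters mirror :class:`~vulnmeta.pooling.RandomEffectsMeta` with the
    addition of the moderator vector ``x``.  Requires k ≥ 3 studies and a
    non-constant moderator.
    """

    def __init__(
        self,
        y,
        se,
        x,
        labels: Sequence[str] | None = None,
        ci_level: float = 0.95,
    ):
        self.y = np.asarray(y, dtype=float)
        self.se = np.asarray(se, dtype=float)
        self.x = np.asarray(x, dtype=float)
        if self.y.size == 0:
            raise NoDataError("no estimates to regress")
        if not (self.y.shape == self.se.shape == self.x.shape) or self.y.ndim != 1:
            raise ValueError("y, se and x must be 1-d arrays of equal length")
        if self.y.size < 3:
            raise InsufficientStudiesError(
                f"meta-regression needs k >= 3 studies, got {self.y.size}"
            )
        if not np.all(self.se > 0):
            raise ValueError("all standard errors must be positive")
        if np.ptp(self.x) == 0:
            raise RankDeficientError("moderator is constant across studies")
        self.labels = (
            tuple(labels)
            if labels is not None
            else tuple(f"study_{i + 1}" for i in range(self.y.size))
        )
        self.ci_level = ci_level

    @classmethod
    def from_moderated(
        cls,
        data: Sequence[ModeratedEstimate],
        labels: Sequence[str] | None = None,
        ci_level: float = 0.95,
    ) -> "MetaRegression":
        return cls(
            [m.estimate.log_point for m in data],
            [m.estimate.se for m in data],
            [m.moderator for m in data],
            labels=labels,
            ci_level=ci_level,
        )

    @classmethod
    def from_dataframe(
        cls,
        df,
        y: str = "log_point",
        se: str = "se",
        x: str = "mean_ldl",
        label: str = "study_id",
    ) -> "MetaRegression":
        labels = df[label].astype(str).tolist() if label in df else None
        return cls(
            df[y].to_numpy(), df[se].to_numpy(), df[x].to_numpy(), labels=labels
        )

    def fit(
        self, method: str = "reml", tol: float = 1e-8, maxiter: int = 100
    ) -> MetaRegressionResults:
        """Estimate τ² by ``method`` ("reml" or "mom") and fit WLS at it.

        ``tau_squared_null`` is refit under the same method for the
        intercept-only design so R² compares like with like.
        """
        if method not in {"reml", "mom"}:
            raise ValueError(f"unknown tau^2 method {method!r}")
        v = self.se**2
        X = np.column_stack([np.ones_like(self.x), self.x])
        X0 = X[:, :1]
        if method == "reml":
            tau2, n_iter = _tau2_reml(X, self.y, v, tol=tol, maxiter=maxiter)
            tau2_null, _ = _tau2_reml(X0, self.y, v, tol=tol, maxiter=maxiter)
        else:
            tau2 = _tau2_mom(X, self.y, v)
            tau2_null = _tau2_mom(X0, self.y, v)
            n_iter = 0
        beta, cov = _wls(X, self.y, 1.0 / (v + tau2))
        return MetaRegressionResults(
            params=beta,
            cov_params=cov,
            tau_squared_residual=tau2,
            tau_squared_null=tau2_null,
            k=self.y.size,
            method=method,
            n_iter=n_iter,
            ci_level=self.ci_level,
            x=self.x,
            y=self.y,
            se=self.se,
            labels=self.labels,
        )


def fit_meta_regression(
    data: Sequence[ModeratedEstimate],
    method: str = "reml",
    labels: Sequence[str] | None = None,
    ci_level: float = 0.95,
) -> MetaRegressionResults:
    """Fit a random-effects meta-regression from moderated estimates."""
    return MetaRegression.from_moderated(data, labels, ci_level).fit(method)
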