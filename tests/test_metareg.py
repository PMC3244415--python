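"""Meta-regression tests: exact WLS cases, REML oracle, external reference."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq

from vulnmeta import (
    InsufficientStudiesError,
    MetaRegression,
    RankDeficientError,
    r_squared_explained,
)
from vulnmeta.simulate import CohortSpec, CollectionConfig, VulnerabilityModel, simulate_collection
from vulnmeta.pipeline import run_meta_regression

# shared small dataset with genuine residual heterogeneity
Y = [-0.30, 0.25, 0.21, -0.02, 0.52, -0.15, 0.08, 0.40, -0.22, 0.33]
SE = [0.10, 0.08, 0.12, 0.15, 0.09, 0.11, 0.07, 0.13, 0.10, 0.09]
X = [2.4, 2.9, 3.3, 2.6, 4.1, 3.6, 2.8, 3.9, 3.1, 4.3]


def reml_score_brute_force(y, se, x, tau2):
    """REML score for tau^2 written scalar-wise from the definition.

    Independent of the package's matrix implementation: weights, hat-matrix
    correction and residuals are accumulated with explicit loops over the
    (1, x) design.
    """
    k = len(y)
    w = [1.0 / (s**2 + tau2) for s in se]
    # 2x2 normal equations by hand
    s00 = sum(w)
    s01 = sum(wi * xi for wi, xi in zip(w, x))
    s11 = sum(wi * xi * xi for wi, xi in zip(w, x))
    det = s00 * s11 - s01 * s01
    b0 = (s11 * sum(wi * yi for wi, yi in zip(w, y))
          - s01 * sum(wi * xi * yi for wi, xi, yi in zip(w, x, y))) / det
    b1 = (s00 * sum(wi * xi * yi for wi, xi, yi in zip(w, x, y))
          - s01 * sum(wi * yi for wi, yi in zip(w, y))) / det
    resid = [yi - b0 - b1 * xi for yi, xi in zip(y, x)]
    # tr(P) = sum w_i - tr((X'WX)^{-1} X'W^2X)
    t00 = sum(wi * wi for wi in w)
    t01 = sum(wi * wi * xi for wi, xi in zip(w, x))
    t11 = sum(wi * wi * xi * xi for wi, xi in zip(w, x))
    tr_correction = (s11 * t00 - 2 * s01 * t01 + s00 * t11) / det
    tr_p = sum(w) - tr_correction
    quad = sum((wi * ri) ** 2 for wi, ri in zip(w, resid))
    return 0.5 * (quad - tr_p)


class TestExactCases:
    def test_noiseless_linear_response_recovered_exactly(self):
        x = [1.0, 2.0, 3.0]
        y = [0.1 + 0.2 * xi for xi in x]
        for method in ("reml", "mom"):
            fit = MetaRegression(y, [0.1] * 3, x).fit(method)
            assert fit.params[0] == pytest.approx(0.1, abs=1e-10)
            assert fit.params[1] == pytest.approx(0.2, abs=1e-10)
            assert fit.tau_squared_residual == pytest.approx(0.0, abs=1e-10)

    def test_flat_response_gives_zero_slope(self):
        fit = MetaRegression([0.3] * 4, [0.1] * 4, [1, 2, 3, 4]).fit("mom")
        assert fit.params[1] == pytest.approx(0.0, abs=1e-12)

    def test_equal_se_zero_tau2_equals_ols(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = 0.05 + 0.12 * x  # noiseless so tau2 truncates to 0
        fit = MetaRegression(y, [0.2] * 4, x).fit("mom")
        b1, b0 = np.polyfit(x, y, 1)
        assert fit.params[0] == pytest.approx(b0, abs=1e-10)
        assert fit.params[1] == pytest.approx(b1, abs=1e-10)

    def test_too_few_studies_rejected(self):
        with pytest.raises(InsufficientStudiesError):
            MetaRegression([0.1, 0.2], [0.1, 0.1], [1, 2])

    def test_constant_moderator_rejected(self):
        with pytest.raises(RankDeficientError):
            MetaRegression([0.1, 0.2, 0.3], [0.1] * 3, [2.0, 2.0, 2.0])


class TestTauSquaredEstimators:
    def test_reml_solves_score_equation_from_first_principles(self):
        """Fisher-scoring iterate equals the brentq root of a loop-written score."""
        fit = MetaRegression(Y, SE, X).fit("reml", tol=1e-14, maxiter=500)
        oracle = brentq(
            lambda t: reml_score_brute_force(Y, SE, X, t), 0.0, 1.0, xtol=1e-14
        )
        assert fit.tau_squared_residual == pytest.approx(oracle, abs=1e-10)

    def test_wls_coefficients_match_hand_normal_equations(self):
        fit = MetaRegression(Y, SE, X).fit("reml", tol=1e-14, maxiter=500)
        tau2 = fit.tau_squared_residual
        w = [1.0 / (s**2 + tau2) for s in SE]
        s00, s01 = sum(w), sum(wi * xi for wi, xi in zip(w, X))
        s11 = sum(wi * xi * xi for wi, xi in zip(w, X))
        sy = sum(wi * yi for wi, yi in zip(w, Y))
        sxy = sum(wi * xi * yi for wi, xi, yi in zip(w, X, Y))
        det = s00 * s11 - s01 * s01
        assert fit.params[0] == pytest.approx((s11 * sy - s01 * sxy) / det, abs=1e-10)
        assert fit.params[1] == pytest.approx((s00 * sxy - s01 * sy) / det, abs=1e-10)
        # coefficient covariance comes from the same normal equations
        assert fit.bse[1] == pytest.approx(math.sqrt(s00 / det), abs=1e-10)

    def test_matches_metafor_reference_values(self):
        """Frozen references computed with R metafor (rma with moderator).

        metafor's REML stops at a looser internal criterion, hence the 1e-5
        comparison on tau^2; the method-of-moments values are closed-form
        and match to 1e-10.
        """
        reml = MetaRegression(Y, SE, X).fit("reml", tol=1e-12, maxiter=500)
        assert reml.tau_squared_residual == pytest.approx(0.036188617515, abs=1e-5)
        assert reml.tau_squared_null == pytest.approx(0.066988065300, abs=1e-5)
        assert reml.params[0] == pytest.approx(-0.853175614669, abs=1e-5)
        assert reml.params[1] == pytest.approx(0.292371915126, abs=1e-5)
        assert reml.bse[1] == pytest.approx(0.110253819095, abs=1e-5)

        mom = MetaRegression(Y, SE, X).fit("mom")
        assert mom.tau_squared_residual == pytest.approx(0.036971476485, abs=1e-10)
        assert mom.tau_squared_null == pytest.approx(0.064481139436, abs=1e-10)
        assert mom.params[0] == pytest.approx(-0.853352306728, abs=1e-10)
        assert mom.params[1] == pytest.approx(0.292412322214, abs=1e-10)
        assert mom.bse[1] == pytest.approx(0.111183203877, abs=1e-10)

    def test_moderator_shift_moves_intercept_not_slope(self):
        c = 1.7
        a = MetaRegression(Y, SE, X).fit("mom")
        b = MetaRegression(Y, SE, [xi + c for xi in X]).fit("mom")
        assert b.params[1] == pytest.approx(a.params[1], abs=1e-10)
        assert b.params[0] == pytest.approx(a.params[0] - a.params[1] * c, abs=1e-10)

    def test_reml_and_mom_slopes_agree_on_well_conditioned_collection(self):
        model = VulnerabilityModel()
        config = CollectionConfig(
            cohorts=tuple(
                CohortSpec(6000, float(l)) for l in np.linspace(2.2, 4.8, 24)
            ),
            case_controls=(),
            trials=(),
        )
        studies, _ = simulate_collection(model, config, seed=11)
        reml = run_meta_regression(studies, "reml")
        mom = run_meta_regression(studies, "mom")
        joint_se = math.hypot(reml.bse[1], mom.bse[1])
        assert abs(reml.params[1] - mom.params[1]) < joint_se


class TestPrediction:
    def test_prediction_at_zero_is_intercept(self):
        fit = MetaRegression(Y, SE, X).fit("mom")
        pred = fit.predict(0.0)
        assert pred.log_point == pytest.approx(fit.params[0], abs=1e-12)
        assert pred.se == pytest.approx(fit.bse[0], abs=1e-12)

    def test_noiseless_prediction(self):
        x = [1.0, 2.0, 3.0]
        fit = MetaRegression([0.1 + 0.2 * xi for xi in x], [0.1] * 3, x).fit("mom")
        assert fit.predict(2.0).log_point == pytest.approx(0.5, abs=1e-10)

    def test_prediction_se_minimal_at_weighted_mean_moderator(self):
        fit = MetaRegression(Y, SE, X).fit("reml")
        w = 1.0 / (np.array(SE) ** 2 + fit.tau_squared_residual)
        xbar = float(w @ np.array(X) / w.sum())
        grid = np.linspace(min(X) - 1, max(X) + 1, 201)
        ses = [fit.predict(g).se for g in grid]
        assert fit.predict(xbar).se <= min(ses) + 1e-12


class TestRSquared:
    @pytest.mark.parametrize(
        "tau_null, tau_resid, expected",
        [(0.10, 0.04, 60.0), (0.05, 0.05, 0.0), (0.05, 0.08, 0.0), (0.0, 0.0, 0.0)],
    )
    def test_values(self, tau_null, tau_resid, expected):
        assert r_squared_explained(tau_null, tau_resid) == pytest.approx(expected)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            r_squared_explained(-0.1, 0.0)
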