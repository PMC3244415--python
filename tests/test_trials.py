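"""Trial standardization, stratified pooling and benefit comparison tests."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vulnmeta import (
    EffectEstimate,
    StratifiedTrialRecord,
    VulnerabilityModel,
    compare_estimates_z,
    invert_ratio,
    pool_stratified_trials,
    predicted_vs_observed,
    ratio_via_metaregression,
    standardize_per_mmol,
    trial_stratum_effect,
)
from vulnmeta.metareg import MetaRegressionResults
from vulnmeta.simulate import simulate_trial


def make_trial(
    ctl_carrier=(80, 1000),
    ctl_non=(50, 1000),
    act_carrier=(40, 1000),
    act_non=(35, 1000),
    Y=1.0,
    tid="t1",
):
    return StratifiedTrialRecord(
        id=tid,
        control={"carrier": ctl_carrier, "noncarrier": ctl_non},
        active={"carrier": act_carrier, "noncarrier": act_non},
        delta_ldl=Y,
    )


class TestStandardization:
    def test_unit_ldl_difference_is_identity(self):
        e = EffectEstimate(-0.4, 0.1)
        s = standardize_per_mmol(e, 1.0)
        assert s.log_point == e.log_point and s.se == e.se

    def test_square_root_halving(self):
        # RR 0.64 over a 2 mmol/L difference -> 0.8 per mmol/L exactly
        e = EffectEstimate(math.log(0.64), 0.1)
        assert standardize_per_mmol(e, 2.0).point == pytest.approx(0.8, abs=1e-12)

    def test_se_scales_linearly(self):
        e = EffectEstimate(0.0, 0.10)
        assert standardize_per_mmol(e, 0.5).se == pytest.approx(0.20, abs=1e-12)

    @pytest.mark.parametrize("bad_y", [0.0, -1.0])
    def test_nonpositive_ldl_difference_rejected(self, bad_y):
        with pytest.raises(ValueError):
            standardize_per_mmol(EffectEstimate(0.1, 0.1), bad_y)

    @given(
        lp=st.floats(-1, 1),
        se=st.floats(0.01, 0.5),
        y1=st.floats(0.2, 3.0),
        y2=st.floats(0.2, 3.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_composes_multiplicatively(self, lp, se, y1, y2):
        e = EffectEstimate(lp, se)
        twice = standardize_per_mmol(standardize_per_mmol(e, y1), y2)
        once = standardize_per_mmol(e, y1 * y2)
        assert twice.log_point == pytest.approx(once.log_point, abs=1e-12)
        assert twice.se == pytest.approx(once.se, abs=1e-12)


class TestStratumEffect:
    def test_null_effect_for_identical_arms(self):
        t = make_trial((50, 1000), (50, 1000), (50, 1000), (50, 1000), Y=1.3)
        for stratum in ("carrier", "noncarrier"):
            assert trial_stratum_effect(t, stratum).point == pytest.approx(1.0)

    def test_intent_to_treat_rr_hand_values(self):
        t = make_trial((80, 1000), (80, 1000), (40, 1000), (40, 1000), Y=1.0)
        e = trial_stratum_effect(t, "carrier")
        assert e.point == pytest.approx(0.5, abs=1e-12)
        se = math.sqrt(1 / 40 - 1 / 1000 + 1 / 80 - 1 / 1000)
        assert e.se == pytest.approx(se, abs=1e-12)
        assert e.se == pytest.approx(0.19, abs=2e-3)

    def test_standardization_by_two_mmol(self):
        t2 = make_trial((80, 1000), (80, 1000), (40, 1000), (40, 1000), Y=2.0)
        e = trial_stratum_effect(t2, "carrier")
        assert e.point == pytest.approx(math.sqrt(0.5), abs=1e-12)
        assert e.se == pytest.approx(0.095, abs=1e-3)

    def test_genotype_strata_aggregate_to_carrier(self):
        t = StratifiedTrialRecord(
            id="g",
            control={"argarg": (10, 150), "argtrp": (30, 450), "trptrp": (25, 400)},
            active={"argarg": (6, 150), "argtrp": (20, 450), "trptrp": (22, 400)},
            delta_ldl=1.0,
        )
        e = trial_stratum_effect(t, "carrier")
        expected = (26 / 600) / (40 / 600)
        assert e.point == pytest.approx(expected, abs=1e-12)


class TestComparison:
    def test_identical_estimates_compare_null(self):
        e = EffectEstimate(-0.3, 0.05)
        c = compare_estimates_z(e, e)
        assert c.ratio.point == pytest.approx(1.0)
        assert c.z == pytest.approx(0.0)
        assert c.p == pytest.approx(1.0)

    def test_printed_strata_reproduce_published_lower_bound(self, printed_strata):
        carriers, non_carriers = printed_strata
        c = compare_estimates_z(carriers, non_carriers)
        lo, hi = c.ratio.ci
        assert round(c.ratio.point, 2) == 0.88  # rounded inputs; 0.87 unrounded
        assert round(lo, 2) == 0.77
        assert round(hi, 2) == 1.00

    def test_antisymmetry(self):
        e1, e2 = EffectEstimate(-0.31, 0.05), EffectEstimate(-0.19, 0.04)
        prod = (
            compare_estimates_z(e1, e2).ratio.point
            * compare_estimates_z(e2, e1).ratio.point
        )
        assert prod == pytest.approx(1.0, abs=1e-12)

    def test_p_and_z_consistency(self):
        c = compare_estimates_z(
            EffectEstimate(-0.31, 0.05), EffectEstimate(-0.19, 0.04)
        )
        assert c.z == pytest.approx(c.log_ratio / c.se, abs=1e-12)
        assert c.ratio.point == pytest.approx(math.exp(c.log_ratio), abs=1e-12)


class TestInvertRatio:
    def test_published_interaction_ratio_inverts_to_benefit_ratio(self):
        e = invert_ratio(
            __import__("vulnmeta").estimate_from_ci(1.15, 1.06, 1.25)
        )
        lo, hi = e.ci
        assert round(e.point, 2) == 0.87
        assert round(lo, 2) == 0.80
        assert round(hi, 2) == 0.94

    def test_null_fixed_point(self):
        e = EffectEstimate(0.0, 0.1)
        assert invert_ratio(e).point == pytest.approx(1.0)

    @given(lp=st.floats(-1, 1), se=st.floats(0.01, 0.5))
    @settings(max_examples=50, deadline=None)
    def test_involution(self, lp, se):
        e = EffectEstimate(lp, se)
        back = invert_ratio(invert_ratio(e))
        assert back.log_point == pytest.approx(e.log_point, abs=1e-15)
        assert back.se == e.se


class TestStratifiedPooling:
    def test_null_trials_pool_to_unity_in_both_strata(self):
        trials = [
            make_trial((50, 1000), (40, 1000), (50, 1000), (40, 1000), Y=y, tid=f"t{y}")
            for y in (0.5, 1.0, 1.5)
        ]
        carriers, non_carriers = pool_stratified_trials(trials)
        assert carriers.pooled.point == pytest.approx(1.0, abs=1e-12)
        assert non_carriers.pooled.point == pytest.approx(1.0, abs=1e-12)

    def test_single_trial_passthrough(self):
        t = make_trial()
        carriers, _ = pool_stratified_trials([t])
        direct = trial_stratum_effect(t, "carrier")
        assert carriers.pooled.log_point == pytest.approx(direct.log_point)
        assert carriers.pooled.se == pytest.approx(direct.se)

    def test_unit_ldl_differences_match_unstandardized_pool(self):
        trials = [
            make_trial((70 + i, 900), (52, 900), (40, 900), (38 + i, 900), Y=1.0,
                       tid=f"u{i}")
            for i in range(3)
        ]
        carriers_std, _ = pool_stratified_trials(trials)
        from vulnmeta import pool_random_effects

        unstd = pool_random_effects(
            [trial_stratum_effect(t, "carrier", standardized=False) for t in trials]
        )
        assert carriers_std.pooled.log_point == pytest.approx(
            unstd.pooled.log_point, abs=1e-12
        )

    def test_interaction_favours_carriers_across_replicates(self):
        """Carrier pooled per-mmol/L RR below non-carrier in nearly all reps."""
        model = VulnerabilityModel()
        wins = 0
        n_reps = 50
        for rep in range(n_reps):
            trials = [
                simulate_trial(model, 20000, b, y, seed=rep, study_id=f"t{i}")
                for i, (b, y) in enumerate([(4.5, 1.2), (3.6, 1.0), (3.0, 0.8),
                                            (4.0, 1.1), (3.3, 0.6)])
            ]
            carriers, non_carriers = pool_stratified_trials(trials)
            wins += carriers.pooled.log_point < non_carriers.pooled.log_point
        assert wins >= int(0.95 * n_reps)

    def test_observed_ratio_invariant_to_common_risk_scaling(self):
        """Built from expected counts, doubling both strata's risks leaves
        the carrier/non-carrier ratio of standardized RRs unchanged."""

        def expected_trials(scale):
            base = VulnerabilityModel(baseline_risk=0.02 * scale)
            trials = []
            for i, (b, y) in enumerate([(4.2, 1.0), (3.4, 0.8), (3.0, 1.2)]):
                n = 200000
                rows = {}
                for arm_name, ldl in (("control", b), ("active", b - y)):
                    rows[arm_name] = {
                        "carrier": (round(n * 0.6 * base.risk(True, ldl)),
                                    round(n * 0.6)),
                        "noncarrier": (round(n * 0.4 * base.risk(False, ldl)),
                                       round(n * 0.4)),
                    }
                trials.append(
                    StratifiedTrialRecord(
                        id=f"e{i}", control=rows["control"],
                        active=rows["active"], delta_ldl=y,
                    )
                )
            return trials

        ratios = []
        for scale in (1.0, 2.0):
            carriers, non_carriers = pool_stratified_trials(expected_trials(scale))
            ratios.append(
                compare_estimates_z(carriers.pooled, non_carriers.pooled).ratio.point
            )
        assert ratios[0] == pytest.approx(ratios[1], abs=5e-3)


class TestPredictedVsObserved:
    @staticmethod
    def _fit_with_slope(log_slope, se_slope=0.042):
        return MetaRegressionResults(
            params=np.array([0.0, log_slope]),
            cov_params=np.array([[0.01, 0.0], [0.0, se_slope**2]]),
            tau_squared_residual=0.0,
            tau_squared_null=0.01,
            k=19,
            method="reml",
            n_iter=1,
            ci_level=0.95,
            x=np.zeros(1),
            y=np.zeros(1),
            se=np.ones(1),
            labels=("s",),
        )

    def test_expected_ratio_from_published_slope(self):
        fit = self._fit_with_slope(math.log(1.15))
        carriers, non_carriers = pool_stratified_trials([make_trial()])
        cmp_ = predicted_vs_observed(fit, carriers, non_carriers)
        assert round(cmp_.expected.point, 2) == 0.87

    def test_zero_interaction_gives_null_expected_ratio(self):
        fit = self._fit_with_slope(0.0)
        t = make_trial((50, 1000), (40, 1000), (50, 1000), (40, 1000))
        carriers, non_carriers = pool_stratified_trials([t])
        cmp_ = predicted_vs_observed(fit, carriers, non_carriers)
        assert cmp_.expected.point == pytest.approx(1.0)
        assert cmp_.observed.ratio.point == pytest.approx(1.0, abs=1e-12)

    def test_metareg_route_agrees_with_z_route(self):
        model = VulnerabilityModel()
        trials = [
            simulate_trial(model, 50000, b, y, seed=3, study_id=f"m{i}")
            for i, (b, y) in enumerate([(4.5, 1.2), (3.6, 1.0), (3.0, 0.8),
                                        (4.0, 1.1), (3.3, 0.6), (2.8, 1.25)])
        ]
        carriers, non_carriers = pool_stratified_trials(trials)
        z_route = compare_estimates_z(carriers.pooled, non_carriers.pooled)
        reg_route = ratio_via_metaregression(trials, method="mom")
        assert reg_route.slope.point == pytest.approx(
            z_route.ratio.point, rel=0.02
        )
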