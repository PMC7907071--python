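"""Additive-interaction measures, direction rules and interval estimation."""

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

from addinter import (
    DomainError,
    JointExposureTable,
    attributable_proportions,
    bootstrap_ci,
    classify_direction,
    delta_ci,
    joint_odds_ratios,
    measures_from_table,
    reri,
    run_interaction_analysis,
    synergy_index,
)

from conftest import records_from_joint

ors = st.floats(min_value=0.05, max_value=50.0, allow_nan=False)


class TestPointMeasures:
    def test_family_history_diabetes_worked_values(self):
        """The study's printed FH x DM odds ratios give RERI 8.678, SI 2.265,
        AP 52.48%, PAP 55.85% at full precision."""
        args = (4.354, 4.505, 16.537)
        assert reri(*args) == pytest.approx(8.678)
        assert synergy_index(*args) == pytest.approx(2.2652, abs=5e-4)
        ap, pap = attributable_proportions(*args)
        assert ap == pytest.approx(0.5248, abs=5e-4)
        assert pap == pytest.approx(0.5585, abs=5e-4)

    @pytest.mark.parametrize(
        "args,expected_reri", [((1, 1, 1), 0.0), ((2, 2, 4), 1.0)]
    )
    def test_reri_direct_arithmetic(self, args, expected_reri):
        assert reri(*args) == pytest.approx(expected_reri)

    def test_si_direct_arithmetic(self):
        assert synergy_index(2, 2, 4) == pytest.approx(1.5)

    def test_si_undefined_when_no_individual_excess(self):
        assert synergy_index(1.0, 1.0, 5.0) is None

    def test_ap_direct_arithmetic(self):
        ap, pap = attributable_proportions(2, 2, 4)
        assert ap == pytest.approx(0.25)
        assert pap == pytest.approx(1 / 3)

    def test_pap_undefined_at_null_joint_or(self):
        ap, pap = attributable_proportions(1.0, 1.0, 1.0)
        assert ap == 0.0
        assert pap is None

    def test_nonfinite_input_rejected(self):
        with pytest.raises(DomainError):
            reri(1.0, float("inf"), 2.0)
        with pytest.raises(DomainError):
            synergy_index(-1.0, 2.0, 2.0)


class TestDirections:
    @pytest.mark.parametrize(
        "args,expected",
        [
            ((4.354, 4.505, 16.537), ("positive", "positive")),
            ((0.741, 4.942, 4.0), ("reverse", "negative")),
            ((2, 2, 3.5), ("reverse", "positive")),  # the rules disagree
            ((2, 2, 4), ("additive", "positive")),
        ],
    )
    def test_sum_and_reri_rules(self, args, expected):
        assert classify_direction(*args) == expected


class TestAlgebraicProperties:
    @given(or01=ors, or10=ors, or11=ors)
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_ap_pap_reri_identity(self, or01, or10, or11):
        """ap * or11 = pap * (or11 - 1) = reri for every OR triple."""
        excess = reri(or01, or10, or11)
        ap, pap = attributable_proportions(or01, or10, or11)
        assert ap * or11 == pytest.approx(excess, rel=1e-12, abs=1e-12)
        if pap is not None:
            assert pap * (or11 - 1) == pytest.approx(excess, rel=1e-12, abs=1e-12)

    @given(or01=ors, or10=ors)
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_si_is_one_iff_reri_is_zero(self, or01, or10):
        # on the additive surface or11 = or10 + or01 - 1 (when it stays positive)
        or11 = or10 + or01 - 1.0
        if or11 <= 0:
            return
        si = synergy_index(or01, or10, or11)
        assert reri(or01, or10, or11) == pytest.approx(0.0, abs=1e-12)
        if si is not None:
            assert si == pytest.approx(1.0)

    def test_reri_monotonicity(self):
        base = reri(2.0, 3.0, 7.0)
        assert reri(2.0, 3.0, 7.5) > base
        assert reri(2.5, 3.0, 7.0) < base
        assert reri(2.0, 3.5, 7.0) < base

    def test_exposure_swap_symmetry(self, published):
        for pub in published.values():
            m = measures_from_table(pub.joint, ci_method=None)
            mt = measures_from_table(pub.joint.transposed(), ci_method=None)
            assert mt.or10.point == pytest.approx(m.or01.point)
            assert mt.or01.point == pytest.approx(m.or10.point)
            assert mt.reri == pytest.approx(m.reri)
            assert mt.ap == pytest.approx(m.ap)
            if m.si is not None:
                assert mt.si == pytest.approx(m.si)


class TestJointOddsRatios:
    def test_family_history_and_diabetes_strata(self, published):
        or01, or10, or11 = joint_odds_ratios(published[2].joint)
        assert round(or10.point, 3) == 4.505
        assert round(or01.point, 3) == 4.354

    def test_taste_joint_stratum(self, published):
        *_, or11 = joint_odds_ratios(published[5].joint)
        assert round(or11.point, 3) == 6.521

    def test_identical_strata_are_null(self):
        joint = JointExposureTable(counts={c: (10, 10) for c in ((0, 0), (0, 1), (1, 0), (1, 1))})
        assert all(e.point == 1.0 for e in joint_odds_ratios(joint))


class TestIntervals:
    def test_delta_matches_saturated_logistic_fit(self, published):
        """Closed-form covariance equals the saturated two-factor ML fit."""
        joint = published[3].joint
        rows, y = [], []
        for (e1, e2), (n_case, n_ctrl) in joint.counts.items():
            for is_case, n in ((1, n_case), (0, n_ctrl)):
                rows += [[1, e1 * (1 - e2), e2 * (1 - e1), e1 * e2]] * int(n)
                y += [is_case] * int(n)
        fit = sm.Logit(np.array(y), np.array(rows)).fit(disp=0)
        b, cov = fit.params[1:], fit.cov_params()[1:, 1:]
        grad = np.array([-np.exp(b[0]), -np.exp(b[1]), np.exp(b[2])])
        excess = np.exp(b[2]) - np.exp(b[0]) - np.exp(b[1]) + 1
        se = np.sqrt(grad @ cov @ grad)
        z = 1.959963984540054
        cis = delta_ci(joint)
        assert cis.reri[0] == pytest.approx(excess - z * se, abs=1e-6)
        assert cis.reri[1] == pytest.approx(excess + z * se, abs=1e-6)

    def test_null_table_interval_contains_zero(self):
        joint = JointExposureTable(counts={c: (25, 25) for c in ((0, 0), (0, 1), (1, 0), (1, 1))})
        lo, hi = delta_ci(joint).reri
        assert lo <= 0 <= hi

    def test_bootstrap_is_deterministic_under_seed(self, published):
        a = bootstrap_ci(published[2].joint, reps=1000, seed=99)
        b = bootstrap_ci(published[2].joint, reps=1000, seed=99)
        assert a == b

    def test_bootstrap_brackets_observed_measures(self, published):
        boot = bootstrap_ci(published[2].joint, reps=4000, seed=5)
        m = measures_from_table(published[2].joint, ci_method=None)
        assert boot.reri[0] < m.reri < boot.reri[1]
        assert boot.ap[0] < m.ap < boot.ap[1]
        assert boot.si[0] < m.si < boot.si[1]
        assert boot.n_undefined == 0 and boot.warning is None

    def test_bootstrap_contract_violations(self, published):
        with pytest.raises(DomainError):
            bootstrap_ci(published[2].joint, reps=100, seed=1)
        with pytest.raises(DomainError):
            bootstrap_ci(published[2].joint, reps=1000, seed=None)


class TestComposite:
    def test_composes_crosstab_and_measures(self):
        counts = {(0, 0): (30, 95), (0, 1): (22, 16), (1, 0): (175, 123), (1, 1): (187, 36)}
        records = records_from_joint(counts)
        m = run_interaction_analysis(records, "e1", "e2", ci_method="delta")
        assert round(m.or10.point, 3) == 4.505
        assert m.direction_sum_rule == "positive"
        assert m.cis is not None and m.cis.method == "delta"

    def test_variable_paired_with_itself_rejected(self):
        records = records_from_joint({(0, 0): (5, 5), (0, 1): (5, 5), (1, 0): (5, 5), (1, 1): (5, 5)})
        with pytest.raises(DomainError):
            run_interaction_analysis(records, "e1", "e1")
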