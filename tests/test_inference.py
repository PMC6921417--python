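import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from targetdx import (
    ContingencyTable,
    MACriteria,
    evaluate_strategies,
    exact_upper_pvalue,
    find_qualifying_thresholds,
    joint_mac_test,
)

from oracles import binom_tail, scan_tables_bruteforce

MAC85 = MACriteria(0.85, 0.85)


class TestJointMacTest:
    def test_perfect_results_at_ample_n_reject(self):
        res = joint_mac_test(ContingencyTable(tp=179, fn=0, fp=0, tn=76), MAC85, 0.05)
        assert res.reject_null
        assert res.point_in_region
        assert res.confidence_region_in_region

    def test_point_below_mac_cannot_reject(self):
        res = joint_mac_test(ContingencyTable(tp=150, fn=29, fp=0, tn=76), MAC85, 0.05)
        assert res.estimate.sensitivity < 0.85
        assert not res.point_in_region
        assert not res.reject_null

    def test_component_pvalues_are_exact_binomial_tails(self):
        # frozen from the direct tail-sum enumeration oracle
        res = joint_mac_test(ContingencyTable(tp=170, fn=9, fp=2, tn=74), MAC85, 0.05)
        assert res.p_sensitivity == pytest.approx(2.2857341983504986e-05, rel=1e-9)
        assert res.p_specificity == pytest.approx(0.00044604155912706663, rel=1e-9)
        assert res.p_joint == max(res.p_sensitivity, res.p_specificity)
        assert res.reject_null

    @given(
        tp=st.integers(0, 40),
        fn=st.integers(0, 40),
        fp=st.integers(0, 40),
        tn=st.integers(0, 40),
        mac_s=st.floats(0.05, 0.95),
        mac_p=st.floats(0.05, 0.95),
        alpha=st.sampled_from([0.025, 0.05, 0.10]),
    )
    def test_duality_and_iut_structure(self, tp, fn, fp, tn, mac_s, mac_p, alpha):
        """Joint rejection coincides with both Clopper-Pearson lower bounds
        clearing MAC, rejection implies the point is in the region, and the
        joint p-value is the max of the components."""
        if tp + fn == 0 or fp + tn == 0:
            return
        table = ContingencyTable(tp=tp, fn=fn, fp=fp, tn=tn)
        res = joint_mac_test(table, MACriteria(mac_s, mac_p), alpha)
        assert res.p_joint == max(res.p_sensitivity, res.p_specificity)
        assert res.reject_null == res.confidence_region_in_region
        if res.reject_null:
            assert res.point_in_region

    def test_pvalues_match_oracle(self):
        for k, n, p0 in [(170, 179, 0.85), (9, 10, 0.5), (0, 5, 0.3), (5, 5, 0.9)]:
            assert exact_upper_pvalue(k, n, p0) == pytest.approx(
                binom_tail(k, n, p0), abs=1e-12
            )


class TestEvaluateStrategies:
    def _six_strategies(self):
        # one promising-but-underpowered strategy, five with a point outside
        good_small = ("attia-like", ContingencyTable(tp=18, fn=2, fp=2, tn=18))
        others = [
            (f"rule{i}", ContingencyTable(tp=tp, fn=20 - tp, fp=fp, tn=20 - fp))
            for i, (tp, fp) in enumerate([(14, 2), (12, 1), (16, 4), (10, 2), (15, 5)], 1)
        ]
        return [good_small, *others]

    def test_qualitative_external_validation_pattern(self):
        """Six rules-based strategies of which exactly one has both point
        estimates in the target region but a confidence region reaching
        outside: nothing rejects, one is point-only."""
        summary = evaluate_strategies(self._six_strategies(), MAC85, 0.05)
        assert summary.n_reject == 0
        assert summary.n_point_in_region == 1
        assert summary.n_point_only == 1

    def test_vacuous_mac_rejects_everywhere(self):
        tables = [("a", ContingencyTable(tp=30, fn=0, fp=0, tn=30))]
        summary = evaluate_strategies(tables, MACriteria(0.0, 0.0), 0.05)
        assert summary.n_reject == 1

    def test_singleton_matches_joint_test(self):
        table = ContingencyTable(tp=170, fn=9, fp=2, tn=74)
        single = evaluate_strategies([("only", table)], MAC85, 0.05).results[0]
        direct = joint_mac_test(table, MAC85, 0.05)
        assert single.p_joint == direct.p_joint
        assert single.reject_null == direct.reject_null
        assert single.label == "only"

    def test_duplicate_labels_rejected(self):
        t = ContingencyTable(tp=1, fn=1, fp=1, tn=1)
        with pytest.raises(ValueError, match="duplicate"):
            evaluate_strategies([("x", t), ("x", t)], MAC85)
        with pytest.raises(ValueError):
            evaluate_strategies([], MAC85)


class TestThresholdScan:
    def test_separated_classes_have_a_qualifying_threshold(self):
        rng = np.random.default_rng(7)
        scores = np.concatenate([rng.uniform(0, 1, 30), rng.uniform(2, 3, 30)])
        status = np.array([0] * 30 + [1] * 30)
        rows = find_qualifying_thresholds(scores, status, MACriteria(0.9, 0.9))
        perfect = [r for r in rows if r.sensitivity == 1.0 and r.specificity == 1.0]
        assert perfect and all(r.in_region_point for r in perfect)

    def test_uninformative_score_never_beats_chance(self):
        scores = [1.0] * 20
        status = [0, 1] * 10
        rows = find_qualifying_thresholds(scores, status, MACriteria(0.6, 0.6))
        assert all(r.sensitivity + r.specificity <= 1.0 + 1e-12 for r in rows)
        assert not any(r.in_region_point for r in rows)

    def test_rows_match_bruteforce_tables(self):
        rng = np.random.default_rng(11)
        scores = rng.normal(size=20).round(2)
        status = (rng.uniform(size=20) < 0.5).astype(int)
        if status.sum() in (0, 20):
            status[0] = 1 - status[0]
        for direction in ("higher_positive", "lower_positive"):
            rows = find_qualifying_thresholds(
                scores, status, MACriteria(0.5, 0.5), direction=direction
            )
            # one row per distinct-score gap plus the two infinite ends
            assert len(rows) == len(np.unique(scores)) + 1
            for row in rows:
                tp, fp, fn, tn = scan_tables_bruteforce(
                    scores, status, row.threshold, direction
                )
                assert (row.table.tp, row.table.fp, row.table.fn, row.table.tn) == (
                    tp,
                    fp,
                    fn,
                    tn,
                )

    @given(st.data())
    def test_monotone_tradeoff_along_the_scan(self, data):
        """As the threshold rises (higher_positive), sensitivity never
        increases and specificity never decreases."""
        n = data.draw(st.integers(4, 30))
        scores = data.draw(
            st.lists(st.floats(-5, 5, allow_nan=False), min_size=n, max_size=n)
        )
        status = data.draw(
            st.lists(st.integers(0, 1), min_size=n, max_size=n).filter(
                lambda s: 0 < sum(s) < len(s)
            )
        )
        rows = find_qualifying_thresholds(scores, status, MACriteria(0.5, 0.5))
        sens = [r.sensitivity for r in rows]
        spec = [r.specificity for r in rows]
        assert all(a >= b - 1e-12 for a, b in zip(sens, sens[1:]))
        assert all(a <= b + 1e-12 for a, b in zip(spec, spec[1:]))

    def test_single_class_input_rejected(self):
        with pytest.raises(ValueError):
            find_qualifying_thresholds([1.0, 2.0], [1, 1], MAC85)
        with pytest.raises(ValueError):
            find_qualifying_thresholds([1.0, math.nan], [0, 1], MAC85)
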