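"""Entropy split search: closed-form entropy, split statistics, selection policy,
and brute-force oracle equivalence."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from heatadapt import (
    DataError,
    SplitCandidate,
    binary_entropy,
    enumerate_candidates,
    evaluate_split,
    select_cutpoint,
)
from heatadapt.cutpoints import CutpointRule, PUBLISHED_RULES

from conftest import make_observations


def brute_force_best_gain(values, labels):
    """Independent exhaustive oracle: best info gain over every distinct
    bipartition induced by a threshold, computed by direct counting."""

    def h(p):
        if p in (0.0, 1.0):
            return 0.0
        return -p * math.log2(p) - (1 - p) * math.log2(1 - p)

    n = len(values)
    p_parent = sum(labels) / n
    parent = h(p_parent)
    best = 0.0
    sorted_vals = sorted(set(values))
    cuts = [(a + b) / 2 for a, b in zip(sorted_vals, sorted_vals[1:])]
    for t in cuts:
        left = [lab for v, lab in zip(values, labels) if v < t]
        right = [lab for v, lab in zip(values, labels) if v >= t]
        child = (len(left) / n) * h(sum(left) / len(left)) + (
            len(right) / n
        ) * h(sum(right) / len(right))
        best = max(best, parent - child)
    return parent, best


class TestBinaryEntropy:
    @pytest.mark.parametrize(
        "p,expected",
        [(0.0, 0.0), (1.0, 0.0), (0.5, 1.0), (0.25, 0.8112781244591328)],
    )
    def test_closed_form(self, p, expected):
        assert binary_entropy(p) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("p", [-0.1, 1.1])
    def test_domain_error(self, p):
        with pytest.raises(DataError):
            binary_entropy(p)

    @given(st.floats(0.0, 1.0))
    @settings(derandomize=True, max_examples=50)
    def test_symmetry_and_bounds(self, p):
        h = binary_entropy(p)
        assert 0.0 <= h <= 1.0
        assert h == pytest.approx(binary_entropy(1.0 - p), abs=1e-12)


class TestEvaluateSplit:
    def test_pure_split_hand_computed(self):
        """Six observations, threshold -13: favorable side pure (p=1),
        unfavorable side pure (p=0); gain equals the full parent bit."""
        obs = make_observations([-20, -15, -14, -5, -2, 0],
                                [True, True, True, False, False, False])
        c = evaluate_split(obs, "d_hr", -13, "below", strict=True)
        assert (c.n_favorable, c.n_total) == (3, 6)
        assert c.p_improved_favorable == 1.0
        assert c.parent_entropy == pytest.approx(1.0)
        assert c.weighted_child_entropy == pytest.approx(0.0)
        assert c.info_gain == pytest.approx(1.0)

    def test_uninformative_symmetric_split(self):
        obs = make_observations([1, 2, 3, 4], [True, False, True, False])
        c = evaluate_split(obs, "d_hr", 2.5, "below", strict=True)
        assert (c.n_favorable, c.p_improved_favorable) == (2, 0.5)
        assert c.info_gain == pytest.approx(0.0, abs=1e-12)

    def test_constant_labels_zero_gain_everywhere(self):
        obs = make_observations([1, 2, 3, 4], [True] * 4)
        for t in (1.5, 2.5, 3.5):
            c = evaluate_split(obs, "d_hr", t, "below", strict=True)
            assert c.parent_entropy == 0.0 and c.info_gain == 0.0

    def test_empty_side_gain_zero(self):
        obs = make_observations([1, 2, 3], [True, False, True])
        c = evaluate_split(obs, "d_hr", -100, "below", strict=True)
        assert c.n_favorable == 0
        assert c.info_gain == pytest.approx(0.0, abs=1e-12)

    def test_boundary_strictness(self):
        obs = make_observations([-13, -14], [True, True])
        strict = evaluate_split(obs, "d_hr", -13, "below", strict=True)
        loose = evaluate_split(obs, "d_hr", -13, "below", strict=False)
        assert strict.n_favorable == 1 and loose.n_favorable == 2

    def test_nonfinite_rejected(self):
        obs = make_observations([1, float("nan"), 3], [True, False, True])
        with pytest.raises(DataError):
            evaluate_split(obs, "d_hr", 2, "below", strict=True)


class TestEnumerateCandidates:
    def test_midpoints_between_distinct_values(self):
        obs = make_observations([1, 2, 3, 2], [True, False, True, False])
        cands = enumerate_candidates(obs, "d_hr", "below", True)
        assert [c.threshold for c in cands] == [1.5, 2.5]

    def test_exhaustive_toy_scan(self):
        obs = make_observations([-20, -15, -14, -5, -2, 0],
                                [True, True, True, False, False, False])
        cands = enumerate_candidates(obs, "d_hr", "below", True)
        assert len(cands) == 5
        best = max(cands, key=lambda c: c.info_gain)
        assert best.threshold == pytest.approx(-9.5)
        assert best.info_gain == pytest.approx(1.0)

    def test_regular_grid_cardinality(self):
        obs = make_observations(list(range(-20, 1)), [True] * 10 + [False] * 11)
        cands = enumerate_candidates(obs, "d_hr", "below", True, grid_step=1.0)
        assert len(cands) == 21
        assert [c.threshold for c in cands] == list(range(-20, 1))

    def test_fewer_than_two_distinct_values(self):
        obs = make_observations([2.0, 2.0], [True, False])
        assert enumerate_candidates(obs, "d_hr", "below", True) == []

    def test_permutation_invariance(self):
        vals = [-20, -15, -14, -5, -2, 0]
        labs = [True, True, False, True, False, False]
        a = enumerate_candidates(make_observations(vals, labs), "d_hr", "below", True)
        rng = np.random.default_rng(0)
        order = rng.permutation(6)
        b = enumerate_candidates(
            make_observations([vals[i] for i in order], [labs[i] for i in order]),
            "d_hr", "below", True,
        )
        assert len(a) == len(b)
        for ca, cb in zip(a, b):
            assert ca.threshold == cb.threshold
            assert (ca.n_favorable, ca.n_total) == (cb.n_favorable, cb.n_total)
            assert ca.info_gain == pytest.approx(cb.info_gain, abs=1e-12)
            assert ca.p_improved_favorable == pytest.approx(cb.p_improved_favorable, abs=1e-12)


class TestSelectCutpoint:
    @staticmethod
    def cand(threshold, n_fav, p, n_total=75):
        return SplitCandidate(threshold, n_fav, n_total, p, 1.0, 0.9, 0.1)

    def test_probability_support_balance(self):
        """Two candidates, 78%/41 cases vs 82%/22 cases: with the default
        quarter-support floor (19 of 75) the higher-probability split wins."""
        cands = [self.cand(-5.0, 41, 0.78), self.cand(-13.0, 22, 0.82)]
        rule, table = select_cutpoint(cands, "d_hr")
        assert rule.threshold == -13.0
        assert len(table) == 2

    def test_support_floor_excludes_small_candidates(self):
        cands = [self.cand(-5.0, 41, 0.78), self.cand(-25.0, 5, 1.0)]
        rule, _ = select_cutpoint(cands, "d_hr")
        assert rule.threshold == -5.0

    def test_no_candidate_meets_support(self):
        cands = [self.cand(-25.0, 5, 1.0)]
        with pytest.raises(DataError, match="lower the fraction"):
            select_cutpoint(cands, "d_hr")

    def test_single_eligible_candidate(self):
        cands = [self.cand(-10.0, 30, 0.7)]
        rule, _ = select_cutpoint(cands, "d_hr")
        assert rule.threshold == -10.0

    def test_tie_breaks_nearest_zero(self):
        cands = [self.cand(-17.0, 22, 0.82), self.cand(-13.0, 22, 0.82)]
        rule, _ = select_cutpoint(cands, "d_hr")
        assert rule.threshold == -13.0

    def test_max_info_gain_policy(self):
        a = SplitCandidate(-5.0, 41, 75, 0.78, 1.0, 0.9, 0.10)
        b = SplitCandidate(-13.0, 22, 75, 0.82, 1.0, 0.8, 0.20)
        rule, _ = select_cutpoint([a, b], "d_hr", policy="max_info_gain")
        assert rule.threshold == -13.0


class TestOracleEquivalence:
    @given(
        st.lists(
            st.tuples(st.integers(-30, 10), st.booleans()),
            min_size=2,
            max_size=12,
        )
    )
    @settings(derandomize=True, max_examples=200)
    def test_best_gain_matches_brute_force(self, pairs):
        """For <=12 observations the scan's best information gain equals an
        independent exhaustive enumeration, and every gain is within bounds."""
        values = [float(v) for v, _ in pairs]
        labels = [l for _, l in pairs]
        obs = make_observations(values, labels)
        cands = enumerate_candidates(obs, "d_hr", "below", strict=True)
        parent, best_oracle = brute_force_best_gain(values, labels)
        if not cands:
            assert len(set(values)) < 2
            return
        best = max(c.info_gain for c in cands)
        assert best == pytest.approx(best_oracle, abs=1e-12)
        for c in cands:
            assert -1e-12 <= c.info_gain <= c.parent_entropy + 1e-12
            assert c.parent_entropy == pytest.approx(parent, abs=1e-12)


def test_published_rules_encode_reported_thresholds():
    by_var = {r.variable: r for r in PUBLISHED_RULES}
    hr, sr, ts = by_var["d_hr"], by_var["d_sr"], by_var["d_ts"]
    assert (hr.threshold, hr.favorable_side, hr.strict) == (-13.0, "below", True)
    assert (sr.threshold, sr.favorable_side, sr.strict) == (0.3, "above", True)
    assert (ts.threshold, ts.favorable_side, ts.strict) == (-0.5, "below", False)


def test_rule_membership_semantics():
    rule = CutpointRule("d_ts", -0.5, "below", strict=False)
    assert rule.is_met(-0.5) and rule.is_met(-1.0) and not rule.is_met(0.0)
    strict = CutpointRule("d_hr", -13.0, "below", strict=True)
    assert not strict.is_met(-13.0) and strict.is_met(-13.5)
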