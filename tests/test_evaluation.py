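"""Discrimination, operating point, calibration, subgroups, labeling."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from triagenlp import (
    auc_ci,
    calibration_bins,
    compute_auc,
    evaluate_scores,
    label_infection,
    subgroup_sensitivity,
    top_weights,
    youden_threshold,
)


def _pair_count_auc(scores, labels):
    scores, labels = np.asarray(scores, float), np.asarray(labels, int)
    pos, neg = scores[labels == 1], scores[labels == 0]
    total = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    return total / (pos.size * neg.size)


class TestLabelInfection:
    def test_exact_membership(self):
        assert label_infection(["038.9"], ["038.9", "486"]) == 1

    def test_empty_codes(self):
        assert label_infection([], ["038.9"]) == 0

    def test_dot_normalization(self):
        assert label_infection(["0389"], ["038.9"]) == 1

    def test_prefix_patterns(self):
        assert label_infection(["038.42"], ["038*"]) == 1
        assert label_infection(["039.1"], ["038*"]) == 0

    def test_empty_criterion_errors(self):
        with pytest.raises(ValueError):
            label_infection(["038.9"], [])

    def test_matches_bruteforce_matcher(self, rng):
        criterion = ["038*", "486", "599.0", "V09*", "683"]
        pool = ["038.9", "038.42", "486", "599.0", "599.9", "V09.1", "683",
                "845.00", "920", "V70.0"]
        exact = {"486", "5990", "683"}
        prefixes = ["038", "V09"]
        for _ in range(20):
            codes = list(rng.choice(pool, size=rng.integers(0, 6)))
            expected = int(
                any(
                    c.replace(".", "") in exact
                    or any(c.replace(".", "").startswith(p) for p in prefixes)
                    for c in codes
                )
            )
            assert label_infection(codes, criterion) == expected


class TestAuc:
    def test_perfect_separation(self):
        assert compute_auc([1, 2, 3, 4], [0, 0, 1, 1]) == 1.0

    def test_all_ties(self):
        assert compute_auc([5, 5, 5, 5], [0, 1, 0, 1]) == 0.5

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            compute_auc([1, 2], [1, 1])

    @given(
        st.lists(st.integers(0, 5), min_size=2, max_size=40).filter(
            lambda s: len(s) >= 2
        ),
        st.randoms(use_true_random=False),
    )
    def test_equals_pair_counting_oracle(self, scores, rnd):
        labels = [rnd.randint(0, 1) for _ in scores]
        if len(set(labels)) < 2:
            labels[0], labels[-1] = 0, 1
        assert compute_auc(scores, labels) == pytest.approx(
            _pair_count_auc(scores, labels), abs=1e-12
        )

    def test_trapezoidal_roc_area_agrees(self, rng):
        scores = rng.integers(0, 10, size=100)  # heavy ties
        labels = rng.integers(0, 2, size=100)
        report = evaluate_scores(scores, labels)
        fpr = np.array([p[0] for p in report.roc])
        tpr = np.array([p[1] for p in report.roc])
        assert fpr[0] == 0 and tpr[0] == 0 and fpr[-1] == 1 and tpr[-1] == 1
        assert np.trapezoid(tpr, fpr) == pytest.approx(report.auc, abs=1e-10)


class TestAucCi:
    def test_interval_contains_auc_and_shrinks(self, rng):
        small = rng.normal(size=50)
        y_small = (small + rng.normal(size=50) > 0).astype(int)
        lo, hi = auc_ci(small, y_small)
        assert lo <= compute_auc(small, y_small) <= hi
        big = rng.normal(size=5000)
        y_big = (big + rng.normal(size=5000) > 0).astype(int)
        lo2, hi2 = auc_ci(big, y_big)
        assert (hi2 - lo2) < (hi - lo)

    def test_label_flip_reflects_interval(self, rng):
        s = rng.normal(size=60)
        y = (s + rng.normal(size=60) > 0).astype(int)
        lo, hi = auc_ci(s, y)
        lo_f, hi_f = auc_ci(s, 1 - y)
        assert lo_f == pytest.approx(1 - hi, abs=1e-12)
        assert hi_f == pytest.approx(1 - lo, abs=1e-12)

    def test_near_degenerate_variance_on_separable_data(self):
        s = np.r_[np.zeros(200), np.ones(200)]
        y = np.r_[np.zeros(200), np.ones(200)].astype(int)
        lo, hi = auc_ci(s, y)
        assert hi - lo < 1e-8


class TestYouden:
    def test_separable_scores(self):
        thr, ppv, sens, spec = youden_threshold([1, 2, 8, 9], [0, 0, 1, 1])
        assert sens == spec == ppv == 1.0 and 2 < thr <= 8

    def test_all_equal_scores(self):
        thr, ppv, sens, spec = youden_threshold([3, 3, 3], [0, 1, 1])
        assert sens + spec - 1 == 0

    def test_matches_exhaustive_enumeration(self, rng):
        scores = rng.integers(0, 8, size=20).astype(float)
        labels = rng.integers(0, 2, size=20)
        if len(set(labels)) < 2:
            labels[0] = 1 - labels[0]
        thr, _, sens, spec = youden_threshold(scores, labels)
        best_j, best_thr = -np.inf, None
        for cand in sorted(set(scores)):
            pred = scores >= cand
            s = (pred & (labels == 1)).sum() / (labels == 1).sum()
            p = (~pred & (labels == 0)).sum() / (labels == 0).sum()
            if s + p - 1 > best_j + 1e-12:
                best_j, best_thr = s + p - 1, cand
        assert thr == best_thr
        assert sens + spec - 1 == pytest.approx(best_j, abs=1e-12)


class TestCalibration:
    def test_bin_counts_partition(self, rng):
        p = rng.random(500)
        y = rng.integers(0, 2, 500)
        bins = calibration_bins(p, y)
        assert sum(b["n"] for b in bins) == 500
        assert len(bins) == 10

    def test_single_bin_zero_fraction(self):
        bins = calibration_bins([0.05] * 20, [0] * 20)
        assert bins[0]["n"] == 20 and bins[0]["observed"] == 0.0
        assert all(b["n"] == 0 and np.isnan(b["observed"]) for b in bins[1:])

    def test_probability_one_lands_in_last_bin(self):
        bins = calibration_bins([1.0, 0.95], [1, 1])
        assert bins[-1]["n"] == 2

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            calibration_bins([1.2], [1])

    def test_calibrated_probabilities_match_bins(self, rng):
        """Under the calibration null, observed fractions track midpoints."""
        p = rng.random(20_000)
        y = (rng.random(20_000) < p).astype(int)
        for b in calibration_bins(p, y):
            mid = (b["lo"] + b["hi"]) / 2
            assert b["ci_low"] - 0.05 <= mid <= b["ci_high"] + 0.05


class TestSubgroups:
    def test_identity_mask_equals_overall(self, rng):
        s = rng.normal(size=100)
        y = rng.integers(0, 2, 100)
        thr = float(np.median(s))
        out = subgroup_sensitivity(s, y, thr, {"all": np.ones(100, bool)})
        overall = (s[y == 1] >= thr).mean()
        assert out["all"] == pytest.approx(overall)

    def test_all_positives_above_threshold(self):
        out = subgroup_sensitivity([5, 6], [1, 1, ], 0.0, {"g": [True, True]})
        assert out["g"] == 1.0

    def test_zero_positive_subgroup_is_nan(self):
        out = subgroup_sensitivity([1, 2], [0, 0], 0.0, {"g": [True, True]})
        assert np.isnan(out["g"])

    def test_matches_filter_oracle(self, rng):
        s = rng.normal(size=60)
        y = rng.integers(0, 2, 60)
        masks = {f"m{i}": rng.random(60) < 0.5 for i in range(4)}
        out = subgroup_sensitivity(s, y, 0.1, masks)
        for name, mask in masks.items():
            idx = [i for i in range(60) if mask[i] and y[i] == 1]
            if not idx:
                assert np.isnan(out[name])
            else:
                expected = np.mean([s[i] >= 0.1 for i in idx])
                assert out[name] == pytest.approx(expected)


class TestTopWeights:
    def test_simple_argmax(self):
        pos, neg = top_weights(["a", "b", "c"], [2.0, -1.0, 0.0], k=1)
        assert pos == [("a", 2.0)] and neg == [("b", -1.0)]

    def test_k_zero(self):
        pos, neg = top_weights(["a"], [1.0], k=0)
        assert pos == [] and neg == []

    def test_k_truncated_to_feature_count(self):
        pos, _ = top_weights(["a", "b"], [1.0, 2.0], k=10)
        assert len(pos) == 2
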