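"""ROC/AUC, bootstrap CIs, optimal cut-off and unpaired AUC comparison."""

import dataclasses

import numpy as np
import pytest

from focaldx.roc import (
    bootstrap_auc,
    compare_auc_unpaired,
    optimal_cutoff,
    roc_curve,
)


def auc_oracle(scores, labels):
    """Exhaustive concordant-pair fraction (ties at half weight)."""
    pos = [s for s, l in zip(scores, labels) if l == "focal"]
    neg = [s for s, l in zip(scores, labels) if l == "non_focal"]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def random_instance(rng, allow_ties=True):
    n_pos = int(rng.integers(1, 16))
    n_neg = int(rng.integers(1, 16))
    if allow_ties and rng.random() < 0.5:
        pool = rng.integers(1, 8, size=n_pos + n_neg) / 2.0  # heavy ties
    else:
        pool = rng.uniform(0.5, 5.0, size=n_pos + n_neg)
    return pool.tolist(), ["focal"] * n_pos + ["non_focal"] * n_neg


class TestRocCurve:
    def test_perfect_separation(self):
        r = roc_curve([2, 3, 1], ["focal", "focal", "non_focal"])
        assert r.auc == 1.0

    def test_uninformative_scores(self):
        r = roc_curve([2.0] * 6, ["focal"] * 3 + ["non_focal"] * 3)
        assert r.auc == 0.5

    def test_matches_pair_enumeration_oracle(self, rng):
        for _ in range(50):
            scores, labels = random_instance(rng)
            assert roc_curve(scores, labels).auc == pytest.approx(
                auc_oracle(scores, labels), abs=1e-12
            )

    def test_matches_sklearn(self, rng):
        sk = pytest.importorskip("sklearn.metrics")
        for _ in range(20):
            scores, labels = random_instance(rng)
            y = [1 if l == "focal" else 0 for l in labels]
            if len(set(y)) < 2:
                continue
            assert roc_curve(scores, labels).auc == pytest.approx(
                sk.roc_auc_score(y, scores), abs=1e-12
            )

    def test_sensitivity_nonincreasing_in_threshold(self, rng):
        scores, labels = random_instance(rng)
        r = roc_curve(scores, labels)
        assert all(a >= b for a, b in zip(r.sens_points, r.sens_points[1:]))
        assert all(a <= b for a, b in zip(r.spec_points, r.spec_points[1:]))

    def test_monotone_transform_invariance(self, rng):
        scores, labels = random_instance(rng)
        transformed = np.exp(np.asarray(scores) / 2).tolist()
        assert roc_curve(scores, labels).auc == pytest.approx(
            roc_curve(transformed, labels).auc, abs=1e-12
        )

    def test_score_negation_complements_auc(self, rng):
        scores, labels = random_instance(rng)
        a = roc_curve(scores, labels).auc
        b = roc_curve([-s for s in scores], labels).auc
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve([1, 2], ["focal", "focal"])


class TestBootstrapAuc:
    def test_perfect_separation_degenerate_ci(self):
        r = bootstrap_auc([2, 3, 1, 0.5], ["focal", "focal", "non_focal", "non_focal"],
                          replicates=200, seed=1)
        assert r.auc_ci == (1.0, 1.0)

    def test_single_replicate_degenerates_to_that_resample(self, rng):
        scores, labels = random_instance(rng, allow_ties=False)
        r = bootstrap_auc(scores, labels, replicates=1, seed=3)
        assert r.auc_ci[0] == r.auc_ci[1] or r.auc_ci[0] <= r.auc <= r.auc_ci[1]

    def test_bit_reproducible_for_fixed_seed(self, rng):
        scores, labels = random_instance(rng)
        a = bootstrap_auc(scores, labels, replicates=500, seed=42)
        b = bootstrap_auc(scores, labels, replicates=500, seed=42)
        assert a == b

    def test_unstratified_variant_runs(self, rng):
        scores, labels = random_instance(rng, allow_ties=False)
        r = bootstrap_auc(scores, labels, replicates=300, seed=5, stratified=False)
        assert r.auc_ci[0] <= r.auc <= r.auc_ci[1]


class TestOptimalCutoff:
    def test_midpoint_for_separated_classes(self):
        r = optimal_cutoff([2, 3, 1], ["focal", "focal", "non_focal"],
                           replicates=50, seed=0)
        assert r.cutoff == 1.5
        assert r.accuracy_at_cutoff == 1.0

    def test_overlapping_example_lowest_maximising_midpoint(self):
        """Focal {1.47, 1.58, 1.72} vs non-focal {1.05, 1.12, 1.20, 1.73}:
        best accuracy 6/7 at the midpoint 1.335."""
        scores = [1.47, 1.58, 1.72, 1.05, 1.12, 1.20, 1.73]
        labels = ["focal"] * 3 + ["non_focal"] * 4
        r = optimal_cutoff(scores, labels, replicates=50, seed=0)
        assert r.accuracy_at_cutoff == pytest.approx(6 / 7)
        assert r.cutoff == pytest.approx((1.20 + 1.47) / 2)

    def test_all_equal_scores_sentinel_cutoff(self):
        r = optimal_cutoff([2.0] * 5, ["focal"] * 2 + ["non_focal"] * 3,
                           replicates=50, seed=0)
        assert np.isinf(r.cutoff)
        assert r.accuracy_at_cutoff == pytest.approx(3 / 5)  # max(prev, 1-prev)

    def test_interior_cutoff_for_balanced_overlapping_classes(self, rng):
        """With equal class sizes, a negative global minimum and a positive
        global maximum, some interior midpoint strictly beats both sentinel
        thresholds, so the estimate lies inside the score range."""
        found = 0
        while found < 10:
            n = int(rng.integers(3, 12))
            pos = rng.uniform(0.5, 5.0, size=n)
            neg = rng.uniform(0.5, 5.0, size=n)
            if not (neg.min() < pos.min() and neg.max() < pos.max()):
                continue
            found += 1
            scores = pos.tolist() + neg.tolist()
            labels = ["focal"] * n + ["non_focal"] * n
            r = optimal_cutoff(scores, labels, replicates=10, seed=0)
            assert min(scores) < r.cutoff < max(scores)

    def test_bootstrap_ci_brackets_point_estimate_usually(self):
        rng = np.random.default_rng(7)
        scores = np.concatenate([rng.normal(2, 0.3, 25), rng.normal(1, 0.3, 25)])
        labels = ["focal"] * 25 + ["non_focal"] * 25
        r = optimal_cutoff(scores.tolist(), labels, replicates=500, seed=9)
        assert r.cutoff_ci[0] <= r.cutoff_ci[1]
        assert 1.0 < r.cutoff < 2.0


class TestCompareAuc:
    def test_cohort_against_itself_is_null(self, rng):
        scores, labels = random_instance(rng, allow_ties=False)
        r = compare_auc_unpaired(scores, labels, scores, labels,
                                 replicates=2000, seed=11)
        assert r.difference == 0.0
        assert r.p_value > 0.9

    def test_separated_vs_coinflip_is_significant(self, rng):
        s1 = np.concatenate([rng.uniform(2, 3, 20), rng.uniform(0, 1, 20)])
        l1 = ["focal"] * 20 + ["non_focal"] * 20
        s2 = rng.uniform(0, 1, 40)
        r = compare_auc_unpaired(s1.tolist(), l1, s2.tolist(), l1,
                                 replicates=2000, seed=13)
        assert r.p_value < 0.01
        assert r.difference > 0.3

    def test_swapping_cohorts_negates_difference(self, rng):
        s1, l1 = random_instance(rng, allow_ties=False)
        s2, l2 = random_instance(rng, allow_ties=False)
        a = compare_auc_unpaired(s1, l1, s2, l2, replicates=1000, seed=17)
        b = compare_auc_unpaired(s2, l2, s1, l1, replicates=1000, seed=17)
        assert a.difference == pytest.approx(-b.difference, abs=1e-12)

    def test_degenerate_variance_flagged(self):
        r = compare_auc_unpaired([2, 1], ["focal", "non_focal"],
                                 [1, 2], ["focal", "non_focal"],
                                 replicates=100, seed=19)
        assert r.degenerate_variance
        assert r.p_value == pytest.approx(1 / 100)

    def test_one_sided_halves_null_mass(self, rng):
        s1 = np.concatenate([rng.normal(2, 0.5, 15), rng.normal(1, 0.5, 15)])
        l1 = ["focal"] * 15 + ["non_focal"] * 15
        s2 = np.concatenate([rng.normal(1.4, 0.5, 15), rng.normal(1, 0.5, 15)])
        two = compare_auc_unpaired(s1.tolist(), l1, s2.tolist(), l1,
                                   replicates=1000, seed=23)
        one = compare_auc_unpaired(s1.tolist(), l1, s2.tolist(), l1,
                                   replicates=1000, seed=23, alternative="greater")
        assert one.p_value == pytest.approx(two.p_value / 2)
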