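"""ROC construction, tie-corrected AUC and the DeLong machinery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import roc_auc_score

from ugib_triage import (
    GroupedScoreCounts,
    auc_tied,
    delong_paired_test,
    delong_se,
    roc_points,
)

# grouped tables with both classes present and at most ~10^4 pairs
grouped_counts = (
    st.lists(st.tuples(st.integers(0, 12), st.integers(0, 12)), min_size=1, max_size=10)
    .map(lambda rows: [(s, p, n) for s, (p, n) in enumerate(rows)])
    .map(GroupedScoreCounts)
    .filter(lambda c: c.n_pos >= 1 and c.n_neg >= 1)
)


def brute_force_auc(counts: GroupedScoreCounts) -> float:
    """Independent oracle: explicit loop over all positive-negative pairs."""
    scores, labels = counts.expand()
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for x in pos:
        for y in neg:
            total += 1.0 if x > y else (0.5 if x == y else 0.0)
    return total / (pos.size * neg.size)


class TestGroupedScoreCounts:
    def test_rejects_unsorted_scores_and_negative_counts(self):
        with pytest.raises(ValueError, match="increasing"):
            GroupedScoreCounts([(2, 1, 1), (1, 1, 1)])
        with pytest.raises(ValueError, match="non-negative"):
            GroupedScoreCounts([(0, -1, 1)])

    def test_expand_group_round_trip(self):
        counts = GroupedScoreCounts([(0, 2, 3), (4, 1, 0)])
        assert GroupedScoreCounts.from_labelled(*counts.expand()) == counts

    def test_csv_round_trip(self, tmp_path):
        counts = GroupedScoreCounts([(0, 2, 3), (4, 1, 0)])
        path = tmp_path / "counts.csv"
        counts.to_csv(path)
        assert GroupedScoreCounts.from_csv(path) == counts


class TestRocPoints:
    def test_perfect_separation(self):
        curve = roc_points(GroupedScoreCounts([(0, 0, 5), (1, 5, 0)]))
        assert curve.points == ((0.0, 0.0), (0.0, 1.0), (1.0, 1.0))

    def test_single_tied_score_is_the_diagonal(self):
        curve = roc_points(GroupedScoreCounts([(0, 5, 5)]))
        assert curve.points == ((0.0, 0.0), (1.0, 1.0))

    def test_degenerate_classes_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            roc_points(GroupedScoreCounts([(0, 5, 0)]))

    @given(grouped_counts)
    def test_curve_monotone_within_unit_square(self, counts):
        pts = roc_points(counts).points
        assert pts[0] == (0.0, 0.0) and pts[-1] == (1.0, 1.0)
        for (f0, t0), (f1, t1) in zip(pts, pts[1:]):
            assert f1 >= f0 and t1 >= t0
            assert 0.0 <= f1 <= 1.0 and 0.0 <= t1 <= 1.0


class TestAucTied:
    def test_all_tied_is_half(self):
        assert auc_tied(GroupedScoreCounts([(3, 7, 9)])) == 0.5

    @given(grouped_counts)
    def test_equals_brute_force_pair_counting(self, counts):
        assert auc_tied(counts) == pytest.approx(brute_force_auc(counts), abs=1e-12)

    @given(grouped_counts)
    def test_equals_trapezoid_area_under_roc(self, counts):
        assert auc_tied(counts) == pytest.approx(
            roc_points(counts).trapezoidal_area(), abs=1e-12
        )

    @given(grouped_counts)
    def test_label_swap_symmetry(self, counts):
        swapped = GroupedScoreCounts([(s, n, p) for s, p, n in counts.rows])
        assert auc_tied(swapped) == pytest.approx(1.0 - auc_tied(counts), abs=1e-12)

    @given(grouped_counts)
    def test_invariant_under_monotone_score_transform(self, counts):
        transformed = GroupedScoreCounts([(2 * s**2 + 3, p, n) for s, p, n in counts.rows])
        assert auc_tied(transformed) == auc_tied(counts)

    @given(grouped_counts)
    def test_matches_sklearn_on_expanded_data(self, counts):
        scores, labels = counts.expand()
        assert auc_tied(counts) == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)


class TestDelongSe:
    def test_single_pair_perfect_auc_zero_se(self):
        est = delong_se([1, 2], [0, 1])
        assert est.auc == 1.0
        assert est.se == 0.0
        assert est.ci95 == (1.0, 1.0)

    def test_grouped_and_ungrouped_auc_agree(self):
        from ugib_triage.fixtures import load_table4

        counts = load_table4("pre_e_rs")
        scores, labels = counts.expand()
        assert delong_se(scores, labels).auc == pytest.approx(auc_tied(counts), abs=1e-12)

    def test_se_close_to_bootstrap_oracle(self):
        """DeLong se within 15% of a 10,000-replicate patient bootstrap."""
        rng = np.random.default_rng(42)
        n = 20
        labels = np.array([0, 1] * (n // 2))
        scores = labels * 1.0 + rng.normal(0, 1.2, n)
        est = delong_se(scores, labels)
        boots = []
        for _ in range(10_000):
            idx = rng.integers(0, n, n)
            if labels[idx].min() == labels[idx].max():
                continue
            boots.append(roc_auc_score(labels[idx], scores[idx]))
        boot_se = float(np.std(boots, ddof=1))
        assert est.se == pytest.approx(boot_se, rel=0.15)

    def test_ci_contains_point_estimate_within_unit_interval(self):
        rng = np.random.default_rng(3)
        labels = rng.integers(0, 2, 60)
        labels[:2] = [0, 1]
        scores = rng.normal(size=60) + labels
        est = delong_se(scores, labels)
        assert 0.0 <= est.ci95[0] <= est.auc <= est.ci95[1] <= 1.0


def brute_force_delong(scores_a, scores_b, labels):
    """Enumeration oracle: placement values and covariances by direct loops."""
    scores_a, scores_b = np.asarray(scores_a, float), np.asarray(scores_b, float)
    labels = np.asarray(labels)
    out = []
    for scores in (scores_a, scores_b):
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        v10 = np.array([np.mean([1.0 if x > y else 0.5 if x == y else 0.0 for y in neg]) for x in pos])
        v01 = np.array([np.mean([1.0 if x > y else 0.5 if x == y else 0.0 for x in pos]) for y in neg])
        out.append((v10, v01))
    (a10, a01), (b10, b01) = out
    m, n = a10.size, a01.size
    var = (
        np.var(a10, ddof=1) / m + np.var(a01, ddof=1) / n
        + np.var(b10, ddof=1) / m + np.var(b01, ddof=1) / n
        - 2 * (np.cov(a10, b10, ddof=1)[0, 1] / m + np.cov(a01, b01, ddof=1)[0, 1] / n)
    )
    return (a10.mean() - b10.mean()) / np.sqrt(var)


class TestDelongPairedTest:
    def test_identical_scores_give_z_zero_p_one(self):
        labels = [0, 1, 0, 1, 1]
        scores = [1.0, 3.0, 2.0, 5.0, 4.0]
        res = delong_paired_test(scores, scores, labels)
        assert res.z == 0.0 and res.p == 1.0

    def test_matches_enumeration_oracle_on_hand_case(self):
        labels = [1, 1, 1, 1, 0, 0, 0, 0]
        scores_a = [8.0, 7.0, 6.0, 3.0, 5.0, 4.0, 2.0, 1.0]
        scores_b = [8.0, 2.0, 4.0, 3.0, 7.0, 6.0, 5.0, 1.0]
        res = delong_paired_test(scores_a, scores_b, labels)
        assert res.z == pytest.approx(brute_force_delong(scores_a, scores_b, labels), abs=1e-10)

    def test_antisymmetric_in_the_two_scores(self):
        rng = np.random.default_rng(5)
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        a = rng.normal(size=40) + labels
        b = rng.normal(size=40)
        fwd = delong_paired_test(a, b, labels)
        rev = delong_paired_test(b, a, labels)
        assert fwd.z == pytest.approx(-rev.z, abs=1e-12)
        assert fwd.p == pytest.approx(rev.p, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="aligned|equal length"):
            delong_paired_test([1, 2, 3], [1, 2], [0, 1, 1])

    @settings(max_examples=25)
    @given(st.integers(0, 2**32 - 1))
    def test_informative_score_beats_noise(self, seed):
        """An informative score's AUC estimate exceeds pure noise at n=200."""
        rng = np.random.default_rng(seed)
        z = rng.normal(size=200)
        labels = (rng.random(200) < 1 / (1 + np.exp(-1.5 * z))).astype(int)
        if labels.min() == labels.max():
            return
        res = delong_paired_test(z + rng.normal(0, 0.5, 200), rng.normal(size=200), labels)
        assert res.auc_a > 0.5
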