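"""Threshold metrics, 2x2 reconstruction, odds ratios, chi-square, search."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import chi2_contingency

from ugib_triage import (
    ConfusionTable,
    GroupedScoreCounts,
    derive_survivor_split,
    metrics_at_cutoff,
    odds_ratio_woolf,
    pearson_chi2,
    reconstruct_confusion,
    threshold_table,
    youden_optimal,
)
from ugib_triage.diagnostics import ThresholdMetrics
from ugib_triage.fixtures import load_table4

GBS_TIMING = (12, 62, 9, 314)
MGBS_TIMING = (12, 62, 9, 289)


class TestMetricsAtCutoff:
    def test_cutoff_below_minimum_score(self):
        counts = GroupedScoreCounts([(2, 3, 4), (5, 1, 2)])
        m = metrics_at_cutoff(counts, 0)
        assert m.sens == 100.0 and m.spec == 0.0

    def test_direct_count_on_study_table(self):
        # strictly-greater rule: positives above 4 are 22+1+12, negatives 0+0+1
        counts = load_table4("pre_e_rs")
        m = metrics_at_cutoff(counts, 4)
        assert m.sens == pytest.approx(100 * 35 / 280)
        assert m.spec == pytest.approx(100 * 309 / 310)

    def test_undefined_metric_is_missing_not_zero(self):
        counts = GroupedScoreCounts([(2, 3, 4)])
        m = metrics_at_cutoff(counts, 5)  # nothing called positive
        assert m.ppv is None
        assert m.sens == 0.0 and m.npv is not None

    @given(
        st.lists(st.tuples(st.integers(0, 9), st.integers(0, 9)), min_size=1, max_size=8)
        .map(lambda rows: GroupedScoreCounts([(s, p, n) for s, (p, n) in enumerate(rows)]))
        .filter(lambda c: c.n_pos >= 1 and c.n_neg >= 1)
    )
    def test_sens_nonincreasing_spec_nondecreasing_in_cutoff(self, counts):
        rows = threshold_table(counts, range(-1, 10))
        for lo, hi in zip(rows, rows[1:]):
            assert hi.sens <= lo.sens
            assert hi.spec >= lo.spec

    def test_empty_cutoff_list_gives_empty_table(self):
        assert threshold_table(GroupedScoreCounts([(0, 1, 1)]), []) == []


class TestYoudenOptimal:
    def test_single_row_returns_its_cutoff(self):
        assert youden_optimal([ThresholdMetrics(3, 50.0, 60.0, None, None)]) == 3

    def test_tie_broken_toward_smaller_cutoff(self):
        rows = [
            ThresholdMetrics(2, 80.0, 40.0, None, None),
            ThresholdMetrics(3, 60.0, 60.0, None, None),
        ]
        assert youden_optimal(rows) == 2

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            youden_optimal([])


class TestReconstructConfusion:
    @pytest.mark.parametrize(
        "sens, spec, n_pos, n_neg, expected",
        [
            (0.88, 0.9752, 25, 565, (22, 14, 3, 551)),
            (1.0, 1.0, 10, 20, (10, 0, 0, 20)),
            (0.7357, 0.8290, 280, 310, (206, 53, 74, 257)),
        ],
    )
    def test_nearest_integer_inversion(self, sens, spec, n_pos, n_neg, expected):
        t = reconstruct_confusion(sens, spec, n_pos, n_neg)
        assert (t.tp, t.fp, t.fn, t.tn) == expected

    def test_round_trip_reproduces_printed_precision(self):
        t = reconstruct_confusion(0.7357, 0.8290, 280, 310)
        assert round(100 * t.tp / (t.tp + t.fn), 2) == 73.57
        assert round(100 * t.tn / (t.tn + t.fp), 2) == 82.90

    def test_out_of_range_inputs_rejected(self):
        with pytest.raises(ValueError):
            reconstruct_confusion(1.2, 0.5, 10, 10)

    @given(
        st.floats(0.0, 1.0),
        st.floats(0.0, 1.0),
        st.integers(1, 500),
        st.integers(1, 500),
    )
    def test_bayes_consistency_of_reconstructed_ppv(self, sens, spec, n_pos, n_neg):
        """PPV from the table equals the Bayes formula at the realized sens/spec."""
        t = reconstruct_confusion(sens, spec, n_pos, n_neg)
        if t.tp + t.fp == 0:
            return
        ppv = t.tp / (t.tp + t.fp)
        pi = n_pos / (n_pos + n_neg)
        real_sens = t.tp / n_pos
        real_fpr = t.fp / n_neg
        denom = real_sens * pi + real_fpr * (1 - pi)
        assert ppv == pytest.approx(real_sens * pi / denom, abs=1e-12)


class TestOddsRatioWoolf:
    def test_published_gbs_timing_values(self):
        res = odds_ratio_woolf(GBS_TIMING)
        assert round(res.odds_ratio, 3) == 6.753
        assert round(res.ci95[0], 3) == 2.729
        assert round(res.ci95[1], 3) == 16.712
        assert round(res.chi2, 3) == 21.675
        assert res.p < 0.001

    def test_published_mgbs_timing_values(self):
        res = odds_ratio_woolf(MGBS_TIMING)
        assert round(res.odds_ratio, 3) == 6.215
        assert round(res.ci95[0], 3) == 2.510
        assert round(res.ci95[1], 3) == 15.390
        assert round(res.chi2, 3) == 19.380

    def test_unit_table_symmetric_about_one_on_log_scale(self):
        res = odds_ratio_woolf((1, 1, 1, 1))
        assert res.odds_ratio == 1.0
        assert np.log(res.ci95[0]) == pytest.approx(-np.log(res.ci95[1]), abs=1e-12)

    def test_row_swap_reciprocity(self):
        fwd = odds_ratio_woolf(GBS_TIMING)
        rev = odds_ratio_woolf((9, 314, 12, 62))
        assert rev.odds_ratio == pytest.approx(1 / fwd.odds_ratio, abs=1e-12)

    @given(st.tuples(*[st.integers(1, 200)] * 4))
    def test_log_ci_width_invariant_under_transposition(self, cells):
        a, b, c, d = cells
        w = lambda r: np.log(r.ci95[1]) - np.log(r.ci95[0])
        assert w(odds_ratio_woolf((a, b, c, d))) == pytest.approx(
            w(odds_ratio_woolf((a, c, b, d))), abs=1e-9
        )

    def test_zero_cell_rejected_with_guidance(self):
        with pytest.raises(ValueError, match="continuity"):
            odds_ratio_woolf((0, 5, 3, 7))

    def test_matches_hand_woolf_formula(self):
        a, b, c, d = 7, 13, 5, 31
        res = odds_ratio_woolf((a, b, c, d))
        se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        lo = np.exp(np.log(a * d / (b * c)) - 1.959963984540054 * se)
        assert res.ci95[0] == pytest.approx(lo, rel=1e-6)


class TestPearsonChi2:
    @pytest.mark.parametrize(
        "table, expected", [(GBS_TIMING, 21.675), (MGBS_TIMING, 19.380)]
    )
    def test_uncorrected_statistic_reproduces_published(self, table, expected):
        chi2, p = pearson_chi2(table)
        assert round(chi2, 3) == expected
        assert p < 0.001

    def test_proportional_rows_give_zero(self):
        chi2, p = pearson_chi2((10, 20, 5, 10))
        assert chi2 == 0.0 and p == 1.0

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            pearson_chi2((0, 0, 3, 4))

    @given(st.tuples(*[st.integers(0, 100)] * 4))
    def test_matches_scipy_without_correction(self, cells):
        a, b, c, d = cells
        if min(a + b, c + d, a + c, b + d) == 0:
            return
        chi2, p = pearson_chi2(cells)
        ref = chi2_contingency([[a, b], [c, d]], correction=False)
        assert chi2 == pytest.approx(ref.statistic, abs=1e-9)
        assert p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_yates_correction_would_not_reproduce_published(self):
        """The published 21.675 pins the uncorrected statistic."""
        ref = chi2_contingency(np.array(GBS_TIMING).reshape(2, 2), correction=True)
        assert round(ref.statistic, 3) != 21.675


class TestDeriveSurvivorSplit:
    def test_recovers_gbs_survivors_from_odds_ratio(self):
        assert derive_survivor_split(397, 12, 9, target_or=6.753) == (62, 314)

    def test_recovers_mgbs_survivors_from_chi2(self):
        assert derive_survivor_split(372, 12, 9, target_chi2=19.380) == (62, 289)

    def test_deaths_exceeding_total_rejected(self):
        with pytest.raises(ValueError, match="total"):
            derive_survivor_split(10, 6, 5, target_or=2.0)

    def test_unmatchable_target_rejected(self):
        with pytest.raises(ValueError, match="no integer"):
            derive_survivor_split(30, 2, 2, target_or=1e6)

    def test_ambiguous_target_rejected(self):
        # a coarse 1-d.p. target matches many splits and must fail loudly
        with pytest.raises(ValueError, match="ambiguous"):
            derive_survivor_split(397, 12, 9, target_or=6.8, decimals=0)

    def test_requires_exactly_one_target(self):
        with pytest.raises(ValueError, match="exactly one"):
            derive_survivor_split(397, 12, 9)


def test_confusion_table_rejects_negative_cells():
    with pytest.raises(ValueError):
        ConfusionTable(tp=-1, fp=0, fn=0, tn=1)
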