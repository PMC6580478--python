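"""Study statistics: chi-squared arm comparison, two-proportion sample
size, and Pugh-chart scoring."""

from __future__ import annotations

import numpy as np
import pytest
import scipy.stats

from earident.study_stats import (
    ContingencyTable2x2,
    LIGHTING_PUGH_CHART,
    PowerDesign,
    PughChart,
    UndefinedTestError,
    chi2_uncorrected,
    counts_from_rate,
    parse_pugh_csv,
    pugh_score,
    two_proportion_sample_size,
)


class TestChi2:
    def test_identical_proportions_give_zero(self):
        stat, p = chi2_uncorrected(ContingencyTable2x2(10, 10, 10, 10))
        assert stat == 0.0
        assert p == 1.0

    def test_perfect_separation_closed_form(self):
        # N (ad - bc)^2 / (r1 r2 c1 c2) = 40 * (400)^2 / 20^4 = 40
        stat, _ = chi2_uncorrected(ContingencyTable2x2(20, 0, 0, 20))
        assert stat == pytest.approx(40.0)

    def test_study_arm_comparison_significant(self):
        """Top-1 accuracies 95.9% vs 24.1% of 194 paired images."""
        a, b = counts_from_rate(95.9, 194)
        c, d = counts_from_rate(24.1, 194)
        assert (a, b, c, d) == (186, 8, 47, 147)
        _, p = chi2_uncorrected(ContingencyTable2x2(a, b, c, d))
        assert p < 0.0001

    def test_zero_margin_undefined(self):
        with pytest.raises(UndefinedTestError):
            chi2_uncorrected(ContingencyTable2x2(5, 5, 0, 0))

    def test_matches_library_implementation(self):
        rng = np.random.default_rng(42)
        checked = 0
        while checked < 100:
            a, b, c, d = rng.integers(0, 200, size=4)
            table = np.array([[a, b], [c, d]])
            if table.sum() == 0 or 0 in table.sum(0) or 0 in table.sum(1):
                continue
            stat, p = chi2_uncorrected(ContingencyTable2x2(int(a), int(b),
                                                           int(c), int(d)))
            ref_stat, ref_p, _, _ = scipy.stats.chi2_contingency(
                table, correction=False)
            assert stat == pytest.approx(ref_stat, abs=1e-8)
            assert p == pytest.approx(ref_p, abs=1e-8)
            checked += 1


class TestSampleSize:
    def test_study_planning_value(self):
        n = two_proportion_sample_size(PowerDesign(0.80, 0.90, 0.05, 0.80))
        assert n == 199

    def test_symmetric_in_proportions(self):
        a = two_proportion_sample_size(PowerDesign(0.80, 0.90))
        b = two_proportion_sample_size(PowerDesign(0.90, 0.80))
        assert a == b

    def test_doubling_effect_quarters_n(self):
        # same mean proportion 0.85, doubled difference
        n1 = two_proportion_sample_size(PowerDesign(0.80, 0.90))
        n2 = two_proportion_sample_size(PowerDesign(0.75, 0.95))
        assert 3.5 < n1 / n2 < 4.6

    def test_monotone_in_effect_and_alpha(self):
        diffs = [0.05, 0.10, 0.15]
        sizes = [two_proportion_sample_size(PowerDesign(0.80, 0.80 + d))
                 for d in diffs]
        assert sizes == sorted(sizes, reverse=True)
        alphas = [0.01, 0.05, 0.10]
        sizes_a = [two_proportion_sample_size(PowerDesign(0.80, 0.90, alpha=a))
                   for a in alphas]
        assert sizes_a == sorted(sizes_a, reverse=True)

    def test_invalid_designs_rejected(self):
        with pytest.raises(ValueError):
            PowerDesign(0.8, 0.8)
        with pytest.raises(ValueError):
            PowerDesign(0.0, 0.9)


class TestPugh:
    def test_lighting_chart_totals(self):
        totals = pugh_score(LIGHTING_PUGH_CHART)
        assert totals == {"Diffused LED plate": 0,
                          "Electroluminescent Ribbons": 0,
                          "LED Strip": 3}
        assert max(totals, key=totals.get) == "LED Strip"

    def test_all_zero_marks(self):
        chart = PughChart(criteria=(("a", 1), ("b", 2)), concepts=("x", "y"),
                          marks=((0, 0), (0, 0)))
        assert pugh_score(chart) == {"x": 0, "y": 0}

    def test_negation_linearity(self):
        negated = PughChart(
            criteria=LIGHTING_PUGH_CHART.criteria,
            concepts=LIGHTING_PUGH_CHART.concepts,
            marks=tuple(tuple(-m for m in row)
                        for row in LIGHTING_PUGH_CHART.marks),
        )
        base = pugh_score(LIGHTING_PUGH_CHART)
        assert pugh_score(negated) == {k: -v for k, v in base.items()}

    def test_invariant_to_criterion_order(self):
        reordered = PughChart(
            criteria=LIGHTING_PUGH_CHART.criteria[::-1],
            concepts=LIGHTING_PUGH_CHART.concepts,
            marks=LIGHTING_PUGH_CHART.marks[::-1],
        )
        assert pugh_score(reordered) == pugh_score(LIGHTING_PUGH_CHART)

    def test_csv_parsing(self):
        text = (
            "criterion,weight,Base,Alt\n"
            "Shadow,2,0,+\n"
            "Price,1,0,-\n"
        )
        chart = parse_pugh_csv(text)
        assert pugh_score(chart) == {"Base": 0, "Alt": 1}

    def test_invalid_marks_rejected(self):
        with pytest.raises(ValueError):
            PughChart(criteria=(("a", 1),), concepts=("x",), marks=((2,),))
        with pytest.raises(ValueError):
            parse_pugh_csv("criterion,weight,A\nShadow,1,?\n")
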