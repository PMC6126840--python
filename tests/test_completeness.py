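"""Completeness scoring, interval schedule, and the equality-of-proportions test."""

import math

import numpy as np
import pytest
import statsmodels.stats.proportion as smp
from scipy.stats import chi2_contingency

from conftest import to_observation_rows

from partoaudit.completeness import (
    BP,
    DEFAULT_SCHEDULE,
    cohort_completeness,
    component_complete,
    round_half_up,
    two_proportion_test,
)
from partoaudit.partograph import build_partograph
from partoaudit.rules import classify
from partoaudit.simulate import SimulationParams, simulate_cohort


def chart(*rows):
    return build_partograph(to_observation_rows(rows), case_id="X")


class TestComponentComplete:
    def test_two_plottings_within_interval(self):
        assert component_complete(chart(("fhr", 0, 140.0), ("fhr", 30, 142.0)), "fhr")

    def test_gap_beyond_interval_fails_default_rule(self):
        assert not component_complete(chart(("fhr", 0, 140.0), ("fhr", 90, 142.0)), "fhr")

    def test_single_plotting_is_never_complete(self):
        assert not component_complete(chart(("dilatation", 0, 5.0)), "dilatation")

    def test_lenient_needs_one_good_pair_strict_needs_all(self):
        c = chart(("fhr", 0, 140.0), ("fhr", 30, 141.0), ("fhr", 120, 142.0))
        assert component_complete(c, "fhr", strict=False)
        assert not component_complete(c, "fhr", strict=True)

    def test_bp_requires_paired_systolic_and_diastolic(self):
        paired = chart(("sbp", 0, 115.0), ("dbp", 0, 75.0), ("sbp", 240, 110.0), ("dbp", 240, 70.0))
        unpaired = chart(("sbp", 0, 115.0), ("dbp", 240, 75.0))
        assert component_complete(paired, BP)
        assert not component_complete(unpaired, BP)

    def test_unknown_component_is_an_error(self):
        with pytest.raises(KeyError):
            component_complete(chart(), "heart_rate")

    def test_deletion_never_makes_an_incomplete_component_complete(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            times = sorted(rng.choice(range(0, 601, 30), size=5, replace=False))
            rows = [("fhr", int(t), 140.0) for t in times]
            full = component_complete(chart(*rows), "fhr")
            k = int(rng.integers(0, len(rows)))
            sub = component_complete(chart(*(rows[:k] + rows[k + 1 :])), "fhr")
            assert not (sub and not full)


class TestSchedule:
    def test_default_intervals_follow_who_monitoring_guidance(self):
        assert DEFAULT_SCHEDULE["fhr"] == DEFAULT_SCHEDULE["pulse"] == 30
        assert DEFAULT_SCHEDULE["temperature"] == DEFAULT_SCHEDULE["urine_volume"] == 120
        assert DEFAULT_SCHEDULE["dilatation"] == DEFAULT_SCHEDULE[BP] == 240
        assert all(i > 0 and i % 30 == 0 for i in DEFAULT_SCHEDULE.values())


class TestTwoProportionTest:
    def test_published_fhr_group_comparison(self):
        # 71.8% of 71 abnormal charts vs 59.6% of 577 normal charts
        result = two_proportion_test(round(0.718 * 71), 71, round(0.596 * 577), 577)
        assert 0.040 <= result.p_value <= 0.052
        assert result.significant

    def test_identical_proportions_give_z_zero(self):
        result = two_proportion_test(10, 20, 10, 20)
        assert result.z == 0.0 and result.p_value == 1.0

    def test_all_zero_groups_are_degenerate(self):
        result = two_proportion_test(0, 71, 0, 577)
        assert result.degenerate and result.p_value is None and not result.significant

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            two_proportion_test(5, 3, 1, 10)
        with pytest.raises(ValueError):
            two_proportion_test(0, 0, 1, 10)

    def test_z_squared_equals_chi_square_and_statsmodels_agrees(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            n1, n2 = int(rng.integers(2, 200)), int(rng.integers(2, 200))
            x1, x2 = int(rng.integers(0, n1 + 1)), int(rng.integers(0, n2 + 1))
            r = two_proportion_test(x1, n1, x2, n2)
            if r.degenerate:
                continue
            chi2, _, _, _ = chi2_contingency(
                [[x1, n1 - x1], [x2, n2 - x2]], correction=False
            )
            assert math.isclose(r.z**2, chi2, abs_tol=1e-9)
            z_sm, p_sm = smp.proportions_ztest([x1, x2], [n1, n2])
            assert math.isclose(r.z, z_sm, abs_tol=1e-12)
            assert math.isclose(r.p_value, p_sm, abs_tol=1e-12)
            swapped = two_proportion_test(x2, n2, x1, n1)
            assert math.isclose(swapped.z, -r.z, abs_tol=1e-12)
            assert math.isclose(swapped.p_value, r.p_value, abs_tol=1e-12)


def test_rounding_matches_hand_tabulation():
    assert round_half_up(71.85) == 71.9
    assert round_half_up(3.14) == 3.1
    assert round_half_up(97.5, 0) == 98.0


class TestCohortCompleteness:
    def _cohort(self, n_complete, n_incomplete):
        charts, results = [], {}
        for i in range(n_complete + n_incomplete):
            cid = f"c{i}"
            rows = [("fhr", 0, 140.0)] + ([("fhr", 30, 141.0)] if i < n_complete else [])
            p = build_partograph(to_observation_rows(rows, case_id=cid), case_id=cid)
            charts.append(p)
            results[cid] = classify(p)
        return charts, results

    def test_all_complete_cohort_scores_100(self):
        charts, results = self._cohort(4, 0)
        table = cohort_completeness(charts, results).set_index("component")
        assert table.loc["fhr", "pct_overall"] == 100.0

    def test_half_complete_cohort_scores_50(self):
        charts, results = self._cohort(1, 1)
        table = cohort_completeness(charts, results).set_index("component")
        assert table.loc["fhr", "pct_overall"] == 50.0

    def test_group_sizes_partition_cohort(self):
        params = SimulationParams(n_cases=120, seed=2, charting_probability={})
        cases, obs, _, _ = simulate_cohort(params)
        by_case: dict[str, list] = {}
        for o in obs:
            by_case.setdefault(o.case_id, []).append(o)
        charts = [build_partograph(v) for v in by_case.values()]
        results = {p.case_id: classify(p) for p in charts}
        table = cohort_completeness(charts, results)
        assert (table["n_abnormal"] + table["n_no_indication"] == table["n_total"]).all()

    def test_completeness_decreases_with_charting_dropout(self):
        # coupled thinning: lower per-interval probability keeps a subset
        for seed in (0, 1, 2):
            pcts = []
            for q in (1.0, 0.9, 0.5, 0.2):
                params = SimulationParams(
                    n_cases=60,
                    seed=seed,
                    admission_dilatation_distribution={4: 1.0},
                    normal_dilatation_rate_sd=0.0,
                    charting_probability={"fhr": q},
                )
                cases, obs, _, _ = simulate_cohort(params)
                by_case: dict[str, list] = {}
                for o in obs:
                    by_case.setdefault(o.case_id, []).append(o)
                charts = [build_partograph(v) for v in by_case.values()]
                results = {p.case_id: classify(p) for p in charts}
                table = cohort_completeness(charts, results).set_index("component")
                pcts.append(table.loc["fhr", "pct_overall"])
            assert pcts == sorted(pcts, reverse=True) or len(set(pcts)) == 1
            assert pcts[0] == 100.0
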