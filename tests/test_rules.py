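"""Rule-engine behaviour against the referral-indication definitions."""

import numpy as np

from conftest import random_chart_rows, to_observation_rows
from oracle import oracle_classify

from partoaudit.partograph import build_partograph
from partoaudit.rules import (
    RuleConfig,
    classify,
    detect_foetal_distress,
    detect_obstructed_labour,
    detect_preeclampsia,
    detect_prolonged_labour,
)


def chart(*rows):
    return build_partograph(to_observation_rows(rows), case_id="X")


class TestFoetalDistress:
    def test_two_low_readings_trigger(self):
        flag, ev = detect_foetal_distress(chart(("fhr", 0, 118.0), ("fhr", 30, 115.0)))
        assert flag and len(ev) == 2

    def test_single_violation_is_not_enough(self):
        flag, _ = detect_foetal_distress(
            chart(("fhr", 0, 118.0), ("fhr", 30, 140.0), ("fhr", 60, 150.0))
        )
        assert not flag

    def test_meconium_alone_triggers(self):
        flag, ev = detect_foetal_distress(
            chart(("fhr", 0, 140.0), ("liquor", 0, "C"), ("liquor", 240, "M"))
        )
        assert flag and ev[0].component == "liquor"

    def test_boundary_values_are_normal(self):
        # thresholds are strict: exactly 120 and 160 do not violate
        flag, _ = detect_foetal_distress(chart(("fhr", 0, 120.0), ("fhr", 30, 160.0)))
        assert not flag

    def test_mixed_direction_violations_count_together(self):
        flag, _ = detect_foetal_distress(chart(("fhr", 0, 115.0), ("fhr", 30, 170.0)))
        assert flag

    def test_consecutive_mode_requires_adjacent_violations(self):
        cfg = RuleConfig(fhr_require_consecutive=True)
        split = chart(("fhr", 0, 110.0), ("fhr", 30, 140.0), ("fhr", 60, 110.0))
        adjacent = chart(("fhr", 0, 110.0), ("fhr", 30, 110.0), ("fhr", 60, 140.0))
        assert not detect_foetal_distress(split, cfg)[0]
        assert detect_foetal_distress(adjacent, cfg)[0]
        assert detect_foetal_distress(split)[0]  # default: any two


class TestProlongedLabour:
    def test_plot_right_of_alert_line(self):
        flag, ev = detect_prolonged_labour(
            chart(("dilatation", 0, 4.0), ("dilatation", 300, 6.0))
        )
        assert flag and ev[0].t_min == 300

    def test_progress_on_the_line_is_normal(self):
        flag, _ = detect_prolonged_labour(
            chart(("dilatation", 0, 4.0), ("dilatation", 120, 6.0), ("dilatation", 360, 10.0))
        )
        assert not flag

    def test_no_active_phase_anchor_means_no_flag(self):
        flag, _ = detect_prolonged_labour(chart(("dilatation", 0, 3.0)))
        assert not flag


class TestObstructedLabour:
    def test_severe_contractions_with_severe_moulding(self):
        flag, _ = detect_obstructed_labour(
            chart(("contraction_duration", 0, "gt40s"), ("moulding", 0, "+++"))
        )
        assert flag

    def test_moulding_without_moderate_contraction_is_not_obstruction(self):
        flag, _ = detect_obstructed_labour(
            chart(("contraction_duration", 0, "lt20s"), ("moulding", 0, "+++"))
        )
        assert not flag

    def test_descent_plateau_with_moderate_contractions(self):
        flag, ev = detect_obstructed_labour(
            chart(
                ("contraction_duration", 0, "s20to40"),
                ("descent", 0, 3.0),
                ("descent", 240, 3.0),
            )
        )
        assert flag and any(e.component == "descent" for e in ev)

    def test_descending_head_is_not_a_plateau(self):
        flag, _ = detect_obstructed_labour(
            chart(
                ("contraction_duration", 0, "s20to40"),
                ("descent", 0, 4.0),
                ("descent", 240, 3.0),
            )
        )
        assert not flag


class TestPreeclampsia:
    def test_systolic_branch_with_albuminuria(self):
        flag, _ = detect_preeclampsia(
            chart(("sbp", 0, 150.0), ("dbp", 0, 85.0), ("urine_albumin", 0, "plus1"))
        )
        assert flag

    def test_boundary_bp_is_normal(self):
        # "more than 140 / more than 90" is strict
        flag, _ = detect_preeclampsia(
            chart(("sbp", 0, 140.0), ("dbp", 0, 90.0), ("urine_albumin", 0, "plus2"))
        )
        assert not flag

    def test_hypertension_without_albuminuria_is_not_preeclampsia(self):
        flag, _ = detect_preeclampsia(
            chart(("sbp", 0, 160.0), ("dbp", 0, 100.0), ("urine_albumin", 0, "neg"))
        )
        assert not flag

    def test_trace_albumin_excluded_by_default_but_configurable(self):
        c = chart(("sbp", 0, 160.0), ("dbp", 0, 100.0), ("urine_albumin", 0, "trace"))
        assert not detect_preeclampsia(c)[0]
        assert detect_preeclampsia(c, RuleConfig(include_trace_albumin=True))[0]


class TestClassify:
    def test_empty_chart_has_no_indication(self):
        result = classify(build_partograph([], case_id="X"))
        assert not result.any_indication and result.evidence == []

    def test_conditions_compose_by_or_with_evidence_for_each(self):
        result = classify(
            chart(
                ("fhr", 0, 110.0),
                ("fhr", 30, 108.0),
                ("dilatation", 0, 4.0),
                ("dilatation", 300, 6.0),
            )
        )
        assert result.foetal_distress and result.prolonged_labour
        assert result.any_indication
        cited = {e.condition for e in result.evidence}
        assert {"foetal_distress", "prolonged_labour"} <= cited

def test_every_true_flag_has_evidence_on_random_charts():
    rng = np.random.default_rng(7)
    for _ in range(300):
        rows = random_chart_rows(rng)
        result = classify(build_partograph(to_observation_rows(rows), case_id="X"))
        for cond, flag in result.flags().items():
            if cond != "any_indication" and flag:
                assert any(e.condition == cond for e in result.evidence)


def test_classifier_matches_brute_force_oracle():
    """1000 random small charts: full agreement with a literal clause-by-clause scan."""
    rng = np.random.default_rng(20130701)
    for i in range(1000):
        rows = random_chart_rows(rng)
        result = classify(build_partograph(to_observation_rows(rows), case_id="X"))
        assert result.flags() == oracle_classify(rows), f"chart {i}: {rows}"


def test_permutation_invariance():
    rng = np.random.default_rng(11)
    for _ in range(100):
        rows = random_chart_rows(rng)
        base = classify(build_partograph(to_observation_rows(rows), case_id="X")).flags()
        perm = list(rows)
        rng.shuffle(perm)
        assert classify(build_partograph(to_observation_rows(perm), case_id="X")).flags() == base


def test_monotonicity_adding_observations_never_clears_flags():
    """No rule has an exculpatory clause: extra evidence cannot clear a flag.

    Dilatation rows are kept fixed because adding an earlier active-phase
    plot re-anchors the alert line, which legitimately changes the
    prolonged-labour geometry in either direction.
    """
    rng = np.random.default_rng(13)
    for _ in range(200):
        rows = random_chart_rows(rng)
        removable = [i for i, r in enumerate(rows) if r[0] != "dilatation"]
        if not removable:
            continue
        full = classify(build_partograph(to_observation_rows(rows), case_id="X")).flags()
        k = removable[int(rng.integers(0, len(removable)))]
        subset = rows[:k] + rows[k + 1 :]
        sub = classify(build_partograph(to_observation_rows(subset), case_id="X")).flags()
        for cond in sub:
            assert not (sub[cond] and not full[cond])
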