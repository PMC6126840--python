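"""Rule-based classification of a partograph for abnormal labour.

Four referral indications are detected from the chart alone, following
the definitions used in national labour-management protocols derived
from WHO guidance:

* **Foetal distress** — foetal heart rate below 120/min or above
  160/min on at least two observations, or any meconium-stained liquor.
* **Prolonged labour** — a cervical-dilatation plot on the right side
  of the alert line, or reaching the action line.
* **Obstructed labour** — moderate or severe uterine contractions
  together with either severe ("+++") moulding of the foetal skull or a
  plateau in descent of the foetal head.
* **Pre-eclampsia** — systolic BP above 140 mmHg or diastolic BP above
  90 mmHg, together with albumin present in urine.

All threshold comparisons are strict, matching the protocol wording
("less than 120", "more than 160", "more than 140/90").  Each detector
returns evidence: the observations that triggered it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from partoaudit.partograph import Partograph, is_right_of_alert, reaches_action
from partoaudit.records_io import Component

MECONIUM_CODE = "M"
SEVERE_MOULDING_CODE = "+++"
ALBUMIN_POSITIVE_CODES = frozenset({"plus1", "plus2", "plus3"})
MODERATE_OR_SEVERE_DURATIONS = frozenset({"s20to40", "gt40s"})


@dataclass(frozen=True)
class RuleConfig:
    """Thresholds and interpretation switches for the four detectors.

    Defaults encode the protocol definitions; the switches expose the
    readings the protocol leaves open (whether the two abnormal FHR
    observations must be consecutive, and whether trace albuminuria
    counts as "presence of albumin" — by clinical convention it does
    not).
    """

    fhr_low: int = 120
    fhr_high: int = 160
    fhr_min_violations: int = 2
    fhr_require_consecutive: bool = False
    sbp_threshold: int = 140
    dbp_threshold: int = 90
    descent_plateau_min_obs: int = 2
    include_trace_albumin: bool = False

    def __post_init__(self):
        if not (0 < self.fhr_low < self.fhr_high):
            raise ValueError("require 0 < fhr_low < fhr_high")
        if min(self.sbp_threshold, self.dbp_threshold) <= 0:
            raise ValueError("BP thresholds must be positive")
        if self.fhr_min_violations < 1 or self.descent_plateau_min_obs < 2:
            raise ValueError("fhr_min_violations >= 1 and descent_plateau_min_obs >= 2")

    @property
    def albumin_positive(self) -> frozenset[str]:
        codes = set(ALBUMIN_POSITIVE_CODES)
        if self.include_trace_albumin:
            codes.add("trace")
        return frozenset(codes)


@dataclass(frozen=True)
class Evidence:
    """One observation cited as triggering a condition."""

    condition: str
    component: str
    t_min: int
    value: object


@dataclass
class AbnormalityResult:
    case_id: str
    foetal_distress: bool
    prolonged_labour: bool
    obstructed_labour: bool
    preeclampsia: bool
    evidence: list[Evidence] = field(default_factory=list)

    @property
    def any_indication(self) -> bool:
        return (
            self.foetal_distress
            or self.prolonged_labour
            or self.obstructed_labour
            or self.preeclampsia
        )

    def flags(self) -> dict[str, bool]:
        return {
            "foetal_distress": self.foetal_distress,
            "prolonged_labour": self.prolonged_labour,
            "obstructed_labour": self.obstructed_labour,
            "preeclampsia": self.preeclampsia,
            "any_indication": self.any_indication,
        }


def detect_foetal_distress(
    p: Partograph, cfg: RuleConfig = RuleConfig()
) -> tuple[bool, list[Evidence]]:
    """FHR out of (fhr_low, fhr_high) on >= 2 observations, or meconium."""
    evidence: list[Evidence] = []
    fhr = p.get(Component.FHR)
    violations = [(t, v) for t, v in fhr if v < cfg.fhr_low or v > cfg.fhr_high]
    if cfg.fhr_require_consecutive:
        hit = False
        run = 0
        run_obs: list[tuple[int, object]] = []
        for t, v in fhr:
            if v < cfg.fhr_low or v > cfg.fhr_high:
                run += 1
                run_obs.append((t, v))
                if run >= cfg.fhr_min_violations:
                    hit = True
                    break
            else:
                run, run_obs = 0, []
        if hit:
            evidence += [Evidence("foetal_distress", "fhr", t, v) for t, v in run_obs]
    elif len(violations) >= cfg.fhr_min_violations:
        evidence += [Evidence("foetal_distress", "fhr", t, v) for t, v in violations]
    meconium = [(t, v) for t, v in p.get(Component.LIQUOR) if v == MECONIUM_CODE]
    evidence += [Evidence("foetal_distress", "liquor", t, v) for t, v in meconium]
    return bool(evidence), evidence


def detect_prolonged_labour(
    p: Partograph, cfg: RuleConfig = RuleConfig()
) -> tuple[bool, list[Evidence]]:
    """Any active-phase dilatation plot right of the alert line or on/past the action line.

    With no active-phase anchor (no dilatation plot >= 4 cm) the line
    geometry is undefined and the result is False.
    """
    if p.anchor is None:
        return False, []
    evidence = [
        Evidence("prolonged_labour", "dilatation", t, v)
        for t, v in p.dilatation_plots_for_line_tests()
        if is_right_of_alert(p.anchor, t, v) or reaches_action(p.anchor, t, v)
    ]
    return bool(evidence), evidence


def detect_obstructed_labour(
    p: Partograph, cfg: RuleConfig = RuleConfig()
) -> tuple[bool, list[Evidence]]:
    """Moderate/severe contractions plus severe moulding or a descent plateau.

    The plateau reading is the minimal one: at least
    ``descent_plateau_min_obs`` consecutive descent observations with
    no decrease in fifths palpable (the head is not descending).
    """
    contractions = [
        (t, v)
        for t, v in p.get(Component.CONTRACTION_DURATION)
        if v in MODERATE_OR_SEVERE_DURATIONS
    ]
    if not contractions:
        return False, []

    severe_moulding = [
        (t, v) for t, v in p.get(Component.MOULDING) if v == SEVERE_MOULDING_CODE
    ]
    plateau: list[tuple[int, object]] = []
    descent = p.get(Component.DESCENT)
    k = cfg.descent_plateau_min_obs
    for i in range(len(descent) - k + 1):
        window = descent[i : i + k]
        vals = [v for _, v in window]
        if all(b >= a for a, b in zip(vals, vals[1:])):
            plateau = window
            break
    if not severe_moulding and not plateau:
        return False, []

    evidence = [
        Evidence("obstructed_labour", "contraction_duration", t, v) for t, v in contractions
    ]
    evidence += [Evidence("obstructed_labour", "moulding", t, v) for t, v in severe_moulding]
    evidence += [Evidence("obstructed_labour", "descent", t, v) for t, v in plateau]
    return True, evidence


def detect_preeclampsia(
    p: Partograph, cfg: RuleConfig = RuleConfig()
) -> tuple[bool, list[Evidence]]:
    """A hypertensive (sbp, dbp) pair plus albuminuria.

    A BP "pair" is any systolic and diastolic reading sharing a
    ``t_min`` (the two are charted together).  A single qualifying pair
    suffices; no repeat reading is required.
    """
    sbp = dict(p.get(Component.SBP))
    dbp = dict(p.get(Component.DBP))
    hypertensive = [
        (t, sbp[t], dbp[t])
        for t in sorted(set(sbp) & set(dbp))
        if sbp[t] > cfg.sbp_threshold or dbp[t] > cfg.dbp_threshold
    ]
    albumin = [
        (t, v) for t, v in p.get(Component.URINE_ALBUMIN) if v in cfg.albumin_positive
    ]
    if not hypertensive or not albumin:
        return False, []
    evidence = []
    for t, s, d in hypertensive:
        evidence.append(Evidence("preeclampsia", "sbp", t, s))
        evidence.append(Evidence("preeclampsia", "dbp", t, d))
    evidence += [Evidence("preeclampsia", "urine_albumin", t, v) for t, v in albumin]
    return True, evidence


def classify(p: Partograph, cfg: RuleConfig = RuleConfig()) -> AbnormalityResult:
    """Run all four detectors; a chart is abnormal if any indication fires.

    Deterministic and independent of input row order (series are
    time-sorted before any rule is applied).
    """
    fd, ev_fd = detect_foetal_distress(p, cfg)
    pl, ev_pl = detect_prolonged_labour(p, cfg)
    ob, ev_ob = detect_obstructed_labour(p, cfg)
    pe, ev_pe = detect_preeclampsia(p, cfg)
    return AbnormalityResult(
        case_id=p.case_id,
        foetal_distress=fd,
        prolonged_labour=pl,
        obstructed_labour=ob,
        preeclampsia=pe,
        evidence=ev_fd + ev_pl + ev_ob + ev_pe,
    )
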