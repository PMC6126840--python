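"""Synthetic labour cohorts for exercising the audit pipeline.

No public deposit of facility birth/referral registers exists, so the
pipeline is tested against simulated cohorts that carry the statistical
structure the audit assumes: per-component labour trajectories on the
partograph's plotting grid, configurable prevalence of the four
abnormal-labour conditions, an independent per-due-interval
charting-dropout model that produces realistic incompleteness, and
referral behaviour (partial compliance plus out-of-scope register
noise).

Ground truth (which condition each case truly has, and whether she was
truly referred) is kept separate from the emitted register files, which
enables parameter-recovery tests: with full charting, the rule engine's
estimated prevalence must recover the configured prevalence.

A deterministic benchmark cohort (:func:`make_reference_fixture`) with
fixed case-flow counts (1548 presented, 1198 admitted, 350 referred
without admission, 663 eligible, 648 charted, 71 abnormal, 5 in-scope
referrals of which 1 flagged) is provided for end-to-end regression
checks of the flow report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from partoaudit.completeness import round_half_up
from partoaudit.records_io import (
    BirthOutcome,
    Component,
    IntrapartumCase,
    MembraneStatus,
    ObservationRow,
    Parity,
    ReasonCode,
    ReferralEntry,
    write_cases,
    write_observations,
    write_referrals,
)

CONDITIONS = ("foetal_distress", "prolonged_labour", "obstructed_labour", "preeclampsia")

CONDITION_REASON = {
    "foetal_distress": ReasonCode.FOETAL_DISTRESS,
    "prolonged_labour": ReasonCode.PROLONGED_LABOUR,
    "obstructed_labour": ReasonCode.OBSTRUCTED_LABOUR,
    "preeclampsia": ReasonCode.PREECLAMPSIA,
}

#: plotting grid, minutes, per component (the chart's printed grid)
COMPONENT_GRID: dict[Component, int] = {
    Component.FHR: 30,
    Component.CONTRACTION_FREQ: 30,
    Component.CONTRACTION_DURATION: 30,
    Component.PULSE: 30,
    Component.TEMPERATURE: 120,
    Component.URINE_VOLUME: 120,
    Component.URINE_ALBUMIN: 120,
    Component.LIQUOR: 240,
    Component.MOULDING: 240,
    Component.DILATATION: 240,
    Component.DESCENT: 240,
    Component.SBP: 240,
    Component.DBP: 240,
}

#: charting window cap, minutes — charts are rarely maintained past 12 h
MAX_MONITOR_MIN = 720

# condition prevalences matching an ~11% any-indication rate with the
# observed dominance of foetal distress over prolonged labour
DEFAULT_PREVALENCE = {
    "foetal_distress": 0.068,
    "prolonged_labour": 0.031,
    "obstructed_labour": 0.006,
    "preeclampsia": 0.005,
}

# admission dilatation: a little over half arrive in active labour at
# <= 8 cm, the rest near or at full dilatation
DEFAULT_ADMISSION_DILATATION = {
    3: 0.05,
    4: 0.10,
    5: 0.12,
    6: 0.12,
    7: 0.08,
    8: 0.08,
    9: 0.25,
    10: 0.20,
}

# per-due-interval charting probabilities ordered like observed register
# completeness: urinalysis charted most faithfully, pulse least
DEFAULT_CHARTING = {
    Component.FHR.value: 0.55,
    Component.CONTRACTION_FREQ.value: 0.70,
    Component.CONTRACTION_DURATION.value: 0.70,
    Component.PULSE.value: 0.10,
    Component.TEMPERATURE.value: 0.40,
    Component.URINE_VOLUME.value: 0.40,
    Component.URINE_ALBUMIN.value: 0.90,
    Component.LIQUOR.value: 0.60,
    Component.MOULDING.value: 0.25,
    Component.DILATATION.value: 0.70,
    Component.DESCENT.value: 0.65,
    Component.SBP.value: 0.65,
    Component.DBP.value: 0.65,
}

FACILITIES = ("Shibpasha", "Kakailsheo", "Murakuri", "Doulatpur", "Khagaura")

_BASE_ADMISSION = datetime(2013, 7, 1, 8, 0)


@dataclass(frozen=True)
class SimulationParams:
    """Configuration of the synthetic labour cohort.

    Rates are in cm/h; FHR in beats/min; probabilities per case (for
    prevalence and referral behaviour) or per due interval (for
    charting).  Conditions are drawn independently per case, so a case
    may carry several indications.
    """

    n_cases: int = 500
    seed: int = 0
    prevalence: dict = field(default_factory=lambda: dict(DEFAULT_PREVALENCE))
    admission_dilatation_distribution: dict = field(
        default_factory=lambda: dict(DEFAULT_ADMISSION_DILATATION)
    )
    normal_dilatation_rate: float = 1.2
    normal_dilatation_rate_sd: float = 0.3
    prolonged_dilatation_rate: float = 0.4
    fhr_baseline: float = 140.0
    fhr_baseline_sd: float = 8.0
    distress_fhr_low: float = 105.0
    distress_fhr_high: float = 175.0
    charting_probability: dict = field(default_factory=lambda: dict(DEFAULT_CHARTING))
    referral_compliance: float = 0.07
    out_of_scope_referral_rate: float = 0.01
    n_referred_without_admission: int = 0
    jitter_min: int = 0

    def __post_init__(self):
        if self.n_cases <= 0:
            raise ValueError("n_cases must be positive")
        probs = (
            list(self.prevalence.values())
            + list(self.charting_probability.values())
            + [self.referral_compliance, self.out_of_scope_referral_rate]
        )
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.normal_dilatation_rate <= 0 or self.prolonged_dilatation_rate <= 0:
            raise ValueError("dilatation rates must be positive")
        total = sum(self.admission_dilatation_distribution.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError("admission dilatation distribution must sum to 1")


@dataclass
class GroundTruth:
    """Per-case truth, never written into the three register CSVs."""

    case_id: str
    conditions: dict[str, bool]
    referred: bool
    referral_reason: Optional[ReasonCode]

    @property
    def any_condition(self) -> bool:
        return any(self.conditions.values())


def _case_rng(seed: int, case_index: int) -> np.random.Generator:
    # per-case substream keyed by (root seed, case counter): cohorts are
    # reproducible even under out-of-order generation
    return np.random.default_rng([seed, case_index])


def _grid(interval: int, end: int) -> list[int]:
    return list(range(0, end + 1, interval))


def simulate_labour(
    params: SimulationParams, case_index: int, rng: Optional[np.random.Generator] = None
) -> tuple[IntrapartumCase, list[ObservationRow], GroundTruth]:
    """Simulate one woman's admission record, chart and ground truth.

    The dilatation trajectory rises linearly from the admission
    dilatation at the case's rate (slow rate for prolonged cases, so
    the plotted line crosses the alert line); condition-specific
    abnormal values are planted on the chart grid; the full chart is
    then thinned by the per-due-interval charting probabilities.
    """
    if rng is None:
        rng = _case_rng(params.seed, case_index)
    case_id = f"S{case_index:05d}"

    conditions = {c: bool(rng.random() < params.prevalence.get(c, 0.0)) for c in CONDITIONS}

    dil_values = sorted(params.admission_dilatation_distribution)
    dil_probs = [params.admission_dilatation_distribution[v] for v in dil_values]
    d_admit = int(rng.choice(dil_values, p=np.asarray(dil_probs) / sum(dil_probs)))

    if conditions["prolonged_labour"]:
        rate = params.prolonged_dilatation_rate
    else:
        # normal progress never slower than the 1 cm/h alert-line slope
        rate = max(
            1.0, rng.normal(params.normal_dilatation_rate, params.normal_dilatation_rate_sd)
        )
    full_min = int(math.ceil((10 - d_admit) / rate * 60)) if d_admit < 10 else 0
    monitor_end = min(full_min, MAX_MONITOR_MIN)

    obs: list[ObservationRow] = []

    def add_num(component: Component, t: int, v: float) -> None:
        obs.append(ObservationRow(case_id, component, t, value_num=v))

    def add_code(component: Component, t: int, v: str) -> None:
        obs.append(ObservationRow(case_id, component, t, value_code=v))

    # --- dilatation: linear trajectory plotted to whole centimetres
    for t in _grid(COMPONENT_GRID[Component.DILATATION], monitor_end):
        d_true = min(10.0, d_admit + rate * t / 60)
        add_num(Component.DILATATION, t, float(round_half_up(d_true, 0)))

    # --- foetal heart rate: baseline within normal band; distress plants
    # a run of three out-of-range readings
    fhr_times = _grid(COMPONENT_GRID[Component.FHR], monitor_end)
    baseline = float(np.clip(rng.normal(params.fhr_baseline, 5), 125, 155))
    fhr_vals = {
        t: float(np.clip(rng.normal(baseline, params.fhr_baseline_sd / 2), 121, 159))
        for t in fhr_times
    }
    meconium = False
    if conditions["foetal_distress"]:
        abnormal_value = (
            params.distress_fhr_low if rng.random() < 0.5 else params.distress_fhr_high
        )
        start = int(rng.integers(0, max(1, len(fhr_times) - 2)))
        for t in fhr_times[start : start + 3]:
            fhr_vals[t] = float(abnormal_value)
        meconium = bool(rng.random() < 0.4)
    for t in fhr_times:
        add_num(Component.FHR, t, round(fhr_vals[t], 0))

    # --- liquor: clear unless meconium-stained from the distress episode
    for t in _grid(COMPONENT_GRID[Component.LIQUOR], monitor_end):
        add_code(Component.LIQUOR, t, "M" if meconium else "C")

    # --- contractions: frequency always charted numerically; duration
    # category drives the obstruction rule.  Severe moulding is the
    # obstruction sign present from the first assessment; arrest of
    # descent is added only when the chart is long enough to show two
    # descent assessments.
    obstructed_with_plateau = (
        conditions["obstructed_labour"]
        and monitor_end >= COMPONENT_GRID[Component.DESCENT]
        and rng.random() < 0.5
    )
    for t in _grid(COMPONENT_GRID[Component.CONTRACTION_FREQ], monitor_end):
        add_num(Component.CONTRACTION_FREQ, t, float(rng.integers(2, 6)))
        if conditions["obstructed_labour"]:
            dur = "gt40s"
        else:
            dur = str(rng.choice(["lt20s", "s20to40", "gt40s"], p=[0.2, 0.5, 0.3]))
        add_code(Component.CONTRACTION_DURATION, t, dur)

    # --- descent: strictly descending head in unobstructed labour (no
    # plateau artefacts); obstructed cases may arrest
    descent_times = _grid(COMPONENT_GRID[Component.DESCENT], monitor_end)
    start_station = 5 if d_admit <= 5 else 4
    for i, t in enumerate(descent_times):
        if obstructed_with_plateau:
            v = start_station  # arrested head
        else:
            v = max(0, start_station - i)
        add_num(Component.DESCENT, t, float(v))

    # --- moulding
    for t in _grid(COMPONENT_GRID[Component.MOULDING], monitor_end):
        if conditions["obstructed_labour"]:
            code = "+++"
        else:
            code = str(rng.choice(["0", "+"], p=[0.8, 0.2]))
        add_code(Component.MOULDING, t, code)

    # --- blood pressure: systolic/diastolic pair charted together
    for t in _grid(COMPONENT_GRID[Component.SBP], monitor_end):
        if conditions["preeclampsia"]:
            sbp = float(rng.integers(150, 171))
            dbp = float(rng.integers(95, 106))
        else:
            sbp = float(np.clip(round(rng.normal(115, 10)), 90, 135))
            dbp = float(np.clip(round(rng.normal(75, 8)), 55, 85))
        add_num(Component.SBP, t, sbp)
        add_num(Component.DBP, t, dbp)

    # --- urinalysis and urine output
    for t in _grid(COMPONENT_GRID[Component.URINE_ALBUMIN], monitor_end):
        if conditions["preeclampsia"]:
            code = str(rng.choice(["plus1", "plus2", "plus3"]))
        else:
            code = str(rng.choice(["neg", "trace"], p=[0.9, 0.1]))
        add_code(Component.URINE_ALBUMIN, t, code)
        add_num(Component.URINE_VOLUME, t, float(rng.integers(100, 401)))

    # --- pulse and temperature
    for t in _grid(COMPONENT_GRID[Component.PULSE], monitor_end):
        add_num(Component.PULSE, t, float(np.clip(round(rng.normal(82, 8)), 55, 130)))
    for t in _grid(COMPONENT_GRID[Component.TEMPERATURE], monitor_end):
        add_num(Component.TEMPERATURE, t, round(float(rng.normal(36.8, 0.3)), 1))

    # --- charting dropout: independent Bernoulli per due interval
    kept: list[ObservationRow] = []
    for o in obs:
        q = params.charting_probability.get(o.component.value, 1.0)
        if q >= 1.0 or rng.random() < q:
            kept.append(o)

    if params.jitter_min:
        jittered = []
        for o in kept:
            dt = int(rng.integers(-params.jitter_min, params.jitter_min + 1))
            jittered.append(replace(o, t_min=max(0, o.t_min + dt)))
        kept = jittered

    admission = _BASE_ADMISSION + timedelta(minutes=7 * case_index)
    delivery = admission + timedelta(minutes=full_min + 30)
    age = int(np.clip(round(rng.normal(24.9, 4.5)), 15, 45))
    case = IntrapartumCase(
        case_id=case_id,
        facility=str(rng.choice(FACILITIES)),
        admission_time=admission,
        age_years=age,
        parity=Parity.NULLIPARA if rng.random() < 0.34 else Parity.MULTIPARA,
        gestation_weeks=int(rng.integers(37, 42)),
        membrane_status=MembraneStatus.RUPTURED
        if rng.random() < 0.85
        else MembraneStatus.INTACT,
        dilatation_on_arrival_cm=d_admit,
        delivery_time=delivery,
        birth_outcome=BirthOutcome.LIVE,
    )

    referred = False
    reason: Optional[ReasonCode] = None
    truth = GroundTruth(case_id, conditions, referred, reason)
    if truth.any_condition and rng.random() < params.referral_compliance:
        truth.referred = True
        truth.referral_reason = next(
            CONDITION_REASON[c] for c in CONDITIONS if conditions[c]
        )
    return case, kept, truth


def simulate_cohort(
    params: SimulationParams, out_dir=None
) -> tuple[list[IntrapartumCase], list[ObservationRow], list[ReferralEntry], list[GroundTruth]]:
    """Simulate a cohort; optionally emit the three register CSVs.

    When ``out_dir`` is given, writes ``cases.csv``,
    ``partograph_obs.csv``, ``referrals.csv`` (schema-conformant) and
    ``ground_truth.csv`` (ignored by the audit).  Identical params +
    seed give byte-identical files.
    """
    cases: list[IntrapartumCase] = []
    observations: list[ObservationRow] = []
    truths: list[GroundTruth] = []
    referrals: list[ReferralEntry] = []

    for i in range(params.n_cases):
        case, obs, truth = simulate_labour(params, i)
        cases.append(case)
        observations.extend(obs)
        truths.append(truth)

    noise_rng = np.random.default_rng([params.seed, 999_983])
    for case, truth in zip(cases, truths):
        if truth.referred:
            referrals.append(
                ReferralEntry(
                    case_id=case.case_id,
                    referral_time=case.admission_time + timedelta(minutes=120),
                    reason_code=truth.referral_reason,
                    admitted_flag=True,
                )
            )
        elif noise_rng.random() < params.out_of_scope_referral_rate:
            referrals.append(
                ReferralEntry(
                    case_id=case.case_id,
                    referral_time=case.delivery_time,
                    reason_code=ReasonCode(
                        str(noise_rng.choice(["pph", "retained_placenta", "general_illness"]))
                    ),
                    admitted_flag=True,
                )
            )
    for j in range(params.n_referred_without_admission):
        referrals.append(
            ReferralEntry(
                case_id=None,
                referral_time=_BASE_ADMISSION + timedelta(minutes=11 * j),
                reason_code=ReasonCode(
                    str(noise_rng.choice(["prolonged_labour", "preeclampsia", "other"]))
                ),
                admitted_flag=False,
            )
        )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_cases(cases, out_dir / "cases.csv")
        write_observations(observations, out_dir / "partograph_obs.csv")
        write_referrals(referrals, out_dir / "referrals.csv")
        pd.DataFrame(
            [
                {
                    "case_id": t.case_id,
                    **{c: t.conditions[c] for c in CONDITIONS},
                    "referred": t.referred,
                    "referral_reason": t.referral_reason.value if t.referral_reason else "",
                }
                for t in truths
            ]
        ).to_csv(out_dir / "ground_truth.csv", index=False)
    return cases, observations, referrals, truths


# ---------------------------------------------------------------------------
# deterministic benchmark fixture
# ---------------------------------------------------------------------------

#: benchmark flow counts (presented / admitted / referred-without-admission /
#: eligible / charted / abnormal / in-scope referrals / flagged referrals)
REFERENCE_COUNTS = {
    "n_presented": 1548,
    "n_admitted": 1198,
    "n_referred_without_admission": 350,
    "n_eligible": 663,
    "n_with_partograph": 648,
    "n_abnormal_indication": 71,
    "n_referred_with_partograph_in_scope": 5,
    "n_referred_with_indication": 1,
}

# abnormal-chart mix among the 71 flagged charts: distress dominates,
# then slow progress; no overlap assumed between conditions
REFERENCE_ABNORMAL_MIX = {
    "foetal_distress": 44,
    "prolonged_labour": 20,
    "obstructed_labour": 4,
    "preeclampsia": 3,
}

_BACKGROUND_FRACTIONS = {
    "facility": {
        "Shibpasha": 0.282,
        "Kakailsheo": 0.252,
        "Murakuri": 0.209,
        "Doulatpur": 0.194,
        "Khagaura": 0.063,
    },
    "age_band": {"15-19": 0.036, "20-24": 0.422, "25-29": 0.359, "30_plus": 0.171, "missing": 0.013},
    "parity": {"nullipara": 0.336, "multipara": 0.659, "missing": 0.015},
    "membranes": {"ruptured": 0.847, "intact": 0.056, "missing": 0.097},
}

_AGE_BAND_VALUE = {"15-19": 18, "20-24": 22, "25-29": 27, "30_plus": 32, "missing": None}


def _apportion(total: int, fractions: dict) -> dict:
    """Integer counts summing to ``total`` by largest remainder."""
    raw = {k: total * f for k, f in fractions.items()}
    counts = {k: int(math.floor(v)) for k, v in raw.items()}
    short = total - sum(counts.values())
    for k in sorted(raw, key=lambda k: raw[k] - counts[k], reverse=True)[:short]:
        counts[k] += 1
    return counts


def _assign_categories(n: int, fractions: dict) -> list:
    counts = _apportion(n, fractions)
    out: list = []
    for k, c in counts.items():
        out.extend([k] * c)
    return out


def _normal_chart(case_id: str, d0: int) -> list[ObservationRow]:
    """A small unremarkable chart: progress exactly on the alert line."""
    d1 = min(10, d0 + 4)
    rows = [
        ObservationRow(case_id, Component.DILATATION, 0, value_num=float(d0)),
        ObservationRow(case_id, Component.DILATATION, (d1 - d0) * 60, value_num=float(d1)),
        ObservationRow(case_id, Component.FHR, 0, value_num=140.0),
        ObservationRow(case_id, Component.FHR, 30, value_num=138.0),
        ObservationRow(case_id, Component.LIQUOR, 0, value_code="C"),
        ObservationRow(case_id, Component.CONTRACTION_FREQ, 0, value_num=3.0),
        ObservationRow(case_id, Component.CONTRACTION_DURATION, 0, value_code="s20to40"),
        ObservationRow(case_id, Component.DESCENT, 0, value_num=4.0),
        ObservationRow(case_id, Component.DESCENT, 240, value_num=3.0),
        ObservationRow(case_id, Component.MOULDING, 0, value_code="0"),
        ObservationRow(case_id, Component.SBP, 0, value_num=115.0),
        ObservationRow(case_id, Component.DBP, 0, value_num=75.0),
        ObservationRow(case_id, Component.URINE_ALBUMIN, 0, value_code="neg"),
        ObservationRow(case_id, Component.URINE_VOLUME, 0, value_num=200.0),
        ObservationRow(case_id, Component.PULSE, 0, value_num=80.0),
        ObservationRow(case_id, Component.TEMPERATURE, 0, value_num=36.8),
    ]
    return rows


def _abnormal_chart(case_id: str, condition: str) -> list[ObservationRow]:
    rows = _normal_chart(case_id, 4)
    if condition == "foetal_distress":
        rows = [r for r in rows if r.component is not Component.FHR]
        rows += [
            ObservationRow(case_id, Component.FHR, 0, value_num=110.0),
            ObservationRow(case_id, Component.FHR, 30, value_num=108.0),
        ]
    elif condition == "prolonged_labour":
        rows = [r for r in rows if r.component is not Component.DILATATION]
        rows += [
            ObservationRow(case_id, Component.DILATATION, 0, value_num=4.0),
            ObservationRow(case_id, Component.DILATATION, 300, value_num=6.0),
        ]
    elif condition == "obstructed_labour":
        rows = [r for r in rows if r.component is not Component.MOULDING]
        rows += [
            ObservationRow(case_id, Component.MOULDING, 0, value_code="+++"),
            ObservationRow(case_id, Component.CONTRACTION_DURATION, 30, value_code="gt40s"),
        ]
    elif condition == "preeclampsia":
        rows = [
            r
            for r in rows
            if r.component not in (Component.SBP, Component.DBP, Component.URINE_ALBUMIN)
        ]
        rows += [
            ObservationRow(case_id, Component.SBP, 0, value_num=150.0),
            ObservationRow(case_id, Component.DBP, 0, value_num=95.0),
            ObservationRow(case_id, Component.URINE_ALBUMIN, 0, value_code="plus2"),
        ]
    else:
        raise ValueError(condition)
    return rows


def make_reference_fixture(
    out_dir=None,
) -> tuple[list[IntrapartumCase], list[ObservationRow], list[ReferralEntry]]:
    """Deterministic benchmark cohort with the fixed flow counts above.

    1198 admitted cases (663 with dilatation <= 8 cm, of whom 648 have
    a chart; 71 charts carry an abnormal-labour indication in the mix
    of :data:`REFERENCE_ABNORMAL_MIX`), 350 referral-register rows
    without admission, 5 in-scope referrals among charted cases (1 of
    them with a charted indication — the other 4 carry a
    prolonged-labour register reason that the chart does not support)
    and 3 out-of-scope referral rows.  Background characteristics are
    apportioned deterministically from fixed facility/age/parity/
    membrane fractions.
    """
    n_admitted = REFERENCE_COUNTS["n_admitted"]
    n_eligible = REFERENCE_COUNTS["n_eligible"]
    n_charted = REFERENCE_COUNTS["n_with_partograph"]

    facilities = _assign_categories(n_admitted, _BACKGROUND_FRACTIONS["facility"])
    ages = [
        _AGE_BAND_VALUE[b]
        for b in _assign_categories(n_admitted, _BACKGROUND_FRACTIONS["age_band"])
    ]
    parities = [
        Parity.MISSING if p == "missing" else Parity(p)
        for p in _assign_categories(n_admitted, _BACKGROUND_FRACTIONS["parity"])
    ]
    membranes = [
        MembraneStatus.MISSING if m == "missing" else MembraneStatus(m)
        for m in _assign_categories(n_admitted, _BACKGROUND_FRACTIONS["membranes"])
    ]
    # eligible cases cycle through 4-8 cm on arrival; the rest arrive at 9-10
    dilatations = [4 + (i % 5) for i in range(n_eligible)] + [
        9 + (i % 2) for i in range(n_admitted - n_eligible)
    ]

    cases: list[IntrapartumCase] = []
    for i in range(n_admitted):
        admission = _BASE_ADMISSION + timedelta(minutes=9 * i)
        cases.append(
            IntrapartumCase(
                case_id=f"C{i + 1:04d}",
                facility=facilities[i],
                admission_time=admission,
                age_years=ages[i],
                parity=parities[i],
                gestation_weeks=39,
                membrane_status=membranes[i],
                dilatation_on_arrival_cm=dilatations[i],
                delivery_time=admission + timedelta(minutes=360),
                birth_outcome=BirthOutcome.LIVE,
            )
        )

    # first 648 eligible cases get charts; the last 15 eligible do not
    charted_cases = cases[:n_charted]
    abnormal_plan: list[Optional[str]] = []
    for cond, k in REFERENCE_ABNORMAL_MIX.items():
        abnormal_plan.extend([cond] * k)
    abnormal_plan.extend([None] * (n_charted - len(abnormal_plan)))

    observations: list[ObservationRow] = []
    for case, cond in zip(charted_cases, abnormal_plan):
        if cond is None:
            observations.extend(
                _normal_chart(case.case_id, max(4, case.dilatation_on_arrival_cm))
            )
        else:
            observations.extend(_abnormal_chart(case.case_id, cond))

    referrals: list[ReferralEntry] = []
    # the one referral whose indication is charted: a prolonged-labour case
    flagged_prolonged = [
        c.case_id
        for c, cond in zip(charted_cases, abnormal_plan)
        if cond == "prolonged_labour"
    ]
    referrals.append(
        ReferralEntry(
            case_id=flagged_prolonged[0],
            referral_time=_BASE_ADMISSION + timedelta(hours=6),
            reason_code=ReasonCode.PROLONGED_LABOUR,
            admitted_flag=True,
        )
    )
    # four register referrals for prolonged labour whose charts show no
    # indication
    unflagged = [c.case_id for c, cond in zip(charted_cases, abnormal_plan) if cond is None]
    for cid in unflagged[:4]:
        referrals.append(
            ReferralEntry(
                case_id=cid,
                referral_time=_BASE_ADMISSION + timedelta(hours=8),
                reason_code=ReasonCode.PROLONGED_LABOUR,
                admitted_flag=True,
            )
        )
    # out-of-scope register rows (retained, marked, never counted)
    for cid, reason in zip(
        unflagged[4:7],
        (ReasonCode.PPH, ReasonCode.RETAINED_PLACENTA, ReasonCode.BIRTH_ASPHYXIA),
    ):
        referrals.append(
            ReferralEntry(
                case_id=cid,
                referral_time=_BASE_ADMISSION + timedelta(hours=9),
                reason_code=reason,
                admitted_flag=True,
            )
        )
    # women referred onward at initial assessment, never admitted
    for j in range(REFERENCE_COUNTS["n_referred_without_admission"]):
        referrals.append(
            ReferralEntry(
                case_id=None,
                referral_time=_BASE_ADMISSION + timedelta(minutes=13 * j),
                reason_code=[
                    ReasonCode.PROLONGED_LABOUR,
                    ReasonCode.PREECLAMPSIA,
                    ReasonCode.OTHER,
                ][j % 3],
                admitted_flag=False,
            )
        )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_cases(cases, out_dir / "cases.csv")
        write_observations(observations, out_dir / "partograph_obs.csv")
        write_referrals(referrals, out_dir / "referrals.csv")
    return cases, observations, referrals
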