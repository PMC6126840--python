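"""Charting-completeness audit of partograph components.

Each monitored component has a WHO-recommended assessment interval:
half-hourly for foetal heart rate, uterine contractions and maternal
pulse; two-hourly for temperature and urine output/analysis;
four-hourly for liquor, moulding, cervical dilatation, descent of the
head and blood pressure.  A component counts as *appropriately
recorded* when the chart holds at least two plottings at the scheduled
interval.

Blood pressure is audited as a composite: a BP plotting is a time at
which both a systolic and a diastolic value were charted (the two are
tested separately by the pre-eclampsia rule but charted as one mark).

Cohort-level proportions are compared between charts with and without
an abnormal-labour indication using the pooled two-proportion z-test
(the classical "equality of proportions" test); a group comparison with
no successes (or no failures) in either group is degenerate and is
reported as a dash rather than a p-value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Optional

import pandas as pd
from scipy import stats

from partoaudit.partograph import Partograph
from partoaudit.records_io import Component
from partoaudit.rules import AbnormalityResult

#: audit label for the composite blood-pressure component
BP = "bp"

#: default assessment schedule, minutes.  BP defaults to four-hourly per
#: the WHO monitoring text; facility practice sometimes charts it
#: half-hourly, so the value is overridable.
DEFAULT_SCHEDULE: dict[str, int] = {
    Component.FHR.value: 30,
    Component.CONTRACTION_FREQ.value: 30,
    Component.PULSE.value: 30,
    Component.TEMPERATURE.value: 120,
    Component.URINE_VOLUME.value: 120,
    Component.URINE_ALBUMIN.value: 120,
    Component.LIQUOR.value: 240,
    Component.MOULDING.value: 240,
    Component.DILATATION.value: 240,
    Component.DESCENT.value: 240,
    BP: 240,
}


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round half away from zero, matching hand-tabulated percentages."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _plot_times(p: Partograph, component: str) -> list[int]:
    if component == BP:
        s = {t for t, _ in p.get(Component.SBP)}
        d = {t for t, _ in p.get(Component.DBP)}
        return sorted(s & d)
    return sorted({t for t, _ in p.get(Component(component))})


def component_complete(
    p: Partograph,
    component: str,
    schedule: Mapping[str, int] = DEFAULT_SCHEDULE,
    strict: bool = False,
) -> bool:
    """Was this component appropriately recorded?

    Requires at least two plottings.  Under the default (lenient) rule
    some adjacent pair of plottings must be no further apart than the
    scheduled interval; under ``strict=True`` every adjacent gap must
    respect the interval.
    """
    if component not in schedule:
        raise KeyError(f"component {component!r} not in schedule")
    interval = schedule[component]
    times = _plot_times(p, component)
    if len(times) < 2:
        return False
    gaps = [b - a for a, b in zip(times, times[1:])]
    return all(g <= interval for g in gaps) if strict else any(g <= interval for g in gaps)


@dataclass(frozen=True)
class TwoProportionResult:
    """Pooled two-sided z-test of p1 == p2 on two binomial samples."""

    x1: int
    n1: int
    x2: int
    n2: int
    p1_hat: float
    p2_hat: float
    z: Optional[float]
    p_value: Optional[float]
    degenerate: bool

    @property
    def significant(self) -> bool:
        return self.p_value is not None and self.p_value < 0.05


def two_proportion_test(x1: int, n1: int, x2: int, n2: int) -> TwoProportionResult:
    """Pooled two-proportion z-test, two-sided, no continuity correction.

    z = (p1 - p2) / sqrt(p(1-p)(1/n1 + 1/n2)) with the pooled
    p = (x1+x2)/(n1+n2).  When the pooled proportion is 0 or 1 the
    variance vanishes and the test is degenerate (no p-value); the
    audit table prints a dash for such rows.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("group sizes must be positive")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("counts must satisfy 0 <= x <= n")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        return TwoProportionResult(x1, n1, x2, n2, p1, p2, None, None, True)
    se = math.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = (p1 - p2) / se
    p_value = 2 * stats.norm.sf(abs(z))
    return TwoProportionResult(x1, n1, x2, n2, p1, p2, z, p_value, False)


@dataclass
class CompletenessResult:
    """Per-case verdicts for every scheduled component."""

    case_id: str
    verdicts: dict[str, bool]
    group: str  # "abnormal" | "no_indication"


def score_case(
    p: Partograph,
    result: AbnormalityResult,
    schedule: Mapping[str, int] = DEFAULT_SCHEDULE,
    strict: bool = False,
) -> CompletenessResult:
    return CompletenessResult(
        case_id=p.case_id,
        verdicts={c: component_complete(p, c, schedule, strict) for c in schedule},
        group="abnormal" if result.any_indication else "no_indication",
    )


def cohort_completeness(
    partographs: Iterable[Partograph],
    results: Mapping[str, AbnormalityResult],
    schedule: Mapping[str, int] = DEFAULT_SCHEDULE,
    strict: bool = False,
) -> pd.DataFrame:
    """Tabulate % appropriately recorded per component, overall and by group.

    Returns a DataFrame with one row per scheduled component and
    columns ``component, interval_min, n_total, n_abnormal,
    n_no_indication, pct_overall, pct_abnormal, pct_no_indication,
    p_value`` (NaN when the group comparison is degenerate or a group
    is empty).  Percentages are rounded half-up to one decimal.
    """
    scored = [score_case(p, results[p.case_id], schedule, strict) for p in partographs]
    n_total = len(scored)
    abn = [s for s in scored if s.group == "abnormal"]
    noi = [s for s in scored if s.group == "no_indication"]
    rows = []
    for comp, interval in schedule.items():
        x_all = sum(s.verdicts[comp] for s in scored)
        x_abn = sum(s.verdicts[comp] for s in abn)
        x_noi = sum(s.verdicts[comp] for s in noi)
        if abn and noi:
            test = two_proportion_test(x_abn, len(abn), x_noi, len(noi))
            p_value = float("nan") if test.degenerate else test.p_value
        else:
            p_value = float("nan")
        rows.append(
            {
                "component": comp,
                "interval_min": interval,
                "n_total": n_total,
                "n_abnormal": len(abn),
                "n_no_indication": len(noi),
                "pct_overall": round_half_up(100 * x_all / n_total) if n_total else float("nan"),
                "pct_abnormal": round_half_up(100 * x_abn / len(abn)) if abn else float("nan"),
                "pct_no_indication": round_half_up(100 * x_noi / len(noi)) if noi else float("nan"),
                "p_value": p_value,
            }
        )
    return pd.DataFrame(rows)
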