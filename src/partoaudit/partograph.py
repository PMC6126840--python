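"""Per-case partograph assembly and alert/action-line geometry.

The WHO modified partograph charts only the active phase of labour
(cervical dilatation >= 4 cm).  Its alert line rises at 1 cm per hour
from the first active-phase dilatation plot; the action line runs
parallel, 4 hours to the right.  A dilatation plot falling to the right
of the alert line signals slow progress; reaching the action line
demands intervention or referral.

All line arithmetic is in integer minutes since admission — the chart
is plotted on a grid, and integer minutes avoid float drift.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from partoaudit.records_io import Component, ObservationRow

#: alert line slope: one centimetre of dilatation per hour
SLOPE_MIN_PER_CM = 60
#: action line offset: four hours right of the alert line
ACTION_OFFSET_MIN = 240

#: dilatation threshold opening the active phase
ACTIVE_PHASE_CM = 4


@dataclass(frozen=True)
class AlertLineGeometry:
    """Alert/action lines anchored at the first active-phase dilatation plot.

    ``alert_time(d)`` is the latest time at which a woman progressing at
    1 cm/h would reach dilatation ``d``; later plots lie right of the
    alert line.
    """

    t0_min: int
    d0_cm: int

    def alert_time(self, d_cm: float) -> int:
        """Time (min) at which the alert line passes dilatation ``d_cm``."""
        if d_cm < self.d0_cm:
            raise ValueError(
                f"dilatation {d_cm} below anchor {self.d0_cm}; alert line undefined"
            )
        return self.t0_min + int((d_cm - self.d0_cm) * SLOPE_MIN_PER_CM)

    def action_time(self, d_cm: float) -> int:
        return self.alert_time(d_cm) + ACTION_OFFSET_MIN


def is_right_of_alert(geometry: AlertLineGeometry, t_min: int, d_cm: float) -> bool:
    """True iff the plot falls strictly right of the alert line.

    A plot exactly on the line is not "on the right side" of it.
    """
    return t_min > geometry.alert_time(d_cm)


def reaches_action(geometry: AlertLineGeometry, t_min: int, d_cm: float) -> bool:
    """True iff the plot reaches (or passes) the action line — inclusive."""
    return t_min >= geometry.action_time(d_cm)


@dataclass
class Partograph:
    """One woman's chart: per-component observation series plus line anchor.

    ``anchor`` is present iff some dilatation observation is >= 4 cm
    (the chart's active phase was opened).  Dilatation plots below the
    anchor dilatation cannot occur physiologically (the cervix does not
    close); such rows are charting errors, excluded from line tests and
    listed in ``regressions``.
    """

    case_id: str
    series: dict[Component, list[tuple[int, object]]] = field(default_factory=dict)
    anchor: Optional[AlertLineGeometry] = None
    regressions: list[tuple[int, float]] = field(default_factory=list)

    def get(self, component: Component) -> list[tuple[int, object]]:
        return self.series.get(component, [])

    def dilatation_plots_for_line_tests(self) -> list[tuple[int, float]]:
        """Active-phase dilatation plots at/after the anchor, regressions excluded."""
        if self.anchor is None:
            return []
        return [
            (t, v)
            for t, v in self.get(Component.DILATATION)
            if t >= self.anchor.t0_min and v >= self.anchor.d0_cm
        ]


def build_partograph(rows: Iterable[ObservationRow], case_id: Optional[str] = None) -> Partograph:
    """Assemble one case's observation rows into a :class:`Partograph`.

    Rows must share a single ``case_id`` (checked).  Each component
    series is sorted by ``t_min``, ties broken by input order.  Empty
    input yields an empty chart with no anchor.
    """
    rows = list(rows)
    ids = {r.case_id for r in rows}
    if len(ids) > 1:
        raise ValueError(f"rows span multiple cases: {sorted(ids)}")
    if case_id is None:
        case_id = rows[0].case_id if rows else ""

    series: dict[Component, list[tuple[int, object]]] = {}
    for r in rows:
        series.setdefault(r.component, []).append((r.t_min, r.value))
    for comp in series:
        series[comp].sort(key=lambda tv: tv[0])  # stable: ties keep input order

    anchor = None
    regressions: list[tuple[int, float]] = []
    dil = series.get(Component.DILATATION, [])
    for t, v in dil:
        if v >= ACTIVE_PHASE_CM:
            anchor = AlertLineGeometry(t0_min=t, d0_cm=int(v))
            break
    if anchor is not None:
        regressions = [
            (t, v) for t, v in dil if t >= anchor.t0_min and v < anchor.d0_cm
        ]
    return Partograph(case_id=case_id, series=series, anchor=anchor, regressions=regressions)
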