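"""Register tables: strict CSV schemas for cases, observations and referrals.

Three flat tables feed the audit:

* ``cases.csv`` — one row per woman admitted in labour (the intrapartum
  case record form).
* ``partograph_obs.csv`` — long format, one row per plotted partograph
  value.
* ``referrals.csv`` — one row per entry in the facility referral
  register; a row without a ``case_id`` is a woman referred after
  initial assessment without admission.

Loaders validate every row and never drop rows silently: each
:class:`LoadResult` satisfies ``rows_in == len(records) + len(rejects)``
and every reject carries its row number and reason.  Missing values are
explicit ``missing`` enum members in memory (mirroring the register
audit convention of reporting a "no information recorded" category),
never empty-string sentinels.

Time is stored as integer minutes since admission (``t_min``);
timestamps in files are ISO-8601 and converted at load.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd


class SchemaError(ValueError):
    """Hard, file-level schema violation (bad header, duplicate ids)."""


class Parity(str, enum.Enum):
    NULLIPARA = "nullipara"
    MULTIPARA = "multipara"
    MISSING = "missing"


class MembraneStatus(str, enum.Enum):
    RUPTURED = "ruptured"
    INTACT = "intact"
    MISSING = "missing"


class BirthOutcome(str, enum.Enum):
    LIVE = "live"
    STILLBIRTH = "stillbirth"
    NEONATAL_DEATH = "neonatal_death"
    MISSING = "missing"


class Component(str, enum.Enum):
    """The monitored partograph components (long-table ``component`` codes)."""

    FHR = "fhr"
    LIQUOR = "liquor"
    MOULDING = "moulding"
    DILATATION = "dilatation"
    DESCENT = "descent"
    CONTRACTION_FREQ = "contraction_freq"
    CONTRACTION_DURATION = "contraction_duration"
    SBP = "sbp"
    DBP = "dbp"
    PULSE = "pulse"
    TEMPERATURE = "temperature"
    URINE_VOLUME = "urine_volume"
    URINE_ALBUMIN = "urine_albumin"


class ReasonCode(str, enum.Enum):
    FOETAL_DISTRESS = "foetal_distress"
    PROLONGED_LABOUR = "prolonged_labour"
    OBSTRUCTED_LABOUR = "obstructed_labour"
    PREECLAMPSIA = "preeclampsia"
    GENERAL_ILLNESS = "general_illness"
    PPH = "pph"
    RETAINED_PLACENTA = "retained_placenta"
    BIRTH_ASPHYXIA = "birth_asphyxia"
    LOW_BIRTH_WEIGHT = "low_birth_weight"
    STILLBIRTH = "stillbirth"
    NEONATAL_DEATH = "neonatal_death"
    OTHER = "other"


#: coded-value domains, per component
CODED_DOMAINS: dict[Component, frozenset[str]] = {
    Component.LIQUOR: frozenset({"I", "C", "M", "A", "B"}),
    Component.MOULDING: frozenset({"0", "+", "++", "+++"}),
    Component.CONTRACTION_DURATION: frozenset({"lt20s", "s20to40", "gt40s"}),
    Component.URINE_ALBUMIN: frozenset({"neg", "trace", "plus1", "plus2", "plus3"}),
}

#: numeric components with optional inclusive (lo, hi) range checks
NUMERIC_RANGES: dict[Component, tuple[Optional[float], Optional[float]]] = {
    Component.FHR: (1, None),
    Component.DILATATION: (0, 10),
    Component.DESCENT: (0, 5),
    Component.CONTRACTION_FREQ: (0, None),
    Component.SBP: (1, None),
    Component.DBP: (1, None),
    Component.PULSE: (1, None),
    Component.TEMPERATURE: (30, 45),
    Component.URINE_VOLUME: (0, None),
}

NUMERIC_COMPONENTS = frozenset(NUMERIC_RANGES)
CODED_COMPONENTS = frozenset(CODED_DOMAINS)


@dataclass(frozen=True)
class IntrapartumCase:
    """One admitted woman's case record."""

    case_id: str
    facility: str
    admission_time: Optional[datetime]
    age_years: Optional[int]
    parity: Parity
    gestation_weeks: Optional[int]
    membrane_status: MembraneStatus
    dilatation_on_arrival_cm: int
    delivery_time: Optional[datetime] = None
    birth_outcome: BirthOutcome = BirthOutcome.MISSING


@dataclass(frozen=True)
class ObservationRow:
    """One plotted partograph value; exactly one of value_num / value_code set."""

    case_id: str
    component: Component
    t_min: int
    value_num: Optional[float] = None
    value_code: Optional[str] = None

    @property
    def value(self):
        return self.value_num if self.value_num is not None else self.value_code


@dataclass(frozen=True)
class ReferralEntry:
    """One referral-register row; ``case_id`` absent = referred without admission."""

    case_id: Optional[str]
    referral_time: Optional[datetime]
    reason_code: ReasonCode
    admitted_flag: bool


@dataclass(frozen=True)
class RowError:
    row_number: int  # 1-based data row number (header excluded)
    case_id: str
    message: str


@dataclass
class LoadResult:
    """Records accepted plus enumerated rejects; nothing dropped silently."""

    records: list
    rejects: list[RowError] = field(default_factory=list)

    @property
    def rows_in(self) -> int:
        return len(self.records) + len(self.rejects)

    def __iter__(self):
        return iter(self.records)

    def __len__(self):
        return len(self.records)


CASE_COLUMNS = [
    "case_id",
    "facility",
    "admission_time",
    "age_years",
    "parity",
    "gestation_weeks",
    "membrane_status",
    "dilatation_on_arrival_cm",
    "delivery_time",
    "birth_outcome",
]
OBS_COLUMNS = ["case_id", "component", "t_min", "value_num", "value_code"]
REFERRAL_COLUMNS = ["case_id", "referral_time", "reason_code", "admitted_flag"]


def _read_table(path, columns: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(df.columns) != list(columns):
        raise SchemaError(
            f"{path}: header {list(df.columns)!r} does not match schema {list(columns)!r}"
        )
    return df


def _parse_timestamp(text: str, what: str) -> Optional[datetime]:
    if text == "":
        return None
    try:
        return datetime.fromisoformat(text)
    except ValueError as exc:
        raise ValueError(f"{what}: not ISO-8601: {text!r}") from exc


def _parse_int(text: str, what: str) -> Optional[int]:
    if text == "":
        return None
    try:
        return int(text)
    except ValueError as exc:
        raise ValueError(f"{what}: not an integer: {text!r}") from exc


def _parse_enum(text: str, enum_cls, what: str, missing_ok: bool = True):
    if text == "" and missing_ok:
        return enum_cls("missing")
    try:
        return enum_cls(text)
    except ValueError as exc:
        valid = sorted(m.value for m in enum_cls)
        raise ValueError(f"{what}: {text!r} not in {valid}") from exc


def read_cases(path) -> LoadResult:
    """Load ``cases.csv``; duplicate case ids are a hard error."""
    df = _read_table(path, CASE_COLUMNS)
    records: list[IntrapartumCase] = []
    rejects: list[RowError] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=1):
        case_id = row.case_id.strip()
        try:
            if case_id == "":
                raise ValueError("case_id: must be non-empty")
            if case_id in seen:
                raise SchemaError(f"{path}: duplicate case_id {case_id!r} at data row {i}")
            dil = _parse_int(row.dilatation_on_arrival_cm, "dilatation_on_arrival_cm")
            if dil is None or not 0 <= dil <= 10:
                raise ValueError(
                    f"dilatation_on_arrival_cm: {row.dilatation_on_arrival_cm!r} outside 0-10"
                )
            admission = _parse_timestamp(row.admission_time, "admission_time")
            delivery = _parse_timestamp(row.delivery_time, "delivery_time")
            if admission is not None and delivery is not None and delivery < admission:
                raise ValueError("delivery_time before admission_time")
            records.append(
                IntrapartumCase(
                    case_id=case_id,
                    facility=row.facility,
                    admission_time=admission,
                    age_years=_parse_int(row.age_years, "age_years"),
                    parity=_parse_enum(row.parity, Parity, "parity"),
                    gestation_weeks=_parse_int(row.gestation_weeks, "gestation_weeks"),
                    membrane_status=_parse_enum(
                        row.membrane_status, MembraneStatus, "membrane_status"
                    ),
                    dilatation_on_arrival_cm=dil,
                    delivery_time=delivery,
                    birth_outcome=_parse_enum(row.birth_outcome, BirthOutcome, "birth_outcome"),
                )
            )
            seen.add(case_id)
        except SchemaError:
            raise
        except ValueError as exc:
            rejects.append(RowError(i, case_id, str(exc)))
    return LoadResult(records, rejects)


def _parse_observation(row, i: int) -> ObservationRow:
    case_id = row.case_id.strip()
    if case_id == "":
        raise ValueError("case_id: must be non-empty")
    try:
        component = Component(row.component)
    except ValueError as exc:
        raise ValueError(f"component: unknown {row.component!r}") from exc
    t_min = _parse_int(row.t_min, "t_min")
    if t_min is None or t_min < 0:
        raise ValueError(f"t_min: {row.t_min!r} must be a non-negative integer")
    has_num = row.value_num != ""
    has_code = row.value_code != ""
    if has_num == has_code:
        raise ValueError("exactly one of value_num / value_code must be populated")
    if component in NUMERIC_COMPONENTS:
        if not has_num:
            raise ValueError(f"{component.value}: expects value_num")
        try:
            v = float(row.value_num)
        except ValueError as exc:
            raise ValueError(f"value_num: not numeric: {row.value_num!r}") from exc
        lo, hi = NUMERIC_RANGES[component]
        if (lo is not None and v < lo) or (hi is not None and v > hi):
            raise ValueError(f"{component.value}: value {v} outside [{lo}, {hi}]")
        return ObservationRow(case_id, component, t_min, value_num=v)
    if not has_code:
        raise ValueError(f"{component.value}: expects value_code")
    if row.value_code not in CODED_DOMAINS[component]:
        raise ValueError(
            f"{component.value}: code {row.value_code!r} not in "
            f"{sorted(CODED_DOMAINS[component])}"
        )
    return ObservationRow(case_id, component, t_min, value_code=row.value_code)


def read_observations(path) -> LoadResult:
    """Load ``partograph_obs.csv`` sorted by (case_id, component, t_min)."""
    df = _read_table(path, OBS_COLUMNS)
    records: list[ObservationRow] = []
    rejects: list[RowError] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            records.append(_parse_observation(row, i))
        except ValueError as exc:
            rejects.append(RowError(i, row.case_id, str(exc)))
    # stable sort keeps input order within (case, component, t) ties
    records.sort(key=lambda r: (r.case_id, r.component.value, r.t_min))
    return LoadResult(records, rejects)


def read_referrals(path) -> LoadResult:
    """Load ``referrals.csv``; an admitted referral without case_id is a hard error."""
    df = _read_table(path, REFERRAL_COLUMNS)
    records: list[ReferralEntry] = []
    rejects: list[RowError] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        case_id = row.case_id.strip() or None
        try:
            admitted = {"true": True, "false": False}.get(row.admitted_flag.strip().lower())
            if admitted is None:
                raise ValueError(f"admitted_flag: {row.admitted_flag!r} not true/false")
            if admitted and case_id is None:
                raise SchemaError(
                    f"{path}: data row {i}: admitted_flag=true requires a case_id"
                )
            records.append(
                ReferralEntry(
                    case_id=case_id,
                    referral_time=_parse_timestamp(row.referral_time, "referral_time"),
                    reason_code=_parse_enum(
                        row.reason_code, ReasonCode, "reason_code", missing_ok=False
                    ),
                    admitted_flag=admitted,
                )
            )
        except SchemaError:
            raise
        except ValueError as exc:
            rejects.append(RowError(i, case_id or "", str(exc)))
    return LoadResult(records, rejects)


def _fmt_ts(ts: Optional[datetime]) -> str:
    return "" if ts is None else ts.isoformat(timespec="minutes")


def _fmt_opt(v) -> str:
    return "" if v is None else str(v)


def write_cases(cases: Iterable[IntrapartumCase], path) -> None:
    rows = [
        {
            "case_id": c.case_id,
            "facility": c.facility,
            "admission_time": _fmt_ts(c.admission_time),
            "age_years": _fmt_opt(c.age_years),
            "parity": "" if c.parity is Parity.MISSING else c.parity.value,
            "gestation_weeks": _fmt_opt(c.gestation_weeks),
            "membrane_status": ""
            if c.membrane_status is MembraneStatus.MISSING
            else c.membrane_status.value,
            "dilatation_on_arrival_cm": c.dilatation_on_arrival_cm,
            "delivery_time": _fmt_ts(c.delivery_time),
            "birth_outcome": ""
            if c.birth_outcome is BirthOutcome.MISSING
            else c.birth_outcome.value,
        }
        for c in cases
    ]
    pd.DataFrame(rows, columns=CASE_COLUMNS).to_csv(path, index=False)


def write_observations(obs: Iterable[ObservationRow], path) -> None:
    rows = [
        {
            "case_id": o.case_id,
            "component": o.component.value,
            "t_min": o.t_min,
            "value_num": "" if o.value_num is None else _fmt_num(o.value_num),
            "value_code": _fmt_opt(o.value_code),
        }
        for o in obs
    ]
    pd.DataFrame(rows, columns=OBS_COLUMNS).to_csv(path, index=False)


def _fmt_num(v: float) -> str:
    # integers print without trailing .0 so files round-trip bytewise
    return str(int(v)) if float(v).is_integer() else repr(float(v))


def write_referrals(refs: Iterable[ReferralEntry], path) -> None:
    rows = [
        {
            "case_id": _fmt_opt(r.case_id),
            "referral_time": _fmt_ts(r.referral_time),
            "reason_code": r.reason_code.value,
            "admitted_flag": "true" if r.admitted_flag else "false",
        }
        for r in refs
    ]
    pd.DataFrame(rows, columns=REFERRAL_COLUMNS).to_csv(path, index=False)


def write_report(report, out_dir) -> dict[str, Path]:
    """Write a cohort-flow report as ``report.json`` + ``report.md``.

    Returns the paths written.  The JSON is the machine-readable form
    (:meth:`CohortFlowReport.to_dict` round-trips through it); the
    markdown mirrors the flow-diagram counts and the background /
    completeness summary tables for human review.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    json_path = out_dir / "report.json"
    md_path = out_dir / "report.md"
    payload = report.to_dict()
    json_path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    md_path.write_text(report.to_markdown())
    return {"json": json_path, "markdown": md_path}
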