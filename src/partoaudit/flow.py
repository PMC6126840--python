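"""Cohort case flow: eligibility, partograph linkage, referral matching.

Reproduces the audit's flow diagram: of all women presenting in labour,
some are admitted (the rest referred onward without admission); among
admitted women, those arriving in active labour at 8 cm dilatation or
less are eligible for partograph-based analysis (beyond 8 cm the woman
is near full dilatation and the chart no longer informs decisions);
among eligible women, charts that were actually initiated are
classified for abnormal-labour indications; finally the referral
register is matched one-to-one to identify which flagged cases were in
fact referred.

Referral reasons unrelated to intrapartum monitoring (maternal general
illness, postpartum haemorrhage, retained placenta, and neonatal
reasons) are beyond the scope of a partograph-based indication: such
rows are retained and marked out of scope, not deleted, and do not
count as referred cases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from partoaudit.completeness import (
    DEFAULT_SCHEDULE,
    cohort_completeness,
    round_half_up,
)
from partoaudit.partograph import Partograph, build_partograph
from partoaudit.records_io import (
    IntrapartumCase,
    MembraneStatus,
    ObservationRow,
    Parity,
    ReasonCode,
    ReferralEntry,
)
from partoaudit.rules import AbnormalityResult, RuleConfig, classify

logger = logging.getLogger(__name__)

#: maximum dilatation on arrival (cm) for partograph-based analysis, inclusive
ELIGIBLE_MAX_DILATATION_CM = 8

OUT_OF_SCOPE_REASONS = frozenset(
    {
        ReasonCode.GENERAL_ILLNESS,
        ReasonCode.PPH,
        ReasonCode.RETAINED_PLACENTA,
        ReasonCode.BIRTH_ASPHYXIA,
        ReasonCode.LOW_BIRTH_WEIGHT,
        ReasonCode.STILLBIRTH,
        ReasonCode.NEONATAL_DEATH,
    }
)


@dataclass(frozen=True)
class ScopeFilter:
    """Referral reasons beyond the scope of a partograph-based indication."""

    out_of_scope_reasons: frozenset[ReasonCode] = OUT_OF_SCOPE_REASONS

    def in_scope(self, reason: ReasonCode) -> bool:
        return reason not in self.out_of_scope_reasons


def filter_eligible(cases: Iterable[IntrapartumCase]) -> list[IntrapartumCase]:
    """Cases admitted with cervical dilatation of 8 cm or less (inclusive)."""
    return [c for c in cases if c.dilatation_on_arrival_cm <= ELIGIBLE_MAX_DILATATION_CM]


@dataclass(frozen=True)
class LinkedReferral:
    case_id: str
    reason_code: ReasonCode
    in_scope: bool
    has_partograph: bool
    flagged: bool


@dataclass
class LinkageResult:
    """Referral register joined to cases and classification results."""

    linked: list[LinkedReferral] = field(default_factory=list)
    n_without_admission: int = 0
    orphans: list[str] = field(default_factory=list)
    n_duplicates_collapsed: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "case_id": r.case_id,
                    "reason_code": r.reason_code.value,
                    "in_scope": r.in_scope,
                    "has_partograph": r.has_partograph,
                    "flagged": r.flagged,
                }
                for r in self.linked
            ],
            columns=["case_id", "reason_code", "in_scope", "has_partograph", "flagged"],
        )


def link_referrals(
    cases: Iterable[IntrapartumCase],
    referrals: Iterable[ReferralEntry],
    scope: ScopeFilter = ScopeFilter(),
    results: Optional[Mapping[str, AbnormalityResult]] = None,
    partographs: Optional[Mapping[str, Partograph]] = None,
) -> LinkageResult:
    """Match referral-register rows one-to-one to admitted cases.

    Rows without a case id are women referred without admission and are
    only counted.  Duplicate register rows for one case collapse to the
    earliest referral event (by referral time, then input order).
    Rows whose case id matches no case record are logged as orphans and
    excluded from counts.
    """
    results = results or {}
    partographs = partographs or {}
    case_ids = {c.case_id for c in cases}
    out = LinkageResult()

    by_case: dict[str, ReferralEntry] = {}
    for entry in referrals:
        if entry.case_id is None:
            out.n_without_admission += 1
            continue
        if entry.case_id not in case_ids:
            logger.warning("referral register row matches no case: %r", entry.case_id)
            out.orphans.append(entry.case_id)
            continue
        prev = by_case.get(entry.case_id)
        if prev is None:
            by_case[entry.case_id] = entry
        else:
            out.n_duplicates_collapsed += 1
            if (
                entry.referral_time is not None
                and (prev.referral_time is None or entry.referral_time < prev.referral_time)
            ):
                by_case[entry.case_id] = entry
            logger.info("collapsed duplicate referral for case %r", entry.case_id)

    for case_id, entry in sorted(by_case.items()):
        result = results.get(case_id)
        chart = partographs.get(case_id)
        out.linked.append(
            LinkedReferral(
                case_id=case_id,
                reason_code=entry.reason_code,
                in_scope=scope.in_scope(entry.reason_code),
                has_partograph=chart is not None and bool(chart.series),
                flagged=result.any_indication if result is not None else False,
            )
        )
    return out


def _pct(x: int, n: int) -> float:
    return round_half_up(100 * x / n) if n else 0.0


def _pct_int(x: int, n: int) -> int:
    return int(round_half_up(100 * x / n, 0)) if n else 0


def _age_band(age: Optional[int]) -> str:
    if age is None:
        return "no_information"
    if age < 20:
        return "15-19"
    if age < 25:
        return "20-24"
    if age < 30:
        return "25-29"
    return "30_plus"


@dataclass
class CohortFlowReport:
    """Counts at every node of the case-flow diagram plus background tables."""

    n_presented: int
    n_admitted: int
    n_referred_without_admission: int
    n_eligible: int
    n_with_partograph: int
    pct_partograph_initiated: int
    n_abnormal_indication: int
    pct_abnormal: int
    pct_admitted: int
    pct_referred_without_admission: int
    n_referred_with_partograph_in_scope: int
    n_referred_with_indication: int
    n_referrals_out_of_scope: int
    indication_counts: dict[str, int]
    background_tables: dict[str, dict[str, dict[str, float]]]
    completeness_table: Optional[pd.DataFrame] = None

    def to_dict(self) -> dict:
        d = {
            "flow": {
                "n_presented": self.n_presented,
                "n_admitted": self.n_admitted,
                "n_referred_without_admission": self.n_referred_without_admission,
                "n_eligible": self.n_eligible,
                "n_with_partograph": self.n_with_partograph,
                "pct_partograph_initiated": self.pct_partograph_initiated,
                "n_abnormal_indication": self.n_abnormal_indication,
                "pct_abnormal": self.pct_abnormal,
                "pct_admitted": self.pct_admitted,
                "pct_referred_without_admission": self.pct_referred_without_admission,
                "n_referred_with_partograph_in_scope": self.n_referred_with_partograph_in_scope,
                "n_referred_with_indication": self.n_referred_with_indication,
                "n_referrals_out_of_scope": self.n_referrals_out_of_scope,
            },
            "indication_counts": dict(self.indication_counts),
            "background_tables": self.background_tables,
        }
        if self.completeness_table is not None:
            d["completeness_table"] = self.completeness_table.where(
                self.completeness_table.notna(), None
            ).to_dict(orient="records")
        return d

    def to_markdown(self) -> str:
        lines = [
            "# Partograph audit report",
            "",
            "## Case flow",
            "",
            f"- Women presented in labour: {self.n_presented}",
            f"- Admitted for childbirth: {self.n_admitted} ({self.pct_admitted}%)",
            f"- Referred without admission: {self.n_referred_without_admission} "
            f"({self.pct_referred_without_admission}%)",
            f"- Admitted with dilatation <= 8 cm (eligible): {self.n_eligible}",
            f"- Partograph initiated: {self.n_with_partograph} "
            f"({self.pct_partograph_initiated}%)",
            f"- At least one abnormal-labour indication: {self.n_abnormal_indication} "
            f"({self.pct_abnormal}%)",
            f"- In-scope referrals among partograph cases: "
            f"{self.n_referred_with_partograph_in_scope}",
            f"- Referred with a charted indication: {self.n_referred_with_indication}",
            f"- Referral rows out of partograph scope: {self.n_referrals_out_of_scope}",
            "",
            "## Indications among abnormal partographs",
            "",
        ]
        for cond, n in self.indication_counts.items():
            lines.append(f"- {cond}: {n}")
        lines += ["", "## Background characteristics of admitted women", ""]
        for table, rows in self.background_tables.items():
            lines.append(f"### {table}")
            lines.append("")
            lines.append("| category | n | % |")
            lines.append("| --- | ---: | ---: |")
            for cat, cell in rows.items():
                lines.append(f"| {cat} | {cell['n']} | {cell['pct']} |")
            lines.append("")
        if self.completeness_table is not None:
            lines.append("## Appropriate recording of partograph components")
            lines.append("")
            df = self.completeness_table
            lines.append(
                "| component | interval (min) | % overall | % abnormal | "
                "% no indication | p-value |"
            )
            lines.append("| --- | ---: | ---: | ---: | ---: | ---: |")
            for row in df.itertuples(index=False):
                p = "-" if pd.isna(row.p_value) else f"{row.p_value:.3f}"
                lines.append(
                    f"| {row.component} | {row.interval_min} | {row.pct_overall} | "
                    f"{row.pct_abnormal} | {row.pct_no_indication} | {p} |"
                )
            lines.append("")
        return "\n".join(lines)


def _background_tables(cases: Sequence[IntrapartumCase]) -> dict:
    n = len(cases)

    def table(categories: list[str], key) -> dict[str, dict[str, float]]:
        counts = {cat: 0 for cat in categories}
        for c in cases:
            counts[key(c)] += 1
        return {cat: {"n": x, "pct": _pct(x, n)} for cat, x in counts.items()}

    facilities = sorted({c.facility for c in cases})
    return {
        "facility": table(facilities, lambda c: c.facility),
        "age_band": table(
            ["15-19", "20-24", "25-29", "30_plus", "no_information"],
            lambda c: _age_band(c.age_years),
        ),
        "parity": table(
            ["nullipara", "multipara", "no_information"],
            lambda c: "no_information" if c.parity is Parity.MISSING else c.parity.value,
        ),
        "dilatation_band": table(
            ["8_cm_or_less", "more_than_8_cm"],
            lambda c: "8_cm_or_less"
            if c.dilatation_on_arrival_cm <= ELIGIBLE_MAX_DILATATION_CM
            else "more_than_8_cm",
        ),
        "membrane_status": table(
            ["ruptured", "intact", "no_information"],
            lambda c: "no_information"
            if c.membrane_status is MembraneStatus.MISSING
            else c.membrane_status.value,
        ),
    }


def build_flow_report(
    cases: Sequence[IntrapartumCase],
    partographs: Mapping[str, Partograph],
    results: Mapping[str, AbnormalityResult],
    linkage: LinkageResult,
    completeness_table: Optional[pd.DataFrame] = None,
) -> CohortFlowReport:
    """Aggregate all pipeline stages into one report.

    ``partographs``/``results`` cover the eligible cases; a chart with
    no observations counts as "partograph not initiated".
    """
    eligible = filter_eligible(cases)
    with_chart = [
        c for c in eligible if c.case_id in partographs and partographs[c.case_id].series
    ]
    abnormal = [c for c in with_chart if results[c.case_id].any_indication]
    chart_ids = {c.case_id for c in with_chart}

    in_scope = [r for r in linkage.linked if r.in_scope and r.case_id in chart_ids]
    n_admitted = len(cases)
    n_presented = n_admitted + linkage.n_without_admission

    indication_counts = {
        "foetal_distress": 0,
        "prolonged_labour": 0,
        "obstructed_labour": 0,
        "preeclampsia": 0,
    }
    for c in abnormal:
        for cond, flag in results[c.case_id].flags().items():
            if cond in indication_counts and flag:
                indication_counts[cond] += 1

    return CohortFlowReport(
        n_presented=n_presented,
        n_admitted=n_admitted,
        n_referred_without_admission=linkage.n_without_admission,
        n_eligible=len(eligible),
        n_with_partograph=len(with_chart),
        pct_partograph_initiated=_pct_int(len(with_chart), len(eligible)),
        n_abnormal_indication=len(abnormal),
        pct_abnormal=_pct_int(len(abnormal), len(with_chart)),
        pct_admitted=_pct_int(n_admitted, n_presented),
        pct_referred_without_admission=_pct_int(linkage.n_without_admission, n_presented),
        n_referred_with_partograph_in_scope=len(in_scope),
        n_referred_with_indication=sum(r.flagged for r in in_scope),
        n_referrals_out_of_scope=sum(not r.in_scope for r in linkage.linked),
        indication_counts=indication_counts,
        background_tables=_background_tables(cases),
        completeness_table=completeness_table,
    )


def run_audit(
    cases: Sequence[IntrapartumCase],
    observations: Sequence[ObservationRow],
    referrals: Sequence[ReferralEntry],
    rule_cfg: RuleConfig = RuleConfig(),
    schedule: Mapping[str, int] = DEFAULT_SCHEDULE,
    scope: ScopeFilter = ScopeFilter(),
    strict_completeness: bool = False,
) -> CohortFlowReport:
    """Run the full audit pipeline on loaded register tables."""
    eligible = filter_eligible(cases)
    by_case: dict[str, list[ObservationRow]] = {}
    for o in observations:
        by_case.setdefault(o.case_id, []).append(o)

    partographs = {
        c.case_id: build_partograph(by_case.get(c.case_id, []), case_id=c.case_id)
        for c in eligible
    }
    results = {cid: classify(p, rule_cfg) for cid, p in partographs.items()}

    charted = [p for p in partographs.values() if p.series]
    completeness = (
        cohort_completeness(charted, results, schedule, strict_completeness)
        if charted
        else None
    )
    linkage = link_referrals(cases, referrals, scope, results, partographs)
    return build_flow_report(cases, partographs, results, linkage, completeness)
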