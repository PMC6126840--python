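"""Brute-force abnormal-labour oracle, independent of the package internals.

Applies the four referral-indication clauses literally to a flat list of
``(component, t_min, value)`` tuples, with no shared code with
``partoaudit.rules`` or ``partoaudit.partograph``.  Used to cross-check
the rule engine on randomly generated charts.
"""

from __future__ import annotations


def _series(rows, component):
    return sorted(((t, v) for comp, t, v in rows if comp == component), key=lambda tv: tv[0])


def oracle_foetal_distress(rows) -> bool:
    fhr = _series(rows, "fhr")
    n_bad = sum(1 for _, v in fhr if v < 120 or v > 160)
    meconium = any(v == "M" for _, v in _series(rows, "liquor"))
    return n_bad >= 2 or meconium


def oracle_prolonged_labour(rows) -> bool:
    dil = _series(rows, "dilatation")
    anchor = next(((t, int(v)) for t, v in dil if v >= 4), None)
    if anchor is None:
        return False
    t0, d0 = anchor
    for t, v in dil:
        if t < t0 or v < d0:
            continue
        alert = t0 + (int(v) - d0) * 60
        if t > alert or t >= alert + 240:
            return True
    return False


def oracle_obstructed_labour(rows) -> bool:
    moderate = any(
        v in ("s20to40", "gt40s") for _, v in _series(rows, "contraction_duration")
    )
    if not moderate:
        return False
    severe_moulding = any(v == "+++" for _, v in _series(rows, "moulding"))
    descent = [v for _, v in _series(rows, "descent")]
    plateau = any(b >= a for a, b in zip(descent, descent[1:]))
    return severe_moulding or plateau


def oracle_preeclampsia(rows) -> bool:
    sbp = dict(_series(rows, "sbp"))
    dbp = dict(_series(rows, "dbp"))
    hypertensive = any(sbp[t] > 140 or dbp[t] > 90 for t in set(sbp) & set(dbp))
    albumin = any(
        v in ("plus1", "plus2", "plus3") for _, v in _series(rows, "urine_albumin")
    )
    return hypertensive and albumin


def oracle_classify(rows) -> dict[str, bool]:
    flags = {
        "foetal_distress": oracle_foetal_distress(rows),
        "prolonged_labour": oracle_prolonged_labour(rows),
        "obstructed_labour": oracle_obstructed_labour(rows),
        "preeclampsia": oracle_preeclampsia(rows),
    }
    flags["any_indication"] = any(flags.values())
    return flags
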