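import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracle module

from partoaudit.records_io import Component, ObservationRow
from partoaudit.simulate import make_reference_fixture

NUMERIC_CHOICES = {
    "fhr": list(range(100, 181, 5)),
    "dilatation": list(range(0, 11)),
    "descent": list(range(0, 6)),
    "sbp": list(range(100, 181, 5)),
    "dbp": list(range(60, 111, 5)),
}
CODED_CHOICES = {
    "liquor": ["I", "C", "M", "A", "B"],
    "moulding": ["0", "+", "++", "+++"],
    "contraction_duration": ["lt20s", "s20to40", "gt40s"],
    "urine_albumin": ["neg", "trace", "plus1", "plus2", "plus3"],
}
_COMPONENTS = list(NUMERIC_CHOICES) + list(CODED_CHOICES)


def random_chart_rows(rng: np.random.Generator, max_obs: int = 20):
    """A random small chart as (component, t_min, value) tuples.

    Times are distinct within each component so ordering is
    unambiguous.
    """
    rows = []
    n = int(rng.integers(0, max_obs + 1))
    counts: dict[str, list[int]] = {}
    grid = list(range(0, 631, 30))
    for _ in range(n):
        comp = str(rng.choice(_COMPONENTS))
        used = counts.setdefault(comp, [])
        free = [t for t in grid if t not in used]
        if not free:
            continue
        t = int(rng.choice(free))
        used.append(t)
        if comp in NUMERIC_CHOICES:
            v: object = float(rng.choice(NUMERIC_CHOICES[comp]))
        else:
            v = str(rng.choice(CODED_CHOICES[comp]))
        rows.append((comp, t, v))
    return rows


def to_observation_rows(rows, case_id="X"):
    out = []
    for comp, t, v in rows:
        if isinstance(v, str):
            out.append(ObservationRow(case_id, Component(comp), t, value_code=v))
        else:
            out.append(ObservationRow(case_id, Component(comp), t, value_num=v))
    return out


@pytest.fixture(scope="session")
def reference_cohort():
    return make_reference_fixture()
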