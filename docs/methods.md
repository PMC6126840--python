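# Methods

This document records the model implemented by `partoaudit`, every
parameter default with its rationale, what the synthetic-cohort
generator does and does not emulate, and the numerical conventions
that shape edge-case behaviour.

## 1. Chart model

A partograph is represented as a per-case mapping from **component**
to a time-sorted series of `(t_min, value)` pairs, where `t_min` is
the integer number of minutes since facility admission.  Thirteen
components are recognised: `fhr`, `liquor`, `moulding`, `dilatation`,
`descent`, `contraction_freq`, `contraction_duration`, `sbp`, `dbp`,
`pulse`, `temperature`, `urine_volume`, `urine_albumin`.  Numeric
components carry `value_num`; categorical components carry a
`value_code` drawn from a fixed coded domain (e.g. liquor ∈
{I, C, M, B, A}; moulding ∈ {0, +, ++, +++}; albumin ∈
{neg, trace, plus1, plus2, plus3}).  Exactly one of the two value
fields must be populated per row; violations are rejected row-wise
with a reason, never silently dropped.

### Alert and action lines

The active phase starts at 4 cm cervical dilatation.  The **anchor**
of a chart is the earliest dilatation plot with value ≥ 4 cm; charts
with no such plot have undefined line geometry and can never be
flagged for prolonged labour.  From anchor `(t0, d0)`:

* alert line: `alert_time(d) = t0 + 60 · (d − d0)` minutes
  (1 cm/hour);
* action line: `alert_time(d) + 240` minutes (four hours to the
  right).

A plot `(t, d)` is **right of the alert line** iff `t > alert_time(d)`
(strict: a plot exactly on the line is normal progress) and **reaches
the action line** iff `t ≥ alert_time(d) + 240` (inclusive: reaching
the line is already the escalation criterion).  `alert_time` is
undefined for `d` below the anchor dilatation and raises.

## 2. Referral-indication rules

Each detector returns a boolean plus the evidence rows that triggered
it.  All threshold comparisons are strict, matching protocol wording
("less than 120", "more than 160", "more than 140/90").

| Condition | Definition (defaults) |
| --- | --- |
| foetal distress | FHR < 120 or > 160 on ≥ 2 observations (any two; a consecutive-run mode is available), **or** any meconium-stained liquor (`M`) |
| prolonged labour | any active-phase dilatation plot right of the alert line or reaching the action line |
| obstructed labour | ≥ 1 moderate/severe contraction-duration code ({`s20to40`, `gt40s`}) **and** (severe `+++` moulding **or** a descent plateau: ≥ 2 consecutive descent observations with no decrease in fifths palpable) |
| pre-eclampsia | a systolic/diastolic pair sharing a `t_min` with sbp > 140 or dbp > 90, **and** urinary albumin ∈ {plus1, plus2, plus3} (trace excluded by default, configurable) |

Interpretation switches live in `RuleConfig`
(`fhr_require_consecutive`, `include_trace_albumin`, thresholds,
`descent_plateau_min_obs`); defaults encode the protocol readings and
the clinical convention that trace albuminuria does not count as
"presence of albumin".

**Monotonicity caveat.**  Adding observations to a chart never clears
a foetal-distress, obstructed-labour or pre-eclampsia flag (no rule
has an exculpatory clause).  The same is *not* true of prolonged
labour: adding an earlier active-phase dilatation plot moves the
anchor and with it the whole alert line, which can legitimately flag
or un-flag later plots.  Example: {(0 min, 4 cm), (60, 8), (200, 9)}
is unflagged, but deleting the first plot re-anchors at (60, 8) and
makes (200, 9) fall right of the new alert line.  The property tests
therefore hold dilatation rows fixed when exercising monotonicity.

## 3. Completeness audit

Each component has a recommended plotting interval:

| interval | components |
| --- | --- |
| 30 min | fhr, contraction_freq, pulse |
| 120 min | temperature, urine_volume, urine_albumin |
| 240 min | liquor, moulding, dilatation, descent, bp |

`bp` is a composite: a BP "plot" exists at the times where both `sbp`
and `dbp` were recorded.  Protocol sources are not unanimous on the BP
interval (half-hourly appears in some tabulations, four-hourly in the
accompanying prose); the package defaults to **240 min** and the
schedule is a plain dict argument, so either reading is one line of
configuration away.

A chart is **complete** for a component (default, lenient reading) if
it has ≥ 2 plottings and at least one adjacent pair is ≤ the interval
apart; `strict=True` requires *every* gap ≤ the interval.  Cohort
output is a table of completeness percentages overall and split
abnormal vs no-indication, with a pooled two-proportion z-test per
row.

### Two-proportion test

For counts `x1/n1` vs `x2/n2`, pooled `p = (x1+x2)/(n1+n2)`,
`z = (p1 − p2) / sqrt(p(1−p)(1/n1 + 1/n2))`, two-sided p-value
`2·Φ(−|z|)` with no continuity correction.  When the pooled proportion
is 0 or 1 the statistic is degenerate and the result carries
`p_value = NaN` (rendered "–" in CSV output).  The closed form is
cross-checked in the tests against `statsmodels.stats.proportion.
proportions_ztest` and against `z² = χ²` from
`scipy.stats.chi2_contingency` (no correction, 1 df).

### Rounding

All reported percentages use decimal **round-half-up**
(`decimal.Decimal` with `ROUND_HALF_UP`): one decimal place in
completeness tables, whole percent in flow counts.  Banker's rounding
(`round()`) is deliberately avoided so that printed tables match
hand-computed values.

## 4. Case flow and referral linkage

* **Eligibility**: admitted at cervical dilatation ≤ 8 cm
  (inclusive); beyond 8 cm the woman is near full dilatation and the
  chart no longer informs a referral decision.
* **Flow nodes**: presented = admitted + referred-without-admission;
  eligible ⊆ admitted; charted ⊆ eligible; abnormal ⊆ charted.  All
  identities are asserted in tests on random cohorts.
* **Referral linkage**: register rows are matched one-to-one to case
  ids.  Rows with no case id are women referred onward without
  admission (counted only).  Duplicate rows for one case collapse to
  the earliest referral time.  Orphan rows (unknown case id) are
  logged and excluded.  Reasons unrelated to intrapartum monitoring —
  maternal general illness, postpartum haemorrhage, retained placenta,
  birth asphyxia, low birth weight, stillbirth, neonatal death — are
  marked *out of scope* rather than deleted and never count as a
  chart-driven referral.  The scope set is configurable
  (`ScopeFilter`).
* Background tables (facility, age band, parity, dilatation on
  arrival, membrane status) are reported as percentages of admitted
  cases; age bands are 15–19, 20–24, 25–29, 30+, with missing age as
  `no_information`.

## 5. Synthetic-cohort generator

### What it emulates

Each case draws an admission dilatation, a labour trajectory
(dilatation advancing at a per-case rate), and a condition profile,
then charts observations on the component grid above, thinned by
per-component charting probabilities.  Conditions plant
clinically coherent evidence:

* *prolonged labour*: slow trajectory (0.4 cm/h) that falls right of
  the alert line;
* *foetal distress*: a three-reading run at 105 or 175 beats/min
  (normal readings are clipped to [121, 159] so only planted runs can
  trigger the rule);
* *obstructed labour*: moderate/severe contraction codes plus severe
  moulding always; arrest of descent additionally when the labour is
  long enough to have two 240-min descent plots;
* *pre-eclampsia*: a hypertensive sbp/dbp pair plus positive albumin.

Referral behaviour is simulated separately: a flagged case is referred
with probability `referral_compliance`; out-of-scope referrals and
referred-without-admission rows are added independently.

### Determinism

Every case uses its own NumPy substream
`np.random.default_rng([seed, case_index])`; referral noise uses
`[seed, 999_983]`.  Regenerating with the same `SimulationParams`
yields byte-identical CSVs.  Thinning draws one uniform per due
interval regardless of the probability level, so lowering a charting
probability deterministically removes (never adds) observations — the
dropout-monotonicity tests rely on this coupling.

### Parameter defaults

| parameter | default | rationale |
| --- | --- | --- |
| condition prevalence | foetal distress 0.068, prolonged labour 0.031, obstructed 0.006, pre-eclampsia 0.005 | orders of magnitude typical of primary-facility audits where foetal distress dominates |
| admission dilatation | {3: .05, 4: .10, 5: .12, 6: .12, 7: .08, 8: .08, 9: .25, 10: .20} | roughly half of arrivals beyond 8 cm, matching late-presentation patterns at primary facilities |
| normal dilatation rate | N(1.2, 0.3) cm/h, clipped at ≥ 1.0 | clip guarantees a normal trajectory, plotted at integer cm on the 240-min grid, can never fall right of the alert line (provable: round(x) ≥ L for x ≥ L with integer L), so false prolonged-labour flags are impossible |
| prolonged rate | 0.4 cm/h | at the anchor + 240 min the plot is ≤ anchor + 3 cm while the line requires anchor + 4 cm, so the flag always fires |
| monitoring cap | 720 min | a chart page's practical span |
| charting probabilities | per component, 0.10 (pulse) – 0.90 (urine albumin) | wide spread so completeness contrasts are visible; an empty map means full charting |

### What it does not emulate

Inter-observer measurement error, second-stage and postpartum events,
twin pregnancies, augmentation/intervention effects on the trajectory,
facility-level clustering of practice quality, and informative
missingness (charting probability is independent of the values
observed, except that planted abnormal evidence for a case's assigned
condition is always charted so ground truth stays recoverable).

## 6. Reference fixture

`make_reference_fixture()` builds, deterministically and without
random draws, a 1 548-woman cohort shaped like a realistic
multi-facility audit: 1 198 admitted (77 %), 350 referred without
admission (23 %), 663 eligible at ≤ 8 cm, 648 charted (98 %), 71
charts abnormal (11 %) with indication mix 44 foetal distress /
20 prolonged labour / 4 obstructed / 3 pre-eclampsia, five in-scope
referrals of which one was flagged, and three out-of-scope referrals.
The indication counts are constructed as **non-overlapping** (each
abnormal chart carries exactly one condition); real charts can carry
several, and the classifier handles overlap — the fixture simply does
not exercise it.  Background marginals (facility, age, parity,
membranes, dilatation) are apportioned by largest remainder so each
table sums exactly to the admitted count.

## 7. Numerical conventions and limitations

* Times are integer minutes since admission; timestamps in files are
  ISO-8601.  No timezone handling (single-facility clock assumed).
* Strict vs inclusive inequalities: right-of-alert strict, reach-action
  inclusive, eligibility ≤ 8 inclusive, FHR/BP thresholds strict.
* Duplicate case ids and admitted referrals without a case id are hard
  schema errors; other invalid rows become per-row rejects with
  messages.
* Problem sizes used in the benchmark script (2 000-case recovery
  cohorts, a 200-case fully-charted long-labour cohort) are this
  package's own choices, sized so sampling error (≈ ±1.4 percentage
  points at 11 % prevalence, n = 2 000) stays well inside the reported
  bands.
* The completeness score is a proxy: it measures plotting frequency,
  not plotting accuracy, and the lenient default rewards one good
  interval per chart.
* The rule engine classifies what was *charted*; an uncharted abnormal
  labour is invisible to it, which is precisely the gap the
  completeness audit is meant to expose.
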