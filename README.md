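# partoaudit

Audit toolkit for WHO modified-partograph use in low-resource maternity
facilities: it loads intrapartum registers, reconstructs each woman's
partograph, classifies charts for abnormal-labour referral indications,
scores how completely each chart component was plotted, and links the
facility referral register back to the flagged cases.  A built-in
synthetic-cohort generator with known ground truth supports validation
and methodological experiments.

## The scientific problem

The WHO modified partograph is a one-page chart on which birth
attendants plot the active phase of labour (cervical dilatation of
4 cm or more) against time.  Its central device is the **alert line**,
drawn at 1 cm/hour from the first active-phase dilatation plot, and
the **action line**, drawn four hours to its right.  A dilatation plot
that falls to the right of the alert line — or reaches the action
line — signals labour that is progressing too slowly and should prompt
escalation, typically referral from a primary-care facility to a
higher-level hospital.

In practice, partographs at primary facilities are often incompletely
filled in, and referral decisions are often made (or not made) without
regard to what the chart shows.  Auditing this requires answering four
linked questions from routine registers:

1. **Flow** — of the women presenting in labour, how many were
   admitted, how many were eligible for partograph-based monitoring
   (admitted at ≤ 8 cm dilatation), and for how many was a chart
   actually started?
2. **Indications** — which charts show an abnormality that warrants
   referral?  Four rule-based indications are detected:
   - *foetal distress*: foetal heart rate below 120 or above 160
     beats/min on at least two observations, or meconium-stained
     liquor;
   - *prolonged labour*: a dilatation plot right of the alert line or
     reaching the action line;
   - *obstructed labour*: moderate/severe uterine contractions
     together with severe (+++) moulding or arrest of descent of the
     foetal head;
   - *pre-eclampsia*: systolic blood pressure above 140 mmHg or
     diastolic above 90 mmHg, paired with albuminuria.
3. **Completeness** — was each chart component (foetal heart rate,
   contractions, dilatation, descent, liquor, moulding, blood
   pressure, pulse, temperature, urine) plotted at its recommended
   frequency?  Were abnormal labours monitored more completely than
   normal ones?  (Compared with a pooled two-proportion z-test.)
4. **Linkage** — of the cases the chart flags, which were actually
   referred, and which referrals had nothing to do with the chart
   (e.g. postpartum haemorrhage, neonatal causes)?

## Worked example

Simulate a cohort with known ground truth and audit it end to end:

```python
from partoaudit import SimulationParams, simulate_cohort, run_audit

params = SimulationParams(
    n_cases=500, seed=42,
    referral_compliance=0.7,          # P(referral | charted indication)
    out_of_scope_referral_rate=0.03,  # referrals unrelated to the chart
    n_referred_without_admission=60,  # women referred onward at the door
)
cases, obs, refs, truths = simulate_cohort(params)
report = run_audit(cases, obs, refs)
print(report.to_dict()["flow"])
```

prints (exactly, for this seed):

```python
{'n_presented': 560, 'n_admitted': 500, 'n_referred_without_admission': 60,
 'n_eligible': 291, 'n_with_partograph': 291, 'pct_partograph_initiated': 100,
 'n_abnormal_indication': 25, 'pct_abnormal': 9, 'pct_admitted': 89,
 'pct_referred_without_admission': 11, 'n_referred_with_partograph_in_scope': 27,
 'n_referred_with_indication': 19, 'n_referrals_out_of_scope': 9}
```

So 560 women presented; 500 were admitted (89 %) and 60 referred
without admission (11 %).  291 were admitted at ≤ 8 cm and therefore
eligible; all 291 had a chart; 25 charts (9 %) showed an abnormal
indication (18 foetal distress, 8 prolonged labour, with one overlap),
and 19 of the flagged cases appear in the referral register.  The
completeness table reports, per component, the percentage of charts
plotted at the recommended frequency, split by abnormal versus
no-indication charts with a two-proportion test — for this seed the
blood-pressure row is `pct_abnormal = 20.0` vs
`pct_no_indication = 6.0`, `p = 0.0098`:

```python
print(report.completeness_table.to_string(index=False))
```

The same pipeline runs from the command line on CSV registers:

```sh
partoaudit simulate --seed 42 --n-cases 500 --out data/
partoaudit audit --cases data/cases.csv --obs data/partograph_obs.csv \
    --referrals data/referrals.csv --out out/
# out/report.json, out/report.md, out/completeness_table.csv
partoaudit classify --obs data/partograph_obs.csv --out out/flags.csv
```

A deterministic reference cohort mirroring a realistic facility audit
is also available:

```python
from partoaudit.simulate import make_reference_fixture
cases, obs, refs = make_reference_fixture()
run_audit(cases, obs, refs).to_dict()["flow"]
# {'n_presented': 1548, 'n_admitted': 1198, 'n_referred_without_admission': 350,
#  'n_eligible': 663, 'n_with_partograph': 648, 'pct_partograph_initiated': 98,
#  'n_abnormal_indication': 71, 'pct_abnormal': 11, 'pct_admitted': 77,
#  'pct_referred_without_admission': 23, 'n_referred_with_partograph_in_scope': 5,
#  'n_referred_with_indication': 1, 'n_referrals_out_of_scope': 3}
```

## Package layout

| Module | Role |
| --- | --- |
| `partoaudit.records_io` | CSV schemas, validation, round-trip readers/writers |
| `partoaudit.partograph` | alert/action line geometry, per-case chart assembly |
| `partoaudit.rules` | the four referral-indication detectors with evidence |
| `partoaudit.completeness` | plotting-frequency audit, two-proportion z-test |
| `partoaudit.flow` | eligibility, referral linkage, the full audit report |
| `partoaudit.simulate` | synthetic cohorts with ground truth; reference fixture |
| `partoaudit.cli` | `partoaudit simulate / classify / audit` |

See `docs/methods.md` for the model, parameter defaults, generator
semantics and numerical conventions.
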