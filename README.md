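# aecap — adverse-event capture for cancer trials

`aecap` is a desk-scale reimplementation of the computational core of an
adverse-event (AE) capture system for oncology clinical trials: automated
CTCAE toxicity grading of laboratory results, HL7 v2 ORU-R01 ingestion,
an AE lifecycle with per-visit assessment and deduplication, and AE
document/export generation. Everything runs locally on synthetic data —
no interface engine, EHR, or database server is required.

It is aimed at clinical research informaticists and trial-safety teams who
want a testable, scriptable model of the lab-grading and AE-assessment
workflow, and at developers who need a reference implementation with exact,
machine-checkable semantics.

## The grading model

A numeric lab value *v* is graded relative to its reference range
[LLN, ULN] (lower/upper limit of normal):

* *v* < LLN → **low** direction; *v* > ULN → **high** direction; otherwise
  **normal** (grade 0). Equality with a limit is normal — the inequalities
  are strict.
* Each gradeable lab type carries up to two directional rules, each naming
  its own CTCAE term and MedDRA code. Potassium (K, LLN 3.5 / ULN 5.1
  mEq/L) has two AEs: *Hypokalemia* (MedDRA 10021018) below LLN and
  *Hyperkalemia* (MedDRA 10020647) above ULN.
* A rule is an ordered list of severity bands mapping value intervals to
  CTCAE grades 1–4, written the way CTCAE prints them (`<LLN – 3.0`,
  `>ULN – 5.5`). Bands are half-open toward severity: low-direction bands
  are `[lower, upper)` and high-direction bands `(lower, upper]`, so the
  printed numeric bound is always inclusive. Grade 0 means no band
  matched; grade 5 (death) is never assigned numerically.
* Grades attainable only with clinical information (symptomatic,
  hospitalization, life-threatening) are declared *context-dependent*; the
  engine surfaces them as a `needs_clinical_info` flag, never as a number.
  Clinician overrides are recorded alongside — never instead of — the
  automatic grade.

Out-of-range values with no applicable rule are retained as
out-of-range-ungradeable and forwarded to the workflow, as are grade-0
results. The shipped demonstration rule table covers 28 lab types.

Downstream, graded results auto-create lab-source AEs (one ongoing AE per
participant, study and term — repeat abnormals update the grade instead of
duplicating), visit assessments must evaluate every ongoing AE before a
provider can finalize them against an encounter CSN, and unfinalized work
older than 24 hours emits reminder records.

## Worked example

```python
from datetime import datetime
from aecap import default_catalog, default_rules, default_ranges, grade_result
from aecap.hl7io import LabResult

catalog = default_catalog()
rules = default_rules(catalog)
ranges = default_ranges()

for value in (3.3, 5.3, 4.2, 2.4):
    result = LabResult("MSG1", "MRN001", "K", value, "mEq/L",
                       datetime(2014, 3, 3), reference_range=(3.5, 5.1))
    g = grade_result(result, rules, ranges, catalog)
    print(value, g.direction, g.numeric_grade, g.ae_term_id,
          g.meddra_code, g.needs_clinical_info)
```

prints

```
3.3 low 1 hypokalemia 10021018 True
5.3 high 1 hyperkalemia 10020647 False
4.2 normal 0 None None False
2.4 low 4 hypokalemia 10021018 False
```

K = 3.3 mEq/L is below LLN 3.5, so it grades as hypokalemia grade 1
(band `3.0 ≤ v < LLN`); the `True` flag notes that grade 2 for this term
is symptomatic-only, so clinical information could raise the final grade.
K = 5.3 exceeds ULN 5.1 and grades as hyperkalemia grade 1; 4.2 is normal;
2.4 falls in the most severe hypokalemia band (`v < 2.5`, grade 4).

The same engine is scriptable from the shell:

```bash
aecap simulate --seed 7 --out sim/          # registry CSVs, labs.hl7, truth.csv
aecap init-state --registry sim --state state.json
aecap labs ingest --state state.json --hl7 sim/labs.hl7
aecap reminders --state state.json --now 2014-03-10T00:00:00
aecap report --state state.json --study S001 --format csv --out aes.csv
```

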