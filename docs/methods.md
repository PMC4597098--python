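# Methods

## Scope and model

`aecap` models the computational path of an adverse-event capture system
for cancer trials: laboratory results arrive as HL7 v2 ORU-R01 messages,
are filtered to registered study participants, graded against CTCAE-style
rules relative to each result's reference range, and fed into an AE
lifecycle that enforces deduplication, per-visit assessment completeness,
provider-only finalization, and 24-hour reminders. Documents and
case-report exports are generated from the resulting state. External
services of a production deployment (interface engine, EHR bridges,
authentication, e-mail transport, regulatory reporting channels) are
deliberately absent; their contracts are represented by files, records,
and injected components.

## Grading semantics

**Direction.** For a value *v* and range [LLN, ULN]: low iff *v* < LLN,
high iff *v* > ULN, normal otherwise. Inequalities are strict, so equality
with a limit is normal. The range attached to the result's own OBX-7
segment takes precedence over configured defaults, because laboratories
report instrument-specific ranges.

**Bands.** CTCAE prints lab criteria as intervals anchored at the limits
(`<LLN – 3.0`, `>ULN – 5.5`). We encode them half-open toward severity:
low-direction bands are `[lower, upper)` and high-direction bands
`(lower, upper]`, making the printed numeric bound inclusive (a potassium
of 3.0 is still grade 1 under `<LLN – 3.0`) and the limit itself excluded
(it is normal). Bands within a rule must be contiguous and non-overlapping
in order of increasing severity; the loader rejects violations. Grade 0 is
the absence of a matching band; grade 5 is never numerically assignable.
A rule may additionally declare *context-dependent* grades (e.g.
"symptomatic" grade 2 for hypokalemia): whenever such a grade exceeds the
assigned numeric grade, the result carries `needs_clinical_info=True`. A
rule composed purely of clinical bands can be flagged `clinical_only`, in
which case even in-range values are flagged for review.

**Units.** Units are compared case-insensitively after light
normalization; the single accepted equivalence is mEq/L ≡ mmol/L for
monovalent ions (K, Na, Cl, Li), where the two scales are numerically
identical. Any other disagreement marks the result ungradeable with an
explicit unit-mismatch flag — never a silent conversion.

**Shipped tables.** The package ships a demonstration rule table covering
28 lab types (six of them with dual low/high rules naming distinct AE
terms) and matching reference-range defaults. The potassium limits, terms,
and MedDRA v12.0 codes are the canonical worked example; the remaining
bands are CTCAE v4-consistent demonstration content authored for this
package, structured identically to what a site would supply. The term
catalog (~46 entries over five organ systems, CTCAE v4 plus two v3
entries) is likewise a demonstration subset; full vocabularies use the
same CSV schema.

## Catalog categorization

A term is a *diagnosis* exactly when it carries a non-empty ICD-9 code,
otherwise a *symptom*; blank cells in tabular sources count as absent.
Diagnosis lists are grouped under clinical subheadings (alphabetical,
terms without a subheading last) with names alphabetical within a group;
symptom lists are flat and alphabetical. Terms are never deduplicated
across CTCAE versions: a v3 and a v4 entry with the same name are
distinct.

## Lifecycle rules

* At most one *ongoing* AE per (participant, study, term). Creation
  against an ongoing episode fails, naming the blocking AE. A resolved
  term may recur as a new episode with its own onset and history.
* A lab result re-grading an ongoing same-term AE updates its grade with
  a history entry rather than erroring; the intent of the deduplication
  rule is one record per episode. Because messages can arrive out of
  order, the history date of such an update is clamped to be no earlier
  than the previous entry, keeping histories chronological.
* One open assessment per participant+study; it opens pre-populated with
  every ongoing AE, `pending_items` is the not-yet-evaluated subset (the
  UI notion of red-framed items), and finalization is atomic: all
  evaluations are validated first, applied under a snapshot that is
  restored on any mid-commit failure, and the assessment becomes
  immutable afterward.
* Finalizing/signing requires an authorized provider (deny-by-default
  access control) and an encounter CSN belonging to the participant.
* Reminders: any open assessment or unsigned lab document older than the
  24-hour threshold emits one reminder record per re-reminder interval
  (default 24 h, configurable). The clock is injected everywhere; no
  logic reads the wall clock.

## Synthetic data

The generator emulates the *input side* of the system: a registry
(studies with one investigational agent each, provider/nurse/coordinator
per study, participants with unique 8-digit MRNs enrolled in one or
occasionally two studies, encounters with unique CSNs), an HL7 ORU stream,
and visit scenarios with pre-existing ongoing AEs.

Lab generation is **truth-table first**: per result the intended grade is
sampled before the value. With probability `abnormal_rate` (default 0.3) a
rule and a band are chosen — band choice weighted by `severity_mix`
(default 0.4/0.25/0.2/0.15 for grades 1–4, renormalized over the grades
the rule defines) — and the value is drawn strictly inside the band;
otherwise the value is drawn inside the normal range. Values are rounded
to 3 decimals after sampling with an interior margin of
`max(0.05·span, 0.002)`, so rounding can never push a value across a band
boundary; unbounded severe sides are truncated to a finite window of half
the bound's magnitude (at least 1 unit). The emitted truth table therefore
states the exact expected direction and grade of every observation, making
end-to-end validation of the pipeline exact rather than statistical. One
seed drives three independent sub-streams (registry, labs, visits) via
`numpy.random.SeedSequence.spawn`, so runs are fully reproducible and the
streams do not perturb each other.

What the generator does **not** model: physiology or longitudinal lab
trajectories, analyzer-specific reference ranges or units, free-text or
coded non-numeric results beyond a skipped-observation path, message
corruption, or realistic AE incidence. Passing tests therefore
demonstrate the correctness of the grading/lifecycle machinery under
well-formed inputs, not clinical performance on real feeds.

## Problem sizes and numerical choices

The test suite validates the pipeline on 1,000 truth-labeled results over
20 participants and 3 studies, exercises the lifecycle with 10,000
randomized operations (invariants checked every 500), and compares the
band-lookup engine against an exhaustive linear-scan oracle on 10,000
random values per rule, drawn uniformly over a window extending five
range-widths beyond each limit. Percentage metrics (share of data queries
that are AE-related) round half-up to an integer, reproducing 69% for
73 of 106 queries. HL7 timestamps are written as `YYYYMMDDHHMMSS`; ranges
in OBX-7 must be `low-high` — any other syntax is treated as absent
rather than guessed at.

## Known limitations

* The HL7 reader is a tolerant subset (MSH/PID/PV1/OBR/OBX, default
  encoding characters); escape sequences and repetition separators are
  not interpreted.
* MedDRA codes outside the potassium pair are demonstration fixtures;
  sites must supply licensed vocabularies for production use.
* Attribution is a free-text (agent, relatedness) pair; seriousness,
  expectedness, and action-taken attributes are not modeled.
* The embedded store is a whole-state JSON snapshot — appropriate at desk
  scale, not for concurrent multi-user operation.
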