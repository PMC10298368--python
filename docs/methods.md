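# Methods

## Scope and model

`refluxdx` implements deterministic, rule-based classification — no fitted
parameters, no learned models. Its scientific content is (i) the Chicago
Classification 3.0 decision hierarchy over high-resolution manometry
metrics, (ii) the GERD phenotyping cascade over endoscopy + ambulatory
pH-impedance findings, and (iii) the windowed symptom–reflux association
statistics (SI, SAP, SSI). All classification is a pure function of the
inputs and an explicit configuration object, and every decision returns an
ordered trace of the rules that fired, so a reviewing physician can audit
why a label was produced.

## CC 3.0 engine (`refluxdx.hrm`)

Per-swallow scoring uses the consensus metric cutoffs, all exposed in
`Cc30Config`:

| parameter | default | unit | meaning |
|---|---|---|---|
| `dci_failed` | 100 | mmHg·s·cm | below: failed swallow |
| `dci_weak` | 450 | mmHg·s·cm | below (and ≥ failed): weak |
| `dci_hyper` | 8000 | mmHg·s·cm | above: hypercontractile |
| `dl_premature` | 4.5 | s | below (with DCI ≥ 450): premature |
| `break_large_cm` | 5 | cm | above (with DCI ≥ 450): fragmented |
| `irp_uln` | 15 | mmHg | median-IRP upper limit of normal |
| `frac_premature/pep/hyper` | 0.20 | — | study-level fraction gates |
| `frac_ineffective/fragmented` | 0.50 | — | study-level fraction gates |

Decisions that were genuinely open and how they were fixed:

* **Premature requires vigor.** A swallow with DL < 4.5 s but DCI < 450 is
  scored failed/weak, not premature: a premature contraction is defined on
  a measurable contraction.
* **Tie between spastic and pressurization features under elevated IRP.**
  When both the premature fraction and the PEP fraction meet their gates,
  type III achalasia wins — the spastic feature is the more specific
  finding. The firing order is recorded in the trace.
* **Boundary conventions.** Median IRP exactly at the ULN counts as
  elevated (≥); fraction gates are ≥; "all failed" means strictly 100%.
* **IEM before fragmented peristalsis.** A study meeting both the ≥50%
  ineffective and ≥50% fragmented gates is labelled IEM.
* **Median** for an even swallow count is the mean of the two central order
  statistics.

Classification is order-invariant and total: every valid study maps to
exactly one of the ten labels (property-tested by fuzzing).

## Symptom association (`refluxdx.association`)

The recording [0, T) is split into consecutive windows (default 120 s; the
final partial window is kept). A window is reflux-positive when any episode
interval (half-open) overlaps it, and symptom-positive when a
reflux-associated symptom onset falls in it, where a symptom is
reflux-associated if an episode overlaps the closed window
[onset − 120 s, onset]. SAP uses the upper-tail Fisher exact probability
P(X ≥ a) on the resulting 2×2 table, computed with the hypergeometric
survival function; the test suite verifies it against exact integer
enumeration for every table with total ≤ 60 (tolerance 1e-12, observed
agreement ≈ 4e-16).

Degenerate inputs produce absent statistics, not zeros: SI and SAP are
undefined without symptoms, SSI without episodes. Meal periods can be
supplied as masked intervals whose windows are dropped (default: none).
One caveat documented deliberately: SI and SSI are invariant under a time
shift of all events, but SAP is not exactly so, because a shift extends the
recording and adds symptom- and reflux-negative windows to the table; the
tests therefore assert invariance of SI/SSI and of the three informative
cells under window-aligned shifts.

## GERD phenotyping (`refluxdx.gerd`)

Cascade order: endoscopy → acid exposure → symptom association. Defaults in
`GerdConfig`: AET cutoff 4.0% (the pre-Lyon convention of a 2017-era
system; at-cutoff counts as abnormal), impedance episode count pathologic at
≥ 80 and borderline at 40–79, SAP positive at ≥ 95%, SI at ≥ 50%, and the
association rule `sap-or-si` (either index suffices; `sap-only` and
`si-only` are selectable since the choice of index is site policy). A
negative endoscopy without pH monitoring cannot be phenotyped and raises
`insufficient-data` rather than guessing. On/off-PPI status is carried as
metadata only.

The six combined pH/impedance report categories partition the status grid:
"pathological acid reflux" replaces "pH pathologic & impedance normal"
when acid-type episodes dominate (> half of the total count, requiring the
optional `acid_episode_count` field), and borderline impedance with normal
pH maps to "both normal", since borderline alone is not pathologic.

## Report mining (`refluxdx.report`)

The 48-parameter canonical record is defined entirely by a schema data file
(`data/schema_48.yaml`): 9 acid-exposure parameters, 12 impedance episode
counts (4 chemistries × total/upright/recumbent), 3 proximal-extent counts,
3 bolus-exposure percentages, 3 median bolus-clearance times, 12 symptom
analysis values (count/SI/SAP/SSI for 3 symptom groups), 4 study-metadata
values, 2 composites. The published description of the source system gives
only the parameter count, not the list, so this schema is a documented
stand-in with the correct cardinality and realistic content; other report
dialects can be described in data without code changes, which is why the
schema class itself does not hard-code 48.

Parsing normalizes case, diacritics, and whitespace, accepts decimal commas
(Turkish/Dutch locale exports), keeps the first occurrence of a duplicated
key, and never fails on copy-paste noise — unknown lines become issues. The
renderer emits floats in shortest round-trip representation, so
parse ∘ render is exact identity on complete records (property-tested over
100 seeds).

## Synthetic data (`refluxdx.simulate`)

The generator replaces the source registry, which is not publicly
deposited. It emulates *metric-level* data only: per-swallow HRM numbers,
endoscopy grades, pH-impedance summaries, and reflux/symptom event streams
over a 24-h recording — not pressure topography, raw pH traces, or
realistic inter-metric correlation. Passing round-trip tests therefore
demonstrate that the rule engines implement their stated logic exactly, not
that the package would reach any particular accuracy on real tracings.

Sampling ranges keep ≥ 20% margin from every decision threshold (e.g.
failed DCI in [0, 80] vs the 100 cutoff, elevated IRP in [18, 30] vs 15);
fraction-gated branches use 3/10 swallows against the 0.20 gate and 7/10
against 0.50. GERD cases for reflux hypersensitivity couple every symptom
30 s after an episode onset (realized SI = 100, SAP > 95 at the generated
8–14 symptoms over 24 h); functional-heartburn cases place all symptoms
> 10 min clear of any episode (SI = 0, SAP = 0). Cohort generation expands
per-label margins (sex counts plus age-band counts, as printed registry
tables provide them) by positional pairing — the unpublished joint
sex × age cells are not modeled — with ages sampled uniformly within bands.
Determinism: a single master seed streams through named per-patient
sub-generators, so output is byte-identical for a given spec + seed.

## Summaries and agreement (`refluxdx.summary`)

Percentage shares round half away from zero, matching the printed registry
tables; the female-excess statistic is 100 × (F − M) / label total, the
only denominator convention consistent with the published 43%
(functional heartburn) and 35% (type II achalasia) values, and it is
sign-symmetric (negative = male excess). Agreement between system and
reference labels reports accuracy and macro-averaged precision/recall/F1 as
percentages. The bundled questionnaire catalog reports computed column
sums; its transcribed per-row cells sum to 652,127 data items, which is
what the implementation reports for that column.

## Problem sizes and verification

The default test run exercises: the full fixture cohorts (2052 and 133
patients), exhaustive Fisher verification over all 635,375 tables with
total ≤ 60, 10,000 fuzzed manometry studies, 200 manometry and 200 GERD
generator→classifier round-trips, and 100 report round-trips — about half a
minute end to end. `scripts/acceptance.py` recomputes the headline
quantities at the same sizes.

## Known limitations

* CC 4.0 (positional maneuvers, provocative swallows) is out of scope, as
  are raw pressure-matrix and pH-trace processing.
* The phenotype cascade does not model a borderline acid-exposure band; the
  borderline impedance status appears only in the report categories.
* The synthetic cohorts reproduce margins, not joint distributions, and no
  physiological covariance between HRM, endoscopy, and pH findings.
* Symptom grouping in the report schema (heartburn / regurgitation / chest
  pain) is a representative choice; real exports vary by site.
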