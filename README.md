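# refluxdx

Rule-based decision support for esophageal reflux diagnostics: a Chicago
Classification 3.0 (CC 3.0) engine for high-resolution manometry (HRM), a
GERD phenotyping cascade, symptom–reflux association statistics for 24-h
pH-impedance monitoring, a schema-driven miner for copy-pasted pH-impedance
report text, and a seeded synthetic-cohort generator with summary tables and
agreement metrics.

It is written for gastroenterology groups and informaticians who want the
phenotyping logic of a reflux registry as a reusable, testable library
rather than buried in a hospital application: every classifier returns a
trace of the rules that fired, every threshold is configuration, and every
classifier has an inverse generator that produces inputs with known ground
truth.

## What it computes

**CC 3.0 manometry diagnosis.** Each wet swallow is scored from its distal
contractile integral (DCI, mmHg·s·cm), distal latency (DL, s), largest
isobaric-contour break (cm) and panesophageal pressurization (PEP) into
{failed, weak, fragmented, premature, hypercontractile, normal}; the study
diagnosis then follows the CC 3.0 hierarchy on the median 4-s integrated
relaxation pressure (IRP). With median IRP ≥ 15 mmHg: ≥20% premature →
type III achalasia; ≥20% PEP → type II; 100% failed → type I; otherwise EGJ
outflow obstruction. With normal IRP: 100% failed → absent contractility;
≥20% premature → distal esophageal spasm; ≥20% hypercontractile →
jackhammer esophagus; ≥50% failed+weak → ineffective esophageal motility
(IEM); ≥50% fragmented → fragmented peristalsis; else normal motility —
ten diagnoses in all.

**GERD phenotype.** Endoscopy first: any Los Angeles grade A–D → erosive
esophagitis. Otherwise acid exposure time (AET, % of time pH < 4) ≥ 4% →
non-erosive reflux disease (NERD); otherwise a positive symptom–reflux
association (SAP ≥ 95% and/or SI ≥ 50%) → reflux hypersensitivity; else
functional heartburn. The in-house endoscopy most recently performed is
preferred; external procedures are used only when none exists.

**Symptom association.** SI = % of symptoms preceded by reflux within
2 min; SAP = 100 × (1 − p), p the one-tailed Fisher exact probability on
2-min windows cross-classified by reflux and symptom occurrence; SSI = % of
reflux episodes followed by a symptom within 2 min.

**Report mining.** A 48-parameter canonical record is extracted from
key–value report text (case-, diacritic-, and locale-tolerant, including
decimal commas), with per-line provenance and non-fatal issues; a renderer
provides exact round-trips.

## Worked example

```python
import datetime
from refluxdx import (SwallowMetrics, HrmStudy, classify_study,
                      EndoscopyRecord, PhImpedanceSummary, classify_gerd)

# ten failed swallows, three with panesophageal pressurization, elevated IRP
swallows = tuple(SwallowMetrics(dci=0, irp4=26, pep=i < 3) for i in range(10))
dx = classify_study(HrmStudy(patient_id="demo", swallows=swallows))
print(dx.label, "|", dx.category, "| median IRP", dx.median_irp)
print(dx.trace)

endo = EndoscopyRecord(date=datetime.date(2019, 5, 2), site="in-house", la_grade="none")
summary = PhImpedanceSummary(aet_total=1.8, reflux_episode_count=34, si=75.0, sap=98.2)
print(classify_gerd(endo, summary).label)
```

prints

```
type II achalasia | EGJ-outflow disorder | median IRP 26.0
('median-irp=26', 'irp-elevated', 'pep-fraction=0.3', '-> type II achalasia')
reflux hypersensitivity
```

The first patient's pressurization fraction (3/10 ≥ 20%) resolves type II
achalasia ahead of the all-failed rule; the second has normal acid exposure
but a positive association (SAP 98.2 ≥ 95), hence reflux hypersensitivity.

The same flows are available from the shell:

```sh
refluxdx simulate --kind hrm --target "type I achalasia" --seed 1 --out sim/
refluxdx classify-hrm --in sim/swallows.csv
refluxdx parse-report --in report.txt --strict
refluxdx summarize --in labels.csv --bands decades
```

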