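# clinrules

A rule-based clinical decision support engine for drug prescription and
deprescription in complex chronic patients — older adults with
multimorbidity (two or more chronic diseases) and polypharmacy (five or
more concurrent drugs). The packaged knowledge base covers the atrial
fibrillation / oral anticoagulation scenario, with criteria of the
STOPP/START and LESS-CHRON style alongside guideline recommendations.

## The model

Clinical knowledge is declared, not coded:

* a **clinical concept** is a named variable — a condition, a drug or
  drug class, or a score — with a value kind (boolean, number,
  category) and optional HL7 FHIR R4 and SNOMED CT terminology
  annotations;
* a **premise** constrains one concept (`is_true`, `≥ 3`,
  `between (2, 5)`, …);
* a **mini-rule** binds a single premise, and a **super-rule** an
  and/or combination of premises, to a **clinical statement** — the
  recommendation text shown to the professional, with its category
  (prescribe / deprescribe / monitor) and evidence provenance (source
  document, section, page, level of evidence).

A patient record asserts conditions, medications and observations.
Facts are derived against the knowledge base with a drug-class
hierarchy closure (prescribing the brand *Aldocumar* asserts
acenocoumarol, vitamin K antagonist, and oral anticoagulant), and
unasserted booleans default per the record policy: **open** — UNKNOWN
(absence of evidence is not evidence of absence) — or **closed** —
FALSE, for records known to be complete.

Rules are evaluated under **strong Kleene (K3) three-valued logic**:
UNKNOWN propagates unless dominated (FALSE in a conjunction, TRUE in a
disjunction). Writing F < U < T, conjunction is `min` and disjunction
`max`. A TRUE rule fires its statement with the satisfied premises as
an auditable justification. For an UNKNOWN rule the engine runs a
**missing-information counterfactual analysis**: it enumerates both
resolutions of every unknown premise and reports which missing items
are *decision-relevant* — where completing the record could change
whether the rule fires.

Convenience calculators for CHA₂DS₂-VASc and HAS-BLED are included so
synthetic patients carry coherent risk scores; the PROFUND index and
Pfeiffer questionnaire are treated as opaque numeric inputs.

## Worked example

The packaged reference knowledge base holds the 12 published rules of
the anticoagulation scenario; the packaged case patient is a 70-year-old
man with nine chronic pathologies and fourteen prescribed drugs,
including acetylsalicylic acid (an antiaggregant) and Aldocumar (a
vitamin K antagonist), under the closed record policy.

```python
from clinrules import evaluate_patient, mapping_coverage, screen_eligibility
from clinrules.fixtures import patient_zero, reference_kb

kb = reference_kb()
patient = patient_zero()
print(mapping_coverage(kb))
print(screen_eligibility(patient, kb).eligible)

result = evaluate_patient(kb, patient)
print(len(result.prescribe_group), len(result.deprescribe_group), len(result.not_evaluable))
for cf in result.not_evaluable:
    print(cf.rule_id, cf.decision_relevant_atoms)
```

prints

```
(1.0, 0.45652173913043476)
True
6 3 1
r12 ('has_bled',)
```

meaning: every concept carries a FHIR annotation and 46% carry SNOMED
codes; the patient meets all eligibility criteria (age ≥ 65, ≥ 5 drugs,
≥ 2 chronic conditions, atrial fibrillation, an oral anticoagulant, not
at end of life); the engine emits **9 recommendations** — 6 prescribing
or monitoring (keep the therapeutic range time high, monitor blood
pressure and renal function, …) and 3 deprescription (among them
"It is recommended to deprescribe ASA [acetylsalicylic acid] as it is
of no benefit.") — and one rule (the NIHSS super-rule) cannot be
evaluated because the record lacks a HAS-BLED value, the single missing
item whose completion could change that decision.

The same run from the shell, rendered as the professional-facing
report:

```sh
clinrules evaluate --patient src/clinrules/data/patient_zero.yaml
```

Other commands: `clinrules validate-kb <kb.yaml>`, `clinrules screen
--patient <file>`, `clinrules score cha2ds2vasc|hasbled ...`,
`clinrules simulate --seed 1 --n-patients 10`. FHIR R4 Bundle JSON
files are accepted wherever a patient file is (use `--reference-date`
for age computation).

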