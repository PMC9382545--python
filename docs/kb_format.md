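# Knowledge-base file format

A knowledge base is one YAML document with four top-level keys:
`name`, `version`, `concepts`, `hierarchy`, `rules`. The machine
schema is available as `clinrules.knowledge.kb_json_schema()`;
`clinrules validate-kb <file>` checks a document and reports issues.

## Concepts

```yaml
concepts:
- id: atrial_fibrillation          # lowercase snake-case slug, unique
  label: Atrial fibrillation       # display wording
  value_kind: boolean              # boolean | number | category
  chronic: true                    # counts toward multimorbidity
  section: anamnesis               # input-form grouping (metadata only):
                                   # anamnesis | exploration |
                                   # complementary_tests | treatment
  fhir: {resource_type: Condition, code_system: 'http://snomed.info/sct', code: '49436004'}
  snomed: '49436004'               # optional; 6-18 digit numeral
- id: has_bled
  label: HAS-BLED bleeding-risk score
  value_kind: number
  units: points                    # only for number concepts
  fhir: {resource_type: Observation, code_system: 'urn:clinrules:score', code: has-bled}
```

The `fhir` triple drives FHIR R4 bundle ingestion by exact
(resource type, code system, code) match. `Condition` maps to
`conditions`, `MedicationStatement`/`MedicationRequest` to
`medications`, `Observation` to `observations`.

## Hierarchy

Is-a links from specific concepts to classes; the graph must be
acyclic. Asserting a child asserts every ancestor.

```yaml
hierarchy:
- {child: aldocumar, parent: acenocoumarol}
- {child: acenocoumarol, parent: vitamin_k_antagonist}
- {child: vitamin_k_antagonist, parent: oral_anticoagulant}
```

## Rules

```yaml
rules:
- id: r11
  kind: super                      # mini: single premise; super: connective
  expr:
    all_of:                        # n-ary AND (>= 2 children); any_of = OR
    - {concept: atrial_fibrillation, comparator: is_true}
    - any_of:
      - {concept: mitral_stenosis, comparator: is_true}
      - {concept: mechanical_heart_valve, comparator: is_true}
  statement:
    text: Do Not Prescribe New Oral Anticoagulants ...
    category: prescribe            # prescribe | deprescribe | monitor
    evidence:
      source_document: Clinical practice guideline ...   # required
      section: Valvular atrial fibrillation              # optional
      page: '31'                                         # optional
      evidence_level: III-B                              # optional
```

Premise comparators by value kind:

| value_kind | comparators                                 | value            |
|------------|---------------------------------------------|------------------|
| boolean    | `is_true`, `is_false`                       | none             |
| number     | `eq ne lt le gt ge`, `between`              | scalar; `[lo, hi]` for between |
| category   | `eq`, `ne`                                  | string           |

`save_kb`/`load_kb` round-trip any valid document structurally;
validation reports every broken invariant (dangling ids, hierarchy
cycles, comparator/kind mismatches, kind/shape mismatches, malformed
SNOMED codes) as issue records with severity, location and message.

## Patient files

```yaml
patient_id: patient-0
sex: male            # male | female | unknown
age: 70
conditions: [atrial_fibrillation, arterial_hypertension]
medications: [aldocumar, acetylsalicylic_acid]
observations: {cha2ds2_vasc: 3}
record_policy: closed   # closed: unasserted booleans FALSE; open: UNKNOWN
```
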