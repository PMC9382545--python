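# Methods

## Knowledge representation

The engine separates *what is known* from *how it is evaluated*. A
knowledge base is a plain YAML document (dialect in
[`kb_format.md`](kb_format.md)) holding clinical concepts, an is-a
hierarchy, and rules. Concepts carry terminology annotations: a FHIR
R4 triple (resource type, code system, code) used for bundle ingestion,
and an optional SNOMED CT identifier. SNOMED validation is syntactic
only (a 6–18 digit numeral): no terminology server is consulted and no
check-digit verification is attempted, so the engine has no network
dependency. `mapping_coverage` reports the fraction of concepts
carrying each annotation; for a KB without concepts it returns `None`
rather than a division error.

Rule expressions use n-ary `and`/`or` connectives (two or more
children) with nesting for precedence, e.g. *atrial fibrillation AND
(mitral stenosis OR mechanical heart valve)*. Negation is intentionally
absent from the grammar: negative conditions are written with the
`is_false` and `ne` comparators. A rule with a single leaf premise is a
*mini-rule*; anything with a connective is a *super-rule* — the kind
field is validated against the expression shape.

Statement categories are `prescribe`, `deprescribe`, and `monitor`.
Surveillance advice ("blood pressure should be monitored closely") is
semantically distinct from initiating a drug, so it gets its own
category, but reports display it under the prescribing group to keep
the two-group presentation clinicians expect (prescribing /
deprescription), plus the third section for rules not evaluable from
the record.

An optional rdflib Turtle export mirrors the concept layer and the is-a
links for inspection with ontology tooling; the YAML document remains
the source of truth and no description-logic reasoning is performed.

## Fact building and record policies

`build_facts` materializes one entry per KB concept. Asserted
conditions and medications become TRUE; hierarchy closure marks every
ancestor class TRUE with `derived_from_hierarchy` provenance (the
closure is a plain transitive traversal of the acyclic is-a graph;
monotone in the record, as the property tests check). Everything else
defaults by policy: the **open** policy leaves unasserted booleans
UNKNOWN, the **closed** policy sets them FALSE. The open policy is the
default — in a live record, absence of a drug line does not establish
the drug is not taken. The closed policy exists for curated complete
records, such as the packaged case transcription. Numeric and
categorical concepts are never defaulted: without an observation they
stay UNKNOWN under either policy, since a closed-world assumption has
no natural value for a score.

Three record-derived quantities are published as facts when the KB
declares the concepts: `age` (years), `sex`, and `medication_count`
(distinct medication concepts — prescription lines for the same
concept collapse, but e.g. rapid and mixed insulin are distinct
concepts and count as two). Their provenance is `asserted` because
they come from the record itself, not from a policy default or the
hierarchy.

FHIR R4 Bundles are ingested by exact (resource type, code system,
code) string matching against concept annotations — deterministic and
auditable, with no subsumption or translation. Entries that match no
concept go to a skipped-entries report instead of failing the import.
Age is computed against an explicit reference date parameter, never the
wall clock, so ingestion is reproducible.

## Evaluation semantics

Premises evaluate to TRUE/FALSE/UNKNOWN; UNKNOWN exactly when the
underlying fact is UNKNOWN. Expressions combine under strong Kleene
(K3): with F < U < T, `and` is minimum and `or` is maximum. K3 is the
conservative choice for clinical advice — a recommendation is shown
only when its premises are established, is suppressed only when
refuted, and anything in between is surfaced explicitly as "not
evaluable for lack of information" rather than silently dropped. With
a fully determined fact base K3 coincides with classical two-valued
evaluation, and resolving an UNKNOWN fact can never flip a rule that
was already determined (refinement monotonicity); both are enforced by
property tests against independent oracles.

Fired rules carry their satisfied premises (with observed values) as
the justification; under K3 a TRUE expression always has at least one
TRUE leaf, so the justification is never empty. Distinct rules with
identical statements are all reported — each carries its own evidence.
Output order is rule-id order throughout. Recommendations never write
back into the fact base; there is no forward chaining and no conflict
resolution beyond the grouping.

## Counterfactual analysis of missing information

For an UNKNOWN rule, each distinct unknown leaf premise is an *atom*
resolvable two ways: premise satisfied or not. This is deliberately
premise-level, not value-level — for a numeric premise like
`HAS-BLED ≥ 3` the two hypotheses are "threshold met" and "threshold
not met", with no sampling of score values. All 2^k resolutions are
enumerated; `fire_possible` holds if some resolution makes the rule
fire, `fire_certain` if all do, and an atom is *decision-relevant* iff
flipping it alone changes the outcome in some context of the other
atoms. Enumeration subsumes the single-unknown two-hypothesis check
and is well defined for several simultaneous unknowns. Two different
premises over the same concept resolve independently (the analysis
does not model value-level coupling between them); reports key atoms
by concept id. A guard refuses enumeration beyond 16 atoms by default
(65 536 evaluations) with an explicit error rather than degrading
silently.

## Eligibility screening

The screening mirrors common inclusion criteria for studies of complex
chronic patients: age ≥ 65; polypharmacy, ≥ 5 distinct medication
concepts; multimorbidity, ≥ 2 conditions flagged `chronic` in the KB;
the index condition (atrial fibrillation) asserted; at least one
medication under the oral-anticoagulant class via the hierarchy; and
exclusion for end-of-life patients (short-term prognosis), carried as
an input flag — the engine does not compute prognosis. Every threshold
and concept id is a parameter of `EligibilityCriteria`. A criterion
undecidable against the KB reports `unknown` and the patient is not
eligible; each criterion reports its measured quantity for audit.

## Risk scores

CHA₂DS₂-VASc (stroke risk in atrial fibrillation) and HAS-BLED
(bleeding risk under anticoagulation) use the standardized point
values: one point per item except two for age ≥ 75 and for prior
stroke/TIA in CHA₂DS₂-VASc; HAS-BLED scores renal and liver
abnormality separately and drugs and alcohol separately, one point
each. These point assignments are standard clinical knowledge external
to any specific knowledge base. Both scores are monotone in their
components and bounded by 9. The PROFUND index and Pfeiffer
questionnaire are opaque numeric inputs by design: reimplementing them
from secondary descriptions would risk silent divergence from the
validated instruments.

## Synthetic patient generator

`generate_patients` emulates an older multimorbid cohort of the kind
screened for anticoagulation studies: ages from a normal distribution
(default mean 78, SD 8, clipped to 40–100), attribute presence sampled
per concept prevalence (defaults chosen as typical outpatient figures
for this population, e.g. hypertension 0.75, atrial fibrillation 0.85,
vitamin-K antagonist use 0.60 across acenocoumarol and its brand), and
CHA₂DS₂-VASc / HAS-BLED computed from the sampled morbidity profile so
scores cohere with conditions. A single seeded `random.Random` stream
drives everything; concepts are sampled in sorted-id order, so a seed
fixes the full output.

`missingness` is the probability that a *present* attribute is omitted
from the record. Records assert positives only, so an attribute known
to be absent is not representable, and under the open policy "absent"
and "omitted" both surface as UNKNOWN. Consequently the generator's
UNKNOWN fraction equals the missingness rate only at prevalence 1.0,
which is how the binomial calibration test is phrased. This is the
generator's main departure from real data, along with independence of
comorbidities given the prevalences and the absence of dose, timing
and adherence structure: passing tests show the engine's logic is
correct on such records, not that the default prevalences reproduce
any particular clinic's case mix.

## Fixtures and the worked example

The packaged reference KB contains exactly the 12 rules whose logic is
public in the anticoagulation scenario: the nine case rules (premise
sets such as {atrial fibrillation, vitamin K antagonist} for the
therapeutic-range-time statement), the ticlopidine mini-rule
("Deprescribe in any case."), the new-oral-anticoagulant
contraindication super-rule, and the NIHSS super-rule. The deployed
system it models contained further rules whose content is not public;
they are not invented, though the format supports authoring them.
Three choices in the fixture are explicitly placeholders or encodings:
the NIHSS rule's HAS-BLED threshold (≥ 3) stands for "a certain value"
on the score, its statement text is supplied (the source does not
print one), and "multiple prescribed treatments" is encoded as
`medication_count ≥ 2`. Evidence sections, pages and levels on fixture
rules are illustrative; the source documents are the real ones. SNOMED
annotations cover 21 of 46 concepts (46%) — real codes where
well-known, absent otherwise, mirroring the partial coverage typical
of such mappings. Rules r05–r07 share the premise set {atrial
fibrillation, oral anticoagulant} yet stay distinct rules, because
each binds a different statement.

The case patient (male, 70, nine chronic pathologies, fourteen drugs,
CHA₂DS₂-VASc 3) uses the closed policy: the case boxes are the
complete record. Under it, exactly the nine case rules fire; the
ticlopidine and valve rules are refuted, and the NIHSS rule is not
evaluable because no HAS-BLED result is recorded — its counterfactual
report names `has_bled` as the only decision-relevant missing item.
The record deliberately carries no HAS-BLED observation for that
reason. All nine pathologies are flagged chronic; the multimorbidity
criterion needs only two.

## Numerical and testing choices

Everything is integer or exact-comparison arithmetic; there are no
tolerances. Property tests run on seeded `random.Random` streams or
derandomized Hypothesis profiles so failures reproduce; the brute-force
counterfactual oracle, the classical `all`/`any` evaluator, and the
rank (min/max) oracle in the tests are independent reimplementations,
not calls back into the engine. Problem sizes (500 generated rules for
the counterfactual and classical-limit suites, 100 KBs for round-trip,
120 patients for the missingness calibration) keep the full suite in a
few seconds while giving the binomial test a standard error near 0.013.

## Known limitations

No forward chaining, rule priorities, or interaction checking between
fired statements; no dose/frequency modeling; FHIR ingestion is exact
code matching with no terminology translation; the counterfactual
analysis treats unknown premises as independent binary atoms; and the
KB ships only the publicly printed rules, so coverage of the scenario
is illustrative rather than clinically complete.
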