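# The retrospective validation case: a 70-year-old man with multimorbidity
# and polypharmacy, anticoagulated for atrial fibrillation.  The closed
# record policy reflects that this transcription is the complete record.
patient_id: patient-0
sex: male
age: 70
conditions:
- dyslipidemia
- obesity
- arterial_hypertension
- diabetes_mellitus_2
- atrial_fibrillation
- asthma
- copd
- mild_nonproliferative_retinopathy
- prostatic_adenocarcinoma
medications:
- rapid_insulin
- mixed_insulin
- metformin
- irbesartan
- hydrochlorothiazide
- amlodipine
- paracetamol
- decapeptyl
- tamsulosin
- bicalutamide
- acetylsalicylic_acid
- aldocumar
- atorvastatin
- omeprazole
observations:
  cha2ds2_vasc: 3
record_policy: closed
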