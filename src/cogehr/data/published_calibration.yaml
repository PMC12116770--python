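# Default calibration for the synthetic EHR + linked-claims generator.
#
# Values are the published cohort-level summaries this pipeline is designed
# around: documented-impairment prevalence, per-domain documentation marginals
# (conditional on any documented impairment), linked-claims utilization means,
# psychiatric comorbidity prevalences, and demographic category frequencies.
# Negative-binomial streams use the (mean, dispersion k) parameterization with
# variance = mean + mean^2 / k.  Dispersions, decoy rates, the note-count
# distribution and the eligibility-draw rates are modeling choices documented
# in docs/methods.md.
name: published_calibration
seed: 0
n_patients: 2000
include_notes: true
impairment_prevalence: 0.252

# Optional logistic link between note count and documentation probability:
# P(documented | N notes) = expit(intercept + slope * ln N).  Calibrated
# jointly with notes_per_patient so that patients with <=5 notes document at
# ~2.5%, patients with >50 notes at ~52.3%, and overall at ~25.2%.
note_count_coupling:
  enabled: true
  intercept: -4.4692
  slope: 0.9756

# Conditional P(domain documented | any documented impairment).  The
# generator back-solves unconditional planting probabilities so that these
# conditional marginals hold among patients with at least one planted domain.
domain_marginals:
  reasoning_problem_solving: 0.704
  working_memory: 0.271
  attention_vigilance: 0.192
  verbal_learning_memory: 0.166
  speed_of_processing: 0.151

# Relative weights for choosing the documented phrase category within a
# planted domain (patient counts of the published category frequencies).
category_weights:
  attention_vigilance:
    reduced attention: 3242
    poor concentration: 829
    difficulty understanding: 130
    difficulty staying focused: 123
  reasoning_problem_solving:
    insight and judgment: 13935
    learning new technology: 96
    difficulty learning: 187
    handling changes: 73
    manage bills money: 132
    planning: 30
    difficulty problem solving: 6
    difficulties with concrete thinking: 31
  speed_of_processing:
    poverty of thought: 1543
    thought blocking: 1078
    participate in conversation: 289
    slow thinking: 239
    difficulty integrating thoughts, feelings, and behavior: 244
    ability to perform tasks: 40
    unable to do things quickly: 10
  verbal_learning_memory:
    difficulty expressing themselves: 2151
    hindered speech: 1473
    limited vocabulary: 188
    follow conversation: 60
    remembering what they are going to say: 15
  working_memory:
    poor memory: 2821
    remembering how to get to places: 1435
    difficulties remembering things: 1263
    remembering names of people: 516
    remembering where they put things: 25
    remembering chores and responsibilities: 8

# Per-note probability of inserting one decoy sentence of each kind (a
# lexicon phrase under a negation / question / goal / family-history
# construction).  Applied to impaired and unimpaired patients alike.
confounder_rates:
  negation: 0.05
  question: 0.02
  goal: 0.02
  family_history: 0.02

# Notes per patient: shift + NegBin(mean, dispersion).
notes_per_patient:
  shift: 1
  mean: 50.0
  dispersion: 0.5

html_markup_rate: 0.3

demographics:
  age_bands:
    "18-44": 0.425
    "45-64": 0.465
    "65+": 0.110
  gender:
    male: 0.627
    female: 0.373
  race:
    white: 0.420
    black: 0.262
    asian: 0.055
    other: 0.173
    unknown: 0.090
  ethnicity:
    hispanic: 0.061
    non_hispanic: 0.559
    unknown: 0.380
  region:
    northeast: 0.131
    midwest: 0.162
    south: 0.249
    west: 0.438
    other: 0.020
  payer:
    commercial: 0.047
    dual: 0.085
    medicaid: 0.706
    medicare: 0.076
    self_insured: 0.005
    other: 0.009
    unknown: 0.072

# Pre-index psychiatric comorbidity prevalences per stratum.
comorbidity_prevalences:
  impaired:
    anxiety: 0.390
    bipolar_disorder: 0.239
    depression: 0.363
    panic_disorder: 0.043
    ptsd: 0.108
    substance_use_disorder: 0.334
  not_impaired:
    anxiety: 0.288
    bipolar_disorder: 0.213
    depression: 0.310
    panic_disorder: 0.026
    ptsd: 0.082
    substance_use_disorder: 0.308

cci_distribution:
  impaired: {mean: 0.80, sd: 1.50}
  not_impaired: {mean: 0.80, sd: 1.43}

bmi:
  impaired: {mean: 29.7, sd: 6.5}
  not_impaired: {mean: 30.1, sd: 6.3}

# Annual claim-count streams per stratum (12-month post-index window).
# All-cause claims are the sum of the four streams: impaired
# 45.0 + 37.8 + 1.43 + 0.38 = 84.61, unimpaired 40.3 + 35.9 + 1.38 + 0.32 =
# 77.90.  The inpatient means are the adjusted-estimate values 0.38 / 0.32.
utilization:
  outpatient:
    impaired: {mean: 45.0, dispersion: 2.0}
    not_impaired: {mean: 40.3, dispersion: 2.0}
  pharmacy:
    impaired: {mean: 37.8, dispersion: 2.5}
    not_impaired: {mean: 35.9, dispersion: 2.5}
  er:
    impaired: {mean: 1.43, dispersion: 0.7}
    not_impaired: {mean: 1.38, dispersion: 0.7}
  inpatient:
    impaired: {mean: 0.38, dispersion: 5.0}
    not_impaired: {mean: 0.32, dispersion: 5.0}

# Length of stay per admission (days): 1 + NegBin(mean-1, dispersion).
length_of_stay:
  impaired: {mean: 17.4, dispersion: 3.0}
  not_impaired: {mean: 15.4, dispersion: 3.0}

# Content rates solved so expected relapse episodes are 0.43 / 0.39 given the
# ER and inpatient count means above (see docs/methods.md).
relapse_content:
  er_psychiatric_rate: 0.1587
  inpatient_primary_sz_rate: 0.5344

treatment_patterns:
  psychosocial:
    impaired:
      cbt: 0.002
      psychotherapy: 0.329
      family_therapy: 0.009
      psychosocial_rehab: 0.045
      group_therapy: 0.037
    not_impaired:
      cbt: 0.001
      psychotherapy: 0.240
      family_therapy: 0.007
      psychosocial_rehab: 0.040
      group_therapy: 0.029
  therapy_days:
    impaired: {mean: 10.6, dispersion: 2.0}
    not_impaired: {mean: 8.7, dispersion: 2.0}
  pharmacy_classes:
    impaired:
      fga: 0.198
      sga: 0.801
      mood_stabilizer: 0.226
      antidepressant: 0.574
    not_impaired:
      fga: 0.193
      sga: 0.709
      mood_stabilizer: 0.184
      antidepressant: 0.508

# Explicit per-patient eligibility draws (cohort-criterion satisfaction).
# Rates chosen so overall EHR eligibility is ~25.2% of generated patients.
eligibility:
  p_under_18: 0.01
  p_meets_sz_encounters: 0.55
  p_pre_index_activity: 0.50
  p_excluded_dx: 0.07
  enrollment:
    impaired: 0.1245
    not_impaired: 0.1479

dx_codes:
  schizophrenia: ["F20.9", "F20.0", "F20.5", "295.90"]
  routine: ["I10", "E11.9", "Z00.00", "J06.9", "M54.5"]
  psychiatric: ["F41.1", "F32.9", "F33.1", "F43.10", "F10.20", "F31.9"]
  sz_primary: ["F20.9", "F25.0"]
  comorbidity:
    anxiety: ["F41.1", "F41.9"]
    bipolar_disorder: ["F31.81", "F31.9"]
    depression: ["F32.9", "F33.1"]
    panic_disorder: ["F41.0"]
    ptsd: ["F43.10"]
    substance_use_disorder: ["F10.20", "F12.20"]
  exclusion:
    dementia: ["F03.90", "G30.9"]
    frontotemporal_disease: ["G31.09"]
    prion_disease: ["A81.00"]
    autism: ["F84.0"]
    epilepsy: ["G40.909"]
    intellectual_disability: ["F79"]
    multiple_sclerosis: ["G35"]
    parkinsons: ["G20"]
    stroke: ["I63.9"]
    tbi: ["S06.9"]

date_window:
  start: "2016-01-01"
  index_end: "2022-02-28"
  end: "2023-02-28"
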