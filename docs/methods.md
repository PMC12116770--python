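# Methods

This note documents the models, calibrations and design choices behind the
package: what the pipeline computes, what the synthetic-data generator does
and does not emulate, and where the genuinely open decisions were made.

## Rule-based extraction

**Lexicon.** Five cognitive-impairment domains are retained for clinical-note
screening (attention & vigilance, reasoning & problem solving, speed of
processing, verbal learning & memory, working memory), following the MCCB
domain structure with "social cognition" dropped (rarely documented in notes)
and visual learning folded into verbal learning & memory (overlapping
keywords). The bundled lexicon carries 30 phrase categories; each category's
label was turned into case-insensitive regex alternatives with flexible
inter-word whitespace (`\s+`), simple morphological alternates
(`difficulty|difficulties`, `forgets?`), and `\b` anchors at both ends of
every alternative so substring hits ("attention" inside "inattention") cannot
fire unless a pattern says so. The file format is flat YAML so users can
extend or replace the vocabulary.

"Insight and judgment" is special-cased: it is also a routine
mental-status-exam heading, so the bundled entry requires an impairment
qualifier ("impaired", "poor", "limited", "fair", …) somewhere in the same
sentence. `compile_lexicon(..., enforce_qualifiers=False)` restores broad
matching of the bare heading. Whether bare headings should count is genuinely
undecidable from published frequency tables alone; the qualifier-gated
default is the conservative reading and is a configuration toggle, not a
hard-coded rule.

**Preprocessing and segmentation.** Notes may arrive wrapped in HTML; a
lenient stdlib-parser stripper decodes entity references and replaces
block-level tags with newlines (inline tags with spaces) so words never fuse
across markup. Sentence segmentation is punctuation-driven: `.`/`!`/`?`
followed by whitespace ends a sentence unless the token is a known
abbreviation (Dr., e.g., vs., …) or part of a decimal; newlines (list items)
always break. Spans carry 0-based half-open character offsets into the
stripped text for auditability.

**Context exclusion.** A match only counts as documentation when its sentence
shows none of four excluding contexts: negation, question, care goal, family
history. Scope is the whole sentence — a trigger anywhere disqualifies every
match in that sentence — because sub-sentence scope modelling (NegEx-style
windows) is out of scope here. Trigger vocabularies are explicit,
configurable defaults (e.g. negation: no, not, denies, denied, without,
negative for, absence of, intact); published method descriptions name the
four criteria but not the trigger lists, so ours are a documented choice.
When several rules apply, the audit label follows the fixed precedence
negation > question > goal > family_history; the exclusion outcome is
identical either way.

A patient's profile is the OR over retained mentions: a domain flag is true
iff at least one non-excluded mention of that domain exists, and
`any_impairment` is the OR over domains. Flags are monotone in the note set.

## Synthetic EHR + claims generator

The generator emulates the statistical structure the analysis consumes; it
makes no attempt at realistic clinical language, privacy-preserving
synthesis, or costs.

**Documentation planting.** Configured `domain_marginals` are *conditional*
on a patient having any documented domain (the form such tables are reported
in). The generator back-solves unconditional Bernoulli planting
probabilities p_d = t_d·(1−q), where q solves q = Π_d (1 − t_d(1−q)) (the
empty-set probability, found by bracketed root-finding), then
rejection-samples non-empty domain sets. The conditional marginals therefore
equal the configured targets in expectation; feasibility requires
Σ t_d > 1 (an impaired patient averages more than one domain). Within a
planted domain the phrase category is drawn with weights proportional to the
published category frequencies. Planted phrases appear in affirmative
declarative template sentences; decoy sentences — the same phrases under
negation / question / goal / family-history constructions — are inserted per
note at the configured `confounder_rates` for impaired and unimpaired
patients alike, and filler sentences contain no lexicon phrase. Notes are
wrapped in HTML paragraph markup with probability 0.3.

**Note volume and the documentation link.** Notes per patient follow
1 + NegBin(mean 50, dispersion 0.5) — a long-tailed volume distribution over
a multi-year observation period. When the optional coupling is enabled,
documentation probability follows a logistic link on log note count,
p(N) = expit(−4.4692 + 0.9756·ln N), calibrated jointly with the note-count
law so that patients with ≤5 notes are documented at ≈2.5%, patients with
>50 notes at ≈52.3%, and the population overall at ≈25.2%. This reproduces
the observed documentation-vs-volume association as a generator behaviour;
it is a modelling choice, not a claim about mechanism.

**Utilization.** All count streams are negative binomial with mean μ and
dispersion k, variance μ + μ²/k, drawn independently per patient given the
stratum. Calibrated means (impaired / unimpaired): outpatient 45.0 / 40.3,
pharmacy 37.8 / 35.9, ER 1.43 / 1.38, inpatient 0.38 / 0.32 (the
adjusted-estimate values); all-cause claims are the sum of the four streams
(84.61 / 77.90), not a separate draw. Dispersions (2.0, 2.5, 0.7, 5.0) are
not published and were chosen once to give realistic overdispersion for
ambulatory-claims data. Length of stay per admission is 1 + NegBin with
means 17.4 / 15.4 days. Relapse-qualifying content is planted by giving each
ER claim a psychiatric primary diagnosis with probability 0.1587 and each
inpatient claim a primary schizophrenia/schizoaffective code with
probability 0.5344 — the unique solution of the 2×2 linear system that makes
expected relapse episodes 0.43 / 0.39 given the ER and inpatient count
means. Within-stratum correlation across streams is not modelled (the group
summaries being emulated carry no correlation information), and impairment
affects claims only through the group-level (μ, k) — there is no
individual-level latent severity.

**Eligibility.** Every cohort criterion is decided by an explicit per-patient
draw recorded in the gold labels, and the records are then constructed to
satisfy or violate that criterion exactly (e.g. a second outpatient
schizophrenia encounter on a distinct date, an activity anchor 13–23 months
before index, coverage ending before month 12). Draw rates (under-18 1%,
≥2 encounters 55%, pre-index activity 50%, exclusion diagnosis 7%) are
invented — attrition composition is not published — and chosen so overall
EHR eligibility is ≈25%. Enrollment is group-specific (12.45% / 14.79%) so
the linked subcohort is ≈14% of the EHR cohort with ≈22% impaired. This
makes the cohort builder testable patient-by-patient: on synthetic data its
output must equal the recorded draws for 100% of patients, and the test
suite asserts exactly that.

## Cohort construction

Index date = earliest schizophrenia-coded record (prefix 295 / F20 on
dot-stripped codes, both code systems accepted) inside the 2016-01-01 to
2022-02-28 window; earlier out-of-window codes do not move the index.
Age is computed from birth year at the index year. "EHR activity" means any
recorded event (diagnosis or note). The two qualifying outpatient encounters
must fall on distinct service dates. Exclusion conditions use per-condition
timing: neurodegenerative/acquired conditions (stroke, dementia, prion
disease, multiple sclerosis, TBI, frontotemporal disease, Parkinson's)
disqualify only when coded before index; developmental/chronic conditions
(autism, epilepsy, intellectual disability) disqualify at any time.
Continuous enrollment requires medical *and* pharmacy coverage spanning
index to index + 12 months with a configurable gap allowance (default
0 days — "continuous" read strictly; many claims studies allow 30–45 day
gaps, hence the knob). Baseline comorbidity flags use ≥1 qualifying code in
[index − 12 mo, index); BMI is the closest observation within ±12 months,
ties resolved to the pre-index value; the CCI score is consumed as a
patient-level field (computing it from raw codes is out of scope).

## Statistical analysis

Stratified comparisons use Welch's t (unequal variances, two-sided) for
means and Pearson's χ² without continuity correction for proportions, with
no multiplicity adjustment. Length of stay per admission is averaged over
admitted patients only; therapy days per year over patients receiving any
psychosocial intervention — both denominators are documented choices.

Adjusted inpatient-admission rates come from an NB2 maximum-likelihood
regression (log link, no offset — exposure is a fixed 12 months) of
admission counts on the impairment indicator plus age, gender, race, region,
CCI score, anxiety, bipolar disorder, depression, panic disorder, PTSD and
substance use disorder. Categorical covariates enter as indicators with the
largest category as reference. The fit fails loudly on all-zero outcomes or
non-convergence (BFGS, Nelder-Mead fallback). Adjusted rates are obtained by
marginal standardization over the pooled cohort; the ratio is the ratio of
the standardized means. Relapse counting treats each qualifying claim as one
episode (no same-stay merging; a merge window is configurable).

## What passing tests show — and don't

The synthetic corpus is a *clean-room* stress test: phrases are planted
verbatim from the lexicon, decoys use the bundled trigger vocabulary, and
sentences are well-formed. Extraction therefore achieves F1 = 1.0 on it with
the rules on (and precision ≈0.3 with the rules off, showing the exclusion
rules carry real weight). Real clinical text — typos, idiosyncratic
phrasings, templated exam blocks, copy-forward — would yield the published
0.77–0.94 range, not 1.0; passing here demonstrates correctness of the
mechanics, not real-world recall. Likewise, Monte-Carlo recovery of the
calibrated marginals validates the calibration plumbing, not the published
estimates themselves, which come from proprietary data.

## Numerical and testing choices

Problem sizes: domain-marginal recovery uses 2,000 impaired patients
(binomial SE ≈ 1 point per domain); regression and claims summaries use
5,000-patient cohorts; the coefficient-coverage simulation uses 400
replicates at n = 5,000 with a moderate-mean design (exp(β₀) = 2), where the
Wald asymptotics being verified apply. All randomness flows from a single
`numpy` Generator seed; identical seeds give byte-identical outputs, which
the suite asserts end-to-end. Degenerate inputs are flagged, not fabricated:
zero denominators yield null percentages, 0/0 precision is reported as
undefined, empty strata produce summaries with NaN p-values.

## Known limitations

No sub-sentence exclusion scope or coreference; no temporal resolution of
symptom onset; no spelling correction or statistical NER; generator language
is templated English; utilization streams are conditionally independent;
record linkage, de-identification and cost outcomes are out of scope.
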