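"""Run the NLP extractor over the EHR-population notes.

Produces the per-domain documentation report (counts and percentages among
patients with any documented impairment), the overall documented prevalence,
and the documentation-by-note-volume buckets.  Under the default calibration
the domain percentages should sit near their configured marginals
(reasoning/problem-solving highest by far), prevalence near 25%, and bucket
prevalence should rise steeply with note count.
"""

from pathlib import Path

import pandas as pd

from cogehr.hcru_analysis import bucket_by_note_count
from cogehr.lexicon import compile_lexicon, default_lexicon
from cogehr.nlp_extractor import corpus_domain_report, extract_patient_profiles
from cogehr.synthetic_ehr import load_dataset

ROOT = Path(__file__).resolve().parents[1]
ds = load_dataset(ROOT / "scratch" / "ehr_population")
cl = compile_lexicon(default_lexicon())

result = extract_patient_profiles(ds.notes, cl, patient_ids=ds.patients["patient_id"])
report = corpus_domain_report(result.profiles)
buckets = bucket_by_note_count(result.profiles)

results = ROOT / "results"
results.mkdir(exist_ok=True)
report.to_csv(results / "domain_report.csv", index=False)
buckets.to_csv(results / "note_count_buckets.csv", index=False)
result.profiles_frame().to_csv(ROOT / "scratch" / "ehr_population_profiles.csv", index=False)
result.mention_log_frame().to_csv(ROOT / "scratch" / "ehr_population_mentions.csv", index=False)

overall = report[report["level"] == "overall"].iloc[0]
print(f"documented prevalence: {overall['percent']:.1f}% "
      f"({overall['count']}/{overall['denominator']})")
print(report[report["level"] == "domain"][["domain", "count", "percent"]]
      .to_string(index=False))
print("\ndocumentation by note volume:")
print(buckets.to_string(index=False))
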