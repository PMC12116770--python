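"""Generate the two synthetic study datasets.

1. An EHR-population run (default calibration, note-count coupling on) used
   for the extraction, cohort-attrition and documentation-vs-note-volume
   analyses.
2. A fully-linked cohort run (every patient eligible and continuously
   enrolled) used for the HCRU and adjusted-estimate analyses, mirroring a
   linked-claims subcohort with the published impairment share.

Datasets are written under scratch/ (they are large and regenerable); the
row counts and the manifest summary go to results/.
"""

import json
import sys
from pathlib import Path

from cogehr.synthetic_ehr import generate_dataset, published_calibration_config, write_dataset

ROOT = Path(__file__).resolve().parents[1]
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 2016

ehr_cfg = published_calibration_config().updated({"n_patients": 8000})
linked_cfg = published_calibration_config().updated({
    "n_patients": 5000,
    "impairment_prevalence": 0.221,
    "note_count_coupling.enabled": False,
    "eligibility.p_under_18": 0.0,
    "eligibility.p_meets_sz_encounters": 1.0,
    "eligibility.p_pre_index_activity": 1.0,
    "eligibility.p_excluded_dx": 0.0,
    "eligibility.enrollment.impaired": 1.0,
    "eligibility.enrollment.not_impaired": 1.0,
})

summary = {}
for name, cfg, seed in [("ehr_population", ehr_cfg, SEED),
                        ("linked_cohort", linked_cfg, SEED + 1)]:
    ds = generate_dataset(cfg, seed=seed)
    out = ROOT / "scratch" / name
    write_dataset(ds, out)
    summary[name] = {
        "seed": seed,
        "patients": len(ds.patients),
        "notes": len(ds.notes),
        "diagnoses": len(ds.diagnoses),
        "claims": len(ds.claims),
        "gold_impaired": int(ds.gold["impaired"].sum()),
    }
    print(f"{name}: {summary[name]}")

results = ROOT / "results"
results.mkdir(exist_ok=True)
(results / "simulation_summary.json").write_text(json.dumps(summary, indent=1))
print(f"datasets under {ROOT / 'scratch'}; summary in results/simulation_summary.json")
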