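"""Quality-control scoring: sample patients, compare predicted vs gold
domain labels, and compute per-domain precision / recall / F1.

The scoring unit is the patient-domain pair: a domain counts as a true
positive for a patient when both the extractor and the gold label mark it
documented.  F1 is the harmonic mean 2*p*r/(p+r); scores above 0.8 are
conventionally read as good classifier performance.  Undefined ratios
(0/0) are flagged rather than silently propagated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .lexicon import DOMAINS
from .nlp_extractor import PatientImpairmentProfile

__all__ = ["DomainScore", "f1_score", "sample_qc_patients", "score_domains"]


@dataclass(frozen=True)
class DomainScore:
    domain: str
    tp: int
    fp: int
    fn: int
    tn: int
    precision: float
    recall: float
    f1: float
    precision_defined: bool = True
    recall_defined: bool = True

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if not (0.0 <= precision <= 1.0 and 0.0 <= recall <= 1.0):
        raise ValueError("precision and recall must lie in [0, 1]")
    if precision + recall == 0.0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def sample_qc_patients(
    patient_ids: Sequence[str], n: int, seed: int
) -> list[str]:
    """Simple random sample of patients without replacement (reproducible)."""
    ids = list(patient_ids)
    if n > len(ids):
        raise ValueError(f"cannot sample {n} of {len(ids)} patients")
    rng = np.random.default_rng(seed)
    picked = rng.choice(len(ids), size=n, replace=False)
    return [ids[i] for i in sorted(picked)]


def _gold_domains(gold: Mapping[str, object], pid: str) -> set[str]:
    try:
        value = gold[pid]
    except KeyError as exc:
        raise KeyError(f"patient {pid!r} missing from gold labels") from exc
    if isinstance(value, str):
        return set(filter(None, value.split(";")))
    return set(value)


def score_domains(
    profiles: Sequence[PatientImpairmentProfile],
    gold: Mapping[str, object],
    subset: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-domain confusion counts and scores, plus an overall
    any-impairment row.

    ``gold`` maps patient_id to a set of documented domains (or a
    ";"-joined string, as stored in the generator's gold table).  ``subset``
    restricts scoring to those patients; every subset patient must be
    present in both the profiles and the gold labels.
    """
    by_id = {p.patient_id: p for p in profiles}
    ids = list(subset) if subset is not None else [p.patient_id for p in profiles]
    for pid in ids:
        if pid not in by_id:
            raise KeyError(f"patient {pid!r} missing from predictions")

    rows = []
    targets = list(DOMAINS) + ["any_impairment"]
    for target in targets:
        tp = fp = fn = tn = 0
        for pid in ids:
            prof = by_id[pid]
            gd = _gold_domains(gold, pid)
            if target == "any_impairment":
                pred, truth = prof.any_impairment, bool(gd)
            else:
                pred, truth = prof.domain_flags[target], target in gd
            if pred and truth:
                tp += 1
            elif pred:
                fp += 1
            elif truth:
                fn += 1
            else:
                tn += 1
        p_def, r_def = tp + fp > 0, tp + fn > 0
        precision = tp / (tp + fp) if p_def else 0.0
        recall = tp / (tp + fn) if r_def else 0.0
        rows.append(
            DomainScore(
                domain=target, tp=tp, fp=fp, fn=fn, tn=tn,
                precision=precision, recall=recall,
                f1=f1_score(precision, recall),
                precision_defined=p_def, recall_defined=r_def,
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])
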