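"""Pivot-anchored scoring: clinician thresholds -> per-item flag rule ->
patient 0/1 flags, flag totals and the raw total score used for referral
cut-points.

Pivot anchoring elicits from each clinician, per item, the lowest response
category that signals a clinically meaningful potential bladder problem.
The per-item rule aggregates responding clinicians: the flag threshold is
the modal reported category (ties resolved toward the lower, more sensitive
category, matching the "lowest rating" elicitation), and the endorsement
percentage drives the >50%-of-clinicians inclusion criterion.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import ClinicianSurvey, ResponseMatrix, RunConfig, ValidationError

__all__ = [
    "PivotRule",
    "ScoredPatient",
    "aggregate_thresholds",
    "flag_matrix",
    "raw_total_score",
    "classify",
    "score_patients",
]


@dataclass
class PivotRule:
    """Per-item flag thresholds and clinician endorsement percentages.

    ``thresholds[item_id]`` is the category at or above which a response is
    flagged (None when no clinician endorsed the item); ``endorsement_pct``
    is the percent of responding clinicians marking the item relevant.
    """

    thresholds: dict[str, int | None]
    endorsement_pct: dict[str, float]
    n_responders: int

    def met_clinician(self, item_id: str, majority: float = 0.5) -> bool:
        """Strict majority: endorsement must exceed ``majority`` x 100 %."""
        if self.thresholds.get(item_id) is None:
            return False
        return self.endorsement_pct[item_id] > majority * 100.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "item_id": list(self.thresholds),
                "flag_threshold": [self.thresholds[i] for i in self.thresholds],
                "endorsement_pct": [self.endorsement_pct[i] for i in self.thresholds],
            }
        )


@dataclass
class ScoredPatient:
    person: object
    flags: dict[str, int] = field(repr=False)
    flag_score: int = 0
    raw_total: int = 0
    refer_recommended: bool = False


def aggregate_thresholds(survey: ClinicianSurvey, cfg: RunConfig | None = None) -> PivotRule:
    """Aggregate a clinician survey into a per-item pivot rule.

    Threshold = modal reported category among endorsing clinicians, ties
    broken toward the lower category; endorsement over all responders.
    """
    thresholds: dict[str, int | None] = {}
    endorsement: dict[str, float] = {}
    n = survey.n_responders
    for it in survey.items:
        rel = survey.relevant[it.item_id]
        endorsement[it.item_id] = 100.0 * float(rel.sum()) / n
        reported = survey.thresholds[it.item_id][rel].dropna()
        if len(reported) == 0:
            thresholds[it.item_id] = None
            continue
        counts = Counter(int(v) for v in reported)
        best = max(counts.values())
        thresholds[it.item_id] = min(c for c, k in counts.items() if k == best)
    return PivotRule(thresholds, endorsement, n)


def flag_matrix(responses: ResponseMatrix, rule: PivotRule) -> pd.DataFrame:
    """0/1 flag per (person, item): 1 iff response >= the item's threshold.

    Missing responses flag 0; the count of such cells is recorded in
    ``flags.attrs['missing_as_zero']``.
    """
    lacking = [i for i in responses.item_ids if rule.thresholds.get(i) is None]
    if lacking:
        raise ValidationError(f"items lack a flag threshold: {lacking}")
    flags = {}
    n_missing = 0
    for item_id in responses.item_ids:
        col = responses.values[item_id]
        t = rule.thresholds[item_id]
        n_missing += int(col.isna().sum())
        flags[item_id] = (col >= t).fillna(False).astype(int)
    out = pd.DataFrame(flags, index=responses.persons)
    out.attrs["missing_as_zero"] = n_missing
    return out


def raw_total_score(responses: ResponseMatrix, retained_items: list[str]) -> pd.Series:
    """Per-person sum of ordinal responses over the retained items.

    Binary items are excluded from the total (the Yes/No help item is a flag,
    not a severity rating). Missing responses contribute 0; the number of
    cells so treated is recorded in ``totals.attrs['missing_as_zero']``.
    """
    for i in retained_items:
        responses.item(i)  # raises KeyError for unknown items
    ordinal = [i for i in retained_items if not responses.item(i).is_binary]
    sub = responses.values[ordinal]
    totals = sub.fillna(0).sum(axis=1).astype(int)
    totals.attrs["missing_as_zero"] = int(sub.isna().to_numpy().sum())
    return totals


def classify(score, cut: int):
    """Referral recommended iff score >= cut (inclusive)."""
    if cut < 0:
        raise ValidationError(f"cut must be >= 0, got {cut}")
    if np.ndim(score) == 0 and not isinstance(score, pd.Series):
        return bool(score >= cut)
    return np.asarray(score) >= cut


def score_patients(
    responses: ResponseMatrix,
    rule: PivotRule,
    retained_items: list[str],
    cut: int,
) -> list[ScoredPatient]:
    """Full pivot scoring: flags, flag score, raw total, referral decision."""
    flaggable = [i for i in retained_items if rule.thresholds.get(i) is not None]
    flags = flag_matrix(responses.subset(flaggable), rule)
    totals = raw_total_score(responses, retained_items)
    out = []
    for person in responses.persons:
        total = int(totals.loc[person])
        out.append(
            ScoredPatient(
                person=person,
                flags={i: int(flags.loc[person, i]) for i in flaggable},
                flag_score=int(flags.loc[person].sum()),
                raw_total=total,
                refer_recommended=classify(total, cut),
            )
        )
    return out
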