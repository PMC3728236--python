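"""Core data containers, file readers/writers and run configuration.

The universal input is a wide person x item table of ordinal responses
(categories 0..m_i per item, missing allowed), accompanied by a clinician
survey (per-item relevance flag + pivot threshold) and binary referral
labels. All files are comma-separated UTF-8 text with ``NA`` as the missing
marker.

Categories are 0-based: the 16 ordinal items use a 0-4 frequency scale
(4 = "All of the time"); the final help-seeking item is 0/1 (No/Yes).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

SUBSCALES = (
    "symptom_intensity",
    "impact",
    "symptom_frequency",
    "coping",
    "help_seeking",
)

MISSING = "NA"


class ValidationError(ValueError):
    """Raised when an input value violates an instrument contract."""


@dataclass(frozen=True)
class ItemSpec:
    """One instrument item: id, label, highest ordinal category, subscale."""

    item_id: str
    label: str = ""
    max_category: int = 4
    subscale: str = "symptom_intensity"

    def __post_init__(self) -> None:
        if not self.item_id:
            raise ValidationError("item_id must be non-empty")
        if int(self.max_category) < 1:
            raise ValidationError(
                f"item {self.item_id!r}: max_category must be >= 1, "
                f"got {self.max_category}"
            )
        if self.subscale not in SUBSCALES:
            raise ValidationError(
                f"item {self.item_id!r}: unknown subscale {self.subscale!r}; "
                f"expected one of {SUBSCALES}"
            )

    @property
    def is_binary(self) -> bool:
        return self.max_category == 1


def default_instrument() -> list[ItemSpec]:
    """The 17-item long-form instrument: 16 ordinal (0-4) items plus a
    binary (Yes/No) help-seeking item."""
    specs = [
        ("item1", "Urinate right away", "symptom_frequency"),
        ("item2", "Make sure know where bathrooms are", "coping"),
        ("item3", "Urinary accidents/leakage", "symptom_frequency"),
        ("item4", "Use of leakage protection in the day", "coping"),
        ("item5", "Use of leakage protection at night", "coping"),
        ("item6", "Limit amount of fluid", "coping"),
        ("item7", "Need to urinate right away", "symptom_intensity"),
        ("item8", "Wake to urinate", "symptom_intensity"),
        ("item9", "Number of times urinated", "symptom_intensity"),
        ("item10", "Activities with friends and family affected", "impact"),
        ("item11", "Ability to work affected", "impact"),
        ("item12", "Social activities affected", "impact"),
        ("item13", "Embarrassed", "impact"),
        ("item14", "Frustrated", "impact"),
        ("item15", "Worried", "impact"),
        ("item16", "Depressed", "impact"),
    ]
    items = [ItemSpec(i, lab, max_category=4, subscale=s) for i, lab, s in specs]
    items.append(
        ItemSpec("item17", "Receive help", max_category=1, subscale="help_seeking")
    )
    return items


def _check_unique(ids: Sequence, what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dups = seen[seen.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what}: {dups}")


@dataclass
class ResponseMatrix:
    """Person x item table of ordinal responses.

    ``values`` is a float DataFrame indexed by person id with one column per
    item id; missing cells are NaN. Every non-missing value must be an
    integer in [0, max_category] for its item.
    """

    values: pd.DataFrame
    items: list[ItemSpec]

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        item_ids = [it.item_id for it in self.items]
        _check_unique(item_ids, "item ids")
        _check_unique(self.values.index, "person ids")
        unknown = [c for c in self.values.columns if c not in item_ids]
        if unknown:
            raise ValidationError(f"unknown item columns: {unknown}")
        missing_cols = [i for i in item_ids if i not in self.values.columns]
        if missing_cols:
            raise ValidationError(f"missing item columns: {missing_cols}")
        self.values = self.values[item_ids]
        for it in self.items:
            col = self.values[it.item_id]
            obs = col.dropna()
            bad = obs[(obs < 0) | (obs > it.max_category) | (obs != obs.round())]
            if len(bad):
                person, value = bad.index[0], bad.iloc[0]
                raise ValidationError(
                    f"response out of range: person {person!r}, item "
                    f"{it.item_id!r}, value {value!r} (allowed 0..{it.max_category})"
                )

    @property
    def persons(self) -> pd.Index:
        return self.values.index

    @property
    def item_ids(self) -> list[str]:
        return [it.item_id for it in self.items]

    def item(self, item_id: str) -> ItemSpec:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise KeyError(item_id)

    def subset(self, item_ids: Iterable[str]) -> "ResponseMatrix":
        ids = list(item_ids)
        return ResponseMatrix(self.values[ids].copy(), [self.item(i) for i in ids])

    def ordinal_item_ids(self) -> list[str]:
        return [it.item_id for it in self.items if not it.is_binary]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ResponseMatrix):
            return NotImplemented
        return self.items == other.items and self.values.equals(other.values)


@dataclass
class ClinicianSurvey:
    """Clinician x item relevance flags and pivot thresholds.

    ``relevant`` is a boolean DataFrame (clinician x item); ``thresholds``
    holds the lowest response category the clinician flags as a clinically
    meaningful potential bladder problem (NaN when the item was not marked
    relevant). A threshold must be >= 1: flagging category 0 would flag
    every patient.
    """

    relevant: pd.DataFrame
    thresholds: pd.DataFrame
    items: list[ItemSpec]

    def __post_init__(self) -> None:
        if len(self.relevant) == 0:
            raise ValidationError("no clinicians in survey")
        _check_unique(self.relevant.index, "clinician ids")
        item_ids = [it.item_id for it in self.items]
        self.relevant = self.relevant[item_ids].astype(bool)
        self.thresholds = self.thresholds[item_ids].astype(float)
        if not self.relevant.index.equals(self.thresholds.index):
            raise ValidationError("relevance and threshold rows misaligned")
        for it in self.items:
            thr = self.thresholds[it.item_id]
            rel = self.relevant[it.item_id]
            orphan = thr.notna() & ~rel
            if orphan.any():
                who = orphan[orphan].index[0]
                raise ValidationError(
                    f"clinician {who!r}: threshold given for item "
                    f"{it.item_id!r} without marking it relevant"
                )
            obs = thr.dropna()
            bad = obs[(obs < 1) | (obs > it.max_category) | (obs != obs.round())]
            if len(bad):
                who, value = bad.index[0], bad.iloc[0]
                raise ValidationError(
                    f"clinician {who!r}: threshold {value!r} for item "
                    f"{it.item_id!r} outside 1..{it.max_category}"
                )

    @property
    def clinicians(self) -> pd.Index:
        return self.relevant.index

    @property
    def n_responders(self) -> int:
        return len(self.relevant)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ClinicianSurvey):
            return NotImplemented
        return (
            self.items == other.items
            and self.relevant.equals(other.relevant)
            and self.thresholds.equals(other.thresholds)
        )


@dataclass
class ReferralLabels:
    """Per-person binary flag: clinician would recommend urologist referral."""

    referred: pd.Series

    def __post_init__(self) -> None:
        _check_unique(self.referred.index, "person ids")
        self.referred = self.referred.astype(bool)

    @property
    def persons(self) -> pd.Index:
        return self.referred.index

    def aligned_to(self, persons: pd.Index) -> pd.Series:
        if set(persons) != set(self.referred.index):
            raise ValidationError("labels do not cover the same persons")
        return self.referred.loc[persons]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ReferralLabels):
            return NotImplemented
        return self.referred.equals(other.referred)


@dataclass
class RunConfig:
    """Analysis thresholds and numerical settings.

    infit_band          acceptable mean-square infit/outfit range
    floor_limit         max percent of responses at category 0 (strict <)
    corr_limit          min corrected item-rest correlation (>=)
    clinician_majority  fraction of responding clinicians required (strict >)
    jmle_tol            convergence tolerance on max logit change
    or_zero_cell_policy 'undefined' (report missing OR) or 'haldane' (+0.5)
    """

    infit_band: tuple[float, float] = (0.60, 1.40)
    floor_limit: float = 50.0
    corr_limit: float = 0.80
    clinician_majority: float = 0.5
    jmle_tol: float = 1e-4
    jmle_max_iter: int = 200
    seed: int = 0
    or_zero_cell_policy: str = "undefined"

    # alternative infit band printed alongside the default in the short-form
    # criteria table; selectable as a preset
    STRICT_INFIT_BAND = (0.80, 1.20)

    def __post_init__(self) -> None:
        low, high = self.infit_band
        if not (0 < low < high):
            raise ValidationError(f"invalid infit band {self.infit_band}")
        if not (0 < self.clinician_majority < 1):
            raise ValidationError(
                f"clinician_majority must be in (0,1), got {self.clinician_majority}"
            )
        if self.jmle_tol <= 0:
            raise ValidationError("jmle_tol must be positive")
        if self.or_zero_cell_policy not in ("undefined", "haldane"):
            raise ValidationError(
                f"unknown or_zero_cell_policy {self.or_zero_cell_policy!r}"
            )
        self.infit_band = (float(low), float(high))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "infit_band" in raw:
            raw["infit_band"] = tuple(raw["infit_band"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["infit_band"] = list(self.infit_band)
        return d


# ---------------------------------------------------------------------------
# readers / writers


def read_responses(path: str | Path, instrument: list[ItemSpec]) -> ResponseMatrix:
    """Read a person x item CSV (first column person ids, header item ids)."""
    df = pd.read_csv(path, index_col=0, na_values=[MISSING], keep_default_na=False)
    df.index = df.index.astype(str)
    return ResponseMatrix(df, list(instrument))


def write_responses(matrix: ResponseMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, na_rep=MISSING, index_label="person")


def read_clinician_survey(
    path: str | Path, instrument: list[ItemSpec]
) -> ClinicianSurvey:
    """Read a clinician survey CSV: one row per clinician, per-item column
    pairs ``<item>__relevant`` (0/1) and ``<item>__threshold`` (int or NA)."""
    df = pd.read_csv(path, index_col=0, na_values=[MISSING], keep_default_na=False)
    if len(df) == 0:
        raise ValidationError("no clinicians in survey file")
    df.index = df.index.astype(str)
    rel = {}
    thr = {}
    for it in instrument:
        rcol, tcol = f"{it.item_id}__relevant", f"{it.item_id}__threshold"
        if rcol not in df.columns or tcol not in df.columns:
            raise ValidationError(f"survey file missing columns for {it.item_id!r}")
        rel[it.item_id] = df[rcol].astype(float).fillna(0).astype(bool)
        thr[it.item_id] = pd.to_numeric(df[tcol], errors="raise")
    return ClinicianSurvey(pd.DataFrame(rel), pd.DataFrame(thr), list(instrument))


def write_clinician_survey(survey: ClinicianSurvey, path: str | Path) -> None:
    out = {}
    for it in survey.items:
        out[f"{it.item_id}__relevant"] = survey.relevant[it.item_id].astype(int)
        out[f"{it.item_id}__threshold"] = survey.thresholds[it.item_id]
    pd.DataFrame(out, index=survey.clinicians).to_csv(
        path, na_rep=MISSING, index_label="clinician"
    )


def read_labels(path: str | Path) -> ReferralLabels:
    df = pd.read_csv(path, index_col=0, na_values=[MISSING], keep_default_na=False)
    if "referred" not in df.columns:
        raise ValidationError("labels file must have a 'referred' column")
    df.index = df.index.astype(str)
    col = df["referred"]
    if col.isna().any():
        raise ValidationError("missing referral labels are not allowed")
    bad = col[~col.astype(float).isin([0.0, 1.0])]
    if len(bad):
        raise ValidationError(
            f"labels must be 0/1: person {bad.index[0]!r} has {bad.iloc[0]!r}"
        )
    return ReferralLabels(col.astype(float).astype(bool))


def write_labels(labels: ReferralLabels, path: str | Path) -> None:
    labels.referred.astype(int).rename("referred").to_csv(path, index_label="person")


def write_roc_points(points: pd.DataFrame, path: str | Path) -> None:
    """Export ROC points as (threshold, fpr, sensitivity) rows; fpr = 1-Sp."""
    points.to_csv(path, index=False)


def read_roc_points(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def _to_frame(results) -> pd.DataFrame:
    if isinstance(results, pd.DataFrame):
        return results
    if hasattr(results, "to_frame") and not isinstance(results, pd.Series):
        return results.to_frame()
    if isinstance(results, (list, tuple)):
        rows = []
        for r in results:
            if dataclasses.is_dataclass(r):
                rows.append(dataclasses.asdict(r))
            else:
                rows.append(dict(r))
        return pd.DataFrame(rows)
    if dataclasses.is_dataclass(results):
        return pd.DataFrame([dataclasses.asdict(results)])
    raise TypeError(f"cannot serialise {type(results).__name__} as a report")


def write_report(results, path: str | Path) -> None:
    """Write any stage output as a delimited table plus a machine-readable
    JSON file alongside (same stem, ``.json`` suffix).

    ResponseMatrix / ClinicianSurvey / ReferralLabels round-trip through
    their dedicated writers; everything else is flattened row-wise.
    """
    path = Path(path)
    if isinstance(results, ResponseMatrix):
        write_responses(results, path)
        return
    if isinstance(results, ClinicianSurvey):
        write_clinician_survey(results, path)
        return
    if isinstance(results, ReferralLabels):
        write_labels(results, path)
        return
    frame = _to_frame(results)
    frame.to_csv(path, na_rep=MISSING, index=False)
    records = json.loads(frame.to_json(orient="records"))
    path.with_suffix(".json").write_text(json.dumps(records, indent=1))
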