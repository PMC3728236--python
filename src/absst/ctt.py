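"""Classical test theory item statistics used as short-form inclusion criteria.

Three screens: floor/ceiling percentages (an item concentrated at the lowest
category cannot discriminate), corrected item-rest correlation (how well an
item tracks the remaining ordinal items), and KR-20 internal consistency for
dichotomous matrices (e.g. the pivot-anchored flag matrix).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import ResponseMatrix, RunConfig, ValidationError

__all__ = [
    "CTTItemStats",
    "floor_ceiling",
    "item_total_correlation",
    "kr20",
    "item_statistics",
]


@dataclass
class CTTItemStats:
    """Per-item classical statistics.

    ``item_total_r`` is the corrected (item-rest) Pearson correlation: the
    item is excluded from the total it is correlated with. The uncorrected
    item-total correlation is reported alongside. NaN marks an undefined
    correlation (zero variance).
    """

    item_id: str
    floor_pct: float
    ceiling_pct: float
    item_total_r: float
    item_total_r_uncorrected: float
    n_used: int


def floor_ceiling(responses: ResponseMatrix, item_id: str) -> tuple[float, float]:
    """Percent of non-missing responses at category 0 and at max_category."""
    spec = responses.item(item_id)
    col = responses.values[item_id].dropna()
    if len(col) == 0:
        raise ValidationError(f"item {item_id!r} has no non-missing responses")
    floor_pct = 100.0 * float((col == 0).mean())
    ceiling_pct = 100.0 * float((col == spec.max_category).mean())
    return floor_pct, ceiling_pct


def _rest_scores(responses: ResponseMatrix, item_id: str) -> pd.Series:
    """Sum of the *other* ordinal items per person (missing skipped; NaN when
    every other ordinal item is missing)."""
    others = [i for i in responses.ordinal_item_ids() if i != item_id]
    if not others:
        raise ValidationError(f"no other ordinal items to form a rest score for {item_id!r}")
    sub = responses.values[others]
    rest = sub.sum(axis=1, skipna=True)
    rest[sub.notna().sum(axis=1) == 0] = np.nan
    return rest


def item_total_correlation(
    responses: ResponseMatrix, item_id: str, corrected: bool = True
) -> float:
    """Pearson correlation between an item and the scale rest-score.

    Corrected form (default) excludes the item from the total. Returns NaN
    when either side has zero variance or fewer than 3 complete pairs.
    """
    col = responses.values[item_id]
    rest = _rest_scores(responses, item_id)
    if not corrected:
        rest = rest.add(col, fill_value=0.0)
    use = col.notna() & rest.notna()
    if use.sum() < 3:
        return float("nan")
    x = col[use].to_numpy(dtype=float)
    y = rest[use].to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def kr20(binary: pd.DataFrame) -> float:
    """Kuder-Richardson Formula 20 for a person x item 0/1 matrix.

    KR-20 = (k/(k-1)) * (1 - sum(p_i * q_i) / var(total)), population
    variance convention. Returns NaN when the total score has zero variance.
    Equals coefficient alpha on the same dichotomous matrix.
    """
    mat = pd.DataFrame(binary).dropna(axis=0, how="any")
    vals = mat.to_numpy(dtype=float)
    if vals.ndim != 2 or vals.shape[1] < 2 or vals.shape[0] < 2:
        raise ValidationError("kr20 needs >= 2 persons and >= 2 binary items")
    if not np.isin(vals, (0.0, 1.0)).all():
        raise ValidationError("kr20 requires a 0/1 matrix")
    k = vals.shape[1]
    p = vals.mean(axis=0)
    total_var = float(np.var(vals.sum(axis=1), ddof=0))
    if total_var == 0:
        return float("nan")
    return float(k / (k - 1) * (1.0 - (p * (1 - p)).sum() / total_var))


def item_statistics(
    responses: ResponseMatrix, cfg: RunConfig | None = None
) -> list[CTTItemStats]:
    """Floor/ceiling and item-rest correlations for every ordinal item."""
    out = []
    for item_id in responses.ordinal_item_ids():
        fl, ce = floor_ceiling(responses, item_id)
        col = responses.values[item_id]
        rest = _rest_scores(responses, item_id)
        out.append(
            CTTItemStats(
                item_id=item_id,
                floor_pct=fl,
                ceiling_pct=ce,
                item_total_r=item_total_correlation(responses, item_id),
                item_total_r_uncorrected=item_total_correlation(
                    responses, item_id, corrected=False
                ),
                n_used=int((col.notna() & rest.notna()).sum()),
            )
        )
    return out
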