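"""Predictive-validity engine: 2x2 confusion tables, diagnostic metrics,
cut-point sweeps, ROC / c-statistic, logistic regression and the
Hosmer-Lemeshow calibration test.

Positive class = clinician recommends urologist referral; predicted
positive = total score >= cut (inclusive). The diagnostic odds ratio
(TP*TN)/(FN*FP) is undefined when an off-diagonal cell is zero; by default
it is reported as missing (printed "."), with the Haldane-Anscombe +0.5
correction available as a policy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import ReferralLabels, ValidationError

__all__ = [
    "ConfusionTable",
    "CutpointMetrics",
    "LogisticFit",
    "HosmerLemeshowResult",
    "contingency_table",
    "diagnostic_metrics",
    "roc_auc",
    "cutpoint_sweep",
    "fit_logistic",
    "hosmer_lemeshow",
    "format_table3",
    "plot_roc",
]


def _as_labels(labels) -> np.ndarray:
    if isinstance(labels, ReferralLabels):
        return labels.referred.to_numpy(dtype=bool)
    return np.asarray(labels, dtype=bool)


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 screening table at one cut-point."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass
class CutpointMetrics:
    """One diagnostic-performance row: all rates as percents in [0, 100],
    c-statistic in [0, 1], odds ratio NaN when undefined."""

    cut: int
    odds_ratio: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    pct_correct: float
    c_statistic: float = float("nan")


@dataclass
class LogisticFit:
    intercept: float
    slope: float
    se_intercept: float
    se_slope: float
    converged: bool
    message: str = ""


@dataclass
class HosmerLemeshowResult:
    chi2: float
    df: int
    pvalue: float
    table: pd.DataFrame = field(repr=False, default=None)


def contingency_table(scores, labels, cut: int) -> ConfusionTable:
    """Cross-classify (score >= cut) against the referral label."""
    s = np.asarray(scores, dtype=float)
    y = _as_labels(labels)
    if len(s) == 0:
        raise ValidationError("empty score/label input")
    if len(s) != len(y):
        raise ValidationError("scores and labels are not aligned")
    pred = s >= cut
    return ConfusionTable(
        tp=int(np.sum(pred & y)),
        fn=int(np.sum(~pred & y)),
        fp=int(np.sum(pred & ~y)),
        tn=int(np.sum(~pred & ~y)),
    )


def diagnostic_metrics(
    t: ConfusionTable, policy: str = "undefined", cut: int = 0
) -> CutpointMetrics:
    """Se, Sp, PPV, NPV, percent correctly classified and the diagnostic
    odds ratio from a 2x2 table. Undefined quantities (zero denominators,
    zero off-diagonal cells under the 'undefined' policy) come back NaN."""
    if t.tp + t.fn < 1 or t.fp + t.tn < 1:
        raise ValidationError("both classes must be present")
    se = 100.0 * t.tp / (t.tp + t.fn)
    sp = 100.0 * t.tn / (t.fp + t.tn)
    ppv = 100.0 * t.tp / (t.tp + t.fp) if t.tp + t.fp else float("nan")
    npv = 100.0 * t.tn / (t.tn + t.fn) if t.tn + t.fn else float("nan")
    pct = 100.0 * (t.tp + t.tn) / t.n
    if policy == "haldane":
        a, b, c, d = (x + 0.5 for x in (t.tp, t.tn, t.fn, t.fp))
        or_ = (a * b) / (c * d)
    elif policy == "undefined":
        or_ = (t.tp * t.tn) / (t.fn * t.fp) if t.fn * t.fp else float("nan")
    else:
        raise ValidationError(f"unknown zero-cell policy {policy!r}")
    return CutpointMetrics(
        cut=cut,
        odds_ratio=float(or_),
        sensitivity=se,
        specificity=sp,
        ppv=ppv,
        npv=npv,
        pct_correct=pct,
    )


def roc_auc(scores, labels) -> tuple[pd.DataFrame, float]:
    """Empirical ROC points and AUC.

    AUC uses the rank (Mann-Whitney concordance) formula with ties counted
    one half, which equals the trapezoidal area under the empirical ROC;
    for a dichotomised predictor it reduces to (Se + Sp)/2.
    """
    s = np.asarray(scores, dtype=float)
    y = _as_labels(labels)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("roc_auc requires both classes present")
    ranks = stats.rankdata(s)
    auc = (ranks[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    thresholds = np.concatenate([[np.inf], np.unique(s)[::-1]])
    rows = []
    for thr in thresholds:
        pred = s >= thr
        rows.append(
            {
                "threshold": thr,
                "fpr": float(np.sum(pred & ~y)) / n_neg,
                "sensitivity": float(np.sum(pred & y)) / n_pos,
            }
        )
    return pd.DataFrame(rows), float(auc)


def cutpoint_sweep(scores, labels, cuts) -> list[CutpointMetrics]:
    """One metrics row per cut, in the given order; the per-cut c-statistic
    is the AUC of the dichotomised predictor (score >= cut), i.e.
    (Se + Sp)/2."""
    y = _as_labels(labels)
    s = np.asarray(scores, dtype=float)
    out = []
    for cut in cuts:
        t = contingency_table(s, y, cut)
        m = diagnostic_metrics(t, cut=int(cut))
        _, m.c_statistic = roc_auc((s >= cut).astype(float), y)
        out.append(m)
    return out


def fit_logistic(x, y) -> LogisticFit:
    """Maximum-likelihood logistic regression of the referral label on one
    predictor (Newton-Raphson via statsmodels).

    For a binary predictor with all four cells positive, exp(slope) equals
    the cross-product odds ratio. Complete or quasi-complete separation is
    reported as converged=False with a diagnostic message.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    x = np.asarray(x, dtype=float)
    yv = _as_labels(y).astype(float)
    if len(x) < 2:
        raise ValidationError("need at least 2 observations")
    if yv.min() == yv.max():
        raise ValidationError("labels contain a single class")
    X = sm.add_constant(x)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            res = sm.Logit(yv, X).fit(disp=0, maxiter=200)
    except (PerfectSeparationError, Warning, np.linalg.LinAlgError) as exc:
        return LogisticFit(
            np.nan, np.nan, np.nan, np.nan, False, f"separation or non-convergence: {exc}"
        )
    params, bse = res.params, res.bse
    if not res.mle_retvals.get("converged", False) or np.abs(params).max() > 15:
        return LogisticFit(
            float(params[0]), float(params[1]), float(bse[0]), float(bse[1]),
            False, "possible separation: extreme coefficients",
        )
    return LogisticFit(
        float(params[0]), float(params[1]), float(bse[0]), float(bse[1]), True
    )


def hosmer_lemeshow(probs, labels, groups: int = 10) -> HosmerLemeshowResult:
    """Hosmer-Lemeshow goodness-of-fit test on fitted probabilities.

    Deciles-of-risk grouping: equal-count groups by sorted probability with
    ties kept together; X^2 = sum (O - n p)^2 / (n p (1-p)); df = G - 2.
    Groups whose mean probability is exactly 0 or 1 are merged with a
    neighbour (df adjusted, warning issued).
    """
    p = np.asarray(probs, dtype=float)
    y = _as_labels(labels).astype(float)
    if groups < 3:
        raise ValidationError("need at least 3 groups")
    if len(p) < groups:
        raise ValidationError("fewer observations than groups")
    order = np.argsort(p, kind="stable")
    p_s, y_s = p[order], y[order]
    n = len(p_s)
    # cut positions at n*g/G, extended so tied probabilities stay together
    bounds = [0]
    for g in range(1, groups):
        b = int(round(n * g / groups))
        b = max(b, bounds[-1])
        while 0 < b < n and p_s[b] == p_s[b - 1]:
            b += 1
        bounds.append(min(b, n))
    bounds.append(n)
    raw_groups = [
        (y_s[a:b], p_s[a:b]) for a, b in zip(bounds[:-1], bounds[1:]) if b > a
    ]
    # merge degenerate groups (mean p exactly 0 or 1) into a neighbour
    merged: list[tuple[np.ndarray, np.ndarray]] = []
    for yy, pp in raw_groups:
        if merged and pp.mean() in (0.0, 1.0):
            warnings.warn("merging degenerate Hosmer-Lemeshow group")
            py, ppv = merged[-1]
            merged[-1] = (np.concatenate([py, yy]), np.concatenate([ppv, pp]))
        else:
            merged.append((yy, pp))
    if merged and merged[0][1].mean() in (0.0, 1.0) and len(merged) > 1:
        warnings.warn("merging degenerate Hosmer-Lemeshow group")
        y0, p0 = merged.pop(0)
        y1, p1 = merged[0]
        merged[0] = (np.concatenate([y0, y1]), np.concatenate([p0, p1]))
    rows = []
    chi2 = 0.0
    for yy, pp in merged:
        ng, og, pg = len(yy), yy.sum(), pp.mean()
        eg = ng * pg
        chi2 += (og - eg) ** 2 / (ng * pg * (1 - pg))
        rows.append({"n": ng, "observed": og, "expected": eg, "mean_p": pg})
    df = len(merged) - 2
    if df < 1:
        raise ValidationError("too few usable groups for the HL test")
    pvalue = float(stats.chi2.sf(chi2, df))
    return HosmerLemeshowResult(float(chi2), df, pvalue, pd.DataFrame(rows))


def format_table3(metrics: list[CutpointMetrics]) -> pd.DataFrame:
    """Display-rounded performance table: odds ratio/Se/Sp at 2 dp, PPV/NPV/
    percent correct at 1 dp, c-statistic at 3 dp, '.' for undefined ORs."""
    rows = []
    for m in metrics:
        rows.append(
            {
                "cut_point": f">= {m.cut}",
                "odds_ratio": "." if np.isnan(m.odds_ratio) else f"{m.odds_ratio:.2f}",
                "sensitivity": f"{m.sensitivity:.2f}",
                "specificity": f"{m.specificity:.2f}",
                "ppv_pct": f"{m.ppv:.1f}",
                "npv_pct": f"{m.npv:.1f}",
                "pct_warranting_referral": f"{m.pct_correct:.1f}",
                "c_statistic": f"{m.c_statistic:.3f}",
            }
        )
    return pd.DataFrame(rows)


def plot_roc(points: pd.DataFrame, auc: float | None = None, path=None):
    """Plot an ROC curve (1-Sp against Se) from exported ROC points."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot(points["fpr"], points["sensitivity"], marker="o", drawstyle="steps-post")
    ax.plot([0, 1], [0, 1], ls="--", color="grey", lw=0.8)
    ax.set_xlabel("1 - Specificity (false positive rate)")
    ax.set_ylabel("Sensitivity (true positive rate)")
    title = "ROC of total score predicting urologist referral"
    if auc is not None:
        title += f" (AUC = {auc:.3f})"
    ax.set_title(title, fontsize=10)
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return ax
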