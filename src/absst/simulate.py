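"""Study-like synthetic inputs: Partial Credit Model responses, clinician
pivot surveys, referral labels, and the deterministic fixture that encodes
the published cut-point performance table.

The generator emulates the validation study's conditions: 151 MS patients
recruited by 28 clinicians of whom 23 returned the pivot survey, ordinal
0-4 responses on 16 symptom/impact/coping items plus one binary
help-seeking item, and a clinician referral recommendation linked to the
completed questionnaire's total score.

Randomness: one seed per run; each stage draws from an independent
sub-stream derived from the stage name, so adding a stage never shifts
another stage's draws.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import ItemSpec, ReferralLabels, ResponseMatrix, ValidationError, default_instrument
from .pcm import category_probabilities
from .scoring import PivotRule

__all__ = [
    "SimulationConfig",
    "stage_rng",
    "simulate_pcm_responses",
    "simulate_clinician_survey",
    "simulate_referrals",
    "build_table3_fixture",
    "TABLE3_CUTS",
]

TABLE3_CUTS = (21, 9, 6, 4, 1)


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent generator for one pipeline stage, derived from the run
    seed and the stage name (stable across runs and stage additions)."""
    key = zlib.crc32(stage.encode())
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(key,)))


def _default_item_steps(instrument: list[ItemSpec]) -> dict[str, list[float]]:
    """Ordered step difficulties per item: item locations spread over
    -1..+2 logits (symptoms common, severe impact rarer) with step offsets
    -1.5..+1.5 around each location; the binary help item sits at +0.5."""
    ordinal = [it for it in instrument if not it.is_binary]
    locs = np.linspace(-1.0, 2.0, len(ordinal))
    steps = {}
    for it, loc in zip(ordinal, locs):
        offsets = np.linspace(-1.5, 1.5, it.max_category)
        steps[it.item_id] = list(loc + offsets)
    for it in instrument:
        if it.is_binary:
            steps[it.item_id] = [0.5]
    return steps


@dataclass
class SimulationConfig:
    """Generative truth for one simulated study.

    theta_mean / theta_sd   latent severity distribution (logits); the
                            default N(-1, 1.5^2) concentrates responses
                            toward the floor, as screening populations do
    item_steps              per-item PCM step difficulties delta_ik (logits)
    referral_intercept/slope  logistic-link coefficients on the raw total
                            score (defaults give ~1/3 referral prevalence)
    referral_on             'raw_total' (clinician judges the completed
                            questionnaire) or 'latent'
    clinician_count / clinician_response_rate  survey denominator and the
                            per-clinician probability of returning it
    relevance_prob          probability a responder marks an item relevant
    threshold_jitter_prob   probability a reported threshold is off by one
    """

    n_persons: int = 151
    theta_mean: float = -1.0
    theta_sd: float = 1.5
    item_steps: dict[str, list[float]] | None = None
    instrument: list[ItemSpec] = field(default_factory=default_instrument)
    referral_intercept: float = -5.5
    referral_slope: float = 0.25
    referral_on: str = "raw_total"
    clinician_count: int = 28
    clinician_response_rate: float = 23 / 28
    relevance_prob: float = 0.7
    threshold_jitter_prob: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_persons < 2:
            raise ValidationError("n_persons must be >= 2")
        if self.theta_sd <= 0:
            raise ValidationError("theta_sd must be positive")
        if self.item_steps is None:
            self.item_steps = _default_item_steps(self.instrument)
        for it in self.instrument:
            steps = np.asarray(self.item_steps.get(it.item_id, []), dtype=float)
            if steps.shape != (it.max_category,):
                raise ValidationError(
                    f"item {it.item_id!r} needs {it.max_category} steps, "
                    f"got {steps.shape}"
                )
            if not np.all(np.isfinite(steps)):
                raise ValidationError(f"non-finite steps for {it.item_id!r}")
        if self.referral_on not in ("raw_total", "latent"):
            raise ValidationError(f"unknown referral_on {self.referral_on!r}")


def simulate_pcm_responses(
    cfg: SimulationConfig,
) -> tuple[ResponseMatrix, pd.Series]:
    """Draw one response per (person, item) from PCM category probabilities
    at the person's true latent severity. Returns the matrix and the true
    thetas (for recovery checks)."""
    rng = stage_rng(cfg.seed, "responses")
    persons = [f"p{i + 1:03d}" for i in range(cfg.n_persons)]
    theta = rng.normal(cfg.theta_mean, cfg.theta_sd, size=cfg.n_persons)
    cols = {}
    for it in cfg.instrument:
        probs = category_probabilities(theta, cfg.item_steps[it.item_id])
        u = rng.random(cfg.n_persons)
        cols[it.item_id] = (u[:, None] >= probs.cumsum(axis=1)).sum(axis=1)
    values = pd.DataFrame(cols, index=pd.Index(persons, name="person"), dtype=float)
    matrix = ResponseMatrix(values, list(cfg.instrument))
    return matrix, pd.Series(theta, index=values.index, name="theta_true")


def simulate_clinician_survey(cfg: SimulationConfig, true_rule: PivotRule):
    """Survey returned by a random subset of clinicians; each responder
    marks items relevant with ``relevance_prob`` and reports the true
    threshold, off by one category with ``threshold_jitter_prob`` (clipped
    to the item's 1..m range)."""
    from .data import ClinicianSurvey

    rng = stage_rng(cfg.seed, "clinician_survey")
    responded = rng.random(cfg.clinician_count) < cfg.clinician_response_rate
    responders = [f"c{i + 1:02d}" for i in range(cfg.clinician_count) if responded[i]]
    if not responders:
        raise ValidationError("no clinician responded; re-seed or raise the rate")
    rel, thr = {}, {}
    for it in cfg.instrument:
        t_true = true_rule.thresholds.get(it.item_id)
        if t_true is None:
            raise ValidationError(f"true rule lacks a threshold for {it.item_id!r}")
        if not 1 <= t_true <= it.max_category:
            raise ValidationError(
                f"true threshold {t_true} outside 1..{it.max_category} "
                f"for {it.item_id!r}"
            )
        relevant = rng.random(len(responders)) < cfg.relevance_prob
        jitter = rng.random(len(responders)) < cfg.threshold_jitter_prob
        direction = rng.choice([-1, 1], size=len(responders))
        reported = np.clip(t_true + jitter * direction, 1, it.max_category)
        rel[it.item_id] = pd.Series(relevant, index=responders)
        thr[it.item_id] = pd.Series(
            np.where(relevant, reported.astype(float), np.nan), index=responders
        )
    return ClinicianSurvey(pd.DataFrame(rel), pd.DataFrame(thr), list(cfg.instrument))


def simulate_referrals(scores: pd.Series, cfg: SimulationConfig) -> ReferralLabels:
    """Referral recommendation ~ Bernoulli(logistic(a + b * score))."""
    from scipy.special import expit

    rng = stage_rng(cfg.seed, "referrals")
    s = np.asarray(scores, dtype=float)
    p = expit(cfg.referral_intercept + cfg.referral_slope * s)
    referred = rng.random(len(s)) < p
    index = scores.index if isinstance(scores, pd.Series) else pd.RangeIndex(len(s))
    return ReferralLabels(pd.Series(referred, index=index, name="referred"))


# Deterministic score/label allocation consistent with the published
# cut-point table: at cuts (21, 9, 6, 4, 1) it reproduces every printed
# sensitivity, specificity, PPV, NPV, odds-ratio, percent-correct and
# per-cut c-statistic cell. 49 referred + 102 non-referred = 151. Scores sit
# at bin lower edges; any placement within bins yields the same table.
_FIXTURE_REFERRED = ((21, 1), (9, 33), (6, 8), (4, 4), (1, 2), (0, 1))
_FIXTURE_NON_REFERRED = ((9, 4), (6, 3), (4, 25), (1, 55), (0, 15))


def build_table3_fixture() -> tuple[pd.Series, ReferralLabels]:
    """The 151 (raw total score, referral label) pairs that reproduce the
    published cut-point performance table exactly (constant output)."""
    scores, labels, ids = [], [], []
    i = 0
    for group, referred in ((_FIXTURE_REFERRED, True), (_FIXTURE_NON_REFERRED, False)):
        for score, count in group:
            for _ in range(count):
                i += 1
                ids.append(f"p{i:03d}")
                scores.append(score)
                labels.append(referred)
    index = pd.Index(ids, name="person")
    return (
        pd.Series(scores, index=index, name="raw_total"),
        ReferralLabels(pd.Series(labels, index=index, name="referred")),
    )
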