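"""End-to-end orchestration: simulate (or load) -> classical item screening
-> Rasch analysis -> pivot scoring -> item reduction -> predictive validity,
with a manifest for byte-reproducible reruns.

Every stage writes plain delimited files into the output directory, so any
stage can also be run standalone on those files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib.metadata import version as _pkg_version
from pathlib import Path

import pandas as pd
import yaml

from . import ctt as ctt_mod
from . import data as io
from . import diagnostics as dx
from . import pcm as pcm_mod
from . import reduction, scoring, simulate

logger = logging.getLogger(__name__)

__all__ = ["PipelineManifest", "run_pipeline", "default_true_rule"]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class PipelineManifest:
    """Reproducibility record: config snapshot, input/output hashes, seed."""

    config: dict
    seed: int
    input_hashes: dict[str, str]
    output_hashes: dict[str, str]
    stage_versions: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)

    def write(self, path: Path) -> None:
        Path(path).write_text(self.to_json())


def default_true_rule(instrument) -> scoring.PivotRule:
    """Generative truth for simulated clinician surveys: flag only the top
    category on intensity/frequency symptom items (frequent symptoms are
    only actionable when constant), category 3 on impact/coping items, and
    any 'Yes' on the binary help item."""
    thresholds, endorsement = {}, {}
    for it in instrument:
        if it.is_binary:
            thresholds[it.item_id] = 1
        elif it.subscale in ("symptom_intensity", "symptom_frequency"):
            thresholds[it.item_id] = it.max_category
        else:
            thresholds[it.item_id] = max(1, it.max_category - 1)
        endorsement[it.item_id] = 100.0
    return scoring.PivotRule(thresholds, endorsement, n_responders=0)


def _load_or_simulate(cfg: dict, out: Path, seed: int):
    instrument = io.default_instrument()
    inputs = {}
    if "inputs" in cfg:
        paths = cfg["inputs"]
        for key in ("responses", "survey", "labels"):
            if key not in paths:
                raise io.ValidationError(f"config inputs missing {key!r} path")
            if not Path(paths[key]).exists():
                raise io.ValidationError(f"input file not found: {paths[key]}")
        responses = io.read_responses(paths["responses"], instrument)
        survey = io.read_clinician_survey(paths["survey"], instrument)
        labels = io.read_labels(paths["labels"])
        inputs = {k: _sha256(Path(p)) for k, p in paths.items()}
    else:
        sim_kwargs = dict(cfg.get("simulate", {}))
        sim_kwargs["seed"] = seed
        sim_cfg = simulate.SimulationConfig(**sim_kwargs)
        responses, theta = simulate.simulate_pcm_responses(sim_cfg)
        survey = simulate.simulate_clinician_survey(
            sim_cfg, default_true_rule(instrument)
        )
        gen_total = scoring.raw_total_score(responses, responses.ordinal_item_ids())
        labels = simulate.simulate_referrals(gen_total, sim_cfg)
        theta.to_csv(out / "theta_true.csv", index_label="person")
        io.write_responses(responses, out / "responses.csv")
        io.write_clinician_survey(survey, out / "survey.csv")
        io.write_labels(labels, out / "labels.csv")
        inputs = {
            k: _sha256(out / f"{k}.csv") for k in ("responses", "survey", "labels")
        }
    return responses, survey, labels, inputs


def run_pipeline(config_path: str | Path) -> PipelineManifest:
    """Execute all stages per the YAML config; returns the manifest.

    Config keys: ``out_dir``; either ``inputs: {responses, survey, labels}``
    (CSV paths) or ``simulate: {...}`` (SimulationConfig fields); optional
    ``seed``, ``cuts``, ``selection_policy``, ``referral_cut``,
    ``run_config`` (RunConfig fields).
    """
    cfg = yaml.safe_load(Path(config_path).read_text()) or {}
    out = Path(cfg.get("out_dir", "absst_out"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    rc_kwargs = dict(cfg.get("run_config", {}))
    rc_kwargs.setdefault("seed", seed)
    if "infit_band" in rc_kwargs:
        rc_kwargs["infit_band"] = tuple(rc_kwargs["infit_band"])
    run_cfg = io.RunConfig(**rc_kwargs)

    def stage(name):
        logger.info("stage: %s", name)

    stage("inputs")
    responses, survey, labels, input_hashes = _load_or_simulate(cfg, out, seed)

    stage("ctt")
    ctt_stats = ctt_mod.item_statistics(responses, run_cfg)
    io.write_report(ctt_stats, out / "ctt.csv")

    stage("rasch")
    fits = pcm_mod.fit_by_subscale(responses, run_cfg)
    fit_stats = []
    item_tables, scale_rows = [], []
    for sub, fit in fits.items():
        fit_stats.extend(fit.fit_statistics())
        t = fit.item_table()
        t.insert(0, "subscale", sub)
        item_tables.append(t)
        s = fit.separation_reliability()
        scale_rows.append({"subscale": sub, **dataclasses.asdict(s)})
    pd.concat(item_tables).to_csv(out / "rasch_items.csv", index=False)
    io.write_report(scale_rows, out / "rasch_scale.csv")
    pd.concat([f.person_table() for f in fits.values()], axis=1, keys=fits).to_csv(
        out / "rasch_persons.csv"
    )

    stage("pivot")
    rule = scoring.aggregate_thresholds(survey, run_cfg)
    for fit in fit_stats:
        logger.info(
            "criterion infit %s: %.3f (band %s)",
            fit.item_id, fit.infit_mnsq, run_cfg.infit_band,
        )
    io.write_report(rule.to_frame(), out / "pivot_rule.csv")

    stage("reduce")
    report = reduction.evaluate_criteria(ctt_stats, fit_stats, rule, run_cfg)
    policy = cfg.get("selection_policy", "any_criterion")
    retained = reduction.select_items(report, policy)
    io.write_report(report.to_frame(), out / "criteria.csv")
    (out / "retained_items.txt").write_text("\n".join(retained) + "\n")
    logger.info("retained %d items under %s: %s", len(retained), policy, retained)

    stage("score")
    referral_cut = int(cfg.get("referral_cut", 6))
    scored = scoring.score_patients(responses, rule, retained, referral_cut)
    scored_df = pd.DataFrame(
        [
            {
                "person": s.person,
                "flag_score": s.flag_score,
                "raw_total": s.raw_total,
                "refer_recommended": s.refer_recommended,
            }
            for s in scored
        ]
    )
    scored_df.to_csv(out / "scores.csv", index=False)

    stage("validate")
    totals = scored_df.set_index("person")["raw_total"]
    y = labels.aligned_to(totals.index)
    cuts = list(cfg.get("cuts", simulate.TABLE3_CUTS))
    metrics = dx.cutpoint_sweep(totals, y, cuts)
    io.write_report(metrics, out / "cutpoints.csv")
    dx.format_table3(metrics).to_csv(out / "cutpoints_display.csv", index=False)
    points, auc = dx.roc_auc(totals, y)
    io.write_roc_points(points, out / "roc.csv")
    logit = dx.fit_logistic(totals.to_numpy(), y)
    validity = {"auc_total_score": auc, **dataclasses.asdict(logit)}
    if logit.converged:
        import numpy as np

        p = 1.0 / (1.0 + np.exp(-(logit.intercept + logit.slope * totals.to_numpy())))
        hl = dx.hosmer_lemeshow(p, y)
        validity.update(hl_chi2=hl.chi2, hl_df=hl.df, hl_pvalue=hl.pvalue)
    (out / "validity.json").write_text(json.dumps(validity, indent=1))

    artefacts = sorted(p for p in out.iterdir() if p.is_file() and p.name != "manifest.json")
    manifest = PipelineManifest(
        config=cfg,
        seed=seed,
        input_hashes=input_hashes,
        output_hashes={p.name: _sha256(p) for p in artefacts},
        stage_versions={s: _version() for s in
                        ("inputs", "ctt", "rasch", "pivot", "reduce", "score", "validate")},
    )
    manifest.write(out / "manifest.json")
    return manifest


def _version() -> str:
    try:
        return _pkg_version("absst")
    except Exception:
        return "0"
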