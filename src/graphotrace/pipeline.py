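"""End-to-end experiment pipeline on simulated data.

Mirrors the study flow: synthesize the stimulus ring, simulate the cohort's
assessment blocks (pre / post / retention), score discrimination accuracy and
distance error, run the mixed-design and baseline-adjusted statistics, and —
for the two-hand experiment — simulate and score tracing kinematics per hand
and session.  Every artifact is written to the output directory and recorded
in a manifest of SHA-256 hashes, so two runs with the same configuration and
seed produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import pandas as pd

from . import assessment, cohort, kinematics, shapes, stats
from .io import RunConfig, write_shape_set, write_traces, write_trials


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _float_fmt(df: pd.DataFrame) -> pd.DataFrame:
    return df.round(12)


def run_experiment_pipeline(config: RunConfig) -> Path:
    """Execute shapes -> cohort_sim -> assessment/kinematics -> stats.

    Returns the output directory.  Raises the failing stage's error; partial
    outputs written before the failure are preserved.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    def emit(name: str, writer) -> Path:
        path = out / name
        writer(path)
        manifest[name] = _sha256(path)
        return path

    # stage: shapes
    shape_set = shapes.generate_shape_set(config.shape_config, seed=config.seed)
    emit("shape_set.json", lambda p: write_shape_set(shape_set, p))

    # stage: cohort simulation
    groups = None
    if config.group_overrides:
        base = (cohort.EXPERIMENT1_GROUPS if config.experiment == 1
                else cohort.EXPERIMENT2_GROUPS)
        groups = tuple(dataclasses.replace(g, **config.group_overrides.get(g.label, {}))
                       for g in base)
    trials = cohort.simulate_cohort(config.experiment, configs=groups,
                                    seed=config.seed, lapse=config.kernel_lapse)
    emit("trials.csv", lambda p: write_trials(trials, p))

    # stage: assessment scoring
    scores = assessment.score_trial_table(trials)
    emit("scores.csv", lambda p: _float_fmt(scores).to_csv(p, index=False))
    adjusted = assessment.baseline_adjust(scores)
    emit("scores_baseline_adjusted.csv",
         lambda p: _float_fmt(adjusted).to_csv(p, index=False))

    # stage: statistics
    report_frames = []
    for measure in ("accuracy", "distance_error"):
        table = scores.rename(columns={measure: "value"})
        res = stats.mixed_anova(table)
        frame = res.to_frame()
        frame.insert(0, "measure", measure)
        frame["mauchly_w"] = res.sphericity.mauchly_w
        frame["mauchly_p"] = res.sphericity.p
        frame["gg_epsilon"] = res.sphericity.gg_epsilon
        report_frames.append(frame)
    anova_report = pd.concat(report_frames, ignore_index=True)
    emit("anova_report.csv",
         lambda p: _float_fmt(anova_report).to_csv(p, index=False))

    posthoc_rows = []
    for measure in ("accuracy", "distance_error"):
        table = scores.rename(columns={measure: "value"})
        for ph in stats.bonferroni_posthoc(table):
            posthoc_rows.append({"measure": measure, **dataclasses.asdict(ph)})
    emit("posthoc_report.csv",
         lambda p: _float_fmt(pd.DataFrame(posthoc_rows)).to_csv(p, index=False))

    bayes_rows = []
    for measure in ("accuracy", "distance_error"):
        table = scores.rename(columns={measure: "value"})
        for br in stats.bayes_factor_anova(table):
            bayes_rows.append({"measure": measure, "model": br.model,
                               "bf01": br.bf01})
    emit("bayes_report.csv",
         lambda p: _float_fmt(pd.DataFrame(bayes_rows)).to_csv(p, index=False))

    # stage: kinematics (two-hand experiment only)
    if config.experiment == 2:
        traces = []
        for hand_params in (cohort.NONDOMINANT_PARAMS, cohort.DOMINANT_PARAMS):
            for day in (1, 2):
                traces += cohort.simulate_hand_session_traces(
                    shape_set, hand_params,
                    n_per_shape=config.n_trace_trials_per_shape,
                    seed=config.seed, session_day=day)
        emit("traces.csv", lambda p: write_traces(traces, p))
        metrics = kinematics.score_trace_table(traces, shape_set)
        emit("trace_metrics.csv",
             lambda p: _float_fmt(metrics).to_csv(p, index=False))
        emit("tracing_session_means.csv",
             lambda p: _float_fmt(kinematics.session_means(metrics))
             .to_csv(p, index=False))

    (out / "manifest.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=2), encoding="utf-8")
    return out
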