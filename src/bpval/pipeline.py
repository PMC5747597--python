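"""End-to-end pipeline: load or simulate a study, run the validation,
reliability and agreement stages, and write machine-readable reports.

Outputs (all under ``output_dir``):

* ``reliability.json``  — per session x variable mean (SD), range, ICC
  (95% CI), SEM, plus intersession paired-t results
* ``validation.json``   — band counts, requirements, phase verdicts,
  mean +/- SD of differences and the overall verdict
* ``agreement.json``    — per-scope device means, t-test, Pearson r,
  Bland-Altman bias and limits
* ``ba_points_<scope>.csv`` — Bland-Altman point sets for plotting
* ``summary.txt``       — plain-text run summary with the overall verdict
* ``manifest.json``     — inputs, seed, package version, options in force

Reports are JSON-first, deterministic, and contain no timestamps so a rerun
with the same manifest is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import __version__
from .agreement import (
    Scope,
    TTestMode,
    bland_altman,
    device_correlation,
    device_mean_comparison,
    participant_means,
)
from .io import read_study, write_study
from .model import StudyDataset, Variable
from .protocol import ValidationVerdict, validate_device
from .reliability import (
    IccModel,
    RepeatedMeasuresMatrix,
    icc_estimate,
    intersession_change_test,
    normality_check,
)
from .simulate import SimulationConfig, generate_study, load_scenario

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline",
           "reliability_report", "agreement_report", "validation_report"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    input_path: Optional[Union[str, Path]] = None
    scenario: Optional[Union[str, Path]] = None
    variables: Sequence[str] = ("SBP", "DBP", "HR")
    sessions: Sequence[int] = (1, 2)
    icc_model: IccModel = IccModel.TWO_WAY_RANDOM_ABSOLUTE
    ttest_mode: TTestMode = TTestMode.INDEPENDENT
    output_dir: Union[str, Path] = "bpval_out"
    seed: Optional[int] = None
    check_normality: bool = False

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.scenario is None):
            raise ValueError("exactly one of input_path or scenario must be set")


def _round2(x: float) -> Optional[float]:
    return None if x is None or not np.isfinite(x) else round(float(x), 2)


def _jsonable(x):
    if dataclasses.is_dataclass(x) and not isinstance(x, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(x).items()}
    if isinstance(x, dict):
        return {str(k): _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    if isinstance(x, (np.floating, float)):
        x = float(x)
        return x if np.isfinite(x) else None
    if isinstance(x, (np.integer,)):
        return int(x)
    if hasattr(x, "value"):
        return x.value
    return x


def reliability_report(
    dataset: StudyDataset,
    variables: Sequence[str],
    icc_model: IccModel = IccModel.TWO_WAY_RANDOM_ABSOLUTE,
    check_normality: bool = False,
    seed: int = 0,
) -> dict:
    """Intrasession and intersession reliability per variable."""
    report: dict = {"icc_model": icc_model.value, "sessions": {}, "intersession": {}}
    for sess in (1, 2):
        block = {}
        for var in variables:
            rows = [
                s.test_values()
                for s in dataset.iter_series(session=sess, variable=var, complete_only=True)
            ]
            if len(rows) < 2:
                continue
            est = icc_estimate(RepeatedMeasuresMatrix(np.array(rows)), icc_model)
            block[var] = {
                "units": Variable(var).units,
                "n": est.n,
                "k": est.k,
                "mean": _round2(est.mean),
                "sd": _round2(est.sd),
                "range": [_round2(est.range[0]), _round2(est.range[1])],
                "icc": _round2(est.icc),
                "icc_ci": [_round2(est.ci_low), _round2(est.ci_high)],
                "sem": _round2(est.sem),
                "interpretation": est.interpretation,
            }
        report["sessions"][str(sess)] = block

    completers = dataset.complete_participants((1, 2), variables)
    for var in variables:
        if len(completers) < 2:
            continue
        m1, m2 = [], []
        for pid in completers:
            m1.append(float(np.mean(dataset.get_series(pid, 1, var).test_values())))
            m2.append(float(np.mean(dataset.get_series(pid, 2, var).test_values())))
        matrix = RepeatedMeasuresMatrix(np.column_stack([m1, m2]))
        est = icc_estimate(matrix, icc_model)
        ttest = intersession_change_test(m1, m2)
        entry = {
            "units": Variable(var).units,
            "n": est.n,
            "mean": _round2(est.mean),
            "sd": _round2(est.sd),
            "range": [_round2(est.range[0]), _round2(est.range[1])],
            "icc": _round2(est.icc),
            "icc_ci": [_round2(est.ci_low), _round2(est.ci_high)],
            "sem": _round2(est.sem),
            "interpretation": est.interpretation,
            "paired_t": _round2(ttest.t),
            "paired_p": _round2(ttest.p),
            "mean_change": _round2(ttest.mean_change),
        }
        if check_normality:
            pooled = np.concatenate([m1, m2])
            nres = normality_check(pooled, seed=seed)
            entry["normality"] = {"ks": _round2(nres.statistic), "p": _round2(nres.p)}
        report["intersession"][var] = entry
    return report


def validation_report(verdict: ValidationVerdict) -> dict:
    req = verdict.requirements
    report = {
        "n_subjects": verdict.n_subjects,
        "requirements": {
            "scale_factor": req.scale_factor,
            "pair_two_of": list(req.pair_two_of),
            "pair_all_of": list(req.pair_all_of),
            "subj_min_good": req.subj_min_good,
            "subj_max_bad": req.subj_max_bad,
        },
        "results": {},
        "overall": verdict.overall.value,
        "failing_criteria": verdict.failing(),
    }
    for (sess, var), r in sorted(verdict.results.items()):
        report["results"][f"session{sess}:{var}"] = {
            "band_counts": list(r.phase1.counts["band_counts"]),
            "beyond_b3": r.phase1.counts["beyond_b3"],
            "phase1": r.phase1.verdict.value,
            "subject_counts": r.phase2.counts,
            "phase2": r.phase2.verdict.value,
            "mean_difference": _round2(r.mean_difference),
            "sd_difference": _round2(r.sd_difference),
            "units": Variable(var).units,
        }
    return report


def agreement_report(
    dataset: StudyDataset,
    variables: Sequence[str],
    ttest_mode: TTestMode = TTestMode.INDEPENDENT,
) -> tuple[dict, dict[str, pd.DataFrame]]:
    """Agreement per scope x variable plus Bland-Altman point tables."""
    report: dict = {"ttest_mode": ttest_mode.value, "scopes": {}}
    points: dict[str, pd.DataFrame] = {}
    for scope in Scope:
        block = {}
        rows = []
        for var in variables:
            means = participant_means(dataset, scope, [var])
            if len(means) < 3:
                continue
            comp = device_mean_comparison(means, ttest_mode)
            corr = device_correlation(means)
            ba = bland_altman(means)
            block[var] = {
                "units": Variable(var).units,
                "n": comp.n,
                "criterion_mean": _round2(comp.criterion_mean),
                "criterion_sd": _round2(comp.criterion_sd),
                "test_mean": _round2(comp.test_mean),
                "test_sd": _round2(comp.test_sd),
                "t": _round2(comp.t),
                "t_p": _round2(comp.p),
                "pearson_r": None if corr.degenerate else round(corr.r, 3),
                "pearson_p": _round2(corr.p),
                "bland_altman": {
                    "bias": _round2(ba.bias),
                    "sd_diff": _round2(ba.sd_diff),
                    "loa_low": _round2(ba.loa_low),
                    "loa_high": _round2(ba.loa_high),
                },
            }
            rows.extend(
                {"participant_id": pid, "variable": var, "avg": avg, "diff": diff}
                for pid, avg, diff in ba.points
            )
        report["scopes"][scope.value] = block
        if rows:
            points[scope.value] = pd.DataFrame(rows)
    return report, points


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and write the report bundle.

    Returns the manifest dict (also written to ``manifest.json``).
    Raises PipelineError naming the failing stage.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    variables = list(config.variables)

    stage = "load"
    try:
        if config.scenario is not None:
            sim = load_scenario(config.scenario)
            if config.seed is not None:
                sim = sim.replace(seed=config.seed)
            dataset = generate_study(sim)
            write_study(dataset, out / "study.csv")
            source = {"scenario": str(config.scenario), "seed": sim.seed}
        else:
            dataset = read_study(config.input_path)
            source = {"input": str(config.input_path)}

        stage = "validation"
        verdict = validate_device(dataset, variables=variables,
                                  sessions=config.sessions)
        val_report = validation_report(verdict)
        (out / "validation.json").write_text(json.dumps(val_report, indent=2) + "\n")

        stage = "reliability"
        rel_report = reliability_report(
            dataset, variables, config.icc_model,
            check_normality=config.check_normality, seed=config.seed or 0,
        )
        (out / "reliability.json").write_text(json.dumps(rel_report, indent=2) + "\n")

        stage = "agreement"
        agr_report, points = agreement_report(dataset, variables, config.ttest_mode)
        (out / "agreement.json").write_text(json.dumps(agr_report, indent=2) + "\n")
        for scope, frame in points.items():
            frame.to_csv(out / f"ba_points_{scope}.csv", index=False)

        stage = "summary"
        lines = [
            "bpval run summary",
            f"source: {source}",
            f"participants with complete data: {verdict.n_subjects}",
            f"variables: {', '.join(variables)}",
            f"overall verdict: {verdict.overall.value.upper()}",
        ]
        lines.extend(f"  FAIL: {item}" for item in val_report["failing_criteria"])
        (out / "summary.txt").write_text("\n".join(lines) + "\n")

        manifest = {
            "tool": "bpval",
            "version": __version__,
            "source": source,
            "options": {
                "variables": variables,
                "sessions": list(config.sessions),
                "icc_model": config.icc_model.value,
                "ttest_mode": config.ttest_mode.value,
                "check_normality": config.check_normality,
            },
            "overall_verdict": verdict.overall.value,
            "outputs": sorted(p.name for p in out.iterdir() if p.name != "manifest.json"),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        return manifest
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
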