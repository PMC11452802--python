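"""End-to-end pipeline: simulate -> score -> classify -> hybrid.

``run_pipeline`` ties the four analysis stages together, writing every
intermediate artifact (manifest, probabilities, scores, predictions,
metrics, hybrid reports) plus a run log recording parameters, seed and
library versions. All randomness flows from the single config seed, so a
rerun with the same config produces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import (
    CVPrediction,
    balanced_accuracy,
    leave_pair_out_cv,
    predictions_frame,
    roc_auroc,
)
from .hybrid import run_hybrid, threshold_sweep
from .io import (
    ensure_dir,
    read_manifest,
    read_probability_table,
    write_manifest,
    write_predictions,
    write_probability_table,
    write_scores,
)
from .scores import DEFAULT_CLUSTER_MIN_S, DEFAULT_THRESHOLD, SCORE_NAMES, scores_table
from .simulate import (
    ConfigError,
    MarkovEmissionParams,
    SimulationConfig,
    generate_cohort,
)

logger = logging.getLogger("ticscreen")

#: Univariate predictors reported by default: the two scores with the
#: strongest discrimination between groups.
DEFAULT_PREDICTORS = ("proportion_tic_intervals", "clusters_per_minute")


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs; serializable to/from YAML."""

    out_dir: str = "ticscreen_run"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    tic_threshold: float = DEFAULT_THRESHOLD
    cluster_min_s: int = DEFAULT_CLUSTER_MIN_S
    predictors: tuple[str, ...] = DEFAULT_PREDICTORS
    ridge: float = 1e-6
    decision_threshold: float = 0.5
    confidence_threshold: float = 0.9
    expert_accuracy_pct: float = 95.0
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 < self.tic_threshold < 1.0):
            raise ConfigError(f"tic_threshold must be in (0, 1), got {self.tic_threshold}")
        if self.cluster_min_s < 1:
            raise ConfigError("cluster_min_s must be >= 1")
        if not (0.0 < self.decision_threshold < 1.0):
            raise ConfigError("decision_threshold must be in (0, 1)")
        if not (0.5 <= self.confidence_threshold < 1.0):
            raise ConfigError("confidence_threshold must be in [0.5, 1)")
        if not (0.0 <= self.expert_accuracy_pct <= 100.0):
            raise ConfigError("expert_accuracy_pct must be in [0, 100]")
        if self.ridge < 0:
            raise ConfigError("ridge must be >= 0")
        unknown = [p for p in self.predictors if p not in SCORE_NAMES]
        if unknown:
            raise ConfigError(f"unknown predictors {unknown}; valid scores: {list(SCORE_NAMES)}")
        self.simulation.validate()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["predictors"] = list(self.predictors)
        d["simulation"]["videos_per_participant"] = list(
            self.simulation.videos_per_participant
        )
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.pop("simulation", {})
        if isinstance(sim, dict):
            sim = dict(sim)
            for key in ("gts_params", "hc_params"):
                if key in sim and isinstance(sim[key], dict):
                    sim[key] = MarkovEmissionParams(**sim[key])
            if "videos_per_participant" in sim:
                sim["videos_per_participant"] = tuple(sim["videos_per_participant"])
            sim = SimulationConfig(**sim)
        if "predictors" in d:
            d["predictors"] = tuple(d["predictors"])
        return cls(simulation=sim, **d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.from_dict(payload)


def setup_logging(level: int = logging.INFO) -> None:
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        logger.addHandler(handler)
    logger.setLevel(level)


def _metrics_for_predictions(
    preds: list[CVPrediction], decision_threshold: float
) -> dict:
    roc = roc_auroc(preds)
    return {
        "auroc": roc.auroc,
        "balanced_accuracy": balanced_accuracy(preds, decision_threshold),
        "n_videos": len(preds),
    }


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Execute all stages and write artifacts; returns written paths.

    Fits one univariate cross-validated model per configured predictor plus
    the multivariate model on the configured predictor set, and a hybrid
    review report per model.
    """
    config.validate()
    out = ensure_dir(config.out_dir)
    paths = {
        "config": out / "config.yaml",
        "manifest": out / "manifest.csv",
        "probabilities": out / "probabilities.csv",
        "scores": out / "scores.csv",
        "predictions": out / "predictions.csv",
        "metrics": out / "metrics.json",
        "hybrid": out / "hybrid_report.json",
        "sweep": out / "hybrid_sweep.csv",
        "run_log": out / "run_log.json",
    }

    with open(paths["config"], "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)

    logger.info("simulate: generating cohort (%d pairs)", config.simulation.n_pairs)
    sim = dataclasses.replace(config.simulation, seed=config.seed)
    cohort = generate_cohort(sim)
    manifest = cohort.manifest()
    write_manifest(manifest, paths["manifest"])
    write_probability_table(cohort.videos, paths["probabilities"])

    logger.info("score: computing tic summary scores for %d videos", len(cohort.videos))
    scores = scores_table(cohort.videos, config.tic_threshold, config.cluster_min_s)
    write_scores(scores, paths["scores"])

    model_specs: dict[str, list[str]] = {p: [p] for p in config.predictors}
    if len(config.predictors) > 1:
        model_specs["multivariate"] = list(config.predictors)

    all_preds = []
    metrics: dict[str, dict] = {}
    hybrid_reports: dict[str, dict] = {}
    sweep_frames = []
    grid = np.round(np.arange(0.5, 1.0, 0.05), 2)
    for name, predictor_list in model_specs.items():
        logger.info("classify: leave-pair-out CV, model=%s", name)
        preds = leave_pair_out_cv(manifest, scores, predictor_list, ridge=config.ridge)
        frame = predictions_frame(preds)
        frame.insert(0, "model", name)
        all_preds.append(frame)
        metrics[name] = _metrics_for_predictions(preds, config.decision_threshold)
        logger.info(
            "classify: model=%s AUROC=%.3f balanced accuracy=%.1f%%",
            name, metrics[name]["auroc"], metrics[name]["balanced_accuracy"],
        )
        report = run_hybrid(
            preds,
            confidence_threshold=config.confidence_threshold,
            expert_accuracy=config.expert_accuracy_pct,
            seed=config.seed,
            decision_threshold=config.decision_threshold,
        )
        hybrid_reports[name] = dataclasses.asdict(report)
        logger.info(
            "hybrid: model=%s review burden=%.1f%% combined accuracy=%.1f%%",
            name, report.review_fraction, report.combined_accuracy,
        )
        sweep = threshold_sweep(
            preds, grid, expert_accuracy=config.expert_accuracy_pct, seed=config.seed
        )
        sweep.insert(0, "model", name)
        sweep_frames.append(sweep)

    write_predictions(pd.concat(all_preds, ignore_index=True), paths["predictions"])
    with open(paths["metrics"], "w") as fh:
        json.dump(metrics, fh, indent=2)
    with open(paths["hybrid"], "w") as fh:
        json.dump(hybrid_reports, fh, indent=2)
    pd.concat(sweep_frames, ignore_index=True).to_csv(paths["sweep"], index=False)

    run_log = {
        "package": "ticscreen",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "versions": {
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "artifacts": {k: str(v) for k, v in paths.items()},
    }
    with open(paths["run_log"], "w") as fh:
        json.dump(run_log, fh, indent=2)
    logger.info("pipeline complete; artifacts in %s", out)
    return paths
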