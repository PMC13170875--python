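"""End-to-end experiment orchestration.

One config, one seed, one output directory: generate a synthetic cohort,
train each model arm (text-only, audio-only, gated fusion) under the
repeated-iteration protocol, compare arms with the tiered statistical
framework, optionally run the mock-LLM harness, and write every table plus
a replayable manifest. A single global seed fans out to per-stage seeds
through ``numpy.random.SeedSequence.spawn`` so stages are independently
reproducible.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (
    CohortConfig,
    EmbeddingConfig,
    generate_synthetic_cohort,
    write_labels_csv,
)
from .evaluation import (
    PrevalenceSimConfig,
    prevalence_resample,
    roc_curve,
    run_repeated_iterations,
)
from .llm import MockBackend, PromptSpec, make_transcript, run_repetitions
from .model import ModelConfig
from .stats import compare_models

logger = logging.getLogger("crisisdetect")

__all__ = ["ExperimentConfig", "run_experiment", "stage_seeds"]

ARMS = ("text_only", "audio_only", "fused")


@dataclass
class ExperimentConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    embedding: EmbeddingConfig = field(default_factory=EmbeddingConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    arms: tuple[str, ...] = ARMS
    n_iter: int = 100
    n_rep: int = 5
    aggregator: str = "mean"
    prevalence: PrevalenceSimConfig = field(default_factory=PrevalenceSimConfig)
    run_prevalence_sim: bool = True
    run_llm: bool = False
    llm_flip_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if len(set(self.arms)) != len(self.arms):
            raise ValueError("arm names must be unique")
        for arm in self.arms:
            if arm not in ARMS:
                raise ValueError(f"unknown arm {arm!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["arms"] = list(self.arms)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        for key, typ in (("cohort", CohortConfig), ("embedding", EmbeddingConfig),
                         ("model", ModelConfig), ("prevalence", PrevalenceSimConfig)):
            if key in d and isinstance(d[key], dict):
                sub = dict(d[key])
                for k, v in sub.items():
                    if isinstance(v, list):
                        sub[k] = tuple(v)
                d[key] = typ(**sub)
        if "arms" in d:
            d["arms"] = tuple(d["arms"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_plain(self.to_dict()), fh, sort_keys=False)


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def stage_seeds(global_seed: int, stages=("cohort", "embedding", "training", "prevalence", "llm")) -> dict[str, int]:
    """Deterministic fan-out of one global seed into per-stage seeds (< 2^31)."""
    children = np.random.SeedSequence(global_seed).spawn(len(stages))
    return {s: int(c.generate_state(1)[0] % (2**31 - 1)) for s, c in zip(stages, children)}


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_experiment(config: ExperimentConfig, outdir) -> dict:
    """Run the full pipeline and write a report bundle under ``outdir``.

    Writes labels CSV, per-arm metric tables (long format with bootstrap
    CIs), per-iteration values, the model-comparison matrix, ROC points and
    prevalence-simulation draws for the high-risk label, and a manifest
    sufficient to replay the run. Returns the manifest dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    manifest: dict = {
        "config": _plain(config.to_dict()),
        "stage_seeds": seeds,
        "software": {"crisisdetect": __version__, "python": platform.python_version(),
                     "numpy": np.__version__},
        "outputs": [],
    }

    def emit(name: str, frame: pd.DataFrame) -> None:
        path = outdir / name
        frame.to_csv(path, index=False)
        manifest["outputs"].append(name)
        logger.info("wrote %s", path)

    stage = "simulate"
    try:
        cohort_cfg = CohortConfig(**{**config.cohort.__dict__, "seed": seeds["cohort"]})
        emb_cfg = EmbeddingConfig(**{**config.embedding.__dict__, "seed": seeds["embedding"]})
        cohort = generate_synthetic_cohort(cohort_cfg, emb_cfg)
        write_labels_csv(cohort, outdir / "labels.csv")
        manifest["outputs"].append("labels.csv")
        logger.info("simulated cohort: %d records", len(cohort.records))

        stage = "train_evaluate"
        arm_samples: dict[str, dict[str, np.ndarray]] = {}
        scores_by_arm = {}
        for arm in config.arms:
            model_cfg = dict(config.model.__dict__)
            if arm == "text_only":
                model_cfg["input_dim"] = emb_cfg.text_dim
            elif arm == "audio_only":
                model_cfg["input_dim"] = (
                    emb_cfg.audio_dim if config.aggregator == "mean" else 128
                )
            else:
                model_cfg["input_dim"] = emb_cfg.text_dim
                model_cfg["audio_input_dim"] = (
                    emb_cfg.audio_dim if config.aggregator == "mean" else 128
                )
            report, per_iter, (probs, y_prosp) = run_repeated_iterations(
                cohort,
                ModelConfig(**model_cfg),
                mode=arm,
                n_iter=config.n_iter,
                aggregator=config.aggregator,
                seed=seeds["training"],
                collect_scores=True,
            )
            table = report.table.copy()
            table.insert(0, "model", arm)
            per_iter = per_iter.copy()
            per_iter.insert(0, "model", arm)
            emit(f"metrics_{arm}.csv", table)
            emit(f"per_iteration_{arm}.csv", per_iter)
            scores_by_arm[arm] = (probs, y_prosp)
            arm_samples[arm] = {
                f"{label}/{metric}": grp["value"].to_numpy()
                for (label, metric), grp in per_iter.groupby(["label", "metric"], sort=False)
            }
            logger.info("arm %s: high_risk F1 mean %.3f", arm,
                        report.value("high_risk", "f1"))

        stage = "roc"
        for arm, (probs, y_prosp) in scores_by_arm.items():
            fpr, tpr, thr, auc = roc_curve(probs[:, 3], y_prosp[:, 3])
            emit(f"roc_{arm}.csv", pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr}))
            manifest.setdefault("auc_high_risk", {})[arm] = auc

        stage = "compare"
        if len(config.arms) >= 2:
            comparisons = compare_models(arm_samples, seed=seeds["training"])
            emit("comparisons.csv", comparisons)

        stage = "prevalence"
        if config.run_prevalence_sim:
            probs, y_prosp = scores_by_arm[config.arms[0]]
            preds = (probs[:, 3] >= config.model.decision_threshold).astype(int)
            prev_cfg = PrevalenceSimConfig(
                **{**config.prevalence.__dict__, "seed": seeds["prevalence"]}
            )
            n_pos = int((y_prosp[:, 3] == 1).sum())
            n_neg = int((y_prosp[:, 3] == 0).sum())
            if n_pos >= prev_cfg.n_positive_per_draw and n_neg >= prev_cfg.n_negative_per_draw:
                draws = prevalence_resample(y_prosp[:, 3], preds, prev_cfg)
                emit("prevalence_sim.csv", draws)
            else:
                logger.warning(
                    "skipping prevalence simulation: prospective set has %d/%d "
                    "positives/negatives, need %d/%d",
                    n_pos, n_neg, prev_cfg.n_positive_per_draw, prev_cfg.n_negative_per_draw,
                )
                manifest["prevalence_sim_skipped"] = True

        stage = "llm"
        if config.run_llm:
            prosp = [r for r in cohort.records if r.cohort_year == "prospective"]
            dataset = [(r.call_id, make_transcript(r.call_id, r), r.labels()) for r in prosp]
            backend = MockBackend(
                {r.call_id: r.labels() for r in prosp},
                flip_rate=config.llm_flip_rate,
                seed=seeds["llm"],
            )
            report, per_rep, records, failed = run_repetitions(
                backend, dataset, PromptSpec(), n_rep=config.n_rep, seed=seeds["llm"]
            )
            emit("metrics_llm_mock.csv", report.table)
            emit("per_repetition_llm_mock.csv", per_rep)
            with open(outdir / "predictions_llm_mock.jsonl", "w") as fh:
                for rec in records:
                    fh.write(json.dumps(rec.__dict__) + "\n")
            manifest["outputs"].append("predictions_llm_mock.jsonl")
            manifest["llm_failed_calls"] = failed
    except Exception as exc:  # noqa: BLE001 - structured stage reporting
        raise StageError(stage, exc) from exc

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def replay_from_manifest(manifest_path, outdir) -> dict:
    """Re-run an experiment from its manifest; outputs are reproduced."""
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    config = ExperimentConfig.from_dict(manifest["config"])
    return run_experiment(config, outdir)
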