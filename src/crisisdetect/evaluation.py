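"""Per-label metrics, repeated-iteration protocol, bootstrap CIs, ROC, and
the prevalence-aware screening simulation.

The evaluation design mirrors a prospective screening study: models are
trained on a 9:1 train/validation re-partition of an earlier-period pool,
evaluated on a fixed later-period prospective set, and the whole procedure
is repeated (100 iterations in the full protocol) to capture variability
from the random splits. Aggregates are reported as means with percentile
bootstrap 95% confidence intervals over the per-iteration values.

The prevalence-aware simulation re-evaluates fixed prospective predictions
on repeated subsamples with a 4:270 high-risk-to-control ratio (~1.5%
prevalence, matching real hotline statistics), which leaves sensitivity and
specificity untouched but drags precision down to its low-prevalence PPV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn import metrics as _skm

from .cohort import LABEL_NAMES, SyntheticCohort
from .model import ModelConfig, aggregate_segments, fit, predict_labels, predict_proba

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "PrevalenceSimConfig",
    "confusion",
    "metrics_from_confusion",
    "bootstrap_ci",
    "per_label_metrics",
    "run_repeated_iterations",
    "prevalence_resample",
    "roc_curve",
    "prepare_features",
]

METRIC_NAMES = ("precision", "recall", "f1", "accuracy")


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class PrevalenceSimConfig:
    n_positive_per_draw: int = 4
    n_negative_per_draw: int = 270
    n_draws: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_positive_per_draw, self.n_negative_per_draw, self.n_draws) <= 0:
            raise ValueError("all counts must be positive")


@dataclass
class MetricReport:
    """Mean and bootstrap CI per (label, metric) over iterations."""

    table: pd.DataFrame  # columns: label, metric, mean, ci_low, ci_high
    per_iteration: pd.DataFrame = field(repr=False, default=None)

    def value(self, label: str, metric: str, column: str = "mean") -> float:
        row = self.table[(self.table.label == label) & (self.table.metric == metric)]
        return float(row[column].iloc[0])


def confusion(y_true, y_pred) -> ConfusionCounts:
    y_true = np.asarray(y_true).astype(int).ravel()
    y_pred = np.asarray(y_pred).astype(int).ravel()
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def metrics_from_confusion(c: ConfusionCounts) -> dict:
    """Precision, recall, F1, accuracy from a confusion table.

    Zero-denominator ratios are reported as 0.0 and flagged in the
    ``undefined`` set rather than propagating NaN.
    """
    if c.n == 0:
        raise ValueError("empty confusion table")
    undefined = set()
    if c.tp + c.fp > 0:
        precision = c.tp / (c.tp + c.fp)
    else:
        precision = 0.0
        undefined.add("precision")
    if c.tp + c.fn > 0:
        recall = c.tp / (c.tp + c.fn)
    else:
        recall = 0.0
        undefined.add("recall")
    if precision + recall > 0:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        f1 = 0.0
        undefined.add("f1")
    accuracy = (c.tp + c.tn) / c.n
    return {"precision": precision, "recall": recall, "f1": f1,
            "accuracy": accuracy, "undefined": undefined}


def per_label_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> pd.DataFrame:
    """Long-format metrics for (n, 4) truth/prediction matrices."""
    y_true = np.atleast_2d(np.asarray(y_true, int))
    y_pred = np.atleast_2d(np.asarray(y_pred, int))
    rows = []
    for j, label in enumerate(LABEL_NAMES):
        m = metrics_from_confusion(confusion(y_true[:, j], y_pred[:, j]))
        for metric in METRIC_NAMES:
            rows.append({"label": label, "metric": metric, "value": m[metric]})
    return pd.DataFrame(rows)


def bootstrap_ci(values, n_boot: int = 1000, level: float = 0.95, seed: int = 0):
    """Percentile bootstrap CI for the mean of `values`.

    Resamples the values with replacement, takes the mean of each resample,
    and reports the (1-level)/2 and 1-(1-level)/2 percentiles.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("need at least one value")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    boot_means = values[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(boot_means, [alpha, 1.0 - alpha])
    return float(values.mean()), float(lo), float(hi)


def aggregate_report(per_iteration: pd.DataFrame, n_boot: int = 1000, seed: int = 0) -> MetricReport:
    """Bootstrap-aggregate long-format per-iteration metric values."""
    rows = []
    for (label, metric), grp in per_iteration.groupby(["label", "metric"], sort=False):
        mean, lo, hi = bootstrap_ci(grp["value"].to_numpy(), n_boot=n_boot, seed=seed)
        rows.append({"label": label, "metric": metric, "mean": mean, "ci_low": lo, "ci_high": hi})
    return MetricReport(table=pd.DataFrame(rows), per_iteration=per_iteration)


# --------------------------------------------------------------------------
# feature preparation and the repeated-iteration protocol


def prepare_features(cohort: SyntheticCohort, ids: list[str], mode: str,
                     aggregator: str = "mean") -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Stack per-call model inputs for the given mode.

    Audio segment sequences are collapsed with :func:`aggregate_segments`
    (``mean`` or ``birnn``). Fused mode returns ``(X_text, X_audio)``.
    """
    emb = cohort.embeddings
    text = np.stack([emb[i].text for i in ids])
    if mode == "text_only":
        return text
    audio = np.stack([aggregate_segments(emb[i].audio_segments, method=aggregator) for i in ids])
    if mode == "audio_only":
        return audio
    if mode == "fused":
        return text, audio
    raise ValueError(f"unknown mode: {mode!r}")


def labels_for(cohort: SyntheticCohort, ids: list[str]) -> np.ndarray:
    by_id = {r.call_id: r for r in cohort.records}
    return np.stack([by_id[i].labels() for i in ids])


def run_repeated_iterations(
    cohort: SyntheticCohort,
    config: ModelConfig,
    mode: str = "text_only",
    n_iter: int = 100,
    val_fraction: float = 0.1,
    aggregator: str = "mean",
    seed: int = 0,
    n_boot: int = 1000,
    collect_scores: bool = False,
):
    """The repeated re-partitioning protocol.

    Each iteration randomly splits the earlier-period pool 9:1 into
    train/validation, trains the joint model from scratch, and evaluates on
    the fixed prospective set; per-iteration per-label metrics are
    aggregated into a :class:`MetricReport` with bootstrap CIs.

    Returns ``(report, per_iteration_frame)`` and, with
    ``collect_scores=True``, additionally the last iteration's prospective
    probabilities (for ROC / prevalence analyses).
    """
    pool_ids = cohort.subset_ids("train_pool")
    prosp_ids = cohort.subset_ids("prospective")
    if set(pool_ids) & set(prosp_ids):
        raise ValueError("pool and prospective sets must be disjoint")
    n_val = max(1, int(round(val_fraction * len(pool_ids))))
    if len(pool_ids) - n_val < 1:
        raise ValueError("pool too small for the requested split")

    X_prosp = prepare_features(cohort, prosp_ids, mode, aggregator)
    y_prosp = labels_for(cohort, prosp_ids)

    rng = np.random.default_rng(seed)
    frames = []
    last_probs = None
    for it in range(n_iter):
        order = rng.permutation(len(pool_ids))
        val_ids = [pool_ids[i] for i in order[:n_val]]
        tr_ids = [pool_ids[i] for i in order[n_val:]]
        it_config = ModelConfig(**{**config.__dict__, "seed": int(rng.integers(2**31 - 1))})
        model = fit(
            (prepare_features(cohort, tr_ids, mode, aggregator), labels_for(cohort, tr_ids)),
            (prepare_features(cohort, val_ids, mode, aggregator), labels_for(cohort, val_ids)),
            it_config,
            mode=mode,
        )
        probs = predict_proba(model, X_prosp)
        preds = predict_labels(probs, config.decision_threshold)
        frame = per_label_metrics(y_prosp, preds)
        frame["iteration"] = it
        frames.append(frame)
        last_probs = probs
    per_iteration = pd.concat(frames, ignore_index=True)
    report = aggregate_report(per_iteration, n_boot=n_boot, seed=seed)
    if collect_scores:
        return report, per_iteration, (last_probs, y_prosp)
    return report, per_iteration


# --------------------------------------------------------------------------
# prevalence-aware simulation


def prevalence_resample(y_true, y_pred, config: PrevalenceSimConfig) -> pd.DataFrame:
    """Re-evaluate fixed binary predictions at screening prevalence.

    Each draw samples ``n_positive_per_draw`` positives and
    ``n_negative_per_draw`` negatives without replacement from the
    prospective predictions (default 4:270, ~1.5% prevalence) and recomputes
    the four metrics. Returns one row per draw.
    """
    y_true = np.asarray(y_true).astype(int).ravel()
    y_pred = np.asarray(y_pred).astype(int).ravel()
    pos = np.flatnonzero(y_true == 1)
    neg = np.flatnonzero(y_true == 0)
    if len(pos) < config.n_positive_per_draw or len(neg) < config.n_negative_per_draw:
        raise ValueError(
            f"need >= {config.n_positive_per_draw} positives and "
            f">= {config.n_negative_per_draw} negatives "
            f"(have {len(pos)} / {len(neg)})"
        )
    rng = np.random.default_rng(config.seed)
    rows = []
    for d in range(config.n_draws):
        take = np.concatenate([
            rng.choice(pos, size=config.n_positive_per_draw, replace=False),
            rng.choice(neg, size=config.n_negative_per_draw, replace=False),
        ])
        m = metrics_from_confusion(confusion(y_true[take], y_pred[take]))
        rows.append({"draw": d, **{k: m[k] for k in METRIC_NAMES}})
    return pd.DataFrame(rows)


def expected_ppv(sensitivity: float, specificity: float, prevalence: float) -> float:
    """Closed-form positive predictive value at a given prevalence."""
    num = sensitivity * prevalence
    den = num + (1.0 - specificity) * (1.0 - prevalence)
    return num / den if den > 0 else 0.0


# --------------------------------------------------------------------------
# ROC


def roc_curve(scores, labels):
    """Threshold-sweep ROC points and trapezoidal AUC.

    Ties follow the pairwise-probability convention:
    AUC = P(score_pos > score_neg) + 0.5 * P(tie).
    Returns ``(fpr, tpr, thresholds, auc)``.
    """
    labels = np.asarray(labels).astype(int).ravel()
    scores = np.asarray(scores, dtype=float).ravel()
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    fpr, tpr, thr = _skm.roc_curve(labels, scores)
    auc = float(_skm.auc(fpr, tpr))
    return fpr, tpr, thr, auc
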