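"""Prompt-engineering harness for multi-label crisis prediction.

Assembles deterministic few-shot chain-of-thought prompts around a 7-level
risk hierarchy, parses structured JSON answers into the four binary labels,
runs the 5-repetition evaluation protocol against a pluggable backend, and
implements the explanation-quality workflow: stratifying calls into
TP/FP/TN/FN on the high-risk label, generating explanations, and scoring
them with a two-rater five-dimension Likert rubric where a one-point score
difference counts as agreement.

No real API client ships here: a backend is anything with a
``send(prompt) -> str`` method, and :class:`MockBackend` provides a seeded
label-flipping simulator so the whole protocol is testable offline.
"""

from __future__ import annotations

import json
import re
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import LABEL_NAMES
from .evaluation import aggregate_report, per_label_metrics

__all__ = [
    "PromptSpec",
    "PredictionRecord",
    "RubricScore",
    "MockBackend",
    "ParseError",
    "build_prompt",
    "parse_response",
    "run_repetitions",
    "stratify_explanations",
    "rater_agreement",
    "default_risk_hierarchy",
    "make_transcript",
]

RUBRIC_DIMENSIONS = (
    "consistency_with_labeling",
    "logic_and_reasoning_plausibility",
    "completeness_and_accuracy",
    "clinical_and_situational_relevance",
    "clarity_and_comprehensibility",
)

_TRUE = {"true", "yes", "1", "y"}
_FALSE = {"false", "no", "0", "n"}


def default_risk_hierarchy() -> list[str]:
    """Placeholder 7-level risk ladder used as the chain-of-thought scaffold.

    These level descriptions are this package's own synthetic wording (the
    clinical instrument behind the original ladder is not reproduced); they
    span no distress through ideation with a specific plan, the same
    dimensions the binary labels encode.
    """
    return [
        "Level 1: no appreciable distress; conversation is informational.",
        "Level 2: situational stress without depressive symptoms.",
        "Level 3: depressed mood present, no thoughts of self-harm.",
        "Level 4: passive death wishes without concrete suicidal thoughts.",
        "Level 5: active suicidal ideation without a plan and few risk factors.",
        "Level 6: active suicidal ideation without a plan but multiple risk factors.",
        "Level 7: suicidal ideation with a specific method or plan.",
    ]


@dataclass
class PromptSpec:
    task_instructions: str = (
        "You are a clinical triage assistant for a psychological support "
        "hotline. Read the caller transcript and decide four binary labels."
    )
    few_shot_examples: list[tuple[str, dict]] = field(default_factory=list)
    risk_hierarchy: list[str] = field(default_factory=default_risk_hierarchy)
    output_schema: tuple[str, ...] = LABEL_NAMES

    def __post_init__(self) -> None:
        if len(self.risk_hierarchy) != 7:
            raise ValueError("risk_hierarchy must have exactly 7 levels")
        if len(self.output_schema) != 4:
            raise ValueError("output_schema must name exactly 4 fields")


@dataclass
class PredictionRecord:
    call_id: str
    mood: int
    suicidal_ideation: int
    suicide_plan: int
    high_risk: int
    repetition_index: int
    raw_response: str = ""

    def labels(self) -> np.ndarray:
        return np.array(
            [self.mood, self.suicidal_ideation, self.suicide_plan, self.high_risk], dtype=int
        )


@dataclass
class RubricScore:
    call_id: str
    category: str  # TP / FP / TN / FN on the high-risk label
    rater: str
    scores: tuple[int, int, int, int, int]

    def __post_init__(self) -> None:
        if self.category not in ("TP", "FP", "TN", "FN"):
            raise ValueError(f"invalid category {self.category!r}")
        if len(self.scores) != 5 or any(not 1 <= s <= 5 for s in self.scores):
            raise ValueError("scores must be five integers in 1..5")


class ParseError(ValueError):
    pass


def make_transcript(call_id: str, record=None) -> str:
    """Placeholder transcript for a synthetic call.

    Real transcripts are private; this produces a deterministic stand-in
    string that carries the call id (so mock backends can look up the truth)
    and, if a record is given, a crude verbal sketch of its labels.
    """
    lines = [f"[call {call_id}]"]
    if record is not None:
        if record.mood_depressed:
            lines.append("Caller describes persistent low mood.")
        if record.suicidal_ideation:
            lines.append("Caller voices thoughts of not wanting to live.")
        if record.suicide_plan:
            lines.append("Caller mentions a specific method they have considered.")
        if not record.mood_depressed and not record.suicidal_ideation:
            lines.append("Caller is stressed about daily life but stable.")
    return " ".join(lines)


def build_prompt(spec: PromptSpec, transcript: str) -> str:
    """Deterministic prompt assembly: instructions, risk ladder, few-shot
    examples, the transcript, and the JSON output directive."""
    if not transcript or not transcript.strip():
        raise ValueError("transcript must be nonempty")
    parts = [spec.task_instructions, "", "Risk hierarchy (reason step by step through these levels):"]
    parts.extend(spec.risk_hierarchy)
    if spec.few_shot_examples:
        parts.append("")
        parts.append("Examples:")
        for ex_transcript, ex_labels in spec.few_shot_examples:
            parts.append(f"Transcript: {ex_transcript}")
            parts.append("Answer: " + json.dumps({k: bool(ex_labels[k]) for k in spec.output_schema}))
    parts.append("")
    parts.append(f"Transcript: {transcript}")
    parts.append(
        "First reason through the hierarchy, then answer with a single JSON "
        "object with exactly these boolean fields: " + ", ".join(spec.output_schema) + "."
    )
    return "\n".join(parts)


def _coerce_binary(value) -> int:
    if isinstance(value, bool):
        return int(value)
    if isinstance(value, (int, float)) and value in (0, 1):
        return int(value)
    if isinstance(value, str):
        v = value.strip().lower()
        if v in _TRUE:
            return 1
        if v in _FALSE:
            return 0
    raise ParseError(f"cannot interpret label value {value!r}")


def parse_response(text: str, schema: tuple[str, ...] = LABEL_NAMES) -> dict[str, int]:
    """Extract the structured 4-label answer from a (possibly chatty) reply.

    Scans for JSON object literals anywhere in the text, takes the last one
    containing all four schema fields, and maps affirmative/negative
    variants to 0/1. Raises :class:`ParseError` when no complete block is
    found or a value is uninterpretable.
    """
    candidates = []
    for m in re.finditer(r"\{[^{}]*\}", text, flags=re.DOTALL):
        try:
            obj = json.loads(m.group(0))
        except json.JSONDecodeError:
            continue
        if isinstance(obj, dict):
            candidates.append(obj)
    for obj in reversed(candidates):
        if all(k in obj for k in schema):
            return {k: _coerce_binary(obj[k]) for k in schema}
    raise ParseError("no parsable 4-field answer block found")


# --------------------------------------------------------------------------
# backends


class MockBackend:
    """Seeded simulator of an LLM endpoint.

    Replies with a well-formed chain-of-thought plus JSON answer equal to
    the ground-truth labels of the call named in the prompt, each label
    independently flipped with probability ``flip_rate``. Deterministic per
    (call_id, repetition, seed): repetitions are tracked internally per call.
    """

    name = "mock"
    temperature = 0.0

    def __init__(self, truth: dict[str, np.ndarray], flip_rate: float = 0.0, seed: int = 0):
        if not 0.0 <= flip_rate <= 1.0:
            raise ValueError("flip_rate must be in [0, 1]")
        self.truth = {cid: np.asarray(v, dtype=int) for cid, v in truth.items()}
        self.flip_rate = flip_rate
        self.seed = seed
        self._rep_counter: dict[str, int] = {}

    def _labels_for(self, call_id: str, repetition: int) -> np.ndarray:
        y = self.truth[call_id].copy()
        if self.flip_rate > 0:
            # process-stable key (builtin str hashing is salted per process)
            key = zlib.crc32(f"{self.seed}:{call_id}:{repetition}".encode())
            rng = np.random.default_rng(key)
            flips = rng.random(4) < self.flip_rate
            y[flips] = 1 - y[flips]
        return y

    def send(self, prompt: str) -> str:
        m = re.search(r"\[call ([^\]]+)\]", prompt)
        if m is None:
            raise ValueError("mock backend needs a '[call <id>]' marker in the prompt")
        call_id = m.group(1)
        rep = self._rep_counter.get(call_id, 0)
        self._rep_counter[call_id] = rep + 1
        y = self._labels_for(call_id, rep)
        answer = {k: bool(v) for k, v in zip(LABEL_NAMES, y)}
        return (
            "Working through the risk hierarchy: the caller's statements place "
            "them at a level consistent with the labels below.\n"
            + json.dumps(answer)
        )


class ExplanationMockBackend:
    """Canned explanation generator keyed off the call id in the prompt."""

    name = "mock-explainer"
    temperature = 0.0

    def send(self, prompt: str) -> str:
        m = re.search(r"\[call ([^\]]+)\]", prompt)
        cid = m.group(1) if m else "unknown"
        return (
            f"The transcript of call {cid} contains statements about mood and "
            "suicidal thinking that support the predicted labels; key phrases "
            "were weighed against the risk hierarchy levels."
        )


# --------------------------------------------------------------------------
# protocols


def run_repetitions(backend, dataset, spec: PromptSpec, n_rep: int = 5,
                    n_boot: int = 1000, seed: int = 0, max_retries: int = 1):
    """The repeated-prompting evaluation protocol.

    ``dataset`` is a list of ``(call_id, transcript, truth_labels)`` with
    truth as length-4 binary arrays. Each of the ``n_rep`` repetitions sends
    every transcript through the backend, parses the JSON answer (one retry
    on parse failure, then the call is excluded and logged), and computes
    per-label metrics; aggregates carry bootstrap CIs.

    Returns ``(report, per_repetition_frame, prediction_records, failed_ids)``.
    """
    frames = []
    records: list[PredictionRecord] = []
    failed: list[str] = []
    for rep in range(1, n_rep + 1):
        y_true, y_pred = [], []
        for call_id, transcript, truth in dataset:
            prompt = build_prompt(spec, transcript)
            labels = None
            raw = ""
            for _ in range(max_retries + 1):
                raw = backend.send(prompt)
                try:
                    labels = parse_response(raw, spec.output_schema)
                    break
                except ParseError:
                    continue
            if labels is None:
                failed.append(call_id)
                continue
            vec = [labels[k] for k in spec.output_schema]
            records.append(PredictionRecord(call_id, *vec, repetition_index=rep, raw_response=raw))
            y_true.append(np.asarray(truth, dtype=int))
            y_pred.append(vec)
        if not y_true:
            raise RuntimeError(f"all calls failed to parse in repetition {rep}")
        frame = per_label_metrics(np.stack(y_true), np.asarray(y_pred))
        frame["iteration"] = rep
        frames.append(frame)
    per_repetition = pd.concat(frames, ignore_index=True)
    report = aggregate_report(per_repetition, n_boot=n_boot, seed=seed)
    return report, per_repetition, records, failed


def stratify_explanations(predictions: dict[str, int], truth: dict[str, int],
                          k_per_category: int = 10, seed: int = 0):
    """Sample calls per TP/FP/TN/FN cell of the high-risk label.

    Returns ``(selection, warnings)`` where selection maps category to a
    list of call ids (k per category, or all members with a shortfall
    warning when a category is smaller than k).
    """
    if set(predictions) != set(truth):
        raise ValueError("predictions and truth must cover the same calls")
    cats: dict[str, list[str]] = {"TP": [], "FP": [], "TN": [], "FN": []}
    for cid in sorted(predictions):
        p, t = int(predictions[cid]), int(truth[cid])
        cat = {(1, 1): "TP", (1, 0): "FP", (0, 0): "TN", (0, 1): "FN"}[(p, t)]
        cats[cat].append(cid)
    rng = np.random.default_rng(seed)
    selection: dict[str, list[str]] = {}
    warnings: list[str] = []
    for cat, ids in cats.items():
        if len(ids) < k_per_category:
            warnings.append(f"{cat}: only {len(ids)} of {k_per_category} requested")
            selection[cat] = list(ids)
        else:
            take = rng.choice(len(ids), size=k_per_category, replace=False)
            selection[cat] = [ids[i] for i in sorted(take)]
    return selection, warnings


def generate_explanation(backend, transcript: str, predicted_labels: dict[str, int]) -> str:
    """Ask the backend for a natural-language justification of a prediction."""
    prompt = (
        "Explain, for a clinical reviewer, why the following labels fit this "
        f"hotline call.\nLabels: {json.dumps(predicted_labels)}\nTranscript: {transcript}\n"
        "Point to the statements that support each label."
    )
    return backend.send(prompt)


def rater_agreement(s1: RubricScore, s2: RubricScore):
    """Two-rater consistency under the one-point rule.

    A dimension is consistent when the raters' Likert scores differ by at
    most 1. Returns ``(flags, proportion)``.
    """
    if s1.call_id != s2.call_id:
        raise ValueError("rubric scores refer to different calls")
    if s1.category != s2.category:
        raise ValueError("rubric scores disagree on the TP/FP/TN/FN category")
    flags = tuple(abs(a - b) <= 1 for a, b in zip(s1.scores, s2.scores))
    return flags, sum(flags) / len(flags)


def rubric_scores_to_frame(scores: list[RubricScore]) -> pd.DataFrame:
    rows = []
    for s in scores:
        row = {"call_id": s.call_id, "category": s.category, "rater": s.rater}
        row.update(dict(zip(RUBRIC_DIMENSIONS, s.scores)))
        rows.append(row)
    return pd.DataFrame(rows)
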