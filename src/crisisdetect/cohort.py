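"""Synthetic hotline cohorts with correlated crisis labels and embeddings.

The real study data — crisis-hotline call recordings and operator
annotations — is private, so this module generates cohorts that carry the
statistical structure the downstream analysis assumes:

* a latent severity scalar drives four correlated binary labels per call
  (depressed mood, suicidal ideation, suicide plan, high risk);
* high-risk status follows the clinical triage rule: ideation with a
  concrete plan, or ideation without a plan plus a risk-factor score >= 5,
  where moderate depression contributes 1 point and severe depression 2;
* per-call "text" embeddings are informative about the labels while
  "audio" segment embeddings are weakly informative or pure noise,
  mirroring the modality asymmetry observed on real hotline calls.

Everything is a pure function of (config, seed).
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "MoodLevel",
    "CallRecord",
    "CohortConfig",
    "EmbeddingConfig",
    "EmbeddingSet",
    "SyntheticCohort",
    "mood_points",
    "assign_high_risk",
    "generate_cohort",
    "generate_embeddings",
    "generate_synthetic_cohort",
]

LABEL_NAMES = ("mood", "suicidal_ideation", "suicide_plan", "high_risk")

#: Risk-score points contributed by depressed mood: moderate depression adds
#: 1 point, severe depression 2; mild depression counts toward the binary
#: depression label but contributes no points.
_MOOD_POINTS = {"none": 0, "mild": 0, "moderate": 1, "severe": 2}

RISK_SCORE_THRESHOLD = 5


class MoodLevel(str, enum.Enum):
    NONE = "none"
    MILD = "mild"
    MODERATE = "moderate"
    SEVERE = "severe"


def mood_points(mood_level: MoodLevel | str) -> int:
    """Risk-score contribution of the operator-assessed mood level."""
    key = mood_level.value if isinstance(mood_level, MoodLevel) else str(mood_level)
    try:
        return _MOOD_POINTS[key]
    except KeyError:
        raise ValueError(f"unknown mood level: {mood_level!r}") from None


def assign_high_risk(ideation: bool, plan: bool, risk_score: int) -> bool:
    """Apply the high-risk triage rule.

    A call is high risk iff the caller reports suicidal ideation with a
    specific plan, or ideation without a plan together with a risk-factor
    score of at least 5.
    """
    if risk_score < 0:
        raise ValueError("risk_score must be nonnegative")
    ideation = bool(ideation)
    plan = bool(plan)
    return (ideation and plan) or (ideation and not plan and risk_score >= RISK_SCORE_THRESHOLD)


@dataclass
class CallRecord:
    call_id: str
    cohort_year: str  # "train_pool" (2022-analog) or "prospective" (2023-analog)
    mood_level: str
    mood_depressed: bool
    suicidal_ideation: bool
    suicide_plan: bool
    risk_score: int
    high_risk: bool
    latent_severity: float

    def labels(self) -> np.ndarray:
        """The four binary targets in canonical order."""
        return np.array(
            [self.mood_depressed, self.suicidal_ideation, self.suicide_plan, self.high_risk],
            dtype=np.float64,
        )


@dataclass
class CohortConfig:
    """Generation parameters for a labeled synthetic cohort.

    The defaults are calibrated so that the marginal label frequencies of a
    case-control cohort (roughly balanced high-risk vs control) resemble the
    published hotline cohort: ~87% depression, near-universal ideation and
    ~70% plans among high-risk calls; rare plans and ~20% ideation among
    controls.
    """

    n_high_risk: int = 526
    n_control: int = 531
    seed: int = 0
    # latent severity ~ mixture of two normals (candidate cases vs controls)
    severity_mean_case: float = 2.0
    severity_mean_control: float = -1.5
    severity_sd: float = 1.0
    # conditional label mechanisms (logistic in latent severity)
    mood_cutpoints: tuple[float, float, float] = (-0.5, 1.0, 2.2)
    ideation_slope: float = 2.0
    ideation_cut: float = 0.3
    plan_slope: float = 1.6
    plan_cut: float = 1.3
    # non-mood risk-score items: Binomial(n_items, sigmoid(slope*(s-cut)))
    score_items: int = 8
    score_slope: float = 0.9
    score_cut: float = 0.6
    rule_strict: bool = True
    label_noise_rate: float = 0.0
    prospective_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.n_high_risk <= 0 or self.n_control <= 0:
            raise ValueError("cohort counts must be positive")
        if not 0.0 <= self.label_noise_rate <= 1.0:
            raise ValueError("label_noise_rate must be in [0, 1]")
        if not 0.0 <= self.prospective_fraction <= 1.0:
            raise ValueError("prospective_fraction must be in [0, 1]")


@dataclass
class EmbeddingConfig:
    """Parameters of the class-conditional Gaussian embedding generator.

    ``text_dim`` defaults to 3072, the dimension of the large text-embedding
    model used on the real transcripts; ``audio_dim`` defaults to 1024, a
    typical large speech-encoder hidden size. ``*_snr`` scales the label-
    dependent mean relative to unit Gaussian noise; an SNR of 0 yields pure
    noise (an uninformative modality).
    """

    text_dim: int = 3072
    audio_dim: int = 1024
    segments_mean: float = 12.0  # Poisson mean of 10-second segments per call
    segments_min: int = 2
    text_snr: float = 2.0
    audio_snr: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.text_dim <= 0 or self.audio_dim <= 0:
            raise ValueError("embedding dimensions must be positive")
        if self.text_snr < 0 or self.audio_snr < 0:
            raise ValueError("snr must be nonnegative")
        if self.segments_min < 1:
            raise ValueError("segments_min must be >= 1")


@dataclass
class EmbeddingSet:
    """One call's text vector and sequence of audio segment vectors."""

    call_id: str
    text: np.ndarray  # (text_dim,)
    audio_segments: np.ndarray  # (n_segments, audio_dim)


@dataclass
class SyntheticCohort:
    records: list[CallRecord]
    embeddings: dict[str, EmbeddingSet] = field(default_factory=dict)
    cohort_config: CohortConfig | None = None
    embedding_config: EmbeddingConfig | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(r) for r in self.records])

    def label_matrix(self, which: str | None = None) -> np.ndarray:
        recs = self.records if which is None else [r for r in self.records if r.cohort_year == which]
        return np.stack([r.labels() for r in recs])

    def subset_ids(self, which: str) -> list[str]:
        return [r.call_id for r in self.records if r.cohort_year == which]


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _draw_record(rng: np.random.Generator, cfg: CohortConfig, severity: float, idx: int) -> CallRecord:
    s = float(severity)
    c1, c2, c3 = cfg.mood_cutpoints
    # ordinal mood via noisy thresholds on severity
    u = s + rng.logistic(0.0, 0.6)
    if u < c1:
        level = MoodLevel.NONE
    elif u < c2:
        level = MoodLevel.MILD
    elif u < c3:
        level = MoodLevel.MODERATE
    else:
        level = MoodLevel.SEVERE
    ideation = bool(rng.random() < _sigmoid(cfg.ideation_slope * (s - cfg.ideation_cut)))
    # plans only ever occur alongside ideation
    plan = bool(ideation and rng.random() < _sigmoid(cfg.plan_slope * (s - cfg.plan_cut)))
    other_points = int(rng.binomial(cfg.score_items, _sigmoid(cfg.score_slope * (s - cfg.score_cut))))
    risk_score = mood_points(level) + other_points
    high = assign_high_risk(ideation, plan, risk_score)
    return CallRecord(
        call_id=f"call-{idx:05d}",
        cohort_year="train_pool",
        mood_level=level.value,
        mood_depressed=level is not MoodLevel.NONE,
        suicidal_ideation=ideation,
        suicide_plan=plan,
        risk_score=risk_score,
        high_risk=high,
        latent_severity=s,
    )


class CohortGenerationError(RuntimeError):
    pass


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Sample a labeled cohort with exact high-risk / control counts.

    Candidates are drawn from a two-component severity mixture and routed to
    the high-risk or control quota by the triage rule, so label correlations
    arise mechanistically rather than by fiat. Raises
    :class:`CohortGenerationError` if the quotas cannot be filled within a
    bounded number of draws (infeasible probability settings).
    """
    rng = np.random.default_rng(config.seed)
    want_hr, want_ctrl = config.n_high_risk, config.n_control
    hr: list[CallRecord] = []
    ctrl: list[CallRecord] = []
    max_draws = 60 * (want_hr + want_ctrl)
    idx = 0
    for _ in range(max_draws):
        if len(hr) >= want_hr and len(ctrl) >= want_ctrl:
            break
        # target the emptier quota to keep draw counts bounded
        need_hr = len(hr) < want_hr
        need_ctrl = len(ctrl) < want_ctrl
        if need_hr and need_ctrl:
            mu = config.severity_mean_case if rng.random() < 0.5 else config.severity_mean_control
        elif need_hr:
            mu = config.severity_mean_case
        else:
            mu = config.severity_mean_control
        s = rng.normal(mu, config.severity_sd)
        rec = _draw_record(rng, config, s, idx)
        if rec.high_risk and len(hr) < want_hr:
            hr.append(rec)
            idx += 1
        elif not rec.high_risk and len(ctrl) < want_ctrl:
            ctrl.append(rec)
            idx += 1
    if len(hr) < want_hr or len(ctrl) < want_ctrl:
        raise CohortGenerationError(
            f"could not fill quotas ({len(hr)}/{want_hr} high-risk, "
            f"{len(ctrl)}/{want_ctrl} control) within {max_draws} draws"
        )

    records = hr + ctrl
    rng.shuffle(records)

    if config.label_noise_rate > 0:
        # independent flips of the four stored binary labels; mirrors
        # annotation inconsistency in real logs and deliberately breaks the
        # strict rule when nonzero
        if config.rule_strict:
            raise ValueError("label_noise_rate > 0 requires rule_strict=False")
        for rec in records:
            flips = rng.random(4) < config.label_noise_rate
            if flips[0]:
                rec.mood_depressed = not rec.mood_depressed
                rec.mood_level = MoodLevel.MILD.value if rec.mood_depressed else MoodLevel.NONE.value
            if flips[1]:
                rec.suicidal_ideation = not rec.suicidal_ideation
            if flips[2]:
                rec.suicide_plan = not rec.suicide_plan
            if flips[3]:
                rec.high_risk = not rec.high_risk

    # prospective split: later-period test calls, stratified by high-risk status
    for group in (True, False):
        ids = [i for i, r in enumerate(records) if r.high_risk == group]
        n_prosp = int(round(config.prospective_fraction * len(ids)))
        chosen = rng.choice(len(ids), size=n_prosp, replace=False) if n_prosp else []
        for j in chosen:
            records[ids[j]].cohort_year = "prospective"

    return SyntheticCohort(records=records, cohort_config=config)


def generate_embeddings(records: list[CallRecord], config: EmbeddingConfig) -> dict[str, EmbeddingSet]:
    """Class-conditional Gaussian embeddings for each call.

    The modality mean is a fixed random linear map of the call's four labels
    and (standardized) latent severity, scaled by the modality SNR; unit
    Gaussian noise is added per vector. Audio calls get a Poisson number of
    segment vectors sharing the call-level mean, each with independent noise.
    """
    if not records:
        raise ValueError("records must be nonempty")
    rng = np.random.default_rng(config.seed)
    # fixed signal directions, unit-norm columns, shared across the cohort
    w_text = rng.standard_normal((5, config.text_dim))
    w_text /= np.linalg.norm(w_text, axis=1, keepdims=True)
    w_audio = rng.standard_normal((5, config.audio_dim))
    w_audio /= np.linalg.norm(w_audio, axis=1, keepdims=True)

    out: dict[str, EmbeddingSet] = {}
    for rec in records:
        feats = np.concatenate([rec.labels(), [np.tanh(rec.latent_severity / 2.0)]])
        mu_t = config.text_snr * (feats @ w_text)
        mu_a = config.audio_snr * (feats @ w_audio)
        text = mu_t + rng.standard_normal(config.text_dim)
        n_seg = max(config.segments_min, int(rng.poisson(config.segments_mean)))
        audio = mu_a[None, :] + rng.standard_normal((n_seg, config.audio_dim))
        out[rec.call_id] = EmbeddingSet(call_id=rec.call_id, text=text, audio_segments=audio)
    return out


def generate_synthetic_cohort(
    cohort_config: CohortConfig | None = None,
    embedding_config: EmbeddingConfig | None = None,
) -> SyntheticCohort:
    """Labels plus embeddings in one call; the usual entry point."""
    cohort_config = cohort_config or CohortConfig()
    embedding_config = embedding_config or EmbeddingConfig(seed=cohort_config.seed + 1)
    cohort = generate_cohort(cohort_config)
    cohort.embeddings = generate_embeddings(cohort.records, embedding_config)
    cohort.embedding_config = embedding_config
    return cohort


# --------------------------------------------------------------------------
# serialization


def write_labels_csv(cohort: SyntheticCohort, path: str | Path) -> None:
    cohort.to_frame().to_csv(path, index=False)


def read_labels_csv(path: str | Path) -> list[CallRecord]:
    df = pd.read_csv(path)
    return [
        CallRecord(
            call_id=str(r.call_id),
            cohort_year=str(r.cohort_year),
            mood_level=str(r.mood_level),
            mood_depressed=bool(r.mood_depressed),
            suicidal_ideation=bool(r.suicidal_ideation),
            suicide_plan=bool(r.suicide_plan),
            risk_score=int(r.risk_score),
            high_risk=bool(r.high_risk),
            latent_severity=float(r.latent_severity),
        )
        for r in df.itertuples()
    ]


def write_embeddings(embeddings: dict[str, EmbeddingSet], directory: str | Path) -> None:
    """NPZ per modality plus a JSONL manifest of call ids and shapes."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    text = {cid: e.text for cid, e in embeddings.items()}
    audio = {cid: e.audio_segments for cid, e in embeddings.items()}
    np.savez(directory / "text_embeddings.npz", **text)
    np.savez(directory / "audio_embeddings.npz", **audio)
    with open(directory / "manifest.jsonl", "w") as fh:
        for cid, e in embeddings.items():
            fh.write(
                json.dumps(
                    {
                        "call_id": cid,
                        "text_dim": int(e.text.shape[0]),
                        "n_segments": int(e.audio_segments.shape[0]),
                        "audio_dim": int(e.audio_segments.shape[1]),
                    }
                )
                + "\n"
            )


def read_embeddings(directory: str | Path) -> dict[str, EmbeddingSet]:
    directory = Path(directory)
    text = np.load(directory / "text_embeddings.npz")
    audio = np.load(directory / "audio_embeddings.npz")
    return {
        cid: EmbeddingSet(call_id=cid, text=text[cid], audio_segments=audio[cid])
        for cid in text.files
    }


def config_to_yaml(config, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({type(config).__name__: _plain(asdict(config))}, fh)


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj
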