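"""Prompt harness: assembly, parsing, mock protocol, rubric agreement."""

import itertools
import json

import numpy as np
import pytest

from crisisdetect import (
    MockBackend,
    PromptSpec,
    RubricScore,
    build_prompt,
    parse_response,
    rater_agreement,
    run_repetitions,
    stratify_explanations,
)
from crisisdetect.cohort import LABEL_NAMES
from crisisdetect.llm import (
    ExplanationMockBackend,
    ParseError,
    generate_explanation,
    make_transcript,
)


# --------------------------------------------------------------------------
# prompt assembly


def test_build_prompt_deterministic_and_complete():
    spec = PromptSpec(few_shot_examples=[
        ("[call ex-1] caller reports sadness",
         {"mood": 1, "suicidal_ideation": 0, "suicide_plan": 0, "high_risk": 0}),
    ])
    p1 = build_prompt(spec, "[call x] hello")
    p2 = build_prompt(spec, "[call x] hello")
    assert p1 == p2
    for level in spec.risk_hierarchy:
        assert p1.count(level) == 1
    assert "[call x] hello" in p1
    for field in spec.output_schema:
        assert field in p1


def test_build_prompt_zero_shot_and_validation():
    spec = PromptSpec()
    assert "Examples:" not in build_prompt(spec, "[call y] hi")
    with pytest.raises(ValueError):
        build_prompt(spec, "   ")
    with pytest.raises(ValueError):
        PromptSpec(risk_hierarchy=["only one level"])
    with pytest.raises(ValueError):
        PromptSpec(output_schema=("a", "b"))


# --------------------------------------------------------------------------
# parsing


def test_parse_roundtrip_all_16_label_combinations():
    for combo in itertools.product([0, 1], repeat=4):
        answer = json.dumps({k: bool(v) for k, v in zip(LABEL_NAMES, combo)})
        text = "Step-by-step reasoning about the hierarchy...\n" + answer
        parsed = parse_response(text)
        assert tuple(parsed[k] for k in LABEL_NAMES) == combo


def test_parse_accepts_affirmative_variants():
    text = json.dumps({"mood": "yes", "suicidal_ideation": "No",
                       "suicide_plan": 0, "high_risk": "true"})
    parsed = parse_response(text)
    assert [parsed[k] for k in LABEL_NAMES] == [1, 0, 0, 1]


def test_parse_failures():
    with pytest.raises(ParseError):
        parse_response("no structured block at all")
    with pytest.raises(ParseError):
        parse_response(json.dumps({"mood": True, "suicidal_ideation": False,
                                   "suicide_plan": False}))  # missing field
    with pytest.raises(ParseError):
        parse_response(json.dumps({"mood": "maybe", "suicidal_ideation": False,
                                   "suicide_plan": False, "high_risk": False}))


# --------------------------------------------------------------------------
# mock backend and the repetition protocol


def _toy_dataset(n=20, seed=0):
    rng = np.random.default_rng(seed)
    dataset = []
    truth = {}
    for i in range(n):
        cid = f"c{i:03d}"
        y = rng.integers(0, 2, size=4)
        if y[2] and not y[1]:  # keep labels logically coherent
            y[1] = 1
        truth[cid] = y
        dataset.append((cid, f"[call {cid}] synthetic transcript", y))
    return dataset, truth


def test_oracle_mock_gives_perfect_metrics():
    dataset, truth = _toy_dataset()
    backend = MockBackend(truth, flip_rate=0.0, seed=1)
    report, per_rep, records, failed = run_repetitions(
        backend, dataset, PromptSpec(), n_rep=5, seed=1)
    assert not failed
    assert np.allclose(report.table["mean"], 1.0)
    assert np.allclose(report.table.ci_low, 1.0)
    assert np.allclose(report.table.ci_high, 1.0)
    assert len(records) == 5 * len(dataset)
    # aggregate mean is the mean of the 5 per-repetition values
    grp = per_rep.groupby(["label", "metric"])["value"].mean()
    for row in report.table.itertuples():
        assert row.mean == pytest.approx(grp[(row.label, row.metric)])


def test_inverter_mock_gives_zero_accuracy():
    dataset, truth = _toy_dataset(n=10, seed=3)
    backend = MockBackend(truth, flip_rate=1.0, seed=2)
    report, *_ = run_repetitions(backend, dataset, PromptSpec(), n_rep=1, seed=2)
    acc = report.table[report.table.metric == "accuracy"]["mean"]
    assert np.allclose(acc, 0.0)


def test_half_flip_rate_yields_chance_accuracy():
    dataset, truth = _toy_dataset(n=1000, seed=4)
    backend = MockBackend(truth, flip_rate=0.5, seed=5)
    report, *_ = run_repetitions(backend, dataset, PromptSpec(), n_rep=1, seed=5)
    acc = report.table[report.table.metric == "accuracy"]["mean"].to_numpy()
    assert np.all(np.abs(acc - 0.5) <= 0.05)


def test_mock_is_deterministic_per_seed():
    dataset, truth = _toy_dataset(n=8, seed=6)
    outs1 = [MockBackend(truth, 0.4, seed=9).send(f"[call {cid}] x") for cid, _, _ in dataset]
    outs2 = [MockBackend(truth, 0.4, seed=9).send(f"[call {cid}] x") for cid, _, _ in dataset]
    assert outs1 == outs2
    with pytest.raises(ValueError):
        MockBackend(truth, flip_rate=1.2)


def test_parse_retry_and_exclusion_policy():
    dataset, truth = _toy_dataset(n=4, seed=7)

    class FlakyBackend:
        def __init__(self, fail_always_for):
            self.inner = MockBackend(truth, 0.0, seed=0)
            self.fail_always_for = fail_always_for
            self.first_call = set()

        def send(self, prompt):
            import re
            cid = re.search(r"\[call ([^\]]+)\]", prompt).group(1)
            if cid == self.fail_always_for:
                return "garbage with no json"
            if cid not in self.first_call:
                self.first_call.add(cid)
                return "garbage first try"
            return self.inner.send(prompt)

    backend = FlakyBackend(fail_always_for=dataset[0][0])
    report, per_rep, records, failed = run_repetitions(
        backend, dataset, PromptSpec(), n_rep=1, seed=0)
    assert failed == [dataset[0][0]]
    # the flaky-but-recoverable calls were retried successfully
    assert {r.call_id for r in records} == {cid for cid, _, _ in dataset[1:]}


def test_five_repetitions_route_to_ranksum():
    from crisisdetect import compare_models
    dataset, truth = _toy_dataset(n=30, seed=8)
    rep_a, pa, *_ = run_repetitions(MockBackend(truth, 0.2, seed=1), dataset,
                                    PromptSpec(), n_rep=5, seed=1)
    rep_b, pb, *_ = run_repetitions(MockBackend(truth, 0.4, seed=2), dataset,
                                    PromptSpec(), n_rep=5, seed=2)

    def samples(frame, model):
        return {
            f"{label}/{metric}": grp["value"].to_numpy()
            for (label, metric), grp in frame.groupby(["label", "metric"], sort=False)
        }

    result = compare_models({"a": samples(pa, "a"), "b": samples(pb, "b")}, seed=3)
    assert set(result.test) == {"wilcoxon"}


# --------------------------------------------------------------------------
# explanation workflow


def test_stratification_matches_bruteforce(rng):
    for _ in range(100):
        n = int(rng.integers(4, 30))
        pred = {f"c{i}": int(rng.integers(0, 2)) for i in range(n)}
        truth = {f"c{i}": int(rng.integers(0, 2)) for i in range(n)}
        selection, _ = stratify_explanations(pred, truth, k_per_category=n, seed=0)
        for cat, ids in selection.items():
            for cid in ids:
                p, t = pred[cid], truth[cid]
                expected = {"TP": (1, 1), "FP": (1, 0), "TN": (0, 0), "FN": (0, 1)}[cat]
                assert (p, t) == expected


def test_stratification_boundaries():
    pred = {"a": 1, "b": 1, "c": 0, "d": 0}
    truth = {"a": 1, "b": 0, "c": 0, "d": 1}
    sel, warnings = stratify_explanations(pred, truth, k_per_category=1, seed=1)
    assert all(len(ids) == 1 for ids in sel.values())
    # perfect predictions leave FP/FN empty, with shortfall warnings
    sel, warnings = stratify_explanations({"a": 1, "b": 0}, {"a": 1, "b": 0},
                                          k_per_category=1, seed=1)
    assert sel["FP"] == [] and sel["FN"] == []
    assert any("FP" in w for w in warnings) and any("FN" in w for w in warnings)
    with pytest.raises(ValueError):
        stratify_explanations({"a": 1}, {"b": 1})


def test_explanation_generation_mentions_call():
    text = generate_explanation(
        ExplanationMockBackend(), make_transcript("z-1"), {"high_risk": 1})
    assert "z-1" in text


@pytest.mark.parametrize(
    "s1, s2, expected",
    [
        ((5, 4, 3, 2, 1), (4, 5, 2, 3, 2), 1.0),
        ((3, 3, 3, 3, 3), (3, 3, 3, 3, 3), 1.0),
        ((1, 1, 1, 1, 1), (3, 3, 3, 3, 3), 0.0),
        ((1, 2, 3, 4, 5), (2, 4, 3, 2, 5), 0.6),
    ],
)
def test_rater_agreement_cases(s1, s2, expected):
    a = RubricScore("c1", "TP", "rater1", s1)
    b = RubricScore("c1", "TP", "rater2", s2)
    flags, proportion = rater_agreement(a, b)
    assert proportion == pytest.approx(expected)
    assert all(f == (abs(x - y) <= 1) for f, x, y in zip(flags, s1, s2))


def test_rater_agreement_exhaustive_score_pairs():
    """Every (x, y) in 1..5 x 1..5 obeys the one-point rule per dimension."""
    for x in range(1, 6):
        for y in range(1, 6):
            a = RubricScore("c", "TN", "r1", (x,) * 5)
            b = RubricScore("c", "TN", "r2", (y,) * 5)
            flags, prop = rater_agreement(a, b)
            assert all(f == (abs(x - y) <= 1) for f in flags)
            assert prop == (1.0 if abs(x - y) <= 1 else 0.0)


def test_rubric_validation():
    with pytest.raises(ValueError):
        RubricScore("c", "XX", "r", (1, 1, 1, 1, 1))
    with pytest.raises(ValueError):
        RubricScore("c", "TP", "r", (0, 1, 1, 1, 1))
    a = RubricScore("c1", "TP", "r1", (3, 3, 3, 3, 3))
    b = RubricScore("c2", "TP", "r2", (3, 3, 3, 3, 3))
    with pytest.raises(ValueError):
        rater_agreement(a, b)
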