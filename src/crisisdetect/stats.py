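"""Tiered statistical comparison of model metric distributions.

Comparing models whose metric samples come in very different sizes calls
for different tests: Welch's unequal-variance t-test for two large samples
(the 100-iteration deep-learning runs), a permutation test on the
difference of means for mixed sizes (100 iterations vs 5 LLM repetitions),
and the exact Wilcoxon rank-sum test for two small samples (5 vs 5).
Family-wise error across the resulting comparison matrix is controlled by
the Holm-Bonferroni step-down adjustment.

All tests are implemented here from first principles; scipy/statsmodels
serve as independent cross-checks in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as _sps

__all__ = [
    "ComparisonResult",
    "welch_t",
    "permutation_test",
    "wilcoxon_rank_sum",
    "holm_bonferroni",
    "compare_models",
]

LARGE_SAMPLE = 30  # >= this in both groups -> Welch; both below -> rank-sum
EXACT_PERMUTATION_LIMIT = 20_000
EXACT_RANKSUM_LIMIT = 10  # per-group size up to which the null is enumerated


@dataclass
class ComparisonResult:
    model_a: str
    model_b: str
    metric: str
    test: str
    statistic: float
    p_raw: float
    p_adjusted: float = float("nan")


def _as_sample(x, min_size: int = 1) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if x.size < min_size:
        raise ValueError(f"sample needs at least {min_size} values")
    return x


def welch_t(a, b) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test; returns (t, df, two-sided p)."""
    a, b = _as_sample(a, 2), _as_sample(b, 2)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = a.size, b.size
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, float(na + nb - 2), 1.0
        raise ValueError("both samples have zero variance but different means")
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    # Welch-Satterthwaite degrees of freedom
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = float(2.0 * _sps.t.sf(abs(t), df))
    return float(t), float(df), p


def permutation_test(a, b, n_perm: int = 10_000, seed: int = 0) -> tuple[float, float]:
    """Two-sided permutation test on the difference of means.

    Enumerates all splits when C(n_a+n_b, n_a) <= 20,000, otherwise uses
    Monte-Carlo with add-one smoothing. Returns (observed difference, p).
    """
    a, b = _as_sample(a), _as_sample(b)
    pooled = np.concatenate([a, b])
    na, n = a.size, a.size + b.size
    obs = abs(a.mean() - b.mean())
    tol = 1e-12 * max(1.0, obs)
    total = math.comb(n, na)
    total_sum = pooled.sum()
    if total <= EXACT_PERMUTATION_LIMIT:
        combos = np.fromiter(
            (i for c in combinations(range(n), na) for i in c), dtype=np.intp,
            count=total * na,
        ).reshape(total, na)
        sa = pooled[combos].sum(axis=1)
        diffs = np.abs(sa / na - (total_sum - sa) / (n - na))
        count = int(np.sum(diffs >= obs - tol))
        return float(a.mean() - b.mean()), count / total
    rng = np.random.default_rng(seed)
    # row-wise random permutations via argsort of uniform keys
    keys = rng.random((n_perm, n))
    take = np.argsort(keys, axis=1)[:, :na]
    sa = pooled[take].sum(axis=1)
    diffs = np.abs(sa / na - (total_sum - sa) / (n - na))
    count = int(np.sum(diffs >= obs - tol))
    return float(a.mean() - b.mean()), (count + 1) / (n_perm + 1)


def _rank_sum_null(pooled_ranks: np.ndarray, na: int) -> np.ndarray:
    """Exact null distribution of the rank sum of group a (with midranks)."""
    n = pooled_ranks.size
    total = math.comb(n, na)
    combos = np.fromiter(
        (i for c in combinations(range(n), na) for i in c), dtype=np.intp,
        count=total * na,
    ).reshape(total, na)
    return pooled_ranks[combos].sum(axis=1)


def wilcoxon_rank_sum(a, b) -> tuple[float, float]:
    """Wilcoxon rank-sum test; exact by enumeration for small samples.

    Midranks handle ties. For per-group sizes up to 10 the permutation null
    of the rank sum is enumerated exactly and the two-sided p is
    2*min(P(W<=w), P(W>=w)) capped at 1; for larger samples a normal
    approximation with tie correction is used.
    """
    a, b = _as_sample(a), _as_sample(b)
    na, nb = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = _sps.rankdata(pooled)  # midranks
    w = float(ranks[:na].sum())
    if max(na, nb) <= EXACT_RANKSUM_LIMIT:
        null = _rank_sum_null(ranks, na)
        eps = 1e-9
        p_lo = np.mean(null <= w + eps)
        p_hi = np.mean(null >= w - eps)
        p = min(1.0, 2.0 * min(p_lo, p_hi))
        return w, float(p)
    # normal approximation with tie correction
    n = na + nb
    mu = na * (n + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (n * (n - 1))
    sigma2 = na * nb / 12.0 * (n + 1 - tie_term)
    if sigma2 == 0:
        return w, 1.0
    z = (w - mu) / math.sqrt(sigma2)
    return w, float(2.0 * _sps.norm.sf(abs(z)))


def holm_bonferroni(p_raw) -> np.ndarray:
    """Holm's step-down adjustment; output order matches input order."""
    p = np.asarray(p_raw, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("expected a nonempty 1-d array of p-values")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running_max = 0.0
    for rank, i in enumerate(order):
        val = min(1.0, (m - rank) * p[i])
        running_max = max(running_max, val)
        adjusted[i] = running_max
    return adjusted


def _select_test(na: int, nb: int) -> str:
    if na >= LARGE_SAMPLE and nb >= LARGE_SAMPLE:
        return "welch"
    if na < LARGE_SAMPLE and nb < LARGE_SAMPLE:
        return "wilcoxon"
    return "permutation"


def compare_models(samples: dict[str, dict[str, np.ndarray]],
                   n_perm: int = 10_000, seed: int = 0) -> pd.DataFrame:
    """All-pairs comparison of per-model metric distributions.

    ``samples`` maps model id -> metric name -> 1-d array of metric values
    (one per iteration/repetition). The test is chosen per pair from the two
    sample sizes — Welch for two large samples, Wilcoxon rank-sum for two
    small ones, a permutation test for mixed scales — and Holm-Bonferroni is
    applied within each metric family. Returns a long-format frame.
    """
    models = list(samples)
    if len(models) < 2:
        raise ValueError("need at least two models to compare")
    metric_names = list(samples[models[0]])
    rows: list[ComparisonResult] = []
    for metric in metric_names:
        family: list[ComparisonResult] = []
        for ma, mb in combinations(models, 2):
            if metric not in samples[ma] or metric not in samples[mb]:
                raise KeyError(f"metric {metric!r} missing for {ma!r} or {mb!r}")
            a = _as_sample(samples[ma][metric])
            b = _as_sample(samples[mb][metric])
            test = _select_test(a.size, b.size)
            if test == "welch":
                stat, _, p = welch_t(a, b)
            elif test == "wilcoxon":
                stat, p = wilcoxon_rank_sum(a, b)
            else:
                stat, p = permutation_test(a, b, n_perm=n_perm, seed=seed)
            family.append(ComparisonResult(ma, mb, metric, test, float(stat), float(p)))
        adj = holm_bonferroni([r.p_raw for r in family])
        for r, pa in zip(family, adj):
            r.p_adjusted = float(pa)
        rows.extend(family)
    return pd.DataFrame([r.__dict__ for r in rows])
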