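"""Random-pruning null model, sign test, and similarity summaries.

The null model asks: is the similarity change caused by the entropy-guided
pruning different from what *any* same-size pruning would do?  For a compound
pair it draws N uniform random bit subsets of the reduced set's size, scores
each with the Tanimoto coefficient, and locates the observed reduced-set score
in that distribution.  Empirical p-values use the add-one estimator
``p = (1 + #more extreme) / (N + 1)`` so p = 0 is impossible; two-sided means
doubling the smaller tail, capped at 1.

The sign test is the two-sided exact binomial test on the counts of pairs
whose similarity decreased vs increased (ties dropped, success probability
one half).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .matrix import FingerprintMatrix
from .similarity import tanimoto

__all__ = [
    "NullDistribution",
    "SimilaritySummary",
    "random_pruning_null",
    "sign_test",
    "summarize_pairs",
    "group_mean_similarity",
    "relative_change",
]


@dataclass
class NullDistribution:
    """Tanimoto scores of one pair under N random same-size prunings."""

    pair: tuple[str, str]
    observed_reduced_score: float | None
    null_scores: np.ndarray
    N: int
    seed: int
    quartiles: tuple[float, float]
    p_value: float | None
    n_undefined_draws: int = 0

    def to_dict(self) -> dict:
        return {
            "pair": list(self.pair),
            "observed_reduced_score": self.observed_reduced_score,
            "N": self.N,
            "seed": self.seed,
            "quartiles": list(self.quartiles),
            "p_value": self.p_value,
            "n_undefined_draws": self.n_undefined_draws,
            "null_mean": float(np.mean(self.null_scores)),
        }


@dataclass
class SimilaritySummary:
    """Mean/SD/min of a score set plus counts at fixed thresholds."""

    group: str
    n_pairs: int
    mean: float
    std_dev: float
    threshold_counts: dict[float, int] = field(default_factory=dict)
    min_score: float = float("nan")

    @property
    def n_ge_08(self) -> int:
        return self.threshold_counts.get(0.8, 0)

    @property
    def n_ge_07(self) -> int:
        return self.threshold_counts.get(0.7, 0)


def empirical_p_value(null_scores: np.ndarray, observed: float) -> float:
    """Two-sided add-one empirical p: double the smaller tail, cap at 1."""
    nv = null_scores.size
    if nv == 0:
        raise ValueError("no valid null draws")
    p_le = (1 + int((null_scores <= observed).sum())) / (nv + 1)
    p_ge = (1 + int((null_scores >= observed).sum())) / (nv + 1)
    return min(1.0, 2.0 * min(p_le, p_ge))


def random_pruning_null(
    M: FingerprintMatrix,
    pair: tuple[str, str],
    keep: int,
    N: int = 10_000,
    seed: int = 0,
    observed: float | None = None,
) -> NullDistribution:
    """Null distribution of the pair's Tanimoto score under random pruning.

    Each of the N draws keeps a uniform random size-``keep`` subset of the
    bits (without replacement within a draw, independent across draws) and
    scores the pair on that subset.  Draws where both pruned vectors are
    all-zero have no defined score; they are excluded and counted.  When
    ``observed`` (the score on the entropy-selected reduced set) is given, an
    empirical two-sided p-value is attached.  Fully reproducible from ``seed``.
    """
    n = M.n_bits
    if not 1 <= keep < n:
        raise ValueError(f"keep must be in [1, n) = [1, {n})")
    if N < 1:
        raise ValueError("N must be >= 1")
    va = M.row(pair[0]).astype(np.int64)
    vb = M.row(pair[1]).astype(np.int64)
    rng = np.random.default_rng(seed)
    scores = np.empty(N)
    undefined = 0
    for t in range(N):
        idx = rng.choice(n, size=keep, replace=False)
        ia, ib = va[idx], vb[idx]
        union = int((ia | ib).sum())
        if union == 0:
            scores[t] = np.nan
            undefined += 1
        else:
            scores[t] = int((ia & ib).sum()) / union
    valid = scores[~np.isnan(scores)]
    if valid.size == 0:
        raise ValueError("every pruning draw left both vectors all-zero")
    q1, q3 = np.percentile(valid, [25, 75])
    p = empirical_p_value(valid, observed) if observed is not None else None
    return NullDistribution(
        pair=pair,
        observed_reduced_score=observed,
        null_scores=valid,
        N=N,
        seed=seed,
        quartiles=(float(q1), float(q3)),
        p_value=p,
        n_undefined_draws=undefined,
    )


def sign_test(deltas: list[float] | np.ndarray) -> float:
    """Two-sided exact binomial test on the signs of the deltas.

    Zeros are dropped from the trial count (standard sign-test convention).
    All-zero input yields p = 1 with a warning.
    """
    d = np.asarray(deltas, dtype=float)
    if d.size == 0:
        raise ValueError("deltas must be non-empty")
    pos = int((d > 0).sum())
    neg = int((d < 0).sum())
    trials = pos + neg
    if trials == 0:
        warnings.warn("all deltas are zero; sign test p = 1")
        return 1.0
    return float(stats.binomtest(pos, trials, p=0.5, alternative="two-sided").pvalue)


def summarize_pairs(
    scores: list[float] | np.ndarray,
    thresholds: tuple[float, ...] = (0.8, 0.7),
    group: str = "all",
) -> SimilaritySummary:
    """Mean, sample SD (divisor n-1), inclusive threshold counts, and min."""
    s = np.asarray(scores, dtype=float)
    if s.size == 0:
        raise ValueError("scores must be non-empty")
    if s.size == 1:
        warnings.warn("single score; std_dev reported as 0")
        sd = 0.0
    else:
        sd = float(np.std(s, ddof=1))
    return SimilaritySummary(
        group=group,
        n_pairs=int(s.size),
        mean=float(np.mean(s)),
        std_dev=sd,
        threshold_counts={float(t): int((s >= t).sum()) for t in thresholds},
        min_score=float(np.min(s)),
    )


def group_mean_similarity(
    M: FingerprintMatrix, labels: dict[str, str]
) -> dict[str, float]:
    """Per-class mean of within-class pairwise Tanimoto, plus an "All" row.

    Classes with fewer than two members are skipped with a warning.  "All"
    averages over every distinct pair in the matrix regardless of class.
    """
    by_class: dict[str, list[int]] = {}
    for i, cid in enumerate(M.compound_ids):
        lab = labels.get(cid)
        if lab is not None:
            by_class.setdefault(lab, []).append(i)

    out: dict[str, float] = {}
    V = M.values
    for lab, idx in sorted(by_class.items()):
        if len(idx) < 2:
            warnings.warn(f"class {lab!r} has fewer than 2 members; skipped")
            continue
        vals = [
            tanimoto(V[idx[a]], V[idx[b]])
            for a in range(len(idx))
            for b in range(a + 1, len(idx))
        ]
        out[lab] = float(np.mean(vals))

    m = M.n_compounds
    if m >= 2:
        all_vals = [
            tanimoto(V[a], V[b]) for a in range(m) for b in range(a + 1, m)
        ]
        out["All"] = float(np.mean(all_vals))
    return out


def relative_change(score_reduced: float, score_full: float) -> float:
    """``(score_reduced - score_full) / score_full``; requires a nonzero base."""
    if score_full <= 0:
        raise ValueError("score_full must be > 0")
    return (score_reduced - score_full) / score_full
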