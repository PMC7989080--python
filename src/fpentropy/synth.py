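"""Synthetic binary fingerprint matrices with planted linear structure.

Real fingerprint dictionaries contain bits that are (quasi) linearly dependent
on others — e.g. two keys that fire on the same substructure, or a coarse key
that fires exactly when one of two finer keys does.  The generator plants such
dependencies *exactly* while keeping every column binary:

* **duplicate bits** copy a randomly chosen independent column;
* **sum bits** are ``F_c = F_a + F_b`` for two independent columns with
  row-wise disjoint support (``F_a * F_b = 0``), so the sum stays in {0, 1}.
  Disjointness is enforced by masking one Bernoulli(density) support draw
  with a fair coin split between the two parents, which mimics a coarse key
  that fires exactly when one of two finer, mutually exclusive keys does.

Both constructions are genuine linear dependencies, so the matrix rank equals
the rank of the independent block and the planted bits are ground truth for
relatedness detection.  Column positions are shuffled so detection cannot rely
on ordering.  What the generator does **not** emulate: realistic MACCS bit
marginals, substructure co-occurrence, or soft (noisy) collinearity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .matrix import FingerprintMatrix, default_bit_labels

__all__ = ["SynthSpec", "generate", "fig1_toy"]


@dataclass
class SynthSpec:
    """Recipe for one synthetic matrix.

    Parameters
    ----------
    m
        Number of compounds (rows).
    n_indep
        Number of independent Bernoulli(density) bits.
    n_dup
        Bits that exactly duplicate randomly chosen independent bits.
    n_sum
        Bits built as exact sums of two disjoint-support independent bits;
        each sum consumes a dedicated parent pair, so ``n_sum`` may not exceed
        ``floor(n_indep / 2)``.
    density
        On-bit probability of the independent bits, in (0, 1).
    seed
        RNG seed; generation is bit-reproducible.
    """

    m: int = 500
    n_indep: int = 40
    n_dup: int = 10
    n_sum: int = 10
    density: float = 0.4
    seed: int = 0
    planted_dependent: list[int] = field(default_factory=list, repr=False)

    def validate(self) -> None:
        if self.n_indep < 2:
            raise ValueError("n_indep must be >= 2")
        if not 0 < self.density < 1:
            raise ValueError("density must be in (0, 1)")
        if self.n_dup < 0 or self.n_sum < 0:
            raise ValueError("n_dup and n_sum must be >= 0")
        if self.n_sum > self.n_indep // 2:
            raise ValueError(
                f"n_sum={self.n_sum} exceeds floor(n_indep/2)="
                f"{self.n_indep // 2}: not enough disjoint parent pairs"
            )
        if self.m < 1:
            raise ValueError("m must be >= 1")


def _nonzero_bernoulli_column(rng: np.random.Generator, m: int, p: float) -> np.ndarray:
    while True:
        col = (rng.random(m) < p).astype(np.int8)
        if col.any():
            return col


def generate(spec: SynthSpec) -> tuple[FingerprintMatrix, list[int]]:
    """Build the matrix and return it with the planted dependent bit positions.

    The returned positions are 1-based column indices (after shuffling) of the
    ``n_dup + n_sum`` constructed bits; they are also recorded on
    ``spec.planted_dependent``.  No column is all-zero (resampled if drawn).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    m = spec.m

    indep = np.column_stack(
        [_nonzero_bernoulli_column(rng, m, spec.density) for _ in range(spec.n_indep)]
    )

    # Reserve a dedicated parent pair per sum bit: one Bernoulli(density)
    # support is split by a fair coin between the two parents, so they are
    # disjoint by construction and their sum is binary with typical weight.
    parent_pool = rng.permutation(spec.n_indep)
    sum_cols: list[np.ndarray] = []
    for s in range(spec.n_sum):
        a, b = parent_pool[2 * s], parent_pool[2 * s + 1]
        while True:
            support = rng.random(m) < spec.density
            split = rng.random(m) < 0.5
            col_a = (support & split).astype(np.int8)
            col_b = (support & ~split).astype(np.int8)
            if col_a.any() and col_b.any():
                break
        indep[:, a] = col_a
        indep[:, b] = col_b
        sum_cols.append((indep[:, a] + indep[:, b]).astype(np.int8))

    dup_parents = rng.integers(0, spec.n_indep, size=spec.n_dup)
    dup_cols = [indep[:, p].copy() for p in dup_parents]

    cols = [indep[:, j] for j in range(spec.n_indep)] + dup_cols + sum_cols
    n = len(cols)
    order = rng.permutation(n)
    values = np.column_stack([cols[j] for j in order])
    position_of = np.empty(n, dtype=int)
    position_of[order] = np.arange(n)
    planted = sorted(int(position_of[j]) + 1 for j in range(spec.n_indep, n))
    spec.planted_dependent = planted

    M = FingerprintMatrix(
        values,
        [f"c{i}" for i in range(1, m + 1)],
        default_bit_labels(n),
        scheme_name="synthetic",
    )
    return M, planted


def fig1_toy(m: int = 12, seed: int = 7) -> FingerprintMatrix:
    """A small 9-bit matrix with one exact multicollinearity: 2*F1 = F2+F3+F4.

    Every row is drawn only from bit patterns obeying the constraint — F1 off
    with F2..F4 all off, or F1 on with exactly two of F2..F4 on — while bits
    F5..F9 are free Bernoulli(1/2).  Useful for documentation and smoke tests:
    the 9 columns carry at most 8 independent directions.
    """
    rng = np.random.default_rng(seed)
    head_patterns = np.array(
        [
            [0, 0, 0, 0],
            [1, 1, 1, 0],
            [1, 1, 0, 1],
            [1, 0, 1, 1],
        ],
        dtype=np.int8,
    )
    rows = []
    for _ in range(m):
        head = head_patterns[rng.integers(0, len(head_patterns))]
        tail = (rng.random(5) < 0.5).astype(np.int8)
        rows.append(np.concatenate([head, tail]))
    values = np.vstack(rows)
    # guarantee validity of the matrix (no all-zero rows) for similarity use
    for i in range(m):
        if not values[i].any():
            values[i, 4 + rng.integers(0, 5)] = 1
    return FingerprintMatrix(
        values, [f"t{i}" for i in range(1, m + 1)], scheme_name="fig1-toy"
    )
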