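r"""Tanimoto similarity and the related-bit contribution decomposition.

For two l-bit vectors :math:`v_a, v_b` the Tanimoto coefficient is
:math:`Tc = |v_a \cap v_b| / |v_a \cup v_b|` — the ratio of shared on-bits to
total on-bits.  Off bits never enter, so deleting bits that are off in both
vectors leaves the score unchanged.

Given a set of *related* bits (the k-bit subvectors :math:`u_a, u_b`), the
related bits' share of the pair's union and intersection is

.. math::

    \text{union ratio} = \frac{|u_a \cup u_b|}{\epsilon + |v_a \cup v_b|},
    \qquad
    \text{intersection ratio} = \frac{|u_a \cap u_b|}{\epsilon + |v_a \cap v_b|},

with a small :math:`\epsilon` (default 1e-10) guarding empty denominators.
When the related bits contribute more to the intersection than to the union
they inflate Tc; the reverse deflates it.  The exact bookkeeping identity
``Tc(reduced bits) = (I_full - I_rel) / (U_full - U_rel)`` links the
decomposition back to the similarity on the reduced set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matrix import FingerprintMatrix

__all__ = [
    "tanimoto",
    "similarity_matrix",
    "top_k_neighbors",
    "PairContribution",
    "pair_contribution",
    "reduced_tanimoto_identity_check",
]


def _as_bits(v) -> np.ndarray:
    a = np.asarray(v)
    if a.ndim != 1:
        raise ValueError("bit vectors must be 1-D")
    if not np.isin(a, (0, 1)).all():
        raise ValueError("bit vectors must contain only 0/1")
    return a.astype(np.int64)


def tanimoto(a, b) -> float:
    """Tanimoto coefficient of two equal-length bit vectors, in ``[0, 1]``.

    Raises on length mismatch and on a pair with no on-bits at all (the score
    is undefined; upstream filtering removes all-zero vectors).
    """
    va, vb = _as_bits(a), _as_bits(b)
    if va.shape != vb.shape:
        raise ValueError(f"length mismatch: {va.shape[0]} vs {vb.shape[0]}")
    inter = int((va & vb).sum())
    union = int((va | vb).sum())
    if union == 0:
        raise ValueError("undefined similarity: both vectors are all-zero")
    return inter / union


def similarity_matrix(M: FingerprintMatrix) -> np.ndarray:
    """Dense symmetric ``m x m`` Tanimoto matrix with unit diagonal."""
    V = M.values.astype(np.int64)
    on = V.sum(axis=1)
    if (on == 0).any():
        bad = M.compound_ids[int(np.argmax(on == 0))]
        raise ValueError(f"all-zero fingerprint vector for compound {bad!r}")
    inter = V @ V.T
    union = on[:, None] + on[None, :] - inter
    return inter / union


def top_k_neighbors(
    M: FingerprintMatrix, query_id: str, k: int = 50
) -> list[tuple[str, float]]:
    """The ``k`` compounds most similar to the query, with their scores.

    Sorted by descending Tanimoto score; ties broken by ascending compound id
    so rankings are deterministic.  The query itself is excluded.
    """
    qi = M.row_index(query_id)
    if k > M.n_compounds - 1:
        raise ValueError(f"k={k} exceeds the {M.n_compounds - 1} other compounds")
    q = M.values[qi]
    scored = [
        (cid, tanimoto(q, M.values[i]))
        for i, cid in enumerate(M.compound_ids)
        if i != qi
    ]
    scored.sort(key=lambda t: (-t[1], t[0]))
    return scored[:k]


@dataclass
class PairContribution:
    """Union/intersection counts for one pair, full and restricted to the
    related bits, with the two contribution ratios."""

    union_full: int
    intersection_full: int
    union_related: int
    intersection_related: int
    epsilon: float
    union_ratio: float
    intersection_ratio: float

    @property
    def effect_sign(self) -> int:
        """+1 when the related bits inflate Tc, -1 when they deflate it, 0 neutral."""
        return int(np.sign(self.intersection_ratio - self.union_ratio))


def pair_contribution(
    a, b, related: set[int] | list[int], epsilon: float = 1e-10
) -> PairContribution:
    """Contribution of the related bits (1-based positions) to a pair's
    union and intersection sets."""
    va, vb = _as_bits(a), _as_bits(b)
    if va.shape != vb.shape:
        raise ValueError("length mismatch")
    l = va.shape[0]
    rel = sorted(set(int(i) for i in related))
    if any(i < 1 or i > l for i in rel):
        raise ValueError("related positions must be within 1..l")
    idx = [i - 1 for i in rel]
    ua, ub = va[idx], vb[idx]
    union_full = int((va | vb).sum())
    inter_full = int((va & vb).sum())
    union_rel = int((ua | ub).sum())
    inter_rel = int((ua & ub).sum())
    def ratio(num: int, den: int) -> float:
        # with epsilon = 0 and an empty full set the numerator is 0 too: 0/0 := 0
        return num / (epsilon + den) if epsilon + den > 0 else 0.0

    return PairContribution(
        union_full=union_full,
        intersection_full=inter_full,
        union_related=union_rel,
        intersection_related=inter_rel,
        epsilon=epsilon,
        union_ratio=ratio(union_rel, union_full),
        intersection_ratio=ratio(inter_rel, inter_full),
    )


def reduced_tanimoto_identity_check(
    a, b, related: set[int] | list[int]
) -> tuple[float, float]:
    """Tanimoto on the reduced (non-related) bits via two routes.

    Returns ``(Tc on reduced bits, (I_full - I_rel) / (U_full - U_rel))``; the
    two are equal in exact arithmetic for every pair and related set, which
    makes this a useful internal consistency check.
    """
    va, vb = _as_bits(a), _as_bits(b)
    c = pair_contribution(a, b, related, epsilon=0.0)
    denom = c.union_full - c.union_related
    if denom == 0:
        raise ValueError("reduced similarity undefined: no on-bits outside related set")
    rel = set(int(i) for i in related)
    keep = [i for i in range(va.shape[0]) if (i + 1) not in rel]
    direct = tanimoto(va[keep], vb[keep])
    via_counts = (c.intersection_full - c.intersection_related) / denom
    return direct, via_counts
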