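"""Dataset filters and bit-usage analyses for fingerprint matrices.

The filter pipeline mirrors the standard preparation of a fingerprint dataset
before similarity analysis: drop compounds with duplicate 2D structures
(canonical SMILES), drop duplicate fingerprint vectors, drop all-zero vectors,
and drop vectors that are off for more than a given fraction of the bits
(default 90%).  Each stage keeps the first occurrence in row order, so the
pipeline is deterministic and order-stable, and every filter is idempotent.

The usage analysis reports per-bit on-counts, their skewness (Fisher–Pearson
g1), and the pairwise Pearson correlation of "moderately used" bits — those on
for between 25% and 75% of compounds by default.  For binary columns Pearson's
r coincides with the phi coefficient of the 2x2 contingency table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .matrix import CompoundRecord, FingerprintMatrix

__all__ = [
    "FilterReport",
    "UsageReport",
    "dedup_structures",
    "dedup_vectors",
    "remove_zero_and_sparse",
    "apply_filters",
    "usage_report",
]


@dataclass
class FilterReport:
    """Telescoping row counts across the filter stages, in pipeline order."""

    n_input_rows: int = 0
    n_after_smiles_dedup: int | None = None
    n_after_vector_dedup: int | None = None
    n_after_zero_removal: int | None = None
    n_after_sparse_removal: int | None = None
    removed_ids_by_stage: dict[str, list[str]] = field(default_factory=dict)

    def record(self, stage: str, removed: list[str], n_after: int) -> None:
        self.removed_ids_by_stage[stage] = list(removed)
        setattr(self, f"n_after_{stage}", n_after)

    def to_dict(self) -> dict:
        return {
            "n_input_rows": self.n_input_rows,
            "n_after_smiles_dedup": self.n_after_smiles_dedup,
            "n_after_vector_dedup": self.n_after_vector_dedup,
            "n_after_zero_removal": self.n_after_zero_removal,
            "n_after_sparse_removal": self.n_after_sparse_removal,
            "removed_ids_by_stage": self.removed_ids_by_stage,
        }


@dataclass
class UsageReport:
    """Per-bit usage statistics and correlations over moderately used bits.

    ``moderate_bit_indices`` are 1-based.  ``pairwise_r`` is ``None`` (with
    ``too_few_moderate_bits`` set) when fewer than two bits fall in the range.
    """

    on_bit_counts: np.ndarray
    skewness_gamma1: float
    moderate_bit_indices: list[int]
    pairwise_r: np.ndarray | None
    too_few_moderate_bits: bool = False


def dedup_structures(
    records: list[CompoundRecord],
) -> tuple[list[CompoundRecord], list[str]]:
    """Keep the first record per canonical SMILES (falling back to the raw
    SMILES string when no canonicalization has been applied)."""
    kept: list[CompoundRecord] = []
    removed: list[str] = []
    seen: set[str] = set()
    for rec in records:
        key = rec.canonical_smiles or rec.smiles
        if key in seen:
            removed.append(rec.id)
        else:
            seen.add(key)
            kept.append(rec)
    return kept, removed


def dedup_vectors(M: FingerprintMatrix) -> tuple[FingerprintMatrix, list[str]]:
    """Keep the first occurrence (in row order) of each distinct bit vector."""
    seen: set[bytes] = set()
    keep_idx: list[int] = []
    removed: list[str] = []
    for i, row in enumerate(M.values):
        key = row.tobytes()
        if key in seen:
            removed.append(M.compound_ids[i])
        else:
            seen.add(key)
            keep_idx.append(i)
    return M.select_rows(keep_idx), removed


def remove_zero_and_sparse(
    M: FingerprintMatrix, max_off_fraction: float = 0.9
) -> tuple[FingerprintMatrix, list[str], list[str]]:
    """Remove rows whose off-bit count strictly exceeds ``max_off_fraction * n``.

    All-zero rows are removed first (reported separately), then the remaining
    too-sparse rows; the sparse rule subsumes the all-zero one.  Raises when
    nothing survives.
    """
    if not 0 < max_off_fraction < 1:
        raise ValueError("max_off_fraction must be in (0, 1)")
    n = M.n_bits
    on_counts = M.values.sum(axis=1)
    zero = on_counts == 0
    sparse = ~zero & ((n - on_counts) > max_off_fraction * n)
    removed_zero = [cid for cid, z in zip(M.compound_ids, zero) if z]
    removed_sparse = [cid for cid, s in zip(M.compound_ids, sparse) if s]
    keep = [i for i in range(M.n_compounds) if not (zero[i] or sparse[i])]
    if not keep:
        raise ValueError("empty matrix after filtering")
    return M.select_rows(keep), removed_zero, removed_sparse


def apply_filters(
    M: FingerprintMatrix,
    max_off_fraction: float = 0.9,
    records: list[CompoundRecord] | None = None,
) -> tuple[FingerprintMatrix, FilterReport]:
    """Run the full pipeline and return the filtered matrix plus a report.

    When ``records`` is given, compounds removed by structure deduplication are
    dropped from the matrix first; otherwise that stage is a no-op.
    """
    report = FilterReport(n_input_rows=M.n_compounds)

    if records is not None:
        _, removed = dedup_structures(records)
        removed_set = set(removed)
        keep = [i for i, cid in enumerate(M.compound_ids) if cid not in removed_set]
        M = M.select_rows(keep)
        report.record("smiles_dedup", removed, M.n_compounds)
    else:
        report.record("smiles_dedup", [], M.n_compounds)

    M, removed = dedup_vectors(M)
    report.record("vector_dedup", removed, M.n_compounds)

    M, removed_zero, removed_sparse = remove_zero_and_sparse(M, max_off_fraction)
    report.record("zero_removal", removed_zero, report.n_after_vector_dedup - len(removed_zero))
    report.record("sparse_removal", removed_sparse, M.n_compounds)
    return M, report


def usage_report(
    M: FingerprintMatrix, lower: float = 0.25, upper: float = 0.75
) -> UsageReport:
    """On-bit counts, their skewness, and Pearson r over moderate bits.

    A bit is "moderate" when ``lower*m <= on-count <= upper*m`` (both bounds
    inclusive).  With fewer than two such bits the correlation matrix is
    omitted and a warning flag set.
    """
    if not 0 <= lower < upper <= 1:
        raise ValueError("need 0 <= lower < upper <= 1")
    m = M.n_compounds
    counts = M.values.sum(axis=0).astype(np.int64)
    # Fisher–Pearson g1 = m3 / m2^{3/2}; zero for a constant count vector.
    g1 = 0.0 if np.ptp(counts) == 0 else float(stats.skew(counts, bias=True))
    in_range = (counts >= lower * m) & (counts <= upper * m)
    moderate = [int(i) + 1 for i in np.flatnonzero(in_range)]
    if len(moderate) < 2:
        warnings.warn("fewer than 2 moderately used bits; pairwise_r omitted")
        return UsageReport(counts, g1, moderate, None, too_few_moderate_bits=True)
    sub = M.values[:, [i - 1 for i in moderate]].astype(float)
    r = np.corrcoef(sub, rowvar=False)
    return UsageReport(counts, g1, moderate, r)
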