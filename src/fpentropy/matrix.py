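"""Core containers: compound records and the binary fingerprint matrix.

The central object is :class:`FingerprintMatrix`, an ``m x n`` matrix ``A``
whose entry ``a[i, j]`` is the value (0 or 1) of the j-th fingerprint bit for
the i-th compound.  Everything downstream — entropy, similarity, null models —
consumes this container and nothing else.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CompoundRecord", "FingerprintMatrix", "default_bit_labels"]


def default_bit_labels(n: int) -> list[str]:
    """Labels ``F1 .. Fn`` (1-based, matching conventional fingerprint indexing)."""
    return [f"F{i}" for i in range(1, n + 1)]


@dataclass
class CompoundRecord:
    """One compound: an opaque identifier plus its SMILES string.

    ``canonical_smiles`` is filled by a fingerprint backend's canonicalizer and
    is deterministic for a given ``smiles`` under that backend.  ``class_label``
    carries an optional category such as ``"drug"`` or ``"endogenous"``.
    """

    id: str
    smiles: str
    canonical_smiles: str | None = None
    class_label: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("compound id must be non-empty")


@dataclass
class FingerprintMatrix:
    """An m x n binary feature matrix with row and column identity.

    Parameters
    ----------
    values
        Array of shape ``(m, n)`` with entries exactly 0 or 1.
    compound_ids
        Length-m unique row identifiers.
    bit_labels
        Length-n unique column labels; defaults to ``F1..Fn``.
    scheme_name
        Free-form scheme tag, e.g. ``"MACCS"``, ``"Pubchem"``, ``"synthetic"``.
    """

    values: np.ndarray
    compound_ids: list[str]
    bit_labels: list[str] = field(default_factory=list)
    scheme_name: str = "unknown"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        m, n = self.values.shape
        if m < 1 or n < 1:
            raise ValueError(f"matrix must have m >= 1 and n >= 1, got {m}x{n}")
        if not np.isin(self.values, (0, 1)).all():
            bad = np.argwhere(~np.isin(self.values, (0, 1)))[0]
            raise ValueError(
                f"non-binary entry at row {bad[0]}, column {bad[1]}: "
                f"{self.values[bad[0], bad[1]]!r}"
            )
        self.values = self.values.astype(np.int8, copy=False)
        self.compound_ids = [str(c) for c in self.compound_ids]
        if len(self.compound_ids) != m:
            raise ValueError("compound_ids length must equal the row count")
        if len(set(self.compound_ids)) != m:
            raise ValueError("compound_ids must be unique")
        if not self.bit_labels:
            self.bit_labels = default_bit_labels(n)
        self.bit_labels = [str(b) for b in self.bit_labels]
        if len(self.bit_labels) != n:
            raise ValueError("bit_labels length must equal the column count")
        if len(set(self.bit_labels)) != n:
            raise ValueError("bit_labels must be unique")

    # ------------------------------------------------------------------ views
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_compounds(self) -> int:
        return self.values.shape[0]

    @property
    def n_bits(self) -> int:
        return self.values.shape[1]

    def row_index(self, compound_id: str) -> int:
        try:
            return self.compound_ids.index(compound_id)
        except ValueError:
            raise KeyError(f"unknown compound id: {compound_id!r}") from None

    def row(self, compound_id: str) -> np.ndarray:
        """The bit vector of one compound."""
        return self.values[self.row_index(compound_id)]

    def select_rows(self, indices: list[int]) -> "FingerprintMatrix":
        return FingerprintMatrix(
            self.values[indices],
            [self.compound_ids[i] for i in indices],
            list(self.bit_labels),
            self.scheme_name,
        )

    def select_bits(self, positions: list[int]) -> "FingerprintMatrix":
        """Column submatrix for 1-based bit positions, preserving labels."""
        cols = [p - 1 for p in positions]
        if any(c < 0 or c >= self.n_bits for c in cols):
            raise IndexError("bit position out of range (positions are 1-based)")
        return FingerprintMatrix(
            self.values[:, cols],
            list(self.compound_ids),
            [self.bit_labels[c] for c in cols],
            self.scheme_name,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FingerprintMatrix):
            return NotImplemented
        return (
            self.compound_ids == other.compound_ids
            and self.bit_labels == other.bit_labels
            and self.values.shape == other.values.shape
            and bool((self.values == other.values).all())
        )
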