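r"""Eigenvalue-based entropy of a binary feature matrix and relatedness selection.

For an ``m x n`` feature matrix ``A``, the Gram matrix ``A^T A`` is positive
semidefinite with eigenvalues :math:`\lambda_1 \ge \dots \ge \lambda_n \ge 0`.
With normalized eigenvalues :math:`q_j = \lambda_j / \sum_k \lambda_k`, the
eigenvalue-based entropy is

.. math:: H(A) = -\frac{1}{\log n} \sum_{j=1}^n q_j \log q_j,

with the convention :math:`0 \log 0 = 0`.  ``H`` is 0 when the spectrum is
concentrated on a single eigenvector (rank 1) and 1 when every eigenvector
contributes equally (e.g. the identity).

The contribution of bit ``i`` is measured leave-one-out: ``h_i = H(A[-i])``
where ``A[-i]`` is ``A`` with column ``i`` replaced by zeros (the matrix keeps
``n`` columns, so the ``log n`` normalization is unchanged).  Zeroing a column
of ``A`` zeroes row and column ``i`` of the Gram matrix, so all ``h_i`` can be
computed from the ``n x n`` Gram matrix alone — the cost depends on the number
of bits, not the (presumed large) number of compounds.

A bit is classified *related* (quasi linearly dependent on other bits) when its
removal barely moves the entropy:

.. math:: |h_i - h_0| < z \sqrt{\tfrac{1}{n}\sum_j (h_j - h_0)^2},

where ``z`` is the reduced-level threshold (typically 0.1–0.3).  The complement
of the related set is the *reduced* fingerprint set retained for similarity
scoring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .matrix import FingerprintMatrix

__all__ = [
    "EigenSpectrum",
    "EntropyProfile",
    "RelatednessSelection",
    "gram_matrix",
    "eigen_spectrum",
    "entropy",
    "entropy_profile",
    "select_related",
    "reduce_matrix",
    "matrix_rank",
]


@dataclass
class EigenSpectrum:
    """Non-increasing eigenvalues of ``A^T A`` and their normalized weights."""

    eigenvalues: np.ndarray
    normalized: np.ndarray


@dataclass
class EntropyProfile:
    """Full-matrix entropy ``h0`` plus per-bit leave-one-out entropies.

    ``h[i-1]`` is the entropy of the matrix with bit ``i`` zeroed; entries are
    NaN where that matrix was all-zero (entropy undefined).
    """

    h0: float
    h: np.ndarray
    n: int

    @property
    def complete(self) -> bool:
        return not np.isnan(self.h).any()

    @property
    def deviations(self) -> np.ndarray:
        return self.h - self.h0


@dataclass
class RelatednessSelection:
    """Partition of bits 1..n into related (quasi-dependent) and reduced sets."""

    z: float
    rms_deviation: float
    related_indices: list[int]
    reduced_indices: list[int]

    @property
    def fraction_retained(self) -> float:
        n = len(self.related_indices) + len(self.reduced_indices)
        return len(self.reduced_indices) / n


def _as_values(M: FingerprintMatrix | np.ndarray) -> np.ndarray:
    if isinstance(M, FingerprintMatrix):
        return M.values.astype(np.float64)
    return np.asarray(M, dtype=np.float64)


def gram_matrix(M: FingerprintMatrix | np.ndarray) -> np.ndarray:
    """The ``n x n`` matrix ``A^T A``."""
    A = _as_values(M)
    return A.T @ A


def _entropy_from_gram(G: np.ndarray) -> float:
    n = G.shape[0]
    if n < 2:
        raise ValueError("entropy normalization undefined for n = 1 (log n = 0)")
    lam = np.linalg.eigvalsh(G)
    lam = np.clip(lam, 0.0, None)  # numerical negatives of a PSD matrix
    total = lam.sum()
    if total <= 0:
        raise ValueError("entropy undefined: zero spectrum (all-zero matrix)")
    q = lam / total
    nz = q[q > 0]
    return float(-(nz * np.log(nz)).sum() / np.log(n))


def eigen_spectrum(M: FingerprintMatrix | np.ndarray) -> EigenSpectrum:
    """Eigenvalues of the Gram matrix, sorted non-increasing, plus weights."""
    G = gram_matrix(M)
    lam = np.clip(np.linalg.eigvalsh(G), 0.0, None)[::-1]
    total = lam.sum()
    if total <= 0:
        raise ValueError("entropy undefined: zero spectrum (all-zero matrix)")
    return EigenSpectrum(lam, lam / total)


def entropy(M: FingerprintMatrix | np.ndarray, is_gram: bool = False) -> float:
    """Normalized eigenvalue entropy of a feature matrix in ``[0, 1]``.

    ``M`` is an ``m x n`` feature matrix (a :class:`FingerprintMatrix` or
    array), or a precomputed Gram matrix when ``is_gram`` is true.  The
    logarithm base cancels between the entropy sum and ``log n``.
    """
    if is_gram:
        G = np.asarray(M, dtype=np.float64)
        if G.ndim != 2 or G.shape[0] != G.shape[1]:
            raise ValueError("a Gram matrix must be square")
        return _entropy_from_gram(G)
    return _entropy_from_gram(gram_matrix(M))


def entropy_profile(M: FingerprintMatrix | np.ndarray) -> EntropyProfile:
    """``h0`` and all leave-one-out entropies via the Gram-matrix shortcut.

    Computes ``G = A^T A`` once; ``h_i`` is the entropy of ``G`` with row and
    column ``i`` zeroed, identical to recomputing from the column-zeroed
    ``m x n`` matrix.  An already-zero column leaves ``G`` unchanged, so its
    ``h_i`` equals ``h0`` exactly.  If zeroing bit ``i`` empties the matrix,
    ``h_i`` is recorded as NaN with a warning.
    """
    G = gram_matrix(M)
    n = G.shape[0]
    if n < 2:
        raise ValueError("entropy profile requires n >= 2 bits")
    h0 = _entropy_from_gram(G)
    h = np.empty(n)
    diag = np.diag(G)
    for i in range(n):
        if diag[i] == 0:
            h[i] = h0  # zeroing an already-zero row/column is a no-op
            continue
        Gi = G.copy()
        Gi[i, :] = 0.0
        Gi[:, i] = 0.0
        try:
            h[i] = _entropy_from_gram(Gi)
        except ValueError:
            warnings.warn(
                f"bit {i + 1}: matrix is all-zero without it; h_i recorded as NaN"
            )
            h[i] = np.nan
    return EntropyProfile(h0=h0, h=h, n=n)


def select_related(profile: EntropyProfile, z: float) -> RelatednessSelection:
    """Split bits into related and reduced sets at reduced-level threshold ``z``.

    Bit ``i`` is related iff ``|h_i - h0| < z * rms`` (strict), with ``rms``
    the root-mean-square deviation of all ``h_j`` around ``h0`` (divisor
    ``n``).  Selections are nested in ``z``.  When every ``h_i`` equals ``h0``
    the RMS is zero and nothing is selected (warned).
    """
    if z <= 0:
        raise ValueError("z must be > 0")
    if not profile.complete:
        raise ValueError("profile has undefined h_i values; cannot select")
    dev = np.abs(profile.deviations)
    rms = float(np.sqrt(np.mean(profile.deviations**2)))
    if rms == 0.0:
        warnings.warn("all h_i equal h0 (rms = 0); related set is empty")
    related = np.flatnonzero(dev < z * rms)
    reduced = np.flatnonzero(~(dev < z * rms))
    return RelatednessSelection(
        z=z,
        rms_deviation=rms,
        related_indices=[int(i) + 1 for i in related],
        reduced_indices=[int(i) + 1 for i in reduced],
    )


def reduce_matrix(M: FingerprintMatrix, S: RelatednessSelection) -> FingerprintMatrix:
    """Submatrix on the reduced (retained) bits, preserving order and labels."""
    if len(S.related_indices) + len(S.reduced_indices) != M.n_bits:
        raise ValueError("selection does not match the matrix bit count")
    if not S.reduced_indices:
        raise ValueError("reduced set is empty; nothing to retain")
    return M.select_bits(S.reduced_indices)


def matrix_rank(M: FingerprintMatrix | np.ndarray, tol: float | None = None) -> int:
    """Numerical rank: singular values above ``tol``.

    ``tol`` defaults to ``max(m, n) * eps * sigma_max`` (the numpy default).
    """
    A = _as_values(M)
    return int(np.linalg.matrix_rank(A, tol=tol))
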