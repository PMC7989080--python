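"""Eigenvalue entropy, leave-one-out profile, and relatedness selection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fpentropy.entropy import (
    entropy,
    entropy_profile,
    matrix_rank,
    reduce_matrix,
    select_related,
)
from fpentropy.synth import SynthSpec, generate

from conftest import as_fpm, random_binary_matrix, svd_entropy


class TestEntropy:
    def test_identity_has_entropy_one(self):
        assert entropy(np.eye(6)) == pytest.approx(1.0, abs=1e-12)

    def test_rank_one_has_entropy_zero(self):
        col = np.array([[1], [0], [1], [1], [0]])
        assert entropy(np.tile(col, (1, 4))) == pytest.approx(0.0, abs=1e-12)

    def test_matches_direct_svd_oracle(self, rng):
        for _ in range(25):
            A = random_binary_matrix(rng, 8, 5)
            assert entropy(A) == pytest.approx(svd_entropy(A), abs=1e-8)

    def test_gram_input_equivalent(self, rng):
        A = random_binary_matrix(rng, 9, 4).astype(float)
        assert entropy(A.T @ A, is_gram=True) == pytest.approx(entropy(A), abs=1e-12)

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError, match="zero spectrum"):
            entropy(np.zeros((4, 3)))

    def test_single_column_rejected(self):
        with pytest.raises(ValueError, match="n = 1"):
            entropy(np.ones((4, 1)))

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.integers(0, 2**32 - 1), st.integers(2, 8), st.integers(2, 6))
    def test_permutation_and_scale_invariance(self, seed, m, n):
        rng = np.random.default_rng(seed)
        A = random_binary_matrix(rng, m, n, density=0.5).astype(float)
        h = entropy(A)
        assert 0.0 <= h <= 1.0 + 1e-12
        rp, cp = rng.permutation(m), rng.permutation(n)
        assert entropy(A[rp][:, cp]) == pytest.approx(h, abs=1e-10)
        assert entropy(3.7 * A) == pytest.approx(h, abs=1e-10)


class TestEntropyProfile:
    def test_gram_shortcut_equals_column_zero_oracle(self, rng):
        for _ in range(20):
            m, n = rng.integers(4, 15), rng.integers(3, 8)
            A = random_binary_matrix(rng, m, n)
            prof = entropy_profile(as_fpm(A))
            for i in range(n):
                Ai = A.astype(float).copy()
                Ai[:, i] = 0.0
                assert prof.h[i] == pytest.approx(svd_entropy(Ai), abs=1e-8)

    def test_zero_column_leaves_entropy_unchanged(self, rng):
        A = random_binary_matrix(rng, 6, 4)
        A = np.column_stack([A, np.zeros(6, dtype=np.int8)])
        prof = entropy_profile(A)
        assert prof.h[4] == prof.h0  # exact: the Gram matrix is untouched

    def test_identical_columns_have_identical_h(self):
        col = np.array([1, 0, 1, 1, 0, 1])
        other = np.array([0, 1, 1, 0, 1, 0])
        A = np.column_stack([col, col, other])
        prof = entropy_profile(A)
        assert prof.h[0] == prof.h[1]

    def test_emptying_bit_recorded_missing(self):
        A = np.array([[1, 0], [1, 0], [0, 0]])
        with pytest.warns(UserWarning, match="all-zero"):
            prof = entropy_profile(A)
        assert np.isnan(prof.h[0]) and not prof.complete


class TestSelection:
    def test_zero_rms_selects_nothing(self):
        from fpentropy.entropy import EntropyProfile

        prof = EntropyProfile(h0=0.8, h=np.full(4, 0.8), n=4)
        with pytest.warns(UserWarning, match="rms = 0"):
            sel = select_related(prof, 0.3)
        assert sel.related_indices == []
        assert sel.reduced_indices == [1, 2, 3, 4]

    def test_selection_monotone_in_z(self, rng):
        M, _ = generate(SynthSpec(m=120, n_indep=20, n_dup=5, n_sum=5, density=0.4, seed=3))
        prof = entropy_profile(M)
        prev: set[int] = set()
        for z in (0.1, 0.2, 0.3, 0.6, 1.2):
            cur = set(select_related(prof, z).related_indices)
            assert prev <= cur
            prev = cur

    def test_partition_covers_all_bits(self, rng):
        A = random_binary_matrix(rng, 10, 6)
        sel = select_related(entropy_profile(A), 0.5)
        assert sorted(sel.related_indices + sel.reduced_indices) == list(range(1, 7))

    def test_dependent_bits_closer_to_h0_than_independent(self):
        M, planted = generate(
            SynthSpec(m=500, n_indep=40, n_dup=10, n_sum=10, density=0.4, seed=11)
        )
        prof = entropy_profile(M)
        dev = np.abs(prof.deviations)
        pl = [p - 1 for p in planted]
        ind = [i for i in range(M.n_bits) if i + 1 not in planted]
        assert dev[pl].mean() < dev[ind].mean()

    def test_duplicate_bit_ties_parent_deviation_exactly(self):
        M, planted = generate(
            SynthSpec(m=200, n_indep=15, n_dup=5, n_sum=0, density=0.4, seed=2)
        )
        prof = entropy_profile(M)
        V = M.values
        for p in planted:
            twins = [
                j for j in range(M.n_bits)
                if j != p - 1 and (V[:, j] == V[:, p - 1]).all()
            ]
            assert twins  # a duplicate has at least one identical column
            # zeroing either twin yields permutation-similar Gram matrices,
            # so the entropies agree up to eigensolver roundoff
            for j in twins:
                assert prof.h[j] == pytest.approx(prof.h[p - 1], abs=1e-12)

    def test_reduce_matrix_projects_reduced_bits(self, rng):
        A = random_binary_matrix(rng, 30, 9)
        prof = entropy_profile(A)
        sel = select_related(prof, 1.0)
        if not sel.reduced_indices:
            pytest.skip("degenerate draw")
        R = reduce_matrix(as_fpm(A), sel)
        assert R.n_bits == len(sel.reduced_indices)
        assert R.bit_labels == [f"F{i}" for i in sel.reduced_indices]


class TestRank:
    def test_identity(self):
        assert matrix_rank(np.eye(5)) == 5

    def test_duplicate_column_adds_no_rank(self, rng):
        A = random_binary_matrix(rng, 8, 5)
        dup = np.column_stack([A, A[:, 0]])
        assert matrix_rank(dup) == matrix_rank(A)

    def test_matches_exact_rational_rank_oracle(self, rng):
        sympy = pytest.importorskip("sympy")
        for _ in range(10):
            A = random_binary_matrix(rng, 7, 6, density=0.5)
            assert matrix_rank(A) == sympy.Matrix(A.tolist()).rank()

    def test_planted_dependents_add_no_rank(self):
        M, planted = generate(
            SynthSpec(m=300, n_indep=20, n_dup=6, n_sum=4, density=0.4, seed=9)
        )
        indep = [i for i in range(1, M.n_bits + 1) if i not in planted]
        assert matrix_rank(M) == matrix_rank(M.select_bits(indep))
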