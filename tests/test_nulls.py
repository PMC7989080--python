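"""Random-pruning null model, sign test, and summary statistics."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest

from fpentropy.nulls import (
    group_mean_similarity,
    random_pruning_null,
    relative_change,
    sign_test,
    summarize_pairs,
)
from fpentropy.similarity import tanimoto
from fpentropy.synth import SynthSpec, generate

from conftest import as_fpm, random_binary_matrix


def exact_binomial_two_sided(k, n):
    """Oracle: two-sided exact binomial p at p=1/2 via Fraction arithmetic.

    Sums P(X = i) over all outcomes no more probable than the observed one
    (with p = 1/2, P(X = i) is proportional to C(n, i)).
    """
    obs = comb(n, k)
    total = sum(comb(n, i) for i in range(n + 1) if comb(n, i) <= obs)
    return Fraction(total, 2**n)


class TestSignTest:
    @pytest.mark.parametrize(
        "pos, neg, expected",
        [
            (0, 30, 2 * Fraction(1, 2**30)),
            (5, 5, 1),
            (0, 2, Fraction(1, 2)),
        ],
    )
    def test_closed_form_examples(self, pos, neg, expected):
        deltas = [1.0] * pos + [-1.0] * neg
        assert sign_test(deltas) == pytest.approx(float(expected), rel=1e-12)

    def test_matches_exact_fraction_oracle_up_to_60(self):
        for n in (1, 2, 5, 13, 31, 60):
            for k in {0, 1, n // 3, n // 2, n}:
                deltas = [1.0] * k + [-1.0] * (n - k)
                assert sign_test(deltas) == pytest.approx(
                    float(exact_binomial_two_sided(k, n)), rel=1e-10
                )

    def test_zeros_dropped(self):
        assert sign_test([0.0, 0.0, -1.0, -1.0]) == pytest.approx(0.5)

    def test_all_zero_warns_p_one(self):
        with pytest.warns(UserWarning, match="all deltas"):
            assert sign_test([0.0, 0.0]) == 1.0


class TestRandomPruningNull:
    def test_reproducible_for_a_seed(self, rng):
        M = as_fpm(random_binary_matrix(rng, 10, 20))
        a = random_pruning_null(M, ("c1", "c2"), keep=12, N=50, seed=99)
        b = random_pruning_null(M, ("c1", "c2"), keep=12, N=50, seed=99)
        assert np.array_equal(a.null_scores, b.null_scores)
        assert a.quartiles == b.quartiles

    def test_off_bit_insensitive_draws_reproduce_full_score(self):
        # dropping a single bit that is on in both or off in both never
        # changes the score of an identical pair, so with keep = n-1 every
        # null draw equals the full-vector score
        M = as_fpm([[1, 1, 0], [1, 1, 0], [1, 0, 1]])
        nd = random_pruning_null(M, ("c1", "c2"), keep=2, N=40, seed=1)
        full = tanimoto(M.row("c1"), M.row("c2"))
        assert np.allclose(nd.null_scores, full)

    def test_p_value_floor_is_two_over_n_plus_one(self, rng):
        M = as_fpm(random_binary_matrix(rng, 6, 15))
        nd = random_pruning_null(M, ("c1", "c2"), keep=10, N=30, seed=5, observed=2.0)
        # an observed score beyond every null value hits the add-one floor
        assert nd.p_value == pytest.approx(2 / 31)

    def test_p_value_bounds(self, rng):
        M = as_fpm(random_binary_matrix(rng, 8, 15))
        for obs in (0.0, 0.3, 1.0):
            nd = random_pruning_null(
                M, ("c1", "c3"), keep=9, N=25, seed=3, observed=obs
            )
            assert 2 / 26 <= nd.p_value <= 1.0

    def test_keep_must_be_less_than_n(self, rng):
        M = as_fpm(random_binary_matrix(rng, 4, 6))
        with pytest.raises(ValueError, match="keep"):
            random_pruning_null(M, ("c1", "c2"), keep=6, N=5, seed=0)

    def test_no_directional_bias_in_relative_change(self):
        # mean relative change of randomly pruned scores stays within 3 SE of 0
        M, _ = generate(SynthSpec(m=30, n_indep=60, n_dup=0, n_sum=0,
                                  density=0.35, seed=17))
        va, vb = M.row("c1"), M.row("c2")
        full = tanimoto(va, vb)
        nd = random_pruning_null(M, ("c1", "c2"), keep=45, N=2000, seed=17)
        rel = (nd.null_scores - full) / full
        se = rel.std(ddof=1) / np.sqrt(rel.size)
        assert abs(rel.mean()) < 3 * se


class TestSummaries:
    def test_degenerate_and_simple_counts(self):
        s = summarize_pairs([1.0, 1.0, 1.0])
        assert (s.mean, s.std_dev, s.min_score) == (1.0, 0.0, 1.0)
        assert s.n_ge_08 == 3 and s.n_ge_07 == 3
        s2 = summarize_pairs([0.5, 0.9])
        assert s2.n_ge_08 == 1 and s2.n_ge_07 == 1 and s2.min_score == 0.5

    def test_single_score_warns(self):
        with pytest.warns(UserWarning, match="single score"):
            assert summarize_pairs([0.4]).std_dev == 0.0

    def test_matches_brute_force_recount(self, rng):
        scores = rng.random(200)
        s = summarize_pairs(scores, thresholds=(0.8, 0.7, 0.25))
        assert s.mean == pytest.approx(sum(scores) / 200)
        assert s.std_dev == pytest.approx(
            (sum((x - s.mean) ** 2 for x in scores) / 199) ** 0.5
        )
        for t in (0.8, 0.7, 0.25):
            assert s.threshold_counts[t] == sum(1 for x in scores if x >= t)
        assert s.min_score == min(scores)


class TestGroupMeans:
    def test_identical_pair_class_mean_one(self):
        M = as_fpm([[1, 0, 1], [1, 0, 1], [0, 1, 0]])
        out = group_mean_similarity(M, {"c1": "drug", "c2": "drug", "c3": "drug"})
        assert out["drug"] < 1.0  # includes the dissimilar third compound
        out2 = group_mean_similarity(M, {"c1": "drug", "c2": "drug"})
        assert out2["drug"] == 1.0

    def test_singleton_classes_skipped_all_row_kept(self):
        M = as_fpm([[1, 0], [0, 1]])
        with pytest.warns(UserWarning, match="fewer than 2"):
            out = group_mean_similarity(M, {"c1": "a", "c2": "b"})
        assert "a" not in out and "b" not in out
        assert out["All"] == tanimoto([1, 0], [0, 1])

    def test_matches_brute_force_per_class_oracle(self, rng):
        M = as_fpm(random_binary_matrix(rng, 12, 6))
        classes = ["x", "y", "z"]
        labels = {cid: classes[i % 3] for i, cid in enumerate(M.compound_ids)}
        out = group_mean_similarity(M, labels)
        for cls in classes:
            members = [cid for cid in M.compound_ids if labels[cid] == cls]
            vals = [
                tanimoto(M.row(a), M.row(b))
                for i, a in enumerate(members)
                for b in members[i + 1:]
            ]
            assert out[cls] == pytest.approx(np.mean(vals))


class TestRelativeChange:
    @pytest.mark.parametrize(
        "red, full, expected",
        [(0.5, 0.5, 0.0), (0.55, 0.5, 0.1), (0.5, 0.55, -0.5 / 5.5)],
    )
    def test_arithmetic(self, red, full, expected):
        assert relative_change(red, full) == pytest.approx(expected)

    def test_zero_base_rejected(self):
        with pytest.raises(ValueError):
            relative_change(0.1, 0.0)
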