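# Methods notes

## Model and procedure

`fpentropy` treats a compound library as an m×n binary matrix **A** (rows =
compounds, columns = fingerprint bits) and asks which bits are *related* —
quasi linearly dependent on other bits — using only the spectrum of the Gram
matrix **G = AᵀA**.

1. **Eigenvalue entropy.** G is positive semidefinite with eigenvalues
   λ₁ ≥ … ≥ λₙ ≥ 0; with weights qⱼ = λⱼ/Σλₖ the normalized entropy is
   H = −(1/log n)·Σ qⱼ log qⱼ, using the convention 0·log 0 = 0 (required
   whenever rank(A) < n, which binary fingerprint matrices routinely
   exhibit). H = 0 iff the spectrum is concentrated on one eigenvector;
   H = 1 iff all eigenvalues are equal. The log base cancels between the sum
   and log n; natural log is used internally.
2. **Leave-one-out profile.** hᵢ = H(A[−i]) where A[−i] replaces column i by
   zeros but keeps n columns, so the log n normalization is unchanged.
   Zeroing column i of A zeroes row and column i of G, so the whole profile
   is computed from one n×n Gram matrix: cost O(n·n³) independent of m. An
   already-zero column leaves G untouched, hence hᵢ = h₀ *exactly*; such
   bits are always classified related for any z > 0, consistent with the
   goal of discarding uninformative bits.
3. **Relatedness selection.** Bit i is related iff |hᵢ − h₀| < z·RMS with
   RMS = sqrt(Σⱼ(hⱼ − h₀)²/n). The scale is the RMS deviation around h₀
   with divisor n (implemented literally), *not* the sample standard
   deviation of {hᵢ}. The inequality is strict, so a degenerate profile
   (all hᵢ = h₀, RMS = 0) selects nothing, with a warning. Selections are
   nested (monotone) in z.
4. **Similarity decomposition.** For a pair (v_a, v_b) and the related-bit
   subvectors (u_a, u_b), the union ratio |u_a ∪ u_b|/(ε + |v_a ∪ v_b|) and
   intersection ratio |u_a ∩ u_b|/(ε + |v_a ∩ v_b|) locate the related
   bits' effect: intersection ratio above union ratio means they inflate Tc,
   below means they deflate it. ε (default 1e-10, configurable) sits in the
   denominator only. The bookkeeping identity
   Tc(reduced) = (I_full − I_rel)/(U_full − U_rel) holds exactly and is
   enforced as an internal consistency check.
5. **Null model and tests.** For a pair, N uniform random size-k bit subsets
   (k = reduced-set size; default N = 10,000) give a null Tc distribution.
   Empirical p-values use the add-one estimator (1 + #extreme)/(N + 1) so
   p = 0 is impossible; two-sided = double the smaller tail, capped at 1.
   Draws where both pruned vectors are all-zero are excluded and counted.
   Direction of score changes across pairs is tested with the two-sided
   exact binomial sign test at p = ½, zeros dropped (standard convention).

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| z | 0.1 / 0.2 / 0.3 | reduced-level threshold; multiplier on the RMS entropy deviation. Larger z prunes more aggressively. |
| ε | 1e-10 | guards empty union/intersection denominators in the contribution ratios. |
| N | 10,000 | random-pruning draws per pair. |
| max off fraction | 0.9 | rows whose off-bit count strictly exceeds 0.9·n are dropped (subsumes all-zero rows). |
| moderate range | [0.25, 0.75]·m | inclusive on-count band defining "moderately used" bits for the correlation analysis. |

## Numerical choices

- Eigenvalues via symmetric eigendecomposition (`eigvalsh`) of the n×n Gram
  matrix, not SVD of A, so cost is independent of compound count; tiny
  negative eigenvalues from floating point are clipped to 0 before
  normalization. Agreement with direct SVD of the column-zeroed matrix is
  tested to 1e-8.
- Numerical rank = singular values above max(m, n)·eps·σ_max (numpy
  default), cross-checked in tests against exact rational-arithmetic rank.
- Neighbor rankings break score ties by ascending compound id; row
  deduplication keeps the first occurrence — both purely for determinism.
- Skewness of on-bit counts is the moment estimator g₁ = m₃/m₂^{3/2}
  (no small-sample correction); for binary columns Pearson's r equals the
  φ coefficient, which the tests exploit as an independent oracle.
- Pairs with no on-bits at all raise rather than scoring 0: upstream
  filtering removes all-zero vectors, and silently returning a number would
  mask pipeline errors.

## Synthetic data: what it emulates and what it does not

The generator plants *exact* linear dependencies while staying binary:
duplicate bits (copies of random independent columns) and sum bits
F_c = F_a + F_b where the two parents split one Bernoulli(density) support
by a fair coin — disjoint by construction, so the sum is 0/1 with typical
column weight. This mimics a coarse key that fires exactly when one of two
finer, mutually exclusive keys does. Column order is shuffled; the planted
positions are returned as ground truth. Default conditions (m = 500,
n_indep = 40, n_dup = 10, n_sum = 10, density = 0.4) give a 60-bit matrix of
rank ≤ 40.

Not emulated: realistic MACCS/PubChem bit marginals (real usage is highly
skewed), substructure co-occurrence, and *soft* collinearity (noisy
dependence). Passing tests on this generator demonstrate the algebra and the
detection of exact dependence; they do not certify behavior on any
particular chemical library.

A finding from our own experiments, documented as a known limitation: the
magnitude of |hᵢ − h₀| for a dependent bit grows with the weight (on-count)
the bit carries, not only with its linear dependence. Duplicate bits sit
well below the RMS deviation, but dependent bits of near-typical weight can
reach 0.6–1.0 × RMS, so a strict z = 0.3 cut recovers only part of the
planted set (roughly a third to two thirds across seeds at the default
conditions; the fixed-seed regression test pins the planted-recovery suite
at seed 11). Detection of *all* exact dependencies at small z should not be
expected from this statistic; it flags low-spectral-impact bits, of which
exact dependents with small weight are the prime examples.

Statistical test calibrations, chosen once as study conditions: the p-value
uniformity check uses 500 pairs × 200 draws on a 200×160, density-0.3 matrix
with k = 120 — MACCS-like width, where Tanimoto scores are nearly continuous
and the add-one two-sided p-value is approximately Uniform(0,1); the
acceptance band is the 99% Kolmogorov band. On much narrower matrices the
score distribution is heavily tied and the estimator becomes conservative
(p-values stochastically larger than uniform) — expected behavior, not a
defect. The no-directional-bias check uses 2,000 draws and a ±3 standard
error band around a zero mean relative change.

## Design decisions that were genuinely open

- **Fingerprint generation is an adapter.** The math core consumes any
  binary matrix; an RDKit-backed MACCS backend ships for convenience (RDKit
  emits 167 bits with bit 0 a placeholder; it is dropped to yield the
  canonical 166). Canonical-SMILES deduplication is defined within one
  backend's dialect only.
- **A[−i] keeps n columns.** Zeroing rather than deleting the column keeps
  the normalization fixed at log n and makes the Gram shortcut exact.
- **Bit indices are 1-based** in selections, labels (F1..Fn) and serialized
  JSON, matching fingerprint-key numbering conventions in the field.
- **Dense similarity matrices.** At the ~10³-compound scale this is ≤ 10 MB;
  sparsity machinery would buy nothing.
- **Threshold strictness.** ">90% off bits" is strict; the moderate-usage
  band is inclusive at both ends; Eq-style thresholds on summary counts
  (≥ 0.8, ≥ 0.7) are inclusive.

## Known limitations

- Relatedness is unsupervised: a bit flagged related may still be relevant
  for a specific discrimination task; the method deliberately ignores labels.
- The entropy statistic is blind to dependencies carried by high-weight bits
  (see above) and, conversely, flags all-zero or near-uninformative bits as
  related even when they are independent in the linear-algebra sense.
- Empirical p-values are per pair; no multiple-testing correction is applied
  across pairs.
- The `.smi`/CSV readers are deliberately strict (cells exactly "0"/"1") to
  guarantee bit-exact round trips; they do not attempt recovery of malformed
  files.
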