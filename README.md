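# fpentropy

Eigenvalue-entropy analysis of *related* bits in binary 2D chemical
fingerprints, and of how those bits inflate or deflate Tanimoto similarity
scores.

## The problem

Similarity-based virtual screening represents each molecule as a fixed-length
binary fingerprint (166-bit MACCS keys, 881-bit PubChem keys, ...) and scores
pairs with the Tanimoto coefficient

```
Tc(v_a, v_b) = |v_a ∩ v_b| / |v_a ∪ v_b|.
```

Predefined fingerprint dictionaries contain many bits that are (quasi)
linearly dependent on other bits — two keys firing on overlapping
substructures, a coarse key firing whenever one of several finer keys does.
Such *related* bits double-count structural evidence and can bias similarity
scores and screening outcomes. `fpentropy` identifies them without labels or
supervision, quantifies their per-pair effect on Tc, and tests whether
entropy-guided pruning differs from random pruning of the same size.

## The method

For an m×n compound-by-bit matrix **A**, the Gram matrix **AᵀA** has
eigenvalues λ₁ ≥ … ≥ λₙ ≥ 0. With qⱼ = λⱼ/Σλₖ, the eigenvalue-based entropy

```
H(A) = −(1/log n) Σⱼ qⱼ log qⱼ   ∈ [0, 1]
```

is 0 when one eigenvector carries all structure (rank 1) and 1 when all
contribute equally. The contribution of bit *i* is measured leave-one-out:
hᵢ = H(A[−i]) where A[−i] zeroes column *i* (keeping n columns). All hᵢ come
from the n×n Gram matrix alone, so cost scales with the number of bits, not
compounds. Bit *i* is **related** when its removal barely moves the entropy:

```
|hᵢ − h₀| < z · sqrt( Σⱼ (hⱼ − h₀)² / n ),
```

with reduced-level threshold z (typically 0.1–0.3). The complement — the
**reduced** set — is what you keep for similarity scoring. For a compound
pair, the related bits' shares of the union and intersection sets
(ε-guarded ratios) give the direction of their effect on Tc; a random-pruning
null (N same-size random bit subsets) and a two-sided exact binomial sign
test quantify significance.

## Worked example

Generate a 500×60 synthetic matrix with 40 independent bits plus 20 planted
exact linear dependencies (10 duplicates, 10 disjoint-support sums), then run
the pipeline:

```
$ fpentropy synth --m 500 --n-indep 40 --n-dup 10 --n-sum 10 \
      --density 0.4 --seed 11 --out synth.csv --truth truth.json
wrote 500x60 matrix to synth.csv (20 planted dependent bits)

$ fpentropy entropy --matrix synth.csv
H = 0.707600
rank = 40 (m=500, n=60)

$ fpentropy select --matrix synth.csv --z 0.1 --z 0.2 --z 0.3 --out selection.json
h0 = 0.707600
z=0.1: 5 related, 55 reduced (fraction retained 0.917)
z=0.2: 7 related, 53 reduced (fraction retained 0.883)
z=0.3: 12 related, 48 reduced (fraction retained 0.800)

$ fpentropy impact --matrix synth.csv --z 0.3 --no-filter
z=0.3: 12 related bits
fraction of pairs with |delta| > 0.05: 0.2600
fraction of pairs with |delta| > 0.1: 0.0374
fraction of pairs with |delta| > 0.2: 0.0004
sign test over top 30 pairs: p = 1.863e-09
```

Reading the output: the matrix's rank (40) equals its independent block —
the 20 planted bits add no rank. Entropy H = 0.708 reflects a spectrum
dominated by a common component. Selections are nested in z; at z = 0.3,
12 bits are flagged related and dropped. Removing them changes the Tanimoto
score by more than 0.05 for 26% of the 124,750 compound pairs, and among the
30 most-affected pairs the direction of change is unanimous (two-sided exact
binomial p ≈ 1.9×10⁻⁹) — related bits push scores systematically, unlike
random pruning, whose mean relative change is statistically indistinguishable
from zero (`fpentropy null`).

The same pipeline runs on real fingerprint files: any CSV/TSV with a header
of bit labels, a first column of compound ids, and 0/1 cells
(`fpentropy select --matrix maccs.csv --z 0.3`), with
`fpentropy.io.RDKitBackend` available to build 166-bit MACCS matrices from
SMILES.

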