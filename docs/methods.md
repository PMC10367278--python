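# Methods

`lsbucket` implements deterministic *locality-sensitive bucketing* (LSB)
functions for the edit distance on the space S_n = (Σⁿ, edit) of
length-n sequences over an ordered alphabet Σ of size m. An LSB function
f maps each sequence to a *set* of buckets (generalizing locality-sensitive
hashing, which maps to a single bucket) and is **(d₁, d₂)-sensitive** when

1. edit(s, t) ≤ d₁  ⇒  f(s) ∩ f(t) ≠ ∅, and
2. edit(s, t) ≥ d₂  ⇒  f(s) ∩ f(t) = ∅.

Such functions deterministically separate similar from dissimilar
sequences — the motivating use case is candidate-pair generation for long,
noisy reads, where exact k-mer matching loses sensitivity. Distances
strictly inside the gap (d₁, d₂) carry no guarantee; their behavior is
measured, never asserted.

## The constructions

### The optimal (1,2)-sensitive function (`lsb_onetwo`)

Process all of Σⁿ in the lexicographic order induced by the alphabet.
Every occurrence of the smallest symbol σ₁ at position i of a processed
sequence opens a fresh integer bucket holding the m sequences that agree
with it everywhere except position i. The result uses |B| = n·m^(n−1)
buckets, puts every sequence in exactly n of them, and both quantities
are provably minimal for a (1,2)-sensitive function.

Because ids are assigned in lexicographic order, the ids of one sequence
can be computed directly: with ν_i the base-m encoding of the suffix
starting at position i (the number of equal-length strings preceding it)
and

    μ_i(s) = ν_{i+1}(s)                                  if s_i = σ₁
    μ_i(s) = (rank(s_i)−1)(n−i) m^(n−i−1) + m^(n−i)      otherwise,

the total count(s) = Σ μ_i(s) is the number of σ₁ occurrences in all
sequences preceding s, and the n bucket ids follow from one O(n) pass
(`buckets_of`). The (rank − 1) coefficient in μ is forced by
back-substituting the underlying recursion and is pinned by an
enumeration oracle in the tests; with the coefficient off by one the
reference worked example cannot be reproduced. All id arithmetic uses
exact Python integers: ids reach n·m^(n−1), which overflows 64-bit
machine words well before n = 64 on DNA, and the tests exercise n = 64.
The exponential builder (`build_global`) is retained as the oracle and
refuses spaces with mⁿ > 10⁶.

### The (1,1)-guaranteed partition (`partition`)

Σⁿ splits into m blocks B_n^1 ⊔ … ⊔ B_n^m, built recursively: block i of
length n prepends the k-th symbol to block ((i + k − 2) mod m) + 1 of
length n − 1; the base case puts the p-th symbol alone in block p. Every
block has exactly m^(n−1) sequences (minimal) and is *(1,1)-guaranteed*:
any two sequences within edit distance 1 share a 1-neighbor inside the
block. Membership is O(n) without materializing anything: scanning
backwards, a first symbol of rank k maps the suffix index j to
(j + m + 1 − k) mod m. The bare formula leaves the mod-zero case
open; we map 0 to m, the only convention consistent with the printed
small-n partitions (e.g. TG must land in block 4 over DNA).

### Neighborhood schemes (`bucketing`)

For B ⊆ Σⁿ and radius r, f_B^r(s) = N^r(s) ∩ B, with buckets labeled by
sequences. The catalog:

| scheme        | B        | claimed (d₁, d₂)                     | f(s)                 |
|---------------|----------|--------------------------------------|----------------------|
| `lsb12`       | integers | (1, 2)                               | n ids                |
| `full-r`      | Σⁿ       | (2r−1, 2r+1) r odd; (2r, 2r+1) even  | (m−1)n+1 for r = 1   |
| `partition-r` | B_n^i    | (1,3) r=1; (3,5) r=2; (r, 2r+1) else | 1 or n for r = 1     |

The d₂ = 2r + 1 side is the triangle inequality; the d₁ side is what the
choice of B buys. For `partition-1` a block member occupies exactly one
bucket and a non-member exactly n; for `partition-r`, r ≥ 2, only the
upper bound |N^r(s)| is known and the verifier reports the observed
distribution without asserting tightness. The default partition block is
i = 1 (all blocks carry identical guarantees); it is configurable.

`verify_sensitivity` checks both defining properties over *every*
unordered pair of a small space, computing every assignment through the
real code path and every distance by dynamic programming — no theorem is
used to shortcut the check it is supposed to test. It refuses spaces
with mⁿ > 4096 sequences (the scan is quadratic).

## Neighborhood enumeration

N^r(s) ∩ Σⁿ is generated, not filtered: a length-preserving script of
cost ≤ r decomposes into a delete+insert composites plus b substitutions
with 2a + b ≤ r, so candidates are produced by applying composites a
times and a Hamming ball of radius r − 2a, vectorized with numpy gather
matrices. Every candidate satisfies edit ≤ r by construction (it was
produced by ≤ r edits); the risk is *missing* neighbors, so completeness
is verified in the tests against brute-force filtering of Σⁿ for n ≤ 4,
m ∈ {2, 4}, r ≤ 3. Duplicate candidates are tolerated and removed at the
set boundary; this keeps the n = 20, r = 2 assignment at ~1.4 ms.

A useful exact special case: within Σⁿ the radius-1 ball is the Hamming
ball of radius 1 (one length-preserving edit must be a substitution), so
two `full-1` assignments intersect iff Hamming(s, t) ≤ 2. `share_bucket`
uses this closed form for `full-1` only; its equivalence with label-set
intersection is itself under test.

## Edit-type categories

Two equal-length sequences at distance d are in category i if they can
be transformed into each other with i indel pairs and d − 2i
substitutions, but not with i − 1 pairs. We compute the minimal such i by
a DP over (prefix of s, prefix of t, deletions used) that yields, for
each i ≤ ⌊d/2⌋, the minimum number of substitutions in an alignment with
exactly i deletions and i insertions; the category is the first i whose
minimum is ≤ d − 2i. Category 0 coincides with Hamming distance = edit
distance. Categories are reported with `a+bx2` labels (a substitutions,
b indel pairs). An independent memoized recursion over scripts
cross-checks the DP in the tests.

## The simulator and what it establishes

`run_experiment` draws, for each distance d, random pairs of length-n
sequences at *exact* edit distance d and records collision frequencies
per scheme, overall and per category. Defaults state the reference
experiment at desk scale: n = 20 over DNA, d = 1..6, schemes `full-1`,
`partition-1`, `partition-2`, and 2,000 pairs per distance (reduced from
100,000; pass `pairs_per_d=100_000` for full scale — runtime scales
linearly, roughly 25 s at 2,000).

Pair generation is not prescribed anywhere, so it is explicit and
recorded: s is uniform over Σⁿ; the number of indel pairs b is uniform
on 0..⌊d/2⌋ (biasable via `indel_pair_weights`); d − 2b substitutions hit
distinct positions; each indel pair deletes and reinserts at random
positions; the proposal is accepted only when the DP confirms the
distance is exactly d (bounded rejection, default 10,000 rounds).

What a green run establishes: frequencies are exactly 1.0 for d ≤ d₁ and
exactly 0.0 for d ≥ d₂ — these are theorem consequences at any sample
size, and the acceptance test asserts them as hard equalities. What it
does not establish: frequencies strictly inside the gap depend on the
category mix of the proposal distribution, so gap values are only
qualitatively comparable across studies (e.g. the `full-1` gap at d = 2
splits exactly by category: 1.0 for two substitutions, 0.0 for a pure
indel pair). The generator also does not emulate real reads: no error
profiles, no shared genomic context, no reverse complements.

## Numerical and interface choices

- Positions are 1-based in prose, converted once at the code boundary;
  bucket ids are 1-based consecutive integers.
- Sequences from different alphabets never silently mix: every public
  entry point validates symbols eagerly and raises `AlphabetError`.
- FASTA windows are 0-based half-open `[offset, offset + n)`, forward
  strand only (the functions are not reverse-complement symmetric);
  lowercase is folded up; windows containing symbols outside the alphabet
  (e.g. N) are skipped and counted in the log.
- The simulator's TSV echoes its full configuration, including the seed,
  as a leading comment line; identical configuration implies
  byte-identical output.

## Known limitations

- Exhaustive verification and the explicit builders are exponential by
  nature and capped; guarantees at large n rest on the proofs plus the
  small-space exhaustive checks, not on direct enumeration.
- `share_bucket` for `full-r`, r ≥ 2, materializes both label sets; it is
  meant for small n or small r (the production schemes at scale are
  `lsb12` and `partition-r`).
- No (r,r)-guaranteed subsets smaller than B_n^i for r > 1 are attempted,
  and no probabilistic (LSH-family) layering is provided.
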