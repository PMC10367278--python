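"""The metric space: edit distance, neighborhoods, edit-type categories."""

import itertools

import numpy as np
import pytest
from Bio import Align
from hypothesis import given, settings
from hypothesis import strategies as st

from lsbucket import (
    BINARY,
    DNA,
    Alphabet,
    AlphabetError,
    edit_distance,
    edit_type_category,
    hamming_distance,
    neighborhood,
)


def _aligner():
    """Independent Levenshtein oracle via global alignment scoring."""
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = 0
    al.mismatch_score = -1
    al.open_gap_score = -1
    al.extend_gap_score = -1
    return al


def _random_seq(rng, alphabet, n):
    return "".join(rng.choice(alphabet.chars, size=n))


class TestAlphabet:
    def test_ranks_invert_positions(self, dna):
        assert [dna.rank(c) for c in "ACGT"] == [1, 2, 3, 4]
        assert [dna.char(k) for k in (1, 2, 3, 4)] == list("ACGT")

    @pytest.mark.parametrize("bad", ["A", "AA", "ACCA", ["AC", "G"]])
    def test_rejects_degenerate_alphabets(self, bad):
        with pytest.raises(AlphabetError):
            Alphabet(bad)

    def test_foreign_symbols_rejected(self, dna):
        with pytest.raises(AlphabetError):
            dna.validate("ACGN")
        with pytest.raises(AlphabetError):
            edit_distance("ACG", "ANG", dna)

    def test_encode_decode_roundtrip(self, dna):
        assert dna.decode(dna.encode("GATTACA")) == "GATTACA"

    def test_sequences_lexicographic(self, dna):
        seqs = list(dna.sequences(2))
        assert seqs == sorted(seqs)
        assert seqs[:5] == ["AA", "AC", "AG", "AT", "CA"]


class TestEditDistance:
    @pytest.mark.parametrize(
        "s, t, d",
        [
            ("AA", "AA", 0),
            ("AT", "CT", 1),
            ("AC", "CA", 2),  # no single edit maps AC to CA (checked vs full DP)
            ("ACGT", "CGTA", 2),
            ("", "ACG", 3),
            ("AAAA", "TTTT", 4),
        ],
    )
    def test_known_values(self, s, t, d):
        assert edit_distance(s, t) == d

    def test_metric_axioms_exhaustive_binary_s3(self, binary):
        seqs = list(binary.sequences(3))
        dist = {(s, t): edit_distance(s, t) for s in seqs for t in seqs}
        for s in seqs:
            assert dist[s, s] == 0
            for t in seqs:
                assert dist[s, t] == dist[t, s]
                assert (dist[s, t] == 0) == (s == t)
                for u in seqs:
                    assert dist[s, u] <= dist[s, t] + dist[t, u]

    def test_agrees_with_alignment_oracle(self, dna):
        al = _aligner()
        rng = np.random.default_rng(42)
        for _ in range(200):
            n1, n2 = rng.integers(1, 13, size=2)
            s = _random_seq(rng, dna, n1)
            t = _random_seq(rng, dna, n2)
            assert edit_distance(s, t) == -al.score(s, t)


class TestNeighborhood:
    def test_radius_zero_is_singleton(self, dna):
        assert neighborhood("AA", 0, dna) == {"AA"}

    def test_radius_one_size_formula(self, dna, binary):
        # |N^1(s)| = (m-1) n + 1
        assert len(neighborhood("AC", 1, dna)) == 3 * 2 + 1
        for alphabet, n in [(dna, 5), (binary, 7)]:
            rng = np.random.default_rng(n)
            s = _random_seq(rng, alphabet, n)
            assert len(neighborhood(s, 1, alphabet)) == (alphabet.m - 1) * n + 1

    @pytest.mark.parametrize(
        "alphabet, n, r",
        [(DNA, 2, 1), (DNA, 3, 2), (DNA, 4, 2), (BINARY, 4, 2), (BINARY, 3, 3)],
    )
    def test_equals_brute_force_filter(self, alphabet, n, r):
        for s in alphabet.sequences(n):
            brute = {t for t in alphabet.sequences(n) if edit_distance(s, t) <= r}
            assert neighborhood(s, r, alphabet) == brute

    def test_contains_self_and_members_in_range(self, dna):
        s = "GATTAC"
        nb = neighborhood(s, 2, dna)
        assert s in nb
        assert all(len(t) == len(s) and edit_distance(s, t) <= 2 for t in nb)


class TestEditTypeCategory:
    def test_pure_substitutions_are_category_zero(self):
        assert edit_type_category("AAAA", "ATTA") == 0

    def test_indel_pair_example(self):
        # d = 2 but Hamming distance 4: needs one indel pair
        assert edit_type_category("ACGT", "CGTA") == 1

    def test_identical_pair(self):
        assert edit_type_category("ACG", "ACG") == 0

    def test_category_zero_iff_hamming_equals_edit(self, dna):
        rng = np.random.default_rng(3)
        for _ in range(300):
            n = int(rng.integers(2, 10))
            s = _random_seq(rng, dna, n)
            t = _random_seq(rng, dna, n)
            d = edit_distance(s, t)
            cat = edit_type_category(s, t)
            assert 0 <= cat <= d // 2
            assert (cat == 0) == (hamming_distance(s, t) == d)

    def test_symmetric_in_arguments(self, dna):
        rng = np.random.default_rng(4)
        for _ in range(300):
            n = int(rng.integers(2, 9))
            s = _random_seq(rng, dna, n)
            t = _random_seq(rng, dna, n)
            assert edit_type_category(s, t) == edit_type_category(t, s)

    def test_matches_recursive_oracle(self, dna):
        # independent oracle: exhaustive recursion over scripts with exactly
        # (i ins, i del, d-2i subs), memoized, no shared code with the DP
        def min_subs(s, t, dels, inss, memo):
            key = (s, t, dels, inss)
            if key in memo:
                return memo[key]
            if dels == 0 and inss == 0:
                res = (
                    sum(a != b for a, b in zip(s, t))
                    if len(s) == len(t)
                    else 10**6
                )
            else:
                res = 10**6
                if s and dels:
                    res = min(res, min_subs(s[1:], t, dels - 1, inss, memo))
                if t and inss:
                    res = min(res, min_subs(s, t[1:], dels, inss - 1, memo))
                if s and t:
                    res = min(
                        res,
                        (s[0] != t[0]) + min_subs(s[1:], t[1:], dels, inss, memo),
                    )
            memo[key] = res
            return res

        def oracle(s, t):
            d = edit_distance(s, t)
            for i in range(d // 2 + 1):
                if min_subs(s, t, i, i, {}) <= d - 2 * i:
                    return i
            raise AssertionError("unreachable")

        rng = np.random.default_rng(5)
        for _ in range(150):
            n = int(rng.integers(2, 8))
            s = _random_seq(rng, dna, n)
            t = _random_seq(rng, dna, n)
            assert edit_type_category(s, t) == oracle(s, t)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    data=st.data(),
    n=st.integers(min_value=1, max_value=6),
    alphabet=st.sampled_from([DNA, BINARY]),
)
def test_neighborhood_properties(data, n, alphabet):
    """N^1 always contains s, has the closed-form size, and respects radius."""
    s = "".join(
        data.draw(st.sampled_from(alphabet.chars), label=f"pos{i}") for i in range(n)
    )
    nb = neighborhood(s, 1, alphabet)
    assert s in nb
    assert len(nb) == (alphabet.m - 1) * n + 1
    assert all(edit_distance(s, t) <= 1 for t in nb)
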