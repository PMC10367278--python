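"""The metric space of fixed-length sequences under the edit distance.

This module models :math:`S_n = (\\Sigma^n, \\mathrm{edit})`: an ordered
alphabet, unit-cost Levenshtein distance, enumeration of edit-distance
neighborhoods restricted to length-``n`` sequences, and the classification
of equal-length pairs by how many indel pairs an optimal-composition edit
script needs ("edit-type categories").

Conventions
-----------
* Alphabet symbols carry 1-based ranks ``1..m`` following their order; the
  first symbol (rank 1) plays a special role in the bucket constructions.
* Positions are 1-based in prose and docstrings; Python code converts at
  the boundary (``s[i-1]``) and nowhere else.
* Sequences are plain Python strings; every public function validates them
  against the alphabet it is given.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Iterator

import numpy as np

__all__ = [
    "Alphabet",
    "AlphabetError",
    "DNA",
    "BINARY",
    "EditPair",
    "edit_distance",
    "hamming_distance",
    "neighborhood",
    "edit_type_category",
]


class AlphabetError(ValueError):
    """A symbol or sequence is not valid over the given alphabet."""


class Alphabet:
    """An ordered alphabet ``sigma_1 < sigma_2 < ... < sigma_m``.

    The order fixes the lexicographic order on sequences and all index
    arithmetic used by the bucketing constructions. ``rank`` maps a symbol
    to its 1-based position and is the inverse of ``char``.

    Parameters
    ----------
    chars:
        Iterable of distinct single-character symbols, at least two.
    """

    __slots__ = ("chars", "_rank")

    def __init__(self, chars: Iterable[str]):
        chars = tuple(chars)
        if len(chars) < 2:
            raise AlphabetError("an alphabet needs at least two symbols")
        if any(not isinstance(c, str) or len(c) != 1 for c in chars):
            raise AlphabetError("alphabet symbols must be single characters")
        if len(set(chars)) != len(chars):
            raise AlphabetError("alphabet symbols must be distinct")
        self.chars = chars
        self._rank = {c: k + 1 for k, c in enumerate(chars)}

    @property
    def m(self) -> int:
        """Alphabet size ``m = |Sigma|``."""
        return len(self.chars)

    def rank(self, c: str) -> int:
        """1-based rank of symbol ``c``."""
        try:
            return self._rank[c]
        except KeyError:
            raise AlphabetError(
                f"symbol {c!r} is not in alphabet {''.join(self.chars)!r}"
            ) from None

    def char(self, k: int) -> str:
        """Symbol of 1-based rank ``k`` (inverse of :meth:`rank`)."""
        if not 1 <= k <= len(self.chars):
            raise AlphabetError(f"rank {k} out of range 1..{len(self.chars)}")
        return self.chars[k - 1]

    def validate(self, s: str) -> str:
        """Return ``s`` unchanged; raise :class:`AlphabetError` on foreign symbols."""
        for c in s:
            if c not in self._rank:
                raise AlphabetError(
                    f"symbol {c!r} in sequence {s!r} is not in alphabet "
                    f"{''.join(self.chars)!r}"
                )
        return s

    def encode(self, s: str) -> np.ndarray:
        """0-based rank array (dtype uint8) for ``s``."""
        return np.array([self._rank[c] - 1 for c in self.validate(s)], dtype=np.uint8)

    def decode(self, ranks0: Iterable[int]) -> str:
        """String for an iterable of 0-based ranks."""
        return "".join(self.chars[int(k)] for k in ranks0)

    def sequences(self, n: int) -> Iterator[str]:
        """All length-``n`` sequences in lexicographic order."""
        for tup in itertools.product(self.chars, repeat=n):
            yield "".join(tup)

    def __contains__(self, c: str) -> bool:
        return c in self._rank

    def __len__(self) -> int:
        return len(self.chars)

    def __iter__(self) -> Iterator[str]:
        return iter(self.chars)

    def __eq__(self, other) -> bool:
        return isinstance(other, Alphabet) and self.chars == other.chars

    def __hash__(self) -> int:
        return hash(self.chars)

    def __repr__(self) -> str:
        return f"Alphabet({''.join(self.chars)!r})"


#: The DNA alphabet in its conventional order A < C < G < T.
DNA = Alphabet("ACGT")

#: A two-letter alphabet, handy for exhaustive checks on larger n.
BINARY = Alphabet("01")


@dataclass(frozen=True)
class EditPair:
    """A pair of equal-length sequences with its edit distance.

    ``category`` is the edit-type category: the minimal number of indel
    pairs in a script realizing the distance (``None`` when not computed).
    """

    s: str
    t: str
    d: int
    category: int | None = None


def edit_distance(s: str, t: str, alphabet: Alphabet | None = None) -> int:
    """Unit-cost Levenshtein distance between ``s`` and ``t``.

    Substitution, insertion and deletion each cost 1. If ``alphabet`` is
    given, both sequences are validated against it first.
    """
    if alphabet is not None:
        alphabet.validate(s)
        alphabet.validate(t)
    if s == t:
        return 0
    if len(s) > len(t):
        s, t = t, s
    prev = list(range(len(s) + 1))
    for j, tc in enumerate(t, 1):
        cur = [j] + [0] * len(s)
        for i, sc in enumerate(s, 1):
            cur[i] = min(prev[i] + 1, cur[i - 1] + 1, prev[i - 1] + (sc != tc))
        prev = cur
    return prev[-1]


def hamming_distance(s: str, t: str) -> int:
    """Number of mismatching positions between equal-length sequences."""
    if len(s) != len(t):
        raise ValueError("hamming distance requires equal lengths")
    return sum(a != b for a, b in zip(s, t))


# ---------------------------------------------------------------------------
# Neighborhood enumeration.
#
# The r-neighborhood of s within Sigma^n is generated, not filtered: every
# length-preserving script of cost <= r decomposes into a indel pairs plus
# b substitutions with 2a + b <= r, so candidates are produced by applying
# single delete+insert composites a times and then a Hamming ball of radius
# r - 2a.  Each candidate trivially satisfies edit <= r (it was produced by
# at most r edits); completeness is checked against brute-force filtering
# of Sigma^n in the test suite.
# ---------------------------------------------------------------------------


@lru_cache(maxsize=None)
def _indel_gathers(n: int) -> tuple[np.ndarray, np.ndarray]:
    # Gd[p, j]: index into the original length-n row after deleting position p.
    # Gi[q, j]: index into a length-(n-1) row after inserting at position q;
    # the entry at j == q is a placeholder that callers overwrite.
    ar = np.arange(n)
    Gd = np.arange(n - 1)[None, :] + (np.arange(n - 1)[None, :] >= ar[:, None])
    Gi = np.arange(n)[None, :] - (np.arange(n)[None, :] >= ar[:, None])
    return Gd, Gi


def _one_indel_rows(base: np.ndarray, m: int) -> np.ndarray:
    """All rows reachable from ``base`` by one deletion plus one insertion."""
    n = base.size
    if n == 0:
        return base[None, :]
    if n == 1:
        return np.arange(m, dtype=base.dtype)[:, None]
    Gd, Gi = _indel_gathers(n)
    sdel = base[Gd]  # (n, n-1): deletion at each position p
    X = sdel[:, Gi]  # (n, n, n): [p, q, :] = insert placeholder at q
    Y = np.broadcast_to(X, (m, n, n, n)).copy()
    ar = np.arange(n)
    Y[:, :, ar, ar] = np.arange(m, dtype=base.dtype)[:, None, None]
    return Y.reshape(-1, n)


def _hamming_rows(base: np.ndarray, radius: int, m: int) -> np.ndarray:
    """All rows within Hamming distance ``radius`` of ``base`` (with dupes)."""
    n = base.size
    out = [base[None, :].copy()]
    if radius >= 1 and n >= 1:
        reps = np.repeat(np.arange(n), m - 1)
        rows = np.tile(base, (n * (m - 1), 1))
        deltas = np.tile(np.arange(1, m, dtype=np.int64), n)
        rows[np.arange(rows.shape[0]), reps] = (base[reps] + deltas) % m
        out.append(rows)
    if radius >= 2 and n >= 2:
        ii, jj = np.triu_indices(n, k=1)
        kcomb = (m - 1) * (m - 1)
        d1, d2 = np.meshgrid(np.arange(1, m), np.arange(1, m), indexing="ij")
        rows = np.tile(base, (ii.size * kcomb, 1))
        bigI = np.repeat(ii, kcomb)
        bigJ = np.repeat(jj, kcomb)
        D1 = np.tile(d1.ravel(), ii.size)
        D2 = np.tile(d2.ravel(), ii.size)
        ridx = np.arange(rows.shape[0])
        rows[ridx, bigI] = (base[bigI] + D1) % m
        rows[ridx, bigJ] = (base[bigJ] + D2) % m
        out.append(rows)
    # radii beyond 2 only arise in small exhaustive checks; plain loops do.
    for b in range(3, min(radius, n) + 1):
        rows = []
        for pos in itertools.combinations(range(n), b):
            for deltas in itertools.product(range(1, m), repeat=b):
                v = base.copy()
                for p, dlt in zip(pos, deltas):
                    v[p] = (int(v[p]) + dlt) % m
                rows.append(v)
        out.append(np.array(rows, dtype=base.dtype))
    return np.concatenate(out)


def _neighbor_rank_rows(
    base: np.ndarray, r: int, m: int, unique: bool = True
) -> np.ndarray:
    """Rank rows of the radius-``r`` neighborhood of ``base`` in ``Sigma^n``."""
    if r < 0:
        raise ValueError("radius must be non-negative")
    rows = []
    level = base[None, :]
    a = 0
    while True:
        b = r - 2 * a
        if b == 0:
            rows.append(level)
        else:
            for row in level:
                rows.append(_hamming_rows(row, b, m))
        if 2 * (a + 1) > r:
            break
        nxt = np.concatenate([_one_indel_rows(row, m) for row in level])
        a += 1
        # dedupe the level only when it will be expanded further (a duplicate
        # row would multiply the expansion work; plain duplicates are cheap)
        level = np.unique(nxt, axis=0) if r - 2 * a >= 1 else nxt
    out = np.concatenate(rows)
    return np.unique(out, axis=0) if unique else out


def neighborhood(s: str, r: int, alphabet: Alphabet) -> set[str]:
    """The ``r``-neighborhood of ``s`` within length-``n`` sequences.

    Returns exactly ``{t in Sigma^n : edit(s, t) <= r}``; always contains
    ``s``.  For ``r = 1`` this is the Hamming ball of radius one, of size
    ``(m - 1) n + 1``.
    """
    alphabet.validate(s)
    rows = _neighbor_rank_rows(alphabet.encode(s), r, alphabet.m)
    return {alphabet.decode(row) for row in rows}


def edit_type_category(s: str, t: str, alphabet: Alphabet | None = None) -> int:
    """Edit-type category of an equal-length pair.

    The category of a pair at edit distance ``d`` is the minimal ``i`` such
    that ``s`` can be transformed into ``t`` with exactly ``i`` insertions,
    ``i`` deletions and ``d - 2i`` substitutions.  Category 0 is equivalent
    to the Hamming distance equalling the edit distance.  Categories label
    pairs as ``a + b x 2`` with ``a = d - 2i`` substitutions and ``b = i``
    indel pairs.
    """
    if len(s) != len(t):
        raise ValueError("edit-type categories are defined for equal lengths")
    if alphabet is not None:
        alphabet.validate(s)
        alphabet.validate(t)
    d = edit_distance(s, t)
    if d == 0:
        return 0
    n = len(s)
    amax = d // 2
    INF = d + 1
    # f[a][j][k]: min substitutions aligning s[:j] to t[:k] using exactly a
    # deletions (insertions used so far = k - j + a, balanced at j = k = n).
    f = [[[INF] * (n + 1) for _ in range(n + 1)] for _ in range(amax + 1)]
    f[0][0][0] = 0
    for a in range(amax + 1):
        fa = f[a]
        fprev = f[a - 1] if a > 0 else None
        for j in range(n + 1):
            row = fa[j]
            for k in range(n + 1):
                best = row[k]
                if j and k:
                    cand = fa[j - 1][k - 1] + (s[j - 1] != t[k - 1])
                    if cand < best:
                        best = cand
                if j and fprev is not None:
                    cand = fprev[j - 1][k]
                    if cand < best:
                        best = cand
                if k:
                    cand = row[k - 1]
                    if cand < best:
                        best = cand
                row[k] = best
    for i in range(amax + 1):
        if f[i][n][n] <= d - 2 * i:
            return i
    raise RuntimeError(
        f"no balanced script found for a pair at distance {d}; this is a bug"
    )
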