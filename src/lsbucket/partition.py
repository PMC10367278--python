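"""The m-way partition of ``Sigma^n`` into minimum (1,1)-guaranteed subsets.

A subset ``B`` of ``Sigma^n`` is (1,1)-guaranteed when any two sequences
within edit distance 1 have a common 1-neighbor inside ``B``; the induced
bucketing function ``f_B^1(s) = N^1(s) ∩ B`` is then (1,3)-sensitive, and
``f_B^r`` is (r, 2r+1)-sensitive for every radius r.

The construction is recursive.  Base case: the i-th block of ``Sigma^1``
is the singleton holding the i-th symbol.  Step: block ``i`` of length
``n`` prepends symbol ``c_k`` to block ``(i + k - 2) mod m + 1`` of length
``n - 1`` (a rotation of block indices).  Each block has exactly
``m**(n-1)`` sequences, which is optimal.

Membership never requires materializing a block: scanning the sequence
backwards, the block index of ``c_k . suffix`` with suffix index ``j`` is
``(j + m + 1 - k) mod m``, where a result of 0 stands for ``m`` (the mod
convention is fixed by the explicit small-``n`` partitions).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lsb_onetwo import DEFAULT_CAP, _check_cap
from .seqspace import Alphabet

__all__ = [
    "PartitionSpec",
    "build_partition",
    "partition_index",
    "partition_index_batch",
    "is_member",
]


@dataclass(frozen=True)
class PartitionSpec:
    """Selects block ``index`` (1-based) of the partition of ``Sigma^n``."""

    n: int
    alphabet: Alphabet
    index: int

    def __post_init__(self):
        if not 1 <= self.index <= self.alphabet.m:
            raise ValueError(
                f"block index {self.index} out of range 1..{self.alphabet.m}"
            )
        if self.n < 1:
            raise ValueError("n must be >= 1")


def build_partition(
    n: int, alphabet: Alphabet, cap: int = DEFAULT_CAP
) -> list[frozenset[str]]:
    """Materialize all ``m`` blocks of the partition of ``Sigma^n``.

    Exponential in ``n``; exists as an oracle for small spaces (same cap
    policy as the explicit bucket-table builder).  Production paths use
    :func:`partition_index` instead.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    _check_cap(n, alphabet, cap)
    m = alphabet.m
    blocks: list[set[str]] = [{c} for c in alphabet.chars]
    for _ in range(n - 1):
        blocks = [
            {alphabet.chars[k] + x for k in range(m) for x in blocks[(i + k) % m]}
            for i in range(m)
        ]
    return [frozenset(b) for b in blocks]


def partition_index(s: str, alphabet: Alphabet) -> int:
    """1-based index of the partition block containing ``s``, in O(n).

    Backward scan: the last character's rank seeds the base case, then
    each earlier character of rank ``k`` maps the running suffix index
    ``j`` to ``(j + m + 1 - k) mod m`` with 0 standing for ``m``.
    """
    if not s:
        raise ValueError("n must be >= 1")
    alphabet.validate(s)
    m = alphabet.m
    j = alphabet.rank(s[-1])
    for c in s[-2::-1]:
        j = (j - alphabet.rank(c)) % m + 1
    return j


def partition_index_batch(rows: np.ndarray, m: int) -> np.ndarray:
    """Vectorized :func:`partition_index` over 0-based rank rows.

    ``rows`` has shape ``(N, n)`` with entries in ``0..m-1``; returns an
    ``(N,)`` array of 1-based block indices.
    """
    if rows.ndim != 2 or rows.shape[1] < 1:
        raise ValueError("rows must be a non-empty 2-D rank array")
    j0 = rows[:, -1].astype(np.int64)
    for i in range(rows.shape[1] - 2, -1, -1):
        j0 = (j0 - rows[:, i]) % m
    return j0 + 1


def is_member(s: str, spec: PartitionSpec) -> bool:
    """Whether ``s`` lies in the block selected by ``spec`` (no materialization)."""
    if len(s) != spec.n:
        raise ValueError(f"sequence length {len(s)} != spec.n = {spec.n}")
    return partition_index(s, spec.alphabet) == spec.index
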