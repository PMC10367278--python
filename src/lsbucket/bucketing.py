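"""Neighborhood bucketing schemes and the exhaustive sensitivity verifier.

A scheme names one row of the catalog of proved (d1, d2)-sensitive
bucketing functions:

==============  =====================  ===========================
scheme          buckets                claimed (d1, d2)
==============  =====================  ===========================
``lsb12``       integers               (1, 2)
``full-r``      all of ``Sigma^n``     (2r-1, 2r+1) for odd r,
                                       (2r, 2r+1) for even r
``partition-r`` one block ``B_n^i``    (1, 3) for r = 1,
                                       (3, 5) for r = 2,
                                       (r, 2r+1) for r > 2
==============  =====================  ===========================

For the neighborhood schemes the buckets are labeled by length-``n``
sequences and ``f_B^r(s) = N^r(s) ∩ B``; a pair collides when the two
label sets intersect.  ``verify_sensitivity`` checks both defining
properties of a claimed (d1, d2) pair over every sequence pair of a small
space, computing every bucket assignment for real (no theorem shortcuts),
and additionally records the empirical collision behavior at distances
inside the gap, which is category-dependent rather than guaranteed.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .lsb_onetwo import buckets_of
from .partition import partition_index, partition_index_batch
from .seqspace import Alphabet, _neighbor_rank_rows, edit_distance, hamming_distance

__all__ = [
    "SchemeSpec",
    "SensitivityReport",
    "make_scheme",
    "parse_scheme",
    "registry",
    "assign",
    "share_bucket",
    "verify_sensitivity",
]

#: Exhaustive verification refuses beyond this many sequences.
VERIFY_CAP = 4096


@dataclass(frozen=True)
class SchemeSpec:
    """One bucketing scheme with its claimed sensitivity pair.

    ``kind`` is ``"lsb12"``, ``"full"`` or ``"partition"``; ``r`` is the
    neighborhood radius (``None`` for ``lsb12``); ``index`` selects the
    partition block for ``partition`` schemes.
    """

    name: str
    kind: str
    r: int | None
    index: int | None
    d1: int
    d2: int

    def __post_init__(self):
        if self.d1 >= self.d2:
            raise ValueError("a sensitivity pair needs d1 < d2")


def make_scheme(kind: str, r: int | None = None, index: int = 1) -> SchemeSpec:
    """Build a :class:`SchemeSpec` with the claimed (d1, d2) of its row."""
    if kind == "lsb12":
        if r is not None:
            raise ValueError("the lsb12 scheme takes no radius")
        return SchemeSpec("lsb12", "lsb12", None, None, 1, 2)
    if kind == "full":
        if r is None or r < 0:
            raise ValueError("full-r needs a radius r >= 0")
        d1 = 2 * r - 1 if r % 2 else 2 * r
        return SchemeSpec(f"full-{r}", "full", r, None, d1, 2 * r + 1)
    if kind == "partition":
        if r is None or r < 1:
            raise ValueError("partition-r needs a radius r >= 1")
        if r == 1:
            d1 = 1
        elif r == 2:
            d1 = 3
        else:
            d1 = r
        return SchemeSpec(f"partition-{r}", "partition", r, index, d1, 2 * r + 1)
    raise ValueError(f"unknown scheme kind {kind!r}")


_SCHEME_RE = re.compile(r"^(lsb12|full|partition)(?:-(\d+))?$")


def parse_scheme(text: str, r: int | None = None, index: int = 1) -> SchemeSpec:
    """Parse ``"lsb12"``, ``"full-1"``, ``"partition-2"`` (or kind plus ``r``)."""
    mo = _SCHEME_RE.match(text.strip().lower())
    if mo is None:
        raise ValueError(f"unknown scheme {text!r}")
    kind, embedded = mo.group(1), mo.group(2)
    if embedded is not None:
        if r is not None and r != int(embedded):
            raise ValueError(f"conflicting radii in {text!r} and r={r}")
        r = int(embedded)
    if kind == "lsb12" and r is not None:
        raise ValueError("the lsb12 scheme takes no radius")
    return make_scheme(kind, r, index)


def registry(radii: tuple[int, ...] = (1, 2, 3), index: int = 1) -> list[SchemeSpec]:
    """The catalog rows instantiated for the given radii."""
    out = [make_scheme("lsb12")]
    out += [make_scheme("full", r) for r in radii]
    out += [make_scheme("partition", r, index) for r in radii]
    return out


def _assign_rank_rows(s: str, scheme: SchemeSpec, alphabet: Alphabet) -> np.ndarray:
    base = alphabet.encode(s)
    rows = _neighbor_rank_rows(base, scheme.r, alphabet.m, unique=False)
    if scheme.kind == "partition":
        rows = rows[partition_index_batch(rows, alphabet.m) == scheme.index]
    return rows


def _assign_bytes(s: str, scheme: SchemeSpec, alphabet: Alphabet) -> set[bytes]:
    """Bucket labels as raw rank bytes (fast path for collision tests)."""
    rows = np.ascontiguousarray(_assign_rank_rows(s, scheme, alphabet), dtype=np.uint8)
    n = rows.shape[1]
    buf = rows.tobytes()
    return {buf[k * n : (k + 1) * n] for k in range(rows.shape[0])}


def assign(s: str, scheme: SchemeSpec, alphabet: Alphabet) -> set[int] | set[str]:
    """Bucket labels of ``s`` under ``scheme``.

    Integer ids for ``lsb12``; length-``n`` sequence labels for the
    neighborhood schemes.  Partition blocks are never materialized: labels
    are kept iff their O(n) membership query selects the scheme's block.
    """
    if scheme.kind == "lsb12":
        return set(buckets_of(s, alphabet))
    rows = _assign_rank_rows(s, scheme, alphabet)
    return {alphabet.decode(row) for row in rows}


def share_bucket(s: str, t: str, scheme: SchemeSpec, alphabet: Alphabet) -> bool:
    """Whether ``s`` and ``t`` are assigned at least one common bucket."""
    if len(s) != len(t):
        raise ValueError("sequences must have equal length")
    if scheme.kind == "lsb12":
        return not set(buckets_of(s, alphabet)).isdisjoint(buckets_of(t, alphabet))
    if scheme.kind == "full" and scheme.r == 1:
        # The radius-1 ball within Sigma^n is exactly the Hamming ball of
        # radius 1 (a single length-preserving edit must be a substitution),
        # so the two balls intersect iff Hamming(s, t) <= 2.  This equals
        # the enumeration-based answer; the equivalence is tested.
        return hamming_distance(s, t) <= 2
    a = _assign_bytes(s, scheme, alphabet)
    b = _assign_bytes(t, scheme, alphabet)
    return not a.isdisjoint(b)


@dataclass
class SensitivityReport:
    """Outcome of exhaustively checking a scheme's claimed (d1, d2).

    The scheme passes iff both violation lists are empty.  ``gap_behavior``
    maps each distance strictly between d1 and d2 to ``(pairs, collisions)``
    — reported, never judged, since gap behavior is not guaranteed.
    """

    n: int
    alphabet: Alphabet
    scheme: SchemeSpec
    claimed_d1: int
    claimed_d2: int
    checked_pairs: int
    close_violations: list[tuple[str, str, int]]
    far_violations: list[tuple[str, str, int]]
    bucket_count: int
    per_seq_bucket_sizes: dict[int, int]
    gap_behavior: dict[int, tuple[int, int]] = field(default_factory=dict)

    @property
    def passed(self) -> bool:
        return not self.close_violations and not self.far_violations

    def summary(self) -> str:
        lines = [
            f"scheme {self.scheme.name} on |Sigma|={self.alphabet.m}, n={self.n}: "
            f"claimed ({self.claimed_d1}, {self.claimed_d2})-sensitive -> "
            f"{'PASS' if self.passed else 'FAIL'}",
            f"  pairs checked: {self.checked_pairs}",
            f"  |B| = {self.bucket_count}",
            f"  |f(s)| distribution: "
            + ", ".join(f"{k}: {v}" for k, v in sorted(self.per_seq_bucket_sizes.items())),
        ]
        for d, (pairs, coll) in sorted(self.gap_behavior.items()):
            lines.append(f"  gap d={d}: {coll}/{pairs} pairs collide")
        for label, viol in (
            ("close (edit <= d1, disjoint buckets)", self.close_violations),
            ("far (edit >= d2, shared bucket)", self.far_violations),
        ):
            if viol:
                s, t, d = viol[0]
                lines.append(
                    f"  {len(viol)} {label} violations, e.g. ({s}, {t}) at edit {d}"
                )
        return "\n".join(lines)


def verify_sensitivity(
    n: int,
    alphabet: Alphabet,
    scheme: SchemeSpec,
    claimed_d1: int | None = None,
    claimed_d2: int | None = None,
    cap: int = VERIFY_CAP,
) -> SensitivityReport:
    """Exhaustively verify a claimed (d1, d2) over every pair in ``Sigma^n``.

    Every bucket set is computed by the real assignment path and every
    pair's edit distance by dynamic programming; nothing is shortcut by
    the theorems under test.  Refuses when ``m**n`` exceeds ``cap``.
    """
    if alphabet.m**n > cap:
        raise ValueError(
            f"|Sigma|^n = {alphabet.m}^{n} exceeds the verification cap {cap}; "
            "lower n (the check enumerates all sequence pairs)"
        )
    d1 = scheme.d1 if claimed_d1 is None else claimed_d1
    d2 = scheme.d2 if claimed_d2 is None else claimed_d2
    if d1 >= d2:
        raise ValueError("need d1 < d2")
    seqs = list(alphabet.sequences(n))
    fmap = {s: assign(s, scheme, alphabet) for s in seqs}

    if scheme.kind == "lsb12":
        bucket_count = len({b for f in fmap.values() for b in f})
    elif scheme.kind == "full":
        bucket_count = alphabet.m**n
    else:
        bucket_count = sum(
            partition_index(s, alphabet) == scheme.index for s in seqs
        )

    close: list[tuple[str, str, int]] = []
    far: list[tuple[str, str, int]] = []
    gap: dict[int, list[int]] = {d: [0, 0] for d in range(d1 + 1, d2)}
    checked = 0
    for i, s in enumerate(seqs):
        fs = fmap[s]
        for t in seqs[i + 1 :]:
            checked += 1
            d = edit_distance(s, t)
            shares = not fs.isdisjoint(fmap[t])
            if d <= d1 and not shares:
                close.append((s, t, d))
            elif d >= d2 and shares:
                far.append((s, t, d))
            elif d1 < d < d2:
                gap[d][0] += 1
                gap[d][1] += shares
    return SensitivityReport(
        n=n,
        alphabet=alphabet,
        scheme=scheme,
        claimed_d1=d1,
        claimed_d2=d2,
        checked_pairs=checked,
        close_violations=close,
        far_violations=far,
        bucket_count=bucket_count,
        per_seq_bucket_sizes=dict(Counter(len(f) for f in fmap.values())),
        gap_behavior={d: (p, c) for d, (p, c) in gap.items()},
    )
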