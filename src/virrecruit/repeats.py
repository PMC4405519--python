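"""Maximal repeat detection (forward / reverse / palindromic) with an
expectation statistic.

Repeat relations, for occurrences ``s1 = s[p1:p1+l]`` and ``s2 = s[p2:p2+l]``:

* forward:      ``s2 == s1``
* reverse:      ``s2 == reverse(s1)``  (reversed, NOT complemented)
* palindromic:  ``s2 == reverse_complement(s1)``

A pair is *maximal* when extending both occurrences one position outward (in
the sense appropriate to the relation) breaks it.  Forward occurrences may
overlap (tandem repeats); reverse and palindromic occurrences must be
span-disjoint (``p1 + l ≤ p2``), matching the pairwise-occurrence model of the
statistic — extension stops at the disjointness boundary.

The expectation value of a maximal pair of length exactly ``l`` in a random
i.i.d. sequence of length ``n`` with per-position match probability ``p``
(default 1/4) is::

    E = (n² / 2) · p^l · (1 − p)²

the two ``(1 − p)`` factors accounting for the flanking mismatches that make
the pair maximal.  This statistic reproduces, to three significant figures,
every printed E-value of the repeat survey this package re-implements.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .seq_core import SequenceRecord, reverse_complement

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

REPEAT_TYPES = ("forward", "reverse", "palindromic")
_TYPE_CODE = {"forward": "F", "reverse": "R", "palindromic": "P"}


@dataclass(frozen=True)
class RepeatStatModel:
    """Null model for the expectation statistic: i.i.d. bases, match prob ``p``."""

    n: int
    p: float = 0.25

    def __post_init__(self) -> None:
        if not 0 < self.p < 1:
            raise ValueError("p must be in (0,1)")


@dataclass(frozen=True)
class RepeatHit:
    """A maximal repeat pair: type, length, the two 0-based starts, E-value."""

    repeat_type: str
    length: int
    pos1: int
    pos2: int
    evalue: float


def repeat_evalue(n: int, length: int, model: RepeatStatModel | None = None) -> float:
    """Expected number of maximal repeat pairs of length exactly ``length``
    in a random sequence of length ``n``:  E = (n²/2)·p^l·(1−p)²."""
    if not n >= length >= 1:
        raise ValueError("require n ≥ l ≥ 1")
    p = model.p if model is not None else 0.25
    return (n * n / 2.0) * (p ** length) * ((1.0 - p) ** 2)


def _base_eq(x: str, y: str) -> bool:
    # windows containing N never match (conservative)
    return x == y and x != "N"


def _comp_eq(x: str, y: str) -> bool:
    return x != "N" and y != "N" and _COMP.get(x) == y


def _extend_forward(s: str, i: int, j: int, l: int) -> tuple[int, int, int]:
    # relation: s[j+x] == s[i+x]; extend left (i-1,j-1) and right (i+l,j+l)
    n = len(s)
    while i > 0 and j > 0 and _base_eq(s[i - 1], s[j - 1]):
        i -= 1; j -= 1; l += 1
    while i + l < n and j + l < n and _base_eq(s[i + l], s[j + l]):
        l += 1
    return i, j, l


def _extend_mirror(s: str, i: int, j: int, l: int, eq) -> tuple[int, int, int]:
    # relation: s[j+x] corresponds to s[i+l-1-x]; growing occurrence 1 on the
    # right pairs with growing occurrence 2 on the left, and vice versa.
    # Disjointness i + l ≤ j is enforced during extension.
    n = len(s)
    while j - (i + l) >= 2 and eq(s[i + l], s[j - 1]):
        j -= 1; l += 1
    while i > 0 and j + l < n and eq(s[i - 1], s[j + l]):
        i -= 1; l += 1
    return i, j, l


def _seed_pairs_forward(s: str, m: int) -> Iterable[tuple[int, int]]:
    table: dict[str, list[int]] = {}
    for off in range(len(s) - m + 1):
        w = s[off : off + m]
        if "N" in w:
            continue
        table.setdefault(w, []).append(off)
    for positions in table.values():
        for a in range(len(positions)):
            for b in range(a + 1, len(positions)):
                yield positions[a], positions[b]


def _seed_pairs_vs(s: str, other_windows, m: int) -> Iterable[tuple[int, int]]:
    """Pairs (i, j) with window at i in s matching a transformed window at j."""
    table: dict[str, list[int]] = {}
    for off in range(len(s) - m + 1):
        w = s[off : off + m]
        if "N" in w:
            continue
        table.setdefault(w, []).append(off)
    for j, w in other_windows:
        for i in table.get(w, ()):
            yield i, j


def find_maximal_repeats(sequence: SequenceRecord | str, min_len: int = 13,
                         types: Sequence[str] = REPEAT_TYPES,
                         model: RepeatStatModel | None = None) -> list[RepeatHit]:
    """All maximal repeat pairs of length ≥ ``min_len``, each reported once
    with canonical ordering ``pos1 ≤ pos2`` and an attached E-value.

    Seeds of length ``min_len`` are hashed and extended to maximality; the
    result is defined (and tested) by equivalence with a brute-force
    enumeration over all position pairs.
    """
    if min_len < 8:
        raise ValueError("min_len must be ≥ 8")
    s = sequence if isinstance(sequence, str) else sequence.residues
    n = len(s)
    model = model or RepeatStatModel(n=n)
    found: set[tuple[str, int, int, int]] = set()
    if n >= min_len:
        m = min_len
        if "forward" in types:
            for i, j in _seed_pairs_forward(s, m):
                fi, fj, fl = _extend_forward(s, i, j, m)
                if fi != fj:
                    found.add(("forward", fl, min(fi, fj), max(fi, fj)))
        if "reverse" in types:
            # window at j matches reverse of window at i:
            # s[j:j+m] == reverse(s[i:i+m])  <=>  reversed-window table lookup
            rev_windows = []
            for j in range(n - m + 1):
                w = s[j : j + m][::-1]
                if "N" not in w:
                    rev_windows.append((j, w))
            for i, j in _seed_pairs_vs(s, rev_windows, m):
                if i == j:
                    continue
                ci, cj = _canon(i, j)
                if not ci + m <= cj:
                    continue
                fi, fj, fl = _extend_mirror(s, ci, cj, m, _base_eq)
                found.add(("reverse", fl, fi, fj))
        if "palindromic" in types:
            comp_windows = []
            for j in range(n - m + 1):
                w = reverse_complement(s[j : j + m])
                if "N" not in w:
                    comp_windows.append((j, w))
            for i, j in _seed_pairs_vs(s, comp_windows, m):
                if i == j:
                    continue
                ci, cj = _canon(i, j)
                if not ci + m <= cj:
                    continue
                fi, fj, fl = _extend_mirror(s, ci, cj, m, _comp_eq)
                found.add(("palindromic", fl, fi, fj))
    hits = [
        RepeatHit(t, l, p1, p2, repeat_evalue(n, l, model))
        for (t, l, p1, p2) in found
        if l >= min_len
    ]
    hits.sort(key=lambda h: (h.pos1, h.pos2, h.repeat_type))
    return hits


def _canon(i: int, j: int) -> tuple[int, int]:
    return (i, j) if i <= j else (j, i)


def brute_force_maximal_repeats(sequence: str, min_len: int,
                                types: Sequence[str] = REPEAT_TYPES) -> list[RepeatHit]:
    """Exhaustive oracle: test every position pair, extend, keep maximal pairs.

    Quartic-ish time; for testing only.  Implements the same self-overlap
    policy as :func:`find_maximal_repeats`.
    """
    s = sequence
    n = len(s)
    model = RepeatStatModel(n=n)
    found: set[tuple[str, int, int, int]] = set()
    for i in range(n - min_len + 1):
        for j in range(i + 1, n - min_len + 1):
            if "forward" in types and all(
                _base_eq(s[i + x], s[j + x]) for x in range(min_len)
            ):
                fi, fj, fl = _extend_forward(s, i, j, min_len)
                found.add(("forward", fl, min(fi, fj), max(fi, fj)))
            if i + min_len <= j:
                if "reverse" in types and all(
                    _base_eq(s[j + x], s[i + min_len - 1 - x]) for x in range(min_len)
                ):
                    fi, fj, fl = _extend_mirror(s, i, j, min_len, _base_eq)
                    found.add(("reverse", fl, fi, fj))
                if "palindromic" in types and all(
                    _comp_eq(s[i + min_len - 1 - x], s[j + x]) for x in range(min_len)
                ):
                    fi, fj, fl = _extend_mirror(s, i, j, min_len, _comp_eq)
                    found.add(("palindromic", fl, fi, fj))
    hits = [RepeatHit(t, l, p1, p2, repeat_evalue(n, l, model))
            for (t, l, p1, p2) in found if l >= min_len]
    hits.sort(key=lambda h: (h.pos1, h.pos2, h.repeat_type))
    return hits


def repeat_report(contigs: Sequence[SequenceRecord], min_len: int = 13,
                  evalue_max: float = 0.1,
                  types: Sequence[str] = ("reverse", "palindromic"),
                  path: str | Path | None = None) -> list[tuple]:
    """Per-contig repeat survey, filtered at ``evalue_max`` (default 0.1).

    Returns rows ``(contig_id, type_code, length, start1, start2, evalue)``;
    when ``path`` is given the rows are also written as a TSV shaped like the
    repeat table of the survey this package mirrors (R = reverse,
    P = palindromic, F = forward; E-values to 3 significant figures).
    """
    rows: list[tuple] = []
    for contig in contigs:
        for hit in find_maximal_repeats(contig, min_len=min_len, types=types):
            if hit.evalue <= evalue_max:
                rows.append((contig.id, _TYPE_CODE[hit.repeat_type], hit.length,
                             hit.pos1, hit.pos2, hit.evalue))
    rows.sort(key=lambda r: (r[0], -r[2], r[3], r[4], r[1]))
    if path is not None:
        with Path(path).open("w") as fh:
            fh.write("contig\trepeat_type\tlength_nt\tstart1\tstart2\tevalue\n")
            for cid, code, length, p1, p2, ev in rows:
                fh.write(f"{cid}\t{code}\t{length}\t{p1 + 1}\t{p2 + 1}\t{ev:.2e}\n")
    return rows
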