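"""Internal pairwise-alignment kernels.

Two routes coexist deliberately:

* :func:`smith_waterman_dp` — an affine-gap local-alignment dynamic program
  written here, with fully specified tie-breaking.  It is the independent
  oracle the heuristic search is tested against.
* Biopython's ``PairwiseAligner`` (C implementation) behind
  :func:`local_align`, :func:`overlap_align` and :func:`global_align` — the
  fast kernels used inside seed-and-extend recruitment, reference mapping and
  pairwise-identity computation.

Gap convention throughout: a gap of length L costs ``gap_open`` for its first
column and ``gap_extend`` for each further column.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import Align


@dataclass(frozen=True)
class PathAlignment:
    """A pairwise alignment path with scores and per-column bookkeeping."""

    score: float
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    aligned_a: str
    aligned_b: str

    @property
    def columns(self) -> int:
        return len(self.aligned_a)

    @property
    def identities(self) -> int:
        return sum(1 for x, y in zip(self.aligned_a, self.aligned_b) if x == y and x != "-")

    @property
    def identity(self) -> float:
        return self.identities / self.columns if self.columns else 0.0


def _make_aligner(match: float, mismatch: float, gap_open: float, gap_extend: float,
                  mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    if mode == "local":
        aligner.mode = "local"
    elif mode == "global":
        aligner.mode = "global"
    elif mode == "overlap":
        # end-gap-free global: gaps at either end of either sequence are free
        aligner.mode = "global"
        try:
            aligner.end_insertion_score = 0.0
            aligner.end_deletion_score = 0.0
        except AttributeError:  # older Biopython
            aligner.target_end_gap_score = 0.0
            aligner.query_end_gap_score = 0.0
    else:  # pragma: no cover - internal misuse
        raise ValueError(mode)
    return aligner


def _path_from_biopython(aln, a: str, b: str, trim_end_gaps: bool) -> PathAlignment:
    """Convert a Bio.Align.Alignment into a PathAlignment, optionally trimming end gaps."""
    blocks_a, blocks_b = aln.aligned  # arrays of (start, end) pairs, one per matched block
    if len(blocks_a) == 0:
        return PathAlignment(float(aln.score), 0, 0, 0, 0, "", "")
    a_start, a_end = int(blocks_a[0][0]), int(blocks_a[-1][1])
    b_start, b_end = int(blocks_b[0][0]), int(blocks_b[-1][1])
    parts_a: list[str] = []
    parts_b: list[str] = []
    prev_a, prev_b = a_start, b_start
    for (sa, ea), (sb, eb) in zip(blocks_a, blocks_b):
        sa, ea, sb, eb = int(sa), int(ea), int(sb), int(eb)
        if sa > prev_a:  # gap in b
            parts_a.append(a[prev_a:sa])
            parts_b.append("-" * (sa - prev_a))
        if sb > prev_b:  # gap in a
            parts_a.append("-" * (sb - prev_b))
            parts_b.append(b[prev_b:sb])
        parts_a.append(a[sa:ea])
        parts_b.append(b[sb:eb])
        prev_a, prev_b = ea, eb
    return PathAlignment(
        float(aln.score), a_start, a_end, b_start, b_end,
        "".join(parts_a), "".join(parts_b),
    )


def local_align(a: str, b: str, match: float, mismatch: float,
                gap_open: float, gap_extend: float) -> PathAlignment:
    """Best local alignment of ``a`` vs ``b`` (first optimal path of the C aligner)."""
    aligner = _make_aligner(match, mismatch, gap_open, gap_extend, "local")
    alns = aligner.align(a, b)
    if float(alns.score) <= 0:
        return PathAlignment(0.0, 0, 0, 0, 0, "", "")
    return _path_from_biopython(alns[0], a, b, trim_end_gaps=True)


def overlap_align(a: str, b: str, match: float, mismatch: float,
                  gap_open: float, gap_extend: float) -> PathAlignment:
    """End-gap-free global alignment; coordinates/columns exclude the end gaps."""
    aligner = _make_aligner(match, mismatch, gap_open, gap_extend, "overlap")
    alns = aligner.align(a, b)
    return _path_from_biopython(alns[0], a, b, trim_end_gaps=True)


def global_align(a: str, b: str, match: float, mismatch: float,
                 gap_open: float, gap_extend: float) -> PathAlignment:
    aligner = _make_aligner(match, mismatch, gap_open, gap_extend, "global")
    alns = aligner.align(a, b)
    return _path_from_biopython(alns[0], a, b, trim_end_gaps=True)


def glocal_align(a: str, b: str, match: float, mismatch: float,
                 gap_open: float, gap_extend: float) -> PathAlignment:
    """Semi-global alignment: the shorter sequence aligns end to end, end gaps
    of the longer sequence are free.  Prevents the degenerate short-overlap
    optimum of a fully end-gap-free alignment on unrelated sequences."""
    swap = len(b) > len(a)
    t, q = (b, a) if swap else (a, b)
    aligner = _make_aligner(match, mismatch, gap_open, gap_extend, "global")
    try:
        aligner.end_deletion_score = 0.0  # free end gaps on the target (longer)
    except AttributeError:  # pragma: no cover - older Biopython
        aligner.query_end_gap_score = 0.0
    path = _path_from_biopython(aligner.align(t, q)[0], t, q, trim_end_gaps=True)
    if swap:
        path = PathAlignment(path.score, path.b_start, path.b_end,
                             path.a_start, path.a_end,
                             path.aligned_b, path.aligned_a)
    return path


def smith_waterman_dp(a: str, b: str, match: float, mismatch: float,
                      gap_open: float, gap_extend: float) -> PathAlignment:
    """Affine-gap Smith–Waterman with deterministic tie-breaking.

    Ties on the optimal score are broken by smallest ``b`` (subject) start,
    then smallest ``a`` (query) start.  Quadratic time and memory; intended
    for oracle duty and small inputs.
    """
    m, n = len(a), len(b)
    if m == 0 or n == 0:
        raise ValueError("sequences must be non-empty")
    NEG = -1e18
    H = np.zeros((m + 1, n + 1))
    E = np.full((m + 1, n + 1), NEG)  # gap in a (consumes b)
    F = np.full((m + 1, n + 1), NEG)  # gap in b (consumes a)
    for i in range(1, m + 1):
        ai = a[i - 1]
        for j in range(1, n + 1):
            E[i, j] = max(H[i, j - 1] + gap_open, E[i, j - 1] + gap_extend)
            F[i, j] = max(H[i - 1, j] + gap_open, F[i - 1, j] + gap_extend)
            sub = match if ai == b[j - 1] else mismatch
            H[i, j] = max(0.0, H[i - 1, j - 1] + sub, E[i, j], F[i, j])
    best = H.max()
    if best <= 0:
        return PathAlignment(0.0, 0, 0, 0, 0, "", "")

    def _traceback(i: int, j: int) -> PathAlignment:
        al_a: list[str] = []
        al_b: list[str] = []
        end_i, end_j = i, j
        state = "H"
        while i > 0 and j > 0:
            if state == "H":
                if H[i, j] == 0:
                    break
                sub = match if a[i - 1] == b[j - 1] else mismatch
                if H[i, j] == H[i - 1, j - 1] + sub:
                    al_a.append(a[i - 1]); al_b.append(b[j - 1])
                    i -= 1; j -= 1
                elif H[i, j] == E[i, j]:
                    state = "E"
                else:
                    state = "F"
            elif state == "E":
                al_a.append("-"); al_b.append(b[j - 1])
                if E[i, j] == H[i, j - 1] + gap_open:
                    state = "H"
                j -= 1
            else:  # F
                al_a.append(a[i - 1]); al_b.append("-")
                if F[i, j] == H[i - 1, j] + gap_open:
                    state = "H"
                i -= 1
        return PathAlignment(float(best), i, end_i, j, end_j,
                             "".join(reversed(al_a)), "".join(reversed(al_b)))

    # candidate endpoints with the optimal score; pick by (b_start, a_start)
    ends = np.argwhere(H == best)
    paths = [_traceback(int(i), int(j)) for i, j in ends]
    paths.sort(key=lambda p: (p.b_start, p.a_start, p.b_end, p.a_end))
    return paths[0]
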