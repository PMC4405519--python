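"""Reference-guided and greedy de novo assembly, iterated to convergence.

The central operation is :func:`iterate_recruit_assemble`: recruit reads by
homology to a seed sequence, drop reads of DNA-sample origin, place the kept
reads on the current reference, call a majority consensus, extend the
reference with agreeing read overhangs at both ends, and repeat with the
extended consensus as the new query — until the assembly stops extending.

Consensus calling is column-wise majority in reference coordinate space;
gaps count as a symbol (a winning gap deletes the column) and read insertions
supported by a majority of covering reads are spliced in.  This resolves
454-style homopolymer errors wherever depth ≥ 3.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import _align
from .seq_core import ReadRecord, SequenceRecord, gc_content, reverse_complement
from .recruit import (
    KmerIndex, RecruitConfig, ScoringScheme, build_index, filter_by_origin,
    seed_extend_search, _cluster_seeds,
)

logger = logging.getLogger(__name__)


@dataclass
class ReadPlacement:
    """One read placed on a reference/consensus.

    ``aligned`` holds one character per covered reference column (``-`` for a
    deletion in the read); ``insertions`` maps a reference column to read
    bases inserted immediately before it.  ``left_tail``/``right_tail`` are
    unaligned read ends (reference-oriented), used for end extension.
    """

    read_id: str
    offset: int
    strand: str
    aligned: str
    insertions: dict[int, str] = field(default_factory=dict)
    left_tail: str = ""
    right_tail: str = ""

    @property
    def end(self) -> int:
        return self.offset + len(self.aligned)


@dataclass
class Contig:
    """Consensus sequence plus the read layout and per-column depth."""

    id: str
    consensus: str
    placements: list[ReadPlacement]
    depth: np.ndarray

    def __len__(self) -> int:
        return len(self.consensus)

    def record(self) -> SequenceRecord:
        return SequenceRecord(id=self.id, residues=self.consensus)


@dataclass
class AssemblyStats:
    """Per-contig summary: the columns of a metagenomic-assembly report table."""

    contig_id: str
    length_nt: int
    n_reads: int
    identical_sites: int
    mean_pairwise_identity_pct: float
    coverage_mean: float
    coverage_min: int
    coverage_max: int
    gc_pct: float


@dataclass
class IterationRecord:
    iteration: int
    reads_recruited: int
    reads_kept: int
    consensus_length: int
    ext5: int
    ext3: int


@dataclass
class IterateConfig:
    """Knobs of the recruit→assemble loop."""

    min_identity: float = 0.9
    min_overlap: int = 20
    min_end_depth: int = 2
    min_gain: int = 1
    max_iterations: int = 20
    min_aligned: int = 30
    band: int = 16
    map_k: int = 11


_SYMBOLS = "ACGTN-"
_SYM_IDX = {s: i for i, s in enumerate(_SYMBOLS)}


# ---------------------------------------------------------------------------
# read placement


def _reference_kmer_table(ref: str, k: int) -> dict[str, list[int]]:
    table: dict[str, list[int]] = {}
    for off in range(len(ref) - k + 1):
        w = ref[off : off + k]
        if "N" not in w:
            table.setdefault(w, []).append(off)
    return table


def _placement_from_path(read_id: str, strand: str, rseq: str,
                         path: _align.PathAlignment, ref_offset: int) -> ReadPlacement:
    aligned_cols: list[str] = []
    insertions: dict[int, str] = {}
    ref_col = ref_offset + path.b_start
    pending_ins: list[str] = []
    for ra, rb in zip(path.aligned_a, path.aligned_b):
        if rb == "-":  # insertion in read relative to reference
            pending_ins.append(ra)
        else:
            if pending_ins:
                insertions[ref_col] = "".join(pending_ins)
                pending_ins = []
            aligned_cols.append(ra)  # may be '-' (deletion in read)
            ref_col += 1
    # trailing insertion is treated as part of the right tail
    right_tail = ("".join(pending_ins)) + rseq[path.a_end :]
    return ReadPlacement(
        read_id=read_id, offset=ref_offset + path.b_start, strand=strand,
        aligned="".join(aligned_cols), insertions=insertions,
        left_tail=rseq[: path.a_start], right_tail=right_tail,
    )


def map_to_reference(reads: Sequence[ReadRecord | SequenceRecord],
                     reference: SequenceRecord | str,
                     scoring: ScoringScheme | None = None,
                     min_identity: float = 0.9,
                     config: IterateConfig | None = None) -> tuple[list[ReadPlacement], list[str]]:
    """Place each read at its best seeded position on either strand.

    A read is placed when its end-gap-free alignment identity over the aligned
    region is ≥ ``min_identity`` and covers at least ``config.min_aligned``
    columns; reads may overhang the reference ends (the overhang is retained
    as a tail).  Returns (placements, unplaced read ids).
    """
    scoring = scoring or ScoringScheme()
    cfg = config or IterateConfig(min_identity=min_identity)
    ref = reference.residues if isinstance(reference, SequenceRecord) else reference
    if not ref:
        raise ValueError("reference must be non-empty")
    k = cfg.map_k
    table = _reference_kmer_table(ref, k)
    placements: list[ReadPlacement] = []
    unplaced: list[str] = []
    for read in reads:
        best: tuple[float, str, _align.PathAlignment, int, str] | None = None
        for strand in "+-":
            rseq = read.residues if strand == "+" else reverse_complement(read.residues)
            seeds = []
            for off in range(len(rseq) - k + 1):
                for refpos in table.get(rseq[off : off + k], ()):
                    seeds.append((refpos, off))
            if not seeds:
                continue
            _, dmin, dmax = _cluster_seeds(seeds, cfg.band)
            wstart = max(0, dmin - cfg.band)
            wend = min(len(ref), dmax + len(rseq) + cfg.band)
            path = _align.overlap_align(rseq, ref[wstart:wend], scoring.match,
                                        scoring.mismatch, scoring.gap_open, scoring.gap_extend)
            if best is None or path.score > best[0]:
                best = (path.score, strand, path, wstart, rseq)
        if best is None:
            unplaced.append(read.id)
            continue
        _, strand, path, wstart, rseq = best
        if path.columns < cfg.min_aligned or path.identity < min_identity:
            unplaced.append(read.id)
            continue
        placements.append(_placement_from_path(read.id, strand, rseq, path, wstart))
    placements.sort(key=lambda p: (p.offset, p.read_id))
    return placements, unplaced


# ---------------------------------------------------------------------------
# consensus


def call_consensus(placements: Sequence[ReadPlacement],
                   reference: SequenceRecord | str | None = None,
                   reference_length: int | None = None,
                   ) -> tuple[str, np.ndarray, list[ReadPlacement]]:
    """Column-wise majority consensus over placed reads.

    Per reference column the majority symbol among covering reads wins (gap is
    a symbol; a winning gap deletes the column); ties go to the reference base
    when available, else to the lexicographically smallest symbol.  Columns
    with zero coverage inside the span take the reference base.  Insertions
    carried by more than half of the covering reads are spliced in.

    Returns (consensus, per-consensus-column depth, placements re-projected
    into consensus coordinates).
    """
    if not placements:
        raise ValueError("at least one placement required")
    refseq = reference.residues if isinstance(reference, SequenceRecord) else reference
    ref_len = reference_length if reference_length is not None else len(refseq)
    counts = np.zeros((ref_len, len(_SYMBOLS)), dtype=np.int32)
    ins_counts: dict[int, Counter] = {}
    for p in placements:
        for i, ch in enumerate(p.aligned):
            counts[p.offset + i, _SYM_IDX.get(ch, _SYM_IDX["N"])] += 1
        for col, ins in p.insertions.items():
            ins_counts.setdefault(col, Counter())[ins] += 1
    cov = counts.sum(axis=1)

    out_cols: list[tuple[str, int, str]] = []  # (kind 'col'|'ins', ref col, residue(s))
    for col in range(ref_len):
        if col in ins_counts and cov[col] > 0:
            ins, n_ins = sorted(ins_counts[col].items(), key=lambda kv: (-kv[1], kv[0]))[0]
            if 2 * n_ins > cov[col]:
                out_cols.append(("ins", col, ins))
        if cov[col] == 0:
            out_cols.append(("col", col, refseq[col] if refseq else "N"))
            continue
        cmax = counts[col].max()
        winners = [s for s, i in _SYM_IDX.items() if counts[col][i] == cmax]
        if len(winners) > 1 and refseq and refseq[col] in winners:
            winner = refseq[col]
        else:
            winner = min(winners)
        if winner == "-":
            continue  # majority gap deletes the column
        out_cols.append(("col", col, winner))

    consensus_parts: list[str] = []
    for kind, col, res in out_cols:
        consensus_parts.append(res)
    consensus = "".join(consensus_parts)

    # project placements and depth into consensus coordinates
    projected: list[ReadPlacement] = []
    depth = np.zeros(len(consensus), dtype=np.int32)
    # output index of each emitted unit (insertions may span several residues)
    for p in placements:
        chars: list[str] = []
        start_out: int | None = None
        out_pos = 0
        for kind, col, res in out_cols:
            width = len(res)
            if kind == "col":
                if p.offset <= col < p.end:
                    ch = p.aligned[col - p.offset]
                    if start_out is None:
                        start_out = out_pos
                    chars.append(ch)
            else:  # insertion before column col
                covers = p.offset < col <= p.end - 1
                if covers:
                    own = p.insertions.get(col, "")
                    own = (own + "-" * width)[:width]
                    if start_out is None:
                        start_out = out_pos
                    chars.append(own)
            out_pos += width
        aligned = "".join(chars).strip("-")
        if not aligned or start_out is None:
            continue
        full = "".join(chars)
        lead = len(full) - len(full.lstrip("-"))
        proj = ReadPlacement(
            read_id=p.read_id, offset=start_out + lead, strand=p.strand,
            aligned=aligned, insertions={}, left_tail=p.left_tail, right_tail=p.right_tail,
        )
        projected.append(proj)
    # depth: number of placements covering the column (gap or base)
    for proj in projected:
        depth[proj.offset : proj.offset + len(proj.aligned)] += 1
    projected.sort(key=lambda p: (p.offset, p.read_id))
    return consensus, depth, projected


# ---------------------------------------------------------------------------
# end extension


def _extend_one_end(tails: list[str], min_end_depth: int) -> str:
    """Majority-call successive overhang columns while depth ≥ min_end_depth.

    ``tails`` are overhang strings oriented away from the contig (first
    character is adjacent to the contig end).
    """
    ext: list[str] = []
    col = 0
    while True:
        bases = [t[col] for t in tails if len(t) > col]
        if len(bases) < min_end_depth:
            break
        c = Counter(bases)
        top = sorted(c.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
        ext.append(top)
        col += 1
    return "".join(ext)


def extend_reference(contig: Contig, min_end_depth: int = 2,
                     end_margin: int = 2) -> tuple[Contig, int, int]:
    """Extend the consensus with majority-called read overhangs at both ends.

    Only reads whose alignment reaches within ``end_margin`` columns of a
    contig end contribute their tail on that side; a column is appended while
    ≥ ``min_end_depth`` tails cover it.  Returns (contig, 5' extension nt,
    3' extension nt).
    """
    L = len(contig.consensus)
    left_tails = [p.left_tail[::-1] for p in contig.placements
                  if p.left_tail and p.offset <= end_margin]
    right_tails = [p.right_tail for p in contig.placements
                   if p.right_tail and p.end >= L - end_margin]
    ext5 = _extend_one_end(left_tails, min_end_depth)[::-1]
    ext3 = _extend_one_end(right_tails, min_end_depth)
    if not ext5 and not ext3:
        return contig, 0, 0
    new_consensus = ext5 + contig.consensus + ext3
    shift = len(ext5)
    new_placements = [
        ReadPlacement(p.read_id, p.offset + shift, p.strand, p.aligned,
                      dict(p.insertions), p.left_tail, p.right_tail)
        for p in contig.placements
    ]
    new_depth = np.zeros(len(new_consensus), dtype=np.int32)
    new_depth[shift : shift + L] = contig.depth
    # overhang columns get their tail depth
    for i in range(len(ext5)):
        new_depth[len(ext5) - 1 - i] = sum(1 for t in left_tails if len(t) > i)
    for i in range(len(ext3)):
        new_depth[shift + L + i] = sum(1 for t in right_tails if len(t) > i)
    return (Contig(contig.id, new_consensus, new_placements, new_depth),
            len(ext5), len(ext3))


# ---------------------------------------------------------------------------
# iterative recruitment + assembly (the convergence loop)


def iterate_recruit_assemble(seed_sequence: SequenceRecord,
                             read_db: Sequence[ReadRecord] | KmerIndex,
                             manifest: Mapping[str, tuple[str, str]],
                             scoring: ScoringScheme | None = None,
                             recruit_config: RecruitConfig | None = None,
                             config: IterateConfig | None = None,
                             ) -> tuple[Contig, list[IterationRecord]]:
    """Recruit → origin-filter → place → consensus → extend, repeated until the
    assembled sequence stops extending.

    Terminates when the length gain of an iteration falls below
    ``config.min_gain`` (with a stable consensus) or after
    ``config.max_iterations``; reported lengths are non-decreasing (an
    iteration that would shrink the consensus returns the previous contig).
    """
    scoring = scoring or ScoringScheme()
    rcfg = recruit_config or RecruitConfig()
    cfg = config or IterateConfig()
    index = read_db if isinstance(read_db, KmerIndex) else build_index(read_db, rcfg.k)
    ref = SequenceRecord(id=seed_sequence.id, residues=seed_sequence.residues)
    log: list[IterationRecord] = []
    best_contig: Contig | None = None
    prev_len = len(ref.residues)
    for it in range(1, cfg.max_iterations + 1):
        hits = seed_extend_search(ref, index, scoring, rcfg)
        recruited_ids = sorted({h.subject_id for h in hits})
        recruited = [index.by_id[rid] for rid in recruited_ids]
        kept, n_removed, _ = filter_by_origin(recruited, manifest)
        placements, unplaced = map_to_reference(kept, ref, scoring,
                                                cfg.min_identity, cfg)
        if not placements:
            if best_contig is None:
                logger.warning("no reads recruited/placed at iteration 1: "
                               "returning the seed sequence unchanged")
                empty = Contig(seed_sequence.id, seed_sequence.residues, [],
                               np.zeros(len(seed_sequence.residues), dtype=np.int32))
                log.append(IterationRecord(it, len(recruited), len(kept),
                                           len(seed_sequence.residues), 0, 0))
                return empty, log
            break
        consensus, depth, projected = call_consensus(placements, reference=ref)
        contig = Contig(seed_sequence.id, consensus, projected, depth)
        contig, e5, e3 = extend_reference(contig, cfg.min_end_depth)
        new_len = len(contig.consensus)
        if new_len < prev_len and best_contig is not None:
            break  # never let the reported assembly shrink
        log.append(IterationRecord(it, len(recruited), len(kept), new_len, e5, e3))
        converged = (best_contig is not None
                     and new_len - prev_len < cfg.min_gain
                     and contig.consensus == ref.residues)
        best_contig = contig
        ref = SequenceRecord(id=seed_sequence.id, residues=contig.consensus)
        prev_len = new_len
        if converged:
            break
    assert best_contig is not None
    return best_contig, log


# ---------------------------------------------------------------------------
# greedy de novo assembly


def _merge_pair(a: str, b: str, path: _align.PathAlignment) -> str:
    """Merge two sequences along their end-gap-free overlap (a's base wins ties)."""
    merged: list[str] = []
    merged.append(a[: path.a_start] if path.a_start >= path.b_start else b[: path.b_start])
    for ca, cb in zip(path.aligned_a, path.aligned_b):
        merged.append(ca if ca != "-" else cb)
    tail_a = a[path.a_end :]
    tail_b = b[path.b_end :]
    merged.append(tail_a if len(tail_a) >= len(tail_b) else tail_b)
    return "".join(merged)


def denovo_assemble(reads: Sequence[ReadRecord],
                    min_overlap: int = 20, min_identity: float = 0.9,
                    scoring: ScoringScheme | None = None,
                    k: int = 16) -> list[Contig]:
    """Greedy overlap-layout-consensus assembly.

    Best-scoring qualifying overlap first (ties by lexicographic id pair),
    candidate pairs pre-filtered by a shared ``k``-mer in either orientation;
    after each merge, overlaps are recomputed against the merged sequence.
    Singleton reads come back as 1-read contigs.  Each final contig's layout
    and consensus are produced by re-placing its member reads.
    """
    if min_overlap < 20 or min_identity < 0.9:
        raise ValueError("require min_overlap ≥ 20 and min_identity ≥ 0.9")
    scoring = scoring or ScoringScheme()
    if not reads:
        return []
    seqs: dict[str, str] = {r.id: r.residues for r in reads}
    members: dict[str, list[str]] = {r.id: [r.id] for r in reads}
    reads_by_id = {r.id: r for r in reads}

    def kmer_set(s: str) -> set[str]:
        return {s[i : i + k] for i in range(len(s) - k + 1) if "N" not in s[i : i + k]}

    kmers = {rid: kmer_set(s) | kmer_set(reverse_complement(s)) for rid, s in seqs.items()}

    def overlap(x: str, y: str) -> tuple[float, str, _align.PathAlignment] | None:
        best = None
        for orient in "+-":
            ys = seqs[y] if orient == "+" else reverse_complement(seqs[y])
            path = _align.overlap_align(seqs[x], ys, scoring.match, scoring.mismatch,
                                        scoring.gap_open, scoring.gap_extend)
            if path.columns < min_overlap or path.identity < min_identity:
                continue
            if best is None or path.score > best[0]:
                best = (path.score, orient, path)
        return best

    pair_scores: dict[tuple[str, str], tuple[float, str, _align.PathAlignment]] = {}
    ids = sorted(seqs)
    for i, x in enumerate(ids):
        for y in ids[i + 1 :]:
            if kmers[x] & kmers[y]:
                ov = overlap(x, y)
                if ov:
                    pair_scores[(x, y)] = ov

    counter = 0
    while pair_scores:
        (x, y), (score, orient, path) = sorted(
            pair_scores.items(), key=lambda kv: (-kv[1][0], kv[0]))[0]
        ys = seqs[y] if orient == "+" else reverse_complement(seqs[y])
        merged_seq = _merge_pair(seqs[x], ys, path)
        new_id = f"_merge{counter:04d}"
        counter += 1
        for pair in [p for p in pair_scores if x in p or y in p]:
            del pair_scores[pair]
        del seqs[x], seqs[y]
        seqs[new_id] = merged_seq
        members[new_id] = members.pop(x) + members.pop(y)
        kmers[new_id] = kmer_set(merged_seq) | kmer_set(reverse_complement(merged_seq))
        for other in sorted(seqs):
            if other == new_id:
                continue
            if kmers[new_id] & kmers[other]:
                a, b = sorted((new_id, other))
                ov = overlap(a, b)
                if ov:
                    pair_scores[(a, b)] = ov

    contigs: list[Contig] = []
    for n, cid in enumerate(sorted(seqs), start=1):
        member_reads = [reads_by_id[rid] for rid in members[cid]]
        name = f"contig{n}"
        if len(member_reads) == 1:
            r = member_reads[0]
            contigs.append(Contig(name, r.residues,
                                  [ReadPlacement(r.id, 0, "+", r.residues)],
                                  np.ones(len(r.residues), dtype=np.int32)))
            continue
        placements, _ = map_to_reference(member_reads, seqs[cid], scoring,
                                         min_identity)
        consensus, depth, projected = call_consensus(placements, reference=seqs[cid])
        contigs.append(Contig(name, consensus, projected, depth))
    contigs.sort(key=lambda c: (-len(c.consensus), c.id))
    return contigs


# ---------------------------------------------------------------------------
# Table-1-style statistics


def compute_stats(contig: Contig) -> AssemblyStats:
    """Assembly summary statistics for one contig.

    ``identical_sites``: covered columns where all covering reads agree.
    ``mean_pairwise_identity_pct``: mean, over columns with depth ≥ 2, of the
    fraction of agreeing read pairs at the column.  Coverage statistics are
    over all consensus columns; G+C is computed from the consensus.
    """
    if not contig.placements:
        raise ValueError("contig has no placements")
    L = len(contig.consensus)
    counts = np.zeros((L, len(_SYMBOLS)), dtype=np.int64)
    for p in contig.placements:
        for i, ch in enumerate(p.aligned):
            counts[p.offset + i, _SYM_IDX.get(ch, _SYM_IDX["N"])] += 1
    depth = counts.sum(axis=1)
    covered = depth >= 1
    identical = int(np.sum((counts.max(axis=1) == depth) & covered))
    multi = depth >= 2
    agree_pairs = (counts * (counts - 1) // 2).sum(axis=1)
    total_pairs = depth * (depth - 1) // 2
    with np.errstate(invalid="ignore", divide="ignore"):
        col_identity = np.where(multi, agree_pairs / np.maximum(total_pairs, 1), np.nan)
    mean_pairwise = float(np.nanmean(np.where(multi, col_identity, np.nan)) * 100) \
        if multi.any() else 100.0
    return AssemblyStats(
        contig_id=contig.id,
        length_nt=L,
        n_reads=len(contig.placements),
        identical_sites=identical,
        mean_pairwise_identity_pct=mean_pairwise,
        coverage_mean=float(depth.mean()),
        coverage_min=int(depth.min()),
        coverage_max=int(depth.max()),
        gc_pct=100.0 * gc_content(contig.consensus),
    )


def write_stats_tsv(stats: Sequence[AssemblyStats], path: str | Path) -> None:
    """TSV mirroring the columns of the assembly-report table (G+C to 1 dp)."""
    with Path(path).open("w") as fh:
        fh.write("contig\tlength_nt\tn_reads\tidentical_sites\t"
                 "pairwise_identity_pct\tcoverage_mean\tcoverage_min\t"
                 "coverage_max\tgc_pct\n")
        for s in stats:
            fh.write(f"{s.contig_id}\t{s.length_nt}\t{s.n_reads}\t{s.identical_sites}\t"
                     f"{s.mean_pairwise_identity_pct:.1f}\t{s.coverage_mean:.1f}\t"
                     f"{s.coverage_min}\t{s.coverage_max}\t{s.gc_pct:.1f}\n")


def write_iteration_log_tsv(log: Sequence[IterationRecord], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("iteration\treads_recruited\treads_kept\tconsensus_length\text5\text3\n")
        for rec in log:
            fh.write(f"{rec.iteration}\t{rec.reads_recruited}\t{rec.reads_kept}\t"
                     f"{rec.consensus_length}\t{rec.ext5}\t{rec.ext3}\n")


def write_placements_tsv(contigs: Sequence[Contig], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("read_id\tcontig_id\toffset\tstrand\taligned_length\n")
        for c in contigs:
            for p in c.placements:
                fh.write(f"{p.read_id}\t{c.id}\t{p.offset}\t{p.strand}\t{len(p.aligned)}\n")
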