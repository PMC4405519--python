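"""Homology-based read recruitment and pairwise identity.

This module is the stand-in for the BLASTN/TBLASTX searches that recruit
metagenomic reads to a viral query sequence: a seed-and-extend heuristic over
an exact k-mer index, scored with affine gaps, with significance assessed by
Karlin–Altschul E-values (``E = K·m·n·exp(−λS)``).  The recruitment threshold
defaults to E < 1e-5, the cutoff used for read recruitment throughout the
workflow this package implements.

Also here: filtering recruited reads by nucleic-acid origin (RNA-sample reads
are kept; reads positively identified as coming from DNA samples are removed)
and semi-global pairwise identity with the 50–70 / 70–90 / 90–100 % similarity
bands used to summarise between-genome divergence.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio.Align import substitution_matrices
from Bio.Seq import Seq
from scipy.optimize import brentq

from . import _align
from .seq_core import ReadRecord, SequenceRecord, reverse_complement

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScoringScheme:
    """Affine-gap nucleotide scoring.

    Defaults are the BLASTN defaults (+2/−3, gap open −5, extend −2); a gap of
    length L costs ``gap_open + (L−1)·gap_extend``.
    """

    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2

    def __post_init__(self) -> None:
        if self.match <= 0 or self.mismatch >= 0 or self.gap_open >= 0 or self.gap_extend >= 0:
            raise ValueError("match must be > 0; mismatch/gap_open/gap_extend < 0")


@dataclass(frozen=True)
class KarlinAltschulParams:
    """λ, K and the search-space sizes behind ``E = K·m·n·exp(−λS)``."""

    lam: float
    K: float
    search_space_m: int
    search_space_n: int

    def evalue(self, score: float) -> float:
        return self.K * self.search_space_m * self.search_space_n * math.exp(-self.lam * score)


@dataclass
class AlignmentHit:
    """A scored local alignment between a query and a subject read."""

    query_id: str
    subject_id: str
    query_span: tuple[int, int]
    subject_span: tuple[int, int]
    strand: str
    score: float
    identities: int
    aligned_columns: int
    evalue: float | None = None

    @property
    def identity_pct(self) -> float:
        return 100.0 * self.identities / self.aligned_columns if self.aligned_columns else 0.0


@dataclass(frozen=True)
class RecruitConfig:
    """Seed-and-extend parameters; ``evalue_max`` is the recruitment threshold."""

    k: int = 9
    evalue_max: float = 1e-5
    mode: str = "nucleotide"
    min_seed_hits: int = 1
    band: int = 16  # half-width of the extension window around the seed diagonal
    K_nucleotide: float = 0.41  # tabulated gapped K for +2/-3, gap 5/2
    K_protein: float = 0.041

    def __post_init__(self) -> None:
        # k = 4 admits the exhaustive-seeding regime where the heuristic
        # provably matches full Smith–Waterman on short sequences
        if not 4 <= self.k <= 16:
            raise ValueError("k must be in [4, 16]")
        if self.evalue_max <= 0:
            raise ValueError("evalue_max must be > 0")
        if self.mode not in {"nucleotide", "translated"}:
            raise ValueError("mode must be nucleotide or translated")


UNIFORM_FREQS = {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25}


def solve_lambda(scoring: ScoringScheme | Mapping[tuple[str, str], float],
                 base_freqs: Mapping[str, float] | None = None) -> float:
    """Positive root λ of ``Σ_ij p_i p_j exp(λ s_ij) = 1``.

    Works for a nucleotide match/mismatch scheme or for an arbitrary
    residue-pair score mapping (protein matrices).  Raises ``ValueError`` when
    the expected pairwise score is non-negative (no valid λ exists).
    """
    if isinstance(scoring, ScoringScheme):
        freqs = dict(base_freqs or UNIFORM_FREQS)
        letters = sorted(freqs)
        pairs = [
            (freqs[x] * freqs[y], scoring.match if x == y else scoring.mismatch)
            for x in letters for y in letters
        ]
    else:
        freqs = dict(base_freqs or {})
        if not freqs:
            raise ValueError("base_freqs required for matrix scoring")
        pairs = [
            (freqs[x] * freqs[y], scoring[(x, y)])
            for x in freqs for y in freqs
        ]
    expected = sum(p * s for p, s in pairs)
    if expected >= 0:
        raise ValueError(f"expected pairwise score {expected:.3f} ≥ 0: no valid lambda")

    def f(lam: float) -> float:
        return sum(p * math.exp(lam * s) for p, s in pairs) - 1.0

    hi = 1.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e3:  # pragma: no cover - pathological scoring
            raise RuntimeError("failed to bracket lambda")
    lam = brentq(f, 1e-9, hi, xtol=1e-12)
    assert abs(f(lam)) < 1e-10
    return float(lam)


# ---------------------------------------------------------------------------
# k-mer index and seed-and-extend search


class KmerIndex:
    """Exact k-mer index over the forward strand of a read set."""

    def __init__(self, reads: Sequence[ReadRecord | SequenceRecord], k: int):
        self.k = k
        self.reads = list(reads)
        self.by_id = {r.id: r for r in self.reads}
        if len(self.by_id) != len(self.reads):
            raise ValueError("duplicate read ids in index")
        self.total_length = sum(len(r.residues) for r in self.reads)
        self._table: dict[str, list[tuple[int, int]]] = {}
        for idx, read in enumerate(self.reads):
            seq = read.residues
            for off in range(len(seq) - k + 1):
                kmer = seq[off : off + k]
                if "N" in kmer:
                    continue
                self._table.setdefault(kmer, []).append((idx, off))

    def lookup(self, kmer: str) -> list[tuple[int, int]]:
        return self._table.get(kmer, ())


def build_index(reads: Sequence[ReadRecord | SequenceRecord], k: int = 9) -> KmerIndex:
    """Build the exact k-mer index used by :func:`seed_extend_search`."""
    return KmerIndex(reads, k)


def _cluster_seeds(seeds: list[tuple[int, int]], band: int) -> tuple[int, int, int]:
    """Group seeds by diagonal; return (n_seeds, diag_min, diag_max) of the largest cluster."""
    return _seed_clusters(seeds, band)[0]


def _seed_clusters(seeds: list[tuple[int, int]], band: int,
                   ) -> list[tuple[int, int, int]]:
    """Disjoint diagonal clusters (n_seeds, diag_min, diag_max), largest first."""
    diags = sorted(qpos - off for qpos, off in seeds)
    clusters: list[tuple[int, int, int]] = []
    start = 0
    for i in range(1, len(diags) + 1):
        if i == len(diags) or diags[i] - diags[i - 1] > 2 * band:
            clusters.append((i - start, diags[start], diags[i - 1]))
            start = i
    clusters.sort(key=lambda c: (-c[0], c[1]))
    return clusters


def _search_one_strand(qseq: str, index: KmerIndex, scoring: ScoringScheme,
                       config: RecruitConfig) -> dict[int, _align.PathAlignment]:
    """Best windowed local alignment per read for one query orientation."""
    k = index.k
    seeds_by_read: dict[int, list[tuple[int, int]]] = {}
    for qpos in range(len(qseq) - k + 1):
        kmer = qseq[qpos : qpos + k]
        if "N" in kmer:
            continue
        for ridx, off in index.lookup(kmer):
            seeds_by_read.setdefault(ridx, []).append((qpos, off))
    results: dict[int, _align.PathAlignment] = {}
    for ridx, seeds in seeds_by_read.items():
        if len(seeds) < config.min_seed_hits:
            continue
        read = index.reads[ridx]
        rlen = len(read.residues)
        best: _align.PathAlignment | None = None
        # a chance seed can outnumber the true diagonal: extend the top few
        # clusters and keep the best-scoring alignment
        for _, dmin, dmax in _seed_clusters(seeds, config.band)[:3]:
            wstart = max(0, dmin - config.band)
            wend = min(len(qseq), dmax + rlen + config.band)
            path = _align.local_align(qseq[wstart:wend], read.residues,
                                      scoring.match, scoring.mismatch,
                                      scoring.gap_open, scoring.gap_extend)
            if path.columns == 0:
                continue
            shifted = _align.PathAlignment(
                path.score, path.a_start + wstart, path.a_end + wstart,
                path.b_start, path.b_end, path.aligned_a, path.aligned_b,
            )
            if best is None or shifted.score > best.score:
                best = shifted
        if best is not None:
            results[ridx] = best
    return results


def seed_extend_search(query: SequenceRecord, index: KmerIndex,
                       scoring: ScoringScheme | None = None,
                       config: RecruitConfig | None = None,
                       base_freqs: Mapping[str, float] | None = None) -> list[AlignmentHit]:
    """Recruit reads similar to ``query``: seeded, banded, gapped local alignment.

    Both query orientations are searched against the forward-strand index.
    One best hit per (read, strand) is kept; hits with E-value above
    ``config.evalue_max`` are discarded.  Output is sorted by E-value
    ascending, then subject id, then strand — deterministic for fixed inputs.
    """
    scoring = scoring or ScoringScheme()
    config = config or RecruitConfig()
    lam = solve_lambda(scoring, base_freqs)
    m = len(query.residues)
    ka = KarlinAltschulParams(lam, config.K_nucleotide, m, max(index.total_length, 1))
    hits: list[AlignmentHit] = []
    for strand in "+-":
        qseq = query.residues if strand == "+" else reverse_complement(query.residues)
        for ridx, path in _search_one_strand(qseq, index, scoring, config).items():
            ev = ka.evalue(path.score)
            if ev > config.evalue_max:
                continue
            if strand == "+":
                qspan = (path.a_start, path.a_end)
            else:  # map reverse-oriented query coordinates back to forward
                qspan = (m - path.a_end, m - path.a_start)
            hits.append(AlignmentHit(
                query_id=query.id, subject_id=index.reads[ridx].id,
                query_span=qspan, subject_span=(path.b_start, path.b_end),
                strand=strand, score=path.score, identities=path.identities,
                aligned_columns=path.columns, evalue=ev,
            ))
    hits.sort(key=lambda h: (h.evalue, h.subject_id, h.strand))
    return hits


# ---------------------------------------------------------------------------
# translated (six-frame) search


def _six_frames(seq: str) -> list[tuple[int, str]]:
    frames = []
    rc = reverse_complement(seq)
    for f in range(3):
        for base, src in ((0, seq), (3, rc)):
            sub = src[f : f + 3 * ((len(src) - f) // 3)]
            frames.append((f + base, str(Seq(sub).translate())))
    return frames


def _blosum62_dict() -> tuple[dict[tuple[str, str], float], dict[str, float]]:
    mat = substitution_matrices.load("BLOSUM62")
    letters = "ARNDCQEGHILKMFPSTWYV"  # standard residues only, for lambda
    scores = {(x, y): float(mat[x, y]) for x in letters for y in letters}
    freqs = {x: 1.0 / len(letters) for x in letters}
    return scores, freqs


def translated_search(query: SequenceRecord,
                      reads: Sequence[ReadRecord | SequenceRecord] | KmerIndex,
                      config: RecruitConfig | None = None) -> list[AlignmentHit]:
    """Six-frame × six-frame translated comparison (TBLASTX-like).

    Query and read are translated in all six frames and compared with BLOSUM62
    protein local alignment (gap −11/−1); stops translate to ``*`` which
    BLOSUM62 scores negatively against everything.  E-values use a
    protein-space λ and translated search-space sizes (nt length / 3).
    Best hit per read is reported, filtered at ``config.evalue_max``.
    """
    config = config or RecruitConfig(mode="translated")
    read_list = list(reads.reads) if isinstance(reads, KmerIndex) else list(reads)
    scores, freqs = _blosum62_dict()
    lam = solve_lambda(scores, freqs)
    total_nt = sum(len(r.residues) for r in read_list)
    ka = KarlinAltschulParams(lam, config.K_protein,
                              max(len(query.residues) // 3, 1), max(total_nt // 3, 1))
    qframes = _six_frames(query.residues)
    hits: list[AlignmentHit] = []
    for read in read_list:
        best: tuple[float, _align.PathAlignment, int, int] | None = None
        for qf, qprot in qframes:
            if not qprot:
                continue
            for rf, rprot in _six_frames(read.residues):
                if not rprot:
                    continue
                path = _protein_local(qprot, rprot)
                if best is None or path.score > best[0]:
                    best = (path.score, path, qf, rf)
        if best is None:
            continue
        score, path, qf, rf = best
        ev = ka.evalue(score)
        if ev > config.evalue_max:
            continue
        hits.append(AlignmentHit(
            query_id=query.id, subject_id=read.id,
            query_span=(path.a_start, path.a_end), subject_span=(path.b_start, path.b_end),
            strand="+" if rf < 3 else "-",
            score=score, identities=path.identities, aligned_columns=path.columns,
            evalue=ev,
        ))
    hits.sort(key=lambda h: (h.evalue, h.subject_id))
    return hits


def _protein_local(a: str, b: str) -> _align.PathAlignment:
    from Bio import Align
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    aligner.mode = "local"
    alns = aligner.align(a, b)
    if float(alns.score) <= 0:
        return _align.PathAlignment(0.0, 0, 0, 0, 0, "", "")
    return _align._path_from_biopython(alns[0], a, b, trim_end_gaps=True)


# ---------------------------------------------------------------------------
# origin filtering and global identity


def filter_by_origin(reads: Sequence[ReadRecord], manifest: Mapping[str, tuple[str, str]],
                     keep: Iterable[str] = ("RNA",)) -> tuple[list[ReadRecord], int, list[str]]:
    """Remove reads whose sample origin is known and not in ``keep``.

    Reads of unknown origin (absent from the manifest, or tagged unknown) are
    kept with a warning: only reads positively identified as coming from a
    non-kept (DNA) sample are removed.  Returns (kept, removed count,
    removed ids).
    """
    keep_set = set(keep)
    kept: list[ReadRecord] = []
    removed: list[str] = []
    n_unknown = 0
    for read in reads:
        sample_id, origin = manifest.get(read.id, ("", "unknown"))
        if origin == "unknown":
            n_unknown += 1
            kept.append(read)
        elif origin in keep_set:
            kept.append(read)
        else:
            removed.append(read.id)
    if n_unknown:
        logger.warning("%d read(s) of unknown origin kept", n_unknown)
    logger.info("origin filter: %d kept, %d removed", len(kept), len(removed))
    return kept, len(removed), removed


SIMILARITY_BANDS = ((90.0, "90-100"), (70.0, "70-90"), (50.0, "50-70"))


def band_label(identity_pct: float) -> str:
    """Similarity band: 90–100 / 70–90 / 50–70 / <50 %."""
    for lo, label in SIMILARITY_BANDS:
        if identity_pct >= lo:
            return label
    return "<50"


#: scoring used for identity banding: stiff gaps stop the aligner from
#: harvesting chance matches between unrelated sequences
IDENTITY_SCORING = ScoringScheme(match=2, mismatch=-3, gap_open=-10, gap_extend=-6)


def global_align_identity(a: SequenceRecord | str, b: SequenceRecord | str,
                          scoring: ScoringScheme | None = None) -> tuple[float, int, str]:
    """End-gap-free global identity between two sequences.

    Semi-global: the shorter sequence aligns end to end and end gaps of the
    longer are free (and excluded from the column count).  Identity =
    identical columns / aligned columns.  Returns (percent identity, aligned
    columns, similarity band label).
    """
    scoring = scoring or IDENTITY_SCORING
    sa = a if isinstance(a, str) else a.residues
    sb = b if isinstance(b, str) else b.residues
    if not sa or not sb:
        raise ValueError("sequences must be non-empty")
    path = _align.glocal_align(sa, sb, scoring.match, scoring.mismatch,
                               scoring.gap_open, scoring.gap_extend)
    pct = 100.0 * path.identities / path.columns if path.columns else 0.0
    return pct, path.columns, band_label(pct)


def smith_waterman(a: SequenceRecord | str, b: SequenceRecord | str,
                   scoring: ScoringScheme | None = None) -> AlignmentHit:
    """Optimal affine-gap local alignment (the oracle for the heuristic search).

    Tie-breaking: highest score, then smallest subject start, then smallest
    query start.
    """
    scoring = scoring or ScoringScheme()
    sa = a if isinstance(a, str) else a.residues
    sb = b if isinstance(b, str) else b.residues
    path = _align.smith_waterman_dp(sa, sb, scoring.match, scoring.mismatch,
                                    scoring.gap_open, scoring.gap_extend)
    return AlignmentHit(
        query_id=getattr(a, "id", "query"), subject_id=getattr(b, "id", "subject"),
        query_span=(path.a_start, path.a_end), subject_span=(path.b_start, path.b_end),
        strand="+", score=path.score, identities=path.identities,
        aligned_columns=path.columns, evalue=None,
    )


def write_hits_tsv(hits: Sequence[AlignmentHit], path: str | Path) -> None:
    """12-column tabular hit output (1-based inclusive coordinates in the file)."""
    with Path(path).open("w") as fh:
        for h in hits:
            mismatches = h.aligned_columns - h.identities
            qs, qe = h.query_span
            ss, se = h.subject_span
            fh.write("\t".join(map(str, [
                h.query_id, h.subject_id, f"{h.identity_pct:.2f}", h.aligned_columns,
                mismatches, 0, qs + 1, qe, ss + 1, se,
                f"{h.evalue:.2e}" if h.evalue is not None else "NA", f"{h.score:.1f}",
            ])) + "\n")
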