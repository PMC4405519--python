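"""Core sequence types, standard-format I/O and elementary sequence statistics.

Every sequence handled by this package lives on the 5-letter alphabet
``{A, C, G, T, N}``.  IUPAC ambiguity codes encountered on input are collapsed
to ``N`` (with a logged warning) so that every downstream kernel — alignment,
repeat detection, consensus calling, likelihood — only ever sees five symbols.

Coordinates are 0-based, half-open everywhere in memory; rendered report
tables use 1-based inclusive coordinates.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: codons recognised as translation stops
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
START_CODON = "ATG"


class FormatError(ValueError):
    """Malformed input file (FASTA/FASTQ/manifest)."""


class UndefinedValueError(ValueError):
    """A statistic is undefined for the given input (e.g. G+C of an all-N sequence)."""


@dataclass
class SequenceRecord:
    """A nucleotide sequence over ``{A,C,G,T,N}`` with a unique id."""

    id: str
    residues: str
    description: str = ""

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.residues)


@dataclass
class ReadRecord(SequenceRecord):
    """A sequencing read: a :class:`SequenceRecord` plus sample provenance.

    ``origin`` records the nucleic-acid source of the sample the read came
    from (``"RNA"``, ``"DNA"`` or ``"unknown"``); reads from DNA samples are
    removed before assembling RNA viral genomes.
    """

    sample_id: str = ""
    origin: str = "unknown"
    quality: list[int] | None = None


@dataclass(frozen=True)
class OrfCall:
    """An open reading frame: ATG..stop span on one strand.

    ``start``/``end`` are 0-based half-open coordinates on the forward
    sequence; the stop codon is included in the span.
    """

    start: int
    end: int
    strand: str
    frame: int

    @property
    def length_nt(self) -> int:
        return self.end - self.start


def _clean_residues(raw: str, context: str) -> str:
    """Uppercase and collapse non-ACGTN symbols to N (warning logged once per record)."""
    seq = raw.upper()
    if not set(seq) <= ALPHABET:
        n_bad = sum(1 for c in seq if c not in ALPHABET)
        logger.warning(
            "%s: %d residue(s) outside {A,C,G,T,N} mapped to N", context, n_bad
        )
        seq = "".join(c if c in ALPHABET else "N" for c in seq)
    return seq


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    Residues are uppercased; characters outside the alphabet are mapped to
    ``N`` with a warning.  Raises :class:`FormatError` on an empty file, a
    header with no sequence, or a missing file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = _clean_residues(str(rec.seq), f"{path.name}:{rec.id}")
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has a header but no sequence")
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        records.append(SequenceRecord(id=rec.id, residues=seq, description=rec.description))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def read_fastq(path: str | Path) -> list[ReadRecord]:
    """Read a 4-line-record FASTQ file (Sanger quality encoding) into reads.

    An empty file yields an empty list; a quality string whose length differs
    from its sequence raises :class:`FormatError` (via the underlying parser).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    reads: list[ReadRecord] = []
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            seq = _clean_residues(str(rec.seq), f"{path.name}:{rec.id}")
            reads.append(
                ReadRecord(
                    id=rec.id,
                    residues=seq,
                    description=rec.description,
                    quality=list(rec.letter_annotations["phred_quality"]),
                )
            )
    except ValueError as exc:  # Biopython signals length mismatches etc. as ValueError
        raise FormatError(f"{path}: {exc}") from exc
    return reads


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    """Write records as FASTA with fixed line wrapping (deterministic output)."""
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def write_fastq(reads: Iterable[ReadRecord], path: str | Path, default_quality: int = 30) -> None:
    """Write reads as FASTQ; reads without stored qualities get a flat quality."""
    path = Path(path)
    with path.open("w") as fh:
        for rec in reads:
            quals = rec.quality if rec.quality is not None else [default_quality] * len(rec.residues)
            qline = "".join(chr(q + 33) for q in quals)
            fh.write(f"@{rec.id}\n{rec.residues}\n+\n{qline}\n")


_ORIGINS = {"RNA": "RNA", "DNA": "DNA", "UNKNOWN": "unknown"}


def read_sample_manifest(path: str | Path) -> dict[str, tuple[str, str]]:
    """Read the per-read sample manifest: ``read_id <TAB> sample_id <TAB> origin``.

    The origin column is parsed case-insensitively into ``RNA``/``DNA``/
    ``unknown``; unrecognised tokens are recorded as ``unknown`` with a
    warning.  A read id appearing twice with conflicting origins is an error.
    A header row (first field ``read_id``) is tolerated.
    """
    path = Path(path)
    mapping: dict[str, tuple[str, str]] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected 3 tab-separated columns")
            read_id, sample_id, origin_raw = fields[0], fields[1], fields[2]
            if lineno == 1 and read_id.lower() in {"read_id", "read", "id"}:
                continue
            origin = _ORIGINS.get(origin_raw.strip().upper())
            if origin is None:
                logger.warning(
                    "%s:%d: unknown origin token %r recorded as unknown", path, lineno, origin_raw
                )
                origin = "unknown"
            if read_id in mapping and mapping[read_id] != (sample_id, origin):
                raise FormatError(
                    f"{path}:{lineno}: read {read_id!r} re-declared with conflicting entry"
                )
            mapping[read_id] = (sample_id, origin)
    return mapping


def write_sample_manifest(mapping: Mapping[str, tuple[str, str]], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("read_id\tsample_id\torigin\n")
        for read_id in mapping:
            sample_id, origin = mapping[read_id]
            fh.write(f"{read_id}\t{sample_id}\t{origin}\n")


def gc_content(record: SequenceRecord | str) -> float:
    """Fraction (G+C)/(non-N residues); undefined for an all-N sequence."""
    seq = record if isinstance(record, str) else record.residues
    if not seq:
        raise UndefinedValueError("empty sequence")
    counts = Counter(seq)
    denom = len(seq) - counts.get("N", 0)
    if denom == 0:
        raise UndefinedValueError("G+C content undefined: sequence is all N")
    return (counts.get("G", 0) + counts.get("C", 0)) / denom


def reverse_complement(residues: str) -> str:
    """Reverse complement on ``{A,C,G,T,N}`` (complement of N is N)."""
    return residues.translate(_COMPLEMENT)[::-1]


def _scan_orfs_forward(seq: str, min_len_nt: int, strand: str, length: int) -> list[OrfCall]:
    calls = []
    n = len(seq)
    for frame in range(3):
        start: int | None = None
        for pos in range(frame, n - 2, 3):
            codon = seq[pos : pos + 3]
            if start is None:
                if codon == START_CODON:
                    start = pos
            elif codon in STOP_CODONS:
                end = pos + 3
                if end - start >= min_len_nt:
                    if strand == "+":
                        calls.append(OrfCall(start, end, "+", frame))
                    else:
                        # map back onto forward coordinates
                        calls.append(OrfCall(length - end, length - start, "-", frame))
                start = None
    return calls


def find_orfs(record: SequenceRecord | str, min_len_nt: int = 300) -> list[OrfCall]:
    """All ATG→stop open reading frames of length ≥ ``min_len_nt`` in six frames.

    The stop codon is included in the span; calls are sorted by length
    descending (ties by start, then strand).
    """
    if min_len_nt < 6 or min_len_nt % 3:
        raise ValueError("min_len_nt must be ≥ 6 and divisible by 3")
    seq = record if isinstance(record, str) else record.residues
    calls = _scan_orfs_forward(seq, min_len_nt, "+", len(seq))
    calls += _scan_orfs_forward(reverse_complement(seq), min_len_nt, "-", len(seq))
    calls.sort(key=lambda c: (-c.length_nt, c.start, c.strand))
    return calls


def codon_usage(orf_residues: str) -> dict[str, dict[str, float]]:
    """Codon counts and frequencies over the 64 codons of an in-frame sequence.

    Returns ``{"counts": {...}, "frequencies": {...}}`` with frequencies
    summing to 1 over observed codons; every one of the 64 codons appears in
    both tables (zero where unobserved).
    """
    if len(orf_residues) % 3:
        raise ValueError("sequence length must be divisible by 3")
    bases = "ACGT"
    codons = [a + b + c for a in bases for b in bases for c in bases]
    counts = dict.fromkeys(codons, 0)
    total = 0
    for i in range(0, len(orf_residues), 3):
        codon = orf_residues[i : i + 3]
        if codon in counts:  # codons containing N are skipped
            counts[codon] += 1
            total += 1
    if total == 0:
        raise ValueError("no countable codons (all contain N)")
    freqs = {c: counts[c] / total for c in codons}
    return {"counts": counts, "frequencies": freqs}


def motif_screen(
    contigs: Sequence[SequenceRecord], motifs: Mapping[str, str]
) -> list[tuple[str, str, int, str]]:
    """Exact-match screen of plain nucleotide motifs against contigs, both strands.

    Returns ``(motif_id, contig_id, position, strand)`` tuples with 0-based
    positions on the forward contig; an empty list when nothing matches —
    which is the expected outcome when screening host CRISPR direct repeats
    against unrelated viral contigs.
    """
    hits: list[tuple[str, str, int, str]] = []
    for motif_id in motifs:
        motif = motifs[motif_id].upper()
        rc = reverse_complement(motif)
        for contig in contigs:
            seq = contig.residues
            for probe, strand in ((motif, "+"), (rc, "-")):
                if probe == motif and strand == "-":  # palindromic motif: avoid double report
                    continue
                start = seq.find(probe)
                while start != -1:
                    hits.append((motif_id, contig.id, start, strand))
                    start = seq.find(probe, start + 1)
    hits.sort()
    return hits
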