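"""Synthetic acidic-hot-spring RNA metagenome generator.

The generator emulates the statistical structure the discovery workflow
assumes: one "true" viral genome (~5.7 kb, G+C ≈ 50%), additional lineage
genomes diverged to target identities (50–99 %), planted reverse-repeat and
palindromic motifs (13–18 nt), 454-style shotgun reads (~100–500 nt, i.i.d.
substitutions plus ±1 homopolymer-run indels), unrelated background reads,
and a small fraction of viral reads tagged as DNA-sample origin so that the
origin filter has real work to do.

Everything is deterministic under a seed, and every simulated read is
accounted for in a :class:`TruthSet` so downstream recruitment, assembly and
phylogeny can be scored against ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .seq_core import ReadRecord, SequenceRecord, reverse_complement

_BASES = np.array(list("ACGT"))
_BASE_TO_IDX = {b: i for i, b in enumerate("ACGT")}


@dataclass(frozen=True)
class RepeatPlant:
    """A repeat to plant: copy the span at ``pos1`` to ``pos2``, transformed.

    ``repeat_type`` is ``"reverse"`` (second occurrence is the reversed copy)
    or ``"palindromic"`` (reverse-complemented copy).
    """

    repeat_type: str
    length: int
    pos1: int
    pos2: int

    def __post_init__(self) -> None:
        if self.repeat_type not in {"reverse", "palindromic"}:
            raise ValueError("repeat_type must be reverse or palindromic")
        if self.pos2 < self.pos1 + self.length:
            raise ValueError("occurrence spans must be disjoint (pos1 + length ≤ pos2)")


@dataclass
class LineagePlan:
    """Blueprint of the planted community: ancestor + diverged lineages + repeats.

    ``lineage_identities[i]`` is the target identity of lineage *i+1* to its
    anchor genome (``anchors[i]``).  The default community mirrors the
    structure of the system it emulates: a main reference (the ancestor), a
    second diverged reference, one lineage close to each reference, and one
    lone deeply diverged lineage — three lineages in total.  A conserved
    window is kept free of indels in every genome so that a gap-free
    conserved fragment (the phylogenetic marker) survives across lineages.
    """

    ancestor_length: int = 5662
    ancestor_gc: float = 0.507
    group_identity: float = 0.85
    lineage_identities: Sequence[float] = (0.95, 0.95, 0.85)
    anchors: Sequence[str] = ("ancestor", "reference2", "center")
    conserved_window: tuple[int, int] | None = (2500, 2964)
    repeat_plants: Sequence[RepeatPlant] = ()

    def __post_init__(self) -> None:
        self.lineage_identities = tuple(self.lineage_identities)
        self.anchors = tuple(self.anchors)
        self.repeat_plants = tuple(self.repeat_plants)
        if self.conserved_window is not None:
            self.conserved_window = tuple(self.conserved_window)
        if self.ancestor_length < 1000:
            raise ValueError("ancestor_length must be ≥ 1000")
        for t in (*self.lineage_identities, self.group_identity):
            if not 0.5 <= t <= 1.0:
                raise ValueError("identities must be in [0.5, 1.0]")
        if len(self.anchors) != len(self.lineage_identities):
            raise ValueError("anchors must match lineage_identities in length")
        for a in self.anchors:
            if a not in {"ancestor", "reference2", "center"}:
                raise ValueError("anchors must be ancestor/reference2/center")


@dataclass
class ReadSimConfig:
    """454-style read simulation parameters (defaults are a coarse 454 caricature)."""

    coverage_per_genome: float = 20.0
    read_length_range: tuple[int, int] = (100, 500)
    substitution_rate: float = 0.01
    homopolymer_indel_rate: float = 0.005
    background_read_count: int = 500
    dna_origin_fraction: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.read_length_range
        if not (50 <= lo <= hi <= 1000):
            raise ValueError("read_length_range must lie within [50, 1000]")
        for rate in (self.substitution_rate, self.homopolymer_indel_rate):
            if not 0 <= rate <= 0.1:
                raise ValueError("error rates must be in [0, 0.1]")
        if self.coverage_per_genome <= 0:
            raise ValueError("coverage must be > 0")


@dataclass
class TruthSet:
    """Ground truth of a simulation: genomes, per-read provenance, manifest."""

    genomes: dict[str, SequenceRecord]
    read_origin: dict[str, tuple[str, int, str]]  # read_id -> (source, true start, strand)
    manifest: dict[str, tuple[str, str]]  # read_id -> (sample_id, origin)


def generate_ancestor(length: int = 5662, gc: float = 0.507, seed: int = 0,
                      record_id: str = "ancestor") -> SequenceRecord:
    """I.i.d. random genome with P(G)+P(C) = ``gc``; deterministic under seed."""
    if not 0.3 <= gc <= 0.7:
        raise ValueError("gc must be in [0.3, 0.7]")
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    seq = "".join(rng.choice(_BASES, size=length, p=probs))
    return SequenceRecord(id=record_id, residues=seq)


def evolve_lineage(genome: SequenceRecord, target_identity: float, seed: int = 0,
                   record_id: str | None = None,
                   protect: tuple[int, int] | None = None) -> SequenceRecord:
    """Diverge a genome to a target global-alignment identity.

    The edit budget ``(1 − target) · L`` is spent 90 % on point substitutions
    (distinct positions, always to a different base) and 10 % on indels of
    1–3 nt, keeping realized end-gap-free global identity within about ±0.02
    of the target.  A ``protect`` window receives substitutions but no
    indels, so a gap-free conserved fragment survives in every lineage.
    """
    record, _ = evolve_lineage_windowed(genome, target_identity, seed,
                                        record_id=record_id, protect=protect)
    return record


def evolve_lineage_windowed(genome: SequenceRecord, target_identity: float,
                            seed: int = 0, record_id: str | None = None,
                            protect: tuple[int, int] | None = None,
                            ) -> tuple[SequenceRecord, tuple[int, int] | None]:
    """Like :func:`evolve_lineage`, additionally returning the protected
    window's coordinates in the evolved genome (shifted by upstream indels)."""
    if not 0.5 <= target_identity <= 1.0:
        raise ValueError("target_identity must be in [0.5, 1.0]")
    rng = np.random.default_rng(seed)
    seq = list(genome.residues)
    L = len(seq)
    # the aligner recovers chance matches near indels and in diverged tracts,
    # inflating measured identity ~ 0.18 d² at divergence d; pre-compensate so
    # measured identity lands on the target
    d = 1.0 - target_identity
    budget = (d / (1.0 - 0.18 * d)) * L
    n_subs = int(round(0.9 * budget))
    indel_nt = int(round(0.1 * budget))
    if n_subs:
        positions = rng.choice(L, size=min(n_subs, L), replace=False)
        for pos in positions:
            cur = seq[pos]
            choices = [b for b in "ACGT" if b != cur]
            seq[pos] = choices[rng.integers(0, 3)]
    window = list(protect) if protect is not None else None
    # small indels: alternate insertions and deletions so length drifts little
    spent = 0
    insert = True
    while spent < indel_nt and len(seq) > 10:
        size = int(rng.integers(1, 4))
        pos = int(rng.integers(0, len(seq)))
        if window is not None:
            span = (pos, pos) if insert else (pos, pos + size)
            if span[1] > window[0] and span[0] < window[1]:
                continue  # indel would touch the protected window: resample
        if insert:
            frag = "".join(rng.choice(_BASES, size=size))
            seq[pos:pos] = list(frag)
            if window is not None and pos <= window[0]:
                window[0] += size
                window[1] += size
        else:
            del seq[pos : pos + size]
            if window is not None and pos + size <= window[0]:
                window[0] -= size
                window[1] -= size
        spent += size
        insert = not insert
    record = SequenceRecord(
        id=record_id or f"{genome.id}_id{target_identity:.2f}", residues="".join(seq)
    )
    return record, (tuple(window) if window is not None else None)


def plant_repeats(genome: SequenceRecord, repeat_plants: Sequence[RepeatPlant]) -> SequenceRecord:
    """Write the transformed copy of each designated span at its target position.

    The genome length is unchanged; plants (including their source spans) must
    not overlap one another.
    """
    spans = []
    for p in repeat_plants:
        spans.append((p.pos1, p.pos1 + p.length))
        spans.append((p.pos2, p.pos2 + p.length))
    spans.sort()
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        if s2 < e1:
            raise ValueError("planted repeat spans overlap")
    if spans and (spans[0][0] < 0 or spans[-1][1] > len(genome.residues)):
        raise ValueError("planted repeat outside genome")
    seq = list(genome.residues)
    for p in repeat_plants:
        src = "".join(seq[p.pos1 : p.pos1 + p.length])
        copy = src[::-1] if p.repeat_type == "reverse" else reverse_complement(src)
        seq[p.pos2 : p.pos2 + p.length] = list(copy)
    return SequenceRecord(id=genome.id, residues="".join(seq), description=genome.description)


def _apply_read_errors(seq: str, rng: np.random.Generator, sub_rate: float,
                       hp_rate: float) -> str:
    chars = list(seq)
    if sub_rate > 0:
        mask = rng.random(len(chars)) < sub_rate
        for pos in np.flatnonzero(mask):
            cur = chars[pos]
            choices = [b for b in "ACGT" if b != cur]
            chars[pos] = choices[rng.integers(0, 3)]
    if hp_rate > 0:
        # homopolymer runs ≥ 3 in the (post-substitution) read: ±1 with prob hp_rate
        out: list[str] = []
        i = 0
        n = len(chars)
        while i < n:
            j = i
            while j < n and chars[j] == chars[i]:
                j += 1
            run = chars[i:j]
            if j - i >= 3 and rng.random() < hp_rate:
                if rng.random() < 0.5:
                    run = run + [chars[i]]
                else:
                    run = run[:-1]
            out.extend(run)
            i = j
        chars = out
    return "".join(chars)


def simulate_reads(genomes: Mapping[str, SequenceRecord] | Sequence[SequenceRecord],
                   config: ReadSimConfig,
                   rna_sample_id: str = "spring_rna",
                   dna_sample_id: str = "spring_dna") -> tuple[list[ReadRecord], dict, TruthSet]:
    """454-style shotgun simulation over one or more genomes plus background.

    Per genome, ``ceil(coverage × L / mean_read_length)`` reads with uniform
    start, strand and length (truncated at the genome end); i.i.d.
    substitutions; homopolymer runs ≥ 3 lengthened/shortened by one base at
    the configured per-run rate.  Exactly
    ``round(dna_origin_fraction × n_viral)`` viral reads are tagged as
    DNA-sample origin; background reads are i.i.d. uniform sequence tagged
    RNA.  Returns (reads, manifest, truth).
    """
    if not isinstance(genomes, Mapping):
        genomes = {g.id: g for g in genomes}
    rng = np.random.default_rng(config.seed)
    lo, hi = config.read_length_range
    mean_len = (lo + hi) / 2.0
    reads: list[ReadRecord] = []
    read_origin: dict[str, tuple[str, int, str]] = {}
    counter = 0
    for gid in genomes:
        gseq = genomes[gid].residues
        L = len(gseq)
        n_reads = math.ceil(config.coverage_per_genome * L / mean_len)
        for _ in range(n_reads):
            length = int(rng.integers(lo, hi + 1))
            start = int(rng.integers(0, max(L - 50, 1)))
            frag = gseq[start : start + length]
            strand = "+" if rng.random() < 0.5 else "-"
            oriented = frag if strand == "+" else reverse_complement(frag)
            errored = _apply_read_errors(oriented, rng, config.substitution_rate,
                                         config.homopolymer_indel_rate)
            rid = f"r{counter:06d}"
            counter += 1
            reads.append(ReadRecord(id=rid, residues=errored))
            read_origin[rid] = (gid, start, strand)
    n_viral = len(reads)
    for _ in range(config.background_read_count):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(_BASES, size=length))
        rid = f"r{counter:06d}"
        counter += 1
        reads.append(ReadRecord(id=rid, residues=seq))
        read_origin[rid] = ("background", -1, "+")
    # tag exactly round(fraction × n_viral) viral reads as DNA-sample origin
    n_dna = int(round(config.dna_origin_fraction * n_viral))
    dna_ids = set()
    if n_dna:
        chosen = rng.choice(n_viral, size=n_dna, replace=False)
        dna_ids = {reads[int(i)].id for i in chosen}
    manifest: dict[str, tuple[str, str]] = {}
    for read in reads:
        if read.id in dna_ids:
            read.sample_id, read.origin = dna_sample_id, "DNA"
        else:
            read.sample_id, read.origin = rna_sample_id, "RNA"
        manifest[read.id] = (read.sample_id, read.origin)
    truth = TruthSet(genomes=dict(genomes), read_origin=read_origin, manifest=manifest)
    return reads, manifest, truth


def build_community(plan: LineagePlan, seed: int = 0) -> dict[str, SequenceRecord]:
    """Reference genomes plus one diverged lineage genome per plan entry.

    Returns ``ancestor`` (the main reference), optionally ``reference2``
    (a second, diverged reference), and ``lineage1 … lineageN``, each evolved
    from its anchor at its target identity.  Repeat plants are applied to the
    ancestor before divergence so related lineages inherit mutated copies of
    the planted repeats; the conserved window is indel-protected everywhere.
    """
    center = generate_ancestor(plan.ancestor_length, plan.ancestor_gc, seed=seed,
                               record_id="center")
    windows: dict[str, tuple[int, int] | None] = {"center": plan.conserved_window}
    raw: dict[str, SequenceRecord] = {"center": center}
    for name, s in (("ancestor", 500), ("reference2", 600)):
        rec, w = evolve_lineage_windowed(center, plan.group_identity, seed=seed + s,
                                         record_id=name, protect=plan.conserved_window)
        raw[name] = rec
        windows[name] = w
    for i, target in enumerate(plan.lineage_identities, start=1):
        anchor = plan.anchors[i - 1]
        rec, w = evolve_lineage_windowed(raw[anchor], target, seed=seed + 1000 + i,
                                         record_id=f"lineage{i}",
                                         protect=windows[anchor])
        raw[f"lineage{i}"] = rec
        windows[f"lineage{i}"] = w
    # exact repeat copies are written into every *observed* genome after
    # divergence, emulating shared repeat types across related genomes
    genomes: dict[str, SequenceRecord] = {}
    for name, rec in raw.items():
        if name == "center":
            continue  # the radiation point is not an observed genome
        genomes[name] = plant_repeats(rec, plan.repeat_plants)
    return genomes
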