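"""Reference-guided placement, consensus calling, end extension, the
iterative recruit→assemble loop, greedy de novo assembly, and statistics."""

import numpy as np
import pytest

from virrecruit.assemble import (
    Contig, IterateConfig, ReadPlacement, call_consensus, compute_stats,
    denovo_assemble, extend_reference, iterate_recruit_assemble,
    map_to_reference,
)
from virrecruit.recruit import global_align_identity
from virrecruit.seq_core import ReadRecord, SequenceRecord, reverse_complement
from virrecruit.synthetic_community import (ReadSimConfig, evolve_lineage,
                                            generate_ancestor, simulate_reads)


class TestMapToReference:
    def test_exact_fragment_placed(self):
        ref = generate_ancestor(800, 0.5, seed=1, record_id="ref")
        read = ReadRecord(id="r", residues=ref.residues[100:400])
        placements, unplaced = map_to_reference([read], ref)
        assert not unplaced
        p = placements[0]
        assert p.offset == 100 and p.strand == "+"
        assert p.aligned == ref.residues[100:400]

    def test_reverse_strand_fragment(self):
        ref = generate_ancestor(800, 0.5, seed=1, record_id="ref")
        read = ReadRecord(id="r", residues=reverse_complement(ref.residues[100:400]))
        placements, _ = map_to_reference([read], ref)
        assert placements[0].offset == 100 and placements[0].strand == "-"

    def test_three_prime_overhang_retained(self):
        ref = generate_ancestor(600, 0.5, seed=2, record_id="ref")
        tail = "ACGTTGCA" * 7  # 56 nt beyond the reference end
        read = ReadRecord(id="r", residues=ref.residues[400:] + tail[:50])
        placements, _ = map_to_reference([read], ref)
        p = placements[0]
        assert p.end == 600
        assert p.right_tail == tail[:50]

    def test_diverged_read_unplaced(self):
        ref = generate_ancestor(600, 0.5, seed=3, record_id="ref")
        noise = generate_ancestor(300, 0.5, seed=99, record_id="x")
        placements, unplaced = map_to_reference(
            [ReadRecord(id="r", residues=noise.residues)], ref)
        assert unplaced == ["r"]


class TestCallConsensus:
    def _place(self, reads, ref):
        placements, _ = map_to_reference(reads, ref)
        return placements

    def test_identical_reads(self):
        ref = generate_ancestor(200, 0.5, seed=4, record_id="ref")
        reads = [ReadRecord(id=f"r{i}", residues=ref.residues) for i in range(3)]
        cons, depth, proj = call_consensus(self._place(reads, ref), reference=ref)
        assert cons == ref.residues
        assert depth.tolist() == [3] * 200

    def test_minority_substitution_outvoted(self):
        ref = generate_ancestor(200, 0.5, seed=4, record_id="ref")
        mutated = list(ref.residues)
        mutated[10] = "A" if mutated[10] != "A" else "C"
        reads = [ReadRecord(id=f"r{i}", residues=ref.residues) for i in range(4)]
        reads.append(ReadRecord(id="mut", residues="".join(mutated)))
        cons, _, _ = call_consensus(self._place(reads, ref), reference=ref)
        assert cons == ref.residues

    def test_errorfree_sim_consensus_equals_genome(self, errorfree_world):
        genome = errorfree_world["genome"]
        placements, unplaced = map_to_reference(errorfree_world["reads"], genome)
        assert not unplaced
        cons, _, _ = call_consensus(placements, reference=genome)
        assert cons == genome.residues

    def test_requires_placements(self):
        with pytest.raises(ValueError):
            call_consensus([], reference_length=10)


class TestExtendReference:
    def _contig_with_overhangs(self, n_right=2, overhang="ACGGTTCA" * 25):
        ref = generate_ancestor(400, 0.5, seed=5, record_id="ref")
        reads = [ReadRecord(id=f"r{i}", residues=ref.residues[200:] + overhang[:170])
                 for i in range(n_right)]
        reads.append(ReadRecord(id="body", residues=ref.residues))
        placements, _ = map_to_reference(reads, ref)
        cons, depth, proj = call_consensus(placements, reference=ref)
        return Contig("c", cons, proj, depth)

    def test_agreeing_overhangs_extend_170nt(self):
        contig = self._contig_with_overhangs(n_right=2)
        extended, e5, e3 = extend_reference(contig, min_end_depth=2)
        assert e3 == 170 and e5 == 0
        assert len(extended.consensus) == 570

    def test_single_overhang_no_extension(self):
        contig = self._contig_with_overhangs(n_right=1)
        extended, e5, e3 = extend_reference(contig, min_end_depth=2)
        assert (e5, e3) == (0, 0)
        assert extended.consensus == contig.consensus

    def test_no_overhangs_noop(self):
        ref = generate_ancestor(300, 0.5, seed=6, record_id="ref")
        reads = [ReadRecord(id="r", residues=ref.residues[50:250])]
        placements, _ = map_to_reference(reads, ref)
        cons, depth, proj = call_consensus(placements, reference=ref)
        contig = Contig("c", cons, proj, depth)
        extended, e5, e3 = extend_reference(contig)
        assert (e5, e3) == (0, 0)


class TestIterateRecruitAssemble:
    def test_recovers_planted_genome(self, converged_assembly):
        """From a central 2-kb seed, the loop walks out to ≥ 99 % of the 6-kb
        genome at ≥ 99 % identity (1 % substitutions, homopolymer indels)."""
        contig = converged_assembly["contig"]
        genome = converged_assembly["genome"]
        pct, cols, _ = global_align_identity(contig.consensus, genome.residues)
        assert cols / len(genome.residues) >= 0.99
        assert pct >= 99.0

    def test_lengths_monotone_and_terminates(self, converged_assembly):
        lengths = [rec.consensus_length for rec in converged_assembly["log"]]
        assert lengths == sorted(lengths)
        assert len(lengths) <= IterateConfig().max_iterations

    def test_origin_filter_applied_in_loop(self, converged_assembly):
        for rec in converged_assembly["log"]:
            assert rec.reads_kept <= rec.reads_recruited

    def test_no_homologous_reads_returns_seed(self):
        seed = generate_ancestor(500, 0.5, seed=7, record_id="seed")
        noise_reads = [ReadRecord(id=f"n{i}",
                                  residues=generate_ancestor(300, 0.5, seed=100 + i).residues)
                       for i in range(10)]
        manifest = {r.id: ("s", "RNA") for r in noise_reads}
        contig, log = iterate_recruit_assemble(seed, noise_reads, manifest)
        assert contig.consensus == seed.residues
        assert contig.placements == []
        assert len(log) == 1

    def test_consensus_idempotence(self, converged_assembly):
        """Re-mapping the converged contig's reads and re-calling the
        consensus reproduces it exactly."""
        contig = converged_assembly["contig"]
        by_id = {r.id: r for r in converged_assembly["reads"]}
        member_reads = [by_id[p.read_id] for p in contig.placements]
        placements, _ = map_to_reference(member_reads, contig.consensus)
        cons, _, _ = call_consensus(placements, reference=contig.consensus)
        assert cons == contig.consensus

    def test_coverage_conservation(self, converged_assembly):
        contig = converged_assembly["contig"]
        assert int(contig.depth.sum()) == sum(len(p.aligned) for p in contig.placements)


class TestDenovoAssemble:
    def test_two_overlapping_reads_merge(self):
        g = generate_ancestor(500, 0.5, seed=8, record_id="g")
        r1 = ReadRecord(id="a", residues=g.residues[:300])
        r2 = ReadRecord(id="b", residues=g.residues[200:500])
        contigs = denovo_assemble([r1, r2], min_overlap=50, min_identity=0.95)
        assert len(contigs) == 1
        assert contigs[0].consensus in (g.residues,
                                        reverse_complement(g.residues))

    def test_errorfree_tiling_single_contig(self):
        genome = generate_ancestor(1200, 0.5, seed=9, record_id="g")
        cfg = ReadSimConfig(coverage_per_genome=12, substitution_rate=0.0,
                            homopolymer_indel_rate=0.0, background_read_count=0,
                            seed=10)
        reads, _, _ = simulate_reads({"g": genome}, cfg)
        contigs = denovo_assemble(reads, min_overlap=30, min_identity=0.95)
        top = contigs[0]
        ident = max(global_align_identity(top.consensus, genome.residues)[0],
                    global_align_identity(reverse_complement(top.consensus),
                                          genome.residues)[0])
        assert ident == 100.0
        assert len(top.consensus) >= 0.95 * 1200

    def test_two_genomes_no_chimeras(self):
        g1 = generate_ancestor(1000, 0.5, seed=11, record_id="g1")
        g2 = evolve_lineage(g1, 0.60, seed=12, record_id="g2")
        cfg = ReadSimConfig(coverage_per_genome=10, substitution_rate=0.0,
                            homopolymer_indel_rate=0.0, background_read_count=0,
                            seed=13)
        reads, _, truth = simulate_reads({"g1": g1, "g2": g2}, cfg)
        contigs = denovo_assemble(reads, min_overlap=30, min_identity=0.95)
        for contig in contigs:
            sources = {truth.read_origin[p.read_id][0] for p in contig.placements}
            assert len(sources) == 1

    def test_empty_read_set(self):
        assert denovo_assemble([]) == []

    def test_thresholds_validated(self):
        with pytest.raises(ValueError):
            denovo_assemble([], min_overlap=10)


class TestComputeStats:
    def test_three_identical_reads(self):
        ref = generate_ancestor(100, 0.5, seed=14, record_id="ref")
        reads = [ReadRecord(id=f"r{i}", residues=ref.residues) for i in range(3)]
        placements, _ = map_to_reference(reads, ref)
        cons, depth, proj = call_consensus(placements, reference=ref)
        stats = compute_stats(Contig("c", cons, proj, depth))
        assert stats.length_nt == 100
        assert stats.n_reads == 3
        assert stats.identical_sites == 100
        assert stats.mean_pairwise_identity_pct == pytest.approx(100.0)
        assert (stats.coverage_mean, stats.coverage_min, stats.coverage_max) == (3, 3, 3)

    def test_single_mismatch_column(self):
        ref = SequenceRecord("ref", "ACGTACGTACGT" * 10)
        mutated = list(ref.residues)
        mutated[10] = "A" if mutated[10] != "A" else "C"
        reads = [ReadRecord(id="r0", residues=ref.residues),
                 ReadRecord(id="r1", residues="".join(mutated))]
        placements, _ = map_to_reference(reads, ref)
        cons, depth, proj = call_consensus(placements, reference=ref)
        stats = compute_stats(Contig("c", cons, proj, depth))
        assert stats.identical_sites == len(ref.residues) - 1
        # one disagreeing column among 120 with depth 2: mean pairwise < 100
        assert stats.mean_pairwise_identity_pct == pytest.approx(
            100 * (1 - 1 / len(ref.residues)), abs=1e-6)

    def test_errorfree_sim_all_covered_sites_identical(self, errorfree_world):
        genome = errorfree_world["genome"]
        placements, _ = map_to_reference(errorfree_world["reads"], genome)
        cons, depth, proj = call_consensus(placements, reference=genome)
        contig = Contig("c", cons, proj, depth)
        stats = compute_stats(contig)
        assert stats.identical_sites == int((contig.depth >= 1).sum())
        assert stats.identical_sites >= 0.99 * stats.length_nt
        assert stats.gc_pct == pytest.approx(
            100 * sum(c in "GC" for c in genome.residues) / len(genome.residues))

    def test_requires_placements(self):
        with pytest.raises(ValueError):
            compute_stats(Contig("c", "ACGT", [], np.zeros(4, dtype=int)))
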