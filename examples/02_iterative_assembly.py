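"""Iterative read recruitment and assembly to convergence.

Plants a 4-kb viral genome, simulates 454-style reads (1 % substitutions,
homopolymer indels, unrelated background), then grows a central 1.5-kb seed
outward: recruit reads at E < 1e-5, drop DNA-origin reads, place, call the
majority consensus, extend the ends, repeat until the sequence stops
extending.  Prints the per-iteration log and the recovery achieved.
"""

from virrecruit import (ReadSimConfig, SequenceRecord, generate_ancestor,
                        global_align_identity, iterate_recruit_assemble,
                        simulate_reads, compute_stats)

genome = generate_ancestor(4000, 0.5, seed=7, record_id="virus")
cfg = ReadSimConfig(coverage_per_genome=20, substitution_rate=0.01,
                    homopolymer_indel_rate=0.005, background_read_count=200,
                    seed=8)
reads, manifest, truth = simulate_reads({"virus": genome}, cfg)
seed = SequenceRecord("seed", genome.residues[1200:2700])

contig, log = iterate_recruit_assemble(seed, reads, manifest)

print("iter  recruited  kept  consensus_nt  ext5  ext3")
for rec in log:
    print(f"{rec.iteration:4d}  {rec.reads_recruited:9d}  {rec.reads_kept:4d}"
          f"  {rec.consensus_length:12d}  {rec.ext5:4d}  {rec.ext3:4d}")

pct, cols, band = global_align_identity(contig.consensus, genome.residues)
stats = compute_stats(contig)
print(f"\nFinal contig: {len(contig.consensus)} nt from a {len(seed.residues)}-nt seed")
print(f"Covers {100 * cols / len(genome.residues):.1f} % of the planted genome "
      f"at {pct:.2f} % identity.")
print(f"Reads placed: {stats.n_reads}; mean coverage {stats.coverage_mean:.1f}x; "
      f"G+C {stats.gc_pct:.1f} %.")
print("Lengths are non-decreasing across iterations; the loop stops when the")
print("assembly stops extending — the convergence rule of the workflow.")
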