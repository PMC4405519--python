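# virrecruit

Targeted discovery of divergent viral genomes in metagenomic read sets, by
iterative homology-based read recruitment and assembly to convergence, with
the downstream diversity analyses that characterise the recovered genomes:
maximal-repeat detection with an expectation statistic, pairwise-similarity
banding, HKY85 maximum-likelihood phylogeny with bootstrap, and lineage
assignment.

## Who this is for

Viral metagenomics researchers who have one known (or suspected) viral genome
and a large unassembled read collection, and want every related genome hiding
in it — including relatives at 50–70 % nucleotide identity that a single
de novo assembly would scatter. The archetype is the recovery of putative
archaeal RNA virus genomes from acidic-hot-spring RNA metagenomes: a single
deposited reference recruited thousands of related reads, which assembled
into multiple novel genomes falling into three phylogenetic lineages.

Because the original read databases are no longer downloadable, the package
ships a first-class synthetic-community generator that reproduces the
statistical structure the method assumes (planted genomes, diverged lineages,
planted repeats, 454-style reads with homopolymer errors, DNA-origin
contaminant reads), with full ground truth, so the entire workflow is
testable end to end offline.

## The method

**Recruitment.** A seed-and-extend local-alignment search (BLASTN-like)
against a k-mer index of the reads, scored with affine gaps and assessed by
Karlin–Altschul statistics,

&nbsp;&nbsp;&nbsp;&nbsp;*E* = *K·m·n·e^(−λS)*,

with λ the positive root of Σᵢⱼ *pᵢpⱼ* e^(λ·sᵢⱼ) = 1. Reads with *E* < 10⁻⁵
are recruited; reads positively identified as coming from DNA samples are
removed (the target genomes are RNA viruses). A six-frame translated mode
(BLOSUM62, TBLASTX-like) is available for deeply diverged relatives.

**Iterative assembly.** Recruited reads are placed on the current reference
by banded end-gap-free alignment; a column-wise majority consensus is called
(gaps count as a symbol, majority insertions are spliced in); the consensus
is extended at each end with agreeing read overhangs (depth ≥ 2); and the
extended consensus becomes the next query. The loop repeats until the
assembled sequence stops extending. A greedy overlap-layout-consensus
de novo assembler covers the initial contig-building step.

**Repeats.** All maximal repeat pairs — forward, reverse (reversed copy) and
palindromic (reverse-complemented copy) — of length ≥ *l*min, each scored by
the expectation value

&nbsp;&nbsp;&nbsp;&nbsp;*E* = (*n*²/2) · (1/4)^*l* · (3/4)²,

the expected number of maximal pairs of length exactly *l* in a random
sequence of length *n*.

**Phylogeny.** A gap-free conserved block is extracted from a progressive
multiple alignment; every unrooted binary topology is enumerated (15 for
5 taxa) and scored by Felsenstein pruning under HKY85 with per-topology
branch-length and κ optimisation; bootstrap supports come from column
resampling; lineages are the clades delimited by internal edges with support
≥ 70 % and length ≥ 0.1 substitutions/site.

## Worked example

```bash
python examples/02_iterative_assembly.py
```

prints (numbers from the run on this machine):

```
iter  recruited  kept  consensus_nt  ext5  ext3
   1        106   105          2137   258   379
   2        147   146          2823   369   317
   3        202   201          3543   387   333
   4        244   243          3948   148   257
   5        267   266          3962     0    14
   6        267   266          3962     0     0

Final contig: 3962 nt from a 1500-nt seed
Covers 99.0 % of the planted genome at 100.00 % identity.
Reads placed: 266; mean coverage 19.8x; G+C 50.2 %.
```

A 1.5-kb seed recruited 106 reads (one removed as DNA-sample origin), and six
recruit→assemble rounds grew it to
3,962 nt — 99.0 % of the planted 4-kb genome, error-corrected to 100 %
identity by majority consensus despite 1 % read substitutions and
homopolymer indels. The other examples cover community simulation
(`01`), the repeat survey and its analytic statistic (`03`), tree inference
and lineage assignment (`04`), and the full configuration-driven pipeline
with all report tables (`05`).

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, by running the package's own statistics from scratch, the survey
quantity with a printed reference value — the repeat expectation value for a
14-nt reverse repeat in a 417-nt contig — and writes it as JSON.
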