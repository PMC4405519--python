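# Methods

This note documents the models, statistics and numerical choices behind
`virrecruit`, and what its synthetic-data tests do and do not establish.

## 1. Read recruitment

### Search model

Recruitment is seed-and-extend local alignment of a query sequence against a
read database. Reads are indexed by exact k-mers on their forward strand; the
query is scanned as-is and reverse-complemented (single index, two query
orientations). Seeds on a read are clustered by diagonal (half-width 16,
`RecruitConfig.band`); up to three clusters are extended, because at deep
divergence a chance k-mer on a wrong diagonal can outnumber the true one.
Extension is gapped local alignment (Biopython's C `PairwiseAligner`)
restricted to a query window around the cluster's diagonal range — the
banding that keeps each extension O(read length × band).

Scoring defaults to +2/−3 with gap open −5, extend −2 (a gap of length L
costs open + (L−1)·extend) — BLASTN's defaults. At 70 % identity the expected
score per aligned pair is then +0.5/base; under +1/−2 it would be +0.1/base
and a 150-nt homologous overlap would not reach significance at the
recruitment threshold, so the milder scheme was rejected.

### Significance

Hits are assessed with Karlin–Altschul statistics, E = K·m·n·e^(−λS), λ the
unique positive root of Σ pᵢpⱼe^(λsᵢⱼ) = 1 (bracketed root finding to
|f(λ)| < 1e−10; uniform base frequencies by default). K is not derived here:
nucleotide mode uses 0.41, the tabulated gapped value for +2/−3 with these
gap costs; translated mode uses 0.041 (BLOSUM62). K only shifts the effective
threshold; both constants are exposed in `RecruitConfig`. The recruitment
cutoff is E < 10⁻⁵, the threshold the workflow prescribes.

Word size defaults to k = 9. The run-length statistics of clean k-mers set
the sensitivity floor: at 70 % identity the probability that a 150-nt overlap
contains no clean 11-mer is ≈ exp(−140·0.285·0.715¹¹) ≈ 0.35, so k = 11
cannot reach 90 % recall on 150-nt overlaps, while k = 9 brings the miss
probability to ≈ 0.15 there and ≈ 0.02 at 300 nt. The cost is that most
background reads share a chance 9-mer with a multi-kilobase query and get
(cheaply) extended and rejected.

`smith_waterman` is an independently written affine-gap DP with fully
specified tie-breaking (best score, then smallest subject start, then
smallest query start). It exists as the oracle for the heuristic: on ≤100-nt
sequences with k = 4 the heuristic's window covers the whole query and its
best hit score must equal the DP optimum — asserted over 200 random trials.

### Origin filtering

Reads whose manifest origin is a known non-kept type (DNA, when keeping RNA)
are removed; reads of unknown origin are kept with a warning — the workflow
removes only reads positively identified as DNA-sample derived.

### Translated mode

All six query frames against all six read frames, BLOSUM62, gaps −11/−1,
stops translated to `*` (scored negatively against everything), E-values in
protein space with translated search-space sizes (nt/3). Nucleotide mode is
the tested default; the synthetic communities are nucleotide-calibrated.

## 2. Pairwise identity and similarity bands

`global_align_identity` is semi-global: the shorter sequence aligns end to
end, end gaps of the longer are free and excluded; identity = identical
columns / aligned columns. It uses stiff gap penalties (−10 open, −6 extend)
regardless of the recruitment scheme: with soft gaps, the optimal alignment
of two *unrelated* sequences harvests chance matches through gap shuffling
and reports ≈ 52 % "identity"; stiff gaps keep unrelated pairs below 50 %,
which is what the 50–70 / 70–90 / 90–100 % banding requires, while changing
measured identity of genuine homologs by < 0.5 points. A fully end-gap-free
(overlap) alignment was rejected for this purpose because its score optimum
on unrelated sequences degenerates to a short high-identity fragment.

## 3. Iterative assembly

Placement maps each read to its best seeded position on either strand
(end-gap-free alignment to a windowed reference region); a read is accepted
at ≥ 90 % identity over ≥ 30 aligned columns, and may overhang the reference
ends. Consensus is per-column majority over the placed reads in reference
coordinates: gaps count as a symbol and a winning gap deletes the column;
insertions carried by more than half of the covering reads are spliced in;
ties go to the reference base, then to the lexicographically smallest symbol;
zero-coverage columns inside the span keep the reference base. At depth ≥ 3
this resolves the dominant 454-style error, homopolymer run ±1.

End extension appends majority-called overhang columns while ≥ 2 overhanging
reads cover them (`min_end_depth = 2` — a single read cannot drag the
consensus through its own errors). The loop — recruit, origin-filter, place,
consensus, extend — repeats with the extended consensus as the new query
until length gain < 1 nt with a stable consensus, or 20 iterations. An
iteration that would shrink the consensus returns the previous contig, so
reported lengths are non-decreasing and termination is guaranteed. Depth is
defined as the number of placements whose alignment spans the column
(deletion gaps included), so Σ depth equals Σ aligned span lengths.

De novo assembly is greedy overlap-layout-consensus: all read pairs sharing
a 16-mer (either orientation) are overlap-aligned; the best-scoring
qualifying overlap (≥ 20 nt, ≥ 90 % identity; ties by id pair) is merged;
overlaps are recomputed against the merged sequence; singletons become
1-read contigs. Final layouts re-place each contig's reads and re-call the
consensus. Greedy rather than graph-based: the recruitment regime is a
single target family at modest depth, where greedy is deterministic,
testable, and sufficient — it is not meant for complex communities.

"Identical sites" counts covered columns where all covering reads agree
(so a column no read covers is not counted); "pairwise identity" is the mean
over depth-≥2 columns of the fraction of agreeing read pairs. These are our
reconstructions of assembler-report columns whose definitions the original
tooling does not publish; their values are not a reproduction target.

## 4. Repeat statistics

Maximal repeat pairs of three types are detected: forward (s₂ = s₁), reverse
(s₂ = reverse(s₁) — reversed, *not* complemented) and palindromic
(s₂ = reverse-complement(s₁)). Detection hashes all min-length windows (and
their reversed / reverse-complemented images) and extends each seeded pair to
maximality; correctness is defined by equivalence with an exhaustive
enumeration over all position pairs, asserted on 200 random sequences.
Forward occurrences may overlap (tandem repeats); reverse and palindromic
occurrences must be span-disjoint, matching the pairwise-occurrence model of
the statistic — extension stops at the disjointness boundary. Windows
containing N never match.

The expectation statistic for a maximal pair of length exactly l in an
i.i.d. random sequence of length n with match probability p = 1/4:

    E = (n²/2) · p^l · (1 − p)²

— n²/2 ordered position pairs, p^l for the l matching positions, (1−p)² for
the two flanking mismatches that make the pair maximal. This reconstruction
reproduces all twelve printed reference E-values to three significant
figures from their (n, l) pairs, which is the statistic's calibration test
(it was verified against the printed table before the finder was built). The
screening threshold in reports is E ≤ 0.1.

## 5. Phylogeny

`align_homologs` is a deterministic progressive aligner: the most similar
pair (by semi-global identity) is aligned first, then each remaining
sequence — ordered by best similarity to the profile — is aligned to the
profile's majority consensus and threaded in. It uses the stiff-gap identity
scoring so spurious gaps do not fragment genuinely gap-free conserved runs.
This is a deliberately simple stand-in for production MSA tools, adequate
for the substitution-dominated synthetic communities it serves.

The conserved block is the longest gap-free column run whose mean column
identity (fraction of rows matching the column majority) is ≥ 0.5 — the
between-lineage similarity floor of the system. Tree inference sees no gaps;
N is missing data (partial likelihood 1 for every state).

HKY85 transition probabilities come from the spectral decomposition of the
normalised rate matrix (symmetrised by √π similarity, so the eigensystem is
real), cached per (κ, π). The likelihood is Felsenstein pruning with
site-pattern compression and per-node rescaling. π is estimated from
observed block frequencies.

The search is exhaustive: all unrooted binary topologies by stepwise
addition (1, 3, 15, 105 … — enumeration order is the deterministic
tie-break). Topologies are ranked by a rough pass (cyclic bounded Brent per
branch, fixed κ, 3 rounds, xatol 1e−4); the winner is refined by cyclic
branch-length plus κ optimisation to tolerance 1e−6. The two-stage scheme
exists for bootstrap throughput; topology ranking differences between rough
and refined optimisation were never observed on separated simulations, and
the refined stage restores full precision for the reported tree. Bootstrap
replicates resample columns with replacement and re-run the search without
the refinement stage (topology is all a replicate contributes). Internal
edges optimised to numerically zero length are treated as unresolved and get
no support value.

Lineages: an internal edge qualifies when support ≥ 70 % and length ≥ 0.1
substitutions/site (our operationalisation of the visual lineage grouping;
both thresholds exposed). Each qualifying edge delimits a clade — the
smaller side of its bipartition — and taxa fall into the largest qualifying
clade containing them; taxa in none are singleton lineages. A star-like tree
therefore yields one lineage per taxon.

## 6. The synthetic community

The generator states the world the analyses assume:

- **Reference genome**: i.i.d. bases, 5,662 nt, G+C 0.507 (the deposited
  reference's length and composition).
- **Community structure**: three groups radiating from an unobserved centre
  at 0.85 identity each (≈ 0.70 between groups — the observed between-lineage
  similarity): a main reference with a close lineage (0.95), a second
  reference with a close lineage (0.95), and a lone third lineage. This
  radiating shape is what makes three lineages phylogenetically delimitable;
  deriving the lone lineage directly from a reference would put its
  divergence point *on* that reference's branch (a zero-length internal
  edge).
- **Divergence**: `evolve_lineage` spends the edit budget (1 − t)·L 90 % on
  substitutions (never to the same base) and 10 % on 1–3-nt indels. The
  budget is pre-compensated by d → d/(1 − 0.18·d) because optimal alignment
  recovers chance matches near indels and in diverged tracts (≈ 0.18·d²
  identity inflation, measured); with the compensation, realized identity is
  within ±0.02 of target at every target in [0.6, 0.99] (tested over 20
  seeds each).
- **Conserved window**: a designated window (default 464 nt, the length of
  the real conserved fragment) receives substitutions but no indels in every
  genome, so a gap-free conserved block survives for tree inference —
  emulating the locally conserved replication-gene region of real genomes.
- **Repeats**: planted as exact transformed copies into every observed
  genome after divergence (related genomes share repeat types; exactness is
  what the finder detects). Default plants: five reverse + three palindromic,
  14–18 nt.
- **Reads**: per genome, ⌈coverage·L/mean length⌉ reads; uniform start,
  strand, and length (100–500 nt, bracketing 454 reads); i.i.d. substitutions
  (1 %); homopolymer runs ≥ 3 lengthened/shortened by one base at 0.5 % per
  run — a coarse 454 caricature sufficient to stress consensus calling.
  Exactly round(0.002 × viral reads) are tagged DNA-sample origin (≈ 6 at the
  real study's scale of ~3,000 reads; the exact count makes the
  origin-filter test sharp). Background reads are i.i.d. uniform — guaranteed
  non-recruitable at the default threshold, hence a pure specificity control.

What a green test does **not** establish: real 454 error profiles
(quality-dependent, flowgram-structured), real community abundance skews,
chimeric reads, conserved-region mosaicism, or codon structure — lineage
divergence is uniform outside the conserved window, so translated-mode
advantages are demonstrated only on constructed wobble-randomised cases.

## 7. Numerical and degenerate-input policy

- Coordinates 0-based half-open internally; report files are 1-based
  inclusive. All report tables are TSV; all outputs are byte-reproducible
  under a fixed seed (sorted iteration orders, fixed float formats).
- Alphabet {A,C,G,T,N}; anything else becomes N on input with a warning.
- λ root finding: Brent on a bracketed interval, |residual| < 1e−10.
  Non-negative expected pair score is an error (no valid λ).
- Branch lengths bounded to [1e−8, 10]; κ to [0.05, 100].
- Recruiting zero reads returns the seed unchanged with a warning; an
  all-gappy alignment raises an explicit no-conserved-block error; an all-N
  sequence has undefined G+C (error, not NaN).
- G+C is reported to one decimal place in tables.

## 8. Known limitations

- The heuristic recruiter is not NCBI BLAST: no composition-based statistics,
  no low-complexity masking, bit-score constants not reproduced. E-values
  agree with BLAST in threshold behaviour, not to the digit.
- The exhaustive tree search is capped at 8 taxa by design; larger problems
  belong in a dedicated phylogenetics package.
- The progressive MSA is adequate for ≥ 50 % identity communities; below
  that, block extraction will (correctly) refuse to return a conserved block.
- Reference-guided consensus cannot recover genome ends no read overhangs
  reach; recovered fraction saturates near, not at, 100 %.
- `denovo_assemble` is quadratic in read count; intended for recruited read
  sets (10²–10³ reads), not whole metagenomes.
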