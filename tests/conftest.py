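"""Shared fixtures: small synthetic worlds reused across test modules.

Expensive end-to-end worlds are session-scoped so they are built once.
"""

from __future__ import annotations

import numpy as np
import pytest

from virrecruit.seq_core import SequenceRecord
from virrecruit.synthetic_community import (
    ReadSimConfig, generate_ancestor, evolve_lineage, simulate_reads,
)
from virrecruit.assemble import iterate_recruit_assemble


@pytest.fixture(scope="session")
def planted_genome():
    """A 6-kb random genome (G+C 0.5), the recovery target of the loop tests."""
    return generate_ancestor(6000, 0.5, seed=2, record_id="genome")


@pytest.fixture(scope="session")
def planted_world(planted_genome):
    """454-style reads at 20x with 1% substitutions + homopolymer indels,
    plus unrelated background reads, with full ground truth."""
    cfg = ReadSimConfig(coverage_per_genome=20, substitution_rate=0.01,
                        homopolymer_indel_rate=0.005, background_read_count=300,
                        seed=3)
    reads, manifest, truth = simulate_reads({"genome": planted_genome}, cfg)
    return {"genome": planted_genome, "reads": reads, "manifest": manifest,
            "truth": truth}


@pytest.fixture(scope="session")
def converged_assembly(planted_world):
    """The iterative recruit→assemble loop run from a central 2-kb seed."""
    seed = SequenceRecord("seed", planted_world["genome"].residues[2000:4000])
    contig, log = iterate_recruit_assemble(
        seed, planted_world["reads"], planted_world["manifest"])
    return {"contig": contig, "log": log, **planted_world}


@pytest.fixture(scope="session")
def errorfree_world():
    """Error-free 10x tiling of a 2-kb genome (consensus must equal genome)."""
    genome = generate_ancestor(2000, 0.5, seed=4, record_id="g")
    cfg = ReadSimConfig(coverage_per_genome=10, substitution_rate=0.0,
                        homopolymer_indel_rate=0.0, background_read_count=0,
                        seed=5)
    reads, manifest, truth = simulate_reads({"g": genome}, cfg)
    return {"genome": genome, "reads": reads, "manifest": manifest, "truth": truth}


@pytest.fixture(scope="session")
def five_taxon_lineage_world():
    """Two pairs at ~0.97 within-group identity plus one lone genome,
    ~0.70 identity between groups — the three-lineage test community."""
    anc = generate_ancestor(3000, 0.5, seed=1, record_id="anc")
    window = (1200, 1700)
    from virrecruit.synthetic_community import evolve_lineage_windowed
    gA, wA = evolve_lineage_windowed(anc, 0.84, seed=11, record_id="gA", protect=window)
    gB, wB = evolve_lineage_windowed(anc, 0.84, seed=12, record_id="gB", protect=window)
    C = evolve_lineage(anc, 0.84, seed=13, record_id="C", protect=window)
    A1 = evolve_lineage(gA, 0.985, seed=14, record_id="A1", protect=wA)
    A2 = evolve_lineage(gA, 0.985, seed=15, record_id="A2", protect=wA)
    B1 = evolve_lineage(gB, 0.985, seed=16, record_id="B1", protect=wB)
    B2 = evolve_lineage(gB, 0.985, seed=17, record_id="B2", protect=wB)
    return [A1, A2, B1, B2, C]
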