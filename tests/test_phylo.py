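"""HKY85 likelihood machinery, exhaustive ML search, bootstrap, lineages."""

import math
import random

import numpy as np
import pytest

from virrecruit.phylo import (
    BootstrapConfig, HKY85Params, MultipleAlignment, NoConservedBlockError,
    PhyloTree, align_homologs, assign_lineages, bootstrap_supports,
    brute_force_likelihood, enumerate_topologies, extract_conserved_block,
    hky85_transition, ml_search, tree_likelihood,
)
from virrecruit.recruit import global_align_identity
from virrecruit.seq_core import SequenceRecord
from virrecruit.synthetic_community import evolve_lineage, generate_ancestor


def _simulate_on_tree(tree, params, n_sites, rng):
    """Independent HKY85 sequence simulator used to test estimator recovery."""
    pi = np.array(params.base_freqs)
    seqs = {}

    def walk(node, parent_states):
        if node == tree.root:
            states = rng.choice(4, size=n_sites, p=pi)
        else:
            P = hky85_transition(params, tree.edge_lengths[node])
            states = np.array([rng.choice(4, p=P[s]) for s in parent_states])
        if node in tree.leaf_taxon:
            seqs[tree.leaf_taxon[node]] = "".join("ACGT"[s] for s in states)
        else:
            for child in tree.children[node]:
                walk(child, states)

    walk(tree.root, None)
    return seqs


class TestAlignHomologs:
    def test_identical_pair_gap_free(self):
        g = generate_ancestor(500, 0.5, seed=1, record_id="a")
        msa = align_homologs([g, SequenceRecord("b", g.residues)])
        assert msa.rows[0] == msa.rows[1]
        assert "-" not in msa.rows[0]

    def test_alignment_identity_close_to_planted(self):
        g = generate_ancestor(1500, 0.5, seed=2, record_id="a")
        lin = evolve_lineage(g, 0.9, seed=3, record_id="b")
        msa = align_homologs([g, lin])
        matches = sum(1 for x, y in zip(*msa.rows) if x == y and x != "-")
        cols = sum(1 for x, y in zip(*msa.rows) if not (x == "-" and y == "-"))
        assert abs(matches / cols - 0.9) <= 0.03

    def test_columns_at_least_longest_input(self, five_taxon_lineage_world):
        msa = align_homologs(five_taxon_lineage_world)
        assert msa.n_columns >= max(len(s.residues) for s in five_taxon_lineage_world)
        assert len(msa.taxa) == 5

    def test_single_sequence_rejected(self):
        with pytest.raises(ValueError):
            align_homologs([SequenceRecord("a", "ACGT")])


class TestExtractConservedBlock:
    def test_gap_free_alignment_is_whole_block(self):
        g = generate_ancestor(500, 0.5, seed=4, record_id="a")
        msa = MultipleAlignment(["a", "b"], [g.residues, g.residues])
        block = extract_conserved_block(msa, min_len=100)
        assert (block.start, block.end) == (0, 500)

    def test_central_gap_free_run_of_464(self):
        rng = np.random.default_rng(5)
        core = "".join(rng.choice(list("ACGT"), size=464))
        rows = []
        for i in range(3):
            left = "".join(rng.choice(list("ACGT-"), size=120))
            right = "".join(rng.choice(list("ACGT-"), size=120))
            rows.append(left + core + right)
        msa = MultipleAlignment(["a", "b", "c"], rows)
        block = extract_conserved_block(msa, min_len=100)
        assert block.length_nt >= 464
        assert core in msa.rows[0][block.start : block.end]

    def test_all_gappy_alignment_errors(self):
        msa = MultipleAlignment(["a", "b"], ["A-" * 100, "-C" * 100])
        with pytest.raises(NoConservedBlockError):
            extract_conserved_block(msa, min_len=50)


class TestHky85Transition:
    def test_t_zero_is_identity(self):
        P = hky85_transition(HKY85Params(kappa=3.0), 0.0)
        assert np.allclose(P, np.eye(4), atol=1e-12)

    def test_jukes_cantor_nesting(self):
        t = 0.37
        P = hky85_transition(HKY85Params(kappa=1.0), t)
        jc_same = 0.25 + 0.75 * math.exp(-4 * t / 3)
        assert np.allclose(np.diag(P), jc_same, atol=1e-12)

    def test_long_time_reaches_stationarity(self):
        pi = (0.1, 0.2, 0.3, 0.4)
        P = hky85_transition(HKY85Params(kappa=4.0, base_freqs=pi), 50.0)
        assert np.allclose(P, np.tile(pi, (4, 1)), atol=1e-8)

    def test_rows_sum_and_detailed_balance(self):
        pi = np.array([0.15, 0.25, 0.35, 0.25])
        P = hky85_transition(HKY85Params(kappa=2.5, base_freqs=tuple(pi)), 0.8)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)
        flux = pi[:, None] * P
        assert np.allclose(flux, flux.T, atol=1e-12)

    def test_invalid_pi_rejected(self):
        with pytest.raises(ValueError):
            HKY85Params(base_freqs=(0.5, 0.5, 0.0, 0.0))


class TestTreeLikelihood:
    def test_two_taxon_closed_form(self):
        """Pruning equals the closed-form pairwise likelihood
        Σ_sites log Σ_i π_i P_i,x P_i,y for two taxa."""
        rng = np.random.default_rng(6)
        taxa = ["a", "b", "c"]
        topo = enumerate_topologies(taxa)[0]
        params = HKY85Params(kappa=3.0, base_freqs=(0.3, 0.2, 0.3, 0.2))
        # make c uninformative (all N) so only the a–b pair contributes
        sa = "".join(rng.choice(list("ACGT"), size=40))
        sb = "".join(rng.choice(list("ACGT"), size=40))
        msa = MultipleAlignment(taxa, [sa, sb, "N" * 40])
        ll = tree_likelihood(msa, topo, params)
        idx = {b: i for i, b in enumerate("ACGT")}
        # on the 3-taxon star, a and b connect through the root
        ta = topo.edge_lengths[[n for n, t in topo.leaf_taxon.items() if t == "a"][0]]
        tb = topo.edge_lengths[[n for n, t in topo.leaf_taxon.items() if t == "b"][0]]
        Pa = hky85_transition(params, ta)
        Pb = hky85_transition(params, tb)
        pi = np.array(params.base_freqs)
        expected = sum(
            math.log(sum(pi[i] * Pa[i, idx[x]] * Pb[i, idx[y]] for i in range(4)))
            for x, y in zip(sa, sb))
        assert ll == pytest.approx(expected, abs=1e-8)

    def test_pruning_equals_state_enumeration(self):
        rng = random.Random(7)
        taxa = ["a", "b", "c", "d", "e"]
        topo = enumerate_topologies(taxa)[4]
        for e in topo.edge_lengths:
            topo.edge_lengths[e] = 0.05 + 0.07 * (e % 4)
        rows = ["".join(rng.choice("ACGT") for _ in range(8)) for _ in taxa]
        msa = MultipleAlignment(taxa, rows)
        params = HKY85Params(kappa=2.0, base_freqs=(0.3, 0.2, 0.3, 0.2))
        assert tree_likelihood(msa, topo, params) == pytest.approx(
            brute_force_likelihood(msa, topo, params), abs=1e-8)

    def test_duplicated_columns_double_loglik(self):
        rng = random.Random(8)
        taxa = ["a", "b", "c", "d"]
        topo = enumerate_topologies(taxa)[1]
        rows = ["".join(rng.choice("ACGT") for _ in range(30)) for _ in taxa]
        params = HKY85Params(kappa=2.0)
        ll1 = tree_likelihood(MultipleAlignment(taxa, rows), topo, params)
        ll2 = tree_likelihood(MultipleAlignment(taxa, [r * 2 for r in rows]),
                              topo, params)
        assert ll2 == pytest.approx(2 * ll1, rel=1e-10)

    def test_rerooting_invariance(self):
        """The unrooted likelihood does not depend on which internal node
        serves as the pruning root."""
        from virrecruit.phylo import _tuple_to_tree
        t1 = _tuple_to_tree(("node", 0, 1, ("node", 2, 3)), ["a", "b", "c", "d"])
        t2 = _tuple_to_tree(("node", 2, 3, ("node", 0, 1)), ["a", "b", "c", "d"])
        # same unrooted tree: terminal lengths equal, one internal edge 0.2
        for t in (t1, t2):
            for node, taxon in t.leaf_taxon.items():
                t.edge_lengths[node] = {"a": 0.05, "b": 0.1, "c": 0.15, "d": 0.2}[taxon]
            internal = [n for n in t.edge_lengths if n not in t.leaf_taxon]
            t.edge_lengths[internal[0]] = 0.2
        rng = random.Random(9)
        rows = ["".join(rng.choice("ACGT") for _ in range(60)) for _ in range(4)]
        msa = MultipleAlignment(["a", "b", "c", "d"], rows)
        params = HKY85Params(kappa=3.0)
        assert tree_likelihood(msa, t1, params) == pytest.approx(
            tree_likelihood(msa, t2, params), abs=1e-8)


class TestEnumerateTopologies:
    @pytest.mark.parametrize("n,count", [(3, 1), (4, 3), (5, 15), (6, 105)])
    def test_counts(self, n, count):
        taxa = [f"t{i}" for i in range(n)]
        topos = enumerate_topologies(taxa)
        assert len(topos) == count
        # all topologies distinct by bipartition sets
        keys = {frozenset(t.internal_bipartitions().values()) for t in topos}
        assert len(keys) == count if n > 3 else True

    def test_edge_count(self):
        topo = enumerate_topologies(["a", "b", "c", "d", "e"])[0]
        assert topo.n_edges() == 2 * 5 - 3


class TestMlSearch:
    def test_three_taxa_single_topology(self):
        rng = np.random.default_rng(10)
        taxa = ["a", "b", "c"]
        true = enumerate_topologies(taxa)[0]
        for e in true.edge_lengths:
            true.edge_lengths[e] = 0.1
        seqs = _simulate_on_tree(true, HKY85Params(kappa=4.0), 500, rng)
        best = ml_search(MultipleAlignment(taxa, [seqs[t] for t in taxa]))
        assert best.log_likelihood is not None
        assert set(best.leaf_taxon.values()) == set(taxa)

    def test_optimised_likelihood_beats_generating_parameters(self):
        rng = np.random.default_rng(11)
        taxa = ["a", "b", "c", "d"]
        true = enumerate_topologies(taxa)[0]
        for e in true.edge_lengths:
            true.edge_lengths[e] = 0.1 if e not in true.leaf_taxon else 0.05
        params = HKY85Params(kappa=4.0)
        seqs = _simulate_on_tree(true, params, 1000, rng)
        msa = MultipleAlignment(taxa, [seqs[t] for t in taxa])
        best = ml_search(msa)
        assert best.log_likelihood >= tree_likelihood(msa, true, params) - 1e-6

    def test_too_many_taxa_rejected(self):
        taxa = [f"t{i}" for i in range(9)]
        msa = MultipleAlignment(taxa, ["ACGT" * 10] * 9)
        with pytest.raises(ValueError):
            ml_search(msa)


class TestBootstrapAndLineages:
    def test_identical_sequences_no_resolved_edges(self):
        msa = MultipleAlignment(["a", "b", "c", "d"], ["ACGTTGCA" * 20] * 4)
        tree = bootstrap_supports(msa, BootstrapConfig(replicates=10, seed=0))
        assert tree.supports == {}
        # with no qualifying edges every taxon is its own lineage
        lineages = assign_lineages(tree)
        assert len(set(lineages.values())) == 4

    def test_bootstrap_deterministic_under_seed(self, five_taxon_lineage_world):
        msa = align_homologs(five_taxon_lineage_world)
        block = extract_conserved_block(msa, min_len=100)
        bm = msa.slice(block.start, block.end)
        t1 = bootstrap_supports(bm, BootstrapConfig(replicates=25, seed=3))
        t2 = bootstrap_supports(bm, BootstrapConfig(replicates=25, seed=3))
        assert t1.supports == t2.supports
        assert t1.newick() == t2.newick()

    def test_newick_roundtrip_via_dendropy(self, five_taxon_lineage_world):
        msa = align_homologs(five_taxon_lineage_world)
        block = extract_conserved_block(msa, min_len=100)
        tree = ml_search(msa.slice(block.start, block.end))
        dtree = tree.to_dendropy()
        assert {l.taxon.label for l in dtree.leaf_node_iter()} == set(tree.taxa)

    def test_lineage_relabeling_invariance(self):
        """Renaming taxa permutes the partition but keeps its shape."""
        from virrecruit.phylo import _tuple_to_tree
        tree = _tuple_to_tree(("node", ("node", 0, 1), ("node", 2, 3), 4),
                              ["A1", "A2", "B1", "B2", "C"])
        internals = [n for n in tree.edge_lengths if n not in tree.leaf_taxon]
        for n in internals:
            tree.edge_lengths[n] = 0.3
        tree.supports = {bip: 100.0 for bip in tree.internal_bipartitions().values()}
        part1 = assign_lineages(tree)
        relabel = {"A1": "x1", "A2": "x2", "B1": "y1", "B2": "y2", "C": "z"}
        tree2 = _tuple_to_tree(("node", ("node", 0, 1), ("node", 2, 3), 4),
                               [relabel[t] for t in ["A1", "A2", "B1", "B2", "C"]])
        for n in internals:
            tree2.edge_lengths[n] = 0.3
        tree2.supports = {bip: 100.0 for bip in tree2.internal_bipartitions().values()}
        part2 = assign_lineages(tree2)
        groups1 = sorted(sorted(relabel[t] for t in part1 if part1[t] == lab)
                         for lab in set(part1.values()))
        groups2 = sorted(sorted(t for t in part2 if part2[t] == lab)
                         for lab in set(part2.values()))
        assert groups1 == groups2

    def test_reference_named_lineages(self):
        from virrecruit.phylo import _tuple_to_tree
        tree = _tuple_to_tree(("node", ("node", 0, 1), ("node", 2, 3), 4),
                              ["ref1", "c1", "ref2", "c2", "c3"])
        for n in [n for n in tree.edge_lengths if n not in tree.leaf_taxon]:
            tree.edge_lengths[n] = 0.3
        tree.supports = {bip: 100.0 for bip in tree.internal_bipartitions().values()}
        lineages = assign_lineages(tree, reference_ids=["ref1", "ref2"])
        assert lineages["c1"] == "lineage_ref1"
        assert lineages["c2"] == "lineage_ref2"
        assert lineages["ref1"] == "lineage_ref1"
        assert len(set(lineages.values())) == 3
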