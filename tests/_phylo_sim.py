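"""Independent HKY85 sequence simulator for estimator-recovery tests.

Simulates states down a tree directly from the transition matrices — a
separate route from the likelihood machinery it is used to test.
"""

import numpy as np

from virrecruit.phylo import PhyloTree, HKY85Params, hky85_transition


def simulate_on_tree(tree: PhyloTree, params: HKY85Params, n_sites: int,
                     rng: np.random.Generator) -> dict[str, str]:
    pi = np.array(params.base_freqs)
    seqs: dict[str, str] = {}

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
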