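"""HKY85 maximum-likelihood phylogeny over a conserved alignment block.

The tree search is *exhaustive*: all unrooted binary topologies are
enumerated (1, 3, 15, 105 for 3–6 taxa), branch lengths and the
transition/transversion ratio κ are optimised per topology by cyclic
bracketed 1-D maximisation, and the highest-likelihood tree wins — exact and
deterministic in the ≤ 8-taxon regime this package targets.  Likelihoods are
computed by Felsenstein pruning with site-pattern compression; base
frequencies π are the observed frequencies of the block.

Bootstrap supports resample alignment columns with replacement, re-run the
full search per replicate, and report for each internal edge of the ML tree
the percentage of replicates whose best tree contains the same bipartition.
Lineages are the maximal clades obtained by cutting internal edges that are
both well supported and long.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from . import _align
from .recruit import IDENTITY_SCORING, ScoringScheme, global_align_identity
from .seq_core import SequenceRecord

logger = logging.getLogger(__name__)

_STATES = "ACGT"
_STATE_IDX = {b: i for i, b in enumerate(_STATES)}


class NoConservedBlockError(ValueError):
    """The alignment contains no qualifying gap-free conserved block."""


# ---------------------------------------------------------------------------
# alignment containers


@dataclass
class MultipleAlignment:
    """Aligned rows of equal length over ``{A,C,G,T,N,-}``."""

    taxa: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise ValueError("taxa/rows length mismatch")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("rows must have equal length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def slice(self, start: int, end: int) -> "MultipleAlignment":
        return MultipleAlignment(list(self.taxa), [r[start:end] for r in self.rows])


@dataclass(frozen=True)
class ConservedBlock:
    start: int
    end: int

    @property
    def length_nt(self) -> int:
        return self.end - self.start


@dataclass
class HKY85Params:
    """κ, base frequencies, and optionally per-edge branch lengths."""

    kappa: float = 2.0
    base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    branch_lengths: list[float] | None = None

    def __post_init__(self) -> None:
        pi = np.asarray(self.base_freqs, dtype=float)
        if pi.min() <= 0 or abs(pi.sum() - 1) > 1e-8:
            raise ValueError("base_freqs must be positive and sum to 1")
        if self.kappa < 0:
            raise ValueError("kappa must be ≥ 0")


@dataclass
class BootstrapConfig:
    replicates: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be ≥ 1")


# ---------------------------------------------------------------------------
# progressive alignment and conserved block


def _pairwise_merge(profile: list[str], seq: str, scoring: ScoringScheme) -> list[str]:
    """Align a sequence to a profile via the profile's gapped consensus."""
    cons_chars = []
    for col in range(len(profile[0])):
        col_chars = [r[col] for r in profile]
        counts = {}
        for c in col_chars:
            counts[c] = counts.get(c, 0) + 1
        cons_chars.append(sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0][0])
    consensus = "".join(c if c != "-" else "N" for c in cons_chars)
    path = _align.global_align(consensus, seq, scoring.match, scoring.mismatch,
                               scoring.gap_open, scoring.gap_extend)
    new_profile = [[] for _ in profile]
    new_row: list[str] = []
    prof_col = 0
    # re-inflate end gaps trimmed by the path: handle leading segment
    def emit_profile_col(c: int) -> None:
        for out, row in zip(new_profile, profile):
            out.append(row[c])

    for c in range(path.a_start):
        emit_profile_col(c)
        new_row.append("-")
    for ca, cb in zip(path.aligned_a, path.aligned_b):
        if ca == "-":
            for out in new_profile:
                out.append("-")
            new_row.append(cb)
        elif cb == "-":
            emit_profile_col(path.a_start + prof_col)
            prof_col += 1
            new_row.append("-")
        else:
            emit_profile_col(path.a_start + prof_col)
            prof_col += 1
            new_row.append(cb)
    for c in range(path.a_start + prof_col, len(profile[0])):
        emit_profile_col(c)
        new_row.append("-")
    # any unaligned sequence ends
    lead = seq[: path.b_start]
    tail = seq[path.b_end :]
    rows = ["".join(r) for r in new_profile]
    if lead:
        rows = ["-" * len(lead) + r for r in rows]
        new_row = list(lead) + new_row
    if tail:
        rows = [r + "-" * len(tail) for r in rows]
        new_row = new_row + list(tail)
    return rows + ["".join(new_row)]


def align_homologs(sequences: Sequence[SequenceRecord],
                   scoring: ScoringScheme | None = None) -> MultipleAlignment:
    """Deterministic progressive multiple alignment (most similar pair first).

    Defaults to the stiff-gap identity scoring: soft gap penalties let the
    aligner scatter spurious gaps through diverged regions, which would break
    up genuinely gap-free conserved runs.
    """
    if len(sequences) < 2:
        raise ValueError("need at least 2 sequences to align")
    scoring = scoring or IDENTITY_SCORING
    ids = [s.id for s in sequences]
    seqs = {s.id: s.residues for s in sequences}
    sims: dict[tuple[str, str], float] = {}
    for a, b in itertools.combinations(sorted(ids), 2):
        pct, _, _ = global_align_identity(seqs[a], seqs[b])
        sims[(a, b)] = pct
    (first, second), _ = sorted(sims.items(), key=lambda kv: (-kv[1], kv[0]))[0]
    order = [first, second]
    remaining = [i for i in sorted(ids) if i not in order]
    while remaining:
        def best_sim(x: str) -> float:
            return max(sims[tuple(sorted((x, o)))] for o in order)
        remaining.sort(key=lambda x: (-best_sim(x), x))
        order.append(remaining.pop(0))

    path = _align.global_align(seqs[order[0]], seqs[order[1]], scoring.match,
                               scoring.mismatch, scoring.gap_open, scoring.gap_extend)
    # global alignment: re-attach trimmed end gaps explicitly
    a, b = seqs[order[0]], seqs[order[1]]
    row_a = ("-" * path.b_start) + a[: path.a_start] + path.aligned_a \
        + a[path.a_end :] + "-" * (len(b) - path.b_end)
    row_b = b[: path.b_start] + "-" * path.a_start + path.aligned_b \
        + "-" * (len(a) - path.a_end) + b[path.b_end :]
    profile = [row_a, row_b]
    for taxon in order[2:]:
        profile = _pairwise_merge(profile, seqs[taxon], scoring)
    return MultipleAlignment(order, profile)


def extract_conserved_block(msa: MultipleAlignment, min_len: int = 100,
                            block_identity_min: float = 0.5) -> ConservedBlock:
    """Longest gap-free column run with mean column identity ≥ the threshold.

    Column identity is the fraction of rows matching the column's majority
    base.  Raises :class:`NoConservedBlockError` when no gap-free run of at
    least ``min_len`` columns qualifies.
    """
    n_rows = len(msa.rows)
    n_cols = msa.n_columns
    gap_free = [all(r[c] != "-" for r in msa.rows) for c in range(n_cols)]
    runs: list[tuple[int, int]] = []
    start = None
    for c in range(n_cols + 1):
        if c < n_cols and gap_free[c]:
            if start is None:
                start = c
        elif start is not None:
            runs.append((start, c))
            start = None
    best: tuple[int, int] | None = None
    for s, e in runs:
        if e - s < min_len:
            continue
        ident = 0.0
        for c in range(s, e):
            col = [r[c] for r in msa.rows]
            top = max(col.count(b) for b in set(col))
            ident += top / n_rows
        if ident / (e - s) < block_identity_min:
            continue
        if best is None or (e - s) > (best[1] - best[0]):
            best = (s, e)
    if best is None:
        raise NoConservedBlockError(
            f"no gap-free block of ≥ {min_len} columns at identity ≥ {block_identity_min}")
    return ConservedBlock(*best)


# ---------------------------------------------------------------------------
# HKY85 transition probabilities


def _hky_rate_matrix(kappa: float, pi: np.ndarray) -> np.ndarray:
    Q = np.empty((4, 4))
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            transition = (i, j) in ((0, 2), (2, 0), (1, 3), (3, 1))  # A<->G, C<->T
            Q[i, j] = (kappa if transition else 1.0) * pi[j]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -(pi * np.diag(Q)).sum()  # expected substitutions per unit time
    return Q / mu


_EIGEN_CACHE: dict[tuple, tuple] = {}


def _hky_eigen(kappa: float, pi: np.ndarray):
    key = (float(kappa), tuple(np.round(np.asarray(pi, dtype=float), 12)))
    cached = _EIGEN_CACHE.get(key)
    if cached is not None:
        return cached
    Q = _hky_rate_matrix(kappa, pi)
    # symmetrise: S = diag(sqrt(pi)) Q diag(1/sqrt(pi)) has real eigensystem
    sq = np.sqrt(pi)
    S = (sq[:, None] * Q) / sq[None, :]
    w, U = np.linalg.eigh((S + S.T) / 2)
    left = U.T * sq[None, :]
    right = U / sq[:, None]
    if len(_EIGEN_CACHE) > 4096:  # bootstrap replicates churn kappa values
        _EIGEN_CACHE.clear()
    _EIGEN_CACHE[key] = (w, right, left)
    return w, right, left  # P(t) = right @ diag(exp(w t)) @ left


def hky85_transition(params: HKY85Params, t: float) -> np.ndarray:
    """HKY85 transition probability matrix P(t), rows indexed A,C,G,T.

    Branch length ``t`` is in expected substitutions per site.  Rows sum to 1
    and detailed balance ``π_i P_ij = π_j P_ji`` holds.
    """
    if t < 0:
        raise ValueError("t must be ≥ 0")
    pi = np.asarray(params.base_freqs, dtype=float)
    w, right, left = _hky_eigen(params.kappa, pi)
    P = (right * np.exp(w * t)[None, :]) @ left
    P = np.maximum(P, 0.0)
    P /= P.sum(axis=1, keepdims=True)
    return P


# ---------------------------------------------------------------------------
# trees


@dataclass
class PhyloTree:
    """Unrooted binary tree with branch lengths and optional bootstrap supports.

    Internally rooted at ``root`` (an internal node of degree 3) for pruning;
    ``children`` maps node → child nodes, ``edge_lengths`` maps node → length
    of the edge to its parent.  Leaves carry taxon names.
    """

    taxa: list[str]
    children: dict[int, tuple[int, ...]]
    edge_lengths: dict[int, float]
    root: int
    leaf_taxon: dict[int, str]
    log_likelihood: float | None = None
    supports: dict[frozenset, float] = field(default_factory=dict)
    kappa: float | None = None
    base_freqs: tuple[float, float, float, float] | None = None

    def n_edges(self) -> int:
        return len(self.edge_lengths)

    def leaf_sets(self) -> dict[int, frozenset]:
        """Taxon set below each node (relative to the pruning root)."""
        sets: dict[int, frozenset] = {}

        def walk(node: int) -> frozenset:
            if node in self.leaf_taxon:
                sets[node] = frozenset([self.leaf_taxon[node]])
            else:
                sets[node] = frozenset().union(*(walk(c) for c in self.children[node]))
            return sets[node]

        walk(self.root)
        return sets

    def internal_bipartitions(self) -> dict[int, frozenset]:
        """Internal (non-root, non-leaf) nodes → canonical bipartition key."""
        sets = self.leaf_sets()
        all_taxa = frozenset(self.taxa)
        out = {}
        for node, below in sets.items():
            if node == self.root or node in self.leaf_taxon:
                continue
            side = below if min(below) <= min(all_taxa - below) else all_taxa - below
            if 1 < len(below) < len(all_taxa) - 1:
                out[node] = frozenset((below, all_taxa - below))
        return out

    def newick(self, with_supports: bool = True) -> str:
        def fmt(node: int) -> str:
            if node in self.leaf_taxon:
                return f"{self.leaf_taxon[node]}:{self.edge_lengths[node]:.6f}"
            inner = ",".join(fmt(c) for c in self.children[node])
            label = ""
            if with_supports and self.supports:
                bip = self.internal_bipartitions().get(node)
                if bip is not None and bip in self.supports:
                    label = f"{self.supports[bip]:.0f}"
            if node == self.root:
                return f"({inner}){label};"
            return f"({inner}){label}:{self.edge_lengths[node]:.6f}"

        return fmt(self.root)

    def to_dendropy(self):
        import dendropy
        return dendropy.Tree.get(data=self.newick(), schema="newick")


def enumerate_topologies(taxa: Sequence[str]) -> list[PhyloTree]:
    """All unrooted binary topologies (1, 3, 15, 105 … for 3, 4, 5, 6 taxa).

    Built by stepwise addition: each new taxon is grafted onto every edge of
    every partial topology, in deterministic order.
    """
    taxa = list(taxa)
    if len(taxa) < 3:
        raise ValueError("need ≥ 3 taxa")
    # tree encoding during enumeration: nested tuples of taxon indices
    base = ("node", 0, 1, 2)

    def graft_all(tree, new_leaf):
        """Yield trees with new_leaf attached to every edge of `tree`."""
        # edges are addressed by path positions; rebuild recursively
        def rec(sub):
            # returns list of (new_subtree_with_graft_inside, ) options plus itself unchanged
            options = []
            if isinstance(sub, tuple):
                kids = sub[1:]
                for idx, kid in enumerate(kids):
                    # graft on the edge above kid
                    grafted = ("node", kid, new_leaf)
                    options.append(tuple([*sub[:1 + idx], grafted, *sub[2 + idx:]]))
                    for alt in rec(kid):
                        options.append(tuple([*sub[:1 + idx], alt, *sub[2 + idx:]]))
            return options

        return rec(tree)

    trees = [base]
    for leaf in range(3, len(taxa)):
        trees = [t2 for t in trees for t2 in graft_all(t, leaf)]

    out = []
    for t in trees:
        out.append(_tuple_to_tree(t, taxa))
    return out


def _tuple_to_tree(tup, taxa: list[str], default_bl: float = 0.1) -> PhyloTree:
    children: dict[int, tuple[int, ...]] = {}
    edge_lengths: dict[int, float] = {}
    leaf_taxon: dict[int, str] = {}
    counter = [len(taxa)]  # internal node ids start after leaves

    def build(sub) -> int:
        if isinstance(sub, int):
            leaf_taxon[sub] = taxa[sub]
            edge_lengths[sub] = default_bl
            return sub
        node = counter[0]
        counter[0] += 1
        kids = tuple(build(k) for k in sub[1:])
        children[node] = kids
        edge_lengths[node] = default_bl
        return node

    root = build(tup)
    del edge_lengths[root]  # root of the unrooted representation has no parent edge
    return PhyloTree(taxa=list(taxa), children=children, edge_lengths=edge_lengths,
                     root=root, leaf_taxon=leaf_taxon)


# ---------------------------------------------------------------------------
# likelihood


def _compress_patterns(msa_block: MultipleAlignment) -> tuple[np.ndarray, np.ndarray]:
    cols = np.array([list(r) for r in msa_block.rows]).T  # columns × taxa
    uniq, counts = np.unique(cols, axis=0, return_counts=True)
    return uniq, counts.astype(float)


def _leaf_partials(chars: np.ndarray) -> np.ndarray:
    """(patterns × 4) partials for one leaf; N/- are missing data (all ones)."""
    P = np.zeros((len(chars), 4))
    for i, c in enumerate(chars):
        idx = _STATE_IDX.get(c)
        if idx is None:
            P[i, :] = 1.0
        else:
            P[i, idx] = 1.0
    return P


def tree_likelihood(msa_block: MultipleAlignment, tree: PhyloTree,
                    params: HKY85Params) -> float:
    """Log-likelihood of the block under HKY85 by Felsenstein pruning.

    Identical site patterns are computed once and weighted; ``N`` (and any
    non-ACGT symbol) is treated as missing data.
    """
    patterns, weights = _compress_patterns(msa_block)
    taxon_col = {t: i for i, t in enumerate(msa_block.taxa)}
    leaf_parts = {
        leaf: _leaf_partials(patterns[:, taxon_col[taxon]])
        for leaf, taxon in tree.leaf_taxon.items()
    }
    return _loglik_from_parts(tree, params, leaf_parts, weights)


def _loglik_from_parts(tree: PhyloTree, params: HKY85Params,
                       leaf_parts: Mapping[int, np.ndarray], weights: np.ndarray) -> float:
    pi = np.asarray(params.base_freqs)
    w, right, left = _hky_eigen(params.kappa, pi)

    def pmat(t: float) -> np.ndarray:
        P = (right * np.exp(w * t)[None, :]) @ left
        return np.maximum(P, 1e-300)

    scale_log = np.zeros(len(weights))

    def partial(node: int) -> np.ndarray:
        if node in tree.leaf_taxon:
            return leaf_parts[node]
        part = np.ones_like(next(iter(leaf_parts.values())))
        for child in tree.children[node]:
            child_part = partial(child)
            P = pmat(tree.edge_lengths[child])
            part = part * (child_part @ P.T)
        mx = part.max(axis=1)
        mx = np.where(mx > 0, mx, 1.0)
        nonlocal scale_log
        scale_log = scale_log + np.log(mx)
        return part / mx[:, None]

    root_part = partial(tree.root)
    site_lik = root_part @ pi
    site_lik = np.maximum(site_lik, 1e-300)
    return float(np.sum(weights * (np.log(site_lik) + scale_log)))


def brute_force_likelihood(msa_block: MultipleAlignment, tree: PhyloTree,
                           params: HKY85Params) -> float:
    """Oracle: sum over all internal-node state assignments (4^k per site)."""
    pi = np.asarray(params.base_freqs)
    internals = sorted(tree.children)
    Pm = {n: hky85_transition(params, tree.edge_lengths[n])
          for n in tree.edge_lengths}
    taxon_col = {t: i for i, t in enumerate(msa_block.taxa)}
    total = 0.0
    for col in range(msa_block.n_columns):
        obs = {leaf: msa_block.rows[taxon_col[tax]][col]
               for leaf, tax in tree.leaf_taxon.items()}
        site = 0.0
        for assign in itertools.product(range(4), repeat=len(internals)):
            states = dict(zip(internals, assign))
            p = pi[states[tree.root]]
            for parent, kids in tree.children.items():
                for kid in kids:
                    if kid in tree.leaf_taxon:
                        c = obs[kid]
                        if c in _STATE_IDX:
                            p *= Pm[kid][states[parent], _STATE_IDX[c]]
                        # missing data: sum over states = 1, multiply by 1
                    else:
                        p *= Pm[kid][states[parent], states[kid]]
            site += p
        total += math.log(site)
    return total


# ---------------------------------------------------------------------------
# ML search and bootstrap


def _observed_freqs(msa_block: MultipleAlignment) -> tuple[float, float, float, float]:
    counts = np.zeros(4)
    for row in msa_block.rows:
        for c in row:
            if c in _STATE_IDX:
                counts[_STATE_IDX[c]] += 1
    counts = np.maximum(counts, 1.0)
    freqs = counts / counts.sum()
    return tuple(freqs)


def _optimise_tree(tree: PhyloTree, leaf_parts, weights, pi,
                   kappa0: float, optimise_kappa: bool,
                   tol: float = 1e-6, max_rounds: int = 8,
                   xatol: float = 1e-6) -> tuple[float, float]:
    """Cyclic single-branch + κ optimisation; returns (loglik, kappa)."""
    kappa = kappa0
    params = HKY85Params(kappa=kappa, base_freqs=pi)
    edges = sorted(tree.edge_lengths)
    cur = _loglik_from_parts(tree, params, leaf_parts, weights)
    for _ in range(max_rounds):
        prev = cur
        for edge in edges:
            def neg(bl: float, edge=edge) -> float:
                tree.edge_lengths[edge] = bl
                return -_loglik_from_parts(tree, params, leaf_parts, weights)
            res = minimize_scalar(neg, bounds=(1e-8, 10.0), method="bounded",
                                  options={"xatol": xatol})
            tree.edge_lengths[edge] = float(res.x)
            cur = -res.fun
        if optimise_kappa:
            def negk(kap: float) -> float:
                p = HKY85Params(kappa=kap, base_freqs=pi)
                return -_loglik_from_parts(tree, p, leaf_parts, weights)
            res = minimize_scalar(negk, bounds=(0.05, 100.0), method="bounded",
                                  options={"xatol": 1e-4})
            kappa = float(res.x)
            params = HKY85Params(kappa=kappa, base_freqs=pi)
            cur = -res.fun
        if cur - prev < tol:
            break
    return cur, kappa


def ml_search(msa_block: MultipleAlignment, kappa0: float = 2.0,
              optimise_kappa: bool = True, refine: bool = True) -> PhyloTree:
    """Exhaustive maximum-likelihood tree search under HKY85 (3–8 taxa).

    π is estimated from observed block frequencies.  Topologies are ranked by
    a rough branch-length pass at fixed κ; the winner is then refined with
    full cyclic branch-length + κ optimisation (tolerance 1e-6).
    Deterministic tie-break by enumeration order.
    """
    n = len(msa_block.taxa)
    if not 3 <= n <= 8:
        raise ValueError("exhaustive search supports 3–8 taxa; use an external "
                         "tool for larger problems")
    pi = _observed_freqs(msa_block)
    patterns, weights = _compress_patterns(msa_block)
    taxon_col = {t: i for i, t in enumerate(msa_block.taxa)}
    best: PhyloTree | None = None
    best_ll = -math.inf
    best_parts = None
    for topo in enumerate_topologies(sorted(msa_block.taxa)):
        leaf_parts = {leaf: _leaf_partials(patterns[:, taxon_col[tax]])
                      for leaf, tax in topo.leaf_taxon.items()}
        ll, _ = _optimise_tree(topo, leaf_parts, weights, pi, kappa0,
                               optimise_kappa=False, tol=1e-3, max_rounds=3,
                               xatol=1e-4)
        if ll > best_ll + 1e-9:
            best_ll = ll
            best = topo
            best_parts = leaf_parts
    assert best is not None
    if refine:
        ll, kappa = _optimise_tree(best, best_parts, weights, pi, kappa0,
                                   optimise_kappa=optimise_kappa)
    else:  # bootstrap replicates only need the winning topology
        ll, kappa = best_ll, kappa0
    best.log_likelihood = ll
    best.kappa = kappa if optimise_kappa else kappa0
    best.base_freqs = pi
    return best


def bootstrap_supports(msa_block: MultipleAlignment,
                       config: BootstrapConfig | None = None,
                       kappa0: float = 2.0) -> PhyloTree:
    """ML tree with bootstrap supports (percent of replicates per bipartition).

    Columns are resampled with replacement per replicate and the exhaustive
    search re-run; deterministic under ``config.seed``.
    """
    config = config or BootstrapConfig()
    best = ml_search(msa_block, kappa0=kappa0)
    if best.kappa:
        kappa0 = best.kappa  # replicates reuse the refined estimate
    # internal edges optimised to (numerically) zero length are unresolved:
    # they carry no signal and get no support value
    target_bips = {bip for node, bip in best.internal_bipartitions().items()
                   if best.edge_lengths[node] > 1e-6}
    if not target_bips:
        return best
    rng = np.random.default_rng(config.seed)
    n_cols = msa_block.n_columns
    counts = {bip: 0 for bip in target_bips}
    for _ in range(config.replicates):
        idx = rng.integers(0, n_cols, size=n_cols)
        rows = ["".join(r[i] for i in idx) for r in msa_block.rows]
        rep = MultipleAlignment(list(msa_block.taxa), rows)
        rep_tree = ml_search(rep, kappa0=kappa0, refine=False)
        rep_bips = set(rep_tree.internal_bipartitions().values())
        for bip in target_bips & rep_bips:
            counts[bip] += 1
    best.supports = {bip: 100.0 * c / config.replicates for bip, c in counts.items()}
    return best


def assign_lineages(tree: PhyloTree, reference_ids: Sequence[str] = (),
                    support_min: float = 70.0,
                    cut_len_min: float = 0.1) -> dict[str, str]:
    """Partition taxa into lineages by the tree's strong, long internal edges.

    An internal edge *qualifies* when its bootstrap support is ≥
    ``support_min`` and its length ≥ ``cut_len_min``; each qualifying edge
    delimits a clade (the smaller side of its bipartition; on a tie, the side
    not containing the alphabetically first taxon).  Taxa are assigned to the
    largest qualifying clade containing them; taxa in none form singleton
    lineages — so a star-like tree with no qualifying edges yields one
    lineage per taxon.  A lineage containing exactly one reference taxon is
    named after it; the rest get deterministic ``lineageN`` labels.
    """
    all_taxa = frozenset(tree.taxa)
    clades: list[frozenset] = []
    for node, bip in tree.internal_bipartitions().items():
        support = tree.supports.get(bip, 100.0 if not tree.supports else 0.0)
        if support < support_min or tree.edge_lengths[node] < cut_len_min:
            continue
        side_a, side_b = sorted(bip, key=lambda s: (len(s), sorted(s)))
        if len(side_a) == len(side_b):
            clade = side_a if min(all_taxa) not in side_a else side_b
        else:
            clade = side_a
        clades.append(clade)
    clades.sort(key=lambda c: (-len(c), sorted(c)))
    groups: list[list[str]] = []
    assigned: set[str] = set()
    for clade in clades:
        fresh = sorted(set(clade) - assigned)
        if fresh and not assigned & set(clade):
            groups.append(fresh)
            assigned.update(fresh)
    for taxon in sorted(all_taxa - assigned):
        groups.append([taxon])
    groups.sort(key=lambda g: g[0])
    ref_set = set(reference_ids)
    labels: dict[str, str] = {}
    n_novel = 0
    for group in groups:
        refs = [t for t in group if t in ref_set]
        if len(refs) == 1:
            name = f"lineage_{refs[0]}"
        else:
            n_novel += 1
            name = f"lineage{n_novel}"
        for taxon in group:
            labels[taxon] = name
    return labels
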