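"""Heuristic maximum-parsimony tree search.

Desk-scale replacement for a "new technology" parsimony run: random
addition sequence starting trees, subtree-pruning-regrafting (SPR) hill
climbing, and a character-reweighting parsimony ratchet to escape local
optima. Equally parsimonious topologies are retained (deduplicated by
bipartition set) up to a configurable cap.

Search trees are kept in rooted-binary form (a degree-2 root marks a
position on an edge of the unrooted tree), which permits exact O(sites)
evaluation of *every* SPR regraft of a pruned subtree at once: with
down-pass state sets ``D`` and up-pass sets ``U`` around an edge, the
set of states insertable on the edge at no extra cost is
``F = D & U`` if non-empty else ``D | U``, and regrafting a subtree
whose root Fitch set is ``R`` costs one extra step per site exactly when
``F & R`` is empty. The same identity scores all attachment points
during stepwise addition. Both shortcuts are property-tested against
full rescoring.

Parsimony-uninformative characters add the same step count to every
topology; the search internally scores informative site patterns only
and adds the invariant offset back into reported scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .treekit import (
    Alignment,
    EncodedMatrix,
    Node,
    Tree,
    TreeError,
    tree_pattern_lengths,
)

__all__ = [
    "SearchConfig",
    "BestTrees",
    "parsimony_score",
    "stepwise_addition",
    "spr_hill_climb",
    "ratchet_search",
]


@dataclass(frozen=True)
class SearchConfig:
    """Ratchet search settings.

    n_starts: random-addition replicates; ratchet_iters: perturbation
    rounds per start (0 = plain multi-start SPR); perturb_fraction:
    fraction of characters up-weighted (x2) during perturbation;
    max_trees: cap on retained equally parsimonious topologies.
    """

    n_starts: int = 2
    ratchet_iters: int = 2
    perturb_fraction: float = 0.25
    max_trees: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        if self.ratchet_iters < 0:
            raise ValueError("ratchet_iters must be >= 0")
        if not 0.0 < self.perturb_fraction < 1.0:
            raise ValueError("perturb_fraction must be in (0, 1)")
        if self.max_trees < 1:
            raise ValueError("max_trees must be >= 1")


@dataclass
class BestTrees:
    """Equally parsimonious topologies at the best score found."""

    trees: list
    score: int


def parsimony_score(tree: Tree, alignment: Alignment) -> int:
    """Total Fitch parsimony length of ``alignment`` on ``tree``."""
    tree_taxa = set(tree.leaf_labels())
    aln_taxa = set(alignment.ids)
    if tree_taxa != aln_taxa:
        diff = sorted(tree_taxa ^ aln_taxa)
        raise TreeError(
            f"tree and alignment taxa differ (symmetric difference "
            f"{diff[:10]}{'...' if len(diff) > 10 else ''})")
    enc = EncodedMatrix.from_alignment(alignment)
    return int((tree_pattern_lengths(tree, enc) * enc.weights).sum())


# ---------------------------------------------------------------------------
# internal machinery on rooted-binary trees
# ---------------------------------------------------------------------------

def _informative_split(enc: EncodedMatrix):
    """(masks, weights, row-lookup, offset) keeping informative patterns.

    ``offset`` is the tree-independent step contribution of variable but
    parsimony-uninformative patterns.
    """
    inf = enc.pattern_max > enc.pattern_min
    offset = int((enc.pattern_min[~inf] * enc.weights[~inf]).sum())
    return enc.masks[:, inf], enc.weights[inf].astype(np.float64), inf, offset


def _combine(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    i = a & b
    return np.where(i == 0, a | b, i)


class _ScoreState:
    """Pattern data shared by one search run."""

    def __init__(self, enc: EncodedMatrix):
        self.taxa = enc.taxa
        self.row = {t: i for i, t in enumerate(enc.taxa)}
        self.masks, self.w, self.inf_mask, self.offset = _informative_split(enc)
        self.enc = enc
        self.P = self.masks.shape[1]

    def leaf_mask(self, label: str) -> np.ndarray:
        return self.masks[self.row[label]]


def _down_pass(root: Node, st: _ScoreState, weights: np.ndarray):
    """Fitch down-pass below ``root``: state sets D, per-pattern steps,
    and the weighted total."""
    nodes: list[Node] = []
    stack = [root]
    while stack:
        n = stack.pop()
        nodes.append(n)
        stack.extend(n.children)
    D: dict[int, np.ndarray] = {}
    steps = np.zeros(st.P, dtype=np.int64)
    for n in reversed(nodes):
        if n.is_leaf:
            D[id(n)] = st.leaf_mask(n.label)
        else:
            a, b = n.children
            da, db = D[id(a)], D[id(b)]
            i = da & db
            miss = i == 0
            D[id(n)] = np.where(miss, da | db, i)
            steps += miss
    return D, steps, float((steps * weights).sum())


def _edge_sets(tree: Tree, st: _ScoreState, weights: np.ndarray):
    """Insertable-state set F for every unrooted edge of ``tree``.

    Returns (edge_nodes, F matrix, weighted length). Edge ``i`` is the
    edge above ``edge_nodes[i]``; the duplicate second root-child edge is
    omitted.
    """
    D, _, total = _down_pass(tree.root, st, weights)
    U: dict[int, np.ndarray] = {}
    order = [n for n in tree.preorder() if n is not tree.root]
    ra, rb = tree.root.children
    U[id(ra)] = D[id(rb)]
    U[id(rb)] = D[id(ra)]
    for n in order:
        p = n.parent
        if p is tree.root:
            continue
        sib = p.children[0] if p.children[1] is n else p.children[1]
        U[id(n)] = _combine(U[id(p)], D[id(sib)])
    edge_nodes = [n for n in order if n is not rb]
    F = np.empty((len(edge_nodes), st.P), dtype=np.uint8)
    for i, n in enumerate(edge_nodes):
        F[i] = _combine(D[id(n)], U[id(n)])
    return edge_nodes, F, total


def _attach_costs(F: np.ndarray, R: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Extra steps from joining a subtree with root set ``R`` on each edge."""
    return ((F & R[None, :]) == 0).dot(weights)


def _resolve_binary(tree: Tree) -> Tree:
    """Copy of ``tree`` in rooted-binary form, lengths dropped.

    A degree-3+ root is regrouped (for degree 3 this preserves the
    unrooted topology; the degree-2 root then marks an edge position).
    Internal polytomies are resolved deterministically by successive
    pairing — a topology refinement, acceptable for a search start.
    """
    out = tree.copy()
    for n in list(out.preorder()):
        n.length = None
        while len(n.children) > 2:
            a = n.children.pop()
            b = n.children.pop()
            sub = Node()
            sub.children = [b, a]
            a.parent = b.parent = sub
            n.add(sub)
    return out


def _detach(tree: Tree, v: Node):
    """Detach subtree ``v`` for SPR; return restore record."""
    w = v.parent
    g = w.parent
    order = list(w.children)
    other = order[0] if order[1] is v else order[1]
    w.children = []
    v.parent = None
    other.parent = None
    if g is None:
        tree.root = other
        idx = None
    else:
        idx = g.children.index(w)
        g.children[idx] = other
        other.parent = g
        w.parent = None
    return (w, g, idx, order, other)


def _restore(tree: Tree, rec) -> None:
    w, g, idx, order, other = rec
    w.children = order
    for c in order:
        c.parent = w
    if g is None:
        w.parent = None
        tree.root = w
    else:
        g.children[idx] = w
        w.parent = g


def _attach(tree: Tree, v: Node, w: Node, u: Node) -> None:
    """Re-insert subtree ``v`` (with spare node ``w``) on the edge above ``u``."""
    p = u.parent
    idx = p.children.index(u)
    w.children = [u, v]
    u.parent = w
    v.parent = w
    w.parent = p
    p.children[idx] = w


def _tree_score(tree: Tree, st: _ScoreState, weights: np.ndarray) -> float:
    _, _, total = _down_pass(tree.root, st, weights)
    return total


def _spr_sweep(tree: Tree, st: _ScoreState, weights: np.ndarray,
               current: float) -> tuple[float, bool]:
    """One deterministic pass over all prune/regraft moves; improving
    moves are applied immediately (first-improvement per prune)."""
    improved = False
    candidates = [n for n in tree.preorder() if n.parent is not None]
    for v in candidates:
        if v.parent is None:  # became root after an earlier move
            continue
        w = v.parent
        other = w.children[0] if w.children[1] is v else w.children[1]
        if w.parent is None and other.is_leaf:
            continue  # remaining tree would be a single leaf
        rec = _detach(tree, v)
        D_sub, _, sub_total = _down_pass(v, st, weights)
        edge_nodes, F, rem_total = _edge_sets(tree, st, weights)
        costs = _attach_costs(F, D_sub[id(v)], weights)
        best = int(np.argmin(costs))
        best_score = rem_total + sub_total + float(costs[best])
        if best_score < current - 1e-9:
            _attach(tree, v, rec[0], edge_nodes[best])
            current = best_score
            improved = True
        else:
            _restore(tree, rec)
    return current, improved


def _climb(tree: Tree, st: _ScoreState, weights: np.ndarray,
           max_passes: int = 60) -> float:
    current = _tree_score(tree, st, weights)
    for _ in range(max_passes):
        current, improved = _spr_sweep(tree, st, weights, current)
        if not improved:
            break
    return current


def _stepwise(st: _ScoreState, seed: int) -> Tree:
    taxa = list(st.taxa)
    if len(taxa) < 3:
        raise ValueError("stepwise addition needs at least 3 taxa")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    order = [taxa[i] for i in rng.permutation(len(taxa))]
    root = Node()
    inner = Node()
    root.add(Node(order[0]))
    root.add(inner)
    inner.add(Node(order[1]))
    inner.add(Node(order[2]))
    tree = Tree(root)
    weights = st.w
    for label in order[3:]:
        edge_nodes, F, _ = _edge_sets(tree, st, weights)
        costs = _attach_costs(F, st.leaf_mask(label), weights)
        u = edge_nodes[int(np.argmin(costs))]
        leaf = Node(label)
        w = Node()
        _attach(tree, leaf, w, u)
    return tree


def _bipartition_key(tree: Tree, index: dict) -> frozenset:
    """Hashable unrooted-topology key via leaf-index bitmasks."""
    full = (1 << len(index)) - 1
    below: dict[int, int] = {}
    splits = set()
    for n in tree.postorder():
        if n.is_leaf:
            below[id(n)] = 1 << index[n.label]
        else:
            mask = 0
            for c in n.children:
                mask |= below[id(c)]
            below[id(n)] = mask
            if n.parent is not None:
                splits.add(min(mask, full ^ mask))
    return frozenset(splits)


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def stepwise_addition(alignment: Alignment, seed: int) -> Tree:
    """Random-addition-sequence starting tree.

    Taxa are inserted in a seeded random order, each at the attachment
    edge minimizing the parsimony score (first edge in deterministic
    traversal order on ties). Deterministic given ``seed``.
    """
    if alignment.n_taxa < 3:
        raise ValueError("stepwise addition needs at least 3 taxa")
    st = _ScoreState(EncodedMatrix.from_alignment(alignment))
    return _stepwise(st, seed)


def spr_hill_climb(tree: Tree, alignment: Alignment) -> Tree:
    """SPR hill climbing to a local optimum.

    Returns a tree whose score never exceeds the input's and that no
    single SPR move improves. Polytomies in the input are resolved
    deterministically before climbing.
    """
    st = _ScoreState(EncodedMatrix.from_alignment(alignment))
    work = _resolve_binary(tree)
    _climb(work, st, st.w)
    return work


def _perturbed_weights(st: _ScoreState, fraction: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Up-weight (x2) a random fraction of the informative characters."""
    enc = st.enc
    cols = np.flatnonzero(st.inf_mask[enc.col_to_pattern])
    if cols.size == 0:
        return st.w
    k = max(1, int(round(fraction * cols.size)))
    chosen = rng.choice(cols, size=k, replace=False)
    # map chosen original columns onto informative-pattern indices
    pat_index = np.cumsum(st.inf_mask) - 1
    extra = np.bincount(pat_index[enc.col_to_pattern[chosen]],
                        minlength=st.P)
    return st.w + extra.astype(np.float64)


def ratchet_search(alignment: Alignment, config: SearchConfig) -> BestTrees:
    """Multi-start SPR search with a character-reweighting ratchet.

    Each start climbs from a random-addition tree; every ratchet
    iteration reclimbs under perturbed character weights, then under the
    original weights, accepting the result when not worse. All trees
    attaining the best score are retained (bipartition-deduplicated, up
    to ``max_trees`` with a warning on truncation). Fully reproducible
    given ``config.seed``; per-start seed streams are independent, so
    raising ``n_starts`` never worsens the result.
    """
    st = _ScoreState(EncodedMatrix.from_alignment(alignment))
    index = {t: i for i, t in enumerate(sorted(st.taxa))}
    pool: list[tuple[float, Tree]] = []
    for start in range(config.n_starts):
        start_seed = int(np.random.SeedSequence(
            config.seed, spawn_key=(start, 0)).generate_state(1)[0]
            & 0x7FFFFFFF)
        tree = _stepwise(st, start_seed)
        score = _climb(tree, st, st.w)
        pool.append((score, tree.copy()))
        for it in range(config.ratchet_iters):
            rng = np.random.default_rng(
                np.random.SeedSequence(config.seed,
                                       spawn_key=(start, it + 1)))
            trial = tree.copy()
            _climb(trial, st, _perturbed_weights(
                st, config.perturb_fraction, rng))
            trial_score = _climb(trial, st, st.w)
            pool.append((trial_score, trial.copy()))
            if trial_score <= score:
                tree, score = trial, trial_score
    best = min(s for s, _ in pool)
    seen: set = set()
    trees: list[Tree] = []
    truncated = False
    for s, t in pool:
        if s > best + 1e-9:
            continue
        key = _bipartition_key(t, index)
        if key in seen:
            continue
        if len(trees) >= config.max_trees:
            truncated = True
            break
        seen.add(key)
        trees.append(t)
    if truncated:
        warnings.warn(f"more than max_trees={config.max_trees} equally "
                      "parsimonious topologies; set truncated deterministically")
    return BestTrees(trees=trees, score=int(round(best)) + st.offset)
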