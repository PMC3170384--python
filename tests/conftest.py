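"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the package's own algorithms:
parsimony lengths are brute-forced by enumerating internal-node state
assignments, and search optima by enumerating every unrooted topology.
"""

from __future__ import annotations

import numpy as np
import pytest

from taxonsignal.treekit import CharacterColumn, Node, Tree


# ---------------------------------------------------------------------------
# brute-force parsimony oracle
# ---------------------------------------------------------------------------

def brute_force_fitch(tree: Tree, column: CharacterColumn) -> int:
    """Minimum state changes by exhaustive enumeration of internal-node
    assignments (leaves pick their best state given the parent)."""
    alphabet = list(column.alphabet)
    observed = sorted(set().union(*(column.states[l]
                                    for l in tree.leaf_labels())))
    k = len(observed)
    state_idx = {s: i for i, s in enumerate(observed)}
    nodes = list(tree.postorder())
    internal = [n for n in nodes if not n.is_leaf]
    leaves = [n for n in nodes if n.is_leaf]
    int_idx = {id(n): i for i, n in enumerate(internal)}
    n_int = len(internal)

    n_assign = k ** n_int
    grid = np.array(np.unravel_index(np.arange(n_assign),
                                     (k,) * n_int)).T  # (n_assign, n_int)
    cost = np.zeros(n_assign, dtype=np.int64)
    for n in internal:
        if n.parent is not None:
            cost += grid[:, int_idx[id(n)]] != grid[:, int_idx[id(n.parent)]]
    # leaf edge costs: 1 unless the parent state is in the leaf's set
    member = np.zeros((k, len(leaves)), dtype=bool)
    for j, leaf in enumerate(leaves):
        for s in column.states[leaf.label]:
            if s in state_idx:
                member[state_idx[s], j] = True
    for j, leaf in enumerate(leaves):
        cost += ~member[grid[:, int_idx[id(leaf.parent)]], j]
    return int(cost.min())


# ---------------------------------------------------------------------------
# exhaustive topology enumeration
# ---------------------------------------------------------------------------

def _edges_for_insertion(tree: Tree) -> list[Node]:
    """One node per unrooted edge (skip the duplicate second root child)."""
    order = [n for n in tree.preorder() if n.parent is not None]
    if len(tree.root.children) == 2:
        order = [n for n in order if n is not tree.root.children[1]]
    return order


def _insert_leaf(tree: Tree, edge_child: Node, label: str) -> None:
    parent = edge_child.parent
    mid = Node()
    idx = parent.children.index(edge_child)
    parent.children[idx] = mid
    mid.parent = parent
    mid.children = [edge_child]
    edge_child.parent = mid
    mid.add(Node(label))


def all_unrooted_topologies(labels):
    """Yield every unrooted binary topology on ``labels`` (as rooted
    trees with a degree-2 root). 3->1, 5->15, 6->105, 7->945 trees."""
    labels = list(labels)
    if len(labels) < 3:
        raise ValueError("need >= 3 labels")
    root = Node()
    root.add(Node(labels[0]))
    inner = root.add(Node())
    inner.add(Node(labels[1]))
    inner.add(Node(labels[2]))
    trees = [Tree(root)]
    for label in labels[3:]:
        nxt = []
        for t in trees:
            for i in range(len(_edges_for_insertion(t))):
                clone = t.copy()
                _insert_leaf(clone, _edges_for_insertion(clone)[i], label)
                nxt.append(clone)
        trees = nxt
    yield from trees


def exhaustive_best_score(alignment) -> int:
    """Optimal parsimony score over every topology (small taxon sets)."""
    from taxonsignal.treekit import EncodedMatrix, tree_pattern_lengths
    enc = EncodedMatrix.from_alignment(alignment)
    return min(int((tree_pattern_lengths(t, enc) * enc.weights).sum())
               for t in all_unrooted_topologies(alignment.ids))


# ---------------------------------------------------------------------------
# random instances
# ---------------------------------------------------------------------------

def random_binary_tree(labels, rng: np.random.Generator) -> Tree:
    labels = list(labels)
    root = Node()
    root.add(Node(labels[0]))
    inner = root.add(Node())
    inner.add(Node(labels[1]))
    inner.add(Node(labels[2]))
    tree = Tree(root)
    for label in labels[3:]:
        edges = _edges_for_insertion(tree)
        _insert_leaf(tree, edges[int(rng.integers(len(edges)))], label)
    return tree


def random_multifurcating_tree(labels, rng: np.random.Generator) -> Tree:
    """Random tree with polytomies: contract random internal edges."""
    tree = random_binary_tree(labels, rng)
    for node in list(tree.preorder()):
        if (node.parent is not None and not node.is_leaf
                and rng.random() < 0.35):
            parent = node.parent
            idx = parent.children.index(node)
            parent.children[idx:idx + 1] = node.children
            for c in node.children:
                c.parent = parent
    return tree


def random_alignment(labels, length, rng: np.random.Generator,
                     with_ambiguity: bool = False):
    from taxonsignal.treekit import Alignment
    bases = "ACGT" + ("N-" if with_ambiguity else "")
    probs = None
    if with_ambiguity:
        probs = [0.23, 0.23, 0.23, 0.23, 0.04, 0.04]
    seqs = ["".join(rng.choice(list(bases), size=length, p=probs))
            for _ in labels]
    return Alignment(list(labels), seqs)


def random_binary_column(labels, rng: np.random.Generator) -> CharacterColumn:
    members = [l for l in labels if rng.random() < 0.5]
    if not members:
        members = [list(labels)[0]]
    return CharacterColumn.from_membership(list(labels), members)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def clean_dataset():
    """Small clean (scramble-free) simulated dataset, strong family signal."""
    from taxonsignal.synthdata import SimConfig, generate_dataset
    return generate_dataset(SimConfig(n_families=4, spp_per_family=6,
                                      seq_length=400, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
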