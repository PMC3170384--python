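"""Trees, character columns, alignments and parsimony step counting.

This module provides the data structures shared by the whole package: a
light-weight mutable phylogenetic tree (polytomies allowed), aligned DNA
matrices, single character columns (molecular sites or binary
group-membership characters), and the parsimony machinery on top of them —
minimum steps ``m``, observed Fitch steps ``s``, star-tree maximum steps
``g`` and the ensemble consistency/retention indices CI and RI.

Scoring semantics are *unrooted*: the root of a :class:`Tree` is a
representational convenience and never changes a parsimony length. Step
counting on multifurcating nodes uses Hartigan's count rule (the unit-cost
generalization of Fitch's intersection/union rule), which is exact for
soft polytomies.

Ambiguity handling follows barcode practice: ``-``, ``N`` and ``?`` are
fully missing (any state), other IUPAC codes map to their state subsets.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import dendropy
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "DNA_STATES",
    "BINARY_STATES",
    "Node",
    "Tree",
    "NewickParseError",
    "TreeError",
    "parse_newick",
    "write_newick",
    "read_newick_file",
    "write_newick_file",
    "CharacterColumn",
    "Alignment",
    "EncodedMatrix",
    "fitch_length",
    "min_steps",
    "max_steps",
    "tree_pattern_lengths",
    "ensemble_ci_ri",
    "CiRiResult",
    "detach_clade",
    "insert_on_edge",
]

DNA_STATES = "ACGT"
BINARY_STATES = "01"

#: IUPAC nucleotide codes -> allowed states. Gap and ? are fully missing.
IUPAC_CODES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT", "-": "ACGT", "?": "ACGT",
}


class TreeError(ValueError):
    """Structural problem with a tree or a tree/character mismatch."""


class NewickParseError(ValueError):
    """Malformed Newick input; ``position`` is a 0-based character offset."""

    def __init__(self, message: str, position: int | None = None):
        if position is not None:
            message = f"{message} (position {position})"
        super().__init__(message)
        self.position = position


# ---------------------------------------------------------------------------
# Tree structure
# ---------------------------------------------------------------------------

class Node:
    """A tree node. Leaves carry a taxon label; edges an optional length."""

    __slots__ = ("label", "length", "parent", "children")

    def __init__(self, label: str | None = None, length: float | None = None):
        self.label = label
        self.length = length
        self.parent: "Node | None" = None
        self.children: list["Node"] = []

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({self.label!r}, n_children={len(self.children)})"


class Tree:
    """Rooted representation of a (possibly unrooted) phylogeny.

    Invariants: connected and acyclic by construction; leaf labels unique
    and non-empty; internal nodes have >= 2 children except that a root
    of degree 2 is permitted (it stands for a position on an edge of the
    unrooted tree).
    """

    def __init__(self, root: Node):
        self.root = root

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "Tree":
        return parse_newick(text)

    def copy(self) -> "Tree":
        mapping: dict[int, Node] = {}
        new_root = Node(self.root.label, self.root.length)
        mapping[id(self.root)] = new_root
        for node in self.preorder():
            if node is self.root:
                continue
            clone = Node(node.label, node.length)
            mapping[id(node.parent)].add(clone)
            mapping[id(node)] = clone
        return Tree(new_root)

    # -- traversal ---------------------------------------------------------

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        # iterative to cope with deep caterpillar trees
        out: list[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return reversed(out)

    def leaves(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def __len__(self) -> int:
        return len(self.leaves())

    # -- queries -----------------------------------------------------------

    def mrca(self, labels: Iterable[str]) -> Node:
        """Most recent common ancestor (in the rooted representation)."""
        want = set(labels)
        found = {n.label: n for n in self.leaves() if n.label in want}
        missing = want - set(found)
        if missing:
            raise TreeError(f"labels not in tree: {sorted(missing)}")
        paths = []
        for node in found.values():
            path = []
            while node is not None:
                path.append(node)
                node = node.parent
            paths.append(list(reversed(path)))
        mrca = None
        for level in zip(*paths):
            first = level[0]
            if all(n is first for n in level):
                mrca = first
            else:
                break
        return mrca

    def bipartitions(self) -> frozenset[frozenset[frozenset[str]]]:
        """Non-trivial bipartitions of the leaf set (unrooted splits)."""
        all_leaves = frozenset(self.leaf_labels())
        n = len(all_leaves)
        below: dict[int, frozenset[str]] = {}
        splits = set()
        for node in self.postorder():
            if node.is_leaf:
                below[id(node)] = frozenset([node.label])
            else:
                clade = frozenset().union(*(below[id(c)] for c in node.children))
                below[id(node)] = clade
                if node.parent is not None and 1 < len(clade) < n - 1:
                    splits.add(frozenset([clade, all_leaves - clade]))
        return frozenset(splits)

    # -- mutation ----------------------------------------------------------

    def suppress_unifurcations(self) -> None:
        """Remove internal nodes with a single child, merging edge lengths."""
        changed = True
        while changed:
            changed = False
            for node in list(self.preorder()):
                if not node.is_leaf and len(node.children) == 1:
                    child = node.children[0]
                    if node.length is not None or child.length is not None:
                        child.length = (node.length or 0.0) + (child.length or 0.0)
                    if node.parent is None:
                        child.parent = None
                        self.root = child
                    else:
                        idx = node.parent.children.index(node)
                        node.parent.children[idx] = child
                        child.parent = node.parent
                    changed = True

    def reroot_at_edge(self, node: Node) -> "Tree":
        """Return a copy rerooted on the edge above ``node``.

        The leaf set and bipartition set are preserved; parsimony lengths
        are unaffected (unrooted semantics).
        """
        if node.parent is None:
            return self.copy()
        # map nodes of the copy to mirror the original path
        clone = self.copy()
        # locate the mirrored node by path of child indices
        path = []
        cur = node
        while cur.parent is not None:
            path.append(cur.parent.children.index(cur))
            cur = cur.parent
        target = clone.root
        for idx in reversed(path):
            target = target.children[idx]

        new_root = Node()
        old_parent = target.parent
        old_parent.children.remove(target)
        target.parent = None
        half = None if target.length is None else target.length / 2.0
        target.length = half
        new_root.add(target)

        # reverse the chain from old_parent up to the old root
        prev = new_root
        prev_edge_len = half
        cur = old_parent
        while cur is not None:
            nxt = cur.parent
            edge_len_above_cur = cur.length
            if nxt is not None:
                nxt.children.remove(cur)
            cur.parent = None
            cur.length = prev_edge_len
            prev.add(cur)
            prev = cur
            prev_edge_len = edge_len_above_cur
            cur = nxt
        out = Tree(new_root)
        out.suppress_unifurcations()
        return out

    # -- output ------------------------------------------------------------

    def to_newick(self, lengths: bool = True) -> str:
        return write_newick(self, lengths=lengths)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tree(n_leaves={len(self)})"


def detach_clade(tree: Tree, node: Node) -> Node:
    """Detach ``node`` (leaf or clade) from ``tree``, suppressing the
    resulting unifurcation. Returns the detached node (parent cleared)."""
    parent = node.parent
    if parent is None:
        raise TreeError("cannot detach the root")
    parent.children.remove(node)
    node.parent = None
    if len(parent.children) == 1:
        other = parent.children[0]
        if parent.parent is None:
            other.parent = None
            other.length = None if other.length is None and parent.length is None else (other.length or 0.0)
            tree.root = other
        else:
            if parent.length is not None or other.length is not None:
                other.length = (parent.length or 0.0) + (other.length or 0.0)
            idx = parent.parent.children.index(parent)
            parent.parent.children[idx] = other
            other.parent = parent.parent
    return node


def insert_on_edge(tree: Tree, edge_child: Node, subtree: Node,
                   split: float = 0.5) -> Node:
    """Insert ``subtree`` on the edge above ``edge_child``.

    A new node is created splitting the edge (fraction ``split`` of the
    original length goes below the new node). Returns the new node.
    """
    parent = edge_child.parent
    if parent is None:
        raise TreeError("edge_child has no parent edge")
    mid = Node()
    if edge_child.length is not None:
        mid.length = edge_child.length * (1.0 - split)
        edge_child.length = edge_child.length * split
    idx = parent.children.index(edge_child)
    parent.children[idx] = mid
    mid.parent = parent
    mid.children = [edge_child]
    edge_child.parent = mid
    mid.add(subtree)
    return mid


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

def _check_balance(text: str) -> None:
    depth = 0
    in_quote = False
    for i, ch in enumerate(text):
        if ch == "'":
            in_quote = not in_quote
        elif not in_quote:
            if ch == "(":
                depth += 1
            elif ch == ")":
                depth -= 1
                if depth < 0:
                    raise NewickParseError("unbalanced ')'", i)
    if depth != 0:
        raise NewickParseError(f"{depth} unclosed '('", len(text))


def parse_newick(text: str) -> Tree:
    """Parse one Newick tree. Plain or quoted labels, optional branch
    lengths. Raises :class:`NewickParseError` naming the offending position
    for unbalanced parentheses, duplicate leaf labels or empty input."""
    if not text or not text.strip():
        raise NewickParseError("empty Newick input", 0)
    stripped = text.strip()
    if not stripped.endswith(";"):
        raise NewickParseError("Newick string must end with ';'", len(text) - 1)
    _check_balance(stripped)
    try:
        dtree = dendropy.Tree.get(
            data=stripped,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises various error types
        raise NewickParseError(f"could not parse Newick: {exc}") from None

    def convert(dnode) -> Node:
        label = None
        if dnode.taxon is not None:
            label = dnode.taxon.label
        elif dnode.is_leaf():
            label = dnode.label
        node = Node(label=label, length=dnode.edge.length)
        for dchild in dnode.child_nodes():
            node.add(convert(dchild))
        return node

    import sys
    old_limit = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old_limit, 10000))
    try:
        root = convert(dtree.seed_node)
    finally:
        sys.setrecursionlimit(old_limit)
    tree = Tree(root)
    tree.suppress_unifurcations()
    labels = tree.leaf_labels()
    if any(lab is None or lab == "" for lab in labels):
        raise NewickParseError("tree contains an unlabelled leaf")
    seen: set[str] = set()
    for lab in labels:
        if lab in seen:
            raise NewickParseError(f"duplicate leaf label {lab!r}",
                                   stripped.find(lab))
        seen.add(lab)
    return tree


_PLAIN_LABEL = re.compile(r"^[^\s()\[\]:;,']+$")


def _format_label(label: str) -> str:
    if _PLAIN_LABEL.match(label):
        return label
    return "'" + label.replace("'", "''") + "'"


def write_newick(tree: Tree, lengths: bool = True) -> str:
    """Serialize a tree to Newick. Round-trips the bipartition set."""
    parts: dict[int, str] = {}
    for node in tree.postorder():
        if node.is_leaf:
            s = _format_label(node.label)
        else:
            s = "(" + ",".join(parts[id(c)] for c in node.children) + ")"
        if lengths and node.length is not None and node.parent is not None:
            s += f":{node.length:g}"
        parts[id(node)] = s
    return parts[id(tree.root)] + ";"


def read_newick_file(path) -> list[Tree]:
    """Read Newick trees, one per line (blank lines ignored)."""
    trees = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                trees.append(parse_newick(line))
    return trees


def write_newick_file(trees: Iterable[Tree], path, lengths: bool = True) -> None:
    with open(path, "w") as fh:
        for t in trees:
            fh.write(write_newick(t, lengths=lengths) + "\n")


# ---------------------------------------------------------------------------
# Characters and alignments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CharacterColumn:
    """Per-taxon state sets for one character (a site or a membership flag).

    ``states`` maps taxon id -> non-empty subset of ``alphabet``; missing
    data is encoded as the full alphabet.
    """

    states: Mapping[str, frozenset]
    alphabet: str = DNA_STATES

    def __post_init__(self):
        if not self.states:
            raise ValueError("empty character column")
        for taxon, ss in self.states.items():
            if not ss:
                raise ValueError(f"empty state set for taxon {taxon!r}")
            if not set(ss) <= set(self.alphabet):
                raise ValueError(
                    f"states {set(ss)} of taxon {taxon!r} outside alphabet")

    @classmethod
    def from_site(cls, taxa: Sequence[str], site: Sequence[str]) -> "CharacterColumn":
        states = {}
        for taxon, base in zip(taxa, site):
            try:
                states[taxon] = frozenset(IUPAC_CODES[base.upper()])
            except KeyError:
                raise ValueError(f"unknown base {base!r} for taxon {taxon!r}")
        return cls(states, DNA_STATES)

    @classmethod
    def from_membership(cls, taxa: Sequence[str], members: Iterable[str]) -> "CharacterColumn":
        mem = set(members)
        states = {t: frozenset("1" if t in mem else "0") for t in taxa}
        return cls(states, BINARY_STATES)

    def mask(self, taxon: str) -> int:
        ss = self.states[taxon]
        return sum(1 << self.alphabet.index(s) for s in ss)


class Alignment:
    """Aligned DNA matrix: unique taxon ids, equal-length sequences."""

    def __init__(self, ids: Sequence[str], seqs: Sequence[str]):
        if len(ids) != len(seqs):
            raise ValueError("ids and seqs differ in length")
        seen: dict[str, int] = {}
        keep_ids: list[str] = []
        keep_seqs: list[str] = []
        dropped = []
        for i, (tid, seq) in enumerate(zip(ids, seqs)):
            if not tid:
                raise ValueError(f"empty taxon id at record {i}")
            if tid in seen:
                dropped.append(tid)
                continue
            seen[tid] = i
            keep_ids.append(tid)
            keep_seqs.append(seq.upper())
        if dropped:
            warnings.warn(
                f"dropped {len(dropped)} duplicate taxon id(s): "
                f"{sorted(set(dropped))[:5]}...", stacklevel=2)
        lengths = {len(s) for s in keep_seqs}
        if len(lengths) > 1:
            raise ValueError(f"unequal sequence lengths: {sorted(lengths)}")
        bad = set("".join(keep_seqs)) - set(IUPAC_CODES)
        if bad:
            raise ValueError(f"unknown residue code(s): {sorted(bad)}")
        self.ids: list[str] = keep_ids
        self.seqs: list[str] = keep_seqs

    @property
    def n_taxa(self) -> int:
        return len(self.ids)

    @property
    def length(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    def sequence(self, taxon: str) -> str:
        return self.seqs[self.ids.index(taxon)]

    def column(self, i: int) -> CharacterColumn:
        return CharacterColumn.from_site(self.ids, [s[i] for s in self.seqs])

    def subset(self, keep: Iterable[str]) -> "Alignment":
        keep_set = set(keep)
        missing = keep_set - set(self.ids)
        if missing:
            raise KeyError(f"taxa not in alignment: {sorted(missing)}")
        pairs = [(t, s) for t, s in zip(self.ids, self.seqs) if t in keep_set]
        return Alignment([p[0] for p in pairs], [p[1] for p in pairs])

    # FASTA I/O via Biopython -------------------------------------------------

    @classmethod
    def read_fasta(cls, path) -> "Alignment":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise ValueError(f"no FASTA records in {path}")
        return cls([r.id for r in records], [str(r.seq) for r in records])

    def write_fasta(self, path, wrap: int = 80) -> None:
        records = [SeqRecord(Seq(s), id=t, description="")
                   for t, s in zip(self.ids, self.seqs)]
        with open(path, "w") as fh:
            writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
            writer.write_file(records)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Alignment(n_taxa={self.n_taxa}, length={self.length})"


# ---------------------------------------------------------------------------
# Encoding and the parsimony kernel
# ---------------------------------------------------------------------------

_DNA_MASKS = np.zeros(256, dtype=np.uint8)
for _code, _states in IUPAC_CODES.items():
    _m = sum(1 << DNA_STATES.index(s) for s in _states)
    _DNA_MASKS[ord(_code)] = _m
    _DNA_MASKS[ord(_code.lower())] = _m


@dataclass
class EncodedMatrix:
    """Bitmask encoding of a character matrix, compressed to unique site
    patterns. ``masks[i, p]`` is the state-set bitmask of taxon ``i`` in
    pattern ``p``; ``weights[p]`` counts columns sharing the pattern.
    ``pattern_min``/``pattern_max`` hold the per-pattern m and g terms."""

    taxa: tuple
    masks: np.ndarray          # (n_taxa, n_patterns) uint8
    weights: np.ndarray        # (n_patterns,) int64
    col_to_pattern: np.ndarray  # (n_columns,) int64
    pattern_min: np.ndarray    # (n_patterns,) int64
    pattern_max: np.ndarray    # (n_patterns,) int64
    n_states: int

    @property
    def n_patterns(self) -> int:
        return self.masks.shape[1]

    @staticmethod
    def _pattern_min_max(masks: np.ndarray, n_states: int):
        """m = (#states among unambiguous entries) - 1; g = star-tree steps
        = n_unambiguous - count of most frequent unambiguous state."""
        single = np.array([1 << s for s in range(n_states)], dtype=np.uint8)
        # counts[s, p] = number of taxa whose mask is exactly state s
        counts = (masks[None, :, :] == single[:, None, None]).sum(axis=1)
        present = (counts > 0).sum(axis=0)
        m = np.maximum(present - 1, 0)
        n_unamb = counts.sum(axis=0)
        g = np.where(n_unamb > 0, n_unamb - counts.max(axis=0), 0)
        return m.astype(np.int64), g.astype(np.int64)

    @classmethod
    def from_alignment(cls, aln: Alignment) -> "EncodedMatrix":
        arr = np.frombuffer("".join(aln.seqs).encode("ascii"),
                            dtype=np.uint8).reshape(aln.n_taxa, aln.length)
        masks = _DNA_MASKS[arr]
        patterns, inverse, counts = np.unique(
            masks, axis=1, return_inverse=True, return_counts=True)
        m, g = cls._pattern_min_max(patterns, 4)
        return cls(tuple(aln.ids), patterns, counts.astype(np.int64),
                   inverse.astype(np.int64), m, g, 4)

    @classmethod
    def from_columns(cls, columns: Sequence[CharacterColumn],
                     taxa: Sequence[str] | None = None) -> "EncodedMatrix":
        if not columns:
            raise ValueError("no columns to encode")
        alphabet = columns[0].alphabet
        if taxa is None:
            taxa = sorted(columns[0].states)
        masks = np.zeros((len(taxa), len(columns)), dtype=np.uint8)
        for j, col in enumerate(columns):
            if col.alphabet != alphabet:
                raise ValueError("mixed alphabets in column set")
            for i, t in enumerate(taxa):
                try:
                    masks[i, j] = col.mask(t)
                except KeyError:
                    raise KeyError(
                        f"taxon {t!r} missing from character column {j}")
        m, g = cls._pattern_min_max(masks, len(alphabet))
        return cls(tuple(taxa), masks, np.ones(len(columns), dtype=np.int64),
                   np.arange(len(columns), dtype=np.int64), m, g,
                   len(alphabet))


def _tree_index(tree: Tree, taxa: Sequence[str]):
    """Postorder node list plus child/leaf index arrays for the kernel."""
    taxon_row = {t: i for i, t in enumerate(taxa)}
    nodes = list(tree.postorder())
    index = {id(n): i for i, n in enumerate(nodes)}
    leaf_rows = np.full(len(nodes), -1, dtype=np.int64)
    children: list[list[int]] = [[] for _ in nodes]
    for n in nodes:
        i = index[id(n)]
        if n.is_leaf:
            if n.label not in taxon_row:
                raise TreeError(f"leaf {n.label!r} has no character data")
            leaf_rows[i] = taxon_row[n.label]
        else:
            children[i] = [index[id(c)] for c in n.children]
    return nodes, leaf_rows, children


def tree_pattern_lengths(tree: Tree, enc: EncodedMatrix) -> np.ndarray:
    """Fitch/Hartigan parsimony length of every pattern on ``tree``.

    Exact for arbitrary polytomies; invariant under rerooting. Returns an
    int64 array of per-pattern step counts (not weighted).
    """
    nodes, leaf_rows, children = _tree_index(tree, enc.taxa)
    n_nodes = len(nodes)
    P = enc.n_patterns
    work = np.empty((n_nodes, P), dtype=np.uint8)
    steps = np.zeros(P, dtype=np.int64)
    shifts = np.arange(enc.n_states, dtype=np.uint8)
    for i in range(n_nodes):
        if leaf_rows[i] >= 0:
            work[i] = enc.masks[leaf_rows[i]]
        else:
            kids = children[i]
            sub = work[kids]                      # (k, P)
            # per-state child counts: Hartigan's rule
            cnt = ((sub[:, None, :] >> shifts[None, :, None]) & 1).sum(
                axis=0, dtype=np.int64)
            K = cnt.max(axis=0)
            prelim = ((cnt == K[None, :]).astype(np.uint8)
                      << shifts[:, None]).sum(axis=0, dtype=np.uint8)
            work[i] = prelim
            steps += len(kids) - K
    return steps


def fitch_length(tree: Tree, column: CharacterColumn) -> int:
    """Minimum number of state changes of ``column`` on ``tree``.

    Every leaf of the tree must have an entry in the column; a missing
    leaf raises :class:`TreeError` naming it.
    """
    leaves = tree.leaf_labels()
    missing = [l for l in leaves if l not in column.states]
    if missing:
        raise TreeError(f"leaf {missing[0]!r} missing from character column")
    enc = EncodedMatrix.from_columns([column], taxa=leaves)
    return int(tree_pattern_lengths(tree, enc)[0])


def min_steps(column: CharacterColumn) -> int:
    """Minimum conceivable steps: distinct unambiguous states minus one."""
    observed = {next(iter(ss)) for ss in column.states.values() if len(ss) == 1}
    return max(len(observed) - 1, 0)


def max_steps(column: CharacterColumn) -> int:
    """Steps on the completely unresolved (star) tree: the number of
    unambiguous entries minus the count of the most frequent state."""
    from collections import Counter
    counts = Counter(next(iter(ss))
                     for ss in column.states.values() if len(ss) == 1)
    if not counts:
        return 0
    return sum(counts.values()) - max(counts.values())


@dataclass
class CiRiResult:
    """Ensemble consistency and retention indices over a character matrix.

    CI = sum(m_i)/sum(s_i) over variable columns; RI = (G-S)/(G-M) over
    columns with g_i > m_i (columns with g_i = m_i carry no retention
    information and are excluded from the RI sums). ``flags`` records
    degenerate situations; degenerate indices are NaN.
    """

    ci: float
    ri: float
    sum_m: int
    sum_s: int
    sum_g: int
    ri_sum_m: int
    ri_sum_s: int
    ri_sum_g: int
    n_variable: int
    n_retention_informative: int
    flags: list = field(default_factory=list)


def ensemble_ci_ri(tree: Tree, alignment: Alignment) -> CiRiResult:
    """Ensemble CI and RI of ``alignment`` on ``tree``.

    The alignment's taxa must equal the tree's leaves. All variable
    columns enter the CI sums (parsimony-uninformative ones included);
    this choice is recorded in the result's ``flags`` metadata.
    """
    tree_taxa = set(tree.leaf_labels())
    aln_taxa = set(alignment.ids)
    if tree_taxa != aln_taxa:
        diff = sorted(tree_taxa ^ aln_taxa)
        raise TreeError(f"tree/alignment taxon mismatch: {diff[:10]}")
    enc = EncodedMatrix.from_alignment(alignment)
    s = tree_pattern_lengths(tree, enc)
    m, g, w = enc.pattern_min, enc.pattern_max, enc.weights
    variable = m > 0
    flags = ["ci_includes_uninformative_variable_columns"]
    sum_m = int((m[variable] * w[variable]).sum())
    sum_s = int((s[variable] * w[variable]).sum())
    sum_g = int((g[variable] * w[variable]).sum())
    if not variable.any():
        flags.append("all_columns_constant_ci_undefined")
        ci = float("nan")
    else:
        ci = sum_m / sum_s
    retention = g > m
    ri_m = int((m[retention] * w[retention]).sum())
    ri_s = int((s[retention] * w[retention]).sum())
    ri_g = int((g[retention] * w[retention]).sum())
    if not retention.any():
        flags.append("no_retention_informative_columns_ri_undefined")
        ri = float("nan")
    else:
        ri = (ri_g - ri_s) / (ri_g - ri_m)
    return CiRiResult(ci=ci, ri=ri, sum_m=sum_m, sum_s=sum_s, sum_g=sum_g,
                      ri_sum_m=ri_m, ri_sum_s=ri_s, ri_sum_g=ri_g,
                      n_variable=int((variable * w).sum()),
                      n_retention_informative=int((retention * w).sum()),
                      flags=flags)
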