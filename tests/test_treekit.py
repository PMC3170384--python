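"""Tree I/O, Fitch step counting, and ensemble CI/RI."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import (
    brute_force_fitch,
    random_alignment,
    random_binary_column,
    random_binary_tree,
    random_multifurcating_tree,
)
from taxonsignal.treekit import (
    Alignment,
    CharacterColumn,
    EncodedMatrix,
    NewickParseError,
    Tree,
    TreeError,
    ensemble_ci_ri,
    fitch_length,
    max_steps,
    min_steps,
    parse_newick,
    tree_pattern_lengths,
    write_newick,
)

LABELS = [f"t{i}" for i in range(12)]


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

class TestNewick:
    def test_parse_basic_topology(self):
        tree = parse_newick("(A,B,(C,D));")
        assert sorted(tree.leaf_labels()) == ["A", "B", "C", "D"]
        cherry = frozenset([frozenset("CD"), frozenset("AB")])
        assert cherry in tree.bipartitions()

    def test_branch_lengths_round_trip(self):
        text = "((A:1,B:1):1,C:2);"
        again = parse_newick(write_newick(parse_newick(text)))
        lengths = {n.label: n.length for n in again.leaves()}
        assert lengths == {"A": 1.0, "B": 1.0, "C": 2.0}

    def test_polytomy_preserved(self):
        tree = parse_newick("(A,B,C,D,E);")
        assert len(tree.root.children) == 5
        assert write_newick(tree).count("(") == 1

    def test_cherry_round_trip(self):
        assert parse_newick(write_newick(parse_newick("(A,B);"))) \
            .bipartitions() == frozenset()

    def test_quoted_labels(self):
        tree = parse_newick("('sp one','sp (two)');")
        assert sorted(tree.leaf_labels()) == ["sp (two)", "sp one"]
        assert sorted(parse_newick(write_newick(tree)).leaf_labels()) \
            == ["sp (two)", "sp one"]

    @pytest.mark.parametrize("bad", ["((A,B,(C,D));", "(A,(B,C)));", "", "  "])
    def test_malformed_input_raises_with_position(self, bad):
        with pytest.raises(NewickParseError):
            parse_newick(bad)

    def test_unbalanced_error_names_position(self):
        with pytest.raises(NewickParseError, match="position"):
            parse_newick("((A,B,(C,D));")

    def test_duplicate_leaf_labels_rejected(self):
        with pytest.raises(NewickParseError, match="duplicate"):
            parse_newick("((A,B),(A,C));")

    @pytest.mark.parametrize("seed", range(6))
    def test_parse_write_identity_on_bipartitions(self, seed):
        rng = np.random.default_rng(seed)
        tree = (random_binary_tree if seed % 2 else
                random_multifurcating_tree)(LABELS, rng)
        assert parse_newick(write_newick(tree)).bipartitions() \
            == tree.bipartitions()


# ---------------------------------------------------------------------------
# Fitch step counting
# ---------------------------------------------------------------------------

def _membership(tree, members):
    return CharacterColumn.from_membership(tree.leaf_labels(), members)


class TestFitchLength:
    def test_monophyletic_group_single_step(self):
        tree = parse_newick("((A,B,C,D),(E,F,G,H));")
        assert fitch_length(tree, _membership(tree, "ABCD")) == 1

    def test_alternating_caterpillar(self):
        tree = parse_newick("(((((A,B),C),D),E),F);")
        col = _membership(tree, "ACE")
        assert fitch_length(tree, col) == 3 == brute_force_fitch(tree, col)

    def test_star_four_against_four(self):
        tree = parse_newick("(A,B,C,D,E,F,G,H);")
        col = _membership(tree, "ABCD")
        assert fitch_length(tree, col) == 4 == brute_force_fitch(tree, col)

    def test_polytomy_needs_hartigan_counting(self):
        # a naive pairwise intersection/union fold would return 1 here
        tree = parse_newick("(A,B,C,D);")
        col = _membership(tree, "AB")
        assert fitch_length(tree, col) == 2 == brute_force_fitch(tree, col)

    def test_missing_leaf_named_in_error(self):
        tree = parse_newick("((A,B),(C,D));")
        col = CharacterColumn.from_membership(["A", "B", "C"], ["A"])
        with pytest.raises(TreeError, match="'D'"):
            fitch_length(tree, col)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_on_random_trees(self, seed):
        rng = np.random.default_rng(1000 + seed)
        n = int(rng.integers(4, 11))
        labels = LABELS[:n]
        tree = (random_binary_tree if seed % 2 else
                random_multifurcating_tree)(labels, rng)
        for _ in range(3):
            col = random_binary_column(labels, rng)
            assert fitch_length(tree, col) == brute_force_fitch(tree, col)
        aln = random_alignment(labels, 5, rng, with_ambiguity=True)
        for i in range(aln.length):
            col = aln.column(i)
            assert fitch_length(tree, col) == brute_force_fitch(tree, col)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_dendropy_on_binary_trees(self, seed):
        import dendropy
        from dendropy.model import parsimony

        rng = np.random.default_rng(2000 + seed)
        labels = LABELS[: int(rng.integers(5, 11))]
        tree = random_binary_tree(labels, rng)
        aln = random_alignment(labels, 12, rng)
        dtree = dendropy.Tree.get(data=write_newick(tree), schema="newick",
                                  preserve_underscores=True)
        dna = dendropy.DnaCharacterMatrix.from_dict(
            dict(zip(aln.ids, aln.seqs)),
            taxon_namespace=dtree.taxon_namespace)
        expected = parsimony.fitch_down_pass(
            dtree.postorder_node_iter(),
            taxon_state_sets_map=dna.taxon_state_sets_map(
                gaps_as_missing=True))
        enc = EncodedMatrix.from_alignment(aln)
        got = int((tree_pattern_lengths(tree, enc) * enc.weights).sum())
        assert got == expected

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 10_000), reroot_at=st.integers(0, 50))
    def test_invariant_under_rerooting_and_leaf_order(self, seed, reroot_at):
        rng = np.random.default_rng(seed)
        labels = LABELS[: int(rng.integers(4, 11))]
        tree = random_binary_tree(labels, rng)
        col = random_binary_column(labels, rng)
        base = fitch_length(tree, col)
        nodes = [n for n in tree.preorder() if n.parent is not None]
        rerooted = tree.reroot_at_edge(nodes[reroot_at % len(nodes)])
        assert sorted(rerooted.leaf_labels()) == sorted(labels)
        assert fitch_length(rerooted, col) == base
        # leaf-order permutation: relabel by a permutation and permute column
        perm = {a: b for a, b in
                zip(labels, rng.permutation(labels).tolist())}
        relabeled = tree.copy()
        for leaf in relabeled.leaves():
            leaf.label = perm[leaf.label]
        permuted = CharacterColumn(
            {perm[t]: s for t, s in col.states.items()}, col.alphabet)
        assert fitch_length(relabeled, permuted) == base

    def test_rerooting_preserves_bipartitions(self):
        rng = np.random.default_rng(3)
        tree = random_binary_tree(LABELS[:8], rng)
        for node in [n for n in tree.preorder() if n.parent is not None][:5]:
            assert tree.reroot_at_edge(node).bipartitions() \
                == tree.bipartitions()


class TestStepBounds:
    def test_min_steps_examples(self):
        taxa = list("ABCDEF")
        both = CharacterColumn.from_membership(taxa, "AB")
        assert min_steps(both) == 1
        constant = CharacterColumn.from_membership(taxa, taxa)
        assert min_steps(constant) == 0
        dna = CharacterColumn.from_site(taxa, "AACCGG")
        assert min_steps(dna) == 2

    def test_max_steps_examples(self):
        taxa = [f"x{i}" for i in range(8)]
        col = CharacterColumn.from_membership(taxa, taxa[:4])
        assert max_steps(col) == 4
        singleton = CharacterColumn.from_membership(taxa, taxa[:1])
        assert max_steps(singleton) == 1
        dna = CharacterColumn.from_site(list("abcdef"), "AAACCG")
        assert max_steps(dna) == 3  # 6 unambiguous - 3 As

    def test_max_steps_is_star_tree_length(self):
        rng = np.random.default_rng(7)
        labels = LABELS[:9]
        star = Tree.from_newick("(" + ",".join(labels) + ");")
        aln = random_alignment(labels, 20, rng, with_ambiguity=True)
        for i in range(aln.length):
            col = aln.column(i)
            assert max_steps(col) == fitch_length(star, col)

    @pytest.mark.parametrize("seed", range(5))
    def test_min_fitch_max_sandwich(self, seed):
        rng = np.random.default_rng(4000 + seed)
        labels = LABELS[: int(rng.integers(5, 12))]
        tree = random_binary_tree(labels, rng)
        aln = random_alignment(labels, 30, rng, with_ambiguity=True)
        for i in range(aln.length):
            col = aln.column(i)
            s = fitch_length(tree, col)
            assert min_steps(col) <= s <= max(max_steps(col), min_steps(col))


# ---------------------------------------------------------------------------
# ensemble CI / RI
# ---------------------------------------------------------------------------

class TestEnsembleCiRi:
    def test_perfectly_congruent_matrix(self):
        tree = parse_newick("((A,B),(C,D));")
        aln = Alignment(list("ABCD"), ["AAT", "AAT", "TTA", "TTA"])
        res = ensemble_ci_ri(tree, aln)
        assert res.ci == 1.0 and res.ri == 1.0

    def test_single_homoplastic_column(self):
        # A=C=E one state, B=D=F the other on a caterpillar: m=1, s=3
        tree = parse_newick("(((((A,B),C),D),E),F);")
        aln = Alignment(list("ABCDEF"), ["A", "C", "A", "C", "A", "C"])
        res = ensemble_ci_ri(tree, aln)
        assert res.ci == pytest.approx(1 / 3)
        assert res.sum_s == 3 == brute_force_fitch(tree, aln.column(0))

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_per_column_bruteforce(self, seed):
        rng = np.random.default_rng(5000 + seed)
        labels = LABELS[:8]
        tree = random_binary_tree(labels, rng)
        aln = random_alignment(labels, 20, rng)
        res = ensemble_ci_ri(tree, aln)
        m = s = g = 0
        for i in range(aln.length):
            col = aln.column(i)
            if min_steps(col) == 0:
                continue
            m += min_steps(col)
            s += brute_force_fitch(tree, col)
            g += max_steps(col)
        assert (res.sum_m, res.sum_s, res.sum_g) == (m, s, g)
        assert res.ci == pytest.approx(m / s)
        assert m / g <= res.ci <= 1.0

    def test_all_constant_flagged(self):
        tree = parse_newick("((A,B),(C,D));")
        aln = Alignment(list("ABCD"), ["AAA"] * 4)
        res = ensemble_ci_ri(tree, aln)
        assert np.isnan(res.ci)
        assert any("constant" in f for f in res.flags)

    def test_taxon_mismatch_reports_difference(self):
        tree = parse_newick("((A,B),(C,D));")
        aln = Alignment(list("ABCE"), ["AT", "AT", "TA", "TA"])
        with pytest.raises(TreeError, match="D"):
            ensemble_ci_ri(tree, aln)


# ---------------------------------------------------------------------------
# Alignment container
# ---------------------------------------------------------------------------

class TestAlignment:
    def test_fasta_round_trip(self, tmp_path):
        aln = Alignment(["sp1", "sp2"], ["ACGT" * 30, "TGCA" * 30])
        path = tmp_path / "aln.fasta"
        aln.write_fasta(path)
        again = Alignment.read_fasta(path)
        assert again.ids == aln.ids and again.seqs == aln.seqs
        assert max(len(l.strip()) for l in open(path) if not
                   l.startswith(">")) <= 80

    def test_duplicate_ids_deduplicated_with_warning(self):
        with pytest.warns(UserWarning, match="duplicate"):
            aln = Alignment(["a", "a", "b"], ["AC", "GG", "GT"])
        assert aln.ids == ["a", "b"]
        assert aln.sequence("a") == "AC"

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="length"):
            Alignment(["a", "b"], ["ACGT", "ACG"])
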