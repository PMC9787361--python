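"""Fitch mapping, monophyly, and character classification on trees."""

import itertools

import dendropy
import numpy as np
import pytest

from plastcmp.char_mapping import (CharacterStateMap, annotate_nodes,
                                   classify_character, fitch_steps,
                                   is_monophyletic, read_newick)
from plastcmp.indels import AlignedMatrix, extract_indel_events
from plastcmp.plastome_io import TaxonomyTable


def _char(states):
    return CharacterStateMap("c", dict(states))


def oracle_min_steps(newick, states):
    """Exhaustive minimum over all internal-node labelings."""
    tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.is_rooted = True
    internals = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    leaves = [n for n in tree.leaf_node_iter()]
    alphabet = sorted({s for s in states.values() if s != "?"})
    best = None
    for combo in itertools.product(alphabet, repeat=len(internals)):
        assign = {id(n): s for n, s in zip(internals, combo)}
        cost = 0
        feasible = True
        for leaf in leaves:
            s = states.get(leaf.taxon.label, "?")
            if s == "?":
                continue
            if assign[id(leaf.parent_node)] != s:
                cost += 1
        for node in internals:
            if node.parent_node is not None:
                cost += assign[id(node)] != assign[id(node.parent_node)]
        if feasible and (best is None or cost < best):
            best = cost
    return best


class TestNewick:
    def test_supports_parsed_from_internal_labels(self):
        tree = read_newick("((A,B)97/0.99,(C,D));")
        sups = [(s.bs, s.pp) for s in tree.supports.values()]
        assert (97.0, 0.99) in sups

    def test_unlabeled_internals_have_null_support(self):
        tree = read_newick("((A,B),(C,D));")
        assert all(s.bs is None and s.pp is None for s in tree.supports.values())

    def test_unbalanced_parentheses_raise(self):
        with pytest.raises(ValueError):
            read_newick("((A,B),(C,D;")


class TestMonophyly:
    tree = read_newick("((A,B),(C,D));")

    def test_true_clade(self):
        ok, node = is_monophyletic(self.tree, {"A", "B"})
        assert ok and {l.taxon.label for l in node.leaf_iter()} == {"A", "B"}

    def test_non_clade(self):
        ok, _ = is_monophyletic(self.tree, {"A", "C"})
        assert not ok

    def test_singleton_is_monophyletic(self):
        ok, _ = is_monophyletic(self.tree, {"A"})
        assert ok

    def test_unknown_taxon_raises(self):
        with pytest.raises(ValueError):
            is_monophyletic(self.tree, {"A", "Z"})


class TestFitch:
    def test_single_clade_character(self):
        tree = read_newick("((A,B),(C,D));")
        res = fitch_steps(tree, _char({"A": "1", "B": "1", "C": "0", "D": "0"}))
        assert (res.steps, res.origins) == (1, 1)

    def test_scattered_character_is_two_origins(self):
        tree = read_newick("((A,B),(C,D));")
        res = fitch_steps(tree, _char({"A": "1", "B": "0", "C": "1", "D": "0"}))
        assert (res.steps, res.origins) == (2, 2)

    def test_wildcard_leaf_is_unconstrained(self):
        tree = read_newick("((A,B),(C,D));")
        res = fitch_steps(tree, _char({"A": "1", "B": "?", "C": "0", "D": "0"}))
        assert res.steps == 1

    def test_all_missing_character_raises(self):
        tree = read_newick("((A,B),(C,D));")
        with pytest.raises(ValueError):
            fitch_steps(tree, _char({"A": "?", "B": "?", "C": "?", "D": "?"}))

    def test_steps_match_exhaustive_oracle_on_random_trees(self):
        rng = np.random.default_rng(15)
        for _ in range(30):
            n = int(rng.integers(4, 9))
            labels = [f"L{i}" for i in range(n)]
            nodes = list(labels)
            while len(nodes) > 1:
                i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
                nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + \
                    [f"({nodes[i]},{nodes[j]})"]
            newick = nodes[0] + ";"
            states = {lab: str(rng.integers(0, 2)) for lab in labels}
            if len(set(states.values())) < 2:
                states[labels[0]] = "1" if states[labels[0]] == "0" else "0"
            tree = read_newick(newick)
            assert fitch_steps(tree, _char(states)).steps == \
                oracle_min_steps(newick, states)

    def test_steps_invariant_under_rerooting(self):
        base = "((A,B),((C,D),(E,F)));"
        states = {"A": "1", "B": "0", "C": "1", "D": "1", "E": "0", "F": "0"}
        want = fitch_steps(read_newick(base), _char(states)).steps
        for alt in ["(((A,B),(C,D)),(E,F));", "((((C,D),(E,F)),A),B);"]:
            assert fitch_steps(read_newick(alt), _char(states)).steps == want


class TestClassification:
    tax = TaxonomyTable([("A", "X"), ("B", "X"), ("C", "Y"), ("D", "Y")])

    def test_family_clade_marker(self):
        tree = read_newick("((A,B),(C,D));")
        cls = classify_character(tree, _char({"A": "1", "B": "1", "C": "0", "D": "0"}),
                                 self.tax)
        assert cls.category == "family-specific" and cls.family == "X"

    def test_distant_leaves_are_homoplastic(self):
        tree = read_newick("((A,B),(C,D));")
        cls = classify_character(tree, _char({"A": "1", "B": "0", "C": "1", "D": "0"}),
                                 self.tax)
        assert cls.category == "homoplastic" and cls.origins == 2

    def test_subfamily_clade_is_clade_specific_not_family(self):
        tree = read_newick("(((A,B),E),(C,D));")
        tax = TaxonomyTable([("A", "X"), ("B", "X"), ("E", "X"),
                             ("C", "Y"), ("D", "Y")])
        cls = classify_character(
            tree, _char({"A": "1", "B": "1", "E": "0", "C": "0", "D": "0"}), tax)
        assert cls.category == "clade-specific"

    def test_single_bearer_is_autapomorphic(self):
        tree = read_newick("((A,B),(C,D));")
        cls = classify_character(tree, _char({"A": "1", "B": "0", "C": "0", "D": "0"}),
                                 self.tax)
        assert cls.category == "autapomorphic"


class TestAnnotation:
    def test_clade_characters_attach_to_their_node(self):
        tree = read_newick("((A,B),(C,D));")
        chars = [CharacterStateMap(f"c{i}", {"A": "1", "B": "1", "C": "0", "D": "0"})
                 for i in range(3)]
        table = annotate_nodes(tree, chars)
        assert list(table.node.unique()) == ["A|B"]
        assert len(table) == 3

    def test_no_informative_characters_gives_empty_ledger(self):
        tree = read_newick("((A,B),(C,D));")
        table = annotate_nodes(tree, [_char({"A": "0", "B": "0", "C": "0", "D": "0"})])
        assert table.empty


class TestCrossModule:
    def test_strict_family_unique_indel_maps_family_specific(self, demo, demo_taxonomy):
        """An indel borne by exactly one (monophyletic) family's taxa maps
        onto the tree as a family-specific character."""
        tree = read_newick(demo.newick)
        locus = "ndhA"
        names, rows = demo.alignments[locus]
        aln = AlignedMatrix(locus, tuple(names), tuple(rows))
        events = extract_indel_events(aln)
        truth = demo.truth.indel_truth[locus]
        fam_sets = {fam: set(demo_taxonomy.taxa_of(fam))
                    for fam in demo_taxonomy.families()}
        checked = 0
        for t, ev in zip(truth, events):
            markers = set(t["markers"])
            fams = [f for f, taxa in fam_sets.items() if taxa == markers]
            if not fams:
                continue
            states = {taxon: "1" if taxon in markers else "0"
                      for taxon in tree.leaves}
            cls = classify_character(tree, CharacterStateMap("e", states),
                                     demo_taxonomy)
            assert cls.category == "family-specific"
            assert cls.family == fams[0]
            checked += 1
        assert checked > 0
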