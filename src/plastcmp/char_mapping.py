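"""Mapping binary/multistate characters onto a rooted phylogeny.

Characters (indel presence/absence, tRNA structural classes) are placed
on a user-supplied rooted tree with Fitch parsimony.  '?' states are
wildcards (the full state set at the leaf).  Origins of the derived
state are counted on one deterministic most-parsimonious reconstruction
that assigns a node its parent's state whenever the downpass set allows
it (transformations are delayed toward the tips, DELTRAN-style); when
an accelerated assignment would differ, the character is flagged
ambiguous.  A character with one origin whose supporting clade is
exactly one family's taxa is a family marker; two or more origins mean
homoplasy.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import pandas as pd

from .plastome_io import TaxonomyTable

__all__ = [
    "PhyloTree",
    "CharacterStateMap",
    "read_newick",
    "is_monophyletic",
    "fitch_steps",
    "classify_character",
    "annotate_nodes",
    "read_character_matrix",
]


@dataclass
class NodeSupport:
    bs: float | None = None   # bootstrap %
    pp: float | None = None   # posterior probability


class PhyloTree:
    """A rooted tree with unique leaf names and optional node supports."""

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if len(set(leaves)) != len(leaves):
            raise ValueError("duplicate leaf names")
        self.leaves = set(leaves)
        self.supports: dict[int, NodeSupport] = {}
        for node in tree.preorder_node_iter():
            if node.is_leaf():
                continue
            label = node.label
            sup = NodeSupport()
            if label:
                parts = str(label).split("/")
                try:
                    if len(parts) == 2:
                        sup = NodeSupport(bs=float(parts[0]), pp=float(parts[1]))
                    elif len(parts) == 1:
                        sup = NodeSupport(bs=float(parts[0]))
                except ValueError:
                    pass
            self.supports[id(node)] = sup

    def support_of(self, node) -> NodeSupport:
        return self.supports.get(id(node), NodeSupport())

    def mrca(self, taxa: set[str]):
        unknown = taxa - self.leaves
        if unknown:
            raise ValueError(f"unknown taxa: {sorted(unknown)}")
        return self.tree.mrca(taxon_labels=list(taxa))

    def leafset(self, node) -> set[str]:
        return {lf.taxon.label for lf in node.leaf_iter()}


def read_newick(text_or_path: str) -> PhyloTree:
    """Read a rooted Newick tree; internal labels 'BS/PP' or a single
    value are interpreted as node supports."""
    text = str(text_or_path)
    if not text.lstrip().startswith("("):
        with open(text_or_path) as fh:
            text = fh.read()
    try:
        tree = dendropy.Tree.get(data=text, schema="newick",
                                 suppress_internal_node_taxa=True,
                                 preserve_underscores=True)
    except Exception as exc:
        raise ValueError(f"Newick parse error: {exc}") from exc
    tree.is_rooted = True
    return PhyloTree(tree)


@dataclass(frozen=True)
class CharacterStateMap:
    """One character: taxon -> state; '?' is missing/inapplicable."""

    character_id: str
    states: dict[str, str]

    def state_of(self, taxon: str) -> str:
        return self.states.get(taxon, "?")

    def observed_states(self) -> set[str]:
        return {s for s in self.states.values() if s != "?"}


def is_monophyletic(tree: PhyloTree, taxa: set[str]):
    """(bool, MRCA node): true iff the MRCA's leaf set equals ``taxa``."""
    taxa = set(taxa)
    node = tree.mrca(taxa)
    return tree.leafset(node) == taxa, node


@dataclass(frozen=True)
class FitchResult:
    steps: int
    origins: int                 # 0->1 transitions for the derived state
    origin_nodes: tuple          # nodes where the derived state arises
    ambiguous: bool              # ACCTRAN and DELTRAN assignments differ
    assignment: dict             # id(node) -> state


def fitch_steps(tree: PhyloTree, char: CharacterStateMap,
                derived_state: str = "1") -> FitchResult:
    """Fitch parsimony steps and derived-state origin count.

    '?' leaves carry the full observed state set (wildcard).  The uppass
    prefers the parent's state when the downpass set permits; the root
    prefers the ancestral ('0' when binary) state on ties.  Origins are
    edges (or the root) where the assignment switches to
    ``derived_state``.
    """
    alphabet = sorted(char.observed_states())
    if not alphabet:
        raise ValueError(f"character {char.character_id}: all states missing")
    full = frozenset(alphabet)
    down: dict[int, frozenset] = {}
    steps = 0
    for node in tree.tree.postorder_node_iter():
        if node.is_leaf():
            s = char.state_of(node.taxon.label)
            down[id(node)] = full if s == "?" else frozenset({s})
        else:
            sets = [down[id(c)] for c in node.child_nodes()]
            inter = frozenset.intersection(*sets)
            if inter:
                down[id(node)] = inter
            else:
                # multifurcation-safe Fitch: greedy pairwise fold
                acc = sets[0]
                for s in sets[1:]:
                    both = acc & s
                    if both:
                        acc = both
                    else:
                        acc = acc | s
                        steps += 1
                down[id(node)] = acc

    ancestral = "0" if "0" in full else alphabet[0]
    assignment: dict[int, str] = {}
    ambiguous = False
    origins = []
    for node in tree.tree.preorder_node_iter():
        cand = down[id(node)]
        parent = node.parent_node
        if parent is None:
            state = ancestral if ancestral in cand else sorted(cand)[0]
            if len(cand) > 1:
                ambiguous = True
        else:
            pstate = assignment[id(parent)]
            if pstate in cand:
                state = pstate
                if len(cand) > 1:
                    ambiguous = True  # an accelerated choice could differ
            else:
                state = sorted(cand)[0]
                if len(cand) > 1:
                    ambiguous = True
        assignment[id(node)] = state
        if state == derived_state and (parent is None or assignment[id(parent)] != derived_state):
            origins.append(node)
    return FitchResult(steps=steps, origins=len(origins),
                       origin_nodes=tuple(origins), ambiguous=ambiguous,
                       assignment=assignment)


@dataclass(frozen=True)
class CharacterClassification:
    character_id: str
    category: str                # clade-specific | family-specific | homoplastic | autapomorphic | invariant
    origins: int
    family: str | None = None
    clade_leaves: tuple[str, ...] = ()
    ambiguous: bool = False


def classify_character(tree: PhyloTree, char: CharacterStateMap,
                       taxonomy: TaxonomyTable | None = None,
                       derived_state: str = "1") -> CharacterClassification:
    """Single-origin characters are clade markers; a clade equal to one
    family's taxa makes a family marker; ≥2 origins is homoplasy.
    Single-leaf markers are reported as autapomorphic, not dropped."""
    res = fitch_steps(tree, char, derived_state=derived_state)
    if res.origins == 0:
        return CharacterClassification(char.character_id, "invariant", 0,
                                       ambiguous=res.ambiguous)
    if res.origins >= 2:
        return CharacterClassification(char.character_id, "homoplastic", res.origins,
                                       ambiguous=res.ambiguous)
    node = res.origin_nodes[0]
    leaves = tuple(sorted(tree.leafset(node)))
    if len(leaves) == 1:
        return CharacterClassification(char.character_id, "autapomorphic", 1,
                                       clade_leaves=leaves, ambiguous=res.ambiguous)
    if taxonomy is not None:
        for fam in taxonomy.families():
            if set(leaves) == set(taxonomy.taxa_of(fam)):
                return CharacterClassification(char.character_id, "family-specific", 1,
                                               family=fam, clade_leaves=leaves,
                                               ambiguous=res.ambiguous)
    return CharacterClassification(char.character_id, "clade-specific", 1,
                                   clade_leaves=leaves, ambiguous=res.ambiguous)


def annotate_nodes(tree: PhyloTree, characters: list[CharacterStateMap],
                   taxonomy: TaxonomyTable | None = None,
                   derived_state: str = "1") -> pd.DataFrame:
    """Node ledger: each single-origin character attached to its origin
    node (identified by its sorted leaf set); homoplastic characters
    listed with node 'HOMOPLASTIC'."""
    rows = []
    for char in characters:
        res = fitch_steps(tree, char, derived_state=derived_state)
        cls = classify_character(tree, char, taxonomy, derived_state)
        if cls.category in ("clade-specific", "family-specific", "autapomorphic"):
            node_key = "|".join(sorted(tree.leafset(res.origin_nodes[0])))
            rows.append({"character": char.character_id, "node": node_key,
                         "category": cls.category, "family": cls.family,
                         "origins": cls.origins})
        elif cls.category == "homoplastic":
            rows.append({"character": char.character_id, "node": "HOMOPLASTIC",
                         "category": cls.category, "family": None,
                         "origins": cls.origins})
    return pd.DataFrame(rows, columns=["character", "node", "category",
                                       "family", "origins"])


def read_character_matrix(path) -> list[CharacterStateMap]:
    """Characters from a taxa × characters TSV (first column = taxon)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    df = df.set_index(df.columns[0])
    return [CharacterStateMap(character_id=col, states=df[col].to_dict())
            for col in df.columns]
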