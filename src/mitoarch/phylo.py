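"""Discrete-character mapping on phylogenies.

Maps categorical tip characters (tRNA-cluster rearrangement pattern,
habitat-depth class) onto a rooted input topology, computes the minimum
number of state changes by parsimony, tests clustering of a character by
tip-label permutation, and cross-tabulates two characters.

Parsimony uses Hartigan's generalization of the Fitch algorithm, which is
exact on multifurcating trees: at each internal node the children's state
sets vote, the node keeps the majority states, and the step count grows
by (number of children - maximum vote).  On strictly bifurcating trees
this reduces to classic Fitch intersection/union counting.

The permutation test shuffles states across tips uniformly and reports
the add-one estimator ``p = (1 + #{perm steps <= observed}) / (1 + n)``,
so a fixed seed gives a reproducible, never-zero p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "parse_newick",
    "write_newick",
    "fitch_parsimony",
    "ParsimonyResult",
    "tip_permutation_test",
    "character_concordance",
    "ConcordanceSummary",
]


class NewickError(ValueError):
    pass


def parse_newick(text: str) -> dendropy.Tree:
    """Parse a newick string into a rooted tree.

    Multifurcations are preserved; branch lengths are accepted but ignored
    by every downstream computation.  Duplicate tip labels are an error.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise NewickError(f"malformed newick: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter() if leaf.taxon]
    if len(labels) != len(set(labels)):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise NewickError(f"duplicate tip labels: {', '.join(dupes)}")
    if len(labels) < 2:
        raise NewickError("tree needs at least 2 tips")
    tree.is_rooted = True
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


@dataclass
class ParsimonyResult:
    """Minimum state changes plus per-node ancestral state sets."""

    steps: int
    state_sets: dict  # dendropy node -> frozenset of states
    root_states: frozenset

    def __int__(self) -> int:
        return self.steps


def fitch_parsimony(
    tree: dendropy.Tree, characters: Mapping[str, str]
) -> ParsimonyResult:
    """Exact minimum number of state changes of one character on the tree.

    ``characters`` maps every tip label to a categorical state; a missing
    tip raises ``KeyError`` naming it.  Returns the step count and the
    per-node candidate ancestral state sets from the bottom-up pass.
    """
    steps = 0
    sets: dict = {}
    root = tree.seed_node
    for node in tree.postorder_node_iter():
        children = node.child_nodes()
        if not children:
            label = node.taxon.label if node.taxon else None
            if label not in characters:
                raise KeyError(f"tip {label!r} has no character state")
            sets[node] = frozenset({characters[label]})
            continue
        votes: dict[str, int] = {}
        for child in children:
            for s in sets[child]:
                votes[s] = votes.get(s, 0) + 1
        top = max(votes.values())
        sets[node] = frozenset(s for s, v in votes.items() if v == top)
        steps += len(children) - top
    return ParsimonyResult(steps=steps, state_sets=sets, root_states=sets[root])


def tip_permutation_test(
    tree: dendropy.Tree,
    characters: Mapping[str, str],
    n_perm: int = 999,
    seed: int = 0,
) -> float:
    """Permutation p-value for phylogenetic clustering of a character.

    The observed parsimony step count is compared with the counts obtained
    after shuffling the state vector across tips uniformly at random.  Low
    p means the character changes fewer times on the real tree than
    expected if states were unrelated to the topology.  A constant
    character has no signal to test: p = 1.0 with a warning.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    labels = sorted(tip_labels(tree))
    states = np.array([characters[x] for x in labels])
    if len(set(states.tolist())) < 2:
        warnings.warn("constant character: permutation test has no signal")
        return 1.0
    observed = fitch_parsimony(tree, characters).steps
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(states)
        if fitch_parsimony(tree, dict(zip(labels, perm))).steps <= observed:
            hits += 1
    return (1 + hits) / (1 + n_perm)


@dataclass
class ConcordanceSummary:
    """Cross-tabulation of two tip characters."""

    table: pd.DataFrame
    perfect_association: bool

    def to_dict(self) -> dict:
        return {
            "table": {
                str(i): {str(c): int(v) for c, v in row.items()}
                for i, row in self.table.iterrows()
            },
            "perfect_association": self.perfect_association,
        }


def character_concordance(
    char1: Mapping[str, str],
    char2: Mapping[str, str],
    tips: Optional[list[str]] = None,
) -> ConcordanceSummary:
    """Contingency table of two characters over their shared tips.

    ``perfect_association`` is True when each state of the first character
    co-occurs with exactly one state of the second (the association is a
    function char1 -> char2 on the shared tips).
    """
    shared = sorted(set(char1) & set(char2) & set(tips or char1))
    if not shared:
        raise ValueError("character maps share no tips")
    s1 = pd.Series({t: char1[t] for t in shared}, name="char1")
    s2 = pd.Series({t: char2[t] for t in shared}, name="char2")
    table = pd.crosstab(s1, s2)
    perfect = bool(((table > 0).sum(axis=1) == 1).all())
    return ConcordanceSummary(table=table, perfect_association=perfect)
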