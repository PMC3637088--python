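"""Detection of supported, taxonomically homogeneous, maximal clades."""

from __future__ import annotations

from dataclasses import dataclass

from .newick_io import Tree, TreeNode
from .taxonomy import DereplicationRule, TaxonomyMap, TrimParams, matching_rule


@dataclass
class CladeCandidate:
    """A supported node whose full leaf set matches one rule.

    ``leaves`` are in the tree's leaf order.
    """

    node: TreeNode
    category: str
    rule: DereplicationRule
    leaves: tuple[str, ...]


def supported_nodes(tree: Tree, threshold: float) -> list[TreeNode]:
    """Internal nodes (root included) whose support passes ``threshold``.

    A threshold of 0 returns every internal node regardless of whether
    a support value is present; otherwise nodes lacking a support are
    excluded.
    """
    if threshold == 0:
        return tree.internal_nodes()
    return [
        node
        for node in tree.internal_nodes()
        if node.support is not None and node.support >= threshold
    ]


def candidate_clades(
    tree: Tree, taxonomy: TaxonomyMap, params: TrimParams
) -> list[CladeCandidate]:
    """One candidate per supported node with a unanimous matching rule.

    Ordered by the position of each clade's first leaf in the tree's
    leaf order (ties -- nested clades sharing a first leaf -- keep the
    enclosing clade first).
    """
    position = {name: i for i, name in enumerate(tree.leaf_order)}
    candidates = []
    for node in supported_nodes(tree, params.support_threshold):
        leaves = node.leaf_names()
        rule = matching_rule(params, taxonomy, leaves)
        if rule is not None:
            candidates.append(
                CladeCandidate(
                    node=node, category=rule.category, rule=rule, leaves=leaves
                )
            )
    candidates.sort(key=lambda c: (position[c.leaves[0]], -len(c.leaves)))
    return candidates


def maximal_clades(candidates: list[CladeCandidate]) -> list[CladeCandidate]:
    """Candidates not strictly contained in a larger same-category candidate.

    Candidates of different categories never absorb one another.  Input
    order (first-leaf position) is preserved.  Within one category the
    survivors are leaf-disjoint, clades of a rooted tree being either
    nested or disjoint.
    """
    leaf_sets = [frozenset(c.leaves) for c in candidates]
    maximal = []
    for i, cand in enumerate(candidates):
        contained = any(
            j != i
            and candidates[j].category == cand.category
            # strict containment absorbs; an equal leaf set (a unary
            # chain in the input) keeps only the first-listed candidate
            and (leaf_sets[i] < leaf_sets[j] or (j < i and leaf_sets[i] == leaf_sets[j]))
            for j in range(len(candidates))
        )
        if not contained:
            maximal.append(cand)
    return maximal
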