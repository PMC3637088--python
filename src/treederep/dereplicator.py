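"""Median-branch-length representative selection and result assembly.

Within each maximal clade, leaves are ranked by closeness of their
basal-node-to-leaf path length to the clade median, and all but a
rule-specified number of representatives are removed.  The median is
used rather than the mean so that one or a few unusually long-branching
leaves do not drag the representatives toward themselves.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .clade_finder import candidate_clades, maximal_clades
from .errors import ValidationError
from .newick_io import Tree, TreeNode
from .taxonomy import TaxonomyMap, TrimParams


@dataclass
class RemovalRecord:
    """Outcome of dereplicating one maximal clade."""

    category: str
    rank: int
    clade_leaves: tuple[str, ...]
    retained: tuple[str, ...]
    removed_count: int
    median: float
    support: Optional[float]


@dataclass
class TrimResult:
    """Global outcome: the retained OTU list plus per-clade records."""

    retained_otus: tuple[str, ...]
    records: list[RemovalRecord]
    params_echo: TrimParams

    @property
    def total_removed(self) -> int:
        return sum(record.removed_count for record in self.records)


def leaf_depths(tree: Tree, clade_node: TreeNode) -> dict[str, float]:
    """Path length from the clade's basal node down to each of its leaves.

    The basal node's own subtending branch is excluded.  Absent branch
    lengths contribute 0, so cladogram input yields all-zero depths.
    Each depth is an exactly-rounded sum (``math.fsum``), so it does
    not depend on traversal order.
    """
    depths: dict[str, float] = {}

    def descend(node: TreeNode, segments: list[float]) -> None:
        if node.is_leaf:
            depths[node.name] = math.fsum(segments)
            return
        for child in node.children:
            descend(child, segments + [child.branch_length or 0.0])

    descend(clade_node, [])
    return depths


def median_depth(depths: Mapping[str, float]) -> float:
    """Sample median of the depth values (even counts: mean of the two
    central values)."""
    if not depths:
        raise ValidationError("median of an empty depth map")
    return statistics.median(depths.values())


def select_representatives(
    depths: Mapping[str, float],
    leaf_order: Sequence[str],
    retain: int,
) -> list[str]:
    """The ``retain`` leaves whose depths lie closest to the median.

    Ties on |depth - median| are broken by earlier position in
    ``leaf_order``; the result is returned in ``leaf_order``.  When the
    clade has no more than ``retain`` leaves, all of them are returned.
    """
    if retain < 1:
        raise ValidationError(f"retain must be >= 1, got {retain}")
    position = {name: i for i, name in enumerate(leaf_order)}
    if len(depths) <= retain:
        return sorted(depths, key=position.__getitem__)
    median = median_depth(depths)
    ranked = sorted(
        depths, key=lambda name: (abs(depths[name] - median), position[name])
    )
    return sorted(ranked[:retain], key=position.__getitem__)


def dereplicate(tree: Tree, taxonomy: TaxonomyMap, params: TrimParams) -> TrimResult:
    """Run the full procedure and assemble a :class:`TrimResult`.

    Maximal clades are processed in leaf order.  A clade with fewer
    leaves than its rule's retain count is skipped entirely (no record,
    nothing removed); a clade with exactly that many leaves is recorded
    with a removed count of 0 so reports are complete.  When maximal
    clades of different categories are nested (rules at different ranks
    both matching), only the outermost is processed, keeping processed
    clades leaf-disjoint.
    """
    clades = maximal_clades(candidate_clades(tree, taxonomy, params))
    leaf_sets = [frozenset(c.leaves) for c in clades]
    processed = [
        clade
        for i, clade in enumerate(clades)
        if not any(j != i and leaf_sets[i] < leaf_sets[j] for j in range(len(clades)))
    ]

    records: list[RemovalRecord] = []
    removed: set[str] = set()
    for clade in processed:
        if len(clade.leaves) < clade.rule.retain:
            continue
        depths = leaf_depths(tree, clade.node)
        median = median_depth(depths)
        retained = tuple(
            select_representatives(depths, tree.leaf_order, clade.rule.retain)
        )
        removed.update(set(clade.leaves) - set(retained))
        records.append(
            RemovalRecord(
                category=clade.category,
                rank=clade.rule.rank,
                clade_leaves=clade.leaves,
                retained=retained,
                removed_count=len(clade.leaves) - len(retained),
                median=median,
                support=clade.node.support,
            )
        )
    retained_otus = tuple(name for name in tree.leaf_order if name not in removed)
    return TrimResult(retained_otus=retained_otus, records=records, params_echo=params)
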