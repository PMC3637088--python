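"""Random test-tree generation and independent brute-force oracles.

:func:`generate_tree` builds random rooted trees with planted,
supported, taxonomically homogeneous clades plus a matching taxonomy
table, so the whole pipeline is testable without any external data.
:func:`brute_force_dereplicate` is a deliberately naive, straight-line
reimplementation of the entire procedure used as an oracle in the test
suite; it shares no algorithmic code with the main path.
"""

from __future__ import annotations

import itertools
import math
import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .dereplicator import RemovalRecord, TrimResult
from .errors import ValidationError
from .newick_io import Tree, TreeNode, write_newick
from .taxonomy import DereplicationRule, TaxonomyMap, TrimParams, serialize_taxonomy

ORACLE_MAX_LEAVES = 25


@dataclass(frozen=True)
class PlantedClade:
    """One monophyletic group to embed in a generated tree."""

    category: str
    lineage: tuple[str, ...]
    n_leaves: int
    support: float


@dataclass
class PlantSpec:
    """Recipe for one random tree with planted clades."""

    n_background_leaves: int
    planted_clades: list[PlantedClade] = field(default_factory=list)
    # uniform bounds for supports on non-planted internal nodes;
    # None leaves those nodes without support values
    support_noise: Optional[tuple[float, float]] = (0.0, 0.6)
    branch_length_mean: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_background_leaves < 0:
            raise ValidationError("n_background_leaves must be >= 0")
        if self.branch_length_mean <= 0:
            raise ValidationError("branch_length_mean must be > 0")
        for clade in self.planted_clades:
            if clade.n_leaves < 1:
                raise ValidationError(
                    f"planted clade {clade.category!r} must have >= 1 leaf"
                )
            if clade.category not in clade.lineage:
                raise ValidationError(
                    f"planted clade category {clade.category!r} does not "
                    f"appear in its lineage {clade.lineage!r}"
                )
        total = self.n_background_leaves + sum(
            c.n_leaves for c in self.planted_clades
        )
        if total < 2:
            raise ValidationError("spec must yield at least 2 leaves in total")


def _random_join(
    units: list[TreeNode],
    rng: random.Random,
    mean: float,
    support_for_new_node,
) -> TreeNode:
    """Random bifurcating topology over ``units`` by repeated pairing."""
    units = list(units)
    while len(units) > 1:
        i, j = rng.sample(range(len(units)), 2)
        a, b = units[i], units[j]
        a.branch_length = rng.expovariate(1.0 / mean)
        b.branch_length = rng.expovariate(1.0 / mean)
        parent = TreeNode(children=[a, b], support=support_for_new_node())
        units = [u for k, u in enumerate(units) if k not in (i, j)]
        units.append(parent)
    return units[0]


def generate_tree(
    spec: PlantSpec,
) -> tuple[Tree, TaxonomyMap, list[tuple[str, frozenset[str]]]]:
    """Build one random tree per ``spec``.

    Returns the tree, the matching taxonomy table and, as ground
    truth, the (category, leaf set) of every planted clade.  Background
    leaves carry distinct singleton lineages so no rule can ever
    unify two of them.  Fully reproducible from ``spec.seed``.
    """
    rng = random.Random(spec.seed)
    mean = spec.branch_length_mean

    def noise_support() -> Optional[float]:
        if spec.support_noise is None:
            return None
        lo, hi = spec.support_noise
        return round(rng.uniform(lo, hi), 4)

    entries: dict[str, tuple[str, ...]] = {}
    expected: list[tuple[str, frozenset[str]]] = []
    units: list[TreeNode] = []

    for index, clade in enumerate(spec.planted_clades):
        leaf_nodes = []
        for k in range(clade.n_leaves):
            name = f"p{index}_{clade.category}_{k}"
            entries[name] = clade.lineage
            leaf_nodes.append(TreeNode(name=name))
        expected.append((clade.category, frozenset(n.name for n in leaf_nodes)))
        if len(leaf_nodes) == 1:
            units.append(leaf_nodes[0])
        else:
            root = _random_join(leaf_nodes, rng, mean, lambda: None)
            for node in root.walk():
                if not node.is_leaf:
                    node.support = clade.support
            units.append(root)

    for k in range(spec.n_background_leaves):
        name = f"bg_{k}"
        entries[name] = (f"bgtax_{k}",)
        units.append(TreeNode(name=name))

    rng.shuffle(units)
    root = _random_join(units, rng, mean, noise_support)
    root.branch_length = None
    if root.is_leaf:
        raise ValidationError("spec must yield at least 2 leaves in total")
    return Tree(root=root), TaxonomyMap(entries=entries), expected


def write_fixture(spec: PlantSpec, directory: str | Path) -> dict[str, str]:
    """Emit Newick + taxonomy TSV + a JSON manifest into ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tree, taxonomy, expected = generate_tree(spec)
    paths = {
        "tree": str(directory / "tree.nwk"),
        "taxonomy": str(directory / "taxonomy.tsv"),
        "manifest": str(directory / "manifest.json"),
    }
    (directory / "tree.nwk").write_text(write_newick(tree) + "\n")
    (directory / "taxonomy.tsv").write_text(serialize_taxonomy(taxonomy))
    manifest = {
        "seed": spec.seed,
        "n_background_leaves": spec.n_background_leaves,
        "branch_length_mean": spec.branch_length_mean,
        "support_noise": spec.support_noise,
        "planted_clades": [
            {
                "category": c.category,
                "lineage": list(c.lineage),
                "n_leaves": c.n_leaves,
                "support": c.support,
            }
            for c in spec.planted_clades
        ],
        "expected": [
            {"category": cat, "leaves": sorted(leaves)} for cat, leaves in expected
        ],
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return paths


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------


def brute_force_dereplicate(
    tree: Tree, taxonomy: TaxonomyMap, params: TrimParams
) -> TrimResult:
    """Naive end-to-end reimplementation, for cross-checking only.

    Every step is done the slow, obvious way: internal nodes collected
    recursively, unanimity tested by direct iteration over rules,
    containment filtered pairwise, and representatives found by
    exhaustively scoring every size-``retain`` subset.  Guarded to
    trees of at most 25 leaves.
    """
    all_leaves = list(tree.leaf_order)
    if len(all_leaves) > ORACLE_MAX_LEAVES:
        raise ValidationError(
            f"oracle accepts at most {ORACLE_MAX_LEAVES} leaves, "
            f"got {len(all_leaves)}"
        )
    position = {name: i for i, name in enumerate(all_leaves)}

    internal: list[TreeNode] = []

    def collect(node: TreeNode) -> None:
        if node.children:
            internal.append(node)
            for child in node.children:
                collect(child)

    collect(tree.root)

    def leaf_names(node: TreeNode) -> list[str]:
        if not node.children:
            return [node.name]
        out: list[str] = []
        for child in node.children:
            out.extend(leaf_names(child))
        return out

    def label(otu: str, rank: int) -> Optional[str]:
        lineage = taxonomy.entries.get(otu)
        if lineage is None or len(lineage) < rank:
            return None
        return lineage[rank - 1]

    # supported nodes + unanimity, by direct iteration
    candidates: list[tuple[TreeNode, DereplicationRule, list[str]]] = []
    for node in internal:
        if params.support_threshold != 0 and (
            node.support is None or node.support < params.support_threshold
        ):
            continue
        leaves = leaf_names(node)
        chosen: Optional[DereplicationRule] = None
        for rule in params.rules:
            ok = True
            for otu in leaves:
                if label(otu, rule.rank) != rule.category:
                    ok = False
                    break
            if ok and (chosen is None or rule.rank > chosen.rank):
                chosen = rule
        if chosen is None and params.default_rule is not None:
            rank, retain = params.default_rule
            labels = [label(otu, rank) for otu in leaves]
            if None not in labels and len(set(labels)) == 1:
                chosen = DereplicationRule(labels[0], rank, retain)
        if chosen is not None:
            candidates.append((node, chosen, leaves))

    # maximality within category, pairwise containment
    maximal = []
    for i, (node, rule, leaves) in enumerate(candidates):
        s = set(leaves)
        absorbed = False
        for j, (_, rule_j, leaves_j) in enumerate(candidates):
            if j == i or rule_j.category != rule.category:
                continue
            s_j = set(leaves_j)
            if s < s_j or (s == s_j and j < i):
                absorbed = True
                break
        if not absorbed:
            maximal.append((node, rule, leaves))

    # outermost wins across categories (nested only; clades are laminar)
    final = []
    for i, (node, rule, leaves) in enumerate(maximal):
        s = set(leaves)
        nested = any(
            j != i and s < set(leaves_j) for j, (_, _, leaves_j) in enumerate(maximal)
        )
        if not nested:
            final.append((node, rule, leaves))
    final.sort(key=lambda entry: position[entry[2][0]])

    records: list[RemovalRecord] = []
    removed: set[str] = set()
    for node, rule, leaves in final:
        if len(leaves) < rule.retain:
            continue
        # depths by per-leaf path walk over parent pointers
        parents: dict[int, TreeNode] = {}

        def link(n: TreeNode) -> None:
            for child in n.children:
                parents[id(child)] = n
                link(child)

        link(node)
        depths: dict[str, float] = {}
        for leaf in node.iter_leaves():
            segments: list[float] = []
            cursor = leaf
            while id(cursor) in parents:
                segments.append(cursor.branch_length or 0.0)
                cursor = parents[id(cursor)]
            # fsum: exactly-rounded, so walk order cannot matter
            depths[leaf.name] = math.fsum(segments)
        values = sorted(depths.values())
        k = len(values)
        if k % 2:
            median = values[k // 2]
        else:
            median = (values[k // 2 - 1] + values[k // 2]) / 2
        # exhaustive subset scoring: minimize the sorted multiset of
        # |depth - median| distances, then earliest leaf positions
        best_key = None
        best_subset = None
        for combo in itertools.combinations(leaves, rule.retain):
            key = (
                tuple(sorted(abs(depths[otu] - median) for otu in combo)),
                tuple(sorted(position[otu] for otu in combo)),
            )
            if best_key is None or key < best_key:
                best_key, best_subset = key, combo
        retained = tuple(sorted(best_subset, key=position.__getitem__))
        removed.update(set(leaves) - set(retained))
        records.append(
            RemovalRecord(
                category=rule.category,
                rank=rule.rank,
                clade_leaves=tuple(leaves),
                retained=retained,
                removed_count=len(leaves) - len(retained),
                median=median,
                support=node.support,
            )
        )
    retained_otus = tuple(name for name in all_leaves if name not in removed)
    return TrimResult(retained_otus=retained_otus, records=records, params_echo=params)
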