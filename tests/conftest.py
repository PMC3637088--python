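"""Shared fixtures: random problem instances and small reference oracles."""

from __future__ import annotations

import random

import pytest

from treederep import (
    DereplicationRule,
    PlantSpec,
    PlantedClade,
    TrimParams,
)

CATEGORIES = ("Metazoa", "Viridiplantae", "Amoebozoa", "Stramenopiles")


def random_spec(rng: random.Random, max_leaves: int = 25) -> PlantSpec:
    """A random PlantSpec with 1-3 planted clades, bounded total size."""
    n_clades = rng.randint(1, 3)
    clades = []
    budget = max_leaves - 2  # leave room for background leaves
    for _ in range(n_clades):
        category = rng.choice(CATEGORIES)
        # lineages share rank 1 so cross-rank rules can overlap clades
        lineage = ("Eukaryota", category)
        if rng.random() < 0.4:
            lineage = lineage + (f"genus_{rng.randint(0, 2)}",)
        n_leaves = rng.randint(1, min(6, max(1, budget)))
        budget -= n_leaves
        support = rng.choice((0.5, 0.9, 1.0))
        clades.append(PlantedClade(category, lineage, n_leaves, support))
        if budget <= 0:
            break
    n_background = rng.randint(2, max(2, min(8, budget)))
    return PlantSpec(
        n_background_leaves=n_background,
        planted_clades=clades,
        support_noise=(0.0, 0.97) if rng.random() < 0.8 else None,
        branch_length_mean=rng.choice((0.05, 0.2)),
        seed=rng.randrange(2**31),
    )


def random_params(
    rng: random.Random, spec: PlantSpec, single_rank: bool = False
) -> TrimParams:
    """Random rule set plausible for ``spec``'s planted categories.

    With ``single_rank`` every rule (and any default) tests the same
    lineage rank, the regime in which a second dereplication pass is
    guaranteed to remove nothing further.
    """
    threshold = rng.choice((0.0, 0.8, 0.95))
    rules: list[DereplicationRule] = []
    seen: set[tuple[str, int]] = set()
    forced_rank = 2 if single_rank else None
    for clade in spec.planted_clades:
        if rng.random() < 0.8:
            rank = forced_rank or clade.lineage.index(clade.category) + 1
            key = (clade.category, rank)
            if key not in seen:
                seen.add(key)
                rules.append(
                    DereplicationRule(clade.category, rank, rng.randint(1, 3))
                )
    if not single_rank and rng.random() < 0.3:
        rules.append(DereplicationRule("Eukaryota", 1, rng.randint(1, 3)))
    default_rule = None
    if rng.random() < 0.4:
        rank = forced_rank if single_rank else rng.randint(1, 3)
        default_rule = (rank, rng.randint(1, 2))
    return TrimParams(
        support_threshold=threshold, rules=rules, default_rule=default_rule
    )


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20260904)


# --- tiny independent oracles used across test modules ---------------------


def resolve_triplet(tree, a: str, b: str, c: str):
    """Rooted-triplet resolution by brute-force ancestor inspection.

    Returns the frozenset pair forming the cherry, or None when the
    triplet is unresolved (all three meet at one node).
    """
    paths = {}
    for target in (a, b, c):
        stack = [(tree.root, [tree.root])]
        while stack:
            node, path = stack.pop()
            if node.is_leaf and node.name == target:
                paths[target] = path
                break
            for child in node.children:
                stack.append((child, path + [child]))

    def lca_depth(x: str, y: str) -> int:
        depth = 0
        for u, v in zip(paths[x], paths[y]):
            if u is not v:
                break
            depth += 1
        return depth

    pairs = {
        frozenset((a, b)): lca_depth(a, b),
        frozenset((a, c)): lca_depth(a, c),
        frozenset((b, c)): lca_depth(b, c),
    }
    deepest = max(pairs.values())
    winners = [pair for pair, depth in pairs.items() if depth == deepest]
    return winners[0] if len(winners) == 1 else None
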