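import itertools
import statistics

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from treederep import (
    DereplicationRule,
    TrimParams,
    ValidationError,
    dereplicate,
    generate_tree,
    leaf_depths,
    load_taxonomy,
    median_depth,
    parse_newick,
    restrict_to_leaves,
    select_representatives,
)

from conftest import random_params, random_spec


class TestLeafDepths:
    def test_hand_sum(self):
        tree = parse_newick("(((A:1,B:3):2,C:4):0.5,out:9);")
        clade = tree.root.children[0]
        assert leaf_depths(tree, clade) == {"A": 3.0, "B": 5.0, "C": 4.0}

    def test_all_lengths_absent(self):
        tree = parse_newick("(((A,B),C),out);")
        clade = tree.root.children[0]
        assert leaf_depths(tree, clade) == {"A": 0.0, "B": 0.0, "C": 0.0}

    def test_matches_parent_pointer_walk(self, rng):
        for _ in range(100):
            tree, _, _ = generate_tree(random_spec(rng))
            parents = {}
            for node in tree.root.walk():
                for child in node.children:
                    parents[id(child)] = node
            clade = rng.choice(tree.internal_nodes())
            depths = leaf_depths(tree, clade)
            for leaf in clade.iter_leaves():
                total, cursor = 0.0, leaf
                while cursor is not clade:
                    total += cursor.branch_length or 0.0
                    cursor = parents[id(cursor)]
                assert depths[leaf.name] == pytest.approx(total, abs=1e-12)


class TestMedianDepth:
    def test_odd(self):
        assert median_depth({"A": 3, "B": 5, "C": 4}) == 4

    def test_even_mean_of_central(self):
        assert median_depth({"A": 1, "B": 3}) == 2

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            median_depth({})

    @given(st.lists(st.floats(0, 100), min_size=1, max_size=30))
    def test_matches_sort_oracle(self, values):
        depths = {f"l{i}": v for i, v in enumerate(values)}
        ordered = sorted(values)
        k = len(ordered)
        if k % 2:
            expected = ordered[k // 2]
        else:
            expected = (ordered[k // 2 - 1] + ordered[k // 2]) / 2
        assert median_depth(depths) == expected


class TestSelectRepresentatives:
    def test_median_attainer_kept(self):
        order = ["A", "B", "C"]
        assert select_representatives({"A": 3, "B": 5, "C": 4}, order, 1) == ["C"]

    def test_ties_broken_by_leaf_order(self):
        order = ["A", "B", "C"]
        assert select_representatives({"A": 1, "B": 1, "C": 1}, order, 2) == [
            "A",
            "B",
        ]

    def test_small_clade_returns_all(self):
        order = ["A", "B"]
        assert select_representatives({"A": 1, "B": 9}, order, 5) == ["A", "B"]

    def test_result_in_leaf_order(self):
        order = ["A", "B", "C", "D"]
        got = select_representatives({"A": 9, "B": 4, "C": 0, "D": 4.1}, order, 2)
        assert got == ["B", "D"]

    def test_retain_below_one_rejected(self):
        with pytest.raises(ValidationError):
            select_representatives({"A": 1, "B": 2}, ["A", "B"], 0)

    @settings(max_examples=300, deadline=None)
    @given(
        st.lists(
            st.floats(0, 10, allow_nan=False), min_size=1, max_size=10
        ),
        st.integers(1, 4),
        st.randoms(use_true_random=False),
    )
    def test_matches_exhaustive_subset_oracle(self, values, retain, hrng):
        names = [f"l{i}" for i in range(len(values))]
        order = list(names)
        hrng.shuffle(order)
        depths = dict(zip(names, values))
        got = select_representatives(depths, order, retain)
        if len(values) <= retain:
            assert got == sorted(names, key=order.index)
            return
        med = statistics.median(values)
        best_key, best = None, None
        for combo in itertools.combinations(names, retain):
            key = (
                tuple(sorted(abs(depths[n] - med) for n in combo)),
                tuple(sorted(order.index(n) for n in combo)),
            )
            if best_key is None or key < best_key:
                best_key, best = key, combo
        assert got == sorted(best, key=order.index)


TAX = load_taxonomy(
    "a1\tEukaryota;Amoebozoa\n"
    + "".join(f"v{i}\tEukaryota;Viridiplantae\n" for i in range(1, 7))
    + "out1\tBacteria\nout2\tBacteria2\n"
)


class TestDereplicate:
    def test_clade_smaller_than_retain_skipped(self):
        # one Amoebozoa OTU, rule retains two -> the clade is ignored
        # and the single OTU survives untouched
        tree = parse_newick("((a1:1,v1:1)0.99:1,(v2:1,out1:1)0.9:1);")
        params = TrimParams(0.8, [DereplicationRule("Amoebozoa", 2, 2)])
        result = dereplicate(tree, TAX, params)
        assert "a1" in result.retained_otus
        assert result.records == []
        assert result.retained_otus == tree.leaf_order

    def test_no_supported_nodes_keeps_everything(self):
        tree = parse_newick("((v1:1,v2:1)0.5:1,(v3:1,v4:1)0.3:1);")
        params = TrimParams(0.8, [DereplicationRule("Viridiplantae", 2, 1)])
        result = dereplicate(tree, TAX, params)
        assert result.retained_otus == tree.leaf_order
        assert result.records == []

    def test_exact_size_clade_recorded_with_zero_removed(self):
        tree = parse_newick("((v1:1,v2:1)0.99:1,out1:5);")
        params = TrimParams(0.8, [DereplicationRule("Viridiplantae", 2, 2)])
        result = dereplicate(tree, TAX, params)
        assert len(result.records) == 1
        assert result.records[0].removed_count == 0
        assert result.retained_otus == tree.leaf_order

    def test_removal_counts_and_records(self):
        tree = parse_newick(
            "(((v1:1,v2:2)1.0:1,(v3:3,v4:4)1.0:1)1.0:1,(out1:1,out2:1)0.9:1);"
        )
        params = TrimParams(0.8, [DereplicationRule("Viridiplantae", 2, 2)])
        result = dereplicate(tree, TAX, params)
        assert len(result.records) == 1
        rec = result.records[0]
        assert set(rec.clade_leaves) == {"v1", "v2", "v3", "v4"}
        assert rec.removed_count == 2
        assert len(rec.retained) == 2
        assert len(result.retained_otus) == 4

    def test_outermost_wins_across_nested_categories(self):
        taxonomy = load_taxonomy(
            "h1\tEukaryota;Metazoa;Homo\n"
            "h2\tEukaryota;Metazoa;Homo\n"
            "h3\tEukaryota;Metazoa;Homo\n"
            "m1\tEukaryota;Metazoa;Mus\n"
            "out\tBacteria\n"
        )
        tree = parse_newick(
            "((((h1:1,h2:1)1.0:1,h3:1)1.0:1,m1:1)1.0:1,out:9);"
        )
        params = TrimParams(
            0.8,
            [DereplicationRule("Homo", 3, 1), DereplicationRule("Metazoa", 2, 2)],
        )
        result = dereplicate(tree, taxonomy, params)
        # only the enclosing Metazoa clade is processed
        assert len(result.records) == 1
        assert result.records[0].category == "Metazoa"
        assert result.records[0].removed_count == 2
        assert len(result.retained_otus) == 3  # 2 metazoans + out

    def test_unmapped_leaves_never_removed(self, rng):
        for _ in range(50):
            spec = random_spec(rng)
            tree, taxonomy, _ = generate_tree(spec)
            params = random_params(rng, spec)
            # unmap one planted leaf; it must always survive
            victim = next(
                (n for n in tree.leaf_order if not n.startswith("bg_")), None
            )
            if victim is None:
                continue
            del taxonomy.entries[victim]
            result = dereplicate(tree, taxonomy, params)
            assert victim in result.retained_otus

    def test_conservation(self, rng):
        for _ in range(100):
            spec = random_spec(rng)
            tree, taxonomy, _ = generate_tree(spec)
            params = random_params(rng, spec)
            result = dereplicate(tree, taxonomy, params)
            assert len(result.retained_otus) + result.total_removed == len(
                tree.leaf_order
            )

    def test_leaves_outside_maximal_clades_retained(self, rng):
        for _ in range(50):
            spec = random_spec(rng)
            tree, taxonomy, _ = generate_tree(spec)
            params = random_params(rng, spec)
            result = dereplicate(tree, taxonomy, params)
            in_clades = set().union(
                *[set(r.clade_leaves) for r in result.records], set()
            )
            for name in tree.leaf_order:
                if name not in in_clades:
                    assert name in result.retained_otus

    def test_median_attainment_odd_retain_one(self, rng):
        hits = 0
        for _ in range(200):
            spec = random_spec(rng)
            tree, taxonomy, _ = generate_tree(spec)
            params = random_params(rng, spec)
            params = TrimParams(
                params.support_threshold,
                [
                    DereplicationRule(r.category, r.rank, 1)
                    for r in params.rules
                ],
                None,
            )
            result = dereplicate(tree, taxonomy, params)
            for rec in result.records:
                if len(rec.clade_leaves) % 2 == 1 and len(rec.retained) == 1:
                    depths = leaf_depths(
                        tree,
                        next(
                            n
                            for n in tree.internal_nodes()
                            if set(n.leaf_names()) == set(rec.clade_leaves)
                        ),
                    )
                    assert depths[rec.retained[0]] == rec.median
                    hits += 1
        assert hits > 10

    def test_idempotence_single_rank_rules(self, rng):
        checked = 0
        for _ in range(150):
            spec = random_spec(rng)
            tree, taxonomy, _ = generate_tree(spec)
            params = random_params(rng, spec, single_rank=True)
            result = dereplicate(tree, taxonomy, params)
            if len(result.retained_otus) < 2:
                continue
            trimmed = restrict_to_leaves(tree, set(result.retained_otus))
            second = dereplicate(trimmed, taxonomy, params)
            assert second.total_removed == 0
            assert second.retained_otus == result.retained_otus
            checked += 1
        assert checked > 100

    def test_threshold_monotonicity_single_rule(self, rng):
        for _ in range(60):
            spec = random_spec(rng)
            tree, taxonomy, _ = generate_tree(spec)
            category = spec.planted_clades[0].category
            rank = spec.planted_clades[0].lineage.index(category) + 1
            rule = DereplicationRule(category, rank, rng.randint(1, 3))
            removed = []
            for threshold in (0.0, 0.5, 0.9, 1.01):
                params = TrimParams(threshold, [rule])
                removed.append(dereplicate(tree, taxonomy, params).total_removed)
            assert removed == sorted(removed, reverse=True)

    def test_retain_monotonicity(self, rng):
        for _ in range(60):
            spec = random_spec(rng)
            tree, taxonomy, _ = generate_tree(spec)
            category = spec.planted_clades[0].category
            rank = spec.planted_clades[0].lineage.index(category) + 1
            threshold = rng.choice((0.0, 0.8))
            removed = []
            for retain in (1, 2, 3, 4):
                params = TrimParams(
                    threshold, [DereplicationRule(category, rank, retain)]
                )
                removed.append(dereplicate(tree, taxonomy, params).total_removed)
            assert removed == sorted(removed, reverse=True)
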