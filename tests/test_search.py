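import numpy as np
import pytest

from backbonemp.backbone import build_backbone, satisfies_constraint
from backbonemp.parsimony import tree_length
from backbonemp.search import (
    SearchConfig,
    UTree,
    constrained_addition_tree,
    exhaustive_search,
    heuristic_search,
    tbr_neighbors,
)
from backbonemp.trees import (
    leafset,
    parse_newick,
    same_topology,
    splits_of,
)

from conftest import enumerate_topologies, make_matrix, random_matrix


def full_backbone(newick, taxa=None):
    t = parse_newick(newick)
    for n in t.preorder_internal_node_iter():
        n.support = 1.0
    return build_backbone(t, 0.70, constrained_taxa=taxa)


class TestAdditionTree:
    def test_fully_resolved_backbone_forces_the_topology(self):
        m = random_matrix(np.random.default_rng(0), 6, 10, k=2)
        target = "((A,B),((C,D),(E,F)));"
        bb = full_backbone(target)
        for seed in range(10):
            t = constrained_addition_tree(m, bb, rng=seed)
            assert same_topology(t, parse_newick(target))

    def test_unconstrained_addition_gives_binary_tree(self):
        m = random_matrix(np.random.default_rng(1), 4, 6)
        t = constrained_addition_tree(m, rng=0)
        assert leafset(t) == frozenset(m.taxon_names)
        assert len(splits_of(t)) == 1

    def test_pair_constraint_makes_sisters_for_every_seed(self):
        m = random_matrix(np.random.default_rng(2), 5, 12, k=2)
        bb = full_backbone("((A,B),C,D,E);")
        want = frozenset(
            (frozenset({"A", "B"}), frozenset({"C", "D", "E"}))
        )
        for seed in range(50):
            t = constrained_addition_tree(m, bb, rng=seed)
            assert want in splits_of(t)


class TestTBR:
    def test_quartet_neighborhood_is_the_other_two_topologies(self):
        t = parse_newick("((A,B),(C,D));")
        out = list(tbr_neighbors(t))
        assert len(out) == 2
        got = {frozenset(splits_of(x)) for x in out}
        expect = {
            frozenset(splits_of(parse_newick("((A,C),(B,D));"))),
            frozenset(splits_of(parse_newick("((A,D),(B,C));"))),
        }
        assert got == expect

    def test_neighbors_preserve_the_leaf_set(self):
        t = parse_newick("(((A,B),C),(D,(E,F)));")
        for nb in tbr_neighbors(t):
            assert leafset(nb) == leafset(t)
            assert len(splits_of(nb)) == 3

    @pytest.mark.parametrize("n", [5, 6])
    def test_neighborhood_matches_independent_characterization(self, n):
        """tree2 is one TBR move from tree1 iff some bisection of tree1
        into parts (L1, L2) leaves both induced subtrees unchanged in
        tree2 AND tree2 has an edge separating L1 from L2 (the
        reconnection edge)."""
        names = [chr(65 + i) for i in range(n)]
        rng = np.random.default_rng(n)
        t = UTree.initial([0, 1, 2], n)
        for leaf in range(3, n):
            edges = t.edges()
            t.insert_leaf(leaf, edges[int(rng.integers(len(edges)))])
        tree = t.to_dendropy(names)

        def induced(splits, sub, full):
            out = set()
            for s in splits:
                a, b = tuple(s)
                ra, rb = a & sub, b & sub
                if len(ra) >= 2 and len(rb) >= 2:
                    out.add(frozenset((ra, rb)))
            return out

        full = leafset(tree)
        t_splits = splits_of(tree)
        # every bisection = an edge's split, plus the trivial leaf splits
        sides = set()
        for s in t_splits:
            a, b = tuple(s)
            sides.add(frozenset(a))
        for name in names:
            sides.add(frozenset(full - {name}))

        def is_tbr_neighbor(other_splits):
            if other_splits == t_splits:
                return False
            for side in sides:
                rest = full - side
                if len(side) >= 2 and len(rest) >= 2 and \
                   frozenset((side, rest)) not in other_splits:
                    continue  # no reconnection edge between the parts
                if induced(t_splits, side, full) == \
                   induced(other_splits, side, full) and \
                   induced(t_splits, rest, full) == \
                   induced(other_splits, rest, full):
                    return True
            return False

        expected = {
            frozenset(splits_of(parse_newick(nwk)))
            for nwk in enumerate_topologies(names)
            if is_tbr_neighbor(splits_of(parse_newick(nwk)))
        }
        got = {frozenset(splits_of(nb)) for nb in tbr_neighbors(tree)}
        assert got == expected


class TestHeuristicSearch:
    def test_all_constant_matrix_scores_zero(self):
        m = make_matrix([[0, 1]] * 5)
        res = heuristic_search(m, SearchConfig(replicates=2, seed=0))
        assert res.length == 0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_minimum_on_six_taxa(self, seed):
        rng = np.random.default_rng(seed)
        m = random_matrix(rng, 6, 20, k=2, p_missing=0.1)
        exact = exhaustive_search(m)
        heur = heuristic_search(
            m, SearchConfig(replicates=2, hold_per_replicate=10, seed=seed)
        )
        assert heur.length == exact.length

    def test_constrained_matches_constrained_exhaustive(self):
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            m = random_matrix(rng, 6, 15, k=2)
            bb = full_backbone("((A,B),(C,D),E,F);")
            exact = exhaustive_search(m, constraint=bb)
            heur = heuristic_search(
                m,
                SearchConfig(replicates=2, hold_per_replicate=10,
                             seed=seed, constraint=bb),
            )
            assert heur.length == exact.length
            for t in heur.trees:
                assert satisfies_constraint(t, bb)

    def test_every_mpt_rescores_to_the_reported_length(self, rng):
        m = random_matrix(rng, 7, 15, k=3, p_missing=0.1)
        res = heuristic_search(
            m, SearchConfig(replicates=3, hold_per_replicate=10, seed=4)
        )
        for t in res.trees:
            assert tree_length(t, m) == res.length

    def test_seed_determinism(self):
        m = random_matrix(np.random.default_rng(9), 7, 12, k=2)
        cfg = SearchConfig(replicates=3, hold_per_replicate=5, seed=123)
        a = heuristic_search(m, cfg)
        b = heuristic_search(m, cfg)
        assert a.length == b.length
        assert {frozenset(splits_of(t)) for t in a.trees} == \
            {frozenset(splits_of(t)) for t in b.trees}

    def test_trace_has_one_entry_per_replicate(self):
        m = random_matrix(np.random.default_rng(10), 6, 10)
        res = heuristic_search(m, SearchConfig(replicates=4, seed=0))
        assert len(res.trace) == 4
        assert min(res.trace) == res.length

    def test_mpts_are_deduplicated_by_split_set(self):
        m = random_matrix(np.random.default_rng(12), 6, 8, k=2)
        res = heuristic_search(
            m, SearchConfig(replicates=4, hold_per_replicate=10, seed=1)
        )
        keys = [frozenset(splits_of(t)) for t in res.trees]
        assert len(keys) == len(set(keys))

    def test_collapse_rule_none_keeps_binary_trees(self):
        m = random_matrix(np.random.default_rng(13), 6, 8, k=2)
        res = heuristic_search(
            m,
            SearchConfig(replicates=2, seed=1, collapse_rule="none"),
        )
        for t in res.trees:
            assert len(splits_of(t)) == 3  # fully resolved on 6 taxa

    def test_constraint_can_only_lengthen_trees(self):
        rng = np.random.default_rng(3)
        m = random_matrix(rng, 6, 20, k=2)
        free = heuristic_search(m, SearchConfig(replicates=2, seed=5))
        bb = full_backbone("((A,C),(B,E),D,F);")
        forced = heuristic_search(
            m, SearchConfig(replicates=2, seed=5, constraint=bb)
        )
        assert forced.length >= free.length
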