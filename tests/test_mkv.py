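import itertools
import math

import numpy as np
import pytest

from backbonemp.mkv import (
    MkvModel,
    MLSearchConfig,
    discrete_gamma_rates,
    fit_mkv,
    mk_transition_probs,
    mkv_log_likelihood,
    nj_start_tree,
    p_distance_matrix,
)
from backbonemp.trees import parse_newick, splits_of

from conftest import make_matrix, random_matrix


def variable_matrix(rng, n_taxa, n_char, k=2, **kw):
    """Random matrix with constant characters removed (the Mkv regime)."""
    m = random_matrix(rng, n_taxa, n_char, k=k, **kw)
    keep = []
    for j in range(m.n_characters):
        observed = set()
        for row in m.cells:
            observed |= row[j].states
        if len(observed) >= 2:
            keep.append(j)
    return m.subset_characters(keep)


def pattern_matrix(names, states, k):
    return make_matrix([[s] for s in states], names=list(names), n_states=k)


def brute_force_site_likelihood(tree, leaf_states, k):
    """Sum over all internal-node states of products of Mk transition
    probabilities, with uniform 1/k at the root."""
    internals = [n for n in tree.postorder_node_iter() if not n.is_leaf()]
    total = 0.0
    for assign in itertools.product(range(k), repeat=len(internals)):
        states = dict(zip(internals, assign))
        for leaf in tree.leaf_node_iter():
            states[leaf] = leaf_states[leaf.taxon.label]
        p = 1.0 / k  # root prior
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            same, diff = mk_transition_probs(k, node.edge.length)
            p *= same if states[node] == states[node.parent_node] else diff
        total += p
    return total


class TestTransitionModel:
    def test_two_taxon_closed_form(self):
        # P(the two leaves differ) over total path v = (k-1)/k (1 - e^{-kv/(k-1)})
        m = pattern_matrix("AB", [0, 1], 2)
        t = parse_newick("(A:0.3,B:0.4);")
        res = mkv_log_likelihood(t, m, MkvModel(correction=False))
        v = 0.7
        p_diff_total = 0.5 * (1 - math.exp(-2 * v))
        # pattern (0,1) is one of the two distinguishable unequal patterns
        assert res.log_likelihood == pytest.approx(math.log(p_diff_total / 2))

    def test_transition_probs_row_sums_to_one(self):
        for k in (2, 3, 5):
            same, diff = mk_transition_probs(k, 0.37)
            assert same + (k - 1) * diff == pytest.approx(1.0)

    @pytest.mark.parametrize("k", [2, 3])
    def test_four_taxon_likelihood_matches_brute_force(self, k):
        rng = np.random.default_rng(k)
        t = parse_newick("((A:0.1,B:0.35):0.2,(C:0.4,D:0.15):0.05);")
        for _ in range(5):
            states = {n: int(rng.integers(k)) for n in "ABCD"}
            m = pattern_matrix("ABCD", [states[n] for n in "ABCD"], k)
            res = mkv_log_likelihood(t, m, MkvModel(k=k, correction=False))
            expect = brute_force_site_likelihood(t, states, k)
            assert res.log_likelihood == pytest.approx(math.log(expect))


class TestMkvCorrection:
    @pytest.mark.parametrize("k,n", [(2, 4), (2, 5), (3, 4)])
    def test_pattern_probabilities_normalize(self, k, n):
        names = [chr(65 + i) for i in range(n)]
        nwk = "(" + ",".join(f"{x}:0.2" for x in names) + ");"
        t = parse_newick(nwk)
        total_all = 0.0
        total_variable = 0.0
        for pattern in itertools.product(range(k), repeat=n):
            m = pattern_matrix(names, list(pattern), k)
            plain = math.exp(
                mkv_log_likelihood(t, m, MkvModel(k=k, correction=False))
                .log_likelihood
            )
            total_all += plain
            if len(set(pattern)) > 1:
                corr = math.exp(
                    mkv_log_likelihood(t, m, MkvModel(k=k, correction=True))
                    .log_likelihood
                )
                total_variable += corr
        assert total_all == pytest.approx(1.0)
        assert total_variable == pytest.approx(1.0)

    def test_correction_raises_every_variable_site_likelihood(self):
        t = parse_newick("((A:0.2,B:0.3):0.1,(C:0.25,D:0.15):0.2);")
        m = make_matrix([[0, 0], [0, 1], [1, 0], [1, 1]])
        plain = mkv_log_likelihood(t, m, MkvModel(correction=False))
        corr = mkv_log_likelihood(t, m, MkvModel(correction=True))
        assert np.all(corr.per_character > plain.per_character)

    def test_invariant_character_rejected_under_strict_mkv(self):
        t = parse_newick("((A:0.2,B:0.3):0.1,C:0.2);")
        m = make_matrix([[0], [0], [0]])
        with pytest.raises(ValueError):
            mkv_log_likelihood(t, m, MkvModel())
        with pytest.warns(UserWarning):
            res = mkv_log_likelihood(t, m, MkvModel(), on_invariant="drop")
        assert res.log_likelihood == 0.0


class TestInvariances:
    def test_likelihood_invariant_to_rerooting(self):
        rng = np.random.default_rng(3)
        m = variable_matrix(rng, 6, 25, k=2, p_missing=0.15)
        nwk = "(((A:0.1,B:0.2):0.15,C:0.3):0.05,(D:0.2,E:0.1):0.12,F:0.4);"
        t1 = parse_newick(nwk)
        base = mkv_log_likelihood(t1, m).log_likelihood
        t2 = parse_newick(nwk)
        node = next(
            n for n in t2.preorder_internal_node_iter()
            if n.parent_node is not None
        )
        t2.reroot_at_node(node, update_bipartitions=False)
        for n in t2.preorder_node_iter():
            if n.parent_node is not None and n.edge.length is None:
                n.edge.length = 0.0
        again = mkv_log_likelihood(t2, m).log_likelihood
        assert again == pytest.approx(base, rel=1e-9)

    def test_gamma_limit_recovers_equal_rates(self):
        rng = np.random.default_rng(4)
        m = variable_matrix(rng, 5, 30, k=2)
        t = parse_newick("(((A:0.1,B:0.2):0.1,C:0.3):0.05,(D:0.2,E:0.1):0.1);")
        equal = mkv_log_likelihood(t, m, MkvModel()).log_likelihood
        near = mkv_log_likelihood(
            t, m, MkvModel(gamma_alpha=1e6)
        ).log_likelihood
        assert abs(near - equal) < 1e-4

    def test_discrete_gamma_rates_average_to_one(self):
        for alpha in (0.2, 1.0, 5.0):
            r = discrete_gamma_rates(alpha, 4)
            assert r.mean() == pytest.approx(1.0, abs=1e-6)
            assert np.all(np.diff(r) > 0)


class TestNeighborJoining:
    def test_three_taxa_unique_topology(self):
        m = make_matrix([[0, 0], [0, 1], [1, 1]], names=list("ABC"))
        t = nj_start_tree(m)
        assert {l.taxon.label for l in t.leaf_node_iter()} == set("ABC")

    def test_p_distance_skips_unshared_characters(self):
        m = make_matrix([[0, "?"], ["?", 1], [0, 1]], names=list("ABC"))
        with pytest.warns(UserWarning):
            d = p_distance_matrix(m)
        # A,B share nothing -> filled with max distance
        assert d[0, 1] == d.max()

    def test_recovers_topology_from_additive_distances(self):
        # distances from a clean split matrix are additive enough for NJ
        rows = [[0] * 6, [0] * 6, [1, 1, 1, 0, 0, 0], [1] * 6]
        rows[2] = [1, 1, 1, 0, 0, 0]
        m = make_matrix(
            [[0, 0, 0, 0, 0, 0],
             [0, 0, 0, 0, 0, 1],
             [1, 1, 1, 0, 1, 0],
             [1, 1, 1, 1, 1, 1]],
            names=list("ABCD"),
        )
        t = nj_start_tree(m)
        want = {frozenset((frozenset("AB"), frozenset("CD")))}
        assert splits_of(t) == want

    def test_branch_lengths_are_positive(self, rng):
        m = random_matrix(rng, 6, 40, k=2, p_missing=0.1)
        t = nj_start_tree(m)
        for n in t.preorder_node_iter():
            if n.parent_node is not None:
                assert n.edge.length > 0


class TestFitMkv:
    def test_recovers_simulated_topology(self):
        from backbonemp.simulate import SimulationConfig, simulate_dataset

        hits = 0
        for seed in range(3):
            cfg = SimulationConfig(
                n_taxa=6, n_characters=300, fossil_fraction=0.0,
                missing_fraction=0.0, seed=seed, n_sample_trees=1,
            )
            tree, matrix, _ = simulate_dataset(cfg)
            fitted, result = fit_mkv(
                matrix,
                MkvModel(),
                MLSearchConfig(n_rounds=2, neighbors_per_round=6,
                               branch_sweeps=1, seed=seed),
            )
            assert np.isfinite(result.log_likelihood)
            if splits_of(fitted) == splits_of(tree):
                hits += 1
        assert hits >= 2

    def test_search_never_decreases_likelihood(self):
        rng = np.random.default_rng(9)
        m = variable_matrix(rng, 5, 60, k=2)
        start = nj_start_tree(m)
        start_ll = mkv_log_likelihood(start, m).log_likelihood
        _, result = fit_mkv(
            m, MkvModel(),
            MLSearchConfig(n_rounds=1, neighbors_per_round=4,
                           branch_sweeps=1, seed=0),
        )
        assert result.log_likelihood >= start_ll
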