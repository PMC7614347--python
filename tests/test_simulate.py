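import numpy as np
import pytest

from backbonemp.matrix import CellKind, matrix_summary
from backbonemp.simulate import (
    SimulationConfig,
    inject_missing,
    perturbed_sample,
    scale_branch_lengths,
    simulate_dataset,
    simulate_matrix,
    simulate_yule_tree,
)
from backbonemp.trees import leafset, mcc_tree, same_topology, splits_of


class TestYule:
    def test_two_taxa_is_a_cherry(self):
        t = simulate_yule_tree(2, 1.0, rng=0)
        assert len(leafset(t)) == 2

    @pytest.mark.parametrize("n", [2, 5, 13, 50])
    def test_leaf_count(self, n):
        t = simulate_yule_tree(n, 1.0, rng=n)
        assert len(leafset(t)) == n

    def test_tree_is_ultrametric(self):
        t = simulate_yule_tree(10, 1.0, rng=1)
        depths = []
        for leaf in t.leaf_node_iter():
            d, node = 0.0, leaf
            while node.parent_node is not None:
                d += node.edge.length
                node = node.parent_node
            depths.append(d)
        assert max(depths) - min(depths) < 1e-9

    def test_depth_grows_with_taxon_count(self):
        rng = np.random.default_rng(2)

        def mean_height(n):
            out = []
            for _ in range(60):
                t = simulate_yule_tree(n, 1.0, rng)
                leaf = next(t.leaf_node_iter())
                d, node = 0.0, leaf
                while node.parent_node is not None:
                    d += node.edge.length
                    node = node.parent_node
                out.append(d)
            return float(np.mean(out))

        assert mean_height(4) < mean_height(16) < mean_height(40)

    def test_scale_sets_height_and_floor(self):
        t = simulate_yule_tree(8, 1.0, rng=3)
        scale_branch_lengths(t, 0.2, min_length=0.01)
        lengths = [
            n.edge.length for n in t.preorder_node_iter()
            if n.parent_node is not None
        ]
        assert min(lengths) >= 0.01


class TestSimulateMatrix:
    def test_zero_rate_without_filtering_gives_constant_characters(self):
        cfg = SimulationConfig(
            n_taxa=6, n_characters=20, variable_only=False,
            fossil_fraction=0.0, seed=0,
        )
        t = simulate_yule_tree(6, 1.0, rng=0)
        for node in t.preorder_node_iter():
            if node.parent_node is not None:
                node.edge.length = 0.0
        m = simulate_matrix(t, cfg, rng=0)
        for j in range(m.n_characters):
            states = {next(iter(row[j].states)) for row in m.cells}
            assert len(states) == 1

    def test_zero_rate_with_filtering_is_an_error(self):
        cfg = SimulationConfig(
            n_taxa=6, n_characters=5, variable_only=True, seed=0)
        t = simulate_yule_tree(6, 1.0, rng=0)
        for node in t.preorder_node_iter():
            if node.parent_node is not None:
                node.edge.length = 0.0
        with pytest.raises(ValueError):
            simulate_matrix(t, cfg, rng=0)

    def test_variable_only_filtering_leaves_no_constant_characters(self):
        cfg = SimulationConfig(
            n_taxa=8, n_characters=100, variable_only=True,
            fossil_fraction=0.0, seed=1,
        )
        t = scale_branch_lengths(simulate_yule_tree(8, 1.0, rng=1), 0.1, 0.01)
        m = simulate_matrix(t, cfg, rng=1)
        for j in range(m.n_characters):
            states = {next(iter(row[j].states)) for row in m.cells}
            assert len(states) > 1

    def test_long_branches_approach_stationary_frequencies(self):
        cfg = SimulationConfig(
            n_taxa=4, n_characters=8000, variable_only=False,
            fossil_fraction=0.0, seed=2,
        )
        t = simulate_yule_tree(4, 1.0, rng=2)
        for node in t.preorder_node_iter():
            if node.parent_node is not None:
                node.edge.length = 50.0
        m = simulate_matrix(t, cfg, rng=2)
        freq1 = np.mean([
            next(iter(row[0 + j].states))
            for row in m.cells for j in range(m.n_characters)
        ])
        assert freq1 == pytest.approx(0.5, abs=0.02)

    def test_fossil_fraction_flags_taxa(self):
        cfg = SimulationConfig(
            n_taxa=13, n_characters=10, fossil_fraction=9 / 52, seed=3,
            variable_only=False,
        )
        t = simulate_yule_tree(13, 1.0, rng=3)
        m = simulate_matrix(t, cfg, rng=3)
        assert matrix_summary(m).n_fossil == round(13 * 9 / 52)


class TestInjectMissing:
    def base(self, seed=0, n_char=224):
        cfg = SimulationConfig(
            n_taxa=24, n_characters=n_char, fossil_fraction=20 / 24,
            variable_only=False, seed=seed,
        )
        t = simulate_yule_tree(cfg.n_taxa, 1.0, rng=seed)
        return cfg, simulate_matrix(t, cfg, rng=seed)

    def test_zero_fraction_is_identity(self):
        cfg, m = self.base()
        cfg.missing_fraction = 0.0
        assert inject_missing(m, cfg, rng=0) == m

    def test_unit_fraction_blanks_everything(self):
        cfg, m = self.base()
        cfg.missing_fraction = 1.0
        out = inject_missing(m, cfg, rng=0)
        assert all(
            c.kind is CellKind.MISSING for row in out.cells for c in row
        )

    def test_fossil_rows_are_about_three_times_as_incomplete(self):
        cfg, m = self.base(seed=5)
        cfg.missing_fraction = 0.1
        cfg.fossil_missing_multiplier = 3.0
        out = inject_missing(m, cfg, rng=5)
        rates = {True: [], False: []}
        for t, row in zip(out.taxa, out.cells):
            miss = sum(1 for c in row if not c.is_observed) / len(row)
            rates[t.extant].append(miss)
        ratio = np.mean(rates[False]) / np.mean(rates[True])
        assert 2.5 <= ratio <= 3.5

    def test_explicit_fossil_fraction_override(self):
        cfg, m = self.base(seed=6)
        cfg.missing_fraction = 0.0
        cfg.fossil_missing_fraction = 0.5
        out = inject_missing(m, cfg, rng=6)
        for t, row in zip(out.taxa, out.cells):
            miss = sum(1 for c in row if not c.is_observed) / len(row)
            if t.extant:
                assert miss == 0.0
            else:
                assert 0.3 < miss < 0.7


class TestPerturbedSample:
    def test_zero_probability_reproduces_the_true_tree(self):
        cfg = SimulationConfig(
            n_taxa=8, n_characters=5, nni_probability=0.0,
            n_sample_trees=10, seed=0,
        )
        t = simulate_yule_tree(8, 1.0, rng=0)
        sample = perturbed_sample(t, cfg, rng=0)
        for s in sample:
            assert same_topology(s, t)
        mcc = mcc_tree(sample)
        for n in mcc.preorder_internal_node_iter():
            if n.parent_node is not None:
                assert n.support == pytest.approx(1.0)

    def test_support_of_true_clades_decreases_with_perturbation(self):
        t = simulate_yule_tree(10, 1.0, rng=4)
        true_splits = splits_of(t)

        def mean_true_support(p):
            cfg = SimulationConfig(
                n_taxa=10, n_characters=5, nni_probability=p,
                n_sample_trees=200, seed=4,
            )
            sample = perturbed_sample(t, cfg, rng=4)
            counts = {s: 0 for s in true_splits}
            for tree in sample:
                here = splits_of(tree)
                for s in true_splits:
                    counts[s] += s in here
            return np.mean([c / len(sample) for c in counts.values()])

        s0, s1, s3 = (mean_true_support(p) for p in (0.0, 0.1, 0.3))
        assert s0 == pytest.approx(1.0)
        assert s0 > s1 > s3


class TestDataset:
    def test_dataset_shapes_and_reproducibility(self):
        cfg = SimulationConfig(
            n_taxa=10, n_characters=50, seed=11, n_sample_trees=5)
        t1, m1, s1 = simulate_dataset(cfg)
        t2, m2, s2 = simulate_dataset(cfg)
        assert same_topology(t1, t2)
        assert m1 == m2
        assert len(s1) == 5
        assert m1.n_taxa == 10 and m1.n_characters == 50
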