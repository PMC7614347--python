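"""Synthetic data with the statistical structure the pipeline assumes.

The generator emulates a morphological total-evidence setting: discrete
characters evolved under the symmetric Mk model (optional discrete-gamma
rate variation) on a pure-birth (Yule) tree; an ascertainment regime that
keeps only variable characters (rejection sampling, matching the Mkv
conditioning); missing data injected at a base rate with a multiplier for
fossil-flagged taxa (fossils are systematically less complete); and a
"posterior sample" built by independent NNI perturbations of a true tree,
standing in for a Bayesian molecular tree sample.

Default dimensions mirror the kind of matrix the pipeline targets:
52 taxa of which 9 are fossils, 224 characters, and a large perturbed
tree sample. Tests and scripts pass smaller values explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import dendropy

from .matrix import (
    CharacterCell,
    CharacterMatrix,
    CharacterMeta,
    TaxonRecord,
)
from .trees import TreeSample, parse_newick
from .search import UTree

__all__ = [
    "SimulationConfig",
    "simulate_yule_tree",
    "scale_branch_lengths",
    "simulate_matrix",
    "inject_missing",
    "perturbed_sample",
    "simulate_dataset",
]


@dataclass
class SimulationConfig:
    n_taxa: int = 52
    n_characters: int = 224
    k_states: int = 2
    birth_rate: float = 1.0
    gamma_alpha: Optional[float] = None
    variable_only: bool = True
    missing_fraction: float = 0.10
    fossil_fraction: float = 9 / 52
    fossil_missing_multiplier: float = 4.0
    # explicit fossil missing rate; overrides multiplier x base when set
    fossil_missing_fraction: Optional[float] = None
    nni_probability: float = 0.1
    n_sample_trees: int = 10_000
    # expected substitutions per character: root-to-tip height after
    # rescaling, and a floor applied per branch so that every internal
    # edge expects a handful of changes across a few hundred characters
    # (morphological characters retained by systematists change rarely;
    # about one change per character over the whole tree)
    tree_height: Optional[float] = 0.15
    min_branch_length: float = 0.03
    seed: int = 0

    def __post_init__(self):
        for name in ("missing_fraction", "fossil_fraction", "nni_probability"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_taxa < 4:
            raise ValueError("n_taxa >= 4 required for non-trivial topologies")
        if self.k_states < 2:
            raise ValueError("k_states >= 2")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def taxon_label(i: int) -> str:
    return f"t{i + 1:02d}"


def simulate_yule_tree(n_taxa: int, birth_rate: float = 1.0,
                       rng=None) -> dendropy.Tree:
    """Pure-birth tree: exponential waiting times between speciations,
    uniform choice of the splitting lineage, all tips extended to the
    present (ultrametric). Leaves are labelled t01, t02, ..."""
    if n_taxa < 2:
        raise ValueError("need >= 2 taxa")
    if birth_rate <= 0:
        raise ValueError("birth rate must be positive")
    rng = _as_rng(rng)
    t_now = 0.0

    class _N:  # tiny mutable node
        __slots__ = ("children", "label", "length", "start")

        def __init__(self, start):
            self.children = []
            self.label = None
            self.length = 0.0
            self.start = start

    root = _N(0.0)
    open_tips = [_N(0.0), _N(0.0)]
    root.children = list(open_tips)
    while len(open_tips) < n_taxa:
        t_now += rng.exponential(1.0 / (birth_rate * len(open_tips)))
        pick = int(rng.integers(len(open_tips)))
        parent = open_tips.pop(pick)
        parent.length = t_now - parent.start
        kids = [_N(t_now), _N(t_now)]
        parent.children = kids
        open_tips.extend(kids)
    t_end = t_now + rng.exponential(1.0 / (birth_rate * len(open_tips)))
    for i, tip in enumerate(open_tips):
        tip.length = t_end - tip.start
        tip.label = taxon_label(i)

    def emit(node) -> str:
        if not node.children:
            return f"{node.label}:{node.length:.10g}"
        inner = ",".join(emit(c) for c in node.children)
        return f"({inner}):{node.length:.10g}"

    inner = ",".join(emit(c) for c in root.children)
    return parse_newick(f"({inner});")


def scale_branch_lengths(tree: dendropy.Tree, height: float,
                         min_length: float = 0.0) -> dendropy.Tree:
    """Rescale branch lengths so the maximum root-to-tip path equals
    ``height`` (expected substitutions per character), then floor every
    branch at ``min_length``. Modifies and returns ``tree``."""
    depths = []
    for leaf in tree.leaf_node_iter():
        d, node = 0.0, leaf
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        depths.append(d)
    top = max(depths)
    if top <= 0:
        raise ValueError("tree has no positive depth to rescale")
    f = height / top
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = max((node.edge.length or 0.0) * f, min_length)
    return tree


def simulate_matrix(tree: dendropy.Tree, config: SimulationConfig,
                    rng=None) -> CharacterMatrix:
    """Evolve discrete characters along ``tree`` under the symmetric
    k-state Mk model, with per-character gamma rate multipliers when
    ``gamma_alpha`` is set. With ``variable_only`` (the Mkv ascertainment
    condition) constant characters are redrawn until variable. The last
    ``round(fossil_fraction * n)`` taxa are fossil-flagged."""
    rng = _as_rng(rng)
    k = config.k_states
    leaves = [l for l in tree.leaf_node_iter()]
    names = [l.taxon.label for l in leaves]
    nodes = list(tree.preorder_node_iter())
    for node in nodes:
        if node.parent_node is not None and (
            node.edge.length is None or node.edge.length < 0
        ):
            raise ValueError("tree must have non-negative branch lengths")
    if config.variable_only:
        total_len = sum(
            n.edge.length for n in nodes if n.parent_node is not None
        )
        if total_len <= 0:
            raise ValueError(
                "zero evolutionary rate cannot produce variable characters"
            )

    def draw_character(rate: float) -> dict:
        states = {}
        for node in nodes:
            if node.parent_node is None:
                states[node] = int(rng.integers(k))
                continue
            v = node.edge.length * rate
            p_same = 1.0 / k + (k - 1) / k * math.exp(-k / (k - 1) * v)
            parent = states[node.parent_node]
            if rng.random() < p_same:
                states[node] = parent
            else:
                others = [s for s in range(k) if s != parent]
                states[node] = others[int(rng.integers(k - 1))]
        return {l.taxon.label: states[l] for l in leaves}

    columns = []
    for _ in range(config.n_characters):
        while True:
            rate = (
                rng.gamma(config.gamma_alpha, 1.0 / config.gamma_alpha)
                if config.gamma_alpha is not None
                else 1.0
            )
            col = draw_character(rate)
            if not config.variable_only or len(set(col.values())) > 1:
                break
        columns.append(col)

    n_fossil = round(config.fossil_fraction * len(names))
    fossil_names = set(names[len(names) - n_fossil:]) if n_fossil else set()
    taxa = [TaxonRecord(n, extant=n not in fossil_names) for n in names]
    cells = [
        [CharacterCell.observed([columns[j][n]]) for j in range(len(columns))]
        for n in names
    ]
    metas = [CharacterMeta(j, n_states=k) for j in range(len(columns))]
    return CharacterMatrix(taxa=taxa, characters=metas, cells=cells)


def inject_missing(matrix: CharacterMatrix, config: SimulationConfig,
                   rng=None) -> CharacterMatrix:
    """Independently blank cells to missing: extant taxa at the base rate,
    fossil-flagged taxa at multiplier x base (capped at 1)."""
    rng = _as_rng(rng)
    base = config.missing_fraction
    fossil_p = (
        config.fossil_missing_fraction
        if config.fossil_missing_fraction is not None
        else min(1.0, base * config.fossil_missing_multiplier)
    )
    cells = []
    for t, row in zip(matrix.taxa, matrix.cells):
        p = base if t.extant else fossil_p
        cells.append([
            CharacterCell.missing() if rng.random() < p else c for c in row
        ])
    return CharacterMatrix(
        taxa=[TaxonRecord(t.name, t.extant) for t in matrix.taxa],
        characters=[
            CharacterMeta(c.index, c.n_states, c.ordered, c.label)
            for c in matrix.characters
        ],
        cells=cells,
    )


def perturbed_sample(true_tree: dendropy.Tree, config: SimulationConfig,
                     rng=None) -> TreeSample:
    """Tree sample in which each tree is the true topology after every
    internal edge independently undergoes a random NNI with probability
    ``nni_probability`` — a cheap stand-in for posterior topological
    uncertainty concentrated around a point estimate."""
    rng = _as_rng(rng)
    names = sorted(l.taxon.label for l in true_tree.leaf_node_iter())
    base = UTree.from_dendropy(true_tree, names)
    trees = []
    for _ in range(config.n_sample_trees):
        t = base.copy()
        internal_edges = [
            (u, v) for u, v in t.edges() if u >= t.n and v >= t.n
        ]
        for u, v in internal_edges:
            if rng.random() >= config.nni_probability:
                continue
            if v not in t.adj[u]:
                # an earlier swap relocated this edge's neighborhood
                continue
            # swap one subtree across the edge: neighbor a of u <-> b of v
            a_opts = [w for w in t.adj[u] if w != v]
            b_opts = [w for w in t.adj[v] if w != u]
            a = a_opts[int(rng.integers(len(a_opts)))]
            b = b_opts[int(rng.integers(len(b_opts)))]
            t._disconnect(u, a)
            t._disconnect(v, b)
            t._connect(u, b)
            t._connect(v, a)
        trees.append(t.to_dendropy(names))
    return TreeSample(trees)


def simulate_dataset(config: SimulationConfig, rng=None):
    """Full synthetic study: Yule tree (rescaled per the config), Mk
    matrix with fossil flags, missing data, and a perturbed tree sample.
    Returns ``(true_tree, matrix, tree_sample)``."""
    rng = _as_rng(rng if rng is not None else config.seed)
    tree = simulate_yule_tree(config.n_taxa, config.birth_rate, rng)
    if config.tree_height is not None:
        scale_branch_lengths(
            tree, config.tree_height, config.min_branch_length)
    matrix = simulate_matrix(tree, config, rng)
    matrix = inject_missing(matrix, config, rng)
    sample = perturbed_sample(tree, config, rng)
    return tree, matrix, sample
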