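"""Parsimony scoring and homoplasy indices.

Two scorers agree by construction and are cross-checked in the test
suite:

* a generalized Sankoff dynamic program (vectorized over characters of
  equal state count) that handles unordered and ordered characters,
  multifurcating trees, missing/inapplicable data and multi-state cells —
  the reporting path;
* a bit-packed Fitch pass over deduplicated site patterns
  (:class:`PackedCharacters` + :func:`packed_fitch_length`) restricted to
  binary trees and unordered characters — the hot path used by heuristic
  tree search.

Per-character step counts feed the ensemble consistency index
CI = Σm/Σs and retention index RI = (Σg−Σs)/(Σg−Σm), where m is the
minimum conceivable number of steps for a character on any tree and g the
maximum (its star-tree length).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import dendropy

from .matrix import CellKind, CharacterMatrix

__all__ = [
    "StepBounds",
    "HomoplasyIndices",
    "tree_length",
    "per_character_steps",
    "char_step_bounds",
    "ensemble_indices",
    "PackedCharacters",
    "packed_fitch_length",
]

_INF = np.float64(1e9)


# ---------------------------------------------------------------------------
# cell -> state set helpers


def effective_states(cell, n_states: int, inapplicable_as_state: bool = False):
    """States a cell may take during optimization. Missing cells (and, by
    default, inapplicable cells) may take any state; with
    ``inapplicable_as_state`` the gap becomes the extra state ``n_states``."""
    k = n_states + 1 if inapplicable_as_state else n_states
    if cell.kind is CellKind.OBSERVED:
        return frozenset(cell.states), k
    if cell.kind is CellKind.INAPPLICABLE and inapplicable_as_state:
        return frozenset([n_states]), k
    return frozenset(range(k)), k


# ---------------------------------------------------------------------------
# Sankoff scoring (general path)


def _tree_arrays(tree: dendropy.Tree, taxon_names: Sequence[str]):
    """Postorder node list with children indices; leaves mapped to rows."""
    name_to_row = {n: i for i, n in enumerate(taxon_names)}
    nodes = list(tree.postorder_node_iter())
    index = {id(n): i for i, n in enumerate(nodes)}
    children = []
    leaf_row = []
    for n in nodes:
        children.append([index[id(c)] for c in n.child_nodes()])
        if n.is_leaf():
            if n.taxon.label not in name_to_row:
                raise KeyError(f"leaf {n.taxon.label!r} has no matrix row")
            leaf_row.append(name_to_row[n.taxon.label])
        else:
            leaf_row.append(-1)
    return children, leaf_row


def _cost_matrix(k: int, ordered: bool) -> np.ndarray:
    states = np.arange(k)
    if ordered:
        return np.abs(states[:, None] - states[None, :]).astype(np.float64)
    return (states[:, None] != states[None, :]).astype(np.float64)


def per_character_steps(
    tree: dendropy.Tree,
    matrix: CharacterMatrix,
    inapplicable_as_state: bool = False,
) -> np.ndarray:
    """Minimum number of steps of every character on ``tree`` (Sankoff DP;
    unit costs for unordered characters, linear costs for ordered ones)."""
    children, leaf_row = _tree_arrays(tree, matrix.taxon_names)
    steps = np.zeros(matrix.n_characters, dtype=np.float64)

    # group characters by (effective state count, ordered) to vectorize
    groups: dict = {}
    for j, meta in enumerate(matrix.characters):
        k = meta.n_states + 1 if inapplicable_as_state else meta.n_states
        groups.setdefault((k, meta.ordered), []).append(j)

    for (k, ordered), char_idx in groups.items():
        cost = _cost_matrix(k, ordered)
        m = len(char_idx)
        node_cost = [None] * len(children)
        for i, ch in enumerate(children):
            if not ch:  # leaf
                c = np.full((k, m), _INF)
                row = matrix.cells[leaf_row[i]]
                for jj, j in enumerate(char_idx):
                    st, _ = effective_states(
                        row[j], matrix.characters[j].n_states,
                        inapplicable_as_state)
                    c[sorted(st), jj] = 0.0
                node_cost[i] = c
            else:
                acc = np.zeros((k, m))
                for cidx in ch:
                    child = node_cost[cidx]
                    # min_t cost(s,t) + child[t]
                    acc += (cost[:, :, None] + child[None, :, :]).min(axis=1)
                    node_cost[cidx] = None
                node_cost[i] = acc
        steps[char_idx] = node_cost[-1].min(axis=0)
    return steps.astype(np.int64) if np.allclose(steps, np.round(steps)) \
        else steps


def tree_length(
    tree: dendropy.Tree,
    matrix: CharacterMatrix,
    inapplicable_as_state: bool = False,
) -> int:
    """Total parsimony length L = Σ_i s_i; invariant to rooting."""
    return int(per_character_steps(tree, matrix, inapplicable_as_state).sum())


# ---------------------------------------------------------------------------
# step bounds


@dataclass
class StepBounds:
    m: np.ndarray  # minimum conceivable steps per character
    g: np.ndarray  # maximum conceivable steps (star tree)


def char_step_bounds(matrix: CharacterMatrix) -> StepBounds:
    """Per-character step bounds.

    m_i = max(0, r_i − 1) with r_i the number of states that appear as
    some taxon's unique observed state. g_i = n_i − f_i on the star tree,
    where ambiguous (multi-state) cells are resolved greedily to their
    most frequent member state before counting the modal state f_i.
    """
    n_char = matrix.n_characters
    m = np.zeros(n_char, dtype=np.int64)
    g = np.zeros(n_char, dtype=np.int64)
    for j in range(n_char):
        singleton_counts: dict = {}
        ambiguous = []
        n_observed = 0
        for row in matrix.cells:
            cell = row[j]
            if not cell.is_observed:
                continue
            n_observed += 1
            if len(cell.states) == 1:
                (s,) = cell.states
                singleton_counts[s] = singleton_counts.get(s, 0) + 1
            else:
                ambiguous.append(cell.states)
        m[j] = max(0, len(singleton_counts) - 1)
        counts = dict(singleton_counts)
        for states in ambiguous:
            pick = max(
                states,
                key=lambda s: (singleton_counts.get(s, 0), -s),
            )
            counts[pick] = counts.get(pick, 0) + 1
        f = max(counts.values(), default=0)
        g[j] = n_observed - f if n_observed else 0
    return StepBounds(m=m, g=g)


# ---------------------------------------------------------------------------
# ensemble indices


@dataclass
class HomoplasyIndices:
    m: np.ndarray
    s: np.ndarray
    g: np.ndarray
    ci_per_char: np.ndarray  # nan where s_i = 0
    CI: float
    RI: float
    per_tree: list  # [(CI, RI)] across the evaluated trees
    included: np.ndarray  # boolean mask of characters entering the sums

    @property
    def ci_range(self):
        vals = [ci for ci, _ in self.per_tree]
        return (min(vals), max(vals))

    @property
    def ri_range(self):
        vals = [ri for _, ri in self.per_tree]
        return (min(vals), max(vals))

    def table(self):
        import pandas as pd

        return pd.DataFrame(
            {"m": self.m, "s": self.s, "g": self.g, "ci": self.ci_per_char}
        )


def _ci_ri(m, s, g, mask):
    sm, ss, sg = m[mask].sum(), s[mask].sum(), g[mask].sum()
    ci = float(sm / ss) if ss > 0 else float("nan")
    ri = float((sg - ss) / (sg - sm)) if sg > sm else float("nan")
    return ci, ri


def ensemble_indices(
    trees,
    matrix: CharacterMatrix,
    include_uninformative: bool = True,
    inapplicable_as_state: bool = False,
) -> HomoplasyIndices:
    """Ensemble CI and RI of one tree or a set of equally parsimonious
    trees. Per-character values come from the first tree; ensemble values
    are additionally reported per tree (``per_tree``) since per-character
    step counts may differ between equally long trees.

    By default every character enters the sums (the convention of TNT's
    ensemble report); ``include_uninformative=False`` restricts them to
    parsimony-informative characters (m_i < g_i).
    """
    if isinstance(trees, dendropy.Tree):
        trees = [trees]
    else:
        trees = list(getattr(trees, "trees", trees))
    if not trees:
        raise ValueError("no trees given")
    bounds = char_step_bounds(matrix)
    mask = (
        np.ones(matrix.n_characters, dtype=bool)
        if include_uninformative
        else bounds.m < bounds.g
    )
    per_tree = []
    s0 = None
    lengths = set()
    for t in trees:
        s = np.asarray(
            per_character_steps(t, matrix, inapplicable_as_state)
        )
        lengths.add(int(s.sum()))
        if s0 is None:
            s0 = s
        per_tree.append(_ci_ri(bounds.m, s, bounds.g, mask))
    if len(lengths) > 1:
        import warnings

        warnings.warn(
            f"trees are not equally parsimonious (lengths {sorted(lengths)})"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        ci_char = np.where(s0 > 0, bounds.m / np.maximum(s0, 1), np.nan)
        ci_char[s0 == 0] = np.nan
    CI, RI = _ci_ri(bounds.m, s0, bounds.g, mask)
    return HomoplasyIndices(
        m=bounds.m, s=s0, g=bounds.g, ci_per_char=ci_char,
        CI=CI, RI=RI, per_tree=per_tree, included=mask,
    )


# ---------------------------------------------------------------------------
# bit-packed Fitch (search hot path)


class PackedCharacters:
    """Characters packed to per-taxon state bitmasks over deduplicated site
    patterns, for fast Fitch length evaluation on binary trees.

    Only unordered characters are packed; ordered characters (rare in
    morphological practice and absent from the default pipeline) must be
    scored through :func:`per_character_steps`.
    """

    def __init__(self, matrix: CharacterMatrix, taxon_order=None,
                 inapplicable_as_state: bool = False):
        if any(c.ordered for c in matrix.characters):
            raise ValueError("packed scorer handles unordered characters only")
        names = list(taxon_order) if taxon_order else matrix.taxon_names
        self.taxon_names = names
        rows = [matrix.taxon_index(n) for n in names]
        n_taxa, n_char = len(names), matrix.n_characters
        cols = np.zeros((n_taxa, n_char), dtype=np.uint64)
        for jj, meta in enumerate(matrix.characters):
            for ii, r in enumerate(rows):
                st, _ = effective_states(
                    matrix.cells[r][jj], meta.n_states, inapplicable_as_state
                )
                mask = 0
                for s in st:
                    mask |= 1 << s
                cols[ii, jj] = mask
        # deduplicate identical site patterns
        patterns, char_to_pattern, weights = {}, np.zeros(n_char, np.int64), []
        cols_T = cols.T
        for j in range(n_char):
            key = cols_T[j].tobytes()
            if key not in patterns:
                patterns[key] = len(patterns)
                weights.append(0)
            pid = patterns[key]
            char_to_pattern[j] = pid
            weights[pid] += 1
        order = sorted(patterns.values())
        uniq = np.zeros((n_taxa, len(order)), dtype=np.uint64)
        for key, pid in patterns.items():
            uniq[:, pid] = np.frombuffer(key, dtype=np.uint64)
        self.leaf_masks = uniq
        self.weights = np.asarray(weights, dtype=np.int64)
        self.char_to_pattern = char_to_pattern
        self.n_patterns = len(order)


def packed_fitch_length(packed: PackedCharacters, postorder, root_leaf: int = 0,
                        n_nodes: Optional[int] = None) -> int:
    """Fitch length of a binary unrooted tree given as a postorder merge
    schedule.

    ``postorder`` is a sequence of ``(target, left, right)`` index triples
    over a node array whose first ``n_taxa`` slots are the leaves in
    ``packed.taxon_names`` order; the final triple's target is combined
    with ``root_leaf`` for the closing edge.
    """
    n_taxa = packed.leaf_masks.shape[0]
    if n_nodes is None:
        n_nodes = n_taxa + len(postorder)
    masks = np.empty((n_nodes, packed.n_patterns), dtype=np.uint64)
    masks[:n_taxa] = packed.leaf_masks
    w = packed.weights
    steps = 0
    for tgt, l, r in postorder:
        inter = masks[l] & masks[r]
        z = inter == 0
        steps += int(w[z].sum())
        masks[tgt] = np.where(z, masks[l] | masks[r], inter)
    if postorder:
        last = postorder[-1][0]
        z = (masks[last] & masks[root_leaf]) == 0
        steps += int(w[z].sum())
    return steps
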