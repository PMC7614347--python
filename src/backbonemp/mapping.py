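"""Character mapping onto trees: most-parsimonious-reconstruction state
sets, branch-level change classification (synapomorphy vs homoplasy), and
bootstrap/jackknife support.

State sets and single reconstructions are derived from a two-direction
Sankoff dynamic program (subtree cost below each node plus outside cost
above it), which handles multifurcating trees, multi-state and
missing/inapplicable cells exactly. ACCTRAN and DELTRAN are the two
extreme single reconstructions: walking root-to-tips through the
cost-optimal choice sets, ACCTRAN prefers a state different from the
parent (changes pushed rootward, favouring reversals), DELTRAN prefers
the parent's state (changes delayed tipward, favouring parallelisms).

A change is called a synapomorphy of a branch when it appears there in
every most-parsimonious tree under both optimizations and its character
shows no homoplasy (ci = 1); with ci < 1 the same mapping is flagged
homoplastic — the black vs white points of standard published character
maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import dendropy

from .matrix import CharacterMatrix
from .parsimony import effective_states, ensemble_indices
from .trees import leafset, make_split, splits_of

__all__ = [
    "CharacterChange",
    "SupportTable",
    "mpr_sets",
    "acctran_states",
    "deltran_states",
    "classify_changes",
    "resample_support",
]

_INF = 1e9


# ---------------------------------------------------------------------------
# two-direction Sankoff machinery (single character)


def _node_list(tree: dendropy.Tree):
    return list(tree.postorder_node_iter())


def _down_costs(tree, matrix: CharacterMatrix, char: int, k: int,
                inapplicable_as_state=False):
    """cost_below[node][s]: optimal steps in the subtree of ``node`` given
    state s at node. Unit (unordered) costs."""
    down = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            cell = matrix.cell(node.taxon.label, char)
            allowed, _ = effective_states(
                cell, matrix.characters[char].n_states, inapplicable_as_state)
            c = np.full(k, _INF)
            c[sorted(s for s in allowed if s < k)] = 0.0
            down[node] = c
        else:
            acc = np.zeros(k)
            for ch in node.child_nodes():
                acc += _edge_in(down[ch])
            down[node] = acc
    return down


def _edge_in(child_cost: np.ndarray) -> np.ndarray:
    """min_t [cost(s,t) + child_cost[t]] for unit costs, for every s."""
    m = child_cost.min()
    return np.minimum(child_cost, m + 1.0)


def _up_costs(tree, down, k: int):
    """cost_above[node][s]: optimal steps outside the subtree of ``node``
    given state s at node."""
    up = {tree.seed_node: np.zeros(k)}
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        kids = node.child_nodes()
        for child in kids:
            # parent-state cost excluding this child's subtree
            rest = up[node].copy()
            for sib in kids:
                if sib is not child:
                    rest += _edge_in(down[sib])
            up[child] = _edge_in(rest)
    return up


def _char_k(matrix: CharacterMatrix, char: int,
            inapplicable_as_state: bool = False) -> int:
    k = matrix.characters[char].n_states
    return k + 1 if inapplicable_as_state else k


def mpr_sets(tree: dendropy.Tree, matrix: CharacterMatrix, char: int,
             inapplicable_as_state: bool = False) -> dict:
    """Per-node most-parsimonious state sets for an unordered character:
    exactly the states a node takes in at least one minimum-step
    assignment. Keys are the tree's nodes (leaves included)."""
    k = _char_k(matrix, char, inapplicable_as_state)
    down = _down_costs(tree, matrix, char, k, inapplicable_as_state)
    up = _up_costs(tree, down, k)
    total_min = down[tree.seed_node].min()
    out = {}
    for node in tree.postorder_node_iter():
        tot = down[node] + up[node]
        assert abs(tot.min() - total_min) < 1e-9  # re-rooting invariance
        out[node] = frozenset(
            int(s) for s in np.flatnonzero(tot <= tot.min() + 1e-9)
        )
    return out


def _walk_assignment(tree, down, prefer_parent: bool):
    """Root-to-tip single MP assignment; DELTRAN when ``prefer_parent``,
    ACCTRAN otherwise. Ties inside the preference class go to the lowest
    state."""
    states = {}
    root = tree.seed_node
    states[root] = int(np.flatnonzero(down[root] <= down[root].min() + 1e-9)[0])
    for node in tree.preorder_node_iter():
        p = states[node]
        for child in node.child_nodes():
            cost = down[child].copy()
            cost += 1.0
            cost[p] -= 1.0  # no step when keeping the parent state
            choices = np.flatnonzero(cost <= cost.min() + 1e-9)
            if prefer_parent:
                pick = p if p in choices else int(choices[0])
            else:
                non_parent = [int(s) for s in choices if s != p]
                pick = non_parent[0] if non_parent else p
            states[child] = int(pick)
    return states


def acctran_states(tree, matrix, char, inapplicable_as_state=False) -> dict:
    k = _char_k(matrix, char, inapplicable_as_state)
    down = _down_costs(tree, matrix, char, k, inapplicable_as_state)
    return _walk_assignment(tree, down, prefer_parent=False)


def deltran_states(tree, matrix, char, inapplicable_as_state=False) -> dict:
    k = _char_k(matrix, char, inapplicable_as_state)
    down = _down_costs(tree, matrix, char, k, inapplicable_as_state)
    return _walk_assignment(tree, down, prefer_parent=True)


def _assignment_changes(tree, states) -> dict:
    """{clade-below-frozenset: (from, to)} for edges with a state change."""
    out = {}
    below = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[node] = frozenset([node.taxon.label])
        else:
            below[node] = frozenset().union(
                *(below[c] for c in node.child_nodes()))
        if node.parent_node is not None:
            s_par, s_me = states[node.parent_node], states[node]
            if s_par != s_me:
                out[below[node]] = (s_par, s_me)
    return out


def assignment_length(tree, states) -> int:
    return sum(
        1
        for node in tree.preorder_node_iter()
        if node.parent_node is not None
        and states[node] != states[node.parent_node]
    )


# ---------------------------------------------------------------------------
# change classification


@dataclass
class CharacterChange:
    character: int
    clade: frozenset  # taxa on the child side of the branch
    from_state: int
    to_state: int
    unambiguous: bool  # present under ACCTRAN and DELTRAN in every MPT
    homoplastic: bool  # character ci < 1 on the evaluated trees


def classify_changes(
    mpts,
    matrix: CharacterMatrix,
    reference: dendropy.Tree,
    inapplicable_as_state: bool = False,
) -> list:
    """Map character changes onto the branches of a reference (consensus)
    tree. A change is reported on a branch when every MPT shows it there
    (under at least one of ACCTRAN/DELTRAN); it is unambiguous when both
    optimizations agree in every MPT. Branches absent from some MPT are
    skipped with a warning. From/to states follow the first MPT's ACCTRAN
    (or DELTRAN where ACCTRAN lacks the change)."""
    trees = list(getattr(mpts, "trees", mpts))
    if not trees:
        raise ValueError("no trees to map on")
    ref_leaves = leafset(reference)
    ref_clades = []
    below = {}
    for node in reference.postorder_node_iter():
        if node.is_leaf():
            below[node] = frozenset([node.taxon.label])
        else:
            below[node] = frozenset().union(
                *(below[c] for c in node.child_nodes()))
            if node.parent_node is not None and len(below[node]) >= 2:
                ref_clades.append(below[node])

    # per-MPT, per-character change maps
    indices = ensemble_indices(trees, matrix,
                               inapplicable_as_state=inapplicable_as_state)
    acc_maps, del_maps = [], []
    for t in trees:
        acc_t, del_t = [], []
        for j in range(matrix.n_characters):
            acc_t.append(_assignment_changes(t, acctran_states(
                t, matrix, j, inapplicable_as_state)))
            del_t.append(_assignment_changes(t, deltran_states(
                t, matrix, j, inapplicable_as_state)))
        acc_maps.append(acc_t)
        del_maps.append(del_t)

    mpt_splits = [splits_of(t) for t in trees]
    out = []
    for clade in ref_clades:
        split = make_split(clade, ref_leaves)
        if split is not None and any(split not in s for s in mpt_splits):
            warnings.warn(
                f"reference branch {sorted(clade)[:3]}... absent from some "
                "MPT; skipped"
            )
            continue
        for j in range(matrix.n_characters):
            in_acc = [clade in acc_maps[i][j] for i in range(len(trees))]
            in_del = [clade in del_maps[i][j] for i in range(len(trees))]
            everywhere = all(a or d for a, d in zip(in_acc, in_del))
            if not everywhere:
                continue
            src = acc_maps[0][j].get(clade) or del_maps[0][j].get(clade)
            ci = indices.ci_per_char[j]
            out.append(
                CharacterChange(
                    character=j,
                    clade=clade,
                    from_state=src[0],
                    to_state=src[1],
                    unambiguous=all(in_acc) and all(in_del),
                    homoplastic=bool(np.isfinite(ci) and ci < 1.0 - 1e-12),
                )
            )
    return out


# ---------------------------------------------------------------------------
# resampling support


@dataclass
class SupportTable:
    frequencies: dict  # canonical bipartition -> frequency in [0, 1]
    kind: str
    reps: int

    def get(self, split) -> float:
        return self.frequencies.get(split, 0.0)

    def annotate(self, tree: dendropy.Tree) -> dendropy.Tree:
        """Attach frequencies as ``node.support`` on matching branches."""
        full = leafset(tree)
        below = {}
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                below[node] = frozenset([node.taxon.label])
                continue
            below[node] = frozenset().union(
                *(below[c] for c in node.child_nodes()))
            if node.parent_node is not None:
                s = make_split(below[node], full)
                if s is not None:
                    node.support = self.get(s)
        return tree


def resample_support(
    matrix: CharacterMatrix,
    config,
    kind: str = "bootstrap",
    reps: int = 100,
    removal_p: float = 0.36,
    rng=None,
) -> SupportTable:
    """Character-resampling clade support.

    Bootstrap resamples characters with replacement to the original count;
    jackknife deletes each character independently with probability
    ``removal_p`` (default 0.36, the e^-1 convention). Each replicate runs
    :func:`~backbonemp.search.heuristic_search` with the given (reduced)
    config; a bipartition's support is the fraction of replicate strict
    consensus trees containing it.
    """
    from dataclasses import replace

    from .search import heuristic_search
    from .trees import TreeSample, strict_consensus

    if kind not in ("bootstrap", "jackknife"):
        raise ValueError("kind must be 'bootstrap' or 'jackknife'")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n_char = matrix.n_characters
    counts: dict = {}
    for rep in range(reps):
        if kind == "bootstrap":
            idx = list(rng.integers(0, n_char, size=n_char))
        else:
            keep = rng.random(n_char) > removal_p
            idx = list(np.flatnonzero(keep))
            if not idx:
                idx = list(range(n_char))
        sub = matrix.subset_characters(idx)
        cfg = replace(config, seed=int(rng.integers(2**31 - 1)))
        result = heuristic_search(sub, cfg)
        cons = strict_consensus(TreeSample(result.trees))
        for s in splits_of(cons):
            counts[s] = counts.get(s, 0) + 1
    return SupportTable(
        frequencies={s: c / reps for s, c in counts.items()},
        kind=kind,
        reps=reps,
    )
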