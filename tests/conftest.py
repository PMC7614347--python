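"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the package's optimized code paths:
`naive_fitch_steps` is a plain set-based Fitch pass over a dendropy tree,
`enumerate_topologies` builds every unrooted binary topology by recursive
leaf insertion on newick strings, and `brute_force_char_min` enumerates
all internal-node state assignments. They exist to check the fast
implementations against first principles on small inputs.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from backbonemp.matrix import (
    CharacterCell,
    CharacterMatrix,
    CharacterMeta,
    TaxonRecord,
)
from backbonemp.trees import parse_newick


def make_matrix(rows, names=None, fossil=(), n_states=None, ordered=()):
    """rows: list per taxon of cell specs — int, set of ints, '?' or '-'."""
    names = names or [chr(65 + i) for i in range(len(rows))]
    taxa = [TaxonRecord(n, n not in fossil) for n in names]
    n_char = len(rows[0])
    cells = []
    for r in rows:
        row = []
        for v in r:
            if v == "?":
                row.append(CharacterCell.missing())
            elif v == "-":
                row.append(CharacterCell.inapplicable())
            elif isinstance(v, (set, frozenset, tuple, list)):
                row.append(CharacterCell.observed(v))
            else:
                row.append(CharacterCell.observed([v]))
        cells.append(row)
    metas = []
    for j in range(n_char):
        obs = [
            s for r in cells for s in r[j].states
        ]
        k = n_states if n_states else max(2, max(obs, default=1) + 1)
        metas.append(CharacterMeta(j, k, ordered=j in ordered))
    return CharacterMatrix(taxa=taxa, characters=metas, cells=cells)


def random_matrix(rng, n_taxa, n_char, k=2, p_missing=0.0, p_inap=0.0,
                  p_poly=0.0, fossil=()):
    names = [chr(65 + i) for i in range(n_taxa)]
    rows = []
    for _ in range(n_taxa):
        row = []
        for _ in range(n_char):
            u = rng.random()
            if u < p_missing:
                row.append("?")
            elif u < p_missing + p_inap:
                row.append("-")
            elif u < p_missing + p_inap + p_poly:
                size = int(rng.integers(2, k + 1))
                row.append(set(rng.choice(k, size=size, replace=False).tolist()))
            else:
                row.append(int(rng.integers(k)))
        rows.append(row)
    return make_matrix(rows, names, fossil=fossil, n_states=k)


# ---------------------------------------------------------------------------
# topology enumeration (independent of the package's search internals)


def enumerate_topologies(names):
    """All unrooted binary topologies as newick strings (leaf insertion)."""
    names = list(names)
    if len(names) < 3:
        raise ValueError("need >= 3 names")

    def insertions(struct, leaf):
        # struct is a nested tuple; insert leaf on every edge
        out = []
        if isinstance(struct, str):
            out.append((struct, leaf))
            return out
        a, b = struct
        out.append((struct, leaf))
        out.extend((x, b) for x in insertions(a, leaf))
        out.extend((a, x) for x in insertions(b, leaf))
        return out

    # represent unrooted tree as a trio (x, y, z) around a hub
    trios = [tuple(names[:3])]
    for leaf in names[3:]:
        new = []
        for trio in trios:
            x, y, z = trio
            for i, part in enumerate(trio):
                for repl in insertions(part, leaf):
                    t = list(trio)
                    t[i] = repl
                    new.append(tuple(t))
        trios = new

    def to_newick(struct):
        if isinstance(struct, str):
            return struct
        return f"({to_newick(struct[0])},{to_newick(struct[1])})"

    return [
        f"({to_newick(x)},{to_newick(y)},{to_newick(z)});" for x, y, z in trios
    ]


# ---------------------------------------------------------------------------
# naive Fitch


def cell_states(matrix, taxon, char):
    cell = matrix.cell(taxon, char)
    if cell.is_observed:
        return frozenset(cell.states)
    return frozenset(range(matrix.characters[char].n_states))


def naive_fitch_steps(tree, matrix, char):
    """Set-based Fitch pass (binary rooted traversal of a dendropy tree)."""
    steps = 0

    def down(node):
        nonlocal steps
        if node.is_leaf():
            return cell_states(matrix, node.taxon.label, char)
        sets = [down(c) for c in node.child_nodes()]
        acc = sets[0]
        for s in sets[1:]:
            inter = acc & s
            if inter:
                acc = inter
            else:
                acc = acc | s
                steps += 1
        return acc

    down(tree.seed_node)
    return steps


def brute_force_char_min(tree, matrix, char, k):
    """Exact minimum steps by enumerating all internal-node assignments."""
    internals = [n for n in tree.postorder_node_iter() if not n.is_leaf()]
    leaves = [n for n in tree.postorder_node_iter() if n.is_leaf()]
    best = None
    best_sets = {n: set() for n in internals + leaves}
    leaf_opts = {n: sorted(cell_states(matrix, n.taxon.label, char))
                 for n in leaves}
    for assign in itertools.product(range(k), repeat=len(internals)):
        states = dict(zip(internals, assign))
        for leaf_combo in itertools.product(
            *(leaf_opts[n] for n in leaves)
        ):
            states.update(zip(leaves, leaf_combo))
            cost = sum(
                1
                for n in internals + leaves
                if n.parent_node is not None
                and states[n] != states[n.parent_node]
            )
            if best is None or cost < best:
                best = cost
                best_sets = {n: {states[n]} for n in internals + leaves}
            elif cost == best:
                for n in internals + leaves:
                    best_sets[n].add(states[n])
    return best, best_sets


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_matrix():
    """char0 convergent (0,1,0,1), char1 clean split (0,0,1,1)."""
    return make_matrix([[0, 0], [1, 0], [0, 1], [1, 1]])


@pytest.fixture
def toy_tree():
    return parse_newick("((A,B),(C,D));")
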