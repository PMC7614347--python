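"""Heuristic maximum-parsimony search under an optional backbone constraint.

The search follows the classic "traditional search" recipe: per replicate,
a random-sequence stepwise-addition tree is built (taxa inserted at the
length-minimizing edge among constraint-satisfying edges), hill-climbed by
tree bisection and reconnection (TBR) accepting the first strictly shorter
constraint-satisfying neighbor, while a bounded buffer holds equally best
trees; replicate buffers are pooled, trimmed to the globally best length,
optionally collapsed (branches whose minimum optimized length is zero),
and deduplicated by bipartition set.

Internally trees are bare adjacency structures over integer leaf ids
(:class:`UTree`) with splits as Python-int bitmasks; the public surface
speaks :class:`dendropy.Tree`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np
import dendropy

from .backbone import BackboneConstraint
from .matrix import CharacterMatrix
from .parsimony import PackedCharacters, packed_fitch_length
from .trees import _quote, parse_newick, leafset

__all__ = [
    "SearchConfig",
    "MPTSet",
    "UTree",
    "constrained_addition_tree",
    "tbr_neighbors",
    "heuristic_search",
    "exhaustive_search",
]


# ---------------------------------------------------------------------------
# unrooted trees over integer leaf ids


class UTree:
    """Unrooted tree: leaves 0..n-1, internal ids allocated upward."""

    __slots__ = ("n", "adj", "_next")

    def __init__(self, n: int, adj=None, next_id=None):
        self.n = n
        self.adj = adj if adj is not None else {}
        self._next = next_id if next_id is not None else n

    @staticmethod
    def initial(triple: Sequence[int], n: int) -> "UTree":
        a, b, c = triple
        t = UTree(n)
        hub = t._new_node()
        for x in (a, b, c):
            t._connect(hub, x)
        return t

    def _new_node(self) -> int:
        i = self._next
        self._next += 1
        self.adj[i] = []
        return i

    def _connect(self, u: int, v: int) -> None:
        self.adj.setdefault(u, []).append(v)
        self.adj.setdefault(v, []).append(u)

    def _disconnect(self, u: int, v: int) -> None:
        self.adj[u].remove(v)
        self.adj[v].remove(u)

    def copy(self) -> "UTree":
        return UTree(self.n, {k: list(v) for k, v in self.adj.items()}, self._next)

    @property
    def leaves(self) -> list:
        return [v for v in self.adj if v < self.n and self.adj[v]]

    def edges(self) -> list:
        return [
            (u, v) for u in self.adj for v in self.adj[u] if u < v
        ]

    def insert_leaf(self, leaf: int, edge) -> None:
        """Attach ``leaf`` by subdividing ``edge`` with a new node."""
        u, v = edge
        w = self._new_node()
        self._disconnect(u, v)
        self._connect(u, w)
        self._connect(w, v)
        self._connect(w, leaf)

    # -- splits ---------------------------------------------------------
    def root_leaf(self) -> int:
        return min(self.leaves)

    def _subtree_masks(self, root: Optional[int] = None) -> dict:
        """Leaf bitmask below each node, away from the root leaf."""
        r = self.root_leaf() if root is None else root
        masks = {r: 1 << r}

        def dfs(u, parent):
            mask = 0
            for w in self.adj[u]:
                if w == parent:
                    continue
                mask |= dfs(w, u)
            if u < self.n:
                mask |= 1 << u
            masks[u] = mask
            return mask

        dfs(self.adj[r][0], r)
        return masks

    def splits(self) -> set:
        """Non-trivial splits as bitmasks of the side away from the
        lowest-id leaf present."""
        full = 0
        for l in self.leaves:
            full |= 1 << l
        masks = self._subtree_masks()
        out = set()
        for u, v in self.edges():
            mu, mv = masks[u], masks[v]
            side = mv if (mv & mu) == mv and mv != mu else (
                mu if (mu & mv) == mu else None
            )
            if side is None:
                # one endpoint is the root leaf: side is the other subtree
                side = mv if u == self.root_leaf() else mu
            if side.bit_count() >= 2 and (full ^ side).bit_count() >= 2:
                out.add(side)
        return out

    def key(self) -> frozenset:
        return frozenset(self.splits())

    # -- scoring support -------------------------------------------------
    def postorder_schedule(self):
        """Binary merge schedule rooted at the lowest present leaf, for
        :func:`backbonemp.parsimony.packed_fitch_length`. Requires a fully
        binary tree."""
        counter = itertools.count(self.n)
        triples = []

        def visit(u, parent):
            if u < self.n:
                return u
            ch = [visit(w, u) for w in self.adj[u] if w != parent]
            if len(ch) != 2:
                raise ValueError("postorder schedule requires a binary tree")
            tgt = next(counter)
            triples.append((tgt, ch[0], ch[1]))
            return tgt

        r = self.root_leaf()
        visit(self.adj[r][0], r)
        return triples

    # -- conversion ------------------------------------------------------
    def to_newick(self, names: Sequence[str]) -> str:
        def emit(u, parent):
            if u < self.n:
                return _quote(names[u])
            parts = [emit(w, u) for w in self.adj[u] if w != parent]
            return "(" + ",".join(parts) + ")"

        r = self.root_leaf()
        root = self.adj[r][0]
        if root < self.n:
            return f"({_quote(names[r])},{_quote(names[root])});"
        parts = [_quote(names[r])] + [
            emit(w, root) for w in self.adj[root] if w != r
        ]
        return "(" + ",".join(parts) + ");"

    def to_dendropy(self, names: Sequence[str]) -> dendropy.Tree:
        return parse_newick(self.to_newick(names))

    @staticmethod
    def from_dendropy(tree: dendropy.Tree, names: Sequence[str]) -> "UTree":
        index = {n: i for i, n in enumerate(names)}
        n = len(names)
        t = UTree(n)

        def build(node):
            if node.is_leaf():
                return index[node.taxon.label]
            me = t._new_node()
            for c in node.child_nodes():
                t._connect(me, build(c))
            return me

        root = tree.seed_node
        kids = root.child_nodes()
        top = t._new_node()
        for c in kids:
            t._connect(top, build(c))
        # suppress a degree-2 node left by a rooted input
        if len(t.adj[top]) == 2:
            a, b = t.adj[top]
            t._disconnect(top, a)
            t._disconnect(top, b)
            t._connect(a, b)
            del t.adj[top]
        return t


# ---------------------------------------------------------------------------
# compiled constraint over leaf-index bitmasks


class _CompiledConstraint:
    """Rooted-clade constraint over leaf-index bitmasks.

    Clade checks are anchored at the lowest-index leaf present — the
    first matrix taxon, the conventional (outgroup-first) rooting of
    parsimony programs. A clade mask mc requires some node whose
    away-from-root leaf set restricts to exactly the placed mc members;
    for a clade containing the root leaf itself the complement is matched
    instead (the unrooted reading of the same edge).
    """

    def __init__(self, backbone: BackboneConstraint, names: Sequence[str]):
        self.index = {n: i for i, n in enumerate(names)}
        missing = backbone.constrained_taxa - set(names)
        if missing:
            raise ValueError(
                f"constrained taxa not in matrix: {sorted(missing)}"
            )
        self.cmask = 0
        for t in backbone.constrained_taxa:
            self.cmask |= 1 << self.index[t]
        self.clade_masks = [
            sum(1 << self.index[x] for x in clade)
            for clade in backbone.clades
        ]

    def _root(self, utree: UTree) -> int:
        return min(utree.leaves)

    def _required(self, placed_cmask: int, root_bit: int) -> set:
        required = set()
        for mc in self.clade_masks:
            inside = mc & placed_cmask
            outside = placed_cmask & ~inside
            if inside.bit_count() >= 2 and outside:
                required.add(outside if inside & root_bit else inside)
        return required

    def _targets(self, utree: UTree, required: set, placed_cmask: int):
        r = self._root(utree)
        have = {
            side & placed_cmask
            for side in utree._subtree_masks(r).values()
        }
        return have

    def ok(self, utree: UTree) -> bool:
        placed = 0
        for l in utree.leaves:
            placed |= 1 << l
        pc = placed & self.cmask
        r = self._root(utree)
        required = self._required(pc, 1 << r)
        if not required:
            return True
        return required <= self._targets(utree, required, pc)

    def enforced_sides(self, utree: UTree) -> set:
        """Full-leafset edge-side masks realizing a requirement (used to
        exempt those branches from collapsing)."""
        placed = 0
        for l in utree.leaves:
            placed |= 1 << l
        pc = placed & self.cmask
        r = self._root(utree)
        required = self._required(pc, 1 << r)
        min_bit = 1 << utree.root_leaf()
        out = set()
        for side in utree._subtree_masks(r).values():
            if side & pc in required:
                # normalize to the canonical (min-leaf) orientation used
                # by the collapse machinery
                out.add(placed ^ side if side & min_bit else side)
        return out


# ---------------------------------------------------------------------------
# config / result containers


@dataclass
class SearchConfig:
    """Search settings; the defaults mirror the study protocol (1000
    random-addition replicates, TBR, ten trees held per replicate)."""

    replicates: int = 1000
    hold_per_replicate: int = 10
    seed: int = 0
    collapse_rule: str = "min_length_zero"  # or "none"
    max_tbr_rounds: int = 10_000
    constraint: Optional[BackboneConstraint] = None

    def __post_init__(self):
        if self.replicates < 1 or self.hold_per_replicate < 1:
            raise ValueError("replicates and hold must be >= 1")
        if self.collapse_rule not in ("none", "min_length_zero"):
            raise ValueError(f"unknown collapse rule {self.collapse_rule!r}")


@dataclass
class MPTSet:
    """Deduplicated equally most-parsimonious trees and their length."""

    trees: list  # dendropy.Tree
    length: int
    config: Optional[SearchConfig] = None
    trace: list = field(default_factory=list)  # per-replicate best length

    def __len__(self):
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)


# ---------------------------------------------------------------------------
# stepwise addition


def _addition_utree(
    packed: PackedCharacters,
    constraint: Optional[_CompiledConstraint],
    rng: np.random.Generator,
) -> "UTree":
    n = len(packed.taxon_names)
    order = list(rng.permutation(n))
    t = UTree.initial(order[:3], n)
    for leaf in order[3:]:
        best_len, best_edges = None, []
        for edge in t.edges():
            cand = t.copy()
            cand.insert_leaf(leaf, edge)
            if constraint is not None and not constraint.ok(cand):
                continue
            ln = _score(packed, cand)
            if best_len is None or ln < best_len:
                best_len, best_edges = ln, [edge]
            elif ln == best_len:
                best_edges.append(edge)
        assert best_edges, "no constraint-satisfying insertion edge"
        edge = best_edges[int(rng.integers(len(best_edges)))]
        t.insert_leaf(leaf, edge)
    return t


def _score(packed: PackedCharacters, t: UTree) -> int:
    n_internal = sum(1 for v in t.adj if v >= t.n)
    return packed_fitch_length(
        packed,
        t.postorder_schedule(),
        root_leaf=t.root_leaf(),
        n_nodes=t.n + n_internal + 1,
    )


def constrained_addition_tree(
    matrix: CharacterMatrix,
    constraint: Optional[BackboneConstraint] = None,
    rng=None,
) -> dendropy.Tree:
    """One random-sequence stepwise-addition tree; taxa are inserted in
    random order at the length-minimizing constraint-satisfying edge, ties
    broken uniformly at random."""
    rng = _as_rng(rng)
    packed = PackedCharacters(matrix)
    compiled = (
        _CompiledConstraint(constraint, packed.taxon_names)
        if constraint is not None
        else None
    )
    t = _addition_utree(packed, compiled, rng)
    return t.to_dendropy(packed.taxon_names)


def _as_rng(rng) -> np.random.Generator:
    if rng is None:
        return np.random.default_rng()
    if isinstance(rng, (int, np.integer)):
        return np.random.default_rng(int(rng))
    return rng


# ---------------------------------------------------------------------------
# TBR


def _tbr_neighbor_utrees(t: UTree, dedup: bool = True) -> Iterator["UTree"]:
    """All trees one TBR move away (bisect any edge, reconnect any edge of
    one part to any edge of the other). Binary input required."""
    self_key = t.key() if dedup else None
    seen = set()
    for u, v in t.edges():
        base = t.copy()
        base._disconnect(u, v)
        heal = {}
        attach = {}
        for side, other in ((u, v), (v, u)):
            if side < t.n:  # detached single leaf
                attach[side] = ("leaf", side)
            else:
                nbrs = list(base.adj[side])
                if len(nbrs) == 2:
                    a, b = nbrs
                    base._disconnect(side, a)
                    base._disconnect(side, b)
                    base._connect(a, b)
                    del base.adj[side]
                    heal[side] = (a, b)
                    attach[side] = ("tree", None)
                else:
                    attach[side] = ("tree", None)

        def edges_of(part_root):
            seen_nodes = {part_root}
            stack = [part_root]
            while stack:
                x = stack.pop()
                for y in base.adj.get(x, ()):
                    if y not in seen_nodes:
                        seen_nodes.add(y)
                        stack.append(y)
            return [
                (a, b)
                for a in seen_nodes
                for b in base.adj.get(a, ())
                if a < b and b in seen_nodes
            ]

        kind_u, _ = attach[u]
        kind_v, _ = attach[v]
        # a surviving node of each component to start traversal from
        root_u = u if kind_u == "leaf" else (heal[u][0] if u in heal else u)
        root_v = v if kind_v == "leaf" else (heal[v][0] if v in heal else v)
        edges_u = [] if kind_u == "leaf" else edges_of(root_u)
        edges_v = [] if kind_v == "leaf" else edges_of(root_v)

        points_u = [("leaf", u)] if kind_u == "leaf" else [("edge", e) for e in edges_u]
        points_v = [("leaf", v)] if kind_v == "leaf" else [("edge", e) for e in edges_v]

        for pu in points_u:
            for pv in points_v:
                cand = base.copy()
                ends = []
                for kind, payload in (pu, pv):
                    if kind == "leaf":
                        ends.append(payload)
                    else:
                        a, b = payload
                        w = cand._new_node()
                        cand._disconnect(a, b)
                        cand._connect(a, w)
                        cand._connect(w, b)
                        ends.append(w)
                cand._connect(ends[0], ends[1])
                if dedup:
                    k = cand.key()
                    if k == self_key or k in seen:
                        continue
                    seen.add(k)
                yield cand


def tbr_neighbors(tree: dendropy.Tree) -> Iterator[dendropy.Tree]:
    """Stream of distinct TBR neighbors of a binary unrooted tree."""
    names = sorted(leafset(tree))
    ut = UTree.from_dendropy(tree, names)
    for cand in _tbr_neighbor_utrees(ut):
        yield cand.to_dendropy(names)


# ---------------------------------------------------------------------------
# collapse rule


def _fitch_state_masks(packed: PackedCharacters, t: UTree):
    """Preliminary (down-pass) and final (up-pass) Fitch state-set bitmask
    arrays per node, rooted on the edge incident to leaf 0."""
    P: dict = {}
    F: dict = {}
    for l in t.leaves:
        P[l] = packed.leaf_masks[l].copy()

    def down(u, parent):
        if u < t.n:
            return P[u]
        ch = [down(w, u) for w in t.adj[u] if w != parent]
        assert len(ch) == 2
        inter = ch[0] & ch[1]
        z = inter == 0
        P[u] = np.where(z, ch[0] | ch[1], inter)
        return P[u]

    r = t.root_leaf()
    top = t.adj[r][0]
    down(top, r)
    # virtual root on the edge joining the root leaf and `top`
    inter = P[r] & P[top]
    z = inter == 0
    F_root = np.where(z, P[r] | P[top], inter)

    def up(u, parent, f_parent):
        if u < t.n:
            F[u] = np.where(P[u] & f_parent != 0, P[u] & f_parent, P[u])
            return
        kids = [w for w in t.adj[u] if w != parent]
        pl, pr = P[kids[0]], P[kids[1]]
        subset = (f_parent & ~P[u]) == 0  # F(parent) ⊆ P(u)
        was_intersection = (pl & pr) != 0
        fu = np.where(
            subset,
            f_parent,
            np.where(
                was_intersection,
                P[u] | (f_parent & (pl | pr)),
                P[u] | f_parent,
            ),
        )
        F[u] = fu
        for w in kids:
            up(w, u, fu)

    up(top, r, F_root)
    F[r] = P[r]
    return P, F


def _collapsed_splits(packed: PackedCharacters, t: UTree,
                      protected=frozenset()) -> frozenset:
    """Split set after contracting internal edges whose minimum optimized
    length is zero for every character (final Fitch sets intersect).
    Sides in ``protected`` (constraint-enforced) are never contracted."""
    _, F = _fitch_state_masks(packed, t)
    masks = t._subtree_masks()
    full = 0
    for l in t.leaves:
        full |= 1 << l
    keep = set()
    for u, v in t.edges():
        if u < t.n or v < t.n:
            continue
        side = masks[v] if (masks[v] & masks[u]) == masks[v] else masks[u]
        if side.bit_count() < 2 or (full ^ side).bit_count() < 2:
            continue
        if side not in protected and bool(np.all((F[u] & F[v]) != 0)):
            continue  # zero-minimum-length branch: collapsed
        keep.add(side)
    return frozenset(keep)


# ---------------------------------------------------------------------------
# heuristic search


def heuristic_search(matrix: CharacterMatrix, config: SearchConfig) -> MPTSet:
    """Random-addition + TBR search; see the module docstring for the
    discipline. Deterministic for a given config and seed."""
    rng = np.random.default_rng(config.seed)
    packed = PackedCharacters(matrix)
    names = packed.taxon_names
    compiled = (
        _CompiledConstraint(config.constraint, names)
        if config.constraint is not None
        else None
    )
    n = len(names)
    if n < 4:
        t = UTree.initial(list(range(3)), n) if n == 3 else None
        if t is None:
            raise ValueError("need at least 3 taxa")
        return MPTSet([t.to_dendropy(names)], _score(packed, t), config, [])

    best_len = None
    pool: dict = {}
    trace = []
    for _ in range(config.replicates):
        t = _addition_utree(packed, compiled, rng)
        length = _score(packed, t)
        buffer = {t.key(): t}
        rounds = 0
        improved = True
        while improved and rounds < config.max_tbr_rounds:
            improved = False
            neighbors = list(_tbr_neighbor_utrees(t))
            rng.shuffle(neighbors)
            for cand in neighbors:
                if compiled is not None and not compiled.ok(cand):
                    continue
                ln = _score(packed, cand)
                if ln < length:
                    t, length = cand, ln
                    buffer = {t.key(): t}
                    improved = True
                    rounds += 1
                    break
                if ln == length and len(buffer) < config.hold_per_replicate:
                    buffer.setdefault(cand.key(), cand)
        trace.append(length)
        if best_len is None or length < best_len:
            best_len = length
            pool = dict(buffer)
        elif length == best_len:
            for k, v in buffer.items():
                pool.setdefault(k, v)

    # final validation + dedup under the collapse rule
    final: dict = {}
    for ut in pool.values():
        assert _score(packed, ut) == best_len
        if compiled is not None:
            assert compiled.ok(ut)
        if config.collapse_rule == "min_length_zero":
            protected = (
                compiled.enforced_sides(ut) if compiled is not None
                else frozenset()
            )
            key = _collapsed_splits(packed, ut, protected)
            if key not in final:
                final[key] = _emit_collapsed(ut, key, names)
        else:
            final.setdefault(frozenset(ut.splits()), ut.to_dendropy(names))
    return MPTSet(list(final.values()), int(best_len), config, trace)


def _emit_collapsed(ut: UTree, split_masks: frozenset, names) -> dendropy.Tree:
    from .trees import tree_from_splits

    full = frozenset(names[l] for l in ut.leaves)
    splits = []
    for mask in split_masks:
        side = frozenset(names[i] for i in _bits(mask))
        splits.append(frozenset((side, full - side)))
    return tree_from_splits(splits, full)


def _bits(mask: int):
    i = 0
    while mask:
        if mask & 1:
            yield i
        mask >>= 1
        i += 1


# ---------------------------------------------------------------------------
# exhaustive search (small n)


def _enumerate_utrees(n: int) -> Iterator["UTree"]:
    def recurse(t: UTree, next_leaf: int):
        if next_leaf == n:
            yield t
            return
        for edge in t.edges():
            cand = t.copy()
            cand.insert_leaf(next_leaf, edge)
            yield from recurse(cand, next_leaf + 1)

    yield from recurse(UTree.initial([0, 1, 2], n), 3)


def exhaustive_search(
    matrix: CharacterMatrix,
    constraint: Optional[BackboneConstraint] = None,
    max_taxa: int = 10,
) -> MPTSet:
    """Exact minimum by enumeration of all unrooted binary topologies
    (feasible for small taxon counts only)."""
    packed = PackedCharacters(matrix)
    names = packed.taxon_names
    n = len(names)
    if n > max_taxa:
        raise ValueError(f"{n} taxa exceeds exhaustive limit {max_taxa}")
    compiled = (
        _CompiledConstraint(constraint, names) if constraint is not None else None
    )
    best_len, best = None, []
    for t in _enumerate_utrees(n):
        if compiled is not None and not compiled.ok(t):
            continue
        ln = _score(packed, t)
        if best_len is None or ln < best_len:
            best_len, best = ln, [t]
        elif ln == best_len:
            best.append(t)
    if best_len is None:
        raise ValueError("no topology satisfies the constraint")
    return MPTSet(
        [t.to_dendropy(names) for t in best], int(best_len), None, []
    )
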