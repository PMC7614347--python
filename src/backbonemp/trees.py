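"""Phylogeny handling: newick I/O, bipartition algebra, consensus, MCC.

Trees are :class:`dendropy.Tree` objects. Support values (posterior
probabilities or resampling frequencies) are normalised to [0, 1] and kept
on ``node.support``; values given in percent are divided by 100 on ingest.

A bipartition (split) of a leaf set is represented canonically as a
frozenset of its two frozenset sides, so equality is independent of
orientation and rooting. Consensus and bipartition extraction operate on
the unrooted form of each tree.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import dendropy

__all__ = [
    "TreeSample",
    "parse_newick",
    "write_newick",
    "read_tree_sample",
    "leafset",
    "make_split",
    "splits_of",
    "restrict_split",
    "induced_splits",
    "same_topology",
    "tree_from_splits",
    "tree_from_clades",
    "edge_sides",
    "strict_consensus",
    "majority_consensus",
    "mcc_tree",
]

_NUM = re.compile(r"[-+]?\d*\.?\d+(?:[eE][-+]?\d+)?")


# ---------------------------------------------------------------------------
# parsing / writing


def _extract_support(node: "dendropy.Node") -> Optional[float]:
    candidates = []
    if node.label:
        candidates.append(node.label)
    candidates.extend(c or "" for c in node.comments)
    for text in candidates:
        m = _NUM.search(text)
        if m:
            v = float(m.group(0))
            return v / 100.0 if v > 1.0 else v
    return None


def parse_newick(text: str, taxon_namespace=None) -> dendropy.Tree:
    """Parse one newick string; numeric internal labels (or bracket
    comments) become ``node.support`` in [0, 1]."""
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            taxon_namespace=taxon_namespace,
            suppress_internal_node_taxa=True,
        )
    except ValueError:
        raise
    except Exception as exc:  # dendropy reader errors are not ValueErrors
        raise ValueError(f"malformed newick: {exc}") from exc
    seen = set()
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is None:
            raise ValueError("unlabelled leaf in newick input")
        if leaf.taxon.label in seen:
            raise ValueError(f"duplicate leaf label {leaf.taxon.label!r}")
        seen.add(leaf.taxon.label)
    for node in tree.preorder_internal_node_iter():
        node.support = _extract_support(node)
    return tree


def write_newick(tree: dendropy.Tree, with_support: bool = True) -> str:
    if with_support:
        for node in tree.preorder_internal_node_iter():
            sup = getattr(node, "support", None)
            if sup is not None:
                node.label = f"{sup:g}"
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def read_tree_sample(path) -> "TreeSample":
    """Read a list of trees: newline-separated newick or a NEXUS trees block."""
    text = Path(path).read_text()
    tns = dendropy.TaxonNamespace()
    if text.lstrip().upper().startswith("#NEXUS"):
        tl = dendropy.TreeList.get(
            data=text, schema="nexus", taxon_namespace=tns,
            suppress_internal_node_taxa=True,
        )
        trees = list(tl)
        for t in trees:
            for node in t.preorder_internal_node_iter():
                node.support = _extract_support(node)
    else:
        trees = [
            parse_newick(line, taxon_namespace=tns)
            for line in text.splitlines()
            if line.strip()
        ]
    return TreeSample(trees)


# ---------------------------------------------------------------------------
# splits


def leafset(tree: dendropy.Tree) -> frozenset:
    return frozenset(l.taxon.label for l in tree.leaf_node_iter())


def make_split(side: Iterable[str], full: frozenset):
    """Canonical bipartition, or None when trivial."""
    side = frozenset(side)
    other = full - side
    if len(side) < 2 or len(other) < 2:
        return None
    return frozenset((side, other))


def _clades(tree: dendropy.Tree):
    """(node, leafset-below) for internal non-root nodes."""
    below = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[node] = frozenset([node.taxon.label])
        else:
            below[node] = frozenset().union(*(below[c] for c in node.child_nodes()))
    return [
        (n, below[n])
        for n in tree.preorder_internal_node_iter()
        if n.parent_node is not None
    ]


def splits_of(tree: dendropy.Tree) -> set:
    """Non-trivial bipartitions of the unrooted form, one per internal edge."""
    full = leafset(tree)
    out = set()
    for _, below in _clades(tree):
        s = make_split(below, full)
        if s is not None:
            out.add(s)
    return out


def restrict_split(split, subset: frozenset):
    """Restrict a bipartition to a taxon subset; None when it degenerates."""
    a, b = tuple(split)
    return make_split(a & subset, subset & (a | b))


def induced_splits(tree: dendropy.Tree, subset: frozenset) -> set:
    """Bipartitions of the subtree induced on ``subset`` (degree-2 nodes
    suppressed), obtained by restricting every bipartition of the tree."""
    out = set()
    for s in splits_of(tree):
        r = restrict_split(s, subset)
        if r is not None:
            out.add(r)
    # trivial splits of the full tree can become non-trivial after
    # restriction only if subset ⊂ leafset, and they restrict to trivial
    # splits anyway, so the edge set above is sufficient.
    return out


def edge_sides(tree: dendropy.Tree) -> set:
    """One leaf set per edge (the side below it), pendant edges included."""
    below = {}
    out = set()
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[node] = frozenset([node.taxon.label])
        else:
            below[node] = frozenset().union(*(below[c] for c in node.child_nodes()))
        if node.parent_node is not None:
            out.add(below[node])
    return out


def same_topology(t1: dendropy.Tree, t2: dendropy.Tree) -> bool:
    """Unrooted topological equality on identical leaf sets."""
    return leafset(t1) == leafset(t2) and splits_of(t1) == splits_of(t2)


# ---------------------------------------------------------------------------
# tree sample


@dataclass
class TreeSample:
    """Ordered list of trees over one shared leaf set, optionally weighted."""

    trees: list
    weights: Optional[list] = None

    def __post_init__(self):
        if not self.trees:
            raise ValueError("empty tree sample")
        ref = leafset(self.trees[0])
        for i, t in enumerate(self.trees[1:], start=1):
            if leafset(t) != ref:
                raise ValueError(f"tree {i} has a different leaf set")
        if self.weights is None:
            self.weights = [1.0] * len(self.trees)
        elif len(self.weights) != len(self.trees):
            raise ValueError("one weight per tree required")

    @property
    def leaf_set(self) -> frozenset:
        return leafset(self.trees[0])

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)


# ---------------------------------------------------------------------------
# consensus


def tree_from_splits(splits: Iterable, leaves: frozenset,
                     support: Optional[dict] = None) -> dendropy.Tree:
    """Build the (possibly multifurcating) tree containing exactly the given
    pairwise-compatible bipartitions. ``support[split]`` values become node
    supports."""
    leaves = frozenset(leaves)
    ref = min(leaves)
    support = support or {}
    # orient every split as the side away from the reference leaf; the
    # resulting clade family is laminar when the splits are compatible.
    clades = []
    for s in splits:
        a, b = tuple(s)
        clade = a if ref not in a else b
        clades.append((clade, support.get(s)))
    return tree_from_clades(clades, leaves)


def tree_from_clades(clades: Iterable, leaves: frozenset) -> dendropy.Tree:
    """Rooted (possibly multifurcating) tree from a laminar family of
    ``(clade, support)`` pairs; incompatible (overlapping, non-nested)
    clades raise ValueError."""
    leaves = frozenset(leaves)
    clades = sorted(clades, key=lambda cs: -len(cs[0]))

    # recursive laminar nesting
    root = {"members": leaves, "sup": None, "children": []}
    for clade, sup in clades:
        node = root
        while True:
            nxt = next(
                (c for c in node["children"] if clade <= c["members"]), None
            )
            if nxt is None:
                break
            node = nxt
        if any(c["members"] & clade for c in node["children"]):
            # absorb children fully inside the new clade
            inside = [c for c in node["children"] if c["members"] <= clade]
            outside = [c for c in node["children"] if not (c["members"] <= clade)]
            if any(c["members"] & clade and not c["members"] <= clade
                   for c in node["children"]):
                raise ValueError("incompatible bipartitions")
            new = {"members": clade, "sup": sup, "children": inside}
            node["children"] = outside + [new]
        else:
            node["children"].append({"members": clade, "sup": sup, "children": []})

    def emit(node) -> str:
        covered = frozenset().union(
            *(c["members"] for c in node["children"])
        ) if node["children"] else frozenset()
        parts = [emit(c) for c in node["children"]]
        parts += [_quote(l) for l in sorted(node["members"] - covered)]
        label = "" if node["sup"] is None else f"{node['sup']:g}"
        return "(" + ",".join(parts) + ")" + label

    return parse_newick(emit(root) + ";")


def _quote(label: str) -> str:
    return f"'{label}'" if re.search(r"[\s(),:;\[\]']", label) else label


def _split_frequencies(sample: TreeSample) -> dict:
    total = sum(sample.weights)
    freqs: dict = {}
    for tree, w in zip(sample.trees, sample.weights):
        for s in splits_of(tree):
            freqs[s] = freqs.get(s, 0.0) + w
    return {s: v / total for s, v in freqs.items()}


def strict_consensus(sample: TreeSample) -> dendropy.Tree:
    """Tree holding exactly the bipartitions present in every input tree."""
    freqs = _split_frequencies(sample)
    keep = {s: f for s, f in freqs.items() if f >= 1.0 - 1e-12}
    return tree_from_splits(keep, sample.leaf_set, support=keep)


def majority_consensus(sample: TreeSample, threshold: float = 0.5) -> dendropy.Tree:
    """Tree of bipartitions with frequency strictly above ``threshold``
    (default 0.5, the classic majority rule); frequencies become supports."""
    if not 0.5 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0.5, 1.0]")
    freqs = _split_frequencies(sample)
    if threshold >= 1.0:
        keep = {s: f for s, f in freqs.items() if f >= 1.0 - 1e-12}
    else:
        keep = {s: f for s, f in freqs.items() if f > threshold + 1e-12}
    return tree_from_splits(keep, sample.leaf_set, support=keep)


# ---------------------------------------------------------------------------
# maximum clade credibility


def _clade_sets(tree: dendropy.Tree) -> list:
    return [below for _, below in _clades(tree)] + [leafset(tree)]


def mcc_tree(sample: TreeSample, burnin: float = 0.0) -> dendropy.Tree:
    """Maximum clade credibility topology of a rooted tree sample.

    Scores each tree by the sum of log clade frequencies taken over the
    sample after discarding the first ``burnin`` fraction; ties go to the
    lowest input index. The winner's internal nodes are annotated with
    their clade frequency (``node.support``).
    """
    if not 0.0 <= burnin < 1.0:
        raise ValueError("burnin must lie in [0, 1)")
    start = int(len(sample.trees) * burnin)
    trees = sample.trees[start:]
    weights = sample.weights[start:]
    if not trees:
        raise ValueError("no trees left after burn-in")
    total = sum(weights)
    freqs: dict = {}
    for tree, w in zip(trees, weights):
        for clade in _clade_sets(tree):
            freqs[clade] = freqs.get(clade, 0.0) + w
    freqs = {c: v / total for c, v in freqs.items()}

    best, best_score = None, -math.inf
    for tree in trees:
        score = sum(math.log(freqs[c]) for c in _clade_sets(tree))
        if score > best_score + 1e-12:
            best, best_score = tree, score
    winner = best.clone(depth=1)
    below = {}
    for node in winner.postorder_node_iter():
        if node.is_leaf():
            below[node] = frozenset([node.taxon.label])
        else:
            below[node] = frozenset().union(*(below[c] for c in node.child_nodes()))
            node.support = freqs.get(below[node], 0.0)
    return winner
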