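"""Molecular backbone constraints for parsimony with floating fossils.

The backbone is built from a support-annotated, rooted molecular tree
(typically the maximum clade credibility tree of a Bayesian sample):
every clade whose posterior probability falls below a threshold is
collapsed into a polytomy, and the remainder is restricted to the
constrained (extant) taxa.

Constraint semantics are rooted-clade based, matching how constraint
trees behave in parsimony programs: a backbone clade C over constrained
taxon set K requires the candidate tree to have some edge whose
restriction to K separates exactly C from K - C. Unconstrained (fossil)
taxa may attach anywhere — inside or around a constrained clade — without
affecting the verdict, and a partial tree built during stepwise addition
is checked against the backbone restricted to the taxa already placed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import dendropy

from .trees import edge_sides, leafset, tree_from_clades

__all__ = ["BackboneConstraint", "build_backbone", "satisfies_constraint"]


@dataclass
class BackboneConstraint:
    """Hard topological constraint on a subset of taxa."""

    tree: dendropy.Tree  # rooted, collapsed + restricted constraint tree
    pp_threshold: float
    constrained_taxa: frozenset
    n_collapsed: int
    collapsed: list  # (clade frozenset, pp) for every collapsed node
    clades: frozenset  # enforced clades, restricted to constrained_taxa


def build_backbone(
    backbone_tree: dendropy.Tree,
    pp_threshold: float = 0.70,
    constrained_taxa: Optional[Iterable[str]] = None,
    missing_pp: str = "error",
) -> BackboneConstraint:
    """Collapse weakly supported clades and restrict to the constrained taxa.

    Parameters
    ----------
    backbone_tree:
        Support-annotated rooted tree (``node.support`` in [0, 1], as
        produced by :func:`backbonemp.trees.parse_newick` or
        :func:`~backbonemp.trees.mcc_tree`).
    pp_threshold:
        Clades with posterior probability strictly below this value are
        collapsed; the conventional conservative setting is 0.70.
    constrained_taxa:
        Taxa the constraint applies to (the extant taxa); defaults to all
        leaves of the backbone tree.
    missing_pp:
        ``"error"`` (default) raises on an internal node without a support
        annotation; ``"one"`` treats missing support as 1.0 (never
        collapsed).
    """
    if missing_pp not in ("error", "one"):
        raise ValueError("missing_pp must be 'error' or 'one'")
    full = leafset(backbone_tree)
    constrained = frozenset(constrained_taxa) if constrained_taxa else full
    if not constrained <= full:
        raise ValueError(
            f"constrained taxa missing from backbone: "
            f"{sorted(constrained - full)}"
        )

    below = {}
    keep: dict = {}
    collapsed = []
    for node in backbone_tree.postorder_node_iter():
        if node.is_leaf():
            below[node] = frozenset([node.taxon.label])
            continue
        below[node] = frozenset().union(*(below[c] for c in node.child_nodes()))
        if node.parent_node is None:
            continue
        if len(below[node]) < 2:
            continue
        pp = getattr(node, "support", None)
        if pp is None:
            if missing_pp == "error":
                raise ValueError(
                    f"internal node {sorted(below[node])[:3]}... lacks a "
                    "support annotation (missing_pp='error')"
                )
            pp = 1.0
        if pp > 1.0:
            pp = pp / 100.0
        if pp < pp_threshold - 1e-12:
            collapsed.append((below[node], pp))
        else:
            # keep the highest pp if distinct nodes restrict identically
            keep[below[node]] = max(pp, keep.get(below[node], 0.0))

    restricted: dict = {}
    for clade, pp in keep.items():
        inside = clade & constrained
        if len(inside) >= 2 and inside != constrained:
            restricted[inside] = max(pp, restricted.get(inside, 0.0))
    tree = tree_from_clades(restricted.items(), constrained)
    for node in tree.preorder_internal_node_iter():
        if node.parent_node is not None:
            members = frozenset(l.taxon.label for l in node.leaf_iter())
            node.support = restricted.get(members)
    return BackboneConstraint(
        tree=tree,
        pp_threshold=pp_threshold,
        constrained_taxa=constrained,
        n_collapsed=len(collapsed),
        collapsed=collapsed,
        clades=frozenset(restricted),
    )


def satisfies_constraint(tree: dendropy.Tree, backbone: BackboneConstraint) -> bool:
    """True when every enforced backbone clade, restricted to the taxa the
    candidate actually contains, is displayed by the candidate.

    The candidate is read as rooted: clade C (restricted) is displayed
    when some node's leaf set restricts to exactly C. When the root has a
    leaf child — the basal-taxon rooting convention used for search
    output — that leaf plays the outgroup role, and a clade containing it
    is matched through its complement (the unrooted reading of the same
    edge). Partial trees from stepwise addition are checked against the
    correspondingly restricted backbone.
    """
    shared = backbone.constrained_taxa & leafset(tree)
    root_leaves = sorted(
        c.taxon.label for c in tree.seed_node.child_nodes() if c.is_leaf()
    )
    root_taxon = root_leaves[0] if root_leaves else None
    have = {side & shared for side in edge_sides(tree)}
    for clade in backbone.clades:
        inside = clade & shared
        outside = shared - inside
        if len(inside) < 2 or not outside:
            continue
        target = outside if root_taxon in inside else inside
        if target not in have:
            return False
    return True
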