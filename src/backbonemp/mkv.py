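"""Mk/Mkv likelihood for discrete morphological characters.

The Mk model (Lewis 2001 family) is a k-state symmetric Markov process
with equal stationary frequencies 1/k; on a branch of expected length v
(substitutions per character),

    P(same) = 1/k + (k-1)/k * exp(-k/(k-1) * v)
    P(diff) = 1/k - 1/k  * exp(-k/(k-1) * v).

The Mkv variant conditions on a character being variable — the
ascertainment regime of morphological matrices, which never contain
constant characters — by dividing every site likelihood by
(1 - sum of constant-pattern likelihoods). Among-character rate
variation uses the discrete-gamma approximation (equal-probability
categories, category means, mean 1).

Each character uses its own state count k (observed states, minimum 2)
unless the model fixes a global k.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import dendropy
from scipy import stats
from scipy.optimize import minimize_scalar

from .matrix import CharacterMatrix
from .trees import parse_newick, _quote

__all__ = [
    "MkvModel",
    "LikelihoodResult",
    "MLSearchConfig",
    "mk_transition_probs",
    "discrete_gamma_rates",
    "mkv_log_likelihood",
    "nj_start_tree",
    "fit_mkv",
]

_BL_FLOOR = 1e-8


@dataclass
class MkvModel:
    k: Optional[int] = None  # None: per-character observed state count
    gamma_alpha: Optional[float] = None
    n_rate_categories: int = 4
    correction: bool = True  # Mkv (variable-characters-only) conditioning

    def __post_init__(self):
        if self.k is not None and self.k < 2:
            raise ValueError("k must be >= 2")
        if self.gamma_alpha is not None and self.gamma_alpha <= 0:
            raise ValueError("gamma shape must be positive")
        if self.n_rate_categories < 1:
            raise ValueError("need >= 1 rate category")


@dataclass
class LikelihoodResult:
    log_likelihood: float
    per_character: np.ndarray
    model: MkvModel


def mk_transition_probs(k: int, v: float) -> tuple:
    """(P(same state), P(different specific state)) after branch length v."""
    if v < 0:
        raise ValueError("negative branch length")
    e = math.exp(-k / (k - 1) * v)
    return 1.0 / k + (k - 1) / k * e, 1.0 / k - 1.0 / k * e


def discrete_gamma_rates(alpha: float, n_categories: int) -> np.ndarray:
    """Mean rates of equal-probability categories of Gamma(alpha, alpha)
    (mean 1); the standard discrete-gamma approximation."""
    if n_categories == 1:
        return np.ones(1)
    bounds = stats.gamma.ppf(
        np.linspace(0, 1, n_categories + 1), a=alpha, scale=1.0 / alpha
    )
    # E[X; X in interval] for Gamma(a, rate a) via the a+1 identity
    upper = stats.gamma.cdf(bounds, a=alpha + 1, scale=1.0 / alpha)
    return n_categories * np.diff(upper)


# ---------------------------------------------------------------------------
# pruning


def _char_groups(matrix: CharacterMatrix, model: MkvModel,
                 on_invariant: str = "error"):
    """Group character indices by effective k; validate observability."""
    groups: dict = {}
    dropped = []
    for j in range(matrix.n_characters):
        observed = set()
        for row in matrix.cells:
            observed |= row[j].states
        if len(observed) < 2 and model.correction:
            if on_invariant == "error":
                raise ValueError(
                    f"character {j} has <2 observed states; invalid under "
                    "the variable-characters-only (Mkv) correction"
                )
            dropped.append(j)
            continue
        k = model.k if model.k is not None else max(2, len(observed))
        groups.setdefault(k, []).append(j)
    if dropped:
        warnings.warn(
            f"dropped {len(dropped)} character(s) with <2 observed states"
        )
    return groups, dropped


def _postorder_edges(tree: dendropy.Tree):
    nodes = list(tree.postorder_node_iter())
    for n in nodes:
        if n is not tree.seed_node:
            v = n.edge.length
            if v is None or v < 0:
                raise ValueError(
                    "every non-root branch needs a non-negative length"
                )
    return nodes


def _group_site_likelihoods(tree, matrix, char_idx, k, rate) -> np.ndarray:
    """Uncorrected site likelihoods for characters of one state count at
    one rate multiplier, plus (returned separately) the constant-pattern
    probability for the same k and rate."""
    m = len(char_idx)
    partial = {}
    const_partial = {}
    for node in _postorder_edges(tree):
        if node.is_leaf():
            arr = np.zeros((k, m))
            row = matrix.row(node.taxon.label)
            for jj, j in enumerate(char_idx):
                cell = row[j]
                if cell.is_observed:
                    allowed = [s for s in cell.states if s < k]
                    if not allowed:
                        arr[:, jj] = 1.0
                    else:
                        arr[allowed, jj] = 1.0
                else:
                    arr[:, jj] = 1.0
            partial[node] = arr
            const_partial[node] = np.zeros(k)
            const_partial[node][0] = 1.0
        else:
            arr = np.ones((k, m))
            carr = np.ones(k)
            for child in node.child_nodes():
                p_same, p_diff = mk_transition_probs(
                    k, child.edge.length * rate)
                down = partial[child]
                csum = down.sum(axis=0)
                arr *= p_diff * csum[None, :] + (p_same - p_diff) * down
                cdown = const_partial[child]
                carr *= p_diff * cdown.sum() + (p_same - p_diff) * cdown
            partial[node] = arr
            const_partial[node] = carr
    root = tree.seed_node
    site = partial[root].mean(axis=0)  # equal root frequencies 1/k
    p_const = const_partial[root].mean() * k  # k symmetric constant patterns
    return site, p_const


def mkv_log_likelihood(
    tree: dendropy.Tree,
    matrix: CharacterMatrix,
    model: Optional[MkvModel] = None,
    on_invariant: str = "error",
) -> LikelihoodResult:
    """Pruning-algorithm log-likelihood of a branch-length tree under the
    Mk(v) model, with optional discrete-gamma rate variation. Missing and
    inapplicable cells contribute all-ones partial likelihoods."""
    model = model or MkvModel()
    groups, dropped = _char_groups(matrix, model, on_invariant)
    rates = (
        discrete_gamma_rates(model.gamma_alpha, model.n_rate_categories)
        if model.gamma_alpha is not None
        else np.ones(1)
    )
    per_char = np.full(matrix.n_characters, np.nan)
    for k, char_idx in groups.items():
        site_acc = np.zeros(len(char_idx))
        const_acc = 0.0
        for rate in rates:
            site, p_const = _group_site_likelihoods(
                tree, matrix, char_idx, k, float(rate))
            site_acc += site / len(rates)
            const_acc += p_const / len(rates)
        if model.correction:
            site_acc = site_acc / (1.0 - const_acc)
        per_char[char_idx] = np.log(site_acc)
    valid = ~np.isnan(per_char)
    return LikelihoodResult(
        log_likelihood=float(per_char[valid].sum()),
        per_character=per_char,
        model=model,
    )


# ---------------------------------------------------------------------------
# neighbor joining on p-distances


def p_distance_matrix(matrix: CharacterMatrix) -> np.ndarray:
    """Pairwise mismatch fraction over characters observed in both taxa;
    overlapping state sets count as a match. Pairs with no shared observed
    character get the maximum observed distance (with a warning)."""
    n = matrix.n_taxa
    d = np.zeros((n, n))
    no_overlap = []
    for i in range(n):
        for j in range(i + 1, n):
            shared = mism = 0
            for c in range(matrix.n_characters):
                a, b = matrix.cells[i][c], matrix.cells[j][c]
                if a.is_observed and b.is_observed:
                    shared += 1
                    if not (a.states & b.states):
                        mism += 1
            if shared == 0:
                no_overlap.append((i, j))
            else:
                d[i, j] = d[j, i] = mism / shared
    if no_overlap:
        fill = d.max()
        for i, j in no_overlap:
            d[i, j] = d[j, i] = fill
        warnings.warn(
            f"{len(no_overlap)} taxon pair(s) share no observed characters; "
            "distance set to the maximum observed"
        )
    return d


def nj_start_tree(matrix: CharacterMatrix) -> dendropy.Tree:
    """Neighbor-joining tree from p-distances (Saitou & Nei agglomeration;
    ties broken at the lowest index pair; negative branch lengths clamped
    to a small positive floor)."""
    if matrix.n_taxa < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    labels = matrix.taxon_names
    d = p_distance_matrix(matrix).astype(float)
    active = list(range(matrix.n_taxa))
    newick = {i: _quote(labels[i]) for i in active}
    dm = {(i, j): d[i, j] for i in active for j in active if i < j}

    def dist(i, j):
        return dm[(i, j) if i < j else (j, i)]

    next_id = matrix.n_taxa
    while len(active) > 2:
        r = {i: sum(dist(i, j) for j in active if j != i) for i in active}
        n = len(active)
        best, pair = None, None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                q = (n - 2) * dist(i, j) - r[i] - r[j]
                if best is None or q < best - 1e-12:
                    best, pair = q, (i, j)
        i, j = pair
        dij = dist(i, j)
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (n - 2))
        lj = dij - li
        li, lj = max(li, _BL_FLOOR), max(lj, _BL_FLOOR)
        u = next_id
        next_id += 1
        for m_ in active:
            if m_ in (i, j):
                continue
            dm[(min(m_, u), max(m_, u))] = 0.5 * (
                dist(i, m_) + dist(j, m_) - dij
            )
        newick[u] = f"({newick[i]}:{li:.10g},{newick[j]}:{lj:.10g})"
        active = [x for x in active if x not in (i, j)] + [u]
    i, j = active
    v = max(dist(i, j), _BL_FLOOR)
    text = f"({newick[i]}:{v / 2:.10g},{newick[j]}:{v / 2:.10g});"
    return parse_newick(text)


# ---------------------------------------------------------------------------
# reduced ML search


@dataclass
class MLSearchConfig:
    """Desk-scale topology search settings: random TBR proposals around the
    current tree with coordinate-wise branch-length optimization."""

    n_rounds: int = 5
    neighbors_per_round: int = 10
    branch_sweeps: int = 2
    seed: int = 0
    bl_max: float = 20.0


def _optimize_branch_lengths(tree, matrix, model, sweeps, bl_max,
                             on_invariant="error"):
    edges = [
        n.edge for n in tree.preorder_node_iter() if n.parent_node is not None
    ]
    for _ in range(sweeps):
        for edge in edges:
            def neg_ll(v):
                edge.length = float(v)
                return -mkv_log_likelihood(
                    tree, matrix, model, on_invariant).log_likelihood

            res = minimize_scalar(
                neg_ll, bounds=(_BL_FLOOR, bl_max), method="bounded",
                options={"xatol": 1e-4},
            )
            edge.length = float(res.x)
    return mkv_log_likelihood(tree, matrix, model, on_invariant)


def fit_mkv(
    matrix: CharacterMatrix,
    model: Optional[MkvModel] = None,
    config: Optional[MLSearchConfig] = None,
    on_invariant: str = "error",
):
    """Maximum-likelihood tree under Mk(v): neighbor-joining start tree,
    then rounds of random TBR rearrangements, each re-optimizing branch
    lengths, accepting only strict log-likelihood improvements. Returns
    ``(tree, LikelihoodResult)``; deterministic for a given seed."""
    from .search import UTree, _tbr_neighbor_utrees
    from .trees import leafset

    model = model or MkvModel()
    config = config or MLSearchConfig()
    rng = np.random.default_rng(config.seed)

    tree = nj_start_tree(matrix)
    for node in tree.preorder_node_iter():
        if node.parent_node is not None and (
            node.edge.length is None or node.edge.length < _BL_FLOOR
        ):
            node.edge.length = _BL_FLOOR
    best = _optimize_branch_lengths(
        tree, matrix, model, config.branch_sweeps, config.bl_max, on_invariant)
    names = sorted(leafset(tree))

    for _ in range(config.n_rounds):
        ut = UTree.from_dendropy(tree, names)
        neighbors = list(_tbr_neighbor_utrees(ut))
        if not neighbors:
            break
        take = min(config.neighbors_per_round, len(neighbors))
        picks = rng.choice(len(neighbors), size=take, replace=False)
        improved = False
        for idx in picks:
            cand = neighbors[int(idx)].to_dendropy(names)
            for node in cand.preorder_node_iter():
                if node.parent_node is not None:
                    node.edge.length = 0.1
            cand_ll = _optimize_branch_lengths(
                cand, matrix, model, config.branch_sweeps, config.bl_max,
                on_invariant)
            if cand_ll.log_likelihood > best.log_likelihood + 1e-9:
                tree, best = cand, cand_ll
                improved = True
        if not improved:
            break
    return tree, best
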