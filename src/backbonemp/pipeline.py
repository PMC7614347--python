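"""End-to-end workflow: matrix + molecular tree sample -> backbone ->
constrained parsimony search -> consensus trees -> homoplasy indices ->
character mapping -> optional resampling support -> report bundle.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import dendropy

from .backbone import BackboneConstraint, build_backbone, satisfies_constraint
from .mapping import classify_changes, resample_support
from .matrix import CharacterMatrix, matrix_summary, read_matrix
from .parsimony import ensemble_indices, tree_length
from .search import MPTSet, SearchConfig, heuristic_search
from .trees import (
    TreeSample,
    leafset,
    majority_consensus,
    mcc_tree,
    read_tree_sample,
    strict_consensus,
    write_newick,
)

__all__ = ["PipelineConfig", "ReportBundle", "run_pipeline"]


@dataclass
class PipelineConfig:
    matrix_path: str
    backbone_path: Optional[str] = None  # tree sample or annotated tree
    constraint_mode: str = "conservative"  # conservative | full | none
    pp_threshold: float = 0.70
    burnin: float = 0.10  # sample fraction discarded before the MCC tree
    name_map_path: Optional[str] = None  # TSV: backbone name -> matrix name
    replicates: int = 1000
    hold: int = 10
    seed: int = 42
    collapse_rule: str = "min_length_zero"
    missing_pp: str = "error"
    support_kind: Optional[str] = None  # bootstrap | jackknife | None
    support_reps: int = 100
    support_replicates: int = 2  # search replicates inside each resample
    jackknife_removal_p: float = 0.36
    output_dir: Optional[str] = None

    def __post_init__(self):
        if self.constraint_mode not in ("conservative", "full", "none"):
            raise ValueError(
                f"unknown constraint mode {self.constraint_mode!r}"
            )


@dataclass
class ReportBundle:
    matrix: CharacterMatrix
    backbone: Optional[BackboneConstraint]
    mpts: MPTSet
    strict: dendropy.Tree
    majority: dendropy.Tree
    indices: object
    changes: list
    support: Optional[object]
    summary: dict


def _load_backbone_tree(config: PipelineConfig) -> dendropy.Tree:
    sample = read_tree_sample(config.backbone_path)
    if len(sample) > 1:
        return mcc_tree(sample, burnin=config.burnin)
    return sample.trees[0]


def _apply_name_map(tree: dendropy.Tree, path: str) -> None:
    mapping = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        src, dst = line.split("\t")
        mapping[src] = dst
    for leaf in tree.leaf_node_iter():
        if leaf.taxon.label in mapping:
            leaf.taxon.label = mapping[leaf.taxon.label]


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Run the full analysis described by ``config``; writes result files
    under ``output_dir`` when given, and returns everything in memory."""
    matrix_path = Path(config.matrix_path)
    if not matrix_path.exists():
        raise FileNotFoundError(f"matrix not found: {matrix_path}")
    matrix = read_matrix(matrix_path)

    backbone = None
    if config.constraint_mode != "none":
        if config.backbone_path is None:
            raise ValueError(
                "constraint mode requires a backbone tree or tree sample"
            )
        if not Path(config.backbone_path).exists():
            raise FileNotFoundError(
                f"backbone not found: {config.backbone_path}"
            )
        btree = _load_backbone_tree(config)
        if config.name_map_path:
            _apply_name_map(btree, config.name_map_path)
        extant = frozenset(t.name for t in matrix.taxa if t.extant)
        missing = extant - leafset(btree)
        if missing:
            raise ValueError(
                "extant matrix taxa absent from the backbone "
                f"(supply a name map): {sorted(missing)}"
            )
        threshold = (
            config.pp_threshold
            if config.constraint_mode == "conservative"
            else 0.0
        )
        backbone = build_backbone(
            btree,
            pp_threshold=threshold,
            constrained_taxa=extant,
            missing_pp=config.missing_pp,
        )

    search_config = SearchConfig(
        replicates=config.replicates,
        hold_per_replicate=config.hold,
        seed=config.seed,
        collapse_rule=config.collapse_rule,
        constraint=backbone,
    )
    mpts = heuristic_search(matrix, search_config)
    sample = TreeSample(list(mpts.trees))
    strict = strict_consensus(sample)
    majority = majority_consensus(sample)
    indices = ensemble_indices(mpts, matrix)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        changes = classify_changes(mpts, matrix, strict)

    support = None
    if config.support_kind:
        support = resample_support(
            matrix,
            SearchConfig(
                replicates=config.support_replicates,
                hold_per_replicate=config.hold,
                seed=config.seed,
                collapse_rule=config.collapse_rule,
                constraint=backbone,
            ),
            kind=config.support_kind,
            reps=config.support_reps,
            removal_p=config.jackknife_removal_p,
            rng=config.seed,
        )
        support.annotate(strict)
        support.annotate(majority)

    # report self-consistency: bundled trees re-score to the reported length
    for t in mpts.trees:
        assert tree_length(t, matrix) == mpts.length
        if backbone is not None:
            assert satisfies_constraint(t, backbone)

    ms = matrix_summary(matrix)
    summary = {
        "n_taxa": ms.n_taxa,
        "n_characters": ms.n_characters,
        "n_fossil": ms.n_fossil,
        "missing_fraction": ms.missing_fraction,
        "n_parsimony_informative": ms.n_parsimony_informative,
        "constraint_mode": config.constraint_mode,
        "pp_threshold": config.pp_threshold,
        "n_collapsed_backbone_nodes": (
            backbone.n_collapsed if backbone else None
        ),
        "best_length": mpts.length,
        "n_mpts": len(mpts),
        "ensemble_ci": indices.CI,
        "ensemble_ri": indices.RI,
        "seed": config.seed,
        "replicates": config.replicates,
        "hold": config.hold,
        "collapse_rule": config.collapse_rule,
    }

    bundle = ReportBundle(
        matrix=matrix,
        backbone=backbone,
        mpts=mpts,
        strict=strict,
        majority=majority,
        indices=indices,
        changes=changes,
        support=support,
        summary=summary,
    )
    if config.output_dir:
        _write_outputs(bundle, config)
    return bundle


def _write_outputs(bundle: ReportBundle, config: PipelineConfig) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "mpts.tre").write_text(
        "".join(write_newick(t, with_support=False) + "\n"
                for t in bundle.mpts.trees)
    )
    (out / "strict.tre").write_text(write_newick(bundle.strict) + "\n")
    (out / "majority.tre").write_text(write_newick(bundle.majority) + "\n")
    if bundle.backbone is not None:
        (out / "backbone.tre").write_text(
            write_newick(bundle.backbone.tree) + "\n"
        )
        rows = ["clade\tpp\taction"]
        for clade, pp in bundle.backbone.collapsed:
            rows.append(f"{'|'.join(sorted(clade))}\t{pp:.4f}\tcollapsed")
        (out / "collapsed_nodes.tsv").write_text("\n".join(rows) + "\n")
    idx = bundle.indices
    rows = ["character\tm\ts\tg\tci"]
    for j in range(len(idx.m)):
        ci = "" if not (idx.ci_per_char[j] == idx.ci_per_char[j]) \
            else f"{idx.ci_per_char[j]:.4f}"
        rows.append(f"{j}\t{idx.m[j]}\t{idx.s[j]}\t{idx.g[j]}\t{ci}")
    (out / "character_steps.tsv").write_text("\n".join(rows) + "\n")
    rows = ["clade\tcharacter\tfrom\tto\tunambiguous\thomoplastic"]
    for ch in bundle.changes:
        rows.append(
            f"{'|'.join(sorted(ch.clade))}\t{ch.character}\t{ch.from_state}"
            f"\t{ch.to_state}\t{int(ch.unambiguous)}\t{int(ch.homoplastic)}"
        )
    (out / "character_changes.tsv").write_text("\n".join(rows) + "\n")
    if bundle.support is not None:
        rows = ["clade\tfrequency"]
        for s, f in sorted(
            bundle.support.frequencies.items(),
            key=lambda kv: -kv[1],
        ):
            side = min(tuple(s), key=lambda x: (len(x), sorted(x)))
            rows.append(f"{'|'.join(sorted(side))}\t{f:.3f}")
        (out / f"{bundle.support.kind}_support.tsv").write_text(
            "\n".join(rows) + "\n"
        )
    (out / "summary.json").write_text(
        json.dumps(bundle.summary, indent=2) + "\n"
    )
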