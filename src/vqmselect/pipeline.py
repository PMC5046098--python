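"""End-to-end orchestration: consolidate -> split -> match -> VQM -> select -> pairs.

The pipeline takes either a phantom specification or per-phase volume/tree
files, runs every stage with one set of parameters and one seed, and writes
per-stage artifacts plus a manifest (parameters, seed, package version,
SHA-256 digest of every artifact) so a run is auditable and reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .correspondence import (
    MatchingParams,
    consolidate_branching_points,
    match_branches,
    remove_subset_branches,
)
from .cpr import straighten_branch
from .model import (
    PhaseSet,
    load_tree,
    load_volume,
    save_tree,
    save_volume,
    split_tree_at_points,
    tree_to_dict,
)
from .agreement import make_preference_pairs
from .phantom import CurveSpec, PhantomSpec, PhaseNoiseSpec, generate_phantom
from .vqm import CrossSectionSpec, compute_group_records, rank_and_select

__all__ = ["PipelineConfig", "run_pipeline", "load_config", "phantom_spec_from_dict"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Inputs, parameters, and output location of one pipeline run."""

    out_dir: Path
    seed: int = 0
    phantom: Optional[PhantomSpec] = None
    # file inputs (used when no phantom spec is given): label -> path
    volumes: dict[str, str] = field(default_factory=dict)
    trees: dict[str, str] = field(default_factory=dict)
    phase_order: list[str] = field(default_factory=list)
    matching: MatchingParams = field(default_factory=MatchingParams)
    cross_section: CrossSectionSpec = field(default_factory=CrossSectionSpec)
    straighten: bool = False

    def __post_init__(self):
        self.out_dir = Path(self.out_dir)
        if self.phantom is None:
            missing = [p for p in list(self.volumes.values()) + list(self.trees.values())
                       if not Path(p).exists()]
            if missing:
                raise FileNotFoundError(f"missing inputs: {missing}")
            if not self.trees:
                raise ValueError("either a phantom spec or tree inputs are required")


def phantom_spec_from_dict(doc: dict) -> PhantomSpec:
    curves = [CurveSpec(c["control_points"], c["radius"]) for c in doc["tree_spec"]]
    phases = [
        PhaseNoiseSpec(
            label=p["label"],
            blur_sigma=p.get("blur_sigma", 0.0),
            jitter_sigma=p.get("jitter_sigma", 0.0),
            dropout_prob=p.get("dropout_prob", 0.0),
        )
        for p in doc["per_phase"]
    ]
    return PhantomSpec(
        grid_shape=tuple(doc["grid_shape"]),
        tree_spec=curves,
        per_phase=phases,
        spacing=tuple(doc.get("spacing", (1.0, 1.0, 1.0))),
        vessel_intensity=doc.get("vessel_intensity", 400.0),
        background_intensity=doc.get("background_intensity", 50.0),
        noise_sigma=doc.get("noise_sigma", 0.0),
        seed=doc.get("seed", 0),
        supersample=doc.get("supersample", 2),
    )


def load_config(path) -> PipelineConfig:
    """Read a YAML pipeline configuration."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    matching = MatchingParams(**doc.get("matching", {}))
    cross_section = CrossSectionSpec(**doc.get("cross_section", {}))
    phantom = phantom_spec_from_dict(doc["phantom"]) if "phantom" in doc else None
    return PipelineConfig(
        out_dir=doc["out_dir"],
        seed=doc.get("seed", 0),
        phantom=phantom,
        volumes=doc.get("volumes", {}),
        trees=doc.get("trees", {}),
        phase_order=doc.get("phase_order", []),
        matching=matching,
        cross_section=cross_section,
        straighten=doc.get("straighten", False),
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_inputs(config: PipelineConfig) -> PhaseSet:
    if config.phantom is not None:
        phase_set, _ = generate_phantom(config.phantom)
        return phase_set
    labels = config.phase_order or list(config.trees)
    phases = []
    for lab in labels:
        tree = load_tree(config.trees[lab])
        vol = load_volume(config.volumes[lab]) if lab in config.volumes else None
        phases.append((lab, vol, tree))
    return PhaseSet(phases)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and write artifacts; returns the run manifest.

    Stages: branching-point consolidation -> tree splitting -> subset-branch
    removal -> branch matching -> (optional CPR straightening) -> VQM ->
    best/worst selection -> randomized preference pairs.  A stage failure
    aborts with the stage name and offending entity in the exception message.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    phase_set = stage("load_inputs", lambda: _load_inputs(config))

    phase_set = stage("consolidate", lambda: consolidate_branching_points(phase_set, config.matching))

    def do_split():
        phases = []
        for lab, vol, tree in phase_set.phases:
            if tree.branching_points:
                tree = split_tree_at_points(tree, tree.branching_points)
            tree = remove_subset_branches(tree, config.matching)
            phases.append((lab, vol, tree))
        return PhaseSet(phases)

    phase_set = stage("split", do_split)

    for lab, _, tree in phase_set.phases:
        p = out / f"tree_{lab.replace('%', '')}.json"
        save_tree(tree, p)
        artifacts[f"tree_{lab}"] = p

    groups = stage("match", lambda: match_branches(phase_set, config.matching))
    groups_doc = [
        {
            "group_id": g.group_id,
            "members": sorted([list(m) for m in g.members]),
            "pair_coverage": {
                f"{a[0]}:{a[1]}|{b[0]}:{b[1]}": list(f)
                for (a, b), f in sorted(g.pair_coverage.items())
            },
        }
        for g in groups
    ]
    p = out / "groups.json"
    p.write_text(json.dumps(groups_doc, indent=1))
    artifacts["groups"] = p

    if config.straighten:
        def do_straighten():
            sdir = out / "straightened"
            sdir.mkdir(exist_ok=True)
            for lab, vol, tree in phase_set.phases:
                if vol is None:
                    continue
                for b in tree.branches:
                    sb = straighten_branch(vol, b)
                    from .model import Volume
                    sp = sdir / f"{lab.replace('%', '')}_{b.id}.nii.gz"
                    save_volume(Volume(sb.data), sp)
                    artifacts[f"straightened_{lab}_{b.id}"] = sp
        stage("straighten", do_straighten)

    records = stage("vqm", lambda: compute_group_records(phase_set, groups, config.cross_section))
    rows = []
    member_to_group = {m: g.group_id for g in groups for m in g.members}
    for (phase, bid), rec in sorted(records.items()):
        rows.append(
            {"group_id": member_to_group[(phase, bid)], "phase": phase,
             "branch_id": bid, "M": rec.m, "vqm": rec.vqm}
        )
    p = out / "vqm.csv"
    pd.DataFrame(rows).to_csv(p, index=False)
    artifacts["vqm"] = p

    phase_order = config.phase_order or phase_set.labels
    selections = stage("select", lambda: rank_and_select(groups, records, phase_order))
    sel_doc = [
        {
            "group_id": s.group_id,
            "best": list(s.best),
            "worst": list(s.worst),
            "pairable": s.pairable,
            "ranking": [[p_, b_, v_] for p_, b_, v_ in s.ranking],
        }
        for s in selections
    ]
    p = out / "selection.json"
    p.write_text(json.dumps(sel_doc, indent=1))
    artifacts["selection"] = p

    pairs = stage("pairs", lambda: make_preference_pairs(selections, config.seed))
    pairs_doc = [
        {
            "pair_id": pr.pair_id,
            "left": list(pr.left),
            "right": list(pr.right),
            "computer_best_side": pr.computer_best_side,
            "seed": pr.seed,
        }
        for pr in pairs
    ]
    p = out / "pairs.json"
    p.write_text(json.dumps(pairs_doc, indent=1))
    artifacts["pairs"] = p

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "phase_order": phase_order,
        "matching": asdict(config.matching),
        "cross_section": asdict(config.cross_section),
        "n_groups": len(groups),
        "n_pairs": len(pairs),
        "artifacts": {k: {"path": str(v), "sha256": _sha256(v)} for k, v in sorted(artifacts.items())},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
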