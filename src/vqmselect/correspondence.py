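"""Cross-phase branching-point consolidation and branch correspondence.

The same anatomical vessel segment appears in every cardiac phase of a
registered multi-phase study, but branching points are detected independently
per phase (and sometimes missed), so branch boundaries disagree.  Two stages
fix this:

1. *Branching-point consolidation*: every branching point is projected into
   every other phase (the identity map, since trees are pre-registered).  A
   projected point is added to the target phase only if it is farther than
   ``d_consolidate`` voxels (default 20) from every existing branching point
   there; otherwise it is grouped with the nearest existing point.  This both
   recovers branching points missed in low-quality phases and links
   corresponding points across phases.

2. *Branch matching*: after splitting trees at the consolidated points, branch
   b_i in phase G corresponds to branch b_j in phase U when, for at least
   ``coverage_min`` (default 70%) of b_i's unit-resampled centerline points,
   the nearest centerline point of the whole tree in U lies on b_j and within
   ``theta`` voxels (default 3) — and the same holds with G and U swapped.
   Pairwise matches over all phase pairs are merged into correspondence groups
   by transitive closure.

Short branches that are near-complete subsets of a longer branch in the same
phase are removed before matching.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .model import (
    Branch,
    BranchingPoint,
    CoronaryTree,
    PhaseSet,
    resample_branch,
)

__all__ = [
    "MatchingParams",
    "NearestHit",
    "CorrespondenceGroup",
    "nearest_centerline_distance",
    "consolidate_branching_points",
    "coverage_fraction",
    "match_branches",
    "remove_subset_branches",
]

log = logging.getLogger(__name__)


@dataclass
class MatchingParams:
    """Thresholds of the consolidation and matching rules (voxel units).

    ``d_consolidate`` is the minimum separation below which a projected
    branching point is merged with an existing one; ``theta`` is the maximum
    nearest-centerline distance for a centerline point to count toward branch
    coverage; ``coverage_min`` is the mutual coverage fraction required for a
    branch correspondence; ``subset_coverage`` governs same-phase subset-branch
    removal.  ``denominator`` selects whether the coverage fraction divides by
    all centerline points of the source branch ("all", default, stricter) or
    only by those within ``theta`` of the target tree ("within_theta").
    """

    d_consolidate: float = 20.0
    theta: float = 3.0
    coverage_min: float = 0.70
    subset_coverage: float = 0.90
    resample_step: float = 1.0
    denominator: str = "all"

    def __post_init__(self):
        for name in ("d_consolidate", "theta", "coverage_min", "subset_coverage", "resample_step"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.coverage_min <= 1 and 0 < self.subset_coverage <= 1):
            raise ValueError("coverage fractions must lie in (0, 1]")
        if self.denominator not in ("all", "within_theta"):
            raise ValueError("denominator must be 'all' or 'within_theta'")


@dataclass
class NearestHit:
    """Nearest-centerline query result: distance and where it was found."""

    distance: float
    branch_id: str
    point_index: int


@dataclass
class CorrespondenceGroup:
    """The (phase, branch id) pairs identified as one anatomical segment."""

    group_id: int
    members: set[tuple[str, str]]  # (phase label, branch id); one per phase at most
    pair_coverage: dict = field(default_factory=dict)  # (member, member) -> (f_ab, f_ba)

    def __post_init__(self):
        phases = [m[0] for m in self.members]
        if len(phases) != len(set(phases)):
            raise ValueError("a correspondence group cannot contain two branches of one phase")
        if not self.members:
            raise ValueError("a correspondence group needs >= 1 member")


# ---------------------------------------------------------------------------
# nearest-distance primitive
# ---------------------------------------------------------------------------

def _tree_point_index(tree: CoronaryTree, step: Optional[float] = None):
    """Stack centerline points of all branches; return (points, branch ids, local indices)."""
    branches = tree.branches
    if step is not None:
        branches = [resample_branch(b, step) for b in branches]
    pts, bids, idxs = [], [], []
    for b in branches:
        p = b.positions
        pts.append(p)
        bids.extend([b.id] * len(p))
        idxs.extend(range(len(p)))
    if not pts:
        return np.empty((0, 3)), [], []
    return np.vstack(pts), bids, idxs


def nearest_centerline_distance(
    point, tree: CoronaryTree, step: Optional[float] = None
) -> NearestHit:
    """Shortest Euclidean distance from a point to any centerline point of a tree.

    Returns the arg-min branch id and the point index within that branch.
    With ``step`` given, branches are first resampled at that arc-length step.
    """
    if not tree.branches:
        raise ValueError("tree has no branches")
    pts, bids, idxs = _tree_point_index(tree, step)
    d = np.linalg.norm(pts - np.asarray(point, dtype=float), axis=1)
    k = int(np.argmin(d))
    return NearestHit(float(d[k]), bids[k], idxs[k])


# ---------------------------------------------------------------------------
# branching-point consolidation
# ---------------------------------------------------------------------------

class _UnionFind:
    def __init__(self):
        self.parent = {}

    def find(self, x):
        self.parent.setdefault(x, x)
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def consolidate_branching_points(
    phase_set: PhaseSet, params: MatchingParams = MatchingParams()
) -> PhaseSet:
    """Project branching points across phases and merge near-duplicates.

    Every branching point of every phase is projected (identity map — trees
    are pre-registered) into every other phase.  In the target phase the
    projected point is added as a new branching point only if its distance to
    every existing branching point there exceeds ``d_consolidate``; otherwise
    a correspondence with the nearest existing point is recorded.  Output
    trees carry the augmented branching-point lists with ``group_id`` linking
    corresponding points across phases.
    """
    labels = phase_set.labels
    # working per-phase point lists (grow as projections are added)
    points: dict[str, list[BranchingPoint]] = {
        lab: [replace(bp) for bp in phase_set.tree(lab).branching_points] for lab in labels
    }
    uf = _UnionFind()
    # keys identify point instances: (phase, index in working list)
    originals = [(lab, i) for lab in labels for i in range(len(points[lab]))]
    for src_lab, i in originals:
        src = points[src_lab][i]
        for tgt_lab in labels:
            if tgt_lab == src_lab:
                continue
            existing = points[tgt_lab]
            if existing:
                d = np.array(
                    [np.linalg.norm(bp.position - src.position) for bp in existing]
                )
                k = int(np.argmin(d))
            else:
                k, d = None, None
            if k is not None and d[k] <= params.d_consolidate:
                uf.union((src_lab, i), (tgt_lab, k))
            else:
                existing.append(
                    BranchingPoint(src.position.copy(), origin_phase=src_lab)
                )
                uf.union((src_lab, i), (tgt_lab, len(existing) - 1))

    # assign dense group ids in deterministic order
    group_of_root: dict = {}
    for lab in labels:
        for i, bp in enumerate(points[lab]):
            root = uf.find((lab, i))
            if root not in group_of_root:
                group_of_root[root] = len(group_of_root)
            bp.group_id = group_of_root[root]
            if not bp.origin_phase:
                bp.origin_phase = lab

    new_phases = []
    for lab, vol, tree in phase_set.phases:
        new_phases.append((lab, vol, replace(tree, branching_points=points[lab])))
    return PhaseSet(new_phases)


# ---------------------------------------------------------------------------
# coverage and matching
# ---------------------------------------------------------------------------

def coverage_fraction(
    branch_a: Branch,
    tree_b: CoronaryTree,
    params: MatchingParams = MatchingParams(),
) -> tuple[float, Optional[str]]:
    """Fraction of branch_a's centerline points whose nearest point in tree_b
    lies on a single (plurality) branch within ``theta`` voxels.

    Returns (fraction, plurality branch id); the id is None when no point of
    branch_a comes within ``theta`` of tree_b.
    """
    if not tree_b.branches:
        raise ValueError("target tree has no branches")
    a = resample_branch(branch_a, params.resample_step)
    pts_b, bids_b, _ = _tree_point_index(tree_b, params.resample_step)
    kd = cKDTree(pts_b)
    dist, idx = kd.query(a.positions)
    within = dist <= params.theta
    if params.denominator == "all":
        denom = len(a.points)
    else:
        denom = int(np.count_nonzero(within))
        if denom == 0:
            return 0.0, None
    votes: dict[str, int] = {}
    for ok, j in zip(within, idx):
        if ok:
            votes[bids_b[j]] = votes.get(bids_b[j], 0) + 1
    if not votes:
        return 0.0, None
    # deterministic plurality: most votes, ties by lexicographic id
    best_id = min(votes, key=lambda bid: (-votes[bid], bid))
    return votes[best_id] / denom, best_id


def match_branches(
    phase_set: PhaseSet, params: MatchingParams = MatchingParams()
) -> list[CorrespondenceGroup]:
    """Establish cross-phase branch correspondence groups.

    For every phase pair and branch pair, a correspondence holds when the
    coverage criterion is met mutually; pairwise matches are merged into
    groups by transitive closure.  Branches with no match form singleton
    groups.  If closure would place two branches of one phase in one group,
    the branch with the higher within-group mutual-coverage sum is kept and
    the loser is demoted to a singleton (logged).
    """
    labels = phase_set.labels
    members = [
        (lab, b.id) for lab in labels for b in phase_set.tree(lab).branches
    ]
    # directed coverage of each branch into each other phase's tree
    cov: dict[tuple[str, str, str], tuple[float, Optional[str]]] = {}
    for g in labels:
        for u in labels:
            if g == u:
                continue
            tree_u = phase_set.tree(u)
            if not tree_u.branches:
                continue
            for b in phase_set.tree(g).branches:
                cov[(g, b.id, u)] = coverage_fraction(b, tree_u, params)

    uf = _UnionFind()
    for m in members:
        uf.find(m)
    edges: dict[tuple, tuple[float, float]] = {}
    for gi in range(len(labels)):
        for ui in range(gi + 1, len(labels)):
            g, u = labels[gi], labels[ui]
            for bg in phase_set.tree(g).branches:
                fwd = cov.get((g, bg.id, u))
                if fwd is None:
                    continue
                f_gu, maj = fwd
                if maj is None or f_gu < params.coverage_min:
                    continue
                back = cov.get((u, maj, g))
                if back is None:
                    continue
                f_ug, maj_back = back
                if maj_back == bg.id and f_ug >= params.coverage_min:
                    edges[((g, bg.id), (u, maj))] = (f_gu, f_ug)
                    uf.union((g, bg.id), (u, maj))

    components: dict = {}
    for m in members:
        components.setdefault(uf.find(m), []).append(m)

    groups: list[CorrespondenceGroup] = []
    singles: list[tuple[str, str]] = []
    for comp in components.values():
        by_phase: dict[str, list] = {}
        for m in comp:
            by_phase.setdefault(m[0], []).append(m)
        kept = set(comp)
        for lab, ms in by_phase.items():
            if len(ms) > 1:
                def score(m):
                    s = 0.0
                    for (a, b), (f1, f2) in edges.items():
                        if m in (a, b):
                            s += f1 + f2
                    return s
                winner = min(ms, key=lambda m: (-score(m), m[1]))
                for m in ms:
                    if m != winner:
                        kept.discard(m)
                        singles.append(m)
                        log.warning(
                            "correspondence conflict in phase %s: dropped %s, kept %s",
                            lab, m[1], winner[1],
                        )
        pc = {
            (a, b): f for (a, b), f in edges.items() if a in kept and b in kept
        }
        groups.append(CorrespondenceGroup(0, set(kept), pc))
    for m in singles:
        groups.append(CorrespondenceGroup(0, {m}))

    # deterministic ordering and dense ids: sort by earliest phase then id
    order = {lab: i for i, lab in enumerate(labels)}
    groups.sort(key=lambda grp: min((order[p], bid) for p, bid in grp.members))
    for i, grp in enumerate(groups):
        grp.group_id = i
    return groups


def remove_subset_branches(
    tree: CoronaryTree, params: MatchingParams = MatchingParams()
) -> CoronaryTree:
    """Drop short branches that are near-complete subsets of a longer branch.

    A branch is removed when at least ``subset_coverage`` of its points lie
    within ``theta`` of a single longer kept branch.  Equal-length duplicates
    are broken deterministically: the lexicographically smaller id survives.
    """
    ranked = sorted(tree.branches, key=lambda b: (-b.arc_length, b.id))
    kept: list[Branch] = []
    for b in ranked:
        redundant = False
        for other in kept:
            probe = CoronaryTree(phase=tree.phase, side=tree.side, branches=[other])
            frac, _ = coverage_fraction(b, probe, params)
            if frac >= params.subset_coverage:
                redundant = True
                log.info("subset branch %s removed (covered by %s)", b.id, other.id)
                break
        if not redundant:
            kept.append(b)
    original_order = {b.id: i for i, b in enumerate(tree.branches)}
    kept.sort(key=lambda b: original_order[b.id])
    return replace(tree, branches=kept)
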