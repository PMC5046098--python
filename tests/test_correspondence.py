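"""Branching-point consolidation, coverage, and cross-phase branch matching."""

import itertools

import numpy as np
import pytest

from vqmselect.correspondence import (
    MatchingParams,
    consolidate_branching_points,
    coverage_fraction,
    match_branches,
    nearest_centerline_distance,
    remove_subset_branches,
)
from vqmselect.model import (
    Branch,
    BranchingPoint,
    CoronaryTree,
    PhaseSet,
    branch_from_arrays,
)
from vqmselect.phantom import PhantomSpec, PhaseNoiseSpec, default_tree_spec, generate_phantom
from vqmselect.studies import group_jaccard

from conftest import random_tree, straight_branch


# ---------------------------------------------------------------------------
# nearest-distance primitive
# ---------------------------------------------------------------------------

def test_nearest_distance_on_centerline_is_zero():
    tree = CoronaryTree(phase="70%", branches=[straight_branch()])
    hit = nearest_centerline_distance([0.0, 0.0, 7.0], tree)
    assert hit.distance == 0.0
    assert hit.branch_id == "b0"
    assert hit.point_index == 7


def test_nearest_distance_345_triangle():
    tree = CoronaryTree(phase="70%", branches=[straight_branch(length=30, n=31)])
    hit = nearest_centerline_distance([3.0, 4.0, 10.0], tree)
    assert hit.distance == pytest.approx(5.0, abs=1e-12)


def test_nearest_distance_equals_bruteforce(rng):
    for _ in range(25):
        tree = random_tree(rng, n_branches=int(rng.integers(1, 4)), n_points=50)
        point = rng.uniform(0, 70, size=3)
        hit = nearest_centerline_distance(point, tree)
        brute = min(
            np.linalg.norm(p.position - point)
            for b in tree.branches
            for p in b.points
        )
        assert hit.distance == pytest.approx(brute, abs=1e-12)


def test_nearest_distance_empty_tree_errors():
    with pytest.raises(ValueError):
        nearest_centerline_distance([0, 0, 0], CoronaryTree(phase="70%"))


# ---------------------------------------------------------------------------
# branching-point consolidation
# ---------------------------------------------------------------------------

def two_phase_set(points_a, points_b):
    ta = CoronaryTree(phase="A", branches=[straight_branch(phase="A", length=60, n=61)],
                      branching_points=[BranchingPoint(np.asarray(p, float), "A") for p in points_a])
    tb = CoronaryTree(phase="B", branches=[straight_branch(phase="B", length=60, n=61)],
                      branching_points=[BranchingPoint(np.asarray(p, float), "B") for p in points_b])
    return PhaseSet([("A", None, ta), ("B", None, tb)])


def test_consolidation_identical_phases_adds_nothing():
    pts = [[0, 0, 10], [0, 0, 40]]
    ps = consolidate_branching_points(two_phase_set(pts, pts))
    for lab in ("A", "B"):
        assert len(ps.tree(lab).branching_points) == 2
    groups_a = [bp.group_id for bp in ps.tree("A").branching_points]
    groups_b = [bp.group_id for bp in ps.tree("B").branching_points]
    assert sorted(groups_a) == sorted(groups_b)


def test_consolidation_far_point_is_projected_as_new():
    # phase A has a point; nearest B point is 25 voxels away (> d=20)
    ps = consolidate_branching_points(two_phase_set([[0, 0, 10]], [[0, 0, 35]]))
    b_points = ps.tree("B").branching_points
    assert len(b_points) == 2  # original + projected copy of A's point
    projected = [bp for bp in b_points if bp.origin_phase == "A"]
    assert len(projected) == 1
    a_group = ps.tree("A").branching_points[0].group_id
    assert projected[0].group_id == a_group


def test_consolidation_near_point_is_merged():
    # nearest B point 10 voxels away (<= d=20): correspondence, no addition
    ps = consolidate_branching_points(two_phase_set([[0, 0, 10]], [[0, 0, 20]]))
    b_points = ps.tree("B").branching_points
    assert len(b_points) == 1
    assert b_points[0].group_id == ps.tree("A").branching_points[0].group_id


# ---------------------------------------------------------------------------
# coverage fraction
# ---------------------------------------------------------------------------

def test_coverage_identical_branch_is_one():
    b = straight_branch(length=30, n=31)
    tree = CoronaryTree(phase="70%", branches=[straight_branch(length=30, n=31)])
    frac, maj = coverage_fraction(b, tree)
    assert frac == 1.0
    assert maj == "b0"


def test_coverage_beyond_theta_is_zero():
    b = straight_branch(start=(4.0, 0.0, 0.0), length=30, n=31)
    tree = CoronaryTree(phase="70%", branches=[straight_branch(length=30, n=31)])
    frac, maj = coverage_fraction(b, tree)
    assert frac == 0.0
    assert maj is None


def test_coverage_half_overlap_matches_bruteforce():
    # first half overlaps branch X, second half veers 10 voxels off
    pos = np.zeros((41, 3))
    pos[:, 2] = np.arange(41.0)
    pos[21:, 0] = np.minimum(np.arange(1, 21) * 2.0, 10.0)
    probe = branch_from_arrays("probe", "U", pos, 2.0)
    target = CoronaryTree(phase="G", branches=[straight_branch(phase="G", length=40, n=41)])
    params = MatchingParams()
    frac, maj = coverage_fraction(probe, target, params)
    assert maj == "b0"
    # brute-force per-point nearest assignment on the resampled probe
    from vqmselect.model import resample_branch

    rp = resample_branch(probe, 1.0)
    tgt = target.branches[0].positions
    votes = sum(
        np.min(np.linalg.norm(tgt - p.position, axis=1)) <= params.theta
        for p in rp.points
    )
    assert frac == pytest.approx(votes / len(rp.points), abs=1e-12)
    assert abs(frac - 0.5) < 0.1


# ---------------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------------

def identical_phase_set(n_phases=6, n_branches=5, seed=0):
    curves = default_tree_spec(n_branches=n_branches, seed=seed)
    labels = [f"p{i}" for i in range(n_phases)]
    spec = PhantomSpec(
        grid_shape=(96, 96, 64),
        tree_spec=curves,
        per_phase=[PhaseNoiseSpec(lab) for lab in labels],
        seed=seed,
    )
    ps, truth = generate_phantom(spec, render_volumes=False)
    return ps, truth


def test_match_identical_phases_full_groups():
    ps, _ = identical_phase_set()
    groups = match_branches(ps)
    assert len(groups) == 5
    assert all(len(g.members) == 6 for g in groups)


def test_match_grossly_misregistered_phases_yields_no_groups():
    a = CoronaryTree(phase="A", branches=[straight_branch(phase="A")])
    b = CoronaryTree(phase="B", branches=[straight_branch(phase="B", start=(50, 50, 0))])
    groups = match_branches(PhaseSet([("A", None, a), ("B", None, b)]))
    assert all(len(g.members) == 1 for g in groups)


def test_match_invariant_under_phase_permutation():
    ps, _ = identical_phase_set(n_phases=4, n_branches=4, seed=3)
    base = {frozenset(g.members) for g in match_branches(ps)}
    permuted = PhaseSet([ps.phases[i] for i in (2, 0, 3, 1)])
    perm = {frozenset(g.members) for g in match_branches(permuted)}
    assert base == perm


def test_no_group_holds_two_branches_of_one_phase():
    ps, _ = identical_phase_set(n_phases=3, n_branches=6, seed=5)
    for g in match_branches(ps):
        phases = [m[0] for m in g.members]
        assert len(phases) == len(set(phases))


def test_phantom_recovery_with_jitter_and_dropout():
    jaccards = []
    for seed in range(5):
        curves = default_tree_spec(n_branches=8, seed=seed)
        spec = PhantomSpec(
            grid_shape=(96, 96, 64),
            tree_spec=curves,
            per_phase=[
                PhaseNoiseSpec(lab, jitter_sigma=1.0, dropout_prob=0.2)
                for lab in ("80%", "75%", "70%", "50%", "45%", "40%")
            ],
            seed=seed,
        )
        ps, truth = generate_phantom(spec, render_volumes=False)
        groups = match_branches(ps)
        jaccards.append(group_jaccard(groups, truth.groups))
    assert np.mean(jaccards) >= 0.95


# ---------------------------------------------------------------------------
# subset-branch removal
# ---------------------------------------------------------------------------

def test_truncated_duplicate_is_removed():
    long = straight_branch("long", length=40, n=41)
    short = straight_branch("short", length=12, n=13)  # first 30% of long
    tree = CoronaryTree(phase="70%", branches=[long, short])
    out = remove_subset_branches(tree)
    assert [b.id for b in out.branches] == ["long"]


def test_disjoint_branches_untouched():
    a = straight_branch("a", start=(0, 0, 0))
    b = straight_branch("b", start=(30, 0, 0))
    tree = CoronaryTree(phase="70%", branches=[a, b])
    out = remove_subset_branches(tree)
    assert [br.id for br in out.branches] == ["a", "b"]


def test_equal_length_copies_tie_break_is_deterministic():
    a = straight_branch("aa")
    b = straight_branch("zz")
    tree = CoronaryTree(phase="70%", branches=[b, a])
    out = remove_subset_branches(tree)
    assert [br.id for br in out.branches] == ["aa"]
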