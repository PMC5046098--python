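"""Data model, file round-trips, tree splitting, and resampling."""

import numpy as np
import pytest

from vqmselect.model import (
    BranchingPoint,
    CoronaryTree,
    TreeSchemaError,
    Volume,
    VolumeFormatError,
    branch_from_arrays,
    load_tree,
    load_volume,
    polyline_length,
    resample_branch,
    save_tree,
    save_volume,
    split_tree_at_points,
)

from conftest import random_tree, straight_branch


@pytest.mark.parametrize("ext", ["nii.gz", "nii", "mha", "mhd"])
def test_volume_roundtrip(tmp_path, rng, ext):
    data = rng.integers(-1000, 2000, size=(7, 6, 5)).astype(np.int16)
    vol = Volume(data, spacing=(0.488, 0.488, 0.625), origin=(1.0, -2.0, 3.5))
    path = tmp_path / f"vol.{ext}"
    save_volume(vol, path)
    back = load_volume(path)
    np.testing.assert_array_equal(back.data, data)
    np.testing.assert_allclose(back.spacing, vol.spacing, atol=1e-6)


def test_load_volume_errors(tmp_path):
    with pytest.raises(VolumeFormatError):
        load_volume(tmp_path / "nope.nii.gz")
    with pytest.raises(VolumeFormatError):
        load_volume(tmp_path / "wrong.txt")
    # 2D payload is rejected
    import nibabel as nib

    img = nib.Nifti1Image(np.zeros((4, 4)), np.eye(4))
    nib.save(img, str(tmp_path / "flat.nii.gz"))
    with pytest.raises(VolumeFormatError):
        load_volume(tmp_path / "flat.nii.gz")


def test_volume_invariants():
    with pytest.raises(VolumeFormatError):
        Volume(np.zeros((3, 3, 3)), spacing=(1.0, 0.0, 1.0))
    with pytest.raises(VolumeFormatError):
        Volume(np.zeros((3, 3)))


def test_tree_roundtrip(tmp_path, rng):
    tree = random_tree(rng, n_branches=2, n_points=10)
    tree.branching_points.append(BranchingPoint(np.array([1.5, 2.5, 3.5]), "70%", 4))
    path = tmp_path / "tree.json"
    save_tree(tree, path)
    back = load_tree(path)
    assert [b.id for b in back.branches] == [b.id for b in tree.branches]
    for b0, b1 in zip(tree.branches, back.branches):
        np.testing.assert_allclose(b1.positions, b0.positions, atol=1e-6)
        np.testing.assert_allclose(b1.radii, b0.radii, atol=1e-6)
    assert back.branching_points[0].group_id == 4


def test_tree_schema_error_names_offending_field(tmp_path):
    doc = {
        "phase": "70%",
        "branches": [
            {"id": "b0", "points": [{"xyz": [0, 0, 0], "radius": 0.0},
                                    {"xyz": [0, 0, 1], "radius": 1.0}]}
        ],
    }
    path = tmp_path / "bad.json"
    path.write_text(__import__("json").dumps(doc))
    with pytest.raises(TreeSchemaError, match=r"branches\[0\].points\[0\].radius"):
        load_tree(path)


def test_split_no_points_is_identity():
    b = straight_branch(n=30)
    tree = CoronaryTree(phase="70%", branches=[b])
    out = split_tree_at_points(tree, [])
    assert len(out.branches) == 1
    np.testing.assert_array_equal(out.branches[0].positions, b.positions)


def test_split_single_point_index_arithmetic():
    b = straight_branch(length=99, n=100)
    tree = CoronaryTree(phase="70%", branches=[b])
    bp = BranchingPoint(b.points[40].position.copy())
    out = split_tree_at_points(tree, [bp])
    sizes = sorted(len(br.points) for br in out.branches)
    assert sizes == [41, 60]
    # the split vertex is shared
    first, second = out.branches
    np.testing.assert_array_equal(first.positions[-1], second.positions[0])


def test_split_y_junction_gives_three_branches():
    trunk = straight_branch("trunk", n=21)
    arm = straight_branch("arm", start=(0, 0, 20), direction=(0, 1, 0), length=10, n=11)
    tree = CoronaryTree(phase="70%", branches=[trunk, arm])
    junction = BranchingPoint(np.array([0.0, 0.0, 10.0]))
    out = split_tree_at_points(tree, [junction])
    assert len(out.branches) == 3


def test_split_matches_bruteforce_run_enumerator(rng):
    """Branch count per polyline = interior branching points + 1; points conserved."""
    for _ in range(10):
        tree = random_tree(rng, n_branches=rng.integers(1, 4), n_points=30)
        expected_count = 0
        points = []
        for b in tree.branches:
            k = int(rng.integers(0, 4))
            interior = sorted(rng.choice(np.arange(1, 29), size=k, replace=False))
            expected_count += len(interior) + 1
            points.extend(BranchingPoint(b.points[i].position.copy()) for i in interior)
        out = split_tree_at_points(tree, points)
        assert len(out.branches) == expected_count
        before = np.unique(np.round(tree.all_positions(), 6), axis=0)
        after = np.unique(np.round(out.all_positions(), 6), axis=0)
        np.testing.assert_array_equal(after, before)


def test_split_rejects_far_branching_point():
    tree = CoronaryTree(phase="70%", branches=[straight_branch()])
    far = BranchingPoint(np.array([50.0, 50.0, 50.0]))
    with pytest.raises(ValueError, match="snap tolerance"):
        split_tree_at_points(tree, [far])


def test_resample_straight_unit_step():
    b = straight_branch(length=10, n=5)
    out = resample_branch(b, 1.0)
    assert len(out.points) == 11
    np.testing.assert_allclose(out.positions[:, 2], np.arange(11), atol=1e-9)


def test_resample_preserves_arc_length_and_spacing(rng):
    tree = random_tree(rng, n_branches=1, n_points=40)
    b = tree.branches[0]
    step = 0.7
    out = resample_branch(b, step)
    assert abs(out.arc_length - b.arc_length) <= step / 2
    gaps = np.linalg.norm(np.diff(out.positions, axis=0), axis=1)
    # interior intervals exactly the requested step (resampled chords can only
    # be shorter than the arc step where the polyline bends between samples)
    assert np.all(gaps[:-1] <= step + 1e-6)
    straight = resample_branch(straight_branch(length=10, n=3), step)
    gaps = np.linalg.norm(np.diff(straight.positions, axis=0), axis=1)
    np.testing.assert_allclose(gaps[:-1], step, atol=1e-6)


def test_resample_step_longer_than_branch():
    b = straight_branch(length=3, n=4)
    out = resample_branch(b, 10.0)
    assert len(out.points) == 2
    np.testing.assert_array_equal(out.positions[0], b.positions[0])
    np.testing.assert_array_equal(out.positions[-1], b.positions[-1])


def test_resample_interpolates_radii():
    pos = np.column_stack([np.zeros(2), np.zeros(2), [0.0, 10.0]])
    b = branch_from_arrays("b0", "70%", pos, np.array([1.0, 3.0]))
    out = resample_branch(b, 1.0)
    np.testing.assert_allclose(out.radii, 1.0 + 0.2 * np.arange(11), atol=1e-9)


def test_polyline_length():
    assert polyline_length(np.array([[0, 0, 0], [3, 4, 0]])) == 5.0
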