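import numpy as np
import pytest

from vqmselect.model import CoronaryTree, branch_from_arrays


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def straight_branch(branch_id="b0", phase="70%", start=(0, 0, 0), direction=(0, 0, 1),
                    length=20.0, n=21, radius=2.0):
    """Straight centerline segment from start along a unit direction."""
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    t = np.linspace(0, length, n)
    pos = np.asarray(start, dtype=float) + t[:, None] * d
    return branch_from_arrays(branch_id, phase, pos, radius)


def random_tree(rng, phase="70%", n_branches=3, n_points=50, extent=60.0, radius=2.0):
    """Random polyline tree (smooth random walks) for brute-force oracles."""
    branches = []
    for i in range(n_branches):
        start = rng.uniform(10, extent - 10, size=3)
        noise = rng.normal(0, 1, size=(n_points - 1, 3))
        # heavily smoothed walk: vessel centerlines bend gently at voxel scale
        kernel = np.ones(9) / 9.0
        noise = np.apply_along_axis(lambda c: np.convolve(c, kernel, mode="same"), 0, noise)
        drift = rng.normal(0, 1, size=3)
        drift /= np.linalg.norm(drift)
        steps = drift + 0.6 * noise
        steps /= np.linalg.norm(steps, axis=1, keepdims=True)
        pos = np.vstack([start, start + np.cumsum(steps, axis=0)])
        branches.append(branch_from_arrays(f"b{i}", phase, pos, radius))
    return CoronaryTree(phase=phase, branches=branches)
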