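"""Curved planar reformation (CPR): straightening a vessel branch.

Each branch and a surrounding neighbourhood are resampled into a rectangular
volume by interpolating the source volume on planar cross sections
perpendicular to the centerline.  Cross-section orientation comes from a
rotation-minimizing frame (double-reflection propagation), which avoids the
normal flips Frenet frames suffer at inflection points and keeps consecutive
cross sections nearly parallel on smooth curves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .model import Branch, Volume

__all__ = ["FrameField", "StraightenedBranch", "build_frames", "straighten_branch"]


@dataclass
class FrameField:
    """Per-centerline-point orthonormal triads (tangent, normal, binormal)."""

    tangents: np.ndarray  # (L, 3)
    normals: np.ndarray  # (L, 3)
    binormals: np.ndarray  # (L, 3)

    def __len__(self):
        return len(self.tangents)


@dataclass
class StraightenedBranch:
    """CPR output: a rectangular volume around one straightened branch.

    ``data`` has shape (L, n, n) — slice k is the cross section at centerline
    point k, sampled on an odd in-plane grid so the centre voxel lies exactly
    on the centerline.  ``oob_mask`` marks samples that fell outside the
    source volume (filled with ``fill_value``).
    """

    data: np.ndarray
    in_plane_spacing: float
    step: float
    branch_id: str
    phase: str
    fill_value: float
    oob_mask: np.ndarray


def _initial_normal(t0: np.ndarray) -> np.ndarray:
    # axis least aligned with the tangent, projected into the normal plane
    axis = np.argmin(np.abs(t0))
    e = np.zeros(3)
    e[axis] = 1.0
    n = e - np.dot(e, t0) * t0
    return n / np.linalg.norm(n)


def build_frames(branch: Branch) -> FrameField:
    """Tangents by central differences; normals by double-reflection RMF."""
    pos = branch.positions
    if len(pos) < 2:
        raise ValueError("branch needs >= 2 points")
    diffs = np.gradient(pos, axis=0)
    norms = np.linalg.norm(diffs, axis=1)
    if np.any(norms < 1e-12):
        raise ValueError("zero-length segment in branch; resample first")
    tangents = diffs / norms[:, None]

    normals = np.empty_like(tangents)
    normals[0] = _initial_normal(tangents[0])
    for i in range(len(pos) - 1):
        v1 = pos[i + 1] - pos[i]
        c1 = float(np.dot(v1, v1))
        if c1 < 1e-24:
            raise ValueError("zero-length segment in branch; resample first")
        nL = normals[i] - (2.0 / c1) * np.dot(v1, normals[i]) * v1
        tL = tangents[i] - (2.0 / c1) * np.dot(v1, tangents[i]) * v1
        v2 = tangents[i + 1] - tL
        c2 = float(np.dot(v2, v2))
        if c2 < 1e-24:
            n_next = nL
        else:
            n_next = nL - (2.0 / c2) * np.dot(v2, nL) * v2
        # re-orthonormalize against accumulated round-off
        n_next = n_next - np.dot(n_next, tangents[i + 1]) * tangents[i + 1]
        normals[i + 1] = n_next / np.linalg.norm(n_next)
    binormals = np.cross(tangents, normals)
    return FrameField(tangents, normals, binormals)


def straighten_branch(
    vol: Volume,
    branch: Branch,
    half_width: float | None = None,
    in_plane_spacing: float = 0.5,
    fill_value: float | None = None,
    frames: FrameField | None = None,
) -> StraightenedBranch:
    """Resample the volume on planes perpendicular to the branch centerline.

    Slice k is the trilinear resampling of the volume on the plane through
    centerline point k spanned by (normal, binormal), on a square grid of
    physical half-extent ``half_width`` voxels with sample pitch
    ``in_plane_spacing``.  Defaults: half_width = 3x the branch mean radius,
    spacing 0.5 voxel.  Samples outside the volume take ``fill_value``
    (default: volume minimum) and are flagged in ``oob_mask``.
    """
    if half_width is None:
        half_width = 3.0 * branch.mean_radius
    if in_plane_spacing <= 0 or half_width <= 0:
        raise ValueError("half_width and in_plane_spacing must be positive")
    if fill_value is None:
        fill_value = float(np.min(vol.data))
    if frames is None:
        frames = build_frames(branch)
    pos = branch.positions
    n_half = int(round(half_width / in_plane_spacing))
    offsets = (np.arange(2 * n_half + 1) - n_half) * in_plane_spacing  # (n,)
    uu, vv = np.meshgrid(offsets, offsets, indexing="ij")  # (n, n)

    L, n = len(pos), 2 * n_half + 1
    coords = (
        pos[:, None, None, :]
        + uu[None, :, :, None] * frames.normals[:, None, None, :]
        + vv[None, :, :, None] * frames.binormals[:, None, None, :]
    )  # (L, n, n, 3)
    flat = coords.reshape(-1, 3).T  # (3, L*n*n)
    upper = np.array(vol.data.shape, dtype=float) - 1.0
    oob = np.any((flat < 0) | (flat > upper[:, None]), axis=0)
    data = map_coordinates(vol.data.astype(float), flat, order=1, mode="constant", cval=fill_value)
    data[oob] = fill_value
    return StraightenedBranch(
        data=data.reshape(L, n, n),
        oob_mask=oob.reshape(L, n, n),
        in_plane_spacing=in_plane_spacing,
        step=float(branch.arc_length / max(len(pos) - 1, 1)),
        branch_id=branch.id,
        phase=branch.phase,
        fill_value=fill_value,
    )
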