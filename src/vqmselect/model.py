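"""Geometric data model for multi-phase coronary vessel trees and image volumes.

A cCTA study reconstructed at several cardiac phases yields, per phase, a 3D
intensity volume and a centerline tree of the segmented coronary arteries
(already co-registered into a common frame).  This module holds the in-memory
containers for those objects plus file I/O (NIfTI / MetaImage for volumes, a
JSON polyline-tree format for centerlines) and the geometric utilities the
matching and quality stages build on: splitting trees at branching points and
uniform arc-length resampling of centerlines.

All coordinates are continuous, 0-based index-space positions (voxel units).
Distances quoted "in voxels" throughout the package are Euclidean distances in
this index space; physical-space (mm) evaluation is available where noted via
the volume spacing.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import nibabel as nib
import numpy as np
import SimpleITK as sitk

__all__ = [
    "Volume",
    "CenterlinePoint",
    "Branch",
    "BranchingPoint",
    "CoronaryTree",
    "PhaseSet",
    "VolumeFormatError",
    "TreeSchemaError",
    "load_volume",
    "save_volume",
    "load_tree",
    "save_tree",
    "split_tree_at_points",
    "resample_branch",
    "branch_from_arrays",
    "polyline_length",
]


class VolumeFormatError(ValueError):
    """Raised when a volume file is missing, unreadable, or not a 3D scalar grid."""


class TreeSchemaError(ValueError):
    """Raised when a tree JSON file violates the schema; names the offending field."""

    def __init__(self, field_name: str, message: str):
        self.field_name = field_name
        super().__init__(f"{field_name}: {message}")


@dataclass
class Volume:
    """A 3D scalar image on a regular grid.

    ``data`` is indexed ``[i, j, k]``; ``spacing`` gives the physical voxel
    size per axis in mm and ``origin`` the physical position of index
    (0, 0, 0).  Intensities are CT-like (arbitrary HU-scale units).
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise VolumeFormatError(f"volume payload must be 3D, got {self.data.ndim}D")
        if min(self.data.shape) < 1:
            raise VolumeFormatError("all three dimensions must be >= 1")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise VolumeFormatError("spacing must be three positive components")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class CenterlinePoint:
    """A sampled point on a vessel centerline with its local lumen radius."""

    position: np.ndarray  # (3,) continuous index-space coordinate
    radius: float  # voxel units, > 0
    tangent: Optional[np.ndarray] = None  # unit vector when present

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError("position must be a 3-vector")
        self.radius = float(self.radius)
        if self.radius <= 0:
            raise ValueError("radius must be > 0")
        if self.tangent is not None:
            self.tangent = np.asarray(self.tangent, dtype=float)
            n = np.linalg.norm(self.tangent)
            if abs(n - 1.0) > 1e-6:
                raise ValueError("tangent must have unit norm")


@dataclass
class Branch:
    """An ordered centerline segment between branching points or endpoints."""

    id: str
    phase: str
    points: list[CenterlinePoint]
    endpoints_are_branching: tuple[bool, bool] = (False, False)

    def __post_init__(self):
        if len(self.points) < 2:
            raise ValueError(f"branch {self.id!r} needs >= 2 points")

    @property
    def positions(self) -> np.ndarray:
        return np.array([p.position for p in self.points])

    @property
    def radii(self) -> np.ndarray:
        return np.array([p.radius for p in self.points])

    @property
    def arc_length(self) -> float:
        return polyline_length(self.positions)

    @property
    def mean_radius(self) -> float:
        return float(np.mean(self.radii))


@dataclass
class BranchingPoint:
    """A bifurcation of the vessel tree, used to split centerlines into branches."""

    position: np.ndarray
    origin_phase: str = ""
    group_id: Optional[int] = None  # cross-phase correspondence id after consolidation

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError("position must be a 3-vector")


@dataclass
class CoronaryTree:
    """All centerline branches of one coronary tree (LCA or RCA) at one phase."""

    phase: str
    side: str = "LCA"
    branches: list[Branch] = field(default_factory=list)
    branching_points: list[BranchingPoint] = field(default_factory=list)

    def __post_init__(self):
        ids = [b.id for b in self.branches]
        if len(ids) != len(set(ids)):
            raise ValueError("branch ids must be unique within a tree")
        for b in self.branches:
            if b.phase != self.phase:
                raise ValueError(
                    f"branch {b.id!r} phase {b.phase!r} != tree phase {self.phase!r}"
                )

    def branch(self, branch_id: str) -> Branch:
        for b in self.branches:
            if b.id == branch_id:
                return b
        raise KeyError(branch_id)

    def all_positions(self) -> np.ndarray:
        """Concatenated centerline points of every branch, (N, 3)."""
        if not self.branches:
            return np.empty((0, 3))
        return np.vstack([b.positions for b in self.branches])


@dataclass
class PhaseSet:
    """The per-phase (volume, tree) inputs for one coronary side of one study.

    ``phases`` is an ordered list of (phase label, Volume or None, CoronaryTree)
    in the clinical listing order, e.g. 80%, 75%, 70%, 50%, 45%, 40%.  All
    trees are assumed co-registered into one index-space frame.
    """

    phases: list[tuple[str, Optional[Volume], CoronaryTree]]

    def __post_init__(self):
        labels = [p[0] for p in self.phases]
        if len(labels) != len(set(labels)):
            raise ValueError("phase labels must be unique")

    @property
    def labels(self) -> list[str]:
        return [p[0] for p in self.phases]

    def tree(self, label: str) -> CoronaryTree:
        for lab, _, tree in self.phases:
            if lab == label:
                return tree
        raise KeyError(label)

    def volume(self, label: str) -> Optional[Volume]:
        for lab, vol, _ in self.phases:
            if lab == label:
                return vol
        raise KeyError(label)


# ---------------------------------------------------------------------------
# construction helpers
# ---------------------------------------------------------------------------

def branch_from_arrays(
    branch_id: str,
    phase: str,
    positions: np.ndarray,
    radii: np.ndarray | float,
    endpoints_are_branching: tuple[bool, bool] = (False, False),
) -> Branch:
    """Build a Branch from an (N, 3) position array and scalar or (N,) radii."""
    positions = np.asarray(positions, dtype=float)
    radii = np.broadcast_to(np.asarray(radii, dtype=float), (len(positions),))
    points = [CenterlinePoint(p, r) for p, r in zip(positions, radii)]
    return Branch(branch_id, phase, points, endpoints_are_branching)


def polyline_length(positions: np.ndarray) -> float:
    """Total arc length of a polyline given as an (N, 3) array."""
    positions = np.asarray(positions, dtype=float)
    if len(positions) < 2:
        return 0.0
    return float(np.sum(np.linalg.norm(np.diff(positions, axis=0), axis=1)))


# ---------------------------------------------------------------------------
# volume I/O
# ---------------------------------------------------------------------------

_NIFTI_SUFFIXES = (".nii", ".nii.gz")
_META_SUFFIXES = (".mha", ".mhd")


def _has_suffix(path: Path, suffixes) -> bool:
    name = path.name.lower()
    return any(name.endswith(s) for s in suffixes)


def load_volume(path) -> Volume:
    """Read a 3D scalar volume from NIfTI (.nii/.nii.gz) or MetaImage (.mha/.mhd).

    Intensities are returned unmodified; spacing and origin come from the
    header.  Raises :class:`VolumeFormatError` for missing files, non-3D
    payloads, or unreadable headers.
    """
    path = Path(path)
    if not path.exists():
        raise VolumeFormatError(f"no such file: {path}")
    if _has_suffix(path, _NIFTI_SUFFIXES):
        try:
            img = nib.load(str(path))
        except Exception as exc:  # nibabel raises several header error types
            raise VolumeFormatError(f"unreadable NIfTI header: {exc}") from exc
        data = np.asanyarray(img.dataobj)
        if data.ndim != 3:
            raise VolumeFormatError(f"expected 3D payload, got {data.ndim}D")
        zooms = img.header.get_zooms()[:3]
        origin = tuple(float(x) for x in img.affine[:3, 3])
        return Volume(data, tuple(float(z) for z in zooms), origin)
    if _has_suffix(path, _META_SUFFIXES):
        try:
            img = sitk.ReadImage(str(path))
        except Exception as exc:
            raise VolumeFormatError(f"unreadable MetaImage: {exc}") from exc
        arr = sitk.GetArrayFromImage(img)
        if arr.ndim != 3:
            raise VolumeFormatError(f"expected 3D payload, got {arr.ndim}D")
        # SimpleITK arrays are (z, y, x); store as (x, y, z)
        data = np.transpose(arr, (2, 1, 0))
        return Volume(data, tuple(img.GetSpacing()), tuple(img.GetOrigin()))
    raise VolumeFormatError(f"unrecognized volume format: {path.name}")


def save_volume(vol: Volume, path) -> Path:
    """Write a Volume to NIfTI or MetaImage; round-trips through load_volume."""
    path = Path(path)
    if _has_suffix(path, _NIFTI_SUFFIXES):
        affine = np.diag(list(vol.spacing) + [1.0])
        affine[:3, 3] = vol.origin
        img = nib.Nifti1Image(vol.data, affine)
        img.header.set_zooms(vol.spacing)
        nib.save(img, str(path))
        return path
    if _has_suffix(path, _META_SUFFIXES):
        img = sitk.GetImageFromArray(np.ascontiguousarray(np.transpose(vol.data, (2, 1, 0))))
        img.SetSpacing(vol.spacing)
        img.SetOrigin(vol.origin)
        sitk.WriteImage(img, str(path))
        return path
    raise VolumeFormatError(f"unrecognized volume format: {path.name}")


# ---------------------------------------------------------------------------
# tree JSON I/O
# ---------------------------------------------------------------------------
# Schema: {"phase": str, "side": "LCA"|"RCA",
#          "branches": [{"id": str, "points": [{"xyz": [x,y,z], "radius": r}]}],
#          "branching_points": [{"xyz": [x,y,z], "origin_phase": str,
#                                "group_id": int|null}]}
# Coordinates are 0-based continuous index-space positions.


def tree_to_dict(tree: CoronaryTree) -> dict:
    return {
        "phase": tree.phase,
        "side": tree.side,
        "branches": [
            {
                "id": b.id,
                "endpoints_are_branching": list(b.endpoints_are_branching),
                "points": [
                    {"xyz": [float(x) for x in p.position], "radius": p.radius}
                    for p in b.points
                ],
            }
            for b in tree.branches
        ],
        "branching_points": [
            {
                "xyz": [float(x) for x in bp.position],
                "origin_phase": bp.origin_phase,
                "group_id": bp.group_id,
            }
            for bp in tree.branching_points
        ],
    }


def tree_from_dict(doc: dict) -> CoronaryTree:
    if not isinstance(doc, dict):
        raise TreeSchemaError("<root>", "document must be a JSON object")
    for key in ("phase", "branches"):
        if key not in doc:
            raise TreeSchemaError(key, "missing required field")
    phase = doc["phase"]
    if not isinstance(phase, str):
        raise TreeSchemaError("phase", "must be a string")
    side = doc.get("side", "LCA")
    branches = []
    for bi, bdoc in enumerate(doc["branches"]):
        bid = bdoc.get("id")
        if not isinstance(bid, str) or not bid:
            raise TreeSchemaError(f"branches[{bi}].id", "must be a non-empty string")
        pts_doc = bdoc.get("points")
        if not isinstance(pts_doc, list) or len(pts_doc) < 2:
            raise TreeSchemaError(f"branches[{bi}].points", "must list >= 2 points")
        points = []
        for pi, pdoc in enumerate(pts_doc):
            xyz = pdoc.get("xyz")
            if not isinstance(xyz, list) or len(xyz) != 3:
                raise TreeSchemaError(
                    f"branches[{bi}].points[{pi}].xyz", "must be a 3-element list"
                )
            radius = pdoc.get("radius")
            if not isinstance(radius, (int, float)) or radius <= 0:
                raise TreeSchemaError(
                    f"branches[{bi}].points[{pi}].radius", "must be a number > 0"
                )
            points.append(CenterlinePoint(np.array(xyz, dtype=float), float(radius)))
        eb = bdoc.get("endpoints_are_branching", [False, False])
        branches.append(Branch(bid, phase, points, (bool(eb[0]), bool(eb[1]))))
    bps = []
    for i, bpdoc in enumerate(doc.get("branching_points", [])):
        xyz = bpdoc.get("xyz")
        if not isinstance(xyz, list) or len(xyz) != 3:
            raise TreeSchemaError(f"branching_points[{i}].xyz", "must be a 3-element list")
        gid = bpdoc.get("group_id")
        bps.append(
            BranchingPoint(
                np.array(xyz, dtype=float),
                origin_phase=bpdoc.get("origin_phase", ""),
                group_id=None if gid is None else int(gid),
            )
        )
    return CoronaryTree(phase=phase, side=side, branches=branches, branching_points=bps)


def load_tree(path) -> CoronaryTree:
    path = Path(path)
    if not path.exists():
        raise TreeSchemaError("<file>", f"no such file: {path}")
    with open(path) as fh:
        doc = json.load(fh)
    return tree_from_dict(doc)


def save_tree(tree: CoronaryTree, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(tree_to_dict(tree), fh, indent=1)
    return path


# ---------------------------------------------------------------------------
# splitting and resampling
# ---------------------------------------------------------------------------

def split_tree_at_points(
    tree: CoronaryTree,
    points: Sequence[BranchingPoint],
    snap_tolerance: float = 2.0,
) -> CoronaryTree:
    """Split each centerline polyline at the given branching points.

    Each branching point is snapped to the nearest centerline vertex of the
    whole tree; a point farther than ``snap_tolerance`` voxels from every
    centerline is rejected.  The resulting branches are maximal runs between
    consecutive branching points / endpoints; adjacent branches share the
    split vertex, so the union of branch points equals the original point set.
    """
    if not tree.branches:
        return replace(tree, branching_points=list(points))

    # nearest vertex over all branches, for each candidate point
    split_at: dict[str, set[int]] = {b.id: set() for b in tree.branches}
    rejected = []
    for bp in points:
        best = (math.inf, None, None)  # distance, branch id, vertex index
        for b in tree.branches:
            d = np.linalg.norm(b.positions - bp.position, axis=1)
            k = int(np.argmin(d))
            if d[k] < best[0]:
                best = (float(d[k]), b.id, k)
        if best[0] > snap_tolerance:
            rejected.append((bp, best[0]))
            continue
        split_at[best[1]].add(best[2])
    if rejected:
        detail = "; ".join(
            f"point {tuple(np.round(bp.position, 2))} nearest centerline {d:.2f} voxels away"
            for bp, d in rejected
        )
        raise ValueError(f"branching points beyond snap tolerance {snap_tolerance}: {detail}")

    new_branches = []
    for b in tree.branches:
        interior = sorted(i for i in split_at[b.id] if 0 < i < len(b.points) - 1)
        if not interior:
            new_branches.append(b)
            continue
        bounds = [0] + interior + [len(b.points) - 1]
        for k in range(len(bounds) - 1):
            lo, hi = bounds[k], bounds[k + 1]
            seg = b.points[lo : hi + 1]
            start_branching = b.endpoints_are_branching[0] if k == 0 else True
            end_branching = (
                b.endpoints_are_branching[1] if k == len(bounds) - 2 else True
            )
            new_branches.append(
                Branch(
                    f"{b.id}.{k}",
                    b.phase,
                    list(seg),
                    (start_branching, end_branching),
                )
            )
    return CoronaryTree(
        phase=tree.phase,
        side=tree.side,
        branches=new_branches,
        branching_points=list(points),
    )


def resample_branch(branch: Branch, step: float = 1.0) -> Branch:
    """Resample a branch to uniform arc-length spacing ``step`` (voxels).

    Endpoints are preserved; the last interval may be shorter than ``step``.
    Radii are linearly interpolated along arc length.
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    pos = branch.positions
    seg = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        raise ValueError(f"branch {branch.id!r} has zero arc length")
    targets = np.arange(0.0, total, step)
    if total - targets[-1] > 1e-12:
        targets = np.concatenate([targets, [total]])
    else:
        targets[-1] = total
    new_pos = np.column_stack([np.interp(targets, s, pos[:, ax]) for ax in range(3)])
    new_rad = np.interp(targets, s, branch.radii)
    # pin endpoints exactly
    new_pos[0], new_pos[-1] = pos[0], pos[-1]
    pts = [CenterlinePoint(p, r) for p, r in zip(new_pos, new_rad)]
    return Branch(branch.id, branch.phase, pts, branch.endpoints_are_branching)
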