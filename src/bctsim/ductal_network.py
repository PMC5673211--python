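"""Random binary-branching lactiferous duct network.

Each lobe grows one tree rooted near the nipple.  A *branch* is a chain
of constant-radius cylinder segments (a redirected continuation keeps
the same branch and diameter); branching is strictly binary and obeys
milk-flow conservation: the cross-sectional areas of the two children
sum exactly to the mother's area.  Children leave the mother at acute
angles.  Segments that would cross into skin or air are re-angled, then
shortened, then the branch is terminated.  Leaf branches are flagged
terminal; their final cylinders later gate where glandular (lobular)
tissue may appear.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .phantom_boundary import (AnatomyParams, bounded_gaussian,
                               bounded_gaussian_mean_sd)
from .volume import AIR, SKIN, GLANDULAR, LabelVolume

__all__ = [
    "DuctParams",
    "DuctCylinder",
    "DuctBranch",
    "DuctTree",
    "branch_diameters",
    "draw_tree_count",
    "grow_network",
    "voxelize_ducts",
    "duct_mask",
    "trees_to_json",
    "trees_from_json",
]


@dataclass(frozen=True)
class DuctParams:
    """Geometry and growth parameters of the ductal network (mm/deg)."""

    major_duct_length: float = 1.0
    major_duct_radius: float = 2.0
    duct_length: float = 7.0
    duct_radius: float = 1.0
    polar_angle_deg: float = 30.0
    azimuthal_angle_deg: float = 60.0
    branch_prob: float = 0.4
    max_depth: int = 12
    #: sd of the angle/length draws as a fraction of their mean
    spread_frac: float = 1.0 / 3.0

    def __post_init__(self):
        if min(self.major_duct_length, self.major_duct_radius,
               self.duct_length, self.duct_radius) <= 0:
            raise ValueError("lengths and radii must be positive")
        if not (0 < self.polar_angle_deg < 90
                and 0 < self.azimuthal_angle_deg < 90):
            raise ValueError("mean branch angles must lie in (0, 90) deg")
        if not 0 <= self.branch_prob <= 1:
            raise ValueError("branch_prob must be a probability")


@dataclass
class DuctCylinder:
    """Geometric primitive: one constant-radius cylinder (mm)."""

    start: np.ndarray
    end: np.ndarray
    radius: float

    @property
    def direction(self) -> np.ndarray:
        d = np.asarray(self.end, float) - np.asarray(self.start, float)
        return d / np.linalg.norm(d)

    @property
    def length(self) -> float:
        return float(np.linalg.norm(np.asarray(self.end) - np.asarray(self.start)))


@dataclass
class DuctBranch:
    """A chain of same-radius cylinders between two branch points."""

    cylinders: list[DuctCylinder]
    parent: int = -1
    children: list[int] = field(default_factory=list)
    is_terminal: bool = False

    @property
    def radius(self) -> float:
        return self.cylinders[0].radius

    @property
    def area(self) -> float:
        return float(np.pi * self.radius ** 2)

    @property
    def end(self) -> np.ndarray:
        return self.cylinders[-1].end

    @property
    def end_direction(self) -> np.ndarray:
        return self.cylinders[-1].direction

    @property
    def terminal_cylinder(self) -> DuctCylinder:
        return self.cylinders[-1]


@dataclass
class DuctTree:
    """Rooted strictly-binary tree of branches (branch 0 = major duct)."""

    branches: list[DuctBranch]

    def leaves(self) -> list[int]:
        return [i for i, b in enumerate(self.branches) if not b.children]

    def terminal_cylinders(self) -> list[DuctCylinder]:
        return [b.terminal_cylinder for b in self.branches if b.is_terminal]

    def all_cylinders(self) -> list[DuctCylinder]:
        return [c for b in self.branches for c in b.cylinders]

    def leaf_area_below(self, index: int) -> float:
        b = self.branches[index]
        if not b.children:
            return b.area
        return sum(self.leaf_area_below(c) for c in b.children)


def branch_diameters(mother_area: float, f: float) -> tuple[float, float]:
    """Diameters of the two children of a flow-conserving split.

    Child cross-sections are ``f`` and ``1 - f`` times the mother area,
    so the areas sum to the mother's exactly.
    """
    if mother_area <= 0:
        raise ValueError("mother_area must be positive")
    if not 0 < f < 1:
        raise ValueError("area fraction must lie strictly inside (0, 1)")
    d1 = 2.0 * np.sqrt(mother_area * f / np.pi)
    d2 = 2.0 * np.sqrt(mother_area * (1.0 - f) / np.pi)
    return d1, d2


def draw_tree_count(params: AnatomyParams, rng: np.random.Generator) -> int:
    """Number of starting ducts (trees), truncated-Gaussian draw."""
    n = bounded_gaussian_mean_sd(params.n_ducts_mean, params.n_ducts_sd, rng)
    return max(1, int(round(n)))


# ---------------------------------------------------------------------------
# growth
# ---------------------------------------------------------------------------

def _orthonormal_frame(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.array([1.0, 0.0, 0.0])
    if abs(u @ a) > 0.9:
        a = np.array([0.0, 0.0, 1.0])
    v = np.cross(u, a)
    v /= np.linalg.norm(v)
    return v, np.cross(u, v)


def _tilt(u: np.ndarray, polar_deg: float, azim_deg: float) -> np.ndarray:
    """Rotate ``u`` by ``polar_deg`` toward azimuth ``azim_deg`` in the plane
    perpendicular to ``u``; acute to ``u`` whenever ``polar_deg`` < 90."""
    v, w = _orthonormal_frame(u)
    th, ph = np.deg2rad(polar_deg), np.deg2rad(azim_deg)
    d = np.cos(th) * u + np.sin(th) * (np.cos(ph) * v + np.sin(ph) * w)
    return d / np.linalg.norm(d)


def _find_nipple(support: LabelVolume) -> np.ndarray:
    """World position of the most anterior (max y) interior voxel."""
    interior = (support.data != AIR) & (support.data != SKIN)
    if not interior.any():
        interior = support.data != AIR
    if not interior.any():
        raise ValueError("support volume has no interior")
    iy = np.nonzero(interior.any(axis=(0, 2)))[0].max()
    ix, iz = np.argwhere(interior[:, iy, :]).mean(axis=0)
    return support.origin_mm + support.voxel_mm * np.array([ix, iy, iz])


def _inside_interior(support: LabelVolume, p: np.ndarray) -> bool:
    idx = np.round((p - support.origin_mm) / support.voxel_mm).astype(int)
    if np.any(idx < 0) or np.any(idx >= np.array(support.shape)):
        return False
    label = support.data[idx[0], idx[1], idx[2]]
    return label != AIR and label != SKIN


def _segment_ok(support: LabelVolume, p0: np.ndarray, p1: np.ndarray) -> bool:
    return all(_inside_interior(support, p0 + t * (p1 - p0))
               for t in (0.5, 1.0))


def _draw(mean: float, frac: float, rng: np.random.Generator) -> float:
    return bounded_gaussian_mean_sd(mean, mean * frac, rng)


def grow_network(n_lobes: int, params: DuctParams, support: LabelVolume,
                 rng: np.random.Generator,
                 skin_retries: int = 20) -> list[DuctTree]:
    """Grow one duct tree per lobe inside the support volume."""
    if n_lobes < 1:
        raise ValueError("need at least one lobe")
    nipple = _find_nipple(support)
    min_radius = support.voxel_mm / 2.0
    return [_grow_tree(params, support, nipple, min_radius, rng, skin_retries)
            for _ in range(n_lobes)]


def _grow_tree(params: DuctParams, support: LabelVolume, nipple: np.ndarray,
               min_radius: float, rng: np.random.Generator,
               skin_retries: int) -> DuctTree:
    u0 = _tilt(np.array([0.0, -1.0, 0.0]),
               _draw(params.polar_angle_deg / 2, params.spread_frac, rng),
               rng.uniform(0.0, 360.0))
    root = DuctBranch([DuctCylinder(nipple.copy(),
                                    nipple + params.major_duct_length * u0,
                                    params.major_duct_radius)])
    branches = [root]
    frontier = [(0, 1)]  # (branch index, depth in segments)
    while frontier:
        idx, depth = frontier.pop()
        branch = branches[idx]
        if depth >= params.max_depth:
            branch.is_terminal = True
            continue
        can_split = branch.radius / np.sqrt(2.0) >= min_radius
        if rng.random() < params.branch_prob and can_split:
            f = float(np.clip(bounded_gaussian(0.0, 1.0, rng), 0.2, 0.8))
            d1, d2 = branch_diameters(branch.area, f)
            polar = _draw(params.polar_angle_deg, params.spread_frac, rng)
            azim = rng.uniform(0.0, 360.0)
            c1 = _new_segment(branch.end, branch.end_direction, d1 / 2,
                              +polar, azim, params, support, rng, skin_retries)
            c2 = _new_segment(branch.end, branch.end_direction, d2 / 2,
                              -polar, azim, params, support, rng, skin_retries)
            if c1 is not None and c2 is not None:
                for cyl in (c1, c2):
                    branches.append(DuctBranch([cyl], parent=idx))
                    branch.children.append(len(branches) - 1)
                    frontier.append((len(branches) - 1, depth + 1))
                continue
            branch.is_terminal = True  # no admissible binary split
        else:
            polar = _draw(params.polar_angle_deg, params.spread_frac, rng)
            azim = rng.uniform(0.0, 360.0)
            cyl = _new_segment(branch.end, branch.end_direction,
                               branch.radius, polar, azim, params, support,
                               rng, skin_retries)
            if cyl is None:
                branch.is_terminal = True
            else:
                branch.cylinders.append(cyl)
                frontier.append((idx, depth + 1))
    for b in branches:
        if not b.children:
            b.is_terminal = True
    return DuctTree(branches)


def _new_segment(start: np.ndarray, u: np.ndarray, radius: float,
                 polar: float, azim: float, params: DuctParams,
                 support: LabelVolume, rng: np.random.Generator,
                 skin_retries: int) -> DuctCylinder | None:
    """One cylinder off direction ``u``; re-angle/shorten to avoid skin."""
    length = _draw(params.duct_length, params.spread_frac, rng)
    sign = 1.0 if polar >= 0 else -1.0
    for attempt in range(skin_retries + 1):
        d = _tilt(u, abs(polar), azim if sign > 0 else azim + 180.0)
        end = start + length * d
        if _segment_ok(support, start, end):
            return DuctCylinder(start.copy(), end, radius)
        if attempt == skin_retries - 1:
            length = max(length / 2.0, support.voxel_mm)
        polar = sign * _draw(params.polar_angle_deg, params.spread_frac, rng)
        azim = rng.uniform(0.0, 360.0)
    return None


# ---------------------------------------------------------------------------
# voxelization / serialization
# ---------------------------------------------------------------------------

def duct_mask(trees: list[DuctTree], volume: LabelVolume,
              terminal_only: bool = False) -> np.ndarray:
    """Boolean mask of voxels whose centers lie inside duct cylinders."""
    mask = np.zeros(volume.shape, dtype=bool)
    for tree in trees or []:
        cyls = (tree.terminal_cylinders() if terminal_only
                else tree.all_cylinders())
        for cyl in cyls:
            _mark_cylinder(mask, volume, cyl)
    return mask


def voxelize_ducts(trees: list[DuctTree], volume: LabelVolume) -> LabelVolume:
    """Label duct voxels glandular; skin and air are never overwritten."""
    out = volume.copy()
    mask = duct_mask(trees, out)
    paintable = (out.data != AIR) & (out.data != SKIN)
    out.data[mask & paintable] = GLANDULAR
    return out


def _mark_cylinder(mask: np.ndarray, vol: LabelVolume, cyl: DuctCylinder):
    vox, origin = vol.voxel_mm, vol.origin_mm
    r = max(cyl.radius, vox / 2.0)  # thin ducts still occupy axis voxels
    lo = np.floor((np.minimum(cyl.start, cyl.end) - r - origin) / vox).astype(int)
    hi = np.ceil((np.maximum(cyl.start, cyl.end) + r - origin) / vox).astype(int)
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi + 1, np.array(mask.shape))
    if np.any(lo >= hi):
        return
    axes = [origin[i] + vox * np.arange(lo[i], hi[i]) for i in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    p = np.stack([gx, gy, gz], axis=-1) - cyl.start
    axis = np.asarray(cyl.end, float) - cyl.start
    length = np.linalg.norm(axis)
    u = axis / length
    t = p @ u
    radial2 = (p ** 2).sum(axis=-1) - t ** 2
    inside = (t >= 0) & (t <= length) & (radial2 <= r ** 2)
    mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] |= inside


def trees_to_json(trees: list[DuctTree], path: str | Path) -> None:
    payload = [[{"cylinders": [{"start": c.start.tolist(),
                                "end": np.asarray(c.end).tolist(),
                                "radius": c.radius} for c in b.cylinders],
                 "parent": b.parent, "children": b.children,
                 "is_terminal": b.is_terminal}
                for b in t.branches] for t in trees]
    Path(path).write_text(json.dumps(payload))


def trees_from_json(path: str | Path) -> list[DuctTree]:
    payload = json.loads(Path(path).read_text())
    trees = []
    for tb in payload:
        branches = [DuctBranch(
            [DuctCylinder(np.array(c["start"]), np.array(c["end"]),
                          c["radius"]) for c in b["cylinders"]],
            b["parent"], list(b["children"]), b["is_terminal"])
            for b in tb]
        trees.append(DuctTree(branches))
    return trees
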