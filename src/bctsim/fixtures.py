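"""Deterministic validation objects (no RNG).

The main fixture is a water cylinder with aluminum and PTFE (Teflon)
rod inserts, axis perpendicular to the fan plane: dense inserts in a
soft host make beam-hardening streaks and cupping obvious in fan-beam
reconstructions while staying simple enough for analytic checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .physics_data import available_materials
from .volume import LabelVolume

__all__ = ["FixtureSpec", "make_cylinder_fixture", "make_uniform_cube",
           "cylinder_rois"]


def _default_inserts() -> list[tuple[str, tuple[float, float], float]]:
    return [("aluminum", (-12.0, 0.0), 5.0), ("ptfe", (12.0, 0.0), 5.0)]


@dataclass(frozen=True)
class FixtureSpec:
    """Cylinder-with-inserts validation phantom (mm units)."""

    shape: tuple[int, int, int] = (64, 64, 64)
    voxel_mm: float = 1.0
    host_material: str = "water"
    host_radius_mm: float = 25.0
    host_height_mm: float = 56.0
    #: (material, (x, z) center, radius)
    inserts: list[tuple[str, tuple[float, float], float]] = \
        field(default_factory=_default_inserts)

    def __post_init__(self):
        known = available_materials()
        for mat in [self.host_material] + [m for m, *_ in self.inserts]:
            if mat not in known:
                raise KeyError(f"unknown material {mat!r}")
        for mat, (cx, cz), r in self.inserts:
            if np.hypot(cx, cz) + r >= self.host_radius_mm:
                raise ValueError(f"{mat} insert not strictly inside the host")
        for i, (_, ci, ri) in enumerate(self.inserts):
            for _, cj, rj in self.inserts[i + 1:]:
                if np.hypot(ci[0] - cj[0], ci[1] - cj[1]) < ri + rj:
                    raise ValueError("inserts overlap")


def _centered_grid(spec: FixtureSpec):
    n = np.array(spec.shape)
    origin = -(n - 1) / 2.0 * spec.voxel_mm
    axes = [origin[i] + spec.voxel_mm * np.arange(n[i]) for i in range(3)]
    return origin, axes


def make_cylinder_fixture(spec: FixtureSpec | None = None) -> LabelVolume:
    """Voxelize the host cylinder (axis +y) and its rod inserts."""
    spec = spec or FixtureSpec()
    origin, (xs, ys, zs) = _centered_grid(spec)
    gx, gz = np.meshgrid(xs, zs, indexing="ij")
    in_y = np.abs(ys) <= spec.host_height_mm / 2.0
    host = (gx ** 2 + gz ** 2) <= spec.host_radius_mm ** 2

    data = np.zeros(spec.shape, dtype=np.uint8)
    data[:, in_y, :] |= host[:, None, :].astype(np.uint8)
    legend = {1: spec.host_material}
    for lab, (mat, (cx, cz), r) in enumerate(spec.inserts, start=2):
        disk = ((gx - cx) ** 2 + (gz - cz) ** 2) <= r ** 2
        data[:, in_y, :] = np.where(disk[:, None, :], lab,
                                    data[:, in_y, :])
        legend[lab] = mat
    return LabelVolume(data, spec.voxel_mm, origin, legend)


def make_uniform_cube(material: str = "water", n: int = 32,
                      voxel_mm: float = 1.0) -> LabelVolume:
    """Uniform single-material cube (for ray-tracing sanity checks)."""
    origin = -(n - 1) / 2.0 * voxel_mm * np.ones(3)
    return LabelVolume(np.ones((n, n, n), dtype=np.uint8), voxel_mm, origin,
                       {1: material})


def cylinder_rois(spec: FixtureSpec, grid_n: int,
                  fov_mm: float) -> dict[str, np.ndarray]:
    """Boolean ROIs on the reconstruction grid (indexed [ix, iz]).

    ``segment``: strip on the line between the two inserts (exclusive of
    both); ``host``: host-only reference regions away from the inserts
    and the inter-insert line.
    """
    if len(spec.inserts) != 2:
        raise ValueError("ROIs are defined for the two-insert fixture")
    px = (np.arange(grid_n) - (grid_n - 1) / 2) * (fov_mm / grid_n)
    gx, gz = np.meshgrid(px, px, indexing="ij")
    (_, c1, r1), (_, c2, r2) = spec.inserts
    c1, c2 = np.array(c1), np.array(c2)
    axis = c2 - c1
    gap = np.linalg.norm(axis)
    u = axis / gap
    t = ((gx - c1[0]) * u[0] + (gz - c1[1]) * u[1]) / gap
    perp = np.abs((gx - c1[0]) * -u[1] + (gz - c1[1]) * u[0])
    margin = 2.0
    segment = ((t > (r1 + margin) / gap) & (t < 1 - (r2 + margin) / gap)
               & (perp < 2.0))
    in_host = (gx ** 2 + gz ** 2) <= (0.8 * spec.host_radius_mm) ** 2
    near_i1 = ((gx - c1[0]) ** 2 + (gz - c1[1]) ** 2) <= (r1 + 4) ** 2
    near_i2 = ((gx - c2[0]) ** 2 + (gz - c2[1]) ** 2) <= (r2 + 4) ** 2
    host = in_host & ~near_i1 & ~near_i2 & (perp > 6.0)
    return {"segment": segment, "host": host}
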