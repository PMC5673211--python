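"""Randomized external breast surface, support volume and skin shell.

The pendant (uncompressed) breast outline is built from two randomized
2-D constructions: an axial outline (union of a few disks in the x-z
plane) and a sagittal profile (a polyline of straight segments whose
bending angles perform a bounded random walk, with the curvature sign
flipped near the chest wall).  The two are combined slice by slice: for
each axial slice along the breast axis the outline is isotropically
rescaled so that its maximal width equals the profile's local width.
A skin shell of fixed thickness is then added with a Euclidean distance
transform.

All random draws use :func:`bounded_gaussian`, a rejection-truncated
Gaussian with mean at the interval midpoint and standard deviation a
quarter of the interval length, so draws honour both the normality and
the stated bounds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume import ADIPOSE, SKIN, LabelVolume

logger = logging.getLogger(__name__)

__all__ = [
    "AnatomyParams",
    "AxialOutline",
    "SagittalProfile",
    "bounded_gaussian",
    "bounded_gaussian_mean_sd",
    "gen_axial_outline",
    "gen_sagittal_profile",
    "combine_to_volume",
    "add_skin",
    "generate_support",
]

MAX_RETRIES = 100


@dataclass(frozen=True)
class AnatomyParams:
    """Population distributions of the modelled breast components.

    Means/SDs are Gaussian parameters; draws are truncated to mean +/- 2 SD.
    Defaults are adult-female reference values (mm and counts).
    """

    ext_diameter_mean: float = 140.0
    ext_diameter_sd: float = 20.0
    ext_thickness_mean: float = 120.0
    ext_thickness_sd: float = 10.0
    skin_thickness: float = 5.0
    n_ducts_mean: float = 17.0
    n_ducts_sd: float = 3.0
    n_lobes_mean: float = 17.0
    n_lobes_sd: float = 3.0
    n_lobules_per_lobe_mean: float = 30.0
    n_lobules_per_lobe_sd: float = 10.0
    n_terminal_ducts_per_lobe_mean: float = 50.0
    n_terminal_ducts_per_lobe_sd: float = 50.0
    # the nominal single-circle diameter used for the axial outline; the
    # final slice mapping rescales the envelope to ext_diameter
    nominal_circle_diameter_mean: float = 90.0
    nominal_circle_diameter_sd: float = 20.0
    center_scatter_mm: float = 10.0

    def __post_init__(self):
        for name in ("ext_diameter_mean", "ext_thickness_mean",
                     "nominal_circle_diameter_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("ext_diameter_sd", "ext_thickness_sd", "skin_thickness"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.skin_thickness >= self.ext_diameter_mean / 2:
            raise ValueError("skin thicker than the breast radius")


def bounded_gaussian(lo: float, hi: float, rng: np.random.Generator,
                     size=None):
    """Gaussian draw constrained to ``[lo, hi]`` by rejection.

    Mean is the interval midpoint, standard deviation a quarter of the
    interval length; out-of-range draws are redrawn.
    """
    if lo >= hi:
        raise ValueError("lo must be < hi")
    mean, sd = (lo + hi) / 2.0, (hi - lo) / 4.0
    x = rng.normal(mean, sd, size=size)
    if size is None:
        while not lo <= x <= hi:
            x = rng.normal(mean, sd)
        return float(x)
    bad = (x < lo) | (x > hi)
    while np.any(bad):
        x[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (x < lo) | (x > hi)
    return x


def bounded_gaussian_mean_sd(mean: float, sd: float,
                             rng: np.random.Generator, size=None):
    """Truncated-Gaussian draw with given mean/sd, bounded to mean +/- 2 sd."""
    if sd == 0:
        return mean if size is None else np.full(size, float(mean))
    return bounded_gaussian(mean - 2 * sd, mean + 2 * sd, rng, size=size)


# ---------------------------------------------------------------------------
# Axial outline: union of disks in the x-z plane
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AxialOutline:
    """Closed 2-D region formed by a union of disks (mm units)."""

    centers: np.ndarray   # (n, 2) -> (x, z)
    diameters: np.ndarray  # (n,)

    def __post_init__(self):
        if not 1 <= len(self.diameters) <= 8:
            raise ValueError("number of circles must be in [1, 8]")

    @property
    def radii(self) -> np.ndarray:
        return self.diameters / 2.0

    def width(self) -> float:
        """Maximal caliper width of the union (exact for disks)."""
        c, r = self.centers, self.radii
        d = np.linalg.norm(c[:, None, :] - c[None, :, :], axis=-1)
        return float((d + r[:, None] + r[None, :]).max())

    def bbox_center(self) -> np.ndarray:
        lo = (self.centers - self.radii[:, None]).min(axis=0)
        hi = (self.centers + self.radii[:, None]).max(axis=0)
        return (lo + hi) / 2.0

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean membership for an (..., 2) array of (x, z) points."""
        p = np.asarray(points, dtype=float)
        d2 = ((p[..., None, :] - self.centers) ** 2).sum(axis=-1)
        return np.any(d2 <= self.radii ** 2, axis=-1)

    def is_connected(self) -> bool:
        n = len(self.diameters)
        d = np.linalg.norm(self.centers[:, None] - self.centers[None], axis=-1)
        adj = d <= (self.radii[:, None] + self.radii[None, :])
        seen, stack = {0}, [0]
        while stack:
            i = stack.pop()
            for j in np.nonzero(adj[i])[0]:
                if j not in seen:
                    seen.add(int(j))
                    stack.append(int(j))
        return len(seen) == n

    def area(self, resolution_mm: float = 0.25) -> float:
        """Union area by dense raster (used by tests and slice mapping checks)."""
        lo = (self.centers - self.radii[:, None]).min(axis=0) - resolution_mm
        hi = (self.centers + self.radii[:, None]).max(axis=0) + resolution_mm
        xs = np.arange(lo[0], hi[0], resolution_mm)
        zs = np.arange(lo[1], hi[1], resolution_mm)
        grid = np.stack(np.meshgrid(xs, zs, indexing="ij"), axis=-1)
        return float(self.contains(grid).sum() * resolution_mm ** 2)


def gen_axial_outline(params: AnatomyParams, n_circles: int | None = None,
                      rng: np.random.Generator | None = None) -> AxialOutline:
    """Draw a connected union of ``n_circles`` disks (default 3 or 4)."""
    rng = np.random.default_rng() if rng is None else rng
    if n_circles is None:
        n_circles = int(rng.integers(3, 5))
    if n_circles < 1:
        raise ValueError("n_circles must be >= 1")
    for _ in range(MAX_RETRIES):
        centers = bounded_gaussian(-1.0, 1.0, rng, size=(n_circles, 2)) \
            * params.center_scatter_mm
        diam = bounded_gaussian_mean_sd(params.nominal_circle_diameter_mean,
                                        params.nominal_circle_diameter_sd,
                                        rng, size=n_circles)
        outline = AxialOutline(centers, np.atleast_1d(diam))
        if outline.is_connected():
            return outline
    raise RuntimeError("could not draw a connected axial outline")


# ---------------------------------------------------------------------------
# Sagittal profile: bounded-random-walk polyline from the nipple
# ---------------------------------------------------------------------------

@dataclass
class SagittalProfile:
    """Breast silhouette in the sagittal plane.

    Vertices run from the nipple toward the chest wall; each row is
    (axial distance from the nipple, half-width) in mm.  ``top`` carries
    the chest-wall curvature inversion at one quarter of the total depth
    from the chest wall; ``bottom`` does not.
    """

    depth_mm: float
    seg_len_mm: float
    top_vertices: np.ndarray      # (n, 2)
    bottom_vertices: np.ndarray
    top_angles_deg: np.ndarray
    bottom_angles_deg: np.ndarray
    bend_index_top: int

    def half_widths(self, y_from_nipple: np.ndarray,
                    side: str = "top") -> np.ndarray:
        v = self.top_vertices if side == "top" else self.bottom_vertices
        return np.interp(y_from_nipple, v[:, 0], v[:, 1], left=0.0)

    def widths(self, y_from_nipple: np.ndarray) -> np.ndarray:
        return (self.half_widths(y_from_nipple, "top")
                + self.half_widths(y_from_nipple, "bottom"))


_THETA_MAX_DEG = 85.0  # keeps every segment advancing toward the chest wall


def _walk_curve(depth: float, seg: float, rng: np.random.Generator,
                invert_at_bend: bool):
    theta = 0.0
    y = w = 0.0
    verts = [(0.0, 0.0)]
    angles = [theta]
    bend_index = -1
    for n in range(10000):
        past_bend = invert_at_bend and y >= 0.75 * depth
        if past_bend and bend_index < 0:
            bend_index = n
        dtheta = bounded_gaussian(0.0, 1.0, rng) * 10.0
        theta = theta - dtheta if past_bend else theta + dtheta
        theta = min(max(theta, -_THETA_MAX_DEG), _THETA_MAX_DEG)
        y += seg * np.cos(np.deg2rad(theta))
        w += seg * np.sin(np.deg2rad(theta))
        if w < 0:
            return None  # profile crossed the axis: self-intersection
        verts.append((y, w))
        angles.append(theta)
        if y >= depth:
            break
    if bend_index < 0:
        bend_index = len(verts) - 1
    return np.array(verts), np.array(angles), bend_index


def gen_sagittal_profile(params: AnatomyParams,
                         rng: np.random.Generator | None = None,
                         n_segments: int = 12) -> SagittalProfile:
    """Draw the sagittal silhouette with a truncated-Gaussian total depth.

    The polyline uses a fixed number of segments (length = depth /
    ``n_segments``), so profiles are statistically self-similar across
    breast sizes and voxel pitches.
    """
    rng = np.random.default_rng() if rng is None else rng
    depth = bounded_gaussian_mean_sd(params.ext_thickness_mean,
                                     params.ext_thickness_sd, rng)
    seg_len_mm = depth / n_segments
    for attempt in range(MAX_RETRIES):
        top = _walk_curve(depth, seg_len_mm, rng, invert_at_bend=True)
        bottom = _walk_curve(depth, seg_len_mm, rng, invert_at_bend=False)
        if top is not None and bottom is not None:
            tv, ta, bend = top
            bv, ba, _ = bottom
            return SagittalProfile(depth, seg_len_mm, tv, bv, ta, ba, bend)
        logger.warning("self-intersecting sagittal profile, redrawing "
                       "(attempt %d)", attempt + 1)
    raise RuntimeError("could not draw a non-self-intersecting profile")


# ---------------------------------------------------------------------------
# Slice-by-slice combination and skin shell
# ---------------------------------------------------------------------------

def combine_to_volume(axial: AxialOutline, sagittal: SagittalProfile,
                      voxel_mm: float,
                      shape: tuple[int, int, int] | None = None,
                      envelope_diameter_mm: float | None = None,
                      margin_voxels: int = 2) -> LabelVolume:
    """Map the two 2-D constructions into a binary support volume.

    For each axial (x-z) slice the outline is isotropically rescaled so
    its maximal width equals the profile's local width, and recentered on
    the profile midline.  If ``envelope_diameter_mm`` is given, profile
    widths are first rescaled so the widest slice matches it.  The nipple
    is anchored near the +y face; if the drawn depth exceeds the grid the
    breast is cropped on the chest-wall side (an air margin is kept so
    the skin shell closes).
    """
    if voxel_mm <= 0:
        raise ValueError("voxel size must be positive")
    if shape is None:
        wmax = envelope_diameter_mm or 1.2 * axial.width()
        nxz = int(np.ceil(wmax / voxel_mm)) + 2 * margin_voxels + 1
        ny = int(np.ceil(sagittal.depth_mm / voxel_mm)) + 2 * margin_voxels + 1
        shape = (nxz, ny, nxz)
    nx, ny, nz = shape

    iy_nip = ny - 1 - margin_voxels
    ys = np.arange(ny) * voxel_mm
    y_from_nipple = (iy_nip - np.arange(ny)) * voxel_mm

    w_top = sagittal.half_widths(y_from_nipple, "top")
    w_bot = sagittal.half_widths(y_from_nipple, "bottom")
    valid = ((y_from_nipple > 0) & (y_from_nipple <= sagittal.depth_mm)
             & (np.arange(ny) >= margin_voxels))
    widths = np.where(valid, w_top + w_bot, 0.0)
    if envelope_diameter_mm is not None and widths.max() > 0:
        scale_env = envelope_diameter_mm / widths.max()
        w_top, w_bot, widths = (a * scale_env for a in (w_top, w_bot, widths))

    outline_w = axial.width()
    outline_c = axial.bbox_center()
    data = np.zeros(shape, dtype=np.uint8)
    xs = (np.arange(nx) - (nx - 1) / 2.0) * voxel_mm
    zs = (np.arange(nz) - (nz - 1) / 2.0) * voxel_mm
    gx, gz = np.meshgrid(xs, zs, indexing="ij")
    for iy in range(ny):
        if not valid[iy] or widths[iy] < voxel_mm:
            continue  # degenerate (sub-voxel) slices are skipped
        s = widths[iy] / outline_w
        c_off = (w_top[iy] - w_bot[iy]) / 2.0
        q = np.stack([gx / s + outline_c[0],
                      (gz - c_off) / s + outline_c[1]], axis=-1)
        data[:, iy, :][axial.contains(q)] = ADIPOSE

    origin = np.array([xs[0], 0.0, zs[0]])
    return LabelVolume(data, voxel_mm, origin)


def add_skin(volume: LabelVolume, thickness_mm: float) -> LabelVolume:
    """Relabel interior voxels within ``thickness_mm`` of air as skin.

    Distances are Euclidean (distance transform of the support), so the
    skin forms a closed shell of uniform physical thickness.
    """
    if thickness_mm < volume.voxel_mm:
        raise ValueError("skin thinner than one voxel")
    support = volume.data > 0
    dist = ndimage.distance_transform_edt(support, sampling=volume.voxel_mm)
    skin = support & (dist <= thickness_mm)
    if not np.any(support & ~skin):
        raise ValueError("skin thickness consumes the whole breast")
    out = volume.copy()
    out.data[skin] = SKIN
    return out


def generate_support(params: AnatomyParams, rng: np.random.Generator,
                     voxel_mm: float,
                     shape: tuple[int, int, int] | None = None) -> LabelVolume:
    """Full boundary stage: outline + profile + slice mapping + skin."""
    outline = gen_axial_outline(params, rng=rng)
    profile = gen_sagittal_profile(params, rng=rng)
    envelope = bounded_gaussian_mean_sd(params.ext_diameter_mean,
                                        params.ext_diameter_sd, rng)
    vol = combine_to_volume(outline, profile, voxel_mm, shape=shape,
                            envelope_diameter_mm=envelope)
    return add_skin(vol, params.skin_thickness)
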