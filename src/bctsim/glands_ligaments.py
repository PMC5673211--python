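"""Cooper's-ligament units, power-law glandular texture, phantom assembly.

Cooper's ligaments are modelled as thin membranes of hollow units, each
unit the union of a few randomized ellipsoids; units are placed until
the breast interior is tiled.  The sub-voxel lobular texture is a white
Gaussian noise field shaped in the Fourier domain by a rotationally
symmetric inverse power law ``W(f) = alpha / f**beta`` and binarized at
a threshold (the field mean by default).  Glandular tissue appears only
inside ligament units traversed by a terminal duct (AND of the unit
interior with the binary texture), which keeps the lobular distribution
anchored to the ductal tree as it is anatomically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .ductal_network import DuctTree, duct_mask
from .phantom_boundary import bounded_gaussian
from .volume import AIR, ADIPOSE, SKIN, GLANDULAR, LIGAMENT, LabelVolume

__all__ = [
    "LigamentUnit",
    "NoiseField",
    "gen_ligament_unit",
    "tile_ligaments",
    "gen_filtered_noise",
    "threshold_glandular",
    "assemble_phantom",
]

#: Mean ellipsoid parameters of a ligament unit; each is multiplied by an
#: independent truncated-Gaussian factor in (0, 2] when a unit is drawn.
CENTER_OFFSET_MEAN_MM = 5.0
ROTATION_MEAN_DEG = 360.0
SEMI_AXIS_MEAN_MM = 20.0
DEFAULT_N_ELLIPSOIDS = 5


@dataclass
class LigamentUnit:
    """Hollow membrane unit: union of randomized ellipsoids.

    Masks are stored on a crop of the phantom grid (``slices``); the
    membrane is the one-voxel boundary shell of the union and is always
    disjoint from the interior.
    """

    centers: np.ndarray      # (n, 3) mm
    semi_axes: np.ndarray    # (n, 3) mm
    rotations_deg: np.ndarray  # (n, 3)
    slices: tuple[slice, slice, slice]
    interior: np.ndarray     # bool, shape of the crop
    membrane: np.ndarray
    duct_passed: bool = False

    @property
    def interior_voxels(self) -> int:
        return int(self.interior.sum())


@dataclass
class NoiseField:
    """Power-law-filtered Gaussian field on the phantom grid."""

    field: np.ndarray
    voxel_mm: float
    alpha: float
    beta: float
    threshold: float | None = None


def _rotation_matrix(deg: np.ndarray) -> np.ndarray:
    ax, ay, az = np.deg2rad(deg)
    cx, sx, cy, sy, cz, sz = (np.cos(ax), np.sin(ax), np.cos(ay),
                              np.sin(ay), np.cos(az), np.sin(az))
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz @ ry @ rx


def gen_ligament_unit(anchor: np.ndarray, n_ellipsoids: int,
                      rng: np.random.Generator, volume: LabelVolume,
                      ) -> LigamentUnit:
    """Draw one hollow unit anchored at a world point (mm).

    Every ellipsoid parameter is its mean value times an independent
    ``rand(0, 2)`` truncated-Gaussian factor: per-coordinate center
    offsets up to 10 mm (random sign), semi-axes up to 40 mm, rotations
    reduced modulo 360 degrees.
    """
    if n_ellipsoids < 1:
        raise ValueError("need at least one ellipsoid")
    anchor = np.asarray(anchor, dtype=float)
    offs = (CENTER_OFFSET_MEAN_MM
            * bounded_gaussian(0.0, 2.0, rng, size=(n_ellipsoids, 3))
            * rng.choice([-1.0, 1.0], size=(n_ellipsoids, 3)))
    centers = anchor + offs
    semi = SEMI_AXIS_MEAN_MM * bounded_gaussian(0.0, 2.0, rng,
                                                size=(n_ellipsoids, 3))
    semi = np.maximum(semi, volume.voxel_mm)
    rot = np.mod(ROTATION_MEAN_DEG * bounded_gaussian(0.0, 2.0, rng,
                                                      size=(n_ellipsoids, 3)),
                 360.0)

    vox, origin = volume.voxel_mm, volume.origin_mm
    reach = semi.max(axis=1)
    lo_mm = (centers - reach[:, None]).min(axis=0)
    hi_mm = (centers + reach[:, None]).max(axis=0)
    lo = np.maximum(np.floor((lo_mm - origin) / vox).astype(int) - 1, 0)
    hi = np.minimum(np.ceil((hi_mm - origin) / vox).astype(int) + 2,
                    np.array(volume.shape))
    sl = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    axes = [origin[i] + vox * np.arange(lo[i], hi[i]) for i in range(3)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)

    inside = np.zeros(grid.shape[:3], dtype=bool)
    for c, s, r in zip(centers, semi, rot):
        local = (grid - c) @ _rotation_matrix(r)  # rotate into body frame
        inside |= ((local / s) ** 2).sum(axis=-1) <= 1.0
    eroded = ndimage.binary_erosion(inside)
    return LigamentUnit(centers, semi, rot, sl, eroded, inside & ~eroded)


def tile_ligaments(volume: LabelVolume, rng: np.random.Generator,
                   n_ellipsoids: int = DEFAULT_N_ELLIPSOIDS,
                   coverage: float = 0.99,
                   stall_limit: int = 50) -> list[LigamentUnit]:
    """Place units at uncovered interior points until coverage is reached.

    Membrane voxels are labelled as ligament on ``volume`` in place
    (never overwriting skin).  Returns the placed units; coverage is the
    fraction of non-skin interior voxels inside some unit's interior or
    membrane.
    """
    interior = (volume.data != AIR) & (volume.data != SKIN)
    n_interior = int(interior.sum())
    if n_interior == 0:
        raise ValueError("volume has no interior to tile")
    covered = np.zeros(volume.shape, dtype=bool)
    units: list[LigamentUnit] = []
    stall = 0
    while (covered & interior).sum() < coverage * n_interior:
        open_idx = np.argwhere(interior & ~covered)
        anchor_idx = open_idx[rng.integers(len(open_idx))]
        anchor = volume.origin_mm + volume.voxel_mm * anchor_idx
        unit = gen_ligament_unit(anchor, n_ellipsoids, rng, volume)
        before = int((covered & interior).sum())
        covered[unit.slices] |= unit.interior | unit.membrane
        gained = int((covered & interior).sum()) - before
        if gained == 0:
            stall += 1
            if stall >= stall_limit:
                raise RuntimeError(
                    f"ligament tiling stalled after {len(units)} units at "
                    f"{(covered & interior).sum() / n_interior:.1%} coverage")
            continue
        stall = 0
        units.append(unit)
        crop = volume.data[unit.slices]
        crop[unit.membrane & (crop == ADIPOSE)] = LIGAMENT
    return units


# ---------------------------------------------------------------------------
# power-law texture
# ---------------------------------------------------------------------------

def gen_filtered_noise(shape: tuple[int, int, int], voxel_mm: float,
                       alpha: float = 1.0, beta: float = 2.0,
                       rng: np.random.Generator | None = None) -> NoiseField:
    """White Gaussian noise shaped by ``alpha / f**beta`` in Fourier space.

    The radial frequency ``f`` is in cycles/mm on the unshifted FFT grid;
    the undefined DC gain is set to zero, so the output field has zero
    mean.  ``beta`` controls texture smoothness (higher = smoother).
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    rng = np.random.default_rng() if rng is None else rng
    white = rng.standard_normal(shape)
    freqs = [np.fft.fftfreq(n, d=voxel_mm) for n in shape]
    fr = np.sqrt(sum(f ** 2 for f in
                     np.meshgrid(*freqs, indexing="ij", sparse=True)))
    with np.errstate(divide="ignore"):
        filt = np.where(fr > 0, alpha / fr ** beta, 0.0)
    out = np.fft.ifftn(np.fft.fftn(white) * filt).real
    return NoiseField(out, voxel_mm, alpha, beta)


def threshold_glandular(noise: NoiseField,
                        threshold: float | None = None) -> np.ndarray:
    """Binarize the texture: 1 where the field >= threshold (glandular).

    The default threshold is the field mean; raising it lowers the
    glandular fraction (the breast-density control knob).
    """
    f = noise.field
    if np.ptp(f) == 0:
        raise ValueError("constant noise field cannot be thresholded")
    t = float(f.mean()) if threshold is None else float(threshold)
    noise.threshold = t
    return (f >= t).astype(np.uint8)


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def assemble_phantom(support: LabelVolume, trees: list[DuctTree],
                     units: list[LigamentUnit],
                     binary_gland: np.ndarray) -> LabelVolume:
    """Combine all components into the final labelled phantom.

    Ligament units traversed by a terminal duct are flagged and their
    interiors ANDed with the binary texture become glandular; all duct
    cylinders are glandular as well.  Label precedence is
    skin > ligament membrane > glandular > adipose, on top of air.
    """
    if binary_gland.shape != support.shape:
        raise ValueError("texture grid does not match the phantom grid")
    out = support.copy()
    terminal = duct_mask(trees, out, terminal_only=True)
    gland = np.zeros(out.shape, dtype=bool)
    for unit in units:
        unit.duct_passed = bool(np.any(terminal[unit.slices] & unit.interior))
        if unit.duct_passed:
            gland[unit.slices] |= unit.interior
    gland &= binary_gland.astype(bool)
    gland |= duct_mask(trees, out)
    # precedence: only adipose may become glandular
    out.data[gland & (out.data == ADIPOSE)] = GLANDULAR
    return out


def glandular_fraction(volume: LabelVolume) -> float:
    """Fraction of non-air voxels labelled glandular."""
    counts = volume.label_counts()
    non_air = sum(v for k, v in counts.items() if k != AIR)
    return counts[GLANDULAR] / non_air if non_air else 0.0
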