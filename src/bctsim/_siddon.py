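"""Numba kernels for exact ray-voxel intersection (Siddon traversal).

Two batch kernels share the same incremental traversal:

* :func:`trace_labels_batch` accumulates intersection length per label
  (the thickness-projection primitive);
* :func:`trace_mu_batch` accumulates ``mu * length`` for one energy bin
  (the conventional per-bin forward projection, kept as an independent
  route for cross-checking the thickness factorization).

Volumes are axis-aligned with isotropic spacing; ``origin`` is the world
position of the center of voxel (0, 0, 0).
"""

from __future__ import annotations

import numpy as np
from numba import njit

_EPS = 1e-12


@njit(cache=False)
def _ray_setup(n, o, vox, s, d):
    """Entry/exit parameters of a ray with a voxel slab along one axis.

    Returns (alpha_lo, alpha_hi, ok). ``o`` is the low plane coordinate.
    """
    if abs(d) > _EPS:
        a0 = (o - s) / d
        a1 = (o + n * vox - s) / d
        if a0 < a1:
            return a0, a1, True
        return a1, a0, True
    if o <= s <= o + n * vox:
        return -1e30, 1e30, True
    return 0.0, 0.0, False


@njit(cache=False)
def _trace_one_labels(labels, vox, ox, oy, oz, sx, sy, sz,
                      ex, ey, ez, out):
    nx, ny, nz = labels.shape
    dx, dy, dz = ex - sx, ey - sy, ez - sz
    length = np.sqrt(dx * dx + dy * dy + dz * dz)
    if length < _EPS:
        return
    # plane origins (voxel faces)
    px, py, pz = ox - vox / 2.0, oy - vox / 2.0, oz - vox / 2.0
    ax0, ax1, okx = _ray_setup(nx, px, vox, sx, dx)
    ay0, ay1, oky = _ray_setup(ny, py, vox, sy, dy)
    az0, az1, okz = _ray_setup(nz, pz, vox, sz, dz)
    if not (okx and oky and okz):
        return
    amin = max(max(ax0, ay0), max(az0, 0.0))
    amax = min(min(ax1, ay1), min(az1, 1.0))
    if amin >= amax:
        return
    # entry voxel
    mid = amin + 1e-10
    i = int((sx + mid * dx - px) / vox)
    j = int((sy + mid * dy - py) / vox)
    k = int((sz + mid * dz - pz) / vox)
    i = min(max(i, 0), nx - 1)
    j = min(max(j, 0), ny - 1)
    k = min(max(k, 0), nz - 1)
    # next-crossing parameters and parameter steps per axis
    if dx > _EPS:
        tx = (px + (i + 1) * vox - sx) / dx
        dtx = vox / dx
        si = 1
    elif dx < -_EPS:
        tx = (px + i * vox - sx) / dx
        dtx = -vox / dx
        si = -1
    else:
        tx, dtx, si = 1e30, 1e30, 0
    if dy > _EPS:
        ty = (py + (j + 1) * vox - sy) / dy
        dty = vox / dy
        sj = 1
    elif dy < -_EPS:
        ty = (py + j * vox - sy) / dy
        dty = -vox / dy
        sj = -1
    else:
        ty, dty, sj = 1e30, 1e30, 0
    if dz > _EPS:
        tz = (pz + (k + 1) * vox - sz) / dz
        dtz = vox / dz
        sk = 1
    elif dz < -_EPS:
        tz = (pz + k * vox - sz) / dz
        dtz = -vox / dz
        sk = -1
    else:
        tz, dtz, sk = 1e30, 1e30, 0

    ac = amin
    while ac < amax - _EPS:
        anext = tx
        if ty < anext:
            anext = ty
        if tz < anext:
            anext = tz
        if anext > amax:
            anext = amax
        seg = (anext - ac) * length
        if seg > 0.0:
            out[labels[i, j, k]] += seg
        ac = anext
        if tx <= anext + _EPS:
            i += si
            tx += dtx
        if ty <= anext + _EPS:
            j += sj
            ty += dty
        if tz <= anext + _EPS:
            k += sk
            tz += dtz
        if i < 0 or i >= nx or j < 0 or j >= ny or k < 0 or k >= nz:
            break


@njit(cache=False)
def trace_labels_batch(labels, vox, origin, srcs, ends, out):
    """Per-label intersection lengths for a batch of rays.

    ``out`` has shape (n_rays, n_labels) and is accumulated in place.
    """
    for r in range(srcs.shape[0]):
        _trace_one_labels(labels, vox, origin[0], origin[1], origin[2],
                          srcs[r, 0], srcs[r, 1], srcs[r, 2],
                          ends[r, 0], ends[r, 1], ends[r, 2], out[r])


@njit(cache=False)
def _trace_one_mu(labels, mu, vox, ox, oy, oz, sx, sy, sz, ex, ey, ez):
    """Accumulate mu*length voxel by voxel along one ray (one energy bin)."""
    nx, ny, nz = labels.shape
    dx, dy, dz = ex - sx, ey - sy, ez - sz
    length = np.sqrt(dx * dx + dy * dy + dz * dz)
    if length < _EPS:
        return 0.0
    px, py, pz = ox - vox / 2.0, oy - vox / 2.0, oz - vox / 2.0
    ax0, ax1, okx = _ray_setup(nx, px, vox, sx, dx)
    ay0, ay1, oky = _ray_setup(ny, py, vox, sy, dy)
    az0, az1, okz = _ray_setup(nz, pz, vox, sz, dz)
    if not (okx and oky and okz):
        return 0.0
    amin = max(max(ax0, ay0), max(az0, 0.0))
    amax = min(min(ax1, ay1), min(az1, 1.0))
    if amin >= amax:
        return 0.0
    mid = amin + 1e-10
    i = min(max(int((sx + mid * dx - px) / vox), 0), nx - 1)
    j = min(max(int((sy + mid * dy - py) / vox), 0), ny - 1)
    k = min(max(int((sz + mid * dz - pz) / vox), 0), nz - 1)
    if dx > _EPS:
        tx, dtx, si = (px + (i + 1) * vox - sx) / dx, vox / dx, 1
    elif dx < -_EPS:
        tx, dtx, si = (px + i * vox - sx) / dx, -vox / dx, -1
    else:
        tx, dtx, si = 1e30, 1e30, 0
    if dy > _EPS:
        ty, dty, sj = (py + (j + 1) * vox - sy) / dy, vox / dy, 1
    elif dy < -_EPS:
        ty, dty, sj = (py + j * vox - sy) / dy, -vox / dy, -1
    else:
        ty, dty, sj = 1e30, 1e30, 0
    if dz > _EPS:
        tz, dtz, sk = (pz + (k + 1) * vox - sz) / dz, vox / dz, 1
    elif dz < -_EPS:
        tz, dtz, sk = (pz + k * vox - sz) / dz, -vox / dz, -1
    else:
        tz, dtz, sk = 1e30, 1e30, 0
    ac = amin
    acc = 0.0
    while ac < amax - _EPS:
        anext = tx
        if ty < anext:
            anext = ty
        if tz < anext:
            anext = tz
        if anext > amax:
            anext = amax
        seg = (anext - ac) * length
        if seg > 0.0:
            acc += mu[labels[i, j, k]] * seg
        ac = anext
        if tx <= anext + _EPS:
            i += si
            tx += dtx
        if ty <= anext + _EPS:
            j += sj
            ty += dty
        if tz <= anext + _EPS:
            k += sk
            tz += dtz
        if i < 0 or i >= nx or j < 0 or j >= ny or k < 0 or k >= nz:
            break
    return acc


@njit(cache=False)
def trace_mu_batch(labels, mu_per_label, vox, origin, srcs, ends, out):
    """Line integrals of mu for one energy bin, re-traversing every ray."""
    for r in range(srcs.shape[0]):
        out[r] = _trace_one_mu(labels, mu_per_label, vox,
                               origin[0], origin[1], origin[2],
                               srcs[r, 0], srcs[r, 1], srcs[r, 2],
                               ends[r, 0], ends[r, 1], ends[r, 2])
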