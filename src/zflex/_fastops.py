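"""Numba kernels for the inner loops of estimation and reconstruction.

These fuse the trilinear warp gather with the rotated ray sum so one
objective evaluation touches each voxel once.  They are numerically
identical to the numpy paths they accelerate (same weights, same order-1
interpolation, zero outside the box).
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["warp_flat", "warp_flat_adjoint", "raysum", "rayscatter",
           "warp_project"]


@njit(cache=True, fastmath=True)
def warp_flat(ref_flat, inside_idx, sample_vox, box):
    """Gather-warp: vol = ref except vol[inside_idx[j]] = ref(sample_vox[j]).

    ``sample_vox`` holds fractional voxel coordinates; reads outside the
    box are 0.
    """
    vol = ref_flat.copy()
    n = inside_idx.shape[0]
    for j in range(n):
        x, y, z = sample_vox[j, 0], sample_vox[j, 1], sample_vox[j, 2]
        fx, fy, fz = int(np.floor(x)), int(np.floor(y)), int(np.floor(z))
        tx, ty, tz = x - fx, y - fy, z - fz
        acc = 0.0
        for dx in range(2):
            ix = fx + dx
            if ix < 0 or ix >= box:
                continue
            wx = tx if dx == 1 else 1.0 - tx
            for dy in range(2):
                iy = fy + dy
                if iy < 0 or iy >= box:
                    continue
                wy = ty if dy == 1 else 1.0 - ty
                for dz in range(2):
                    iz = fz + dz
                    if iz < 0 or iz >= box:
                        continue
                    wz = tz if dz == 1 else 1.0 - tz
                    acc += wx * wy * wz * ref_flat[(ix * box + iy) * box + iz]
        vol[inside_idx[j]] = acc
    return vol


@njit(cache=True, fastmath=True)
def warp_flat_adjoint(vol_flat, inside_idx, sample_vox, box):
    """Exact transpose of :func:`warp_flat`: scatter with the same weights.

    Voxels outside the unit ball pass through unchanged (the gather leaves
    them untouched, so its transpose does too).
    """
    out = vol_flat.copy()
    n = inside_idx.shape[0]
    for j in range(n):
        out[inside_idx[j]] = 0.0
    for j in range(n):
        v = vol_flat[inside_idx[j]]
        if v == 0.0:
            continue
        x, y, z = sample_vox[j, 0], sample_vox[j, 1], sample_vox[j, 2]
        fx, fy, fz = int(np.floor(x)), int(np.floor(y)), int(np.floor(z))
        tx, ty, tz = x - fx, y - fy, z - fz
        for dx in range(2):
            ix = fx + dx
            if ix < 0 or ix >= box:
                continue
            wx = tx if dx == 1 else 1.0 - tx
            for dy in range(2):
                iy = fy + dy
                if iy < 0 or iy >= box:
                    continue
                wy = ty if dy == 1 else 1.0 - ty
                for dz in range(2):
                    iz = fz + dz
                    if iz < 0 or iz >= box:
                        continue
                    wz = tz if dz == 1 else 1.0 - tz
                    out[(ix * box + iy) * box + iz] += wx * wy * wz * v
    return out


@njit(cache=True, fastmath=True)
def raysum(vol_flat, idx8, w8, box, voxel_size):
    """Sum precomputed 8-corner samples along the depth axis.

    idx8/w8 are laid out for sample points in (x, y, depth) C-order;
    returns the image flattened as x*box + y.
    """
    npix = box * box
    out = np.zeros(npix)
    n = idx8.shape[0]
    for i in range(n):
        s = 0.0
        for k in range(8):
            s += w8[i, k] * vol_flat[idx8[i, k]]
        out[i // box] += s
    for p in range(npix):
        out[p] *= voxel_size
    return out


@njit(cache=True, fastmath=True)
def rayscatter(img_flat, idx8, w8, box, voxel_size):
    """Exact transpose of :func:`raysum`."""
    vol = np.zeros(box * box * box)
    n = idx8.shape[0]
    for i in range(n):
        v = img_flat[i // box] * voxel_size
        for k in range(8):
            vol[idx8[i, k]] += w8[i, k] * v
    return vol


@njit(cache=True, fastmath=True)
def warp_project(ref_flat, inside_idx, sample_vox, idx8, w8, box, voxel_size):
    """Fused warp + ray sum used by the per-particle objective."""
    vol = warp_flat(ref_flat, inside_idx, sample_vox, box)
    return raysum(vol, idx8, w8, box, voxel_size)
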