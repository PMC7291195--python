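"""Voxel/pixel rasterization of skeletons.

Process segments are swept as conical frusta (no spherical end caps, so a
straight two-node segment rasterizes to a capped cylinder of the analytic
volume); soma nodes are stamped as spheres. The 2D silhouette sweeps a disc
of linearly interpolated radius along each projected segment.

Occupied voxels are accumulated sparsely (encoded integer indices), so
memory scales with the rendered cell volume rather than its bounding box.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .skeleton import CellSkeleton

_ENC = 2**20  # index encoding base; supports grids up to ~1e6 per axis
_OFF = 2**19


def _encode(idx: np.ndarray) -> np.ndarray:
    i = idx.astype(np.int64) + _OFF
    return (i[:, 0] * _ENC + i[:, 1]) * _ENC + i[:, 2]


def _decode(codes: np.ndarray) -> np.ndarray:
    c = codes.copy()
    iz = c % _ENC
    c //= _ENC
    iy = c % _ENC
    ix = c // _ENC
    return np.stack([ix, iy, iz], axis=1) - _OFF


def _frustum_voxel_indices(a, b, r0, r1, h):
    """Integer voxel indices whose centers lie inside the frustum a->b."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    rmax = max(r0, r1)
    lo = np.minimum(a, b) - rmax
    hi = np.maximum(a, b) + rmax
    i0 = np.floor(lo / h - 0.5).astype(np.int64)
    i1 = np.ceil(hi / h - 0.5).astype(np.int64)
    axes = [np.arange(i0[d], i1[d] + 1) for d in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    idx = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    centers = (idx + 0.5) * h
    v = centers - a
    ab = b - a
    L = np.linalg.norm(ab)
    if L < 1e-12:
        d = np.linalg.norm(v, axis=1)
        keep = d <= rmax
        return idx[keep]
    u = ab / L
    t = v @ u
    perp = np.linalg.norm(v - t[:, None] * u[None, :], axis=1)
    r_t = r0 + (r1 - r0) * np.clip(t / L, 0.0, 1.0)
    keep = (t >= 0.0) & (t <= L) & (perp <= r_t)
    return idx[keep]


def _sphere_voxel_indices(c, r, h):
    return _frustum_voxel_indices(c, c, r, r, h)


def occupied_voxels(skeleton: CellSkeleton, voxel_size: float) -> np.ndarray:
    """(n, 3) unique integer voxel indices occupied by the rendered cell.

    Voxel centers are at ``(i + 0.5) * voxel_size`` in each axis.
    """
    if voxel_size <= 0:
        raise ValueError("voxel_size must be positive")
    chunks = []
    xyz = skeleton.xyz
    rad = skeleton.radius
    for k in np.flatnonzero(skeleton.soma_mask):
        chunks.append(_sphere_voxel_indices(xyz[k], rad[k], voxel_size))
    soma = skeleton.soma_mask
    for pk, ck in skeleton.segments():
        r0 = rad[pk] if not soma[pk] else rad[ck]
        chunks.append(_frustum_voxel_indices(xyz[pk], xyz[ck], r0, rad[ck], voxel_size))
    chunks = [c for c in chunks if len(c)]
    if not chunks:
        return np.zeros((0, 3), dtype=np.int64)
    codes = np.unique(np.concatenate([_encode(c) for c in chunks]))
    return _decode(codes)


def _capsule_pixel_indices(a2, b2, r0, r1, h):
    """2D tapered capsule: disc of interpolated radius swept along a->b."""
    a2 = np.asarray(a2, float)
    b2 = np.asarray(b2, float)
    rmax = max(r0, r1)
    lo = np.minimum(a2, b2) - rmax
    hi = np.maximum(a2, b2) + rmax
    i0 = np.floor(lo / h - 0.5).astype(np.int64)
    i1 = np.ceil(hi / h - 0.5).astype(np.int64)
    gx, gy = np.meshgrid(
        np.arange(i0[0], i1[0] + 1), np.arange(i0[1], i1[1] + 1), indexing="ij"
    )
    idx = np.stack([gx.ravel(), gy.ravel()], axis=1)
    centers = (idx + 0.5) * h
    ab = b2 - a2
    L2 = ab @ ab
    if L2 < 1e-24:
        keep = np.linalg.norm(centers - a2, axis=1) <= rmax
        return idx[keep]
    t = np.clip((centers - a2) @ ab / L2, 0.0, 1.0)
    near = a2 + t[:, None] * ab[None, :]
    r_t = r0 + (r1 - r0) * t
    keep = np.linalg.norm(centers - near, axis=1) <= r_t
    return idx[keep]


def occupied_pixels(skeleton: CellSkeleton, pixel_size: float) -> np.ndarray:
    """(n, 2) unique pixel indices of the z-projection silhouette."""
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    chunks = []
    xy = skeleton.xyz[:, :2]
    rad = skeleton.radius
    soma = skeleton.soma_mask
    for k in np.flatnonzero(soma):
        chunks.append(_capsule_pixel_indices(xy[k], xy[k], rad[k], rad[k], pixel_size))
    for pk, ck in skeleton.segments():
        r0 = rad[pk] if not soma[pk] else rad[ck]
        chunks.append(_capsule_pixel_indices(xy[pk], xy[ck], r0, rad[ck], pixel_size))
    chunks = [c for c in chunks if len(c)]
    if not chunks:
        return np.zeros((0, 2), dtype=np.int64)
    allidx = np.concatenate(chunks)
    codes = np.unique((allidx[:, 0].astype(np.int64) + _OFF) * _ENC + allidx[:, 1] + _OFF)
    return np.stack([codes // _ENC - _OFF, codes % _ENC - _OFF], axis=1)


@dataclass
class RasterVolume:
    """Dense binary volume of a rendered cell, axis order (z, y, x)."""

    data: np.ndarray
    voxel_size: float
    origin: np.ndarray  # world coordinate of voxel index (0,0,0) corner

    @property
    def occupied_volume(self) -> float:
        return float(self.data.astype(bool).sum()) * self.voxel_size**3


def rasterize_skeleton(skeleton: CellSkeleton, voxel_size: float) -> RasterVolume:
    """Render a skeleton into a dense labelled volume (1 = cell, 0 = background).

    Warns when the voxel size exceeds the smallest node radius, since thin
    branches may then leave no occupied voxel.
    """
    if skeleton.radius.size and voxel_size > float(skeleton.radius.min()):
        warnings.warn(
            f"voxel_size {voxel_size} exceeds smallest radius "
            f"{skeleton.radius.min():.3g}; thin branches may vanish",
            stacklevel=2,
        )
    idx = occupied_voxels(skeleton, voxel_size)
    if len(idx) == 0:
        return RasterVolume(
            data=np.zeros((1, 1, 1), dtype=np.uint8),
            voxel_size=voxel_size,
            origin=np.zeros(3),
        )
    lo = idx.min(axis=0)
    shp = idx.max(axis=0) - lo + 1
    vol = np.zeros((shp[2], shp[1], shp[0]), dtype=np.uint8)  # z, y, x
    rel = idx - lo
    vol[rel[:, 2], rel[:, 1], rel[:, 0]] = 1
    return RasterVolume(data=vol, voxel_size=voxel_size, origin=lo * voxel_size)
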