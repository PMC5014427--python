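"""Rasterization of hyphal networks to calibrated voxel stacks.

A voxel is foreground iff its centre lies within one hyphal radius of any
segment polyline (Euclidean distance in µm, so the strong z anisotropy of
the imaging grid is handled naturally).  Grayscale mode emulates stained
confocal data: bright foreground with additive truncated-normal noise over
a low uniform background of residual dye.
"""

from __future__ import annotations

import logging

import numpy as np

from .network import GridSpec, HyphalNetwork, VoxelStack

__all__ = ["rasterize"]

log = logging.getLogger(__name__)

_FOREGROUND_LEVEL = 200
_BACKGROUND_LEVEL = 15


def _mark_segment(mask: np.ndarray, grid: GridSpec, a: np.ndarray, b: np.ndarray,
                  radius: float) -> None:
    cx, cy, cz = grid.centers(0), grid.centers(1), grid.centers(2)
    lo = np.minimum(a, b) - radius
    hi = np.maximum(a, b) + radius
    ix = slice(np.searchsorted(cx, lo[0]), np.searchsorted(cx, hi[0], side="right"))
    iy = slice(np.searchsorted(cy, lo[1]), np.searchsorted(cy, hi[1], side="right"))
    iz = slice(np.searchsorted(cz, lo[2]), np.searchsorted(cz, hi[2], side="right"))
    if ix.start >= ix.stop or iy.start >= iy.stop or iz.start >= iz.stop:
        return
    X, Y, Z = np.meshgrid(cx[ix], cy[iy], cz[iz], indexing="ij")
    P = np.stack([X, Y, Z], axis=-1)
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0:
        d = np.linalg.norm(P - a, axis=-1)
    else:
        t = np.clip(((P - a) @ ab) / denom, 0.0, 1.0)
        d = np.linalg.norm(P - (a + t[..., None] * ab), axis=-1)
    # mask layout is (z, y, x); meshgrid above is (x, y, z)
    mask[iz, iy, ix] |= np.transpose(d <= radius, (2, 1, 0))


def rasterize(
    network: HyphalNetwork,
    grid: GridSpec,
    diameter: float = 3.0,
    mode: str = "binary",
    noise_sd: float = 5.0,
    rng: np.random.Generator | int | None = None,
) -> VoxelStack:
    """Rasterize a network onto a grid; ``mode`` is "binary" or "grayscale".

    Geometry outside the grid is clipped with a logged warning.
    """
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    if mode not in ("binary", "grayscale"):
        raise ValueError(f"unknown mode {mode!r}")
    mask = np.zeros(grid.shape, dtype=bool)
    radius = diameter / 2.0
    lo = np.array([grid.origin.x, grid.origin.y, grid.origin.z])
    hi = lo + grid.spacing() * np.array([grid.nx, grid.ny, grid.nz])
    clipped = False
    for poly in network.iter_polylines():
        if np.any(poly < lo) or np.any(poly > hi):
            clipped = True
        for i in range(len(poly) - 1):
            _mark_segment(mask, grid, poly[i], poly[i + 1], radius)
    if clipped:
        log.warning("network extends beyond the grid; geometry clipped")
    if mode == "binary":
        return VoxelStack(grid, mask)
    gen = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    values = gen.integers(0, _BACKGROUND_LEVEL + 1, size=grid.shape).astype(float)
    noise = gen.normal(0.0, noise_sd, size=grid.shape)
    np.clip(noise, -3 * noise_sd, 3 * noise_sd, out=noise)
    values[mask] = _FOREGROUND_LEVEL + noise[mask]
    return VoxelStack(grid, np.clip(np.round(values), 0, 255).astype(np.uint8))
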