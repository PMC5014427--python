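"""Voxel biomass: MIP, triangle thresholding, regional partition and the
age-of-region alignment.

Biomass at one observation is the number of foreground voxels in the
binarized stack.  The colony is additionally partitioned into three
annular bands of equal radial gap; in each band four portions placed at
fixed compass bearings (whose total area scales with the band's
mid-radius) are counted and normalized by that band's count at the final
observation.  Translating the outer-band curves along the time axis until
they superimpose on the inner band yields each region's age offset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateHistogramError, MycomorphError
from .network import GridSpec, VoxelStack

__all__ = [
    "BiomassCurve",
    "RegionSpec",
    "AgeMap",
    "mip",
    "threshold_triangle",
    "voxel_biomass",
    "regional_biomass",
    "align_ages",
]

_AXES = {"z": 0, "y": 1, "x": 2, 0: 0, 1: 1, 2: 2}


@dataclass
class BiomassCurve:
    """Foreground-voxel counts over time, optionally normalized."""

    times_days: np.ndarray
    counts: np.ndarray
    scope: str = "colony"

    def __post_init__(self) -> None:
        self.times_days = np.asarray(self.times_days, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.times_days.shape != self.counts.shape:
            raise ValueError("times and counts must align")
        if np.any(self.counts < 0):
            raise ValueError("voxel counts must be nonnegative")

    def normalized(self) -> "BiomassCurve":
        """Counts divided by the final-observation total."""
        final = self.counts[-1]
        if final == 0:
            raise MycomorphError(f"{self.scope}: zero final count, cannot normalize")
        return BiomassCurve(self.times_days, self.counts / final, scope=self.scope)


@dataclass
class RegionSpec:
    """Three annular bands of equal radial gap with four portions each.

    Portions are angular sectors of half-width ``portion_half_deg`` centred
    at the given compass bearings; a sector of an equal-gap band has area
    proportional to the band's mid-radius, matching the requirement that
    the analyzed area scale with region radius.
    """

    center_xy: tuple[float, float] = (0.0, 0.0)
    outer_radius: float = 1500.0
    n_regions: int = 3
    bearings_deg: tuple[float, ...] = (45.0, 135.0, 225.0, 315.0)
    portion_half_deg: float = 15.0

    def __post_init__(self) -> None:
        if self.outer_radius <= 0 or self.n_regions < 1:
            raise ValueError("bad region geometry")

    @property
    def gap(self) -> float:
        return self.outer_radius / self.n_regions

    def region_names(self) -> list[str]:
        return [f"R{i + 1}" for i in range(self.n_regions)]

    def bounds(self, name: str) -> tuple[float, float]:
        i = int(name[1:]) - 1
        return i * self.gap, (i + 1) * self.gap

    def region_mask(self, grid: GridSpec, name: str, portions_only: bool = True) -> np.ndarray:
        """Boolean xy mask (ny, nx) of the region (or its four portions)."""
        r0, r1 = self.bounds(name)
        cx = grid.centers(0) - self.center_xy[0]
        cy = grid.centers(1) - self.center_xy[1]
        X, Y = np.meshgrid(cx, cy)  # (ny, nx)
        r = np.hypot(X, Y)
        in_band = (r >= r0) & (r < r1)
        if name == "R1":
            in_band |= r < r0  # innermost band includes the inoculum centre
        if not portions_only:
            return in_band
        ang = np.degrees(np.arctan2(Y, X)) % 360.0
        in_portion = np.zeros_like(in_band)
        for b in self.bearings_deg:
            diff = np.abs((ang - b + 180.0) % 360.0 - 180.0)
            in_portion |= diff <= self.portion_half_deg
        return in_band & in_portion


@dataclass
class AgeMap:
    """Per-region time-axis offset (days); age = observation day − offset."""

    offsets: dict[str, float]

    def age(self, region: str, day: float) -> float:
        return day - self.offsets[region]

    def to_dict(self) -> dict:
        return {"offsets_days": dict(self.offsets)}


# -- operations ------------------------------------------------------------


def mip(stack: VoxelStack | np.ndarray, axis: str | int = "z") -> np.ndarray:
    """Maximum-intensity projection along an axis of a (z, y, x) stack."""
    values = stack.values if isinstance(stack, VoxelStack) else np.asarray(stack)
    if values.size == 0:
        raise MycomorphError("empty stack")
    if axis not in _AXES:
        raise ValueError(f"invalid axis {axis!r}")
    return values.max(axis=_AXES[axis])


def threshold_triangle(values: VoxelStack | np.ndarray) -> tuple[np.ndarray, int]:
    """Triangle-method binarization of an 8-bit image or stack.

    Builds the 256-bin histogram, draws the chord from the histogram peak
    to the far end of the occupied range on the longer-tail side, and picks
    the gray level maximizing the perpendicular distance from the histogram
    to that chord.  Returns (mask of pixels strictly above the threshold,
    threshold).  A constant image has no threshold and is an error.
    """
    arr = values.values if isinstance(values, VoxelStack) else np.asarray(values)
    if arr.dtype == bool:
        raise ValueError("triangle threshold expects grayscale data")
    flat = np.clip(arr, 0, 255).astype(np.uint8).ravel()
    hist = np.bincount(flat, minlength=256).astype(float)
    occupied = np.nonzero(hist)[0]
    if occupied.size < 2:
        raise DegenerateHistogramError("degenerate histogram: single gray level")
    peak = int(hist.argmax())
    first, last = int(occupied[0]), int(occupied[-1])
    if last - peak >= peak - first:
        lo, hi = peak, last
        span = np.arange(lo + 1, hi + 1)
    else:
        lo, hi = first, peak
        span = np.arange(lo, hi)
    if span.size == 0:
        raise DegenerateHistogramError("degenerate histogram: no tail beside the peak")
    # perpendicular distance from (i, hist[i]) to the chord peak->(tail end, 0)
    x_p, y_p = float(peak), float(hist[peak])
    x_e = float(hi if lo == peak else lo)
    d = np.abs(y_p * (span - x_e) - (x_p - x_e) * hist[span])
    thresh = int(span[int(np.argmax(d))])
    return arr > thresh, thresh


def voxel_biomass(stacks: list[VoxelStack], times_days: list[float],
                  scope: str = "colony") -> BiomassCurve:
    """Count foreground voxels of binary stacks sharing one grid."""
    if len(stacks) != len(times_days):
        raise ValueError("one time per stack required")
    if not stacks:
        return BiomassCurve(np.array([]), np.array([]), scope=scope)
    grid = stacks[0].grid
    for s in stacks:
        if s.grid != grid:
            raise MycomorphError("stacks do not share a grid")
        if not s.is_binary:
            raise MycomorphError("voxel_biomass expects binary stacks")
    counts = [float(s.values.sum()) for s in stacks]
    return BiomassCurve(np.asarray(times_days, dtype=float), np.asarray(counts), scope=scope)


def regional_biomass(
    stacks: list[VoxelStack],
    times_days: list[float],
    spec: RegionSpec,
) -> dict[str, BiomassCurve]:
    """Per-region portion counts, normalized per region by its final count."""
    if not stacks:
        raise MycomorphError("no stacks")
    grid = stacks[0].grid
    if not all(s.is_binary for s in stacks):
        raise MycomorphError("regional_biomass expects binary stacks")
    curves: dict[str, BiomassCurve] = {}
    for name in spec.region_names():
        m2d = spec.region_mask(grid, name)  # (ny, nx)
        counts = []
        for s in stacks:
            if s.grid != grid:
                raise MycomorphError("stacks do not share a grid")
            counts.append(float((s.values & m2d[None, :, :]).sum()))
        raw = BiomassCurve(np.asarray(times_days, dtype=float), np.asarray(counts), scope=name)
        curves[name] = raw.normalized() if raw.counts[-1] > 0 else raw
    return curves


def align_ages(
    curves: dict[str, BiomassCurve],
    offsets_days: np.ndarray | list[float] | None = None,
    reference: str = "R1",
) -> AgeMap:
    """Least-squares integer-day alignment of regional curves to R1.

    For each outer region, the offset minimizing the mean squared
    difference to the reference curve over the overlapping support is
    selected (the region curve at time t is compared with the reference at
    t − offset, linearly interpolated).  Fewer than 3 overlapping points
    refuses the alignment.
    """
    if reference not in curves:
        raise MycomorphError(f"reference curve {reference!r} missing")
    if offsets_days is None:
        offsets_days = np.arange(0, 8)
    ref = curves[reference]
    offsets: dict[str, float] = {reference: 0.0}
    for name, curve in curves.items():
        if name == reference:
            continue
        best: tuple[float, float] | None = None
        for s in offsets_days:
            shifted = curve.times_days - s
            sel = (shifted >= ref.times_days[0]) & (shifted <= ref.times_days[-1])
            if sel.sum() < 3:
                continue
            ref_vals = np.interp(shifted[sel], ref.times_days, ref.counts)
            mse = float(np.mean((curve.counts[sel] - ref_vals) ** 2))
            if best is None or mse < best[0] - 1e-15:
                best = (mse, float(s))
        if best is None:
            raise MycomorphError(f"alignment refused for {name}: overlap shorter than 3 points")
        offsets[name] = best[1]
    return AgeMap(offsets)
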