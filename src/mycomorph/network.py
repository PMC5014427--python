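"""Domain model for hyphal colonies as rooted trees in calibrated 3D space.

Coordinates are continuous micrometres (µm) with a user-chosen origin
(conventionally the inoculum centroid); times are hours since inoculation.
A colony snapshot is a forest of rooted trees whose edges ("segments")
carry polyline geometry, so curved hyphae are represented faithfully.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Literal

import numpy as np

from .errors import DisjointTreesError, LineageError, NetworkIntegrityError

__all__ = [
    "Point3D",
    "GridSpec",
    "HyphalNode",
    "Segment",
    "HyphalNetwork",
    "ColonyTimeSeries",
    "VoxelStack",
    "polyline_length",
    "point_at_arc",
]

#: Default hyphal radius (µm) used when a file format carries no radius.
DEFAULT_RADIUS_UM = 1.5

Orientation = Literal["outgoing-branch", "mother-forward", "daughter-1", "daughter-2"]


@dataclass(frozen=True)
class Point3D:
    """A point in calibrated 3D space, micrometres per axis."""

    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        for v in (self.x, self.y, self.z):
            if not math.isfinite(v):
                raise ValueError(f"non-finite coordinate in {self!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass(frozen=True)
class GridSpec:
    """Calibrated voxel grid: spacing (µm), extent (voxels) and origin.

    Voxel indexing is 0-based and half-open; voxel ``(i, j, k)`` spans
    ``origin + [i*dx, (i+1)*dx) × [j*dy, (j+1)*dy) × [k*dz, (k+1)*dz)``
    with its centre at the midpoint.  Defaults follow the confocal
    calibration used throughout: 1.25 µm in-plane, 20 µm between slices.
    """

    dx: float = 1.25
    dy: float = 1.25
    dz: float = 20.0
    nx: int = 256
    ny: int = 256
    nz: int = 16
    origin: Point3D = field(default_factory=lambda: Point3D(0.0, 0.0, 0.0))

    def __post_init__(self) -> None:
        if min(self.dx, self.dy, self.dz) <= 0:
            raise ValueError("voxel spacings must be positive")
        if min(self.nx, self.ny, self.nz) <= 0:
            raise ValueError("grid extents must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        """Array shape in (z, y, x) order, matching multi-page TIFF layout."""
        return (self.nz, self.ny, self.nx)

    def spacing(self) -> np.ndarray:
        return np.array([self.dx, self.dy, self.dz], dtype=float)

    def centers(self, axis: int) -> np.ndarray:
        """Voxel-centre coordinates (µm) along ``axis`` (0=x, 1=y, 2=z)."""
        d = (self.dx, self.dy, self.dz)[axis]
        n = (self.nx, self.ny, self.nz)[axis]
        o = (self.origin.x, self.origin.y, self.origin.z)[axis]
        return o + d * (np.arange(n) + 0.5)


@dataclass
class HyphalNode:
    """A distinguished point of the tree: root, branch site, tip or checkpoint."""

    id: int
    position: np.ndarray  # (3,) µm
    birth: float = 0.0  # hours since inoculation
    parent: int | None = None

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"node {self.id}: bad position {self.position}")


@dataclass
class Segment:
    """A parent→child link carrying its polyline geometry.

    ``points`` has shape (k, 3), k ≥ 2; the first row is the parent node
    position and the last row the child node position.  ``length`` is the
    summed Euclidean length of the polyline.
    """

    parent: int
    child: int
    points: np.ndarray
    length: float = -1.0

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
            raise ValueError(f"segment {self.parent}->{self.child}: bad polyline shape")
        self.points = pts
        true_len = polyline_length(pts)
        if self.length < 0:
            self.length = true_len
        elif abs(self.length - true_len) > 1e-9:
            raise NetworkIntegrityError(
                f"segment {self.parent}->{self.child}: stored length {self.length} "
                f"differs from polyline length {true_len}"
            )


def polyline_length(points: np.ndarray) -> float:
    """Summed Euclidean length of a polyline, shape (k, 3)."""
    pts = np.asarray(points, dtype=float)
    if len(pts) < 2:
        return 0.0
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def point_at_arc(points: np.ndarray, s: float) -> np.ndarray:
    """Point at arc-length ``s`` from the start of a polyline (clamped to ends)."""
    pts = np.asarray(points, dtype=float)
    if s <= 0:
        return pts[0].copy()
    steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(steps)])
    if s >= cum[-1]:
        return pts[-1].copy()
    i = int(np.searchsorted(cum, s, side="right")) - 1
    if steps[i] == 0:
        return pts[i].copy()
    t = (s - cum[i]) / steps[i]
    return pts[i] + t * (pts[i + 1] - pts[i])


class HyphalNetwork:
    """A colony snapshot: forest of rooted hyphal trees with polyline edges.

    The forest property (no cycles, no orphans, at most one parent) is
    verified on construction and is a hard error when violated.
    """

    def __init__(
        self,
        nodes: Iterable[HyphalNode],
        segments: Iterable[Segment],
        time: float = 0.0,
        provenance: dict | None = None,
        validate: bool = True,
    ) -> None:
        self.nodes: dict[int, HyphalNode] = {}
        for n in nodes:
            if n.id in self.nodes:
                raise NetworkIntegrityError(f"duplicate node id {n.id}")
            self.nodes[n.id] = n
        self.segments: dict[int, Segment] = {}  # keyed by child id
        self._children: dict[int, list[int]] = {i: [] for i in self.nodes}
        for s in segments:
            if s.child in self.segments:
                raise NetworkIntegrityError(f"node {s.child} has two parents")
            self.segments[s.child] = s
            self._children.setdefault(s.parent, []).append(s.child)
        for ch in self._children.values():
            ch.sort()
        self.time = float(time)
        self.provenance = dict(provenance or {})
        if validate:
            self.validate()

    # -- structure ---------------------------------------------------------

    def validate(self) -> None:
        for cid, seg in self.segments.items():
            if seg.parent not in self.nodes:
                raise NetworkIntegrityError(f"segment {seg.parent}->{cid}: orphan parent")
            if cid not in self.nodes:
                raise NetworkIntegrityError(f"segment {seg.parent}->{cid}: orphan child")
            self.nodes[cid].parent = seg.parent
        # cycle check: every node must reach a root through parent links
        state: dict[int, int] = {}
        for nid in self.nodes:
            path = []
            cur: int | None = nid
            while cur is not None and state.get(cur, 0) == 0:
                state[cur] = 1
                path.append(cur)
                cur = self.parent_of(cur)
            if cur is not None and state[cur] == 1:
                raise NetworkIntegrityError(f"cycle through node {cur}")
            for p in path:
                state[p] = 2

    def parent_of(self, nid: int) -> int | None:
        seg = self.segments.get(nid)
        return None if seg is None else seg.parent

    def children_of(self, nid: int) -> list[int]:
        return self._children.get(nid, [])

    def roots(self) -> list[int]:
        return sorted(i for i in self.nodes if i not in self.segments)

    def kind_of(self, nid: int) -> str:
        """Node kind from topology: inoculum-root, tip, branch-site or internal."""
        if nid not in self.segments:
            return "inoculum-root"
        ndeg = len(self.children_of(nid))
        if ndeg == 0:
            return "tip"
        if ndeg >= 2:
            return "branch-site"
        return "internal"

    def tips(self) -> list[int]:
        """All and only childless nodes, excluding isolated roots."""
        return sorted(
            i
            for i in self.nodes
            if not self.children_of(i) and i in self.segments
        )

    def branch_sites(self) -> list[int]:
        """Nodes where at least one new branch originates (≥ 2 children).

        The inoculum root is never a branch site even when several initial
        hyphae radiate from it; projected crossings are not graph nodes at
        all, so they can never appear here.
        """
        return sorted(
            i for i in self.nodes if len(self.children_of(i)) >= 2 and i in self.segments
        )

    def total_length(self) -> float:
        return float(sum(s.length for s in self.segments.values()))

    # -- lineage geometry --------------------------------------------------

    def _ancestor_chain(self, nid: int) -> list[int]:
        chain = [nid]
        cur = nid
        while (p := self.parent_of(cur)) is not None:
            chain.append(p)
            cur = p
        return chain

    def path_length(self, a: int, b: int) -> float:
        """Path length (µm) between two nodes on one root-to-tip lineage.

        Symmetric in its arguments.  Raises :class:`LineageError` when the
        nodes are not ancestor/descendant of each other and
        :class:`DisjointTreesError` when they sit in different trees.
        """
        for n in (a, b):
            if n not in self.nodes:
                raise KeyError(f"unknown node id {n}")
        if a == b:
            return 0.0
        chain_a = self._ancestor_chain(a)
        chain_b = self._ancestor_chain(b)
        if chain_a[-1] != chain_b[-1]:
            raise DisjointTreesError(f"nodes {a} and {b} are in different trees")
        if b in chain_a:
            lo, hi = b, a
        elif a in chain_b:
            lo, hi = a, b
        else:
            raise LineageError(f"nodes {a} and {b} do not lie on one lineage")
        total = 0.0
        cur = hi
        while cur != lo:
            seg = self.segments[cur]
            total += seg.length
            cur = seg.parent
        return total

    def arm_polyline(self, nid: int, child: int, max_len: float) -> np.ndarray:
        """Polyline of the arm leaving ``nid`` through ``child``.

        Follows single-child chains until ``max_len`` µm is accumulated or
        the arm ends at a branch site or tip.
        """
        if child not in self.children_of(nid):
            raise LineageError(f"{child} is not a child of {nid}")
        pts = [self.segments[child].points]
        acc = self.segments[child].length
        cur = child
        while acc < max_len:
            ch = self.children_of(cur)
            if len(ch) != 1:
                break
            seg = self.segments[ch[0]]
            pts.append(seg.points[1:])
            acc += seg.length
            cur = ch[0]
        return np.vstack(pts)

    def incoming_polyline(self, nid: int, max_len: float) -> np.ndarray:
        """Polyline ending at ``nid``, extending ≥ ``max_len`` µm towards the
        root, in root→node order.  The walk never crosses a branch site: the
        approach direction of a daughter hypha is measured only along its own
        arm, not through its origin into the mother."""
        seg = self.segments.get(nid)
        if seg is None:
            raise LineageError(f"node {nid} has no incoming segment")
        chunks = [seg.points]
        acc = seg.length
        cur = seg.parent
        while acc < max_len and len(self.children_of(cur)) == 1:
            seg = self.segments.get(cur)
            if seg is None:
                break
            chunks.append(seg.points[:-1])
            acc += seg.length
            cur = seg.parent
        return np.vstack(chunks[::-1])

    def direction_at(self, nid: int, orientation: Orientation, window: float = 20.0) -> np.ndarray:
        """Unit secant direction of an arm at a node.

        The secant runs from the node to the point ``window`` µm along the
        requested arm (or the arm end if shorter).  ``mother-forward`` is the
        approach direction of the incoming hypha: the secant from the point
        ``window`` µm before the node to the node itself.
        """
        if window <= 0:
            raise ValueError("window must be positive")
        if orientation == "mother-forward":
            poly = self.incoming_polyline(nid, window)
            total = polyline_length(poly)
            start = point_at_arc(poly, max(total - window, 0.0))
            vec = self.nodes[nid].position - start
        elif orientation in ("daughter-1", "daughter-2"):
            ch = self.children_of(nid)
            idx = 0 if orientation == "daughter-1" else 1
            if len(ch) <= idx:
                raise LineageError(f"node {nid} has no {orientation}")
            poly = self.arm_polyline(nid, ch[idx], window)
            vec = point_at_arc(poly, window) - self.nodes[nid].position
        elif orientation == "outgoing-branch":
            ch = self.children_of(nid)
            if not ch:
                raise LineageError(f"node {nid} has no outgoing arm")
            if len(ch) == 1:
                poly = self.arm_polyline(nid, ch[0], window)
                vec = point_at_arc(poly, window) - self.nodes[nid].position
            else:
                fwd = self.direction_at(nid, "mother-forward", window)
                best, best_dev = None, -1.0
                for c in ch:
                    poly = self.arm_polyline(nid, c, window)
                    v = point_at_arc(poly, window) - self.nodes[nid].position
                    nv = np.linalg.norm(v)
                    if nv == 0:
                        continue
                    dev = float(np.arccos(np.clip(v @ fwd / nv, -1, 1)))
                    if dev > best_dev:
                        best, best_dev = v, dev
                if best is None:
                    raise LineageError(f"node {nid}: degenerate outgoing arms")
                vec = best
        else:
            raise ValueError(f"unknown orientation {orientation!r}")
        norm = float(np.linalg.norm(vec))
        if norm == 0:
            raise LineageError(f"node {nid}: zero-length arm for {orientation!r}")
        return vec / norm

    # -- misc --------------------------------------------------------------

    def __len__(self) -> int:
        return len(self.nodes)

    def iter_polylines(self) -> Iterator[np.ndarray]:
        for cid in sorted(self.segments):
            yield self.segments[cid].points


@dataclass
class ColonyTimeSeries:
    """Ordered colony snapshots with shared node identity (a node persists)."""

    snapshots: list[HyphalNetwork]

    def __post_init__(self) -> None:
        times = [s.time for s in self.snapshots]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise NetworkIntegrityError("snapshot times must be strictly increasing")
        prev_ids: set[int] = set()
        prev_len = -1.0
        for snap in self.snapshots:
            ids = set(snap.nodes)
            if not prev_ids <= ids:
                raise NetworkIntegrityError("node set must be nondecreasing over time")
            tot = snap.total_length()
            if tot < prev_len - 1e-6:
                raise NetworkIntegrityError("total hyphal length decreased over time")
            prev_ids, prev_len = ids, tot

    @property
    def times(self) -> list[float]:
        return [s.time for s in self.snapshots]

    def __iter__(self) -> Iterator[HyphalNetwork]:
        return iter(self.snapshots)

    def __len__(self) -> int:
        return len(self.snapshots)

    def __getitem__(self, i: int) -> HyphalNetwork:
        return self.snapshots[i]


@dataclass
class VoxelStack:
    """A calibrated scalar voxel array, grayscale (0–255) or binary.

    ``values`` is laid out (z, y, x) to match multi-page TIFF files.
    """

    grid: GridSpec
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"stack shape {self.values.shape} does not match grid {self.grid.shape}"
            )

    @property
    def is_binary(self) -> bool:
        return self.values.dtype == bool

    def foreground_count(self) -> int:
        if self.is_binary:
            return int(self.values.sum())
        return int(np.count_nonzero(self.values))
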