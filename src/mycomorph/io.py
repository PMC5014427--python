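"""Morphology and stack I/O: SWC dialect, JSON network dialect, multi-page TIFF.

SWC is used as the exchange format because hyphal trees are structurally
identical to neuron morphologies.  Type codes: 1 = inoculum root,
5 = branch site, 6 = tip, 0 = internal node, 7 = polyline (geometry-only)
vertex.  Units are µm; radius defaults to half the mean hyphal diameter
(1.5 µm) when unknown.

The JSON dialect (``mycomorph-network/1``) round-trips everything SWC
cannot: observation time, node birth times and provenance.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .errors import MorphologyParseError
from .network import (
    DEFAULT_RADIUS_UM,
    ColonyTimeSeries,
    GridSpec,
    HyphalNetwork,
    HyphalNode,
    Point3D,
    Segment,
    VoxelStack,
)

JSON_FORMAT = "mycomorph-network/1"

_CODE_ROOT, _CODE_INTERNAL, _CODE_BRANCH, _CODE_TIP, _CODE_GEOM = 1, 0, 5, 6, 7


def write_swc(network: HyphalNetwork, path: str | Path, radius: float = DEFAULT_RADIUS_UM) -> None:
    """Write a network as SWC; polyline vertices get type code 7."""
    lines = ["# mycomorph SWC dialect; codes 1=root 5=branch-site 6=tip 0=internal 7=polyline"]
    next_id = (max(network.nodes) if network.nodes else 0) + 1
    kind_code = {"inoculum-root": _CODE_ROOT, "branch-site": _CODE_BRANCH,
                 "tip": _CODE_TIP, "internal": _CODE_INTERNAL}

    def rec(sid: int, code: int, pos: np.ndarray, parent: int) -> None:
        lines.append(
            f"{sid} {code} {pos[0]:.9g} {pos[1]:.9g} {pos[2]:.9g} {radius:.9g} {parent}"
        )

    for root in network.roots():
        stack = [(root, -1)]
        while stack:
            nid, swc_parent = stack.pop()
            if swc_parent == -1:
                rec(nid, _CODE_ROOT, network.nodes[nid].position, -1)
            for child in reversed(network.children_of(nid)):
                seg = network.segments[child]
                prev = nid
                for p in seg.points[1:-1]:
                    rec(next_id, _CODE_GEOM, p, prev)
                    prev = next_id
                    next_id += 1
                rec(child, kind_code[network.kind_of(child)], seg.points[-1], prev)
                stack.append((child, nid))
    Path(path).write_text("\n".join(lines) + "\n")


def read_swc(path: str | Path) -> HyphalNetwork:
    """Read an SWC file into a :class:`HyphalNetwork`.

    Records with type code 7 are treated as polyline vertices and folded
    into segment geometry; all other records become nodes.  Orphan parents,
    duplicate ids and cycles raise :class:`MorphologyParseError` naming the
    offending record.
    """
    recs: dict[int, tuple[int, np.ndarray, int]] = {}
    order: list[int] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 7:
            raise MorphologyParseError(f"line {lineno}: expected 7 fields, got {len(parts)}")
        try:
            sid, code = int(parts[0]), int(parts[1])
            pos = np.array([float(parts[2]), float(parts[3]), float(parts[4])])
            parent = int(parts[6])
        except ValueError as exc:
            raise MorphologyParseError(f"line {lineno}: {exc}") from None
        if sid in recs:
            raise MorphologyParseError(f"line {lineno}: duplicate id {sid}")
        recs[sid] = (code, pos, parent)
        order.append(sid)
    if not recs:
        raise MorphologyParseError(f"{path}: no records")

    children: dict[int, list[int]] = {sid: [] for sid in recs}
    for sid in order:
        _, _, parent = recs[sid]
        if parent != -1:
            if parent not in recs:
                raise MorphologyParseError(f"record {sid}: orphan parent id {parent}")
            children[parent].append(sid)
    # cycle detection over raw records
    seen: dict[int, int] = {}
    for sid in order:
        chain = []
        cur = sid
        while cur != -1 and seen.get(cur, 0) == 0:
            seen[cur] = 1
            chain.append(cur)
            cur = recs[cur][2]
        if cur != -1 and seen[cur] == 1:
            raise MorphologyParseError(f"record {cur}: cycle detected")
        for c in chain:
            seen[c] = 2

    is_node = {sid: recs[sid][0] != _CODE_GEOM for sid in recs}
    nodes = [HyphalNode(sid, recs[sid][1]) for sid in order if is_node[sid]]
    segments: list[Segment] = []

    def nearest_node_ancestor(sid: int) -> tuple[int, list[np.ndarray]]:
        pts: list[np.ndarray] = []
        cur = recs[sid][2]
        while cur != -1 and not is_node[cur]:
            pts.append(recs[cur][1])
            cur = recs[cur][2]
        if cur == -1:
            raise MorphologyParseError(f"record {sid}: polyline chain reaches no node")
        return cur, pts[::-1]

    for sid in order:
        if not is_node[sid] or recs[sid][2] == -1:
            continue
        anc, mid = nearest_node_ancestor(sid)
        poly = np.vstack([recs[anc][1]] + mid + [recs[sid][1]])
        segments.append(Segment(anc, sid, poly))
    return HyphalNetwork(nodes, segments, provenance={"source": str(path)})


# -- JSON dialect ----------------------------------------------------------


def network_to_dict(network: HyphalNetwork) -> dict:
    return {
        "format": JSON_FORMAT,
        "time": network.time,
        "provenance": network.provenance,
        "nodes": [
            {
                "id": n.id,
                "position": [float(v) for v in n.position],
                "birth": n.birth,
            }
            for n in (network.nodes[i] for i in sorted(network.nodes))
        ],
        "segments": [
            {
                "parent": s.parent,
                "child": s.child,
                "points": [[float(v) for v in p] for p in s.points],
            }
            for s in (network.segments[c] for c in sorted(network.segments))
        ],
    }


def network_from_dict(data: dict) -> HyphalNetwork:
    if data.get("format") != JSON_FORMAT:
        raise MorphologyParseError(f"unsupported format tag {data.get('format')!r}")
    nodes = [
        HyphalNode(int(n["id"]), np.asarray(n["position"], dtype=float), birth=float(n.get("birth", 0.0)))
        for n in data["nodes"]
    ]
    segments = [
        Segment(int(s["parent"]), int(s["child"]), np.asarray(s["points"], dtype=float))
        for s in data["segments"]
    ]
    return HyphalNetwork(nodes, segments, time=float(data.get("time", 0.0)),
                         provenance=data.get("provenance", {}))


def write_network_json(network: HyphalNetwork, path: str | Path) -> None:
    Path(path).write_text(json.dumps(network_to_dict(network), indent=1, sort_keys=True))


def read_network_json(path: str | Path) -> HyphalNetwork:
    try:
        data = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise MorphologyParseError(f"{path}: invalid JSON ({exc})") from None
    if not data:
        raise MorphologyParseError(f"{path}: no records")
    return network_from_dict(data)


def read_morphology(path: str | Path) -> HyphalNetwork:
    """Dispatch on extension: ``.swc`` or ``.json``."""
    p = Path(path)
    if p.suffix.lower() == ".swc":
        return read_swc(p)
    if p.suffix.lower() == ".json":
        return read_network_json(p)
    raise MorphologyParseError(f"unknown morphology format: {p.suffix!r}")


def write_morphology(network: HyphalNetwork, path: str | Path) -> None:
    p = Path(path)
    if p.suffix.lower() == ".swc":
        write_swc(network, p)
    elif p.suffix.lower() == ".json":
        write_network_json(network, p)
    else:
        raise MorphologyParseError(f"unknown morphology format: {p.suffix!r}")


def write_series_json(series: ColonyTimeSeries, path: str | Path) -> None:
    payload = {"format": "mycomorph-series/1",
               "snapshots": [network_to_dict(s) for s in series]}
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_series_json(path: str | Path) -> ColonyTimeSeries:
    data = json.loads(Path(path).read_text())
    if data.get("format") != "mycomorph-series/1":
        raise MorphologyParseError(f"{path}: not a mycomorph series file")
    return ColonyTimeSeries([network_from_dict(d) for d in data["snapshots"]])


# -- TIFF stacks -----------------------------------------------------------


def write_stack(stack: VoxelStack, path: str | Path) -> None:
    """Write a voxel stack as a multi-page TIFF (one page per z slice)."""
    values = stack.values
    if values.dtype == bool:
        values = values.astype(np.uint8) * 255
    tifffile.imwrite(str(path), values.astype(np.uint8), photometric="minisblack",
                     metadata={"spacing_um": [stack.grid.dx, stack.grid.dy, stack.grid.dz]})


def read_stack(path: str | Path, grid: GridSpec | None = None) -> VoxelStack:
    values = tifffile.imread(str(path))
    if values.ndim == 2:
        values = values[None, ...]
    if grid is None:
        nz, ny, nx = values.shape
        grid = GridSpec(nx=nx, ny=ny, nz=nz, origin=Point3D(0, 0, 0))
    return VoxelStack(grid, values)
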