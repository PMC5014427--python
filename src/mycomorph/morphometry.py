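"""Branch-site morphometry: AB/LB classification, branch angles, branching
lengths, crossing exclusion and projection-error geometry.

Angles are measured in the 2D (xy) projection, in degrees, exactly as they
would be read off a projection image: an apical (AB) angle between the two
daughter arms, a lateral (LB) angle between the departing daughter and the
mother-forward direction.  Arm directions are window secants
(:meth:`HyphalNetwork.direction_at`).

The projection-error functions convert between projected and real
quantities given the out-of-plane elevation θ_z = arctan(Δz/Δl) of each
arm.  The angle correction is the spherical law of cosines written for
elevations — the self-consistent form of the printed correction formula.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .errors import LineageError, MycomorphError, UndefinedRatioError
from .network import HyphalNetwork, point_at_arc

__all__ = [
    "BranchRecord",
    "MorphometrySummary",
    "ProjectionErrorRecord",
    "CrossingRecord",
    "classify_branch_type",
    "branch_angle",
    "measure_branches",
    "branching_lengths",
    "lb_ab_ratio",
    "angle_projection_error",
    "length_projection_error",
    "crossing_filter",
]

log = logging.getLogger(__name__)

DEFAULT_WINDOW_UM = 20.0

#: A child deviating from mother-forward by less than this fraction of the
#: other child's deviation is treated as the continuation of the mother.
_CONTINUATION_RATIO = 0.5
_CONTINUATION_ABS_DEG = 10.0


@dataclass
class BranchRecord:
    """One measured branch site."""

    site_id: int
    position: np.ndarray
    kind: Literal["AB", "LB"]
    angle_deg: float
    region: str | None = None
    age_days: float | None = None


@dataclass
class MorphometrySummary:
    """Site counts, LB:AB ratio and the branching-length sample of a snapshot."""

    n_lbs: int
    n_abs: int
    n_unclassifiable: int
    lengths: np.ndarray

    @property
    def ratio(self) -> float:
        if self.n_abs == 0:
            raise UndefinedRatioError("no apical branch sites; N_lbs/N_abs undefined")
        return self.n_lbs / self.n_abs


@dataclass
class ProjectionErrorRecord:
    """Projection-error bookkeeping for one measured angle or length."""

    theta_p: float
    theta_z1: float
    theta_z2: float
    eps_theta: float
    l_p: float | None = None
    eps_l: float | None = None
    phi_l: float | None = None


@dataclass
class CrossingRecord:
    """A projected intersection of two hyphal segments."""

    seg_a: int
    seg_b: int
    xy: np.ndarray
    z_a: float
    z_b: float
    label: Literal["crossing", "co-planar contact"]

    @property
    def dz(self) -> float:
        return abs(self.z_a - self.z_b)


# -- classification and angles --------------------------------------------


def _child_deviations(network: HyphalNetwork, site: int, window: float):
    """(child id, deviation from mother-forward in degrees) per child, 3D."""
    fwd = network.direction_at(site, "mother-forward", window)
    out = []
    for c in network.children_of(site):
        poly = network.arm_polyline(site, c, window)
        v = point_at_arc(poly, window) - network.nodes[site].position
        nv = np.linalg.norm(v)
        if nv == 0:
            out.append((c, None))
            continue
        dev = math.degrees(math.acos(float(np.clip(v @ fwd / nv, -1.0, 1.0))))
        out.append((c, dev))
    return out


def classify_branch_type(
    network: HyphalNetwork,
    site: int,
    window: float = DEFAULT_WINDOW_UM,
) -> Literal["AB", "LB", "unclassifiable"]:
    """Classify a branch site as apical (AB) or lateral (LB).

    AB: the mother terminates at the site and two daughters begin there.
    LB: the mother continues through the site and one daughter departs.
    Both cases are degree-3 nodes in the tree encoding, so the continuation
    is recognized geometrically: a child is the mother's continuation when
    its deviation from the mother-forward direction is small compared with
    the other child's.  Degree > 3 or degenerate arms → "unclassifiable".
    """
    children = network.children_of(site)
    if len(children) != 2 or site not in network.segments:
        return "unclassifiable"
    try:
        devs = [d for _, d in _child_deviations(network, site, window)]
    except LineageError:
        return "unclassifiable"
    usable = [d for d in devs if d is not None]
    if not usable:
        return "unclassifiable"
    if len(usable) == 1:
        # one arm has not grown yet (a dormant daughter): the grown arm
        # decides — near-straight means it is the mother continuing (LB)
        return "LB" if usable[0] < 2 * _CONTINUATION_ABS_DEG else "AB"
    lo, hi = sorted(usable)
    if hi == 0:
        return "unclassifiable"
    if lo < _CONTINUATION_RATIO * hi or lo < _CONTINUATION_ABS_DEG:
        return "LB"
    return "AB"


def _projected_unit(network: HyphalNetwork, site: int, child: int, window: float) -> np.ndarray:
    poly = network.arm_polyline(site, child, window)
    v = (point_at_arc(poly, window) - network.nodes[site].position)[:2]
    n = np.linalg.norm(v)
    if n == 0:
        raise LineageError(f"site {site}: zero projected extent of arm through {child}")
    return v / n


def branch_angle(
    network: HyphalNetwork,
    site: int,
    window: float = DEFAULT_WINDOW_UM,
    kind: str | None = None,
) -> float:
    """Branch angle (degrees) at a site, measured in the xy projection.

    AB: angle between the two daughters' projected secants.  LB: angle
    between the departing daughter's projected secant and the projected
    mother-forward direction.  Degenerate arms raise :class:`LineageError`.
    """
    if kind is None:
        kind = classify_branch_type(network, site, window)
    if kind == "unclassifiable":
        raise MycomorphError(f"site {site} is unclassifiable")
    children = network.children_of(site)
    if kind == "AB":
        u1 = _projected_unit(network, site, children[0], window)
        u2 = _projected_unit(network, site, children[1], window)
        cosang = float(np.clip(u1 @ u2, -1.0, 1.0))
        return math.degrees(math.acos(cosang))
    # LB: the daughter is the child deviating more from mother-forward
    fwd3 = network.direction_at(site, "mother-forward", window)
    fwd = fwd3[:2]
    nf = np.linalg.norm(fwd)
    if nf == 0:
        raise LineageError(f"site {site}: mother-forward has zero projected extent")
    fwd = fwd / nf
    devs = []
    for c in children:
        u = _projected_unit(network, site, c, window)
        devs.append((math.degrees(math.acos(float(np.clip(u @ fwd, -1.0, 1.0)))), c, u))
    devs.sort()
    _, _, daughter_u = devs[-1]
    return math.degrees(math.acos(float(np.clip(daughter_u @ fwd, -1.0, 1.0))))


def measure_branches(
    network: HyphalNetwork,
    window: float = DEFAULT_WINDOW_UM,
    region_of=None,
) -> tuple[list[BranchRecord], MorphometrySummary]:
    """Classify and measure every branch site of a snapshot.

    Unclassifiable or degenerate sites are excluded with a logged warning.
    ``region_of`` optionally maps a site position to a region label.
    """
    records: list[BranchRecord] = []
    n_ab = n_lb = n_bad = 0
    for site in network.branch_sites():
        kind = classify_branch_type(network, site, window)
        if kind == "unclassifiable":
            n_bad += 1
            log.debug("site %d unclassifiable; excluded", site)
            continue
        if kind == "AB":
            n_ab += 1
        else:
            n_lb += 1
        try:
            theta = branch_angle(network, site, window, kind=kind)
        except (LineageError, MycomorphError):
            log.debug("site %d has a degenerate arm; angle not measured", site)
            continue
        pos = network.nodes[site].position
        records.append(BranchRecord(
            site_id=site, position=pos.copy(), kind=kind, angle_deg=theta,
            region=region_of(pos) if region_of else None))
    lengths = branching_lengths(network, window=window)
    summary = MorphometrySummary(n_lbs=n_lb, n_abs=n_ab, n_unclassifiable=n_bad,
                                 lengths=lengths)
    return records, summary


def branching_lengths(
    network: HyphalNetwork,
    window: float = DEFAULT_WINDOW_UM,
    include_origin_sites: bool = True,
) -> np.ndarray:
    """Path lengths (µm) between adjacent branch sites along each hypha.

    The tree is decomposed into hyphae: at a lateral site the hypha
    continues through its continuation child, at an apical site it ends and
    two daughter hyphae begin.  Spans from the colony root to a first site
    and from a last site to a tip never count; the span from a daughter
    hypha's origin (itself a branch site) to its first own site counts
    unless ``include_origin_sites`` is false.
    """
    lengths: list[float] = []
    site_kind = {s: classify_branch_type(network, s, window) for s in network.branch_sites()}

    # walk hyphae iteratively: (start node, first child, start-is-site)
    stack: list[tuple[int, int, bool]] = []
    for root in network.roots():
        for c in network.children_of(root):
            stack.append((root, c, False))
    while stack:
        start, child, start_is_site = stack.pop()
        arc = 0.0
        site_arcs: list[float] = [0.0] if (start_is_site and include_origin_sites) else []
        cur, nxt = start, child
        while True:
            arc += network.segments[nxt].length
            cur = nxt
            ch = network.children_of(cur)
            if not ch:
                break  # tip: trailing span discarded
            if len(ch) == 1:
                nxt = ch[0]
                continue
            kind = site_kind.get(cur, "unclassifiable")
            if kind == "AB":
                site_arcs.append(arc)
                for c in ch:
                    stack.append((cur, c, True))
                break
            if kind == "LB":
                site_arcs.append(arc)
                devs = _child_deviations(network, cur, window)
                usable = [(d, c) for c, d in devs if d is not None]
                cont = min(usable)[1]
                for c in ch:
                    if c != cont:
                        stack.append((cur, c, True))
                nxt = cont
                continue
            # unclassifiable: treat as hypha end, daughters start fresh
            for c in ch:
                stack.append((cur, c, False))
            break
        lengths.extend(np.diff(site_arcs))
    return np.asarray(sorted(lengths))


def lb_ab_ratio(records: Sequence[BranchRecord] | MorphometrySummary) -> float:
    """N_lbs / N_abs; an explicit error when there is no apical site."""
    if isinstance(records, MorphometrySummary):
        return records.ratio
    n_lb = sum(r.kind == "LB" for r in records)
    n_ab = sum(r.kind == "AB" for r in records)
    if n_ab == 0:
        raise UndefinedRatioError("no apical branch sites; N_lbs/N_abs undefined")
    return n_lb / n_ab


# -- projection-error geometry --------------------------------------------


def angle_projection_error(theta_p: float, theta_z1: float, theta_z2: float) -> float:
    """Angle error ε_θ = θ_r − θ_p (degrees) from the arms' elevations.

    θ_z1, θ_z2 are each arm's out-of-plane elevation arctan(Δz/Δl); θ_p is
    the projected angle.  The real angle follows from the spherical law of
    cosines: cos θ_r = cos θ_z1 · cos θ_z2 · cos θ_p + sin θ_z1 · sin θ_z2.
    Zero elevations give zero error.
    """
    if not 0.0 < theta_p < 180.0:
        raise ValueError("theta_p must be in (0, 180)")
    if abs(theta_z1) >= 90.0 or abs(theta_z2) >= 90.0:
        raise ValueError("elevations must satisfy |theta_z| < 90")
    tz1, tz2, tp = map(math.radians, (theta_z1, theta_z2, theta_p))
    c = math.cos(tz1) * math.cos(tz2) * math.cos(tp) + math.sin(tz1) * math.sin(tz2)
    if abs(c) > 1.0 + 1e-12:
        raise MycomorphError(f"arccos argument {c} out of range")
    theta_r = math.degrees(math.acos(max(-1.0, min(1.0, c))))
    return theta_r - theta_p


def length_projection_error(l_p: float, theta_z: float) -> tuple[float, float]:
    """Length error ε_l = (1/cos θ_z − 1)·l_p and coefficient φ_l = ε_l/l_p."""
    if l_p <= 0:
        raise ValueError("projected length must be positive")
    if abs(theta_z) >= 90.0:
        raise ValueError("elevation must satisfy |theta_z| < 90")
    phi = 1.0 / math.cos(math.radians(theta_z)) - 1.0
    return phi * l_p, phi


# -- crossings -------------------------------------------------------------


def _sub_segments(network: HyphalNetwork):
    """Elementary straight pieces as arrays: owners, endpoints P0/P1 (3D)."""
    owners, p0s, p1s = [], [], []
    for cid in sorted(network.segments):
        pts = network.segments[cid].points
        keep = np.linalg.norm(np.diff(pts[:, :2], axis=0), axis=1) > 0
        for i in np.nonzero(keep)[0]:
            owners.append(cid)
            p0s.append(pts[i])
            p1s.append(pts[i + 1])
    if not owners:
        return np.empty(0, int), np.empty((0, 3)), np.empty((0, 3))
    return np.asarray(owners), np.asarray(p0s), np.asarray(p1s)


def crossing_filter(
    network: HyphalNetwork,
    z_threshold: float = 3.0,
) -> list[CrossingRecord]:
    """Label projected intersections of distinct hyphae by their depth gap.

    An intersection is a "crossing" iff the two hyphae differ in z by more
    than ``z_threshold`` (default: one hyphal diameter) at the projected
    intersection point; otherwise it is a co-planar contact.  Segment pairs
    sharing a tree node (true branch points) are never intersections, so no
    branch site can ever be labelled a crossing.
    """
    owners, P0, P1 = _sub_segments(network)
    n = len(owners)
    parents = np.array([network.segments[c].parent for c in owners])
    records: list[CrossingRecord] = []
    eps = 1e-12
    for i in range(n - 1):
        cid_a = int(owners[i])
        pa, ca = parents[i], owners[i]
        sel = np.arange(i + 1, n)
        distinct = ((owners[sel] != ca) & (owners[sel] != pa)
                    & (parents[sel] != ca) & (parents[sel] != pa))
        sel = sel[distinct]
        if sel.size == 0:
            continue
        p0, p1 = P0[i], P1[i]
        r = p1[:2] - p0[:2]
        q0, q1 = P0[sel], P1[sel]
        s = q1[:, :2] - q0[:, :2]
        den = r[0] * s[:, 1] - r[1] * s[:, 0]
        ok = np.abs(den) > eps
        b = q0[:, :2] - p0[:2]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (b[:, 0] * s[:, 1] - b[:, 1] * s[:, 0]) / den
            u = (b[:, 0] * r[1] - b[:, 1] * r[0]) / den
        hit = ok & (t >= 0) & (t <= 1) & (u >= 0) & (u <= 1)
        for j, tj, uj in zip(sel[hit], t[hit], u[hit]):
            xy = p0[:2] + tj * r
            z_a = p0[2] + tj * (p1[2] - p0[2])
            z_b = P0[j][2] + uj * (P1[j][2] - P0[j][2])
            label = "crossing" if abs(z_a - z_b) > z_threshold else "co-planar contact"
            records.append(CrossingRecord(cid_a, int(owners[j]), xy,
                                          float(z_a), float(z_b), label))
    return records
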