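"""Stochastic mycelium growth simulator.

Generates seeded :class:`ColonyTimeSeries` whose logged statistics follow
configured laws: per-interval tip activity (Bernoulli, phase-dependent
``k_active``), tip extension rates drawn from a gamma-plus-baseline
mixture, apical/lateral branching with Gaussian branch angles, and
gamma-distributed inter-branch-site path lengths.

Branching is elongation-triggered: every hypha carries a distance-since-
last-site counter with a target drawn from the branching-length law, and a
branch event fires exactly when the counter reaches the target (events are
placed at the exact arc position, so measured inter-site lengths reproduce
the configured law by construction).  During the lag phase events fire with
probability ``k_lag`` only.  Apical events terminate the mother tip and
spawn two daughters deviating symmetrically by ±θ/2 in plane; lateral
events spawn one daughter at θ from the mother-forward direction while the
mother grows on.

At every emitted snapshot each growing tip node is frozen and a fresh tip
node continues the lineage, so node identity is shared across snapshots and
path lengths between a tip's old and new node equal its summed elongation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
import numpy as np

from .errors import ConfigError
from .fitting import GammaParams, GaussianParams, TipRateMixture, mixture_cdf
from .network import ColonyTimeSeries, HyphalNetwork, HyphalNode, Segment

__all__ = ["GrowthConfig", "GrowthEventLog", "grow",
           "BRANCH_LENGTH_LAWS_TABLE_AGES", "BRANCH_LENGTH_LAWS_FIGURE_AGES"]

#: Growth distance (µm) over which the in-plane direction noise sd applies.
_NOISE_REF_UM = 15.0

#: Branching-length laws keyed by hyphal age in days, as tabulated.
BRANCH_LENGTH_LAWS_TABLE_AGES: dict[int, GammaParams] = {
    5: GammaParams(1.32, 0.022),
    7: GammaParams(1.71, 0.039),
    9: GammaParams(1.52, 0.045),
}

#: Alternative age labelling used by the figure captions for the same fits.
BRANCH_LENGTH_LAWS_FIGURE_AGES: dict[int, GammaParams] = {
    8: GammaParams(1.32, 0.022),
    10: GammaParams(1.71, 0.039),
    12: GammaParams(1.52, 0.045),
}


@dataclass(frozen=True)
class GrowthConfig:
    """Parameters of the stochastic growth model.

    Defaults reproduce the fitted statistics of the reference dataset:
    3 µm hyphal diameter, k_active 0.72 (lag) / 0.70 (exponential), a
    gamma(1.51, 0.09) + linear-baseline tip-rate law, Gaussian branch
    angles N(77.6°, 12.3°), gamma branching lengths, LB:AB site ratio 4.5
    and lag-phase branching attenuation 1/5 over a 5-day lag.
    """

    seed: int
    diameter_um: float = 3.0
    k_active_lag: float = 0.72
    k_active_exp: float = 0.70
    tip_rate_law: TipRateMixture | GammaParams | GaussianParams = field(
        default_factory=TipRateMixture)
    branch_angle_law: GaussianParams = field(
        default_factory=lambda: GaussianParams(77.6, 12.3))
    branch_length_law: GammaParams = field(
        default_factory=lambda: GammaParams(1.32, 0.022))
    branch_length_laws_by_age: dict[int, GammaParams] | None = None
    lb_ab_ratio: float = 4.5
    k_lag: float = 0.2
    lag_hours: float = 120.0
    tilt_sd_deg: float = 5.0
    tilt_max_deg: float = 30.0
    direction_noise_sd_deg: float = 3.0
    dt_hours: float = 1.0
    duration_hours: float = 408.0
    snapshot_hours: tuple[float, ...] = (72, 96, 120, 168, 240, 288, 336, 408)
    resample_hours: float = 24.0
    n_initial_hyphae: int = 5
    branching_enabled: bool = True
    max_tips: int | None = 2500
    log_elongation: bool = True

    def __post_init__(self) -> None:
        if self.dt_hours <= 0:
            raise ConfigError("dt_hours must be positive")
        if self.duration_hours <= 0:
            raise ConfigError("duration_hours must be positive")
        if not self.snapshot_hours:
            raise ConfigError("at least one snapshot time is required")
        if min(self.snapshot_hours) <= 0:
            raise ConfigError("snapshot before time 0")
        if max(self.snapshot_hours) > self.duration_hours + 1e-9:
            raise ConfigError("snapshot after end of run")
        for t in self.snapshot_hours:
            if abs(t / self.dt_hours - round(t / self.dt_hours)) > 1e-9:
                raise ConfigError(f"snapshot time {t} is not a multiple of dt")
        r = self.resample_hours / self.dt_hours
        if abs(r - round(r)) > 1e-9 or r < 1:
            raise ConfigError("resample_hours must be a positive multiple of dt")
        for name in ("k_active_lag", "k_active_exp", "k_lag"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ConfigError(f"{name} must be in (0, 1]")
        if self.diameter_um <= 0:
            raise ConfigError("diameter_um must be positive")
        if self.lb_ab_ratio < 0:
            raise ConfigError("lb_ab_ratio must be nonnegative")
        if self.n_initial_hyphae < 1:
            raise ConfigError("need at least one initial hypha")


@dataclass
class GrowthEventLog:
    """Ground-truth record of every stochastic event of a run.

    ``elongations`` rows: (time, tip node id, length µm).
    ``branches`` rows: (time, type, site id, mother tip id, daughter ids,
    sampled angle deg, sampled target length µm).
    ``activity`` rows: (time, tip node id, active, sampled rate µm/h).
    ``suppressed`` rows: (time, tip node id) — lag-phase events that did not fire.
    ``target_draws`` rows: (time, tip node id, target µm) — every draw from the
    branching-length law, including targets never reached before the run ends
    (the fired subset alone is length-biased toward short draws).
    """

    seed: int
    elongations: list[tuple[float, int, float]] = field(default_factory=list)
    branches: list[tuple[float, str, int, int, tuple[int, ...], float, float]] = field(
        default_factory=list)
    activity: list[tuple[float, int, bool, float]] = field(default_factory=list)
    suppressed: list[tuple[float, int]] = field(default_factory=list)
    target_draws: list[tuple[float, int, float]] = field(default_factory=list)

    def drawn_targets(self) -> np.ndarray:
        return np.array([t for (_, _, t) in self.target_draws])

    def branch_count_between(self, t0: float, t1: float) -> int:
        return sum(1 for e in self.branches if t0 < e[0] <= t1)

    def branch_angles(self, kind: str | None = None) -> np.ndarray:
        return np.array([e[5] for e in self.branches if kind is None or e[1] == kind])

    def branch_targets(self) -> np.ndarray:
        return np.array([e[6] for e in self.branches])

    def sampled_rates(self, active_only: bool = True) -> np.ndarray:
        return np.array([r for (_, _, a, r) in self.activity if a or not active_only])

    def elongation_by_node(self, t0: float, t1: float) -> dict[int, float]:
        """Summed elongation per tip node id over the interval (t0, t1]."""
        out: dict[int, float] = {}
        for t, nid, d in self.elongations:
            if t0 < t <= t1:
                out[nid] = out.get(nid, 0.0) + d
        return out


@dataclass
class _Tip:
    node_id: int
    anchor_id: int
    pos: np.ndarray
    azimuth: float
    tilt: float
    active: bool
    rate: float
    counter: float
    target: float
    points: list[np.ndarray]
    birth: float


class _Grower:
    def __init__(self, config: GrowthConfig):
        self.cfg = config
        self.rng = np.random.default_rng(config.seed)
        self.nodes: dict[int, tuple[np.ndarray, float]] = {}  # id -> (pos, birth)
        self.done: list[tuple[int, int, np.ndarray]] = []  # (parent, child, polyline)
        self.tips: dict[int, _Tip] = {}
        self.log = GrowthEventLog(seed=config.seed)
        self._next_id = 0
        self.t = 0.0
        self._p_apical = 1.0 / (1.0 + config.lb_ab_ratio)
        law = config.tip_rate_law
        if isinstance(law, TipRateMixture):
            grid = np.linspace(0.0, law.r_max, 4097)
            cdf = np.asarray(mixture_cdf(grid, law))
            cdf[-1] = 1.0
            self._rate_sampler = lambda: float(np.interp(self.rng.uniform(), cdf, grid))
        elif isinstance(law, GammaParams):
            self._rate_sampler = lambda: float(self.rng.gamma(law.alpha, 1.0 / law.beta))
        else:
            self._rate_sampler = lambda: float(self.rng.normal(law.mu, law.sigma))

    # -- sampling helpers --------------------------------------------------

    def _new_id(self) -> int:
        self._next_id += 1
        return self._next_id - 1

    def _draw_angle(self) -> float:
        law = self.cfg.branch_angle_law
        for _ in range(1000):
            theta = self.rng.normal(law.mu, law.sigma)
            if 0.0 < theta < 180.0:
                return float(theta)
        raise ConfigError("branch-angle law produces no angle in (0, 180)")

    def _length_law(self) -> GammaParams:
        by_age = self.cfg.branch_length_laws_by_age
        if not by_age:
            return self.cfg.branch_length_law
        age_days = self.t / 24.0
        key = min(by_age, key=lambda a: abs(a - age_days))
        return by_age[key]

    def _draw_target(self) -> float:
        law = self._length_law()
        return float(self.rng.gamma(law.alpha, 1.0 / law.beta))

    def _draw_tilt(self) -> float:
        if self.cfg.tilt_sd_deg == 0:
            return 0.0
        for _ in range(1000):
            v = self.rng.normal(0.0, self.cfg.tilt_sd_deg)
            if abs(v) <= self.cfg.tilt_max_deg:
                return math.radians(v)
        return 0.0

    def _k_active(self) -> float:
        return self.cfg.k_active_lag if self.t < self.cfg.lag_hours else self.cfg.k_active_exp

    # -- tip mechanics -----------------------------------------------------

    def _spawn_tip(self, anchor_id: int, pos: np.ndarray, azimuth: float,
                   tilt: float | None = None, inherit: _Tip | None = None,
                   draw_target: bool = True) -> _Tip:
        nid = self._new_id()
        self.nodes[nid] = (pos.copy(), self.t)
        if inherit is not None:
            active, rate, tilt_v = inherit.active, inherit.rate, inherit.tilt
        else:
            active = bool(self.rng.uniform() < self._k_active())
            rate = self._rate_sampler()
            tilt_v = tilt if tilt is not None else self._draw_tilt()
            self.log.activity.append((self.t, nid, active, rate))
        tip = _Tip(node_id=nid, anchor_id=anchor_id, pos=pos.copy(), azimuth=azimuth,
                   tilt=tilt_v, active=active, rate=rate, counter=0.0,
                   target=self._draw_target() if draw_target else float("inf"),
                   points=[pos.copy()], birth=self.t)
        if draw_target:
            self.log.target_draws.append((self.t, nid, tip.target))
        self.tips[nid] = tip
        return tip

    def _move(self, tip: _Tip, dist: float) -> None:
        c = math.cos(tip.tilt)
        d = np.array([c * math.cos(tip.azimuth), c * math.sin(tip.azimuth),
                      math.sin(tip.tilt)])
        tip.pos = tip.pos + d * dist
        tip.points.append(tip.pos.copy())
        self.nodes[tip.node_id] = (tip.pos.copy(), tip.birth)
        if self.cfg.log_elongation:
            self.log.elongations.append((self.t, tip.node_id, dist))

    def _seal(self, tip: _Tip) -> int:
        """Freeze the growing segment; the tip node becomes permanent."""
        pts = tip.points
        if len(pts) == 1:
            pts = [pts[0], pts[0]]
        self.done.append((tip.anchor_id, tip.node_id, np.vstack(pts)))
        return tip.node_id

    def _fire_apical(self, tip: _Tip) -> None:
        site = self._seal(tip)
        del self.tips[tip.node_id]
        theta = self._draw_angle()
        half = math.radians(theta) / 2.0
        d1 = self._spawn_tip(site, tip.pos, tip.azimuth + half)
        d2 = self._spawn_tip(site, tip.pos, tip.azimuth - half)
        self.log.branches.append(
            (self.t, "apical", site, tip.node_id, (d1.node_id, d2.node_id), theta, tip.target))

    def _fire_lateral(self, tip: _Tip) -> _Tip:
        site = self._seal(tip)
        del self.tips[tip.node_id]
        theta = self._draw_angle()
        sign = 1.0 if self.rng.uniform() < 0.5 else -1.0
        daughter = self._spawn_tip(site, tip.pos, tip.azimuth + sign * math.radians(theta))
        cont = self._spawn_tip(site, tip.pos, tip.azimuth, inherit=tip)
        self.log.branches.append(
            (self.t, "lateral", site, tip.node_id, (daughter.node_id, cont.node_id),
             theta, tip.target))
        return cont

    def _advance(self, tip: _Tip, dist: float) -> None:
        cfg = self.cfg
        can_branch = (cfg.branching_enabled and
                      (cfg.max_tips is None or len(self.tips) < cfg.max_tips))
        while dist > 1e-12:
            to_event = tip.target - tip.counter
            if can_branch and to_event <= dist:
                self._move(tip, to_event)
                dist -= to_event
                tip.counter = 0.0
                if self.t < cfg.lag_hours and self.rng.uniform() >= cfg.k_lag:
                    self.log.suppressed.append((self.t, tip.node_id))
                    tip.target = self._draw_target()
                    self.log.target_draws.append((self.t, tip.node_id, tip.target))
                    continue
                if self.rng.uniform() < self._p_apical:
                    self._fire_apical(tip)
                    return  # mother terminated; remainder of the step forfeited
                tip = self._fire_lateral(tip)
                can_branch = cfg.max_tips is None or len(self.tips) < cfg.max_tips
            else:
                self._move(tip, dist)
                tip.counter += dist
                dist = 0.0

    # -- snapshots ---------------------------------------------------------

    def _snapshot(self) -> HyphalNetwork:
        nodes = [HyphalNode(i, pos, birth=b) for i, (pos, b) in self.nodes.items()]
        segments = [Segment(p, c, poly) for p, c, poly in self.done]
        for tip in self.tips.values():
            pts = tip.points if len(tip.points) > 1 else [tip.points[0], tip.points[0]]
            segments.append(Segment(tip.anchor_id, tip.node_id, np.vstack(pts)))
        net = HyphalNetwork(nodes, segments, time=self.t,
                            provenance={"seed": self.cfg.seed, "generator": "mycomorph"})
        for tip in list(self.tips.values()):
            site = self._seal(tip)
            del self.tips[tip.node_id]
            fresh = self._spawn_tip(site, tip.pos, tip.azimuth, inherit=tip,
                                    draw_target=False)
            fresh.counter, fresh.target = tip.counter, tip.target
        return net

    # -- main loop ---------------------------------------------------------

    def run(self) -> tuple[ColonyTimeSeries, GrowthEventLog]:
        cfg = self.cfg
        root = self._new_id()
        self.nodes[root] = (np.zeros(3), 0.0)
        n0 = cfg.n_initial_hyphae
        jitter = self.rng.uniform(-math.pi / n0, math.pi / n0, size=n0)
        for k in range(n0):
            self._spawn_tip(root, np.zeros(3), 2 * math.pi * k / n0 + jitter[k])

        n_steps = int(round(cfg.duration_hours / cfg.dt_hours))
        resample_every = int(round(cfg.resample_hours / cfg.dt_hours))
        snap_steps = {int(round(t / cfg.dt_hours)) for t in cfg.snapshot_hours}
        snapshots: list[HyphalNetwork] = []

        for step in range(n_steps):
            self.t = step * cfg.dt_hours
            order = sorted(self.tips)
            if step % resample_every == 0 and step > 0:
                k = self._k_active()
                draws = self.rng.uniform(size=len(order))
                for nid, u in zip(order, draws):
                    tip = self.tips[nid]
                    tip.active = bool(u < k)
                    tip.rate = self._rate_sampler() if tip.active else tip.rate
                    self.log.activity.append((self.t, nid, tip.active, tip.rate))
            noise = self.rng.normal(0.0, math.radians(cfg.direction_noise_sd_deg),
                                    size=len(order))
            self.t = (step + 1) * cfg.dt_hours  # events during this step carry its end time
            for nid, eps in zip(order, noise):
                tip = self.tips.get(nid)
                if tip is None or not tip.active:
                    continue
                # diffusion-like wander: the configured sd applies per
                # _NOISE_REF_UM of growth so slow tips do not curl up
                tip.azimuth += eps * math.sqrt(tip.rate * cfg.dt_hours / _NOISE_REF_UM)
                self._advance(tip, tip.rate * cfg.dt_hours)
            if (step + 1) in snap_steps:
                snapshots.append(self._snapshot())

        return ColonyTimeSeries(snapshots), self.log


def grow(config: GrowthConfig) -> tuple[ColonyTimeSeries, GrowthEventLog]:
    """Run the stochastic growth model; bit-identical output per seed+config."""
    return _Grower(config).run()
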