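import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mycomorph import morphometry as M
from mycomorph.errors import MycomorphError, UndefinedRatioError
from mycomorph.simulate import GrowthConfig, grow

from conftest import build_network


def oracle_angle_error(theta_p, tz1, tz2):
    """Independent 3D construction: unit vectors with given elevations whose
    projections subtend theta_p; the error is (true angle − theta_p)."""
    def vec(elev, az):
        e, a = math.radians(elev), math.radians(az)
        return np.array([math.cos(e) * math.cos(a), math.cos(e) * math.sin(a),
                         math.sin(e)])
    v1, v2 = vec(tz1, 0.0), vec(tz2, theta_p)
    true = math.degrees(math.acos(float(np.clip(v1 @ v2, -1, 1))))
    return true - theta_p


class TestClassification:
    def test_terminal_bifurcation_is_ab(self, y_network):
        assert M.classify_branch_type(y_network, 1) == "AB"

    def test_mid_hypha_departure_is_lb(self, lateral_network):
        assert M.classify_branch_type(lateral_network, 1) == "LB"

    def test_degree_four_unclassifiable(self):
        net = build_network(
            {0: (0, 0, 0), 1: (10, 0, 0), 2: (20, 0, 0), 3: (10, 10, 0), 4: (10, -10, 0)},
            [(0, 1), (1, 2), (1, 3), (1, 4)])
        assert M.classify_branch_type(net, 1) == "unclassifiable"

    def test_types_match_event_log(self, small_colony):
        series, log = small_colony
        net = series[-1]
        truth = {e[2]: ("AB" if e[1] == "apical" else "LB") for e in log.branches}
        mismatches = sum(
            1 for site in net.branch_sites()
            if (k := M.classify_branch_type(net, site)) != "unclassifiable"
            and k != truth[site])
        assert mismatches == 0

    def test_types_match_event_log_noise_free(self, clean_colony):
        series, log = clean_colony
        net = series[-1]
        truth = {e[2]: ("AB" if e[1] == "apical" else "LB") for e in log.branches}
        for site in net.branch_sites():
            k = M.classify_branch_type(net, site)
            if k != "unclassifiable":
                assert k == truth[site]


class TestBranchAngle:
    def test_planar_ab_angle(self, y_network):
        assert M.branch_angle(y_network, 1) == pytest.approx(80.0, abs=1e-9)

    def test_planar_lb_angle(self, lateral_network):
        assert M.branch_angle(lateral_network, 1) == pytest.approx(90.0, abs=1e-9)

    def test_tilted_arms_match_projected_construction(self):
        # 3D vector-projection oracle: arms with known elevations
        elev1, elev2, proj_angle = 25.0, -10.0, 70.0
        def arm(elev, az, length=40.0):
            e, a = math.radians(elev), math.radians(az)
            return np.array([math.cos(e) * math.cos(a), math.cos(e) * math.sin(a),
                             math.sin(e)]) * length
        p1 = arm(elev1, 55.0)
        p2 = arm(elev2, 55.0 - proj_angle)
        net = build_network(
            {0: (-50, 0, 0), 1: (0, 0, 0), 2: tuple(p1), 3: tuple(p2)},
            [(0, 1), (1, 2), (1, 3)])
        measured = M.branch_angle(net, 1, kind="AB")
        assert measured == pytest.approx(proj_angle, abs=1e-9)

    def test_measured_angles_equal_sampled_zero_noise(self, clean_colony):
        series, log = clean_colony
        net = series[-1]
        sampled = {e[2]: e[5] for e in log.branches}
        n_checked = 0
        for site in net.branch_sites():
            kind = M.classify_branch_type(net, site, window=1.0)
            if kind == "unclassifiable":
                continue
            try:
                theta = M.branch_angle(net, site, window=1.0, kind=kind)
            except MycomorphError:
                continue
            assert theta == pytest.approx(sampled[site], abs=1e-6)
            n_checked += 1
        assert n_checked >= 50

    def test_measured_angle_distribution_ks_consistent(self, small_colony):
        series, _ = small_colony
        records, _ = M.measure_branches(series[-1])
        angles = np.array([r.angle_deg for r in records])
        assert len(angles) >= 250
        d, p = stats.kstest(angles, stats.norm(77.6, 12.3).cdf)
        assert p > 0.01


class TestBranchingLengths:
    def test_arc_positions_spans(self):
        # sites at arc 10, 35, 95 on one hypha → spans {25, 60}
        pos = {0: (0.0, 0, 0)}
        edges = []
        nid = 1
        prev = 0
        for x in (10.0, 35.0, 95.0):
            site, stub = nid, nid + 1
            nid += 2
            pos[site] = (x, 0.0, 0.0)
            pos[stub] = (x, 30.0, 0.0)
            edges += [(prev, site), (site, stub)]
            prev = site
        pos[nid] = (130.0, 0.0, 0.0)
        edges.append((prev, nid))
        net = build_network(pos, edges)
        lengths = M.branching_lengths(net)
        assert np.allclose(sorted(lengths), [25.0, 60.0])

    def test_single_site_contributes_nothing(self, lateral_network):
        assert len(M.branching_lengths(lateral_network)) == 0

    def test_multiset_matches_event_log(self, clean_colony):
        series, log = clean_colony
        net = series[-1]
        n_initial = 10
        hypha_of = {i: i for i in range(1, n_initial + 1)}
        fired: dict[int, list[float]] = {}
        origin_is_site: dict[int, bool] = {i: False for i in range(1, n_initial + 1)}
        unclassifiable = {s for s in net.branch_sites()
                          if M.classify_branch_type(net, s) == "unclassifiable"}
        for _, kind, site, mother, daughters, _, target in log.branches:
            h = hypha_of[mother]
            if site not in unclassifiable:
                # a site with no grown arm is excluded by the measurement,
                # dropping the span that ends there
                fired.setdefault(h, []).append(target)
            if kind == "lateral":
                daughter, cont = daughters
                hypha_of[cont] = h
                hypha_of[daughter] = daughter
                origin_is_site[daughter] = site not in unclassifiable
            else:
                for d in daughters:
                    hypha_of[d] = d
                    origin_is_site[d] = site not in unclassifiable
        expected = []
        for h, targets in fired.items():
            expected.extend(targets if origin_is_site[h] else targets[1:])
        measured = M.branching_lengths(net)
        assert np.allclose(np.sort(measured), np.sort(expected), atol=1e-9)

    def test_origin_spans_can_be_excluded(self, clean_colony):
        series, _ = clean_colony
        net = series[-1]
        with_origin = M.branching_lengths(net, include_origin_sites=True)
        without = M.branching_lengths(net, include_origin_sites=False)
        assert len(without) < len(with_origin)


class TestLbAbRatio:
    def test_simple_ratio(self):
        recs = [M.BranchRecord(i, np.zeros(3), "LB", 80.0) for i in range(45)]
        recs += [M.BranchRecord(99 + i, np.zeros(3), "AB", 80.0) for i in range(10)]
        assert M.lb_ab_ratio(recs) == pytest.approx(4.5)

    def test_zero_lb(self):
        recs = [M.BranchRecord(i, np.zeros(3), "AB", 80.0) for i in range(5)]
        assert M.lb_ab_ratio(recs) == 0.0

    def test_no_ab_is_error(self):
        recs = [M.BranchRecord(0, np.zeros(3), "LB", 80.0)]
        with pytest.raises(UndefinedRatioError):
            M.lb_ab_ratio(recs)


class TestAngleProjectionError:
    def test_in_plane_is_exact(self):
        for tp in (10.0, 90.0, 170.0):
            assert M.angle_projection_error(tp, 0.0, 0.0) == pytest.approx(0.0, abs=1e-12)

    def test_sixty_degree_case(self):
        # elevations of 60° with a right projected angle: cos θ_r = sin²60 = 0.75
        expected = math.degrees(math.acos(0.75)) - 90.0
        assert M.angle_projection_error(90.0, 60.0, 60.0) == pytest.approx(expected)
        assert expected == pytest.approx(-48.59, abs=0.01)

    def test_matches_oracle_on_grid(self):
        rng = np.random.default_rng(1)
        for _ in range(10_000):
            tp = rng.uniform(1.0, 179.0)
            tz1, tz2 = rng.uniform(-80.0, 80.0, size=2)
            assert M.angle_projection_error(tp, tz1, tz2) == pytest.approx(
                oracle_angle_error(tp, tz1, tz2), abs=1e-9)

    @settings(max_examples=200, deadline=None)
    @given(tp=st.floats(1.0, 179.0), tz1=st.floats(-80, 80), tz2=st.floats(-80, 80))
    def test_matches_oracle_property(self, tp, tz1, tz2):
        assert M.angle_projection_error(tp, tz1, tz2) == pytest.approx(
            oracle_angle_error(tp, tz1, tz2), abs=1e-9)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            M.angle_projection_error(0.0, 10.0, 10.0)
        with pytest.raises(ValueError):
            M.angle_projection_error(90.0, 95.0, 0.0)


class TestLengthProjectionError:
    def test_in_plane_zero(self):
        eps, phi = M.length_projection_error(50.0, 0.0)
        assert eps == 0.0 and phi == 0.0

    def test_sixty_degrees(self):
        eps, phi = M.length_projection_error(50.0, 60.0)
        assert eps == pytest.approx(50.0)
        assert phi == pytest.approx(1.0)

    @settings(max_examples=200, deadline=None)
    @given(lp=st.floats(0.1, 500.0), tz=st.floats(-80.0, 80.0))
    def test_matches_3d_segment_oracle(self, lp, tz):
        # oracle: true length of a segment with projected run lp and rise Δz
        dz = lp * math.tan(math.radians(tz))
        true_len = math.hypot(lp, dz)
        eps, phi = M.length_projection_error(lp, tz)
        assert eps == pytest.approx(true_len - lp, rel=1e-9, abs=1e-9)
        assert phi == pytest.approx(eps / lp)

    def test_near_vertical_rejected(self):
        with pytest.raises(ValueError):
            M.length_projection_error(10.0, 90.0)


class TestCrossings:
    def test_deep_crossing_labelled(self):
        net = build_network(
            {0: (0, 0, 0), 1: (100, 0, 0), 2: (50, -50, 40), 3: (50, 50, 40)},
            [(0, 1), (2, 3)])
        (rec,) = M.crossing_filter(net)
        assert rec.label == "crossing"
        assert rec.dz == pytest.approx(40.0)
        assert np.allclose(rec.xy, [50.0, 0.0])

    def test_same_depth_contact(self):
        net = build_network(
            {0: (0, 0, 0), 1: (100, 0, 0), 2: (50, -50, 0), 3: (50, 50, 0)},
            [(0, 1), (2, 3)])
        (rec,) = M.crossing_filter(net)
        assert rec.label == "co-planar contact"

    def test_branch_site_never_a_crossing(self, y_network):
        assert M.crossing_filter(y_network) == []

    def test_no_site_labelled_crossing_in_colony(self):
        cfg = GrowthConfig(seed=3, n_initial_hyphae=6, duration_hours=24,
                           snapshot_hours=(24,), lag_hours=0, max_tips=60)
        series, _ = grow(cfg)
        net = series[-1]
        site_xy = np.array([net.nodes[s].position[:2] for s in net.branch_sites()])
        for rec in M.crossing_filter(net):
            if rec.label == "crossing" and len(site_xy):
                d = np.linalg.norm(site_xy - rec.xy, axis=1)
                assert d.min() > 1e-9


class TestMeasureBranches:
    def test_summary_counts_and_ratio(self, small_colony):
        series, log = small_colony
        _, summary = M.measure_branches(series[-1])
        n_classified = summary.n_lbs + summary.n_abs
        assert n_classified + summary.n_unclassifiable == len(series[-1].branch_sites())
        n_apical = sum(e[1] == "apical" for e in log.branches)
        assert summary.n_abs == pytest.approx(n_apical, abs=3)
        assert 3.0 < summary.ratio < 7.0
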