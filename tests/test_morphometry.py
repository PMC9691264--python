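"""Thickness maps, ETDRS subfields, 3-D reconstruction and group stats."""

import numpy as np
import pytest

from choroidseg.morphometry import (
    SUBFIELD_NAMES, ThicknessMap, choroid_volume, compare_groups,
    compute_surface_features, etdrs_subfields, surface_area,
    surface_curvature, surfaces_to_point_cloud, thickness_map,
)
from choroidseg.trace import BoundaryTrace


def make_map(values, lateral=100.0, sl=100.0, laterality="OD"):
    return ThicknessMap(values, lateral, sl, laterality=laterality)


class TestThicknessMap:
    def test_constant_thickness(self):
        traces = [BoundaryTrace(np.full(8, 10.0), np.full(8, 110.0))
                  for _ in range(4)]
        t = thickness_map(traces, 2.0, 10.0, 50.0)
        assert np.all(t.values == 200.0)

    def test_missing_column_propagates(self):
        bm = np.full(8, 10.0)
        csi = np.full(8, 30.0)
        csi[3] = np.nan
        t = thickness_map([BoundaryTrace(bm, csi)], 2.0, 10.0, 50.0)
        assert np.isnan(t.values[0, 3])
        assert np.isfinite(t.values[0, 2])

    def test_synthetic_volume_round_trip(self, small_config):
        from choroidseg.metrics import extract_boundaries
        from choroidseg.synthetic import generate_volume

        cfg = small_config.replace(thickness_variation=0.0)
        _, masks, _ = generate_volume(cfg)
        traces = [extract_boundaries(m) for m in masks]
        t = thickness_map(traces, cfg.axial_spacing, cfg.lateral_spacing,
                          cfg.slice_spacing)
        assert abs(np.nanmean(t.values) - cfg.mean_choroid_thickness) \
            <= cfg.axial_spacing

    def test_mixed_widths_rejected(self):
        traces = [BoundaryTrace(np.zeros(4), np.ones(4)),
                  BoundaryTrace(np.zeros(5), np.ones(5))]
        with pytest.raises(ValueError):
            thickness_map(traces, 1, 1, 1)


class TestETDRS:
    def grid(self, n=70, spacing=100.0):
        """n x n grid at `spacing` µm covers a 7 mm square: full 6 mm disk."""
        return n, spacing

    def test_constant_map(self):
        n, sp = self.grid()
        rep = etdrs_subfields(make_map(np.full((n, n), 123.0), sp, sp))
        for name in SUBFIELD_NAMES:
            assert np.isclose(rep.subfield_means[name], 123.0)
        assert np.isclose(rep.global_average, 123.0)
        assert np.isclose(rep.center_point_thickness, 123.0)

    def test_half_plane_map_oracle(self):
        """Superior half a, inferior half b: vertical subfields pick their
        half, the central disk straddles both."""
        n, sp = 70, 100.0
        vals = np.where(np.arange(n)[:, None] < (n - 1) / 2, 200.0, 100.0)
        vals = np.broadcast_to(vals, (n, n)).astype(float)
        rep = etdrs_subfields(make_map(vals, sp, sp))
        # the split falls between rows, so halves and the center disk are
        # exactly balanced
        assert np.isclose(rep.subfield_means["CFT"], 150.0)
        for name, expect in (("SIM", 200.0), ("SOM", 200.0),
                             ("IIM", 100.0), ("IOM", 100.0)):
            assert np.isclose(rep.subfield_means[name], expect), name

    def test_laterality_flip_swaps_nasal_temporal(self):
        n, sp = self.grid()
        rng = np.random.default_rng(0)
        vals = rng.uniform(100, 300, (n, n))
        od = etdrs_subfields(make_map(vals, sp, sp, "OD"))
        os_ = etdrs_subfields(make_map(vals, sp, sp, "OS"))
        assert np.isclose(od.subfield_means["NIM"], os_.subfield_means["TIM"])
        assert np.isclose(od.subfield_means["NOM"], os_.subfield_means["TOM"])
        assert np.isclose(od.subfield_means["SIM"], os_.subfield_means["SIM"])
        assert np.isclose(od.subfield_means["IOM"], os_.subfield_means["IOM"])

    def test_area_weighted_conservation(self):
        """Pixel-count-weighted mean of the 9 subfields equals the 6 mm-disk
        mean exactly (the subfields partition the disk)."""
        n, sp = self.grid()
        rng = np.random.default_rng(3)
        for _ in range(5):
            vals = rng.uniform(50, 400, (n, n))
            t = make_map(vals, sp, sp)
            rep = etdrs_subfields(t)
            dy, dx = t.physical_offsets_mm()
            r = np.hypot(dy, dx)
            disk_mean = vals[r <= 3.0].mean()
            # recompute subfield pixel counts for the weights
            counts = {}
            inner = (r > 0.5) & (r <= 1.5)
            outer = (r > 1.5) & (r <= 3.0)
            counts["CFT"] = (r <= 0.5).sum()
            weighted = rep.subfield_means["CFT"] * counts["CFT"]
            total = counts["CFT"]
            from choroidseg.morphometry import _quadrant_masks
            quads = _quadrant_masks(dy, dx, "OD")
            for ring_name, ring in (("I", inner), ("O", outer)):
                for q in "SNIT":
                    cnt = (ring & quads[q]).sum()
                    weighted += rep.subfield_means[f"{q}{ring_name}M"] * cnt
                    total += cnt
            assert abs(weighted / total - disk_mean) / disk_mean < 5e-3

    def test_too_small_grid_rejected(self):
        with pytest.raises(ValueError):
            etdrs_subfields(make_map(np.full((4, 4), 100.0), 100.0, 100.0))


class TestPointCloud:
    def test_flat_boundary_constant_z(self):
        traces = [BoundaryTrace(np.full(6, 25.0), np.full(6, 50.0))
                  for _ in range(3)]
        bm, csi = surfaces_to_point_cloud(traces, 4.0, 10.0, 20.0)
        assert np.allclose(bm[:, 2], 25 * 4.0 / 1000)
        assert np.allclose(csi[:, 2], 50 * 4.0 / 1000)

    def test_point_counts(self):
        bmr = np.array([1.0, np.nan, 2.0, 3.0])
        tr = BoundaryTrace(bmr, bmr + 5)
        bm, csi = surfaces_to_point_cloud([tr, tr], 1, 1, 1)
        assert bm.shape == (6, 3) and csi.shape == (6, 3)

    def test_round_trip_through_file(self, tmp_path):
        rng = np.random.default_rng(1)
        tr = BoundaryTrace(rng.uniform(5, 10, 8), rng.uniform(20, 30, 8))
        bm, _ = surfaces_to_point_cloud([tr], 3.0, 5.0, 7.0)
        f = tmp_path / "cloud.txt"
        np.savetxt(f, bm)
        assert np.allclose(np.loadtxt(f), bm)


class TestVolumeAreaCurvature:
    def test_uniform_volume_closed_form(self):
        # 200 µm over 3x3 mm -> 1.8 mm^3 (rectangle rule, 25 µm cells)
        n = 241
        t = make_map(np.full((n, n), 200.0), 25.0, 25.0)
        v = choroid_volume(t, (3.0, 3.0))
        assert abs(v - 1.8) / 1.8 < 0.05

    def test_volume_linearity_and_additivity(self):
        n = 41
        rng = np.random.default_rng(2)
        vals = rng.uniform(100, 300, (n, n))
        t1 = make_map(vals, 100.0, 100.0)
        t2 = make_map(2 * vals, 100.0, 100.0)
        assert np.isclose(choroid_volume(t2, (2, 2)),
                          2 * choroid_volume(t1, (2, 2)))

    def test_volume_matches_brute_force(self):
        n = 31
        rng = np.random.default_rng(4)
        vals = rng.uniform(0, 400, (n, n))
        t = make_map(vals, 100.0, 100.0)
        got = choroid_volume(t, (2.0, 2.0))
        dy, dx = t.physical_offsets_mm()
        expect = 0.0
        for i in range(n):
            for j in range(n):
                if abs(dx[i, j]) <= 1.0 and abs(dy[i, j]) <= 1.0:
                    expect += vals[i, j] / 1000 * 0.1 * 0.1
        assert np.isclose(got, expect)

    def test_roi_outside_grid_rejected(self):
        t = make_map(np.full((11, 11), 100.0), 100.0, 100.0)
        with pytest.raises(ValueError):
            choroid_volume(t, (5.0, 5.0))

    def test_flat_and_tilted_plane_area(self):
        n = 51
        xs = np.linspace(0, 5, n)
        d = xs[1] - xs[0]
        flat = np.zeros((n, n))
        assert np.isclose(surface_area(flat, d, d), 25.0, rtol=1e-6)
        theta = 0.5
        tilted = np.tile(np.tan(theta) * xs, (n, 1))
        assert np.isclose(surface_area(tilted, d, d), 25.0 / np.cos(theta),
                          rtol=1e-2)

    def test_corrugation_only_increases_area(self):
        n = 41
        rng = np.random.default_rng(5)
        base = np.zeros((n, n))
        bumpy = rng.normal(0, 0.05, (n, n))
        assert surface_area(bumpy, 0.1, 0.1) >= surface_area(base, 0.1, 0.1)

    def test_plane_curvature_zero_and_offset_invariance(self):
        n = 41
        xs = np.linspace(0, 4, n)
        d = xs[1] - xs[0]
        plane = np.tile(0.3 * xs, (n, 1))
        assert surface_curvature(plane, d, d, 1.0) < 1e-8
        R = 10.0
        X, Y = np.meshgrid(np.linspace(-2, 2, n), np.linspace(-2, 2, n))
        dd = 4 / (n - 1)
        sph = np.sqrt(R**2 - X**2 - Y**2)
        k1 = surface_curvature(sph, dd, dd, 1.0)
        k2 = surface_curvature(sph + 7.0, dd, dd, 1.0)
        assert np.isclose(k1, k2, rtol=1e-9)
        assert abs(k1 - 1 / R) * R < 0.05

    def test_full_feature_extraction(self, small_config):
        from choroidseg.synthetic import generate_volume

        cfg = small_config.replace(n_bscans=16, thickness_variation=0.0)
        _, _, traces = generate_volume(cfg)
        extent = ((cfg.width - 1) * cfg.lateral_spacing / 1000,
                  (cfg.n_bscans - 1) * cfg.slice_spacing / 1000)
        roi = (extent[0] * 0.9, extent[1] * 0.9)
        feats = compute_surface_features(
            traces, cfg.axial_spacing, cfg.lateral_spacing, cfg.slice_spacing,
            roi=roi, curvature_window_mm=0.5)
        assert feats.inner_volume > 0
        assert feats.inner_surface_area >= roi[0] * roi[1] * 0.8
        assert feats.bm_curvature >= 0


class TestCompareGroups:
    def test_antisymmetry_and_identity(self):
        a = {"thickness": [200.0, 210.0, 190.0, 205.0]}
        b = {"thickness": [150.0, 160.0, 155.0, 145.0]}
        ab = compare_groups(a, b)
        ba = compare_groups(b, a)
        assert np.isclose(ab["mean_difference"][0], -ba["mean_difference"][0])
        same = compare_groups(a, a)
        assert same["mean_difference"][0] == 0.0
        assert same["p_value"][0] > 0.99

    def test_size_one_group_flagged(self):
        out = compare_groups({"x": [1.0]}, {"x": [2.0, 3.0]})
        assert "no test" in out["note"][0]
        assert np.isnan(out["p_value"][0])

    def test_known_effect_recovered(self):
        """Groups drawn at 230 vs 177 µm (SD 30, n=20): the 95% CI covers
        the true -53 µm difference in at least 90% of replicates."""
        rng = np.random.default_rng(11)
        hits = 0
        reps = 40
        for _ in range(reps):
            a = {"t": rng.normal(230, 30, 20).tolist()}
            b = {"t": rng.normal(177, 30, 20).tolist()}
            row = compare_groups(a, b).iloc[0]
            if row["ci_low"] <= -53.0 <= row["ci_high"]:
                hits += 1
        assert hits / reps >= 0.9
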