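"""Source-model ray tracing and core-position sampling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import kstest

from tg43mc.geometry import (GeometryError, Phantom, SourceModel,
                             locate_material, sample_core_position,
                             trace_path)

MODEL = SourceModel()
WATER = Phantom()


class TestSampleCorePosition:
    def test_support(self):
        rng = np.random.default_rng(1)
        pts = sample_core_position(rng, MODEL, n=100_000)
        rho = np.hypot(pts[:, 0], pts[:, 1])
        assert np.all(rho <= MODEL.core_radius + 1e-12)
        assert np.all(np.abs(pts[:, 2]) <= MODEL.half_length + 1e-12)

    def test_mean_near_centre(self):
        rng = np.random.default_rng(2)
        pts = sample_core_position(rng, MODEL, n=100_000)
        # component std: rho/2 for x,y; L/(2 sqrt(3)) for z
        se_xy = MODEL.core_radius / 2 / np.sqrt(len(pts))
        se_z = MODEL.core_length / np.sqrt(12) / np.sqrt(len(pts))
        assert np.all(np.abs(pts[:, :2].mean(axis=0)) < 4 * se_xy)
        assert abs(pts[:, 2].mean()) < 4 * se_z

    def test_rho_squared_uniform(self):
        """Uniform-in-area: rho^2 ~ U(0, R^2) by K-S test."""
        rng = np.random.default_rng(3)
        pts = sample_core_position(rng, MODEL, n=50_000)
        rho2 = (pts[:, 0] ** 2 + pts[:, 1] ** 2) / MODEL.core_radius**2
        assert kstest(rho2, "uniform").pvalue > 1e-4


class TestTracePath:
    def test_transverse_ray_layer_thicknesses(self):
        segs = trace_path([0, 0, 0], [1, 0, 0], MODEL, WATER).segments
        assert segs[0] == ("iridium", pytest.approx(0.03))
        assert segs[1] == ("steel316l", pytest.approx(0.015))
        assert segs[2][0] == "water"

    def test_axial_ray_to_tip(self):
        segs = trace_path([0, 0, 0], [0, 0, 1], MODEL, WATER).segments
        assert segs[0] == ("iridium", pytest.approx(MODEL.half_length))
        assert segs[1] == ("steel316l", pytest.approx(MODEL.tip_thickness))
        assert segs[2][0] == "water"

    def test_axial_ray_through_cable(self):
        segs = trace_path([0, 0, 0], [0, 0, -1], MODEL, WATER).segments
        mats = [s[0] for s in segs]
        assert mats == ["iridium", "steel316l", "steel304", "water"]
        assert segs[2][1] == pytest.approx(MODEL.cable_length)

    def test_far_interior_point_single_water_segment(self):
        ps = trace_path([30, 0, 0], [1, 0, 0], MODEL, WATER)
        assert ps.segments == (("water", pytest.approx(10.0)),)

    def test_zero_direction_rejected(self):
        with pytest.raises(GeometryError, match="degenerate"):
            trace_path([0, 0, 0], [0, 0, 0], MODEL, WATER)

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=60, deadline=None)
    def test_segments_sum_to_boundary_distance(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.normal(scale=1.0, size=3)
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        ps = trace_path(p, d, MODEL, WATER)
        t = WATER.boundary_distance(p[None], d[None])[0]
        assert ps.total_length == pytest.approx(t, abs=1e-10)

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=60, deadline=None)
    def test_midpoint_material_matches_segment(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.normal(scale=0.2, size=3)
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        ps = trace_path(p, d, MODEL, WATER)
        acc = 0.0
        for mat, length in ps.segments:
            mid = p + (acc + length / 2) * d
            assert locate_material(mid, MODEL, WATER) == mat
            acc += length

    def test_azimuthal_symmetry(self):
        """Rotating origin and direction about the source axis leaves the
        segment list invariant (spherical phantom, so the outer boundary
        is symmetric too)."""
        sphere = Phantom("air_sphere", 40.0, "air")
        rng = np.random.default_rng(9)
        for _ in range(25):
            p = rng.normal(scale=0.3, size=3)
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            phi = rng.uniform(0, 2 * np.pi)
            c, s = np.cos(phi), np.sin(phi)
            rot = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])
            a = trace_path(p, d, MODEL, sphere).segments
            b = trace_path(rot @ p, rot @ d, MODEL, sphere).segments
            assert [m for m, _ in a] == [m for m, _ in b]
            assert np.allclose([x for _, x in a], [x for _, x in b],
                               atol=1e-9)


class TestLocateMaterial:
    def test_reference_points(self):
        assert locate_material([0, 0, 0], MODEL, WATER) == "iridium"
        z_tip_mid = MODEL.half_length + MODEL.tip_thickness / 2
        assert locate_material([0, 0, z_tip_mid], MODEL, WATER) \
            == "steel316l"
        assert locate_material([10, 0, 0], MODEL, WATER) == "water"
        assert locate_material([0, 0, -1.0], MODEL, WATER) == "steel304"

    def test_boundary_belongs_to_inner_region(self):
        assert locate_material([MODEL.core_radius, 0, 0], MODEL, WATER) \
            == "iridium"
        assert locate_material([MODEL.capsule_radius, 0, 0], MODEL,
                               WATER) == "steel316l"


class TestModelValidation:
    def test_core_must_fit_in_capsule(self):
        with pytest.raises(GeometryError):
            SourceModel(core_radius=0.05, capsule_radius=0.045)

    def test_positive_lengths(self):
        with pytest.raises(GeometryError):
            SourceModel(core_length=0.0)
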