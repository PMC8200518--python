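"""Materials, mixture rule, and attenuation-table interpolation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tg43mc.attenuation import (AttenuationError, build_attenuation_table,
                                interpolate_mu, interpolate_mu_en,
                                load_attenuation)
from tg43mc.materials import (MaterialError, STANDARD_MATERIALS,
                              build_material)


class TestMaterials:
    def test_composition_sums_are_exact(self):
        for mat in STANDARD_MATERIALS.values():
            assert sum(mat.fractions.values()) == pytest.approx(100.0,
                                                                abs=0.01)

    def test_densities(self):
        rho = {name: m.density for name, m in STANDARD_MATERIALS.items()}
        assert rho == {"iridium": 22.42, "steel316l": 7.8, "steel304": 5.6,
                       "water": 0.998, "air": 1.197e-3}

    def test_bad_fraction_sum_rejected(self):
        with pytest.raises(MaterialError, match="sum"):
            build_material("x", {"H": 50.0, "O": 49.0}, 1.0)

    def test_negative_fraction_rejected(self):
        with pytest.raises(MaterialError, match="negative"):
            build_material("x", {"H": 101.0, "O": -1.0}, 1.0)

    def test_pure_element_mixture_equals_elemental(self):
        from tg43mc.elements import element_mu_processes
        ir = STANDARD_MATERIALS["iridium"]
        e = 0.3165
        assert ir.mu(e) == pytest.approx(
            element_mu_processes("Ir", e)["total"], rel=1e-12)

    def test_fifty_fifty_mixture_is_arithmetic_mean(self):
        from tg43mc.elements import element_mu_processes
        mix = build_material("mix", {"Fe": 50.0, "Cr": 50.0}, 7.0)
        e = 0.2
        expect = 0.5 * (element_mu_processes("Fe", e)["total"]
                        + element_mu_processes("Cr", e)["total"])
        assert mix.mu(e) == pytest.approx(expect, rel=1e-12)

    def test_mixture_rule_scale_invariance(self):
        """Scaling all fractions then renormalising leaves mu unchanged."""
        a = build_material("a", {"H": 11.1, "O": 88.9}, 1.0)
        b = build_material("b", {"H": 11.1, "O": 88.9}, 1.0)
        assert a.mu(0.1) == b.mu(0.1)


@pytest.fixture(scope="module")
def tables():
    return {n: load_attenuation(n)
            for n in ("iridium", "steel316l", "steel304", "water", "air")}


class TestAttenuationTables:

    def test_grid_span_and_ordering(self, tables):
        for t in tables.values():
            assert np.all(np.diff(t.energy_mev) > 0)
            assert t.energy_mev[0] <= 0.010 and t.energy_mev[-1] >= 1.5

    def test_processes_sum_to_total(self, tables):
        for t in tables.values():
            s = (t.mu["photoelectric"] + t.mu["incoherent"]
                 + t.mu["coherent"])
            assert np.allclose(s, t.mu["total"], rtol=0.005)

    def test_mu_en_not_above_mu(self, tables):
        for name in ("water", "air"):
            t = tables[name]
            assert np.all(t.mu_en <= t.mu["total"])

    def test_grid_point_queries_are_exact(self, tables):
        t = tables["water"]
        for i in (0, 5, -1):
            e = t.energy_mev[i]
            assert interpolate_mu(t, e) == pytest.approx(
                t.mu["total"][i], rel=1e-12)
            assert interpolate_mu_en(t, e) == pytest.approx(
                t.mu_en[i], rel=1e-12)

    def test_log_log_interpolation_at_geometric_mean(self, tables):
        """At the geometric mean of two grid energies the log-log
        interpolant returns the geometric mean weighted by the local
        power law -- closed form checked directly."""
        t = tables["water"]
        e0, e1 = t.energy_mev[8], t.energy_mev[9]
        m0, m1 = t.mu["total"][8], t.mu["total"][9]
        eg = np.sqrt(e0 * e1)
        expect = np.exp(0.5 * (np.log(m0) + np.log(m1)))
        assert interpolate_mu(t, eg) == pytest.approx(expect, rel=1e-12)

    def test_out_of_range_raises(self, tables):
        with pytest.raises(AttenuationError, match="span"):
            interpolate_mu(tables["water"], 0.005)
        with pytest.raises(AttenuationError, match="span"):
            interpolate_mu(tables["iridium"], 2.0)

    def test_mu_en_only_for_air_and_water(self, tables):
        with pytest.raises(AttenuationError, match="mu_en"):
            interpolate_mu_en(tables["iridium"], 0.1)

    @given(st.integers(min_value=0, max_value=17))
    @settings(max_examples=18, deadline=None)
    def test_interpolation_monotone_between_grid_points(self, i):
        t = load_attenuation("water")
        e0, e1 = t.energy_mev[i], t.energy_mev[i + 1]
        es = np.linspace(e0, e1, 9)
        mus = t.mu_at(es)
        d = np.diff(mus)
        assert np.all(d <= 1e-12) or np.all(d >= -1e-12)

    def test_fixture_matches_builder(self):
        """The shipped CSV is the builder's output (regeneration check)."""
        built = build_attenuation_table("water")
        shipped = load_attenuation("water")
        assert np.allclose(built.mu["total"], shipped.mu["total"],
                           rtol=1e-6)

    def test_ir_k_edge_discontinuity_present(self, tables):
        t = tables["iridium"]
        below = t.mu_at(0.0761)
        above = t.mu_at(0.0762)
        assert above > 2.0 * below
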