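"""Constitutive closures: drag, fluid velocity, chemokine, stimulus, sources."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import flowtaxis as ft
from flowtaxis import closures
from flowtaxis.exceptions import SingularMixtureError

finite_s = st.floats(min_value=-50, max_value=50, allow_nan=False)


class TestCarmanKozeny:
    def test_values(self):
        assert ft.carman_kozeny(0.5) == pytest.approx(0.5)
        assert ft.carman_kozeny(0.1) == pytest.approx(72.9)
        assert ft.carman_kozeny(1 - 1e-9) < 1e-17  # g -> 0 toward close packing

    def test_strictly_decreasing(self):
        phi = np.linspace(0.01, 0.99, 200)
        assert np.all(np.diff(ft.carman_kozeny(phi)) < 0)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1, 1.5])
    def test_domain(self, bad):
        with pytest.raises(ValueError):
            ft.carman_kozeny(bad)


class TestFluidVelocity:
    def test_far_field_and_half_packed(self):
        assert ft.fluid_velocity(0.0) == 1.0
        assert ft.fluid_velocity(0.5) == 2.0

    def test_monotone_and_singular(self):
        phi = np.linspace(0.0, 0.9, 100)
        assert np.all(np.diff(ft.fluid_velocity(phi)) > 0)
        with pytest.raises(SingularMixtureError):
            ft.fluid_velocity(np.array([0.2, 1.0]))


class TestChemokineProfile:
    def test_no_cells_no_chemokine(self):
        g = ft.Grid1D(X=10.0, N=101)
        assert np.all(ft.chemokine_profile(np.zeros(g.N), g, Da=0.7) == 0.0)

    def test_left_boundary_zero_and_monotone(self):
        g = ft.Grid1D(X=10.0, N=401)
        phi = 0.3 * np.exp(-g.x**2)
        a = ft.chemokine_profile(phi, g, Da=2.0)
        assert a[0] == 0.0
        assert np.all(np.diff(a) >= 0)
        assert np.all((a >= 0) & (a < 1))

    def test_gaussian_closed_form(self):
        # total secreted mass of a Gaussian layer: integral phi = phi_bar sqrt(pi)
        g = ft.Grid1D(X=20.0, N=4001)
        phi = 0.2 * np.exp(-g.x**2)
        a = ft.chemokine_profile(phi, g, Da=0.5)
        expected = 1.0 - math.exp(-0.5 * 0.2 * math.sqrt(math.pi))
        assert a[-1] == pytest.approx(expected, rel=1e-8)
        assert expected == pytest.approx(0.1624, abs=5e-5)

    def test_negative_da_rejected(self):
        g = ft.Grid1D(X=5.0, N=51)
        with pytest.raises(ValueError):
            ft.chemokine_profile(np.zeros(g.N), g, Da=-1.0)


class TestStimulusProfile:
    def test_no_cues_no_stimulus(self):
        g = ft.Grid1D(X=10.0, N=201)
        p = ft.NondimParams(phi_bar=0.2, Da=0.5, K=0.0, M=0.0)
        phi = 0.2 * np.exp(-g.x**2)
        assert np.all(ft.stimulus_profile(phi, g, p) == 0.0)

    def test_uniform_tensotaxis(self):
        g = ft.Grid1D(X=10.0, N=201)
        p = ft.NondimParams(phi_bar=0.3, Da=0.5, K=10.0, M=0.0)
        phi = np.full(g.N, 0.3)
        s = ft.stimulus_profile(phi, g, p)
        assert s == pytest.approx(-10.0 * 0.09 / (0.7**4))

    def test_tenso_chemo_decomposition_is_exact(self):
        g = ft.Grid1D(X=15.0, N=301)
        phi = 0.35 * np.exp(-g.x**2)
        p = ft.NondimParams(phi_bar=0.35, Da=1.3, K=7.0, M=4.0)
        s = ft.stimulus_profile(phi, g, p)
        s_t = ft.stimulus_profile(phi, g, ft.NondimParams(0.35, 1.3, K=7.0, M=0.0))
        s_c = ft.stimulus_profile(phi, g, ft.NondimParams(0.35, 1.3, K=0.0, M=4.0))
        np.testing.assert_array_equal(s, s_t + s_c)
        assert np.all(s_t <= 0) and np.all(s_c >= 0)

    def test_matches_origin_asymptotics_at_t0(self):
        g = ft.Grid1D(X=30.0, N=12001)
        p = ft.NondimParams(phi_bar=0.2, Da=0.5)
        phi = p.phi_bar * np.exp(-g.x**2)
        s = ft.stimulus_profile(phi, g, p)
        s0 = ft.stimulus_at_origin(0.0, p.phi_bar, p.Da, p.Pec, p.K, p.M)
        assert s[g.center_index] == pytest.approx(s0, rel=1e-6)

    def test_chemotactic_integral_bounded_by_M(self):
        # integral of the chemotactic term = M (1 - exp(-Da * total mass)) <= M
        g = ft.Grid1D(X=20.0, N=4001)
        p = ft.NondimParams(phi_bar=0.4, Da=2.0, K=0.0, M=10.0)
        phi = 0.4 * np.exp(-g.x**2)
        s_c = ft.stimulus_profile(phi, g, p)
        total = np.trapezoid(s_c, dx=g.dx)
        mass = np.trapezoid(phi, dx=g.dx)
        expected = p.M * (1.0 - math.exp(-p.Da * mass))
        assert total == pytest.approx(expected, rel=1e-5)
        assert total <= p.M

    def test_singular_phi_raises(self):
        g = ft.Grid1D(X=5.0, N=51)
        p = ft.NondimParams(phi_bar=0.2, Da=0.5)
        with pytest.raises(SingularMixtureError):
            ft.stimulus_profile(np.full(g.N, 1.0), g, p)


class TestSourceFunctions:
    def test_langevin_values(self):
        assert ft.flux_source(0.0) == 0.0
        # coth(1) - 1 to double precision
        assert ft.flux_source(1.0) == pytest.approx(0.31303528549933130, rel=1e-14)
        assert ft.flux_source(1e3) == pytest.approx(1.0, abs=2e-3)

    @settings(max_examples=100, deadline=None)
    @given(s=finite_s)
    def test_langevin_odd_and_bounded(self, s):
        G = ft.flux_source(s)
        assert ft.flux_source(-s) == pytest.approx(-G, rel=1e-12, abs=1e-15)
        assert abs(G) < 1.0

    def test_density_source(self):
        assert ft.diff_density_source(0.0) == 0.0
        assert ft.diff_density_source(40.0) == pytest.approx(1.0, abs=1e-12)
        s = np.linspace(-5, 5, 11)
        np.testing.assert_allclose(
            ft.diff_density_source(s), np.tanh(s / 2.0), rtol=1e-14
        )

    def test_flux_split_range_and_parity(self):
        assert ft.diff_flux_source(0.0) == 0.5
        assert ft.diff_flux_source(200.0) == pytest.approx(1.0, abs=1e-2)
        s = np.linspace(-30, 30, 301)
        f = ft.diff_flux_source(s)
        np.testing.assert_allclose(f, f[::-1], rtol=1e-13)  # even function
        assert np.all((f >= 0.5) & (f < 1.0))

    @pytest.mark.parametrize(
        "func, series, exact",
        [
            (
                ft.flux_source,
                lambda s: s / 3 - s**3 / 45 + 2 * s**5 / 945,
                lambda s: 1 / math.tanh(s) - 1 / s,
            ),
            (
                ft.diff_flux_source,
                lambda s: 0.5 + s**2 / 24 - s**4 / 240,
                lambda s: 1 - math.tanh(s / 2) / s,
            ),
        ],
        ids=["flux_source", "diff_flux_source"],
    )
    def test_series_branch_continuity(self, func, series, exact):
        """Series and closed-form branches agree to >=10 digits at the switch."""
        s = closures.SERIES_THRESHOLD
        assert series(s) == pytest.approx(exact(s), rel=1e-10)
        # both sides of the switch agree with both formulas
        assert func(s * (1 - 1e-12)) == pytest.approx(exact(s), rel=1e-9)
        assert func(s * (1 + 1e-12)) == pytest.approx(series(s), rel=1e-9)

    def test_langevin_series_matches_quadrature_near_zero(self):
        # independent check of the small-s branch against the kernel moment
        from flowtaxis import kinetic_moments as km

        for s in (1e-5, 5e-5, 1e-4, 2e-4):
            assert ft.flux_source(s) == pytest.approx(
                km.mean_orientation(s), rel=1e-10, abs=1e-16
            )
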