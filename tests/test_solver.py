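"""Four-field PDE solver: initialization, stepping, conservation, limits."""

import math

import numpy as np
import pytest

import flowtaxis as ft
from flowtaxis.exceptions import BlowUpError, SingularMixtureError
from flowtaxis.solver import _Stepper, step


class TestGrid:
    def test_symmetric_uniform_with_center_node(self):
        g = ft.Grid1D(X=30.0, N=1201)
        assert g.x[0] == -30.0 and g.x[-1] == 30.0
        assert g.x[g.center_index] == 0.0
        assert np.allclose(np.diff(g.x), g.dx)

    @pytest.mark.parametrize("kw", [{"N": 100}, {"N": 1}, {"X": 0.0}, {"X": -2.0}])
    def test_validation(self, kw):
        with pytest.raises(ValueError):
            ft.Grid1D(**{"X": 10.0, "N": 101, **kw})


class TestInitialState:
    def test_gaussian_layer_at_rest(self):
        g = ft.Grid1D(X=30.0, N=601)
        st = ft.initialize_state(g, 0.37)
        assert st.phi[g.center_index] == 0.37
        assert st.phi[0] < 1e-300  # exp(-900) underflows: far field truly empty
        for f in (st.psi, st.phi_diff, st.psi_diff):
            assert np.all(f == 0.0)
        assert st.t == 0.0

    def test_phibar_range(self):
        g = ft.Grid1D(X=10.0, N=101)
        for bad in (0.0, 1.0, -0.5):
            with pytest.raises(ValueError):
                ft.initialize_state(g, bad)


class TestStep:
    def test_first_step_is_pure_diffusion(self, small_grid):
        """With psi = 0 initially, the first phi update has no advective part."""
        p = ft.NondimParams(phi_bar=0.2, Da=0.5)
        st = ft.initialize_state(small_grid, p.phi_bar)
        new = step(st, p, small_grid, dt=0.05)
        p0 = ft.NondimParams(phi_bar=0.2, Da=0.5, K=0.0, M=0.0)
        ref = step(ft.initialize_state(small_grid, p.phi_bar), p0, small_grid, dt=0.05)
        np.testing.assert_allclose(new.phi, ref.phi, atol=1e-15)
        assert np.max(np.abs(new.psi)) > 0.0  # flux has started responding

    def test_single_step_conserves_mass(self, small_grid):
        p = ft.NondimParams(phi_bar=0.3, Da=0.5)
        st = ft.initialize_state(small_grid, p.phi_bar)
        new = step(st, p, small_grid, dt=0.05)
        m0 = np.trapezoid(st.phi, dx=small_grid.dx)
        m1 = np.trapezoid(new.phi, dx=small_grid.dx)
        assert m1 == pytest.approx(m0, rel=1e-12)

    def test_zero_stimulus_keeps_zero_flux(self, small_grid):
        p = ft.NondimParams(phi_bar=0.3, Da=0.5, K=0.0, M=0.0)
        st = ft.initialize_state(small_grid, p.phi_bar)
        for _ in range(20):
            st = step(st, p, small_grid, dt=0.05)
        assert np.all(st.psi == 0.0)

    def test_singular_mixture_guard(self, small_grid):
        p = ft.NondimParams(phi_bar=0.5, Da=0.5)
        st = ft.initialize_state(small_grid, 0.5)
        st.phi = np.full(small_grid.N, 0.96)
        with pytest.raises(SingularMixtureError):
            step(st, p, small_grid, dt=0.01)

    def test_unstable_dt_blows_up(self):
        g = ft.Grid1D(X=10.0, N=101)
        p = ft.NondimParams(phi_bar=0.3, Da=0.5, T=10.0)
        with pytest.warns(UserWarning, match="stability"):
            with pytest.raises(BlowUpError):
                ft.run(p, grid=g, dt=30.0, t_end=60000.0, check_boundary=False)


class TestDiffusiveLimit:
    def test_matches_heat_kernel(self):
        """K = M = 0 reduces to pure diffusion of the Gaussian layer."""
        g = ft.Grid1D(X=15.0, N=301)
        p = ft.NondimParams(phi_bar=0.5, Da=0.5, K=0.0, M=0.0)
        traj = ft.run(p, grid=g, dt=0.05, output_times=[0.0, 100.0])
        exact = ft.diffusive_phi(g.x, 100.0, 0.5, p.Pec)
        assert np.max(np.abs(traj.state_at(100.0).phi - exact)) < 5e-4
        assert traj.mass_drift < 1e-9

    def test_second_order_spatial_convergence(self):
        p = ft.NondimParams(phi_bar=0.5, Da=0.5, K=0.0, M=0.0)
        errs = []
        for N in (151, 301):
            g = ft.Grid1D(X=15.0, N=N)
            traj = ft.run(p, grid=g, dt=0.01, output_times=[0.0, 20.0])
            exact = ft.diffusive_phi(g.x, 20.0, 0.5, p.Pec)
            errs.append(np.max(np.abs(traj.state_at(20.0).phi - exact)))
        order = math.log2(errs[0] / errs[1])
        assert 1.7 < order < 2.3


class TestSchemeCrossCheck:
    def test_explicit_and_semi_implicit_converge_together(self):
        """The splitting difference between schemes shrinks as O(dt)."""
        g = ft.Grid1D(X=15.0, N=301)
        p = ft.NondimParams(phi_bar=0.2, Da=0.5)
        diffs = []
        for dt in (0.2, 0.1):
            runs = {
                sch: ft.run(p, grid=g, dt=dt, output_times=[0.0, 50.0], scheme=sch)
                for sch in ("semi-implicit", "explicit")
            }
            diffs.append(
                np.max(
                    np.abs(
                        runs["semi-implicit"].state_at(50.0).phi
                        - runs["explicit"].state_at(50.0).phi
                    )
                )
            )
        assert diffs[1] < 0.75 * diffs[0]
        assert diffs[1] < 1e-4


class TestRunBehavior:
    def test_output_times_and_mass_log(self, small_grid):
        p = ft.NondimParams(phi_bar=0.2, Da=0.5)
        traj = ft.run(p, grid=small_grid, dt=0.05, output_times=[0.0, 5.0, 10.0])
        assert traj.times == [0.0, 5.0, 10.0]
        assert len(traj.mass) == 3
        with pytest.raises(KeyError):
            traj.state_at(7.0)

    def test_subpopulation_bounded_by_total(self, run_phibar04):
        for st in run_phibar04.states:
            assert np.all(np.abs(st.phi_diff) <= st.phi + 1e-8)
            assert np.all(st.psi_diff >= -1e-12)

    def test_narrow_domain_warns(self):
        g = ft.Grid1D(X=3.0, N=61)
        p = ft.NondimParams(phi_bar=0.2, Da=0.5)
        with pytest.warns(UserWarning, match="far-field"):
            ft.run(p, grid=g, dt=0.05, output_times=[0.0, 1.0])

    def test_domain_size_insensitivity(self):
        """Halving/doubling X at fixed dx leaves Ndiff essentially unchanged."""
        p = ft.NondimParams(phi_bar=0.2, Da=0.5)
        nd = {}
        for X, N in ((15.0, 301), (30.0, 601)):
            g = ft.Grid1D(X=X, N=N)
            traj = ft.run(p, grid=g, dt=0.05, output_times=[0.0, 200.0])
            nd[X] = ft.n_diff(traj.state_at(200.0), g)
        assert nd[15.0] == pytest.approx(nd[30.0], rel=1e-3)
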