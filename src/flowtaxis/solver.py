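"""Semi-implicit finite-difference solver for the four-field 1D system.

The macroscopic model tracks four fields on a uniform grid spanning
[-X, X] (standing in for an infinite channel):

    d(phi)/dt      = -d(psi)/dx                          + Pec^-1 d2(phi)/dx2
    d(psi)/dt      = (U/T) G(s) phi          - psi/T     + Pec^-1 d2(psi)/dx2
    d(phi_diff)/dt = -d(psi_diff)/dx
                     + [phi tanh(s/2) - phi_diff]/T      + Pec^-1 d2(phi_diff)/dx2
    d(psi_diff)/dt = (U/T)[1 - tanh(s/2)/s] phi
                                             - psi_diff/T + Pec^-1 d2(psi_diff)/dx2

where s is recomputed from phi each step through the stimulus closure.
phi is the cell volume fraction, psi the cell flux, and (phi_diff,
psi_diff) the downstream-minus-upstream sub-population density and flux --
quantities available only because the macroscopic equations were derived
from a velocity-space probability density.

Discretization: second-order central differences in x; the stiff Pec^-1
diffusion operators are advanced by backward Euler (one pre-factorized
tridiagonal solve per field pair per step), while advection, source and
relaxation terms use forward Euler.  This removes the dt ~ Pec dx^2
diffusive restriction; the remaining explicit terms only require
dt well below the relaxation time T.  A fully explicit variant is kept for
cross-checking the splitting error.

Boundary conditions: no flux at the far field, i.e. d(phi)/dx = 0 and
psi = 0 at x = +/-X, mirrored for the sub-population fields.  The stimulus
closure additionally assumes phi has decayed at the upstream boundary;
this is checked at every output time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from . import closures
from .exceptions import BlowUpError, SingularMixtureError
from .grid import Grid1D
from .scales import NondimParams

#: abort threshold on max(phi): the (1-phi)^-4 tensotactic factor makes the
#: model stiff and physically dubious near close packing
SINGULAR_PHI = 0.95
#: negative phi beyond this magnitude indicates instability, not roundoff
UNDERSHOOT_TOL = 1e-10
#: phi at the domain edges must stay below this for the far-field closure
BOUNDARY_TOL = 1e-8


@dataclass
class FieldState:
    """The four macroscopic fields at one instant."""

    t: float
    phi: np.ndarray
    psi: np.ndarray
    phi_diff: np.ndarray
    psi_diff: np.ndarray
    n_clamped: int = 0

    def copy(self) -> "FieldState":
        return FieldState(
            self.t,
            self.phi.copy(),
            self.psi.copy(),
            self.phi_diff.copy(),
            self.psi_diff.copy(),
        )


@dataclass
class Trajectory:
    """States stored at requested output times, plus run metadata."""

    params: NondimParams
    grid: Grid1D
    dt: float
    times: list[float] = field(default_factory=list)
    states: list[FieldState] = field(default_factory=list)
    mass: list[float] = field(default_factory=list)
    clamped_nodes: int = 0

    @property
    def mass_drift(self) -> float:
        """Max relative deviation of the trapezoid cell mass from its t=0 value."""
        m0 = self.mass[0]
        return max(abs(m - m0) for m in self.mass) / m0

    def state_at(self, t: float) -> FieldState:
        for tt, st in zip(self.times, self.states):
            if abs(tt - t) <= 1e-9 * max(1.0, abs(t)):
                return st
        raise KeyError(f"no stored state at t={t}; have {self.times}")


def initialize_state(grid: Grid1D, phi_bar: float) -> FieldState:
    """Gaussian cell layer phi = phi_bar exp(-x^2), everything else at rest.

    The zero initial flux and sub-population fields correspond to an
    initially isotropic orientation distribution: no cell has yet responded
    to the stimulus.
    """
    if not 0.0 < phi_bar < 1.0:
        raise ValueError(f"phi_bar must lie in (0, 1), got {phi_bar}")
    phi = phi_bar * np.exp(-grid.x**2)
    zero = np.zeros_like(phi)
    return FieldState(0.0, phi, zero.copy(), zero.copy(), zero.copy())


def _laplacian(grid: Grid1D, kind: str) -> sp.csc_matrix:
    """Central second-difference operator with the requested edge closure.

    'neumann' mirrors the first interior node across the edge (zero normal
    derivative); 'dirichlet' rows are replaced by identity in the implicit
    matrix so the edge value stays pinned at zero.
    """
    N, dx = grid.N, grid.dx
    main = np.full(N, -2.0)
    off = np.ones(N - 1)
    L = sp.diags([off, main, off], [-1, 0, 1], format="lil")
    if kind == "neumann":
        L[0, 1] = 2.0
        L[-1, -2] = 2.0
    elif kind == "dirichlet":
        L[0, :] = 0.0
        L[-1, :] = 0.0
    else:  # pragma: no cover
        raise ValueError(kind)
    return (L / dx**2).tocsc()


class _Stepper:
    """Pre-factorized operators for one (grid, Pec, dt) combination."""

    def __init__(self, grid: Grid1D, Pec: float, dt: float, scheme: str):
        self.grid = grid
        self.dt = dt
        self.scheme = scheme
        self.L_n = _laplacian(grid, "neumann")
        self.L_d = _laplacian(grid, "dirichlet")
        if scheme == "semi-implicit":
            I = sp.identity(grid.N, format="csc")
            self.solve_n = splu((I - (dt / Pec) * self.L_n).tocsc()).solve
            A_d = (I - (dt / Pec) * self.L_d).tolil()
            A_d[0, :] = 0.0
            A_d[0, 0] = 1.0
            A_d[-1, :] = 0.0
            A_d[-1, -1] = 1.0
            self.solve_d = splu(A_d.tocsc()).solve
        elif scheme == "explicit":
            self.nu = dt / Pec
        else:
            raise ValueError(f"unknown scheme {scheme!r}")


def _ddx(y: np.ndarray, dx: float) -> np.ndarray:
    """Second-order first derivative: central interior, one-sided edges."""
    return np.gradient(y, dx, edge_order=2)


def step(
    state: FieldState,
    params: NondimParams,
    grid: Grid1D,
    dt: float,
    _stepper: _Stepper | None = None,
) -> FieldState:
    """Advance the four-field system by one time step.

    The stimulus is evaluated from phi at the start of the step; sources,
    relaxation, and the flux-divergence advection terms are then applied
    explicitly and the diffusion operators implicitly.  Returns a new
    state; raises ``BlowUpError`` on non-finite fields or negative phi
    beyond the roundoff tolerance, ``SingularMixtureError`` if phi
    approaches close packing.
    """
    if _stepper is None:
        _stepper = _Stepper(grid, params.Pec, dt, "semi-implicit")
    p = params
    phi, psi, phid, psid = state.phi, state.psi, state.phi_diff, state.psi_diff

    s = closures.stimulus_profile(phi, grid, p)
    G = closures.flux_source(s)
    tanh_half = closures.diff_density_source(s)
    fd = closures.diff_flux_source(s)

    rhs_phi = phi + dt * (-_ddx(psi, grid.dx))
    rhs_psi = psi + dt * ((p.U / p.T) * G * phi - psi / p.T)
    rhs_phid = phid + dt * (-_ddx(psid, grid.dx) + (phi * tanh_half - phid) / p.T)
    rhs_psid = psid + dt * ((p.U / p.T) * fd * phi - psid / p.T)

    if _stepper.scheme == "semi-implicit":
        rhs_psi[0] = rhs_psi[-1] = 0.0
        rhs_psid[0] = rhs_psid[-1] = 0.0
        neu = _stepper.solve_n(np.column_stack([rhs_phi, rhs_phid]))
        dir_ = _stepper.solve_d(np.column_stack([rhs_psi, rhs_psid]))
        phi_n, phid_n = neu[:, 0], neu[:, 1]
        psi_n, psid_n = dir_[:, 0], dir_[:, 1]
    else:
        nu = _stepper.nu
        phi_n = rhs_phi + nu * (_stepper.L_n @ phi)
        phid_n = rhs_phid + nu * (_stepper.L_n @ phid)
        psi_n = rhs_psi + nu * (_stepper.L_d @ psi)
        psid_n = rhs_psid + nu * (_stepper.L_d @ psid)
        psi_n[0] = psi_n[-1] = 0.0
        psid_n[0] = psid_n[-1] = 0.0

    new = FieldState(state.t + dt, phi_n, psi_n, phid_n, psid_n)
    new.n_clamped = _validate(new, dt)
    return new


def _validate(state: FieldState, dt: float) -> int:
    """Clamp roundoff undershoots of phi; abort on instability signatures."""
    phi = state.phi
    if not (
        np.isfinite(phi).all()
        and np.isfinite(state.psi).all()
        and np.isfinite(state.phi_diff).all()
        and np.isfinite(state.psi_diff).all()
    ):
        raise BlowUpError(
            f"non-finite field at t={state.t:.6g} (dt={dt})", t=state.t, dt=dt
        )
    mn = phi.min()
    if mn < -UNDERSHOOT_TOL:
        raise BlowUpError(
            f"phi undershoot {mn:.3e} beyond roundoff tolerance at t={state.t:.6g}",
            t=state.t,
            dt=dt,
        )
    n_clamped = 0
    if mn < 0.0:
        mask = phi < 0.0
        n_clamped = int(mask.sum())
        phi[mask] = 0.0
    if phi.max() >= SINGULAR_PHI:
        raise SingularMixtureError(
            f"max phi = {phi.max():.4f} >= {SINGULAR_PHI} at t={state.t:.6g}"
        )
    return n_clamped


def stable_dt(params: NondimParams, grid: Grid1D, safety: float = 0.2) -> float:
    """Conservative bound on dt for the explicit terms of the split scheme.

    The relaxation terms require dt < 2T; advection moves the (small) flux
    fields at speeds bounded by U, requiring dt < dx/U in the worst case.
    A safety factor well below 1 covers the nonlinear stimulus coupling.
    """
    return safety * min(2.0 * params.T, grid.dx / params.U)


def run(
    params: NondimParams,
    grid: Grid1D | None = None,
    dt: float = 0.01,
    t_end: float | None = None,
    output_times=None,
    scheme: str = "semi-implicit",
    check_boundary: bool = True,
) -> Trajectory:
    """Integrate from the Gaussian initial condition, storing output states.

    ``output_times`` defaults to [0, t_end]; each requested time must be an
    integer number of steps from the previous one (dt is nudged per
    segment, re-factorizing the implicit operator, when it is not).
    """
    grid = grid or Grid1D()
    if output_times is None:
        if t_end is None:
            raise ValueError("provide t_end or output_times")
        output_times = [0.0, t_end]
    output_times = sorted(float(t) for t in output_times)
    if output_times[0] > 0.0:
        output_times = [0.0] + output_times
    if dt >= stable_dt(params, grid, safety=1.0):
        warnings.warn(
            f"dt={dt} exceeds the documented stability bound "
            f"{stable_dt(params, grid, safety=1.0):.3g}; expect blow-up",
            stacklevel=2,
        )

    traj = Trajectory(params=params, grid=grid, dt=dt)
    state = initialize_state(grid, params.phi_bar)
    steppers: dict[float, _Stepper] = {}

    def record(st: FieldState) -> None:
        traj.times.append(st.t)
        traj.states.append(st.copy())
        traj.mass.append(float(np.trapezoid(st.phi, dx=grid.dx)))
        if check_boundary:
            edge = max(st.phi[0], st.phi[-1])
            if edge > BOUNDARY_TOL:
                warnings.warn(
                    f"phi at the domain edge is {edge:.2e} > {BOUNDARY_TOL:.0e} at "
                    f"t={st.t:.6g}; enlarge X for a valid far-field closure",
                    stacklevel=3,
                )

    record(state)
    for t0, t1 in zip(output_times[:-1], output_times[1:]):
        n_steps = max(1, round((t1 - t0) / dt))
        dt_seg = (t1 - t0) / n_steps
        key = round(dt_seg, 12)
        if key not in steppers:
            steppers[key] = _Stepper(grid, params.Pec, dt_seg, scheme)
        stepper = steppers[key]
        for _ in range(n_steps):
            state = step(state, params, grid, dt_seg, _stepper=stepper)
            traj.clamped_nodes += state.n_clamped
        state.t = t1  # avoid accumulated float drift in the time stamp
        record(state)
    return traj
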