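"""Macroscopic observables computed from simulation trajectories.

The headline diagnostic is Ndiff(t), the spatial integral of the
downstream-minus-upstream sub-population density: its sign identifies the
globally dominant migration direction, and its zero in the initial volume
fraction defines the critical transition the phase diagram maps out.
Ndiff also satisfies an exact ODE, dNdiff/dt = R - Ndiff/T with
R = integral of phi tanh(s/2), which provides an independent consistency
check on the PDE integration.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.interpolate import interp1d

from . import closures
from .grid import Grid1D
from .solver import FieldState, Trajectory

#: nodes with phi below this are excluded from velocity ratios (0/0 far field)
VELOCITY_FLOOR = 1e-8


def average_velocity(state: FieldState, floor: float = VELOCITY_FLOOR) -> np.ndarray:
    """Average cell velocity ucavg = psi/phi, NaN-masked where phi < floor."""
    if floor <= 0:
        raise ValueError("floor must be positive")
    out = np.full_like(state.phi, np.nan)
    mask = state.phi >= floor
    out[mask] = state.psi[mask] / state.phi[mask]
    return out


def mass(state: FieldState, grid: Grid1D) -> float:
    """Total cell content, trapezoid rule."""
    return float(np.trapezoid(state.phi, dx=grid.dx))


def n_diff(state: FieldState, grid: Grid1D) -> float:
    """Net downstream-minus-upstream cell content Ndiff."""
    return float(np.trapezoid(state.phi_diff, dx=grid.dx))


def r_integral(state: FieldState, s_profile: np.ndarray, grid: Grid1D) -> float:
    """Stimulus-weighted source integral R = integral of phi tanh(s/2)."""
    return float(
        np.trapezoid(state.phi * closures.diff_density_source(s_profile), dx=grid.dx)
    )


def ndiff_from_ode(times, R_values, T: float, dense: int = 20) -> np.ndarray:
    """Integrate dNdiff/dt = (R(t) - Ndiff)/T from Ndiff(0) = 0.

    Integrating the phi_diff equation over the channel (boundary fluxes
    vanish) turns both the source and the relaxation into 1/T terms, so
    Ndiff relaxes toward the instantaneous R with time constant T.  R(t)
    is linearly interpolated between the sampled values; the ODE is solved
    with an adaptive Runge-Kutta method and evaluated back at the sample
    times.  Agreement with the directly integrated Ndiff validates the PDE
    discretization (both should converge to the same limit).
    """
    times = np.asarray(times, dtype=float)
    R = interp1d(times, np.asarray(R_values, dtype=float), kind="linear")
    sol = solve_ivp(
        lambda t, y: (R(t) - y) / T,
        (times[0], times[-1]),
        [0.0],
        t_eval=times,
        rtol=1e-10,
        atol=1e-14,
        max_step=max((times[-1] - times[0]) / dense, 1e-6),
    )
    return sol.y[0]


def _parabolic_peak(x: np.ndarray, y: np.ndarray) -> float:
    """Sub-grid peak location via a parabola through the 3 nodes at the max."""
    i = int(np.argmax(y))
    if i == 0 or i == len(y) - 1:
        return float(x[i])
    denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
    if denom == 0.0:
        return float(x[i])
    shift = 0.5 * (y[i - 1] - y[i + 1]) / denom
    return float(x[i] + shift * (x[1] - x[0]))


def _half_crossings(x: np.ndarray, y: np.ndarray, level: float) -> tuple[float, float]:
    """Leftmost/rightmost crossings of ``level`` around the peak, linear interp."""
    i_pk = int(np.argmax(y))
    left = np.nan
    for i in range(i_pk, 0, -1):
        if y[i - 1] <= level <= y[i]:
            f = (level - y[i - 1]) / (y[i] - y[i - 1])
            left = x[i - 1] + f * (x[i] - x[i - 1])
            break
    right = np.nan
    for i in range(i_pk, len(y) - 1):
        if y[i + 1] <= level <= y[i]:
            f = (y[i] - level) / (y[i] - y[i + 1])
            right = x[i] + f * (x[i + 1] - x[i])
            break
    return float(left), float(right)


def _is_unimodal(y: np.ndarray, tiny: float = 1e-12) -> bool:
    d = np.diff(y)
    signs = np.sign(d[np.abs(d) > tiny * max(y.max(), 1.0)])
    if len(signs) == 0:
        return True
    changes = int(np.sum(signs[1:] != signs[:-1]))
    return changes <= 1


def track_features(trajectory: Trajectory) -> pd.DataFrame:
    """Trajectories of the peak and the two half-maximum locations.

    Returns a frame with columns t, x_peak, x_half_left, x_half_right.
    The peak is refined to sub-grid accuracy with a local parabola, the
    half-max crossings by linear interpolation on each flank.  Warns (and
    uses the global maximum) if a profile is not unimodal.
    """
    rows = []
    x = trajectory.grid.x
    for st in trajectory.states:
        if not _is_unimodal(st.phi):
            warnings.warn(
                f"phi profile at t={st.t:.6g} is not unimodal; features refer "
                "to the global maximum",
                stacklevel=2,
            )
        xp = _parabolic_peak(x, st.phi)
        lo, hi = _half_crossings(x, st.phi, 0.5 * st.phi.max())
        rows.append((st.t, xp, lo, hi))
    return pd.DataFrame(rows, columns=["t", "x_peak", "x_half_left", "x_half_right"])


def pd_half_width(t, Pec: float) -> tuple[np.ndarray, np.ndarray]:
    """Half-maximum locations +/- sqrt(ln 2 (1 + 4 t/Pec)) for pure diffusion.

    Reference trajectory for a cell layer spreading without any directed
    motion; the peak itself stays at x = 0.
    """
    t = np.asarray(t, dtype=float)
    w = np.sqrt(np.log(2.0) * (1.0 + 4.0 * t / Pec))
    return -w, w


def timeseries(trajectory: Trajectory) -> pd.DataFrame:
    """Scalar diagnostics at every stored output time.

    Columns: t, Ndiff, R, mass, x_peak, x_half_left, x_half_right.  The
    stimulus entering R is recomputed from the stored phi profile.
    """
    grid, params = trajectory.grid, trajectory.params
    feats = track_features(trajectory)
    rows = []
    for st in trajectory.states:
        s = closures.stimulus_profile(st.phi, grid, params)
        rows.append((st.t, n_diff(st, grid), r_integral(st, s, grid), mass(st, grid)))
    out = pd.DataFrame(rows, columns=["t", "Ndiff", "R", "mass"])
    return out.merge(feats, on="t")
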