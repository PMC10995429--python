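"""Numerical critical-condition finder over full PDE simulations.

Locates the initial peak volume fraction at which the net migration
direction flips (Ndiff = 0 at a chosen evaluation time) by root finding in
phi_bar, each evaluation being a full four-field simulation.  Sweeping the
Damkohler number produces the phase-diagram curve, overlaid with its
small-stimulus asymptotic counterpart.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import asymptotics, diagnostics, solver
from .grid import Grid1D
from .scales import NondimParams

#: sweep defaults: a coarser grid and larger step than the production solver
#: settings keep a multi-point sweep tractable; the reported roots change by
#: well under the root tolerance on refinement
SWEEP_GRID = Grid1D(X=30.0, N=601)
SWEEP_DT = 0.02
DEFAULT_BRACKET = (0.01, 0.6)


@dataclass(frozen=True)
class CriticalResult:
    """One critical point: root, bracket used, convergence flag."""

    Da: float
    t_eval: float
    T: float
    phi_cr: float
    converged: bool
    message: str = ""


@dataclass(frozen=True)
class CriticalCurve:
    """Numeric and asymptotic critical curves over a Damkohler sweep."""

    Da_values: np.ndarray
    phi_cr_numeric: np.ndarray
    phi_cr_asymptotic: np.ndarray
    t_eval: float
    T: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "Da": self.Da_values,
                "phi_cr_numeric": self.phi_cr_numeric,
                "phi_cr_asymptotic": self.phi_cr_asymptotic,
                "t_eval": self.t_eval,
                "T": self.T,
                "converged": np.isfinite(self.phi_cr_numeric),
            }
        )


def ndiff_at(
    phi_bar: float,
    t_eval: float,
    params: NondimParams,
    grid: Grid1D = SWEEP_GRID,
    dt: float = SWEEP_DT,
) -> float:
    """Ndiff at t_eval from a full simulation seeded at phi_bar.

    Positive means net downstream (chemotaxis-dominated), negative net
    upstream (tensotaxis-dominated).
    """
    p = replace(params, phi_bar=phi_bar)
    traj = solver.run(p, grid=grid, dt=dt, output_times=[0.0, t_eval])
    return diagnostics.n_diff(traj.state_at(t_eval), grid)


def critical_phibar_numeric(
    Da: float,
    t_eval: float,
    params: NondimParams | None = None,
    bracket: tuple[float, float] = DEFAULT_BRACKET,
    xtol: float = 1e-3,
    grid: Grid1D = SWEEP_GRID,
    dt: float = SWEEP_DT,
    n_scan: int = 6,
) -> CriticalResult:
    """Root of phi_bar -> Ndiff(t_eval) by bracketed scalar iteration.

    Ndiff is positive at low seeding density (weak tensotaxis) and turns
    negative above the transition, so a coarse scan over the bracket
    locates a sign change that Brent's method then refines; each function
    evaluation is a full PDE run.  Returns an unconverged result (phi_cr =
    NaN) when no sign change exists in the bracket, meaning no transition
    occurs at this evaluation time.
    """
    base = params or NondimParams(phi_bar=0.2, Da=Da)
    if base.Da != Da:
        base = replace(base, Da=Da)

    def f(pb: float) -> float:
        return ndiff_at(pb, t_eval, base, grid=grid, dt=dt)

    lo, hi = bracket
    scan = np.linspace(lo, hi, n_scan)
    vals = []
    found = None
    for i, pb in enumerate(scan):
        vals.append(f(pb))
        if i > 0 and np.sign(vals[-1]) != np.sign(vals[-2]) and vals[-2] != 0.0:
            found = (scan[i - 1], scan[i])
            break
    if found is None:
        return CriticalResult(
            Da, t_eval, base.T, float("nan"), False,
            f"no transition at this time: Ndiff has no sign change on {bracket}",
        )
    if not (vals[-2] > 0 > vals[-1]):
        warnings.warn(
            "Ndiff sign pattern is not positive-to-negative across the bracket; "
            "the transition structure may be non-monotone",
            stacklevel=2,
        )
    root = brentq(f, *found, xtol=xtol)
    return CriticalResult(Da, t_eval, base.T, float(root), True)


def sweep_critical_curve(
    Da_list,
    t_eval: float,
    params: NondimParams | None = None,
    grid: Grid1D = SWEEP_GRID,
    dt: float = SWEEP_DT,
    bracket: tuple[float, float] = DEFAULT_BRACKET,
    xtol: float = 1e-3,
) -> CriticalCurve:
    """Critical curve phi_cr(Da) at fixed evaluation time.

    Brackets are warm-started from the previous root; per-point failures
    are recorded as NaN rather than aborting the sweep.  The asymptotic
    curve is evaluated alongside for overlay.
    """
    base = params or NondimParams(phi_bar=0.2, Da=1.0)
    Da_values = np.asarray(list(Da_list), dtype=float)
    numeric = np.full_like(Da_values, np.nan)
    asym = np.full_like(Da_values, np.nan)
    prev_root: float | None = None
    for i, Da in enumerate(Da_values):
        try:
            asym[i] = asymptotics.critical_phibar_asymptotic(
                Da, t_eval, base.Pec, base.K / base.M
            )
        except ValueError:
            pass
        brk = bracket
        if prev_root is not None:
            brk = (max(bracket[0], prev_root / 3), min(bracket[1], prev_root * 3))
        try:
            res = critical_phibar_numeric(
                Da, t_eval, replace(base, Da=Da), bracket=brk,
                xtol=xtol, grid=grid, dt=dt,
            )
            if not res.converged and brk != bracket:
                res = critical_phibar_numeric(
                    Da, t_eval, replace(base, Da=Da), bracket=bracket,
                    xtol=xtol, grid=grid, dt=dt,
                )
            if res.converged:
                numeric[i] = res.phi_cr
                prev_root = res.phi_cr
        except Exception as exc:  # per-point failure, not a sweep abort
            warnings.warn(f"critical point at Da={Da} failed: {exc}", stacklevel=2)
    return CriticalCurve(Da_values, numeric, asym, t_eval, base.T)
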