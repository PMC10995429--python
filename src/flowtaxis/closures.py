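"""Constitutive closures for the mechanochemical stimulus.

The macroscopic model is driven by a signed scalar stimulus s(x, t) that
combines two flow-induced cues:

* tensotaxis — interstitial flow dragging on the cell phase raises the
  upstream fluid pressure; with Darcy drag and the Carman-Kozeny
  permeability g(phi) = (1-phi)^3/phi^2 this yields an upstream (negative)
  contribution -K phi^2/(1-phi)^4;
* autologous chemotaxis — cells secrete a chemokine that the flow advects
  downstream; in the quasi-steady, advection-dominated limit the chemokine
  profile is a(x) = 1 - exp(-Da * cum_phi(x)) and its gradient gives a
  downstream (positive) contribution M Da phi exp(-Da cum_phi).

Velocity-space averaging of the orientation kernel then produces three
scalar source functions of s used by the four macroscopic field equations:
the Langevin function G(s) = coth s - 1/s (mean orientation, flux source),
tanh(s/2) (downstream-minus-upstream density source), and 1 - tanh(s/2)/s
(downstream-minus-upstream flux source).  Near s = 0 all three are
evaluated by truncated series to avoid catastrophic cancellation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .exceptions import SingularMixtureError
from .grid import Grid1D
from .scales import NondimParams

#: |s| below this uses the series branches of the source functions.  The
#: Langevin closed form coth(s) - 1/s subtracts two O(1/s) quantities, so
#: its relative error grows like 6*eps/s^2 (~1e-11 at the switch), while
#: the truncated series is in error by ~3 s^6/4725 (~2e-13 there): both
#: branches carry >=10 significant digits at the threshold.
SERIES_THRESHOLD = 2e-2


@dataclass(frozen=True)
class StimulusField:
    """The stimulus and its ingredients evaluated on a grid.

    ``s`` is the signed stimulus, ``a`` the chemokine concentration (scaled
    by its equilibrium value), ``uf`` the interstitial fluid velocity
    (scaled by the far-field value), and ``cum_phi`` the running integral of
    the cell volume fraction from the left (upstream) boundary.  The fluid
    pressure and the underlying stimulus potentials are analytically
    eliminated and have no separate representation.
    """

    s: np.ndarray
    a: np.ndarray
    uf: np.ndarray
    cum_phi: np.ndarray


def carman_kozeny(phi):
    """Carman-Kozeny drag factor g(phi) = (1-phi)^3/phi^2.

    Strictly decreasing on (0, 1): denser cell packing means lower
    permeability, hence more drag per unit flow and a stronger tensotactic
    cue.  Domain error outside (0, 1).
    """
    phi = np.asarray(phi, dtype=float)
    if np.any(phi <= 0) or np.any(phi >= 1):
        raise ValueError("carman_kozeny requires 0 < phi < 1")
    return (1.0 - phi) ** 3 / phi**2


def fluid_velocity(phi):
    """Interstitial fluid velocity uf = 1/(1-phi).

    Follows from incompressibility of the mixture with far-field inflow
    uf -> 1: the fluid accelerates where cells constrict the pore space.
    """
    phi = np.asarray(phi, dtype=float)
    if np.any(phi >= 1):
        raise SingularMixtureError("phi >= 1: fluid velocity is singular")
    return 1.0 / (1.0 - phi)


def cumulative_cell_mass(phi, grid: Grid1D) -> np.ndarray:
    """Running integral of phi from the left boundary, trapezoid rule.

    The left grid edge stands in for x -> -infinity, where the integral
    vanishes; validity requires phi to have decayed at the boundary.
    """
    phi = np.asarray(phi, dtype=float)
    return cumulative_trapezoid(phi, dx=grid.dx, initial=0.0)


def chemokine_profile(phi, grid: Grid1D, Da: float) -> np.ndarray:
    """Quasi-steady advected chemokine concentration a(x).

    a(x) = 1 - exp(-Da * cum_phi(x)): chemokine secreted by cells upstream
    of x has been carried to x by the flow, saturating toward the
    equilibrium concentration (a = 1) behind a dense layer.  Monotone
    nondecreasing, a = 0 at the upstream boundary.
    """
    if Da < 0:
        raise ValueError(f"Da must be nonnegative, got {Da}")
    return -np.expm1(-Da * cumulative_cell_mass(phi, grid))


def stimulus_profile(phi, grid: Grid1D, params: NondimParams) -> np.ndarray:
    """Signed stimulus s(x) = -K phi^2/(1-phi)^4 + M Da phi exp(-Da cum_phi).

    The tensotactic term is <= 0 (upstream bias), the chemotactic term
    >= 0 (downstream bias); their pointwise competition decides the local
    migration tendency.
    """
    phi = np.asarray(phi, dtype=float)
    if np.any(phi >= 1):
        raise SingularMixtureError("phi >= 1: tensotactic stimulus is singular")
    tenso = -params.K * phi**2 / (1.0 - phi) ** 4
    chemo = params.M * params.Da * phi * np.exp(
        -params.Da * cumulative_cell_mass(phi, grid)
    )
    return tenso + chemo


def evaluate_stimulus(phi, grid: Grid1D, params: NondimParams) -> StimulusField:
    """Evaluate the stimulus together with its ingredient fields."""
    phi = np.asarray(phi, dtype=float)
    cum = cumulative_cell_mass(phi, grid)
    decay = np.exp(-params.Da * cum)
    tenso = -params.K * phi**2 / (1.0 - phi) ** 4
    if np.any(phi >= 1):
        raise SingularMixtureError("phi >= 1: tensotactic stimulus is singular")
    return StimulusField(
        s=tenso + params.M * params.Da * phi * decay,
        a=1.0 - decay,
        uf=fluid_velocity(phi),
        cum_phi=cum,
    )


def flux_source(s):
    """Langevin function G(s) = coth(s) - 1/s, the cell-flux source.

    Mean orientation projection of the exponential orientation kernel: odd,
    |G| < 1, G ~ s/3 near 0 and G -> sign(s) as |s| -> infinity, so the
    directed flux source saturates at the full single-cell speed.
    """
    s = np.asarray(s, dtype=float)
    small = np.abs(s) < SERIES_THRESHOLD
    ss = np.where(small, 1.0, s)  # placeholder avoids 0/0 warnings
    with np.errstate(over="ignore"):
        exact = 1.0 / np.tanh(ss) - 1.0 / ss
    series = s / 3.0 - s**3 / 45.0 + 2.0 * s**5 / 945.0
    out = np.where(small, series, exact)
    return out if out.ndim else float(out)


def diff_density_source(s):
    """Source of the downstream-minus-upstream density: tanh(s/2).

    Hemisphere-difference of the orientation kernel: the rate at which
    reorienting cells net-switch toward the stimulus direction.  Odd,
    bounded in (-1, 1).
    """
    s = np.asarray(s, dtype=float)
    out = np.tanh(s / 2.0)
    return out if out.ndim else float(out)


def diff_flux_source(s):
    """Source of the downstream-minus-upstream flux: 1 - tanh(s/2)/s.

    Hemisphere first-moment difference of the orientation kernel.  Even in
    s, equal to 1/2 at s = 0 (an unbiased population still splits its speed
    evenly between hemispheres) and increasing to 1 as |s| -> infinity.
    """
    s = np.asarray(s, dtype=float)
    small = np.abs(s) < SERIES_THRESHOLD
    ss = np.where(small, 1.0, s)
    exact = 1.0 - np.tanh(ss / 2.0) / ss
    series = 0.5 + s**2 / 24.0 - s**4 / 240.0
    out = np.where(small, series, exact)
    return out if out.ndim else float(out)
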