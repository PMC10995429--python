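"""Small-stimulus asymptotics and the critical-condition equation.

When both the initial volume fraction and the Damkohler number are small,
the stimulus is weak (s = O(phi_bar^2, Da phi_bar) << 1) and the cell layer
spreads essentially by pure diffusion:

    phi(x, t) ~ (phi_bar / b) exp(-x^2 / b^2),   b(t) = sqrt(1 + 4 t / Pec).

At leading order the sub-population fields follow the diffusing profile,
phi_diff = -(T U / 2) d(phi)/dx and psi_diff = (U / 2) phi, so phi_diff is
antisymmetric and integrates to zero: the net migration direction is
decided by the O(s) correction concentrated near the origin, i.e. by the
sign of the stimulus at x = 0.  Setting s|x=0 = 0 yields a transcendental
equation for the critical initial volume fraction,

    (K/M) * phi_cr * exp(sqrt(pi) Da phi_cr / 2)
        / (Da * b * (1 - phi_cr / b)^4) = 1,

which depends only on K/M, Da and t/Pec.  The quartic and exponential
factors are formally subdominant in the small-(phi_bar, Da) limit but are
retained deliberately: they capture the interior maximum of phi_cr(Da)
seen in full simulations at moderate Da.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
from scipy.optimize import brentq

#: fraction of the broadening factor b used as the upper root bracket; the
#: equation has a spurious divergence at phi_bar -> b
BRACKET_FRACTION = 0.95


def broadening(t, Pec: float):
    """Diffusive broadening factor b(t) = sqrt(1 + 4 t / Pec)."""
    return np.sqrt(1.0 + 4.0 * np.asarray(t, dtype=float) / Pec)


def diffusive_phi(x, t, phi_bar: float, Pec: float):
    """Purely diffusive volume-fraction profile (heat-kernel spreading).

    Exact solution of d(phi)/dt = Pec^-1 d2(phi)/dx2 from the Gaussian
    initial layer; conserves the total content phi_bar sqrt(pi).
    """
    b = broadening(t, Pec)
    x = np.asarray(x, dtype=float)
    return phi_bar / b * np.exp(-(x**2) / b**2)


def _check_small_stimulus(phi_bar: float, Da: float, K: float, M: float) -> None:
    if max(K * phi_bar**2, M * Da * phi_bar) > 0.1:
        warnings.warn(
            "leading-order expressions requested outside the small-stimulus "
            f"regime (K phi_bar^2 = {K * phi_bar**2:.3g}, "
            f"M Da phi_bar = {M * Da * phi_bar:.3g})",
            stacklevel=3,
        )


def phidiff_leading(x, t, phi_bar, Da, Pec, T, U, K=10.0, M=10.0):
    """Leading-order downstream-minus-upstream density.

    phi_diff = -(T U / 2) d(phi)/dx with the diffusive phi: antisymmetric
    about the origin, so it carries no net migration signal.
    """
    _check_small_stimulus(phi_bar, Da, K, M)
    b = broadening(t, Pec)
    x = np.asarray(x, dtype=float)
    # d(phi)/dx = -2 x phi / b^2
    return T * U * x * diffusive_phi(x, t, phi_bar, Pec) / b**2


def psidiff_leading(x, t, phi_bar, Da, Pec, T, U, K=10.0, M=10.0):
    """Leading-order downstream-minus-upstream flux: psi_diff = U phi / 2."""
    _check_small_stimulus(phi_bar, Da, K, M)
    return 0.5 * U * diffusive_phi(x, t, phi_bar, Pec)


def stimulus_at_origin(t, phi_bar: float, Da: float, Pec: float, K: float, M: float):
    """Stimulus at the layer center for the diffusively spreading profile.

    s|x=0 = -K p^2/(1-p)^4 + M Da p exp(-sqrt(pi) Da phi_bar / 2) with
    p = phi_bar / b(t).  The chemokine attenuation factor uses the
    cumulative mass up to the origin, phi_bar sqrt(pi)/2, which diffusion
    conserves, so only the peak value decays with time.
    """
    b = broadening(t, Pec)
    p = phi_bar / b
    if np.any(p >= 1.0):
        raise ValueError("phi_bar / b >= 1: outside the physical range")
    tenso = -K * p**2 / (1.0 - p) ** 4
    chemo = M * Da * p * np.exp(-math.sqrt(math.pi) * Da * phi_bar / 2.0)
    return tenso + chemo


def _critical_residual(phi_bar: float, Da: float, b: float, K_over_M: float) -> float:
    """LHS - 1 of the critical-condition equation (monotone near the root)."""
    return (
        K_over_M
        * phi_bar
        * math.exp(math.sqrt(math.pi) * Da * phi_bar / 2.0)
        / (Da * b * (1.0 - phi_bar / b) ** 4)
        - 1.0
    )


def critical_phibar_asymptotic(
    Da: float, t: float, Pec: float = 300.0, K_over_M: float = 1.0, n_scan: int = 400
) -> float:
    """Critical initial volume fraction from the transcendental equation.

    Equivalent to the zero of ``stimulus_at_origin`` in phi_bar: below the
    root chemotaxis wins (net downstream), above it tensotaxis wins (net
    upstream).  Found by a monotone bracketing scan followed by a Brent
    solve on (0, 0.95 b); raises if no sign change exists in that range.
    """
    if Da <= 0 or K_over_M <= 0:
        raise ValueError("Da and K_over_M must be positive")
    b = float(broadening(t, Pec))
    hi = BRACKET_FRACTION * min(b, 1.0 / BRACKET_FRACTION)  # also respect phi < 1
    lo = 1e-12
    # scan upward for the first sign change (the residual is increasing near
    # the physical root but diverges at the bracket end)
    grid = np.linspace(lo, hi, n_scan)
    vals = [_critical_residual(g, Da, b, K_over_M) for g in grid]
    root_bracket = None
    for (g0, v0), (g1, v1) in zip(zip(grid[:-1], vals[:-1]), zip(grid[1:], vals[1:])):
        if v0 <= 0.0 <= v1 or v0 >= 0.0 >= v1:
            root_bracket = (g0, g1)
            break
    if root_bracket is None:
        raise ValueError(
            f"no transition in range: residual has no sign change on (0, {hi:.3g}) "
            f"for Da={Da}, t={t}, K/M={K_over_M}"
        )
    return float(
        brentq(
            _critical_residual,
            *root_bracket,
            args=(Da, b, K_over_M),
            xtol=1e-12,
            rtol=8.9e-16,
        )
    )


def critical_time_asymptotic(
    phi_bar: float, Da: float, Pec: float = 300.0, K_over_M: float = 1.0
) -> float | None:
    """Transition time implied by the critical-condition equation.

    Solves the same equation for t at fixed phi_bar.  Returns ``None``
    when the layer is already chemotaxis-dominated at t = 0 (the implied
    transition time would be negative, i.e. downstream migration prevails
    from the start).
    """
    if not 0 < phi_bar < 1:
        raise ValueError("phi_bar must lie in (0, 1)")

    def g(t: float) -> float:
        return _critical_residual(phi_bar, Da, float(broadening(t, Pec)), K_over_M)

    if g(0.0) <= 0.0:
        return None  # no physical transition: downstream from the start
    t_hi = 1.0
    while g(t_hi) > 0.0:
        t_hi *= 4.0
        if t_hi > 1e12:  # pragma: no cover - residual always decays to -1
            raise RuntimeError("failed to bracket the critical time")
    return float(brentq(g, t_hi / 4.0 if g(t_hi / 4.0) > 0 else 0.0, t_hi, xtol=1e-10))


def tenso_chemo_ratio(
    phi_bar: float, Da: float, t: float, Pec: float = 300.0, K_over_M: float = 1.0
) -> float:
    """Leading-order tensotactic-to-chemotactic magnitude ratio.

    R_TC = K phi_bar / (M Da b): linear in phi_bar, so at sufficiently low
    seeding density chemotaxis always wins and migration is downstream.
    The R_TC = 1 locus approximates the critical curve for small Da.
    """
    return K_over_M * phi_bar / (Da * float(broadening(t, Pec)))
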