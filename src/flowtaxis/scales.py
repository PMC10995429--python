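"""Dimensional scales, nondimensional parameter groups, and conversions.

The simulator itself works entirely in nondimensional variables: length is
normalized by the initial cell-layer width L*, velocity by the far-field
interstitial fluid speed Uf*, and time by L*/Uf*.  This module holds the
dimensional constants from which the seven nondimensional groups derive and
converts between the two descriptions.  All dimensional inputs are reduced
to a single internal unit system (micrometers and seconds) before any group
is formed, since literature values mix per-hour and per-second units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

from .exceptions import InsufficientDimensionalData

_SECONDS_PER = {"s": 1.0, "min": 60.0, "h": 3600.0, "day": 86400.0}


@dataclass(frozen=True)
class DimensionalScales:
    """Dimensional constants of the cell/fluid/chemokine system.

    All fields are optional: a simulation needs only the nondimensional
    groups, and each group requires only a subset of the scales.  Units are
    fixed per field (converted internally to um and s where needed):

    - ``L_star``: initial cell-layer width (um)
    - ``Uf_star``: far-field interstitial fluid speed (um/s)
    - ``Uc_star``: individual cell speed (um/h)
    - ``Dc_star``: cell random-motility diffusivity (um^2/h)
    - ``D_star``: chemokine diffusivity (um^2/s)
    - ``tau_star``: cell reorientation (relaxation) time (s)
    - ``lc_star``: cell-scale sensing length (um)
    - ``varpi_star``: tensotactic potential per unit stress
    - ``chi_star``: chemotactic potential per unit concentration
    - ``kH_star``: hydraulic conductivity (permeability / viscosity)
    - ``beta_p_star``: chemokine secretion rate
    - ``beta_d_star``: chemokine binding (consumption) rate per concentration
    - ``Vc_star``: single-cell volume
    - ``a_eq_star``: equilibrium chemokine concentration (beta_p*/beta_d*)

    ``varpi_star/kH_star`` and ``chi_star*a_eq_star`` only ever appear in the
    products forming K and M, so their units need only be mutually
    consistent such that those groups come out dimensionless.
    """

    L_star: float | None = None
    Uf_star: float | None = None
    Uc_star: float | None = None
    Dc_star: float | None = None
    D_star: float | None = None
    tau_star: float | None = None
    lc_star: float | None = None
    varpi_star: float | None = None
    chi_star: float | None = None
    kH_star: float | None = None
    beta_p_star: float | None = None
    beta_d_star: float | None = None
    Vc_star: float | None = None
    a_eq_star: float | None = None

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if v is not None and not v > 0:
                raise ValueError(f"{f.name} must be strictly positive, got {v}")
        if (
            self.a_eq_star is not None
            and self.beta_p_star is not None
            and self.beta_d_star is not None
        ):
            implied = self.beta_p_star / self.beta_d_star
            if not math.isclose(self.a_eq_star, implied, rel_tol=1e-9):
                raise ValueError(
                    "a_eq_star must equal beta_p_star/beta_d_star "
                    f"({self.a_eq_star} != {implied})"
                )

    def _require(self, group: str, *names: str) -> list[float]:
        vals = []
        for name in names:
            v = getattr(self, name)
            if v is None:
                raise InsufficientDimensionalData(
                    f"insufficient dimensional data: cannot form {group} "
                    f"(missing {name})"
                )
            vals.append(v)
        return vals

    @property
    def equilibrium_concentration(self) -> float:
        """a_eq* = beta_p*/beta_d*, from either the stored value or the rates."""
        if self.a_eq_star is not None:
            return self.a_eq_star
        (bp, bd) = self._require("a_eq", "beta_p_star", "beta_d_star")
        return bp / bd


@dataclass(frozen=True)
class NondimParams:
    """The seven nondimensional groups that fully define a simulation.

    - ``phi_bar``: initial peak cell volume fraction (0 < phi_bar < 1)
    - ``Da``: chemokine Damkohler number, L* beta_d*/(Uf* Vc*)
    - ``U``: cell-to-fluid speed ratio Uc*/Uf* (default 0.003)
    - ``Pec``: cell Peclet number Uf* L*/Dc* (default 300)
    - ``T``: relaxation-time group tau* Uf*/L* (default 10; 100 is the
      slow-reorientation alternative)
    - ``K``: tensotactic stimulus strength lc* varpi* Uf*/kH* (default 10)
    - ``M``: chemotactic stimulus strength lc* chi* a_eq*/L* (default 10)
    """

    phi_bar: float
    Da: float
    U: float = 0.003
    Pec: float = 300.0
    T: float = 10.0
    K: float = 10.0
    M: float = 10.0

    def __post_init__(self) -> None:
        if not 0.0 < self.phi_bar < 1.0:
            raise ValueError(f"phi_bar must lie in (0, 1), got {self.phi_bar}")
        for name in ("Da", "U", "Pec", "T"):
            v = getattr(self, name)
            if not v > 0:
                raise ValueError(f"{name} must be strictly positive, got {v}")
        for name in ("K", "M"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be nonnegative, got {v}")


def nondimensionalize(scales: DimensionalScales, phi_bar: float) -> NondimParams:
    """Form the nondimensional groups from dimensional scales.

    Per-hour quantities (cell speed Uc*, cell diffusivity Dc*) are converted
    to per-second before forming ratios.  ``phi_bar`` is already
    dimensionless and passes through.
    """
    (Uc, Uf) = scales._require("U", "Uc_star", "Uf_star")
    U = (Uc / 3600.0) / Uf
    (Uf, L, Dc) = scales._require("Pec", "Uf_star", "L_star", "Dc_star")
    Pec = Uf * L / (Dc / 3600.0)
    (tau, Uf, L) = scales._require("T", "tau_star", "Uf_star", "L_star")
    T = tau * Uf / L
    (L, bd, Uf, Vc) = scales._require("Da", "L_star", "beta_d_star", "Uf_star", "Vc_star")
    Da = L * bd / (Uf * Vc)
    (lc, varpi, Uf, kH) = scales._require("K", "lc_star", "varpi_star", "Uf_star", "kH_star")
    K = lc * varpi * Uf / kH
    (lc, chi, L) = scales._require("M", "lc_star", "chi_star", "L_star")
    M = lc * chi * scales.equilibrium_concentration / L
    return NondimParams(phi_bar=phi_bar, Da=Da, U=U, Pec=Pec, T=T, K=K, M=M)


def cell_peclet(scales: DimensionalScales) -> float:
    """Pec = Uf* L*/Dc*: fluid advection vs cell random motility."""
    (Uf, L, Dc) = scales._require("Pec", "Uf_star", "L_star", "Dc_star")
    return Uf * L / (Dc / 3600.0)


def chemokine_peclet(scales: DimensionalScales) -> float:
    """Pe = Uf* L*/D*: fluid advection vs chemokine diffusion.

    For physiological scales this is O(1); the chemokine profile closure
    nonetheless neglects diffusion and should be read as the purely
    advective limit (slightly overestimating the chemotactic cue).
    """
    (Uf, L, D) = scales._require("Pe", "Uf_star", "L_star", "D_star")
    return Uf * L / D


def relaxation_time(T: float, scales: DimensionalScales) -> float:
    """Dimensional relaxation time tau* = T L*/Uf* in seconds."""
    (L, Uf) = scales._require("tau", "L_star", "Uf_star")
    return T * L / Uf


def dimensional_time(t_nondim: float, scales: DimensionalScales) -> float:
    """Convert nondimensional time to seconds (time scale L*/Uf*)."""
    (L, Uf) = scales._require("time scale", "L_star", "Uf_star")
    return t_nondim * L / Uf


def format_duration(seconds: float, unit: str) -> int:
    """Express a duration in ``unit`` ('s', 'min', 'h', 'day'), round-half-up.

    Round-half-up (rather than banker's rounding) reproduces conventional
    human-readable statements such as 1000 s ~ 17 min.
    """
    if unit not in _SECONDS_PER:
        raise ValueError(f"unknown unit {unit!r}; choose from {sorted(_SECONDS_PER)}")
    value = seconds / _SECONDS_PER[unit]
    return int(math.floor(value + 0.5))
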