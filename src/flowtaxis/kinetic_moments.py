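"""Spherical-quadrature oracle for the orientation-kernel moments.

The velocity-jump process reorients cells according to an exponential
(von Mises-Fisher-like) transition probability on the unit sphere,

    F(xi) = A exp[s . (xi - eta)],    A = s / (2 pi (1 - e^(-2s))),

peaked along the stimulus direction eta with concentration |s|.  Every
closed-form source function the macroscopic model uses (the Langevin
function, tanh(s/2), 1 - tanh(s/2)/s) is a moment of F over the sphere or
over one of its hemispheres.  This module evaluates those moments by
brute-force quadrature, independently of the closed forms, so the closures
can be validated to quadrature accuracy.

With eta along x and mu = cos(theta) the azimuthal integral is analytic for
weights depending only on mu (axisymmetry), leaving a 1D Gauss-Legendre
quadrature in mu.  Weights involving the perpendicular components retain a
product quadrature with a trapezoid rule in the periodic azimuth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

FULL = "full"
DOWNSTREAM = "downstream"  # hemisphere xi_x > 0
UPSTREAM = "upstream"  # hemisphere xi_x < 0

_AXISYMMETRIC_WEIGHTS = {
    "1": lambda mu: np.ones_like(mu),
    "xi_x": lambda mu: mu,
    "xi_x2": lambda mu: mu**2,
}
# weight(mu, phi) for components needing the azimuth
_AZIMUTHAL_WEIGHTS = {
    "xi_y": lambda mu, ph: np.sqrt(1 - mu**2) * np.cos(ph),
    "xi_z": lambda mu, ph: np.sqrt(1 - mu**2) * np.sin(ph),
    "xi_y2": lambda mu, ph: (1 - mu**2) * np.cos(ph) ** 2,
    "xi_xy": lambda mu, ph: mu * np.sqrt(1 - mu**2) * np.cos(ph),
}


@dataclass(frozen=True)
class TPFSpec:
    """Orientation-kernel specification: stimulus magnitude along x.

    In the 1D channel the stimulus axis eta is fixed to the x axis; a
    negative stimulus is represented by the antisymmetric extension of the
    moments rather than by flipping eta.
    """

    s_mag: float

    def __post_init__(self) -> None:
        if self.s_mag < 0:
            raise ValueError("s_mag must be >= 0; use moment antisymmetry for s < 0")


def normalization_constant(s: float) -> float:
    """A(s) = s / (2 pi (1 - e^(-2s))), with limit 1/(4 pi) as s -> 0."""
    if s == 0.0:
        return 1.0 / (4.0 * np.pi)
    return s / (-2.0 * np.pi * np.expm1(-2.0 * s))


def tpf_value(spec: TPFSpec, mu) -> np.ndarray:
    """Kernel density at cosine-angle mu from the stimulus axis."""
    mu = np.asarray(mu, dtype=float)
    if np.any(np.abs(mu) > 1):
        raise ValueError("mu must lie in [-1, 1]")
    A = normalization_constant(spec.s_mag)
    return A * np.exp(spec.s_mag * (mu - 1.0))


def _mu_interval(hemisphere: str) -> tuple[float, float]:
    if hemisphere == FULL:
        return (-1.0, 1.0)
    if hemisphere == DOWNSTREAM:
        return (0.0, 1.0)
    if hemisphere == UPSTREAM:
        return (-1.0, 0.0)
    raise ValueError(f"unknown hemisphere {hemisphere!r}")


def quad_moment(
    spec: TPFSpec,
    weight: str = "1",
    hemisphere: str = FULL,
    n_polar: int = 256,
    n_azimuth: int = 64,
) -> float:
    """Moment of the kernel by spherical quadrature.

    ``weight`` selects the integrand factor: '1' (normalization), 'xi_x'
    (first moment along the stimulus), 'xi_x2' (second moment), or one of
    'xi_y', 'xi_z', 'xi_y2', 'xi_xy' for perpendicular components.
    ``hemisphere`` restricts mu to [0, 1] ('downstream'), [-1, 0]
    ('upstream') or the full sphere.  The integrand is smooth but sharply
    peaked at mu = 1 for large s; the default polar order resolves s up to
    ~100 to better than 1e-12.
    """
    lo, hi = _mu_interval(hemisphere)
    nodes, wts = np.polynomial.legendre.leggauss(n_polar)
    mu = 0.5 * (hi - lo) * nodes + 0.5 * (hi + lo)
    jac = 0.5 * (hi - lo)
    f = tpf_value(spec, mu)
    if weight in _AXISYMMETRIC_WEIGHTS:
        integrand = _AXISYMMETRIC_WEIGHTS[weight](mu) * f
        return float(2.0 * np.pi * jac * np.sum(wts * integrand))
    if weight in _AZIMUTHAL_WEIGHTS:
        ph = 2.0 * np.pi * np.arange(n_azimuth) / n_azimuth
        wfun = _AZIMUTHAL_WEIGHTS[weight]
        integrand = wfun(mu[:, None], ph[None, :]) * f[:, None]
        # trapezoid on the periodic azimuth == uniform sum * (2 pi / n)
        return float(jac * (2.0 * np.pi / n_azimuth) * np.sum(wts[:, None] * integrand))
    raise ValueError(f"unknown weight selector {weight!r}")


def hemisphere_density_difference(s: float, **kw) -> float:
    """Quadrature for the density split: downstream minus upstream mass.

    Closed form: tanh(s/2).
    """
    spec = TPFSpec(abs(s))
    d = quad_moment(spec, "1", DOWNSTREAM, **kw) - quad_moment(spec, "1", UPSTREAM, **kw)
    return d if s >= 0 else -d


def hemisphere_flux_difference(s: float, **kw) -> float:
    """Quadrature for the speed split: downstream minus upstream |xi_x| moment.

    Closed form: 1 - tanh(s/2)/s (even in s).
    """
    spec = TPFSpec(abs(s))
    return quad_moment(spec, "xi_x", DOWNSTREAM, **kw) - quad_moment(
        spec, "xi_x", UPSTREAM, **kw
    )


def mean_orientation(s: float, **kw) -> float:
    """Quadrature for the full first moment along the stimulus axis.

    Closed form: the Langevin function coth(s) - 1/s (odd in s).
    """
    spec = TPFSpec(abs(s))
    m = quad_moment(spec, "xi_x", FULL, **kw)
    return m if s >= 0 else -m


def second_moment_matrix(s: float, **kw) -> np.ndarray:
    """The 3x3 xi xi^T moment matrix by quadrature (eta along x).

    All entries lie in [-1, 1] for every s; off-diagonals and perpendicular
    first moments vanish by symmetry.
    """
    spec = TPFSpec(abs(s))
    xx = quad_moment(spec, "xi_x2", FULL, **kw)
    yy = quad_moment(spec, "xi_y2", FULL, **kw)
    xy = quad_moment(spec, "xi_xy", FULL, **kw)
    # by axisymmetry zz == yy and the xz / yz entries mirror xy / 0
    return np.array([[xx, xy, xy], [xy, yy, 0.0], [xy, 0.0, yy]])
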