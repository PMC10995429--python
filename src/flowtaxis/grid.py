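"""Uniform symmetric 1D grid standing in for the infinite channel."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class Grid1D:
    """Uniform grid on [-X, X], symmetric about the origin.

    The half-width ``X`` must be large compared with the initial cell-layer
    width (which is 1 in nondimensional units) so that the no-flux far-field
    conditions imposed at the grid edges do not influence the solution.
    ``N`` is kept odd so that x = 0 is a node: peak tracking and comparisons
    with the origin-stimulus asymptotics are then exact at the center.

    Parameters
    ----------
    X : float
        Half-width of the domain (nondimensional; default 30).
    N : int
        Number of nodes (odd; default 1201).
    """

    X: float = 30.0
    N: int = 1201
    x: np.ndarray = field(init=False, repr=False, compare=False)
    dx: float = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.X <= 0:
            raise ValueError(f"grid half-width must be positive, got X={self.X}")
        if self.N < 3 or self.N % 2 == 0:
            raise ValueError(f"node count must be odd and >= 3, got N={self.N}")
        x = np.linspace(-self.X, self.X, self.N)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "dx", float(x[1] - x[0]))

    @property
    def center_index(self) -> int:
        """Index of the x = 0 node."""
        return self.N // 2
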