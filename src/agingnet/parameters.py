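"""Rate parameters of the aging process.

A node flips between the healthy (0) and damaged (1) state at rates that
depend on the fraction ``f`` of its damaged neighbours:

    damage rate    = gamma0 * exp(r_plus * f)        [per year]
    recovery rate  = (gamma0 / R) * exp(-r_minus * f) [per year]

``gamma0`` sets the overall evolution rate of the network, ``R`` tunes the
asymmetry between damage and repair, and ``r_plus``/``r_minus`` control how
strongly a node's environment accelerates damage and suppresses repair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class RateParameters:
    """The four strictly positive tuning parameters (r+, r-, Gamma0, R)."""

    r_plus: float
    r_minus: float
    gamma0: float  # per year
    R: float

    def __post_init__(self) -> None:
        for name in ("r_plus", "r_minus", "gamma0", "R"):
            value = getattr(self, name)
            if not (value > 0.0 and math.isfinite(value)):
                raise ValueError(
                    f"{name}={value!r}: rate parameters must lie in (0,∞)"
                )

    # --- microscopic rates (per year), as functions of the local damage fraction

    def rate_up(self, f: float) -> float:
        """Healthy -> damaged rate at neighbour damage fraction ``f``."""
        return self.gamma0 * math.exp(self.r_plus * f)

    def rate_down(self, f: float) -> float:
        """Damaged -> healthy rate at neighbour damage fraction ``f``."""
        return self.gamma0 / self.R * math.exp(-self.r_minus * f)

    # --- scaled (dimensionless) rates used on the macroscopic time scale s = gamma0*t

    def a_plus_star(self, p):
        """Scaled damage rate exp(r_plus * p)."""
        import numpy as np

        return np.exp(self.r_plus * np.asarray(p, dtype=float))

    def a_minus_star(self, p):
        """Scaled recovery rate exp(-r_minus * p) / R."""
        import numpy as np

        return np.exp(-self.r_minus * np.asarray(p, dtype=float)) / self.R
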