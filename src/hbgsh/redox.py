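"""Half-cell redox potential of the GSH/GSSG couple.

The couple 2 GSH <-> GSSG + 2H+ + 2e- is the dominant thiol redox buffer of
the red cell.  The potential is computed in the fixed 25 degC, pH 7.0 form

    E_hc (mV) = -240 - (59.1/2) * log10([GSH]^2 / [GSSG])

with both concentrations in mol/L.  More GSH at fixed GSSG drives the
potential more negative (more reducing); the squared numerator makes E_hc
twice as sensitive to GSH as to GSSG.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["RedoxPair", "half_cell_potential", "STANDARD_POTENTIAL_MV", "NERNST_SLOPE_MV"]

#: Standard half-cell potential at 25 degC, pH 7.0 (mV).
STANDARD_POTENTIAL_MV = -240.0
#: Nernst slope per decade for the two-electron couple (mV).
NERNST_SLOPE_MV = 59.1 / 2.0


@dataclass(frozen=True)
class RedoxPair:
    """GSH and GSSG molar concentrations.

    ``temperature_C`` is informational only: the equation is the fixed
    25 degC, pH 7.0 form and is not re-scaled.
    """

    gsh_M: float
    gssg_M: float
    temperature_C: float = 25.0

    def __post_init__(self) -> None:
        if self.gsh_M <= 0 or self.gssg_M <= 0:
            raise ValueError("GSH and GSSG concentrations must be strictly positive")


def half_cell_potential(pair: RedoxPair) -> float:
    """Half-cell potential E_hc in mV for a GSH/GSSG pair."""
    return STANDARD_POTENTIAL_MV - NERNST_SLOPE_MV * math.log10(pair.gsh_M**2 / pair.gssg_M)


def half_cell_potential_arrays(gsh_M: np.ndarray, gssg_M: np.ndarray) -> np.ndarray:
    """Vectorised E_hc for per-sample columns (mol/L in, mV out)."""
    gsh = np.asarray(gsh_M, dtype=float)
    gssg = np.asarray(gssg_M, dtype=float)
    if np.any(gsh <= 0) or np.any(gssg <= 0):
        raise ValueError("GSH and GSSG concentrations must be strictly positive")
    return STANDARD_POTENTIAL_MV - NERNST_SLOPE_MV * np.log10(gsh**2 / gssg)
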