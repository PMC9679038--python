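"""Red-cell composition constants and concentration conversions.

Intracellular metabolite levels are measured per gram of hemoglobin but
reasoned about as concentrations in cell water.  The conversions here are
pure arithmetic on three cell-level constants: the mean corpuscular Hb
concentration (MCHC), the water fraction of cell volume, and the molar mass
of the Hb tetramer.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "RbcComposition",
    "DEFAULT_COMPOSITION",
    "hb_mass_to_molar",
    "per_gHb_to_cellwater",
    "cellwater_to_per_gHb",
    "max_release_capacity",
    "release_fraction",
]


@dataclass(frozen=True)
class RbcComposition:
    """Cell-level constants driving all unit conversions.

    Parameters
    ----------
    mchc_g_per_L : float
        Mean corpuscular hemoglobin concentration, g Hb per litre of
        packed cells.  Default 335 g/L.
    water_volume_fraction : float
        Fraction of cell volume that is water.  The canonical water:dry
        ratio is 0.67:0.33, but 0.68 reproduces the standard worked
        conversions (2.5 umol/g Hb -> 1.23 mmol/L cell water) exactly, so
        0.68 is the default; pass 0.67 to use the textual ratio.
    hb_molar_mass : float
        Molar mass of the Hb tetramer in g/mol.  64,000 g/mol makes
        335 g/L correspond to 5.23 mM.
    """

    mchc_g_per_L: float = 335.0
    water_volume_fraction: float = 0.68
    hb_molar_mass: float = 64_000.0

    def __post_init__(self) -> None:
        if self.mchc_g_per_L <= 0:
            raise ValueError("mchc_g_per_L must be positive")
        if not 0.0 < self.water_volume_fraction < 1.0:
            raise ValueError("water_volume_fraction must lie in (0, 1)")
        if self.hb_molar_mass <= 0:
            raise ValueError("hb_molar_mass must be positive")


DEFAULT_COMPOSITION = RbcComposition()


def hb_mass_to_molar(c_g_per_L: float, comp: RbcComposition = DEFAULT_COMPOSITION) -> float:
    """Convert a Hb mass concentration (g/L) to mM tetramer.

    335 g/L with the default molar mass gives 5.23 mM.
    """
    if c_g_per_L < 0:
        raise ValueError("Hb mass concentration must be non-negative")
    return c_g_per_L / comp.hb_molar_mass * 1000.0


def per_gHb_to_cellwater(x_umol_per_gHb: float, comp: RbcComposition = DEFAULT_COMPOSITION) -> float:
    """Convert umol per g Hb to mmol per litre of cell water.

    Multiplies by MCHC (g Hb per L cells) and divides by the water volume
    fraction; with defaults 2.5 umol/g Hb -> 1.23 mM.
    """
    if x_umol_per_gHb < 0:
        raise ValueError("amount per g Hb must be non-negative")
    return x_umol_per_gHb * comp.mchc_g_per_L / comp.water_volume_fraction / 1000.0


def cellwater_to_per_gHb(x_mM: float, comp: RbcComposition = DEFAULT_COMPOSITION) -> float:
    """Inverse of :func:`per_gHb_to_cellwater` (mM cell water -> umol/g Hb)."""
    if x_mM < 0:
        raise ValueError("concentration must be non-negative")
    return x_mM * 1000.0 * comp.water_volume_fraction / comp.mchc_g_per_L


def max_release_capacity(hb_mM: float, sites_per_tetramer: int) -> float:
    """Maximal releasable GSH (mM) for a given Hb concentration.

    With two releasable sites per tetramer and 5.23 mM Hb the capacity is
    10.46 mM (~10.5 mM).
    """
    if hb_mM < 0:
        raise ValueError("Hb concentration must be non-negative")
    if sites_per_tetramer < 0 or int(sites_per_tetramer) != sites_per_tetramer:
        raise ValueError("sites_per_tetramer must be a non-negative integer")
    return hb_mM * sites_per_tetramer


def release_fraction(released_mM: float, capacity_mM: float) -> float:
    """Released GSH as a percentage of the maximal storage capacity."""
    if capacity_mM <= 0:
        raise ValueError("capacity must be strictly positive")
    if released_mM < 0:
        raise ValueError("released amount must be non-negative")
    return 100.0 * released_mM / capacity_mM
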