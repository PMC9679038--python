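"""One-set-of-sites isothermal titration calorimetry: simulation and fitting.

The forward model is the standard single-site-class isotherm for a
perfusion (overfill) cell: after injection i the cumulative displaced
volume dV_i dilutes the macromolecule and accumulates ligand as

    M_i = M0 * (1 - dV_i/2V0) / (1 + dV_i/2V0)
    X_i = X0 * (dV_i/V0)     / (1 + dV_i/2V0)

and the cumulative heat is

    Q_i = (N * M_i * dH * V0 / 2) * [B_i - sqrt(B_i^2 - 4 X_i/(N M_i))],
    B_i = 1 + X_i/(N M_i) + 1/(N Ka M_i)

with the per-injection (measured) heat corrected for the displaced volume:

    dQ_i = Q_i - Q_{i-1} + (v_i/V0) * (Q_i + Q_{i-1}) / 2.

Fitting recovers (N, Ka, dH) by nonlinear least squares; the Gibbs energy
and entropy follow from dG = -RT ln Ka = dH - T dS.  Heats are carried in
joules internally; ucal is accepted at I/O with 1 cal = 4.184 J.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize

__all__ = [
    "R_GAS",
    "CAL_TO_J",
    "ItcProtocol",
    "ItcThermo",
    "ItcTrace",
    "ItcFitError",
    "simulate_trace",
    "fit_one_site",
    "thermo_decompose",
]

R_GAS = 8.314462618  # J / (mol K)
CAL_TO_J = 4.184


class ItcFitError(RuntimeError):
    """Raised when a titration cannot support a one-site fit."""


@dataclass(frozen=True)
class ItcProtocol:
    """Titration geometry and concentrations.

    Defaults follow a low-volume (iTC200-class) experiment: 2.0 uL
    injections of 4 mM ligand into a 200 uL cell holding 85 uM
    macromolecule at 25 degC.
    """

    cell_volume_uL: float = 200.0
    injection_volumes_uL: tuple = tuple([2.0] * 19)
    syringe_conc_mM: float = 4.0
    cell_conc_uM: float = 85.0
    temperature_K: float = 298.15

    def __post_init__(self) -> None:
        if self.cell_volume_uL <= 0 or self.syringe_conc_mM <= 0 or self.cell_conc_uM <= 0:
            raise ValueError("volumes and concentrations must be positive")
        if self.temperature_K <= 0:
            raise ValueError("temperature must be positive")
        if len(self.injection_volumes_uL) == 0 or any(v <= 0 for v in self.injection_volumes_uL):
            raise ValueError("injection volumes must be a non-empty positive list")


@dataclass(frozen=True)
class ItcThermo:
    """One-site thermodynamic parameter set.

    Stores the fitted triple (N, Ka, dH); Kd, dG and TdS are derived so the
    identities Kd = 1/Ka and dG = -RT ln Ka = dH - TdS hold by construction.
    """

    n_sites: float
    ka_per_M: float
    dH_kJ_per_mol: float
    temperature_K: float = 298.15

    def __post_init__(self) -> None:
        if self.n_sites <= 0:
            raise ValueError("stoichiometry must be positive")
        if self.ka_per_M <= 0:
            raise ValueError("association constant must be positive")
        if self.temperature_K <= 0:
            raise ValueError("temperature must be positive")

    @property
    def kd_M(self) -> float:
        return 1.0 / self.ka_per_M

    @property
    def dG_kJ_per_mol(self) -> float:
        return -R_GAS * self.temperature_K * math.log(self.ka_per_M) / 1000.0

    @property
    def TdS_kJ_per_mol(self) -> float:
        return self.dH_kJ_per_mol - self.dG_kJ_per_mol


@dataclass
class ItcTrace:
    """Per-injection heats and molar ratios for one titration."""

    heats_uJ: np.ndarray
    molar_ratio: np.ndarray
    unit: str = "uJ"

    def __post_init__(self) -> None:
        self.heats_uJ = np.asarray(self.heats_uJ, dtype=float)
        self.molar_ratio = np.asarray(self.molar_ratio, dtype=float)
        if self.heats_uJ.shape != self.molar_ratio.shape:
            raise ValueError("heats and molar ratios must have equal length")
        if self.unit not in ("uJ", "ucal"):
            raise ValueError("unit must be 'uJ' or 'ucal'")

    def in_uJ(self) -> np.ndarray:
        return self.heats_uJ * (CAL_TO_J if self.unit == "ucal" else 1.0)


def _cell_concentrations(protocol: ItcProtocol) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-injection (M_i, X_i, dV_i) in M, M, L after dilution."""
    v0 = protocol.cell_volume_uL * 1e-6
    vols = np.asarray(protocol.injection_volumes_uL, dtype=float) * 1e-6
    dv = np.cumsum(vols)
    m0 = protocol.cell_conc_uM * 1e-6
    x0 = protocol.syringe_conc_mM * 1e-3
    m = m0 * (1 - dv / (2 * v0)) / (1 + dv / (2 * v0))
    x = x0 * (dv / v0) / (1 + dv / (2 * v0))
    return m, x, vols


def simulate_trace(protocol: ItcProtocol, thermo: ItcThermo) -> ItcTrace:
    """Noise-free per-injection heats (uJ) under the one-site model."""
    m, x, vols = _cell_concentrations(protocol)
    v0 = protocol.cell_volume_uL * 1e-6
    dh = thermo.dH_kJ_per_mol * 1000.0  # J/mol
    n, ka = thermo.n_sites, thermo.ka_per_M

    b = 1.0 + x / (n * m) + 1.0 / (n * ka * m)
    disc = b**2 - 4.0 * x / (n * m)
    if np.any(disc < 0):  # pragma: no cover - impossible for valid inputs
        raise RuntimeError("negative discriminant in binding isotherm")
    q_cum = (n * m * dh * v0 / 2.0) * (b - np.sqrt(disc))

    q_prev = np.concatenate([[0.0], q_cum[:-1]])
    dq = q_cum - q_prev + (vols / v0) * (q_cum + q_prev) / 2.0
    return ItcTrace(heats_uJ=dq * 1e6, molar_ratio=x / m)


def _simulate_heats_uJ(params: np.ndarray, protocol: ItcProtocol, offset: float = 0.0) -> np.ndarray:
    n, log_ka, dh = params
    thermo = ItcThermo(
        n_sites=n, ka_per_M=10.0**log_ka, dH_kJ_per_mol=dh, temperature_K=protocol.temperature_K
    )
    return simulate_trace(protocol, thermo).heats_uJ + offset


@dataclass
class ItcFitResult:
    """Fitted thermodynamics plus fit diagnostics."""

    thermo: ItcThermo
    offset_uJ: float
    rmse_uJ: float
    n_injections: int
    excluded_first: bool
    warnings: list = field(default_factory=list)


def fit_one_site(
    trace: ItcTrace,
    protocol: ItcProtocol,
    fit_offset: bool = True,
    exclude_first: bool = False,
) -> ItcFitResult:
    """Fit (N, Ka, dH) to a titration by nonlinear least squares.

    Initialisation: N0 from the molar ratio at half the total cumulative
    heat, dH0 from the first-injection heat per mole injected, Ka0 = 1e5
    1/M, with a restart grid over log10 Ka0 in {3,...,8} if the first
    attempt fails to converge.  ``fit_offset`` co-fits a constant
    per-injection heat-of-dilution offset (on by default);
    ``exclude_first`` drops injection 1 from the residuals.
    """
    heats = trace.in_uJ()
    if heats.size < 8:
        raise ItcFitError("need at least 8 injections spanning the transition")
    if heats.size != len(protocol.injection_volumes_uL):
        raise ItcFitError("trace length does not match protocol injection count")
    if np.max(np.abs(heats)) < 1e-6:
        raise ItcFitError("heats are indistinguishable from zero (dH ~ 0); parameters unidentifiable")

    mask = np.ones(heats.size, dtype=bool)
    if exclude_first:
        mask[0] = False

    warnings: list[str] = []
    if np.abs(heats[: max(2, heats.size // 4)]).max() < 0.1 * np.abs(heats).max():
        warnings.append("early injections carry little heat: titration may start saturated")

    m, x, _ = _cell_concentrations(protocol)
    v0 = protocol.cell_volume_uL * 1e-6
    vols = np.asarray(protocol.injection_volumes_uL, dtype=float) * 1e-6

    # N0: molar ratio at which the cumulative heat reaches half its total.
    q_cum = np.cumsum(heats)
    half = q_cum[-1] / 2.0
    idx = int(np.argmin(np.abs(q_cum - half)))
    n0 = float(np.clip(trace.molar_ratio[idx], 0.1, 20.0))
    moles_first = protocol.syringe_conc_mM * 1e-3 * vols[0]
    dh0 = (heats[0] * 1e-6) / moles_first / 1000.0  # kJ/mol
    if dh0 == 0:
        dh0 = -1.0

    def residuals(p: np.ndarray) -> np.ndarray:
        core = p[:3]
        off = p[3] if fit_offset else 0.0
        return _simulate_heats_uJ(core, protocol, off)[mask] - heats[mask]

    scale = np.abs(heats).max()
    best = None
    for log_ka0 in [5.0, 3.0, 4.0, 6.0, 7.0, 8.0]:
        p0 = [n0, log_ka0, dh0] + ([0.0] if fit_offset else [])
        lower = [1e-3, 0.0, -1e4] + ([-scale] if fit_offset else [])
        upper = [50.0, 12.0, 1e4] + ([scale] if fit_offset else [])
        try:
            sol = optimize.least_squares(
                residuals, p0, bounds=(lower, upper), xtol=1e-14, ftol=1e-14, gtol=1e-14
            )
        except Exception:  # pragma: no cover - defensive
            continue
        if best is None or sol.cost < best.cost:
            best = sol
        if sol.cost < (1e-4 * scale) ** 2 * mask.sum():
            break
    if best is None or not best.success:
        raise ItcFitError("one-site fit failed to converge over the restart grid")

    n_fit, log_ka_fit, dh_fit = best.x[:3]
    offset = float(best.x[3]) if fit_offset else 0.0
    rmse = float(np.sqrt(2.0 * best.cost / mask.sum()))
    thermo = ItcThermo(
        n_sites=float(n_fit),
        ka_per_M=10.0 ** float(log_ka_fit),
        dH_kJ_per_mol=float(dh_fit),
        temperature_K=protocol.temperature_K,
    )
    return ItcFitResult(
        thermo=thermo,
        offset_uJ=offset,
        rmse_uJ=rmse,
        n_injections=int(mask.sum()),
        excluded_first=exclude_first,
        warnings=warnings,
    )


def thermo_decompose(ka_per_M: float, dH_kJ_per_mol: float, temperature_K: float = 298.15):
    """(dG, TdS, Kd) from an association constant and enthalpy.

    dG = -RT ln Ka (kJ/mol); TdS = dH - dG; Kd = 1/Ka (M).
    """
    if ka_per_M <= 0:
        raise ValueError("association constant must be positive")
    if temperature_K <= 0:
        raise ValueError("temperature must be positive")
    dg = -R_GAS * temperature_K * math.log(ka_per_M) / 1000.0
    return dg, dH_kJ_per_mol - dg, 1.0 / ka_per_M
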