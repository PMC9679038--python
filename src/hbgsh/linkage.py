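"""Oxygen-linked GSH buffering by hemoglobin.

The model couples three layers:

1. A two-state (MWC) description of O2 binding: every tetramer is either in
   the high-affinity R quaternary state or the low-affinity T state.  ``L``
   is the T/R equilibrium constant at zero O2, ``c = KR/KT`` the ratio of
   the per-site dissociation constants, and ``KR`` the R-state O2
   dissociation constant in mmHg.  A Hill-equation mode is provided for
   phenomenological work.  Neither parameterization is a measured quantity
   here: the defaults (L = 1.7e5, c = 0.014, KR calibrated so P50 = 26 mmHg)
   are this package's constructs, chosen to give a realistic adult O2
   equilibrium curve.

2. State-resolved GSH binding pockets: the R (oxy) conformation carries
   ``n_r`` non-covalent GSH sites per tetramer (default 4, Kd 2 uM), the T
   (deoxy) conformation ``n_t`` (default 2, Kd 17 uM).  The R->T transition
   therefore releases ``n_r - n_t`` molecules per tetramer.

3. Release bookkeeping, in two deliberately distinct variants:

   * the *stoichiometric* model - released GSH is proportional to the
     T-state fraction, ``phi * (n_r - n_t) * [Hb] * fT``, where ``phi`` is
     the mean pocket occupancy; this matches the capacity arithmetic of the
     buffering hypothesis and is the default for reproduction; and
   * the *equilibrium* model - free GSH solves the mass-balance with the
     calorimetric Kd's.  The two disagree at cellular concentrations
     (micromolar Kd's would keep millimolar GSH almost fully bound); both
     are exposed rather than silently reconciled.

Heterotropic linkage of GSH (R-stabilising) and 2,3-bisphosphoglycerate
(T-stabilising) is expressed through an apparent allosteric constant
``L_app``, from which P50 shifts follow.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "MwcParams",
    "GshLinkage",
    "BpgLinkage",
    "ThresholdFit",
    "PhiFit",
    "default_mwc_params",
    "o2_saturation",
    "r_state_fraction",
    "t_state_fraction",
    "saturation_to_pO2",
    "calibrate_KR",
    "stoichiometric_release",
    "predicted_free_gsh",
    "equilibrium_free_gsh",
    "p50_with_gsh",
    "estimate_threshold",
    "fit_phi",
]


@dataclass(frozen=True)
class MwcParams:
    """Two-state (or Hill) O2-binding parameters.

    ``mode='two_state'`` uses (L, c, KR); ``mode='hill'`` uses (p50,
    n_hill).  All pressures in mmHg.
    """

    mode: Literal["two_state", "hill"] = "two_state"
    L: float = 1.7e5
    c: float = 0.014
    KR: float = 1.0
    p50: float = 26.0
    n_hill: float = 2.7

    def __post_init__(self) -> None:
        if self.mode not in ("two_state", "hill"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.L <= 0 or self.KR <= 0 or self.p50 <= 0:
            raise ValueError("L, KR and p50 must be positive")
        if not 0.0 < self.c < 1.0:
            raise ValueError("c must lie in (0, 1)")
        if self.n_hill < 1.0:
            raise ValueError("n_hill must be >= 1")


@dataclass(frozen=True)
class GshLinkage:
    """Per-state GSH site counts, affinities and pocket occupancy.

    ``n_r``/``kd_r`` describe the oxy (R) conformation, ``n_t``/``kd_t``
    the deoxy (T) conformation; Kd's in uM.  ``phi`` is the mean fractional
    occupancy of the releasable pockets, a free parameter of the
    stoichiometric model.
    """

    n_r: int = 4
    kd_r_uM: float = 2.0
    n_t: int = 2
    kd_t_uM: float = 17.0
    phi: float = 0.18

    def __post_init__(self) -> None:
        if not (self.n_r >= self.n_t >= 0):
            raise ValueError("site counts must satisfy n_r >= n_t >= 0")
        if int(self.n_r) != self.n_r or int(self.n_t) != self.n_t:
            raise ValueError("site counts must be integers")
        if self.kd_r_uM <= 0 or self.kd_t_uM <= 0:
            raise ValueError("dissociation constants must be positive")
        if not 0.0 <= self.phi <= 1.0:
            raise ValueError("phi must lie in [0, 1]")


@dataclass(frozen=True)
class BpgLinkage:
    """2,3-BPG affinities for the two quaternary states (mM)."""

    kd_oxy_mM: float = 4.75
    kd_deoxy_mM: float = 0.1

    def __post_init__(self) -> None:
        if self.kd_oxy_mM <= 0 or self.kd_deoxy_mM <= 0:
            raise ValueError("BPG dissociation constants must be positive")


def o2_saturation(pO2, params: MwcParams):
    """Fractional O2 saturation Y at a partial pressure (mmHg).

    Two-state mode evaluates the MWC binding polynomial for a tetramer;
    Hill mode evaluates p^n / (p^n + P50^n).  Accepts scalars or arrays.
    """
    p = np.asarray(pO2, dtype=float)
    if np.any(p < 0):
        raise ValueError("pO2 must be non-negative")
    if params.mode == "hill":
        with np.errstate(divide="ignore", invalid="ignore"):
            pn = p**params.n_hill
            y = pn / (pn + params.p50**params.n_hill)
        y = np.where(p == 0, 0.0, y)
    else:
        a = p / params.KR
        ca = params.c * a
        num = a * (1 + a) ** 3 + params.L * ca * (1 + ca) ** 3
        den = (1 + a) ** 4 + params.L * (1 + ca) ** 4
        y = num / den
    return y if y.ndim else float(y)


def r_state_fraction(pO2, params: MwcParams):
    """Fraction of tetramers in the R quaternary state (two-state only)."""
    if params.mode != "two_state":
        raise ValueError("quaternary-state fractions require mode='two_state'")
    p = np.asarray(pO2, dtype=float)
    if np.any(p < 0):
        raise ValueError("pO2 must be non-negative")
    a = p / params.KR
    ca = params.c * a
    r4 = (1 + a) ** 4
    fr = r4 / (r4 + params.L * (1 + ca) ** 4)
    return fr if fr.ndim else float(fr)


def t_state_fraction(pO2, params: MwcParams):
    """Complement of :func:`r_state_fraction`."""
    fr = r_state_fraction(pO2, params)
    return 1.0 - fr


def saturation_to_pO2(S: float, params: MwcParams) -> float:
    """Invert the O2 equilibrium curve: pO2 (mmHg) at saturation S.

    Root-bracketed bisection (Brent); |Y(result) - S| < 1e-9.
    """
    if not 0.0 < S < 1.0:
        raise ValueError("saturation must lie strictly inside (0, 1)")
    hi = params.p50 if params.mode == "hill" else params.KR
    while o2_saturation(hi, params) < S:
        hi *= 2.0
        if hi > 1e12:  # pragma: no cover - unreachable for valid params
            raise RuntimeError("failed to bracket saturation")
    return float(optimize.brentq(lambda p: o2_saturation(p, params) - S, 0.0, hi, xtol=1e-12, rtol=1e-15))


def calibrate_KR(params: MwcParams, target_p50: float) -> MwcParams:
    """Choose KR so the two-state curve has the requested P50 (mmHg).

    Hill mode is returned unchanged (KR is unused there).  Uses the scaling
    Y(p; KR) = Y(p/KR; 1): solving for the half-saturation point at KR = 1
    gives KR = target_p50 / alpha50 directly.
    """
    if target_p50 <= 0:
        raise ValueError("target P50 must be positive")
    if params.mode == "hill":
        return dataclasses.replace(params, p50=target_p50)
    unit = dataclasses.replace(params, KR=1.0)
    lo, hi = 1e-9, 1.0
    while o2_saturation(hi, unit) < 0.5:
        hi *= 2.0
        if hi > 1e12:
            raise RuntimeError("calibration failed to bracket the half-saturation point")
    alpha50 = optimize.brentq(lambda p: o2_saturation(p, unit) - 0.5, lo, hi, xtol=1e-12, rtol=1e-15)
    out = dataclasses.replace(params, KR=target_p50 / alpha50, p50=target_p50)
    if abs(o2_saturation(target_p50, out) - 0.5) > 1e-6:
        raise RuntimeError("KR calibration did not converge")
    return out


def default_mwc_params(p50: float = 26.0) -> MwcParams:
    """Two-state defaults with KR calibrated to the requested P50."""
    return calibrate_KR(MwcParams(), p50)


def _fT_at_saturation(SO2: float, params: MwcParams) -> float:
    """T-state fraction at a given saturation, with exact endpoint limits."""
    if not 0.0 <= SO2 <= 1.0:
        raise ValueError("SO2 must lie in [0, 1]")
    if SO2 >= 1.0 - 1e-9:
        return 0.0  # pO2 -> infinity; R wins since c < 1
    if SO2 <= 0.0:
        return float(t_state_fraction(0.0, params))
    return float(t_state_fraction(saturation_to_pO2(SO2, params), params))


def stoichiometric_release(SO2: float, hb_mM: float, linkage: GshLinkage, params: MwcParams) -> float:
    """GSH released (mM) at saturation SO2 under the stoichiometric model.

    released = phi * (n_r - n_t) * [Hb] * fT(SO2); monotone non-increasing
    in SO2 and bounded by the storage capacity phi * (n_r - n_t) * [Hb].
    """
    if hb_mM < 0:
        raise ValueError("Hb concentration must be non-negative")
    fT = _fT_at_saturation(SO2, params)
    return linkage.phi * (linkage.n_r - linkage.n_t) * hb_mM * fT


def predicted_free_gsh(
    SO2: float,
    baseline_oxy_gsh_mM: float,
    hb_mM: float,
    linkage: GshLinkage,
    params: MwcParams,
) -> float:
    """Free GSH (mM cell water) predicted at saturation SO2.

    Baseline (fully oxygenated) free GSH plus the stoichiometric release.
    """
    return baseline_oxy_gsh_mM + stoichiometric_release(SO2, hb_mM, linkage, params)


def equilibrium_free_gsh(
    g_total_mM: float,
    hb_mM: float,
    SO2: float,
    linkage: GshLinkage,
    params: MwcParams,
) -> float:
    """Free GSH (mM) solving the state-weighted binding mass balance.

    Solves  g + hb * [fR * n_r * g/(g + Kd_r) + fT * n_t * g/(g + Kd_t)]
    = g_total  by bisection on [0, g_total] (the left side is strictly
    increasing in g).  Kd's are converted from uM to mM internally.
    """
    if g_total_mM < 0 or hb_mM < 0:
        raise ValueError("concentrations must be non-negative")
    if g_total_mM == 0 or hb_mM == 0:
        return float(g_total_mM)
    fT = _fT_at_saturation(SO2, params)
    fR = 1.0 - fT
    kd_r = linkage.kd_r_uM / 1000.0
    kd_t = linkage.kd_t_uM / 1000.0

    def residual(g: float) -> float:
        bound = hb_mM * (fR * linkage.n_r * g / (g + kd_r) + fT * linkage.n_t * g / (g + kd_t))
        return g + bound - g_total_mM

    g = optimize.brentq(residual, 0.0, g_total_mM, xtol=1e-15, rtol=1e-15)
    if abs(residual(g)) > 1e-9 * g_total_mM:  # pragma: no cover - brentq guarantee
        raise RuntimeError("mass-balance solve did not converge")
    return float(g)


def p50_with_gsh(
    g_free_mM: float,
    linkage: GshLinkage,
    params: MwcParams,
    bpg: Optional[BpgLinkage] = None,
    bpg_mM: float = 0.0,
) -> float:
    """P50 (mmHg) under heterotropic GSH (and optionally BPG) linkage.

    GSH rescales the allosteric constant to

        L_app = L * (1 + g/Kd_t)^n_t / (1 + g/Kd_r)^n_r

    which favours R (lower P50) because the R state carries more sites of
    higher affinity.  BPG multiplies L_app by
    (1 + b/Kd_deoxy)/(1 + b/Kd_oxy) for its single central-cavity site,
    favouring T (higher P50).  No GSH-BPG site competition is modelled.
    """
    if params.mode != "two_state":
        raise ValueError("P50 linkage requires mode='two_state'")
    if g_free_mM < 0 or bpg_mM < 0:
        raise ValueError("ligand concentrations must be non-negative")
    g_uM = g_free_mM * 1000.0
    l_app = (
        params.L
        * (1.0 + g_uM / linkage.kd_t_uM) ** linkage.n_t
        / (1.0 + g_uM / linkage.kd_r_uM) ** linkage.n_r
    )
    if bpg_mM > 0:
        if bpg is None:
            bpg = BpgLinkage()
        l_app *= (1.0 + bpg_mM / bpg.kd_deoxy_mM) / (1.0 + bpg_mM / bpg.kd_oxy_mM)
    shifted = dataclasses.replace(params, L=l_app)
    return saturation_to_pO2(0.5, shifted)


@dataclass(frozen=True)
class ThresholdFit:
    """Result of the flat-then-exponential threshold fit.

    ``threshold`` is None when the data carry no detectable rise (the
    exponential term is not supported by the F-style SSE comparison or its
    amplitude is non-positive).
    """

    threshold: Optional[float]
    baseline: float
    amplitude: float
    steepness: float
    sse: float
    sse_flat: float
    f_stat: float
    p_value: float
    n_points: int

    def predict(self, so2) -> np.ndarray:
        """Fitted curve evaluated at saturations (fractions)."""
        s = np.asarray(so2, dtype=float)
        if self.threshold is None:
            return np.full_like(s, self.baseline)
        rise = np.where(s < self.threshold, np.expm1(self.steepness * (self.threshold - s)), 0.0)
        return self.baseline + self.amplitude * rise


def _hinge_design(so2: np.ndarray, s_star: float, k: float) -> np.ndarray:
    rise = np.where(so2 < s_star, np.expm1(k * (s_star - so2)), 0.0)
    return np.column_stack([np.ones_like(so2), rise])


def estimate_threshold(
    so2: Sequence[float],
    gsh: Sequence[float],
    grid: Optional[np.ndarray] = None,
    k_max: float = 60.0,
    alpha: float = 0.05,
) -> ThresholdFit:
    """Estimate the deoxygenation threshold SO2* for GSH liberation.

    Fits g(S) = a for S >= S* and g(S) = a + b*(exp(k*(S* - S)) - 1)
    below, by grid search over S* (default 0.05..0.95, step 0.01) with a
    nested 1-D optimisation over k and a linear solve for (a, b).  A
    threshold is only reported when the exponential term earns its three
    extra parameters under an F-style SSE-ratio test at level ``alpha``
    and its amplitude is positive; otherwise ``threshold`` is None.

    ``so2`` are fractions in [0, 1]; ``gsh`` in any fixed unit (typically
    umol per g Hb).
    """
    s = np.asarray(so2, dtype=float)
    g = np.asarray(gsh, dtype=float)
    if s.shape != g.shape or s.ndim != 1:
        raise ValueError("so2 and gsh must be matching 1-D sequences")
    if s.size < 10:
        raise ValueError("need at least 10 points to estimate a threshold")
    if np.any((s < 0) | (s > 1)):
        raise ValueError("so2 must be fractions in [0, 1]")
    if grid is None:
        # round away arange's accumulation error so grid values are exact
        grid = np.round(np.arange(0.05, 0.95 + 1e-9, 0.01), 10)

    gbar = g.mean()
    sse_flat = float(np.sum((g - gbar) ** 2))

    best: Optional[tuple[float, float, float, np.ndarray]] = None
    for s_star in grid:
        below = s < s_star
        if below.sum() < 2 or (~below).sum() < 2:
            continue

        def sse_of_k(k: float, _s_star=s_star) -> float:
            A = _hinge_design(s, _s_star, k)
            coef, *_ = np.linalg.lstsq(A, g, rcond=None)
            r = g - A @ coef
            return float(r @ r)

        res = optimize.minimize_scalar(sse_of_k, bounds=(1e-2, k_max), method="bounded")
        k_opt = float(res.x)
        A = _hinge_design(s, s_star, k_opt)
        coef, *_ = np.linalg.lstsq(A, g, rcond=None)
        sse = float(np.sum((g - A @ coef) ** 2))
        if best is None or sse < best[0]:
            best = (sse, float(s_star), k_opt, coef)

    if best is None:  # pragma: no cover - grid always admits interior points for n >= 10
        raise RuntimeError("threshold grid search found no admissible split")
    sse, s_star, k_opt, coef = best
    a_hat, b_hat = float(coef[0]), float(coef[1])

    # F-style comparison: 3 extra parameters (S*, k, b) over the flat model.
    n = s.size
    df_extra, df_resid = 3, n - 4
    if sse <= 0:
        f_stat, p_value = math.inf, 0.0
    else:
        f_stat = ((sse_flat - sse) / df_extra) / (sse / df_resid)
        p_value = float(stats.f.sf(f_stat, df_extra, df_resid))

    # Exactly flat data leaves nothing for the exponential term to explain.
    degenerate = sse_flat <= 1e-20 * n * max(1.0, gbar**2)
    no_rise = degenerate or b_hat <= 0 or p_value >= alpha
    return ThresholdFit(
        threshold=None if no_rise else s_star,
        baseline=gbar if no_rise else a_hat,
        amplitude=0.0 if no_rise else b_hat,
        steepness=0.0 if no_rise else k_opt,
        sse=sse,
        sse_flat=sse_flat,
        f_stat=f_stat,
        p_value=p_value,
        n_points=n,
    )


@dataclass(frozen=True)
class PhiFit:
    """Pocket occupancy and baseline recovered from a release curve."""

    phi: float
    baseline_mM: float
    sse: float
    n_points: int


def fit_phi(
    so2: Sequence[float],
    gsh_mM: Sequence[float],
    hb_mM: float,
    linkage: GshLinkage,
    params: MwcParams,
) -> PhiFit:
    """Estimate (baseline, phi) of the stoichiometric release model.

    For fixed binding parameters the model is linear in (baseline, phi):
    g(S) = baseline + phi * (n_r - n_t) * hb * fT(S), so ordinary least
    squares solves it exactly; phi is clipped to [0, 1] with the baseline
    re-estimated if clipping binds.
    """
    s = np.asarray(so2, dtype=float)
    g = np.asarray(gsh_mM, dtype=float)
    if s.shape != g.shape or s.ndim != 1:
        raise ValueError("so2 and gsh must be matching 1-D sequences")
    if s.size < 5:
        raise ValueError("need at least 5 points to fit phi")
    if np.ptp(s) < 1e-12:
        raise ValueError("all SO2 values identical: phi is not identifiable")

    release_unit = np.array(
        [(linkage.n_r - linkage.n_t) * hb_mM * _fT_at_saturation(float(x), params) for x in s]
    )
    A = np.column_stack([np.ones_like(s), release_unit])
    coef, *_ = np.linalg.lstsq(A, g, rcond=None)
    baseline, phi = float(coef[0]), float(coef[1])
    if not 0.0 <= phi <= 1.0:
        phi = min(max(phi, 0.0), 1.0)
        baseline = float(np.mean(g - phi * release_unit))
    resid = g - (baseline + phi * release_unit)
    return PhiFit(phi=phi, baseline_mM=baseline, sse=float(resid @ resid), n_points=s.size)
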