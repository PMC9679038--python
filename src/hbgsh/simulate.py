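"""Synthetic data generators for every pipeline input.

Each generator is a pure function of its parameters and an integer seed,
drawing from a named pseudo-random stream (so adding a generator never
perturbs the draws of another).  What they emulate:

* ``generate_cohort`` - a high-altitude sojourn cohort: repeated sampling
  of the same subjects at sea level (SL) and at altitude (HA), with red-cell
  GSH rising from 3.4 +/- 0.65 to 4.6 +/- 0.64 umol/g Hb at altitude while
  GSSG stays flat, venous O2 saturation falls, and Hb rises.  Subject
  identity enters as a Gaussian random intercept.  SO2, GSSG and Hb level
  settings are plausible placeholders, not measured values.

* ``generate_tonometry`` - gas-controlled equilibration series of GSH
  against SO2.  The default (empirical) shape is flat at the oxygenated
  baseline above a threshold saturation and rises exponentially below it,
  reaching ~6 umol/g Hb at 20% SO2; a mechanistic mode driven by the
  two-state linkage model is available.  BSO (synthesis-blocked) series are
  distributionally identical to control; NEM (thiol-blocked) series are
  flat near zero.

* ``generate_itc`` / ``generate_standard_additions`` - instrument-level
  noise on the deterministic forward models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .composition import DEFAULT_COMPOSITION, RbcComposition, per_gHb_to_cellwater
from .itc import ItcProtocol, ItcThermo, ItcTrace, simulate_trace
from .linkage import GshLinkage, MwcParams, default_mwc_params, predicted_free_gsh
from .quantification import AdditionSeries
from .redox import half_cell_potential_arrays

__all__ = [
    "CohortDesign",
    "CohortParams",
    "TonometryScenario",
    "generate_cohort",
    "generate_tonometry",
    "generate_itc",
    "generate_standard_additions",
    "SAMPLE_TABLE_COLUMNS",
]

# Named streams: each generator owns a fixed prefix so streams never collide.
_STREAMS = {"cohort": 11, "tonometry": 12, "itc": 13, "additions": 14}

SAMPLE_TABLE_COLUMNS = [
    "subject_id",
    "day_label",
    "condition",
    "so2_percent",
    "hb_g_per_L",
    "gsh_umol_per_gHb",
    "gssg_umol_per_gHb",
    "ehc_mV",
]


def _rng(stream: str, seed: int) -> np.random.Generator:
    return np.random.default_rng([_STREAMS[stream], int(seed)])


def _truncated_normal(rng: np.random.Generator, mean, sd, size) -> np.ndarray:
    """Positive draws by redraw (not clipping), keeping the density smooth."""
    out = rng.normal(mean, sd, size=size)
    if np.isscalar(sd) and sd == 0:
        return out
    for _ in range(1000):
        bad = out <= 0
        if not bad.any():
            break
        out[bad] = rng.normal(np.broadcast_to(mean, out.shape)[bad], np.broadcast_to(sd, out.shape)[bad])
    return np.maximum(out, 1e-9)


@dataclass(frozen=True)
class CohortDesign:
    """Sampling design: subjects crossed with labelled timepoints.

    The default mirrors a seven-day sampling plan: two pre-ascent sea-level
    days, altitude days 3 and 18, and three post-descent days.
    """

    n_subjects: int = 12
    timepoints: tuple = (
        ("PRE1", "SL"),
        ("PRE2", "SL"),
        ("HA03", "HA"),
        ("HA18", "HA"),
        ("POST1", "SL"),
        ("POST7", "SL"),
        ("POST28", "SL"),
    )

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        conditions = {c for _, c in self.timepoints}
        if not {"SL", "HA"} <= conditions:
            raise ValueError("design needs at least one SL and one HA timepoint")


@dataclass(frozen=True)
class CohortParams:
    """Cohort-level means and dispersions.

    GSH means/SDs (umol/g Hb) are the anchored values 3.4 +/- 0.65 (SL) and
    4.6 +/- 0.64 (HA).  GSSG, SO2 and Hb settings are invented placeholders
    chosen for physiological plausibility (venous SO2 falling at altitude,
    Hb rising, GSSG flat) and are flagged as such.
    """

    gsh_mean_sl: float = 3.4
    gsh_sd_sl: float = 0.65
    gsh_mean_ha: float = 4.6
    gsh_sd_ha: float = 0.64
    gssg_mean: float = 0.8  # invented
    gssg_sd: float = 0.15  # invented
    so2_mean_sl: float = 70.0  # invented (venous, percent)
    so2_mean_ha: float = 45.0  # invented
    so2_sd: float = 5.0  # invented
    hb_gL_mean_sl: float = 150.0  # invented
    hb_gL_mean_ha: float = 168.0  # invented
    hb_gL_sd: float = 9.0  # invented
    subject_random_effect_sd: float = 0.3

    def __post_init__(self) -> None:
        for name in ("gsh_sd_sl", "gsh_sd_ha", "gssg_sd", "so2_sd", "hb_gL_sd", "subject_random_effect_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("gsh_mean_sl", "gsh_mean_ha", "gssg_mean", "so2_mean_sl", "so2_mean_ha",
                     "hb_gL_mean_sl", "hb_gL_mean_ha"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def generate_cohort(
    design: CohortDesign,
    params: CohortParams,
    seed: int,
    comp: RbcComposition = DEFAULT_COMPOSITION,
) -> pd.DataFrame:
    """Simulate a tidy per-sample table for the sojourn design.

    One row per subject x timepoint with GSH/GSSG (umol/g Hb), venous SO2
    (percent), Hb (g/L) and the derived E_hc (mV, computed on cell-water
    molarities).  Identical seeds give identical tables.
    """
    rng = _rng("cohort", seed)
    n, tps = design.n_subjects, design.timepoints
    subj_effect = rng.normal(0.0, params.subject_random_effect_sd, size=n)

    rows = []
    for i in range(n):
        for label, cond in tps:
            if cond == "HA":
                gsh_mu, gsh_sd = params.gsh_mean_ha, params.gsh_sd_ha
                so2_mu, hb_mu = params.so2_mean_ha, params.hb_gL_mean_ha
            else:
                gsh_mu, gsh_sd = params.gsh_mean_sl, params.gsh_sd_sl
                so2_mu, hb_mu = params.so2_mean_sl, params.hb_gL_mean_sl
            rows.append((f"S{i + 1:02d}", label, cond, gsh_mu + subj_effect[i], gsh_sd, so2_mu, hb_mu))

    frame = pd.DataFrame(rows, columns=["subject_id", "day_label", "condition", "gsh_mu", "gsh_sd", "so2_mu", "hb_mu"])
    m = len(frame)
    gsh = _truncated_normal(rng, frame["gsh_mu"].to_numpy(), frame["gsh_sd"].to_numpy(), m)
    gssg = _truncated_normal(rng, params.gssg_mean, params.gssg_sd, m)
    so2 = np.clip(rng.normal(frame["so2_mu"].to_numpy(), params.so2_sd, size=m), 1.0, 100.0)
    hb = _truncated_normal(rng, frame["hb_mu"].to_numpy(), params.hb_gL_sd, m)

    gsh_M = np.array([per_gHb_to_cellwater(v, comp) for v in gsh]) / 1000.0
    gssg_M = np.array([per_gHb_to_cellwater(v, comp) for v in gssg]) / 1000.0
    ehc = half_cell_potential_arrays(gsh_M, gssg_M)

    out = pd.DataFrame(
        {
            "subject_id": frame["subject_id"],
            "day_label": frame["day_label"],
            "condition": frame["condition"],
            "so2_percent": so2,
            "hb_g_per_L": hb,
            "gsh_umol_per_gHb": gsh,
            "gssg_umol_per_gHb": gssg,
            "ehc_mV": ehc,
        }
    )
    return out


@dataclass(frozen=True)
class TonometryScenario:
    """Settings for one tonometry (gas-equilibration) series.

    ``mode`` selects the biology: ``control`` and ``BSO`` draw from the
    same release curve (blocking de novo synthesis does not touch the
    Hb-bound pool), ``NEM`` alkylates free thiols and flattens the series
    near zero.  ``shape`` selects the curve family for control/BSO:
    ``empirical`` is the flat-then-exponential form with the threshold at
    50% SO2 and ~6 umol/g Hb at 20% SO2; ``mwc`` draws from the two-state
    linkage model (whose release tracks the T-state fraction and rises
    gradually over the whole saturation range).
    """

    mode: str = "control"
    so2_grid_percent: tuple = tuple(np.linspace(98.0, 5.0, 40).round(4))
    noise_sd: float = 0.2
    shape: str = "empirical"
    threshold_so2: float = 0.50
    steepness: float = 5.0
    baseline_umol_per_gHb: float = 2.5
    gsh_at_20pct_umol_per_gHb: float = 6.0
    nem_level_umol_per_gHb: float = 0.2
    hb_mM: float = 5.23
    phi: float = 0.18
    linkage: GshLinkage = field(default_factory=GshLinkage)
    mwc: Optional[MwcParams] = None

    def __post_init__(self) -> None:
        if self.mode not in ("control", "BSO", "NEM"):
            raise ValueError("mode must be control, BSO or NEM")
        if self.shape not in ("empirical", "mwc"):
            raise ValueError("shape must be empirical or mwc")
        grid = np.asarray(self.so2_grid_percent, dtype=float)
        if np.any((grid < 0) | (grid > 100)):
            raise ValueError("so2 grid must lie within [0, 100] percent")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0 < self.threshold_so2 < 1:
            raise ValueError("threshold_so2 is a fraction in (0, 1)")

    def clean_curve(self, comp: RbcComposition = DEFAULT_COMPOSITION) -> np.ndarray:
        """Noise-free GSH (umol/g Hb) on the scenario's SO2 grid."""
        s = np.asarray(self.so2_grid_percent, dtype=float) / 100.0
        if self.mode == "NEM":
            return np.full_like(s, self.nem_level_umol_per_gHb)
        if self.shape == "empirical":
            rise_at_20 = self.gsh_at_20pct_umol_per_gHb - self.baseline_umol_per_gHb
            b = rise_at_20 / np.expm1(self.steepness * (self.threshold_so2 - 0.20))
            rise = np.where(s < self.threshold_so2, np.expm1(self.steepness * (self.threshold_so2 - s)), 0.0)
            return self.baseline_umol_per_gHb + b * rise
        params = self.mwc if self.mwc is not None else default_mwc_params()
        linkage = GshLinkage(
            n_r=self.linkage.n_r,
            kd_r_uM=self.linkage.kd_r_uM,
            n_t=self.linkage.n_t,
            kd_t_uM=self.linkage.kd_t_uM,
            phi=self.phi,
        )
        baseline_mM = per_gHb_to_cellwater(self.baseline_umol_per_gHb, comp)
        gsh_mM = np.array(
            [predicted_free_gsh(float(x), baseline_mM, self.hb_mM, linkage, params) for x in s]
        )
        return gsh_mM * 1000.0 * comp.water_volume_fraction / comp.mchc_g_per_L


def generate_tonometry(
    scenario: TonometryScenario,
    seed: int,
    comp: RbcComposition = DEFAULT_COMPOSITION,
) -> pd.DataFrame:
    """Simulate one tonometry series (SO2 percent vs GSH umol/g Hb).

    Control and BSO consume identical draws, so the same seed yields
    byte-identical series across those modes (the BSO null effect is by
    construction).  Negative GSH values are redrawn, not clipped.
    """
    rng = _rng("tonometry", seed)
    clean = scenario.clean_curve(comp)
    if scenario.noise_sd > 0:
        gsh = _truncated_normal(rng, clean, scenario.noise_sd, clean.size)
    else:
        gsh = clean.copy()
    return pd.DataFrame(
        {
            "so2_percent": np.asarray(scenario.so2_grid_percent, dtype=float),
            "gsh_umol_per_gHb": gsh,
            "mode": scenario.mode,
        }
    )


def generate_itc(
    protocol: ItcProtocol,
    thermo: ItcThermo,
    noise_sd_uJ: float,
    seed: int,
) -> ItcTrace:
    """One-site titration heats with i.i.d. Gaussian injection noise (uJ)."""
    if noise_sd_uJ < 0:
        raise ValueError("noise_sd_uJ must be non-negative")
    trace = simulate_trace(protocol, thermo)
    if noise_sd_uJ > 0:
        rng = _rng("itc", seed)
        trace = ItcTrace(
            heats_uJ=trace.heats_uJ + rng.normal(0.0, noise_sd_uJ, size=trace.heats_uJ.size),
            molar_ratio=trace.molar_ratio,
        )
    return trace


def generate_standard_additions(
    m0_umol: float,
    slope: float,
    n: int,
    noise_sd: float,
    seed: int,
    max_added_umol: float = 2.0,
) -> AdditionSeries:
    """Linear addition series I = slope * (m0 + a) + noise.

    Additions are equally spaced from 0 to ``max_added_umol``.
    """
    if n < 3:
        raise ValueError("need at least 3 additions")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    a = np.linspace(0.0, max_added_umol, n)
    intens = slope * (m0_umol + a)
    if noise_sd > 0:
        rng = _rng("additions", seed)
        intens = intens + rng.normal(0.0, noise_sd, size=n)
    return AdditionSeries(added_umol=tuple(a), intensities=tuple(intens))
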