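"""End-to-end analysis stages over tidy sample tables.

``run_cohort_analysis`` summarises a sojourn cohort and computes four
within-subject paired contrasts (altitude vs sea level, early vs late
altitude, pre vs post, early vs late post).  This is a deliberate
simplification of a repeated-measures ANOVA with subject as a random
factor: each contrast collapses a subject's rows to means and applies a
paired t-test, which is exact for balanced designs and transparent to
audit.  P-values are reported unadjusted by default; Holm adjustment is
available.

``run_tonometry_analysis`` chains unit conversion, threshold estimation
and occupancy fitting over a tonometry series; ``run_itc_analysis`` fits
one-site thermodynamics to each titration of a batch.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .composition import DEFAULT_COMPOSITION, RbcComposition, hb_mass_to_molar, per_gHb_to_cellwater
from .itc import ItcFitError, ItcProtocol, ItcTrace, fit_one_site
from .linkage import GshLinkage, MwcParams, PhiFit, ThresholdFit, default_mwc_params, estimate_threshold, fit_phi

__all__ = [
    "CohortAnalysisError",
    "run_cohort_analysis",
    "run_tonometry_analysis",
    "run_itc_analysis",
    "permute_condition_labels",
]


class CohortAnalysisError(ValueError):
    """Raised when a cohort table cannot support the paired contrasts."""


# (name, description, selector_a, selector_b); selectors pick rows by
# condition or day-label prefix, contrast = mean(a) - mean(b) per subject.
_CONTRASTS = (
    ("HA_vs_SL", "altitude vs sea level", ("condition", "HA"), ("condition", "SL")),
    ("HA18_vs_HA03", "late vs early altitude", ("day", "HA18"), ("day", "HA03")),
    ("POST_vs_PRE", "after descent vs before ascent", ("prefix", "POST"), ("prefix", "PRE")),
    ("POST_late_vs_early", "late vs first post day", ("day", "POST28"), ("day", "POST1")),
)


def _select(sub: pd.DataFrame, how: str, key: str) -> pd.Series:
    if how == "condition":
        rows = sub[sub["condition"] == key]
    elif how == "day":
        rows = sub[sub["day_label"] == key]
    else:
        rows = sub[sub["day_label"].str.startswith(key)]
    return rows["gsh_umol_per_gHb"]


def run_cohort_analysis(
    table: pd.DataFrame,
    holm: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Condition summaries and paired within-subject contrasts.

    Returns ``(summary, contrasts)``: per-condition mean/SD of GSH, GSSG
    and E_hc, and one row per contrast with the mean within-subject
    difference, t statistic, degrees of freedom and p-value.  Subjects
    missing either arm of a contrast abort the analysis with a message
    naming them.
    """
    required = {"subject_id", "day_label", "condition", "gsh_umol_per_gHb"}
    if not required <= set(table.columns):
        raise CohortAnalysisError(f"table missing columns {sorted(required - set(table.columns))}")
    if table["subject_id"].nunique() < 2:
        raise CohortAnalysisError("need at least 2 subjects")

    value_cols = [c for c in ("gsh_umol_per_gHb", "gssg_umol_per_gHb", "ehc_mV") if c in table.columns]
    summary = (
        table.groupby("condition")[value_cols]
        .agg(["mean", "std"])
        .pipe(lambda d: d.set_axis([f"{a}_{b}" for a, b in d.columns], axis=1))
        .reset_index()
    )

    rows = []
    for name, desc, (how_a, key_a), (how_b, key_b) in _CONTRASTS:
        diffs = []
        missing = []
        for subject, sub in table.groupby("subject_id"):
            a = _select(sub, how_a, key_a)
            b = _select(sub, how_b, key_b)
            if a.empty or b.empty:
                missing.append(subject)
                continue
            diffs.append(a.mean() - b.mean())
        if missing and diffs:
            raise CohortAnalysisError(f"contrast {name}: subjects missing one arm: {missing}")
        if not diffs:
            continue  # contrast not represented in this design at all
        diffs = np.asarray(diffs)
        n = diffs.size
        sd = diffs.std(ddof=1)
        if sd <= 1e-12 * max(1.0, abs(diffs.mean())):
            t, p = (np.inf if diffs.mean() > 0 else -np.inf if diffs.mean() < 0 else 0.0), 0.0 if diffs.mean() != 0 else 1.0
        else:
            t, p = stats.ttest_rel(diffs, np.zeros(n))[:2]
        rows.append(
            {
                "contrast": name,
                "description": desc,
                "n_subjects": n,
                "mean_diff_umol_per_gHb": diffs.mean(),
                "sd_diff": sd,
                "t_stat": float(t),
                "df": n - 1,
                "p_value": float(p),
            }
        )
    contrasts = pd.DataFrame(rows)
    if holm and len(contrasts):
        order = np.argsort(contrasts["p_value"].to_numpy())
        m = len(contrasts)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * contrasts["p_value"].iloc[idx])
            adj[idx] = min(running, 1.0)
        contrasts["p_holm"] = adj
    return summary, contrasts


def permute_condition_labels(table: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Permute condition (and day) labels within each subject.

    Used to build the permutation null of the altitude contrast: the
    subject's measurements keep their values but are randomly reassigned
    to the design's timepoints.
    """
    out = table.copy()
    for _, idx in out.groupby("subject_id").groups.items():
        perm = rng.permutation(len(idx))
        out.loc[idx, ["day_label", "condition"]] = (
            out.loc[idx, ["day_label", "condition"]].to_numpy()[perm]
        )
    return out


@dataclass(frozen=True)
class TonometryResult:
    """Tidy outcome of one tonometry series analysis."""

    threshold_so2: Optional[float]
    phi: float
    baseline_umol_per_gHb: float
    baseline_mM: float
    threshold_fit: ThresholdFit
    phi_fit: PhiFit

    def as_row(self) -> dict:
        return {
            "threshold_so2": self.threshold_so2,
            "phi": self.phi,
            "baseline_umol_per_gHb": self.baseline_umol_per_gHb,
            "baseline_mM_cellwater": self.baseline_mM,
            "threshold_p_value": self.threshold_fit.p_value,
            "n_points": self.threshold_fit.n_points,
        }


def run_tonometry_analysis(
    table: pd.DataFrame,
    comp: RbcComposition = DEFAULT_COMPOSITION,
    linkage: Optional[GshLinkage] = None,
    params: Optional[MwcParams] = None,
    hb_mM: Optional[float] = None,
) -> tuple[TonometryResult, pd.DataFrame]:
    """Threshold and occupancy analysis of one (SO2, GSH) series.

    Expects columns ``so2_percent`` and ``gsh_umol_per_gHb``.  Converts to
    fractions and cell-water molarity, estimates the liberation threshold
    on the per-gHb scale, fits (baseline, phi) on the molar scale, and
    returns the tidy result plus a fitted-curve table.
    """
    for col in ("so2_percent", "gsh_umol_per_gHb"):
        if col not in table.columns:
            raise ValueError(f"tonometry table missing column {col!r}")
    if linkage is None:
        linkage = GshLinkage()
    if params is None:
        params = default_mwc_params()
    if hb_mM is None:
        hb_mM = hb_mass_to_molar(comp.mchc_g_per_L, comp)

    s = table["so2_percent"].to_numpy(dtype=float) / 100.0
    g_per_ghb = table["gsh_umol_per_gHb"].to_numpy(dtype=float)
    g_mM = np.array([per_gHb_to_cellwater(v, comp) for v in g_per_ghb])

    tfit = estimate_threshold(s, g_per_ghb)
    pfit = fit_phi(s, g_mM, hb_mM, linkage, params)
    result = TonometryResult(
        threshold_so2=tfit.threshold,
        phi=pfit.phi,
        baseline_umol_per_gHb=(
            tfit.baseline if tfit.threshold is not None else float(np.mean(g_per_ghb))
        ),
        baseline_mM=pfit.baseline_mM,
        threshold_fit=tfit,
        phi_fit=pfit,
    )
    curve = pd.DataFrame(
        {
            "so2_percent": table["so2_percent"].to_numpy(dtype=float),
            "gsh_umol_per_gHb": g_per_ghb,
            "fitted_umol_per_gHb": tfit.predict(s),
        }
    )
    return result, curve


def run_itc_analysis(
    traces: Iterable[ItcTrace],
    protocol: ItcProtocol,
    labels: Optional[Sequence[str]] = None,
    fit_offset: bool = True,
) -> pd.DataFrame:
    """Fit one-site thermodynamics to each titration of a batch.

    Returns one row per trace (order preserved) with N, Ka, Kd, dH, dG,
    TdS and fit diagnostics.  A trace that cannot be fitted contributes a
    row with ``fit_ok = False`` and the failure message rather than a
    silent wrong answer.
    """
    rows = []
    traces = list(traces)
    if labels is None:
        labels = [f"trace{i + 1}" for i in range(len(traces))]
    for label, trace in zip(labels, traces):
        try:
            res = fit_one_site(trace, protocol, fit_offset=fit_offset)
            t = res.thermo
            rows.append(
                {
                    "label": label,
                    "fit_ok": True,
                    "n_sites": t.n_sites,
                    "ka_per_M": t.ka_per_M,
                    "kd_uM": t.kd_M * 1e6,
                    "dH_kJ_per_mol": t.dH_kJ_per_mol,
                    "dG_kJ_per_mol": t.dG_kJ_per_mol,
                    "TdS_kJ_per_mol": t.TdS_kJ_per_mol,
                    "offset_uJ": res.offset_uJ,
                    "rmse_uJ": res.rmse_uJ,
                    "message": "; ".join(res.warnings),
                }
            )
        except ItcFitError as err:
            rows.append(
                {
                    "label": label,
                    "fit_ok": False,
                    "n_sites": np.nan,
                    "ka_per_M": np.nan,
                    "kd_uM": np.nan,
                    "dH_kJ_per_mol": np.nan,
                    "dG_kJ_per_mol": np.nan,
                    "TdS_kJ_per_mol": np.nan,
                    "offset_uJ": np.nan,
                    "rmse_uJ": np.nan,
                    "message": str(err),
                }
            )
    return pd.DataFrame(rows)
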