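"""Desk-scale arithmetic: buffering capacity, release fraction, P50 linkage.

No data files needed.  Chains the unit conversions to the storage-capacity
bookkeeping (how much GSH can 5.23 mM Hb hold and what fraction of it does
a drop to 20% SO2 liberate), quantifies the standard-additions readout of
the simulated series, and tabulates the P50 shifts the heterotropic model
predicts for GSH (left-shift) and BPG (right-shift).
"""

from pathlib import Path

import pandas as pd

from hbgsh.composition import (
    RbcComposition,
    hb_mass_to_molar,
    max_release_capacity,
    per_gHb_to_cellwater,
    release_fraction,
)
from hbgsh.linkage import GshLinkage, default_mwc_params, p50_with_gsh
from hbgsh.quantification import AdditionSeries, standard_additions

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    comp = RbcComposition()
    hb = hb_mass_to_molar(335.0, comp)
    low = per_gHb_to_cellwater(2.5, comp)
    high = per_gHb_to_cellwater(6.0, comp)
    cap = max_release_capacity(hb, 2)
    released = high - low
    frac = release_fraction(released, cap)

    print("Capacity arithmetic (defaults: MCHC 335 g/L, water fraction 0.68):")
    print(f"  Hb concentration        : {hb:.2f} mM")
    print(f"  GSH, fully oxygenated   : 2.5 umol/g Hb = {low:.2f} mM cell water")
    print(f"  GSH, 20% SO2            : 6.0 umol/g Hb = {high:.2f} mM cell water")
    print(f"  liberated on descent    : {released:.2f} mM")
    print(f"  2-site storage capacity : {cap:.1f} mM")
    print(f"  fraction of capacity    : {frac:.1f}%")

    table = pd.read_csv(ROOT / "data" / "standard_additions.csv")
    series = AdditionSeries(
        added_umol=tuple(table["added_umol"]), intensities=tuple(table["intensity"])
    )
    q = standard_additions(series)
    print(f"\nStandard additions on the simulated series: "
          f"m0 = {q.m0_umol:.2f} +/- {q.se_umol:.2f} umol (truth 1.8)")

    params = default_mwc_params()
    linkage = GshLinkage()
    rows = []
    for gsh_mM, bpg_mM in [(0.0, 0.0), (0.5, 0.0), (5.0, 0.0), (0.0, 2.0), (5.0, 2.0)]:
        rows.append(
            {
                "gsh_mM": gsh_mM,
                "bpg_mM": bpg_mM,
                "p50_mmHg": round(p50_with_gsh(gsh_mM, linkage, params, bpg_mM=bpg_mM), 2),
            }
        )
    p50s = pd.DataFrame(rows)
    p50s.to_csv(ROOT / "p50_linkage.csv", index=False)
    print("\nP50 under heterotropic linkage (baseline 26 mmHg):")
    print(p50s.to_string(index=False))
    print(
        "GSH left-shifts the curve (higher O2 affinity); BPG right-shifts it.\n"
        "Note the GSH shift saturates already below 0.5 mM: with micromolar\n"
        "calorimetric Kd's the model overstates the modest shift seen in\n"
        "hemolysates, the same affinity inconsistency the equilibrium release\n"
        "model exposes (see docs/methods.md)."
    )


if __name__ == "__main__":
    main()
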