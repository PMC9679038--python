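"""Generate every synthetic dataset the downstream analyses consume.

Writes, under results/data/: the sojourn cohort table, tonometry series
for control / BSO / NEM scenarios, replicate oxy- and deoxy-state
titrations, and a standard-additions series.  All draws are seeded, so
re-running reproduces the files byte for byte.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from hbgsh.itc import ItcProtocol, ItcThermo, simulate_trace
from hbgsh.simulate import (
    CohortDesign,
    CohortParams,
    TonometryScenario,
    generate_cohort,
    generate_itc,
    generate_standard_additions,
    generate_tonometry,
)

SEED = 20260921
OUT = Path(__file__).resolve().parents[1] / "results" / "data"
OUT.mkdir(parents=True, exist_ok=True)


def main() -> None:
    cohort = generate_cohort(CohortDesign(), CohortParams(), seed=SEED)
    cohort.to_csv(OUT / "cohort.csv", index=False)
    print(f"cohort: {len(cohort)} samples, "
          f"{cohort['subject_id'].nunique()} subjects x {cohort['day_label'].nunique()} days")

    for mode in ("control", "BSO", "NEM"):
        series = generate_tonometry(TonometryScenario(mode=mode), seed=SEED + 1)
        series.to_csv(OUT / f"tonometry_{mode}.csv", index=False)
        print(f"tonometry {mode}: {len(series)} points, "
              f"GSH {series['gsh_umol_per_gHb'].min():.2f}-{series['gsh_umol_per_gHb'].max():.2f} umol/g Hb")

    protocol = ItcProtocol()
    for label, n_sites, kd_uM, dh in (("oxy", 4, 2.0, -20.0), ("deoxy", 2, 17.0, -12.0)):
        thermo = ItcThermo(n_sites=n_sites, ka_per_M=1.0 / (kd_uM * 1e-6), dH_kJ_per_mol=dh)
        noise = 0.02 * float(np.abs(simulate_trace(protocol, thermo).heats_uJ).max())
        for rep in range(3):
            trace = generate_itc(protocol, thermo, noise, seed=SEED + 10 * rep + (0 if label == "oxy" else 5))
            pd.DataFrame(
                {
                    "injection_index": np.arange(1, trace.heats_uJ.size + 1),
                    "injection_volume_uL": list(protocol.injection_volumes_uL),
                    "heat_uJ": trace.heats_uJ,
                }
            ).to_csv(OUT / f"itc_{label}_rep{rep + 1}.csv", index=False)
        print(f"itc {label}: 3 replicate titrations of {trace.heats_uJ.size} injections")

    additions = generate_standard_additions(1.8, 3.0, 6, 0.05, seed=SEED + 30)
    pd.DataFrame({"added_umol": additions.added_umol, "intensity": additions.intensities}).to_csv(
        OUT / "standard_additions.csv", index=False
    )
    print("standard additions: 6 points, true m0 = 1.8 umol")


if __name__ == "__main__":
    main()
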