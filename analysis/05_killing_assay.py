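#!/usr/bin/env python
"""LDH killing-assay computation and group statistics on a synthetic plate.

Builds a plate-reader table whose wells encode known target-lysis levels
per condition and effector:target ratio (absorbances back-computed from
the standard LDH release formula, plus replicate noise), recovers %lysis,
and compares conditions with Bonferroni-corrected two-tailed Mann-Whitney
tests.  Writes results/killing_assay.csv and results/killing_stats.csv.

Finding: recovered %lysis matches the encoded values and increases with
TCR signal strength; all pairwise comparisons against NP68 are significant.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from synapse4d.assays import LDHPlate, percent_lysis
from synapse4d.stats import mannwhitney_bonferroni

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 6026

#: encoded true %lysis at 10:1, halved per ratio step (killing rises with
#: TCR signal strength)
TRUE_LYSIS_10TO1 = {"N4": 60.0, "T4": 45.0, "G4": 25.0, "NP68": 4.0}
RATIOS = ("10:1", "5:1", "2.5:1")
BLANK, EFF, TGT, TMAX, LCTRL = 0.05, 0.15, 0.25, 1.25, 0.08


def build_plate(rng) -> LDHPlate:
    rows = []
    denom = (TMAX - LCTRL) - (TGT - BLANK)
    for cond, base in TRUE_LYSIS_10TO1.items():
        for r_i, ratio in enumerate(RATIOS):
            lysis = base / (2 ** r_i)
            for rep in range(6):
                a490 = (lysis / 100.0 * denom + (EFF - BLANK)
                        + (TGT - BLANK) + BLANK)
                rows.append((f"{cond}-{ratio}-{rep}", "experimental", cond,
                             ratio, a490 + rng.normal(0, 0.01)))
    for role, val in (("effector_spontaneous", EFF),
                      ("target_spontaneous", TGT),
                      ("target_maximum", TMAX),
                      ("medium_blank", BLANK),
                      ("lysis_control", LCTRL)):
        for rep in range(3):
            rows.append((f"{role}-{rep}", role, "", "",
                         val + rng.normal(0, 0.005)))
    return LDHPlate(pd.DataFrame(
        rows, columns=["well", "role", "condition", "ratio", "a490"]))


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    rng = np.random.default_rng(SEED)
    plate = build_plate(rng)
    plate.wells.to_csv(RESULTS / "ldh_plate.csv", index=False)
    lysis = percent_lysis(plate)
    lysis.to_csv(RESULTS / "killing_assay.csv", index=False)
    print(lysis.to_string(index=False))

    top = plate.wells[(plate.wells.role == "experimental")
                      & (plate.wells.ratio == "10:1")]
    groups = {c: g.a490.to_numpy() for c, g in top.groupby("condition")}
    comp = mannwhitney_bonferroni(
        groups, comparisons=[(c, "NP68") for c in ("N4", "T4", "G4")])
    comp.table.to_csv(RESULTS / "killing_stats.csv", index=False)
    print()
    print(comp.table.to_string(index=False))


if __name__ == "__main__":
    main()
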