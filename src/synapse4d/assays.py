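"""LDH-release killing assay: %lysis from plate-reader absorbance tables."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["LDHPlate", "percent_lysis", "REQUIRED_ROLES"]

REQUIRED_ROLES = (
    "experimental",            # effector + target wells
    "effector_spontaneous",
    "target_spontaneous",
    "target_maximum",          # fully lysed targets
    "medium_blank",
    "lysis_control",           # lysis buffer in medium (volume control)
)


@dataclass
class LDHPlate:
    """Long-format A490 readings: columns well, role, condition, ratio, a490."""

    wells: pd.DataFrame

    def __post_init__(self):
        missing = {"well", "role", "a490"} - set(self.wells.columns)
        if missing:
            raise ValueError(f"plate table missing columns: {sorted(missing)}")
        if (self.wells.a490 < 0).any():
            raise ValueError("absorbance readings must be >= 0")
        absent = set(REQUIRED_ROLES) - set(self.wells.role.unique())
        if absent:
            raise ValueError(f"missing control well roles: {sorted(absent)}")
        for col in ("condition", "ratio"):
            if col not in self.wells.columns:
                self.wells[col] = ""

    @classmethod
    def from_csv(cls, path) -> "LDHPlate":
        return cls(pd.read_csv(path))

    def role_mean(self, role: str, ratio=None) -> float:
        rows = self.wells[self.wells.role == role]
        if ratio is not None and (rows.ratio == ratio).any():
            rows = rows[rows.ratio == ratio]
        return float(rows.a490.mean())


def percent_lysis(plate: LDHPlate) -> pd.DataFrame:
    """%lysis per (condition, ratio), replicate mean with SD.

    Standard LDH-release formula::

        100 * ((exp - blank) - (eff_spont - blank) - (tgt_spont - blank))
            / ((tgt_max - lysis_control) - (tgt_spont - blank))

    Adding a constant to every well leaves the result unchanged (blank
    subtraction); a non-positive denominator (target maximum not above
    spontaneous release) raises.
    """
    blank = plate.role_mean("medium_blank")
    tgt_spont = plate.role_mean("target_spontaneous") - blank
    denom = ((plate.role_mean("target_maximum")
              - plate.role_mean("lysis_control")) - tgt_spont)
    if denom <= 0:
        raise ValueError(
            "non-positive denominator: target maximum does not exceed "
            "spontaneous release after correction")
    exp = plate.wells[plate.wells.role == "experimental"]
    out = []
    for (cond, ratio), grp in exp.groupby(["condition", "ratio"]):
        eff_spont = plate.role_mean("effector_spontaneous", ratio) - blank
        vals = 100.0 * (((grp.a490 - blank) - eff_spont - tgt_spont) / denom)
        out.append({
            "condition": cond, "ratio": ratio,
            "percent_lysis": float(vals.mean()),
            "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
            "n": int(len(vals)),
        })
    return pd.DataFrame(out)
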