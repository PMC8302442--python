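"""Per-condition summary tables and figures."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ConditionResults", "condition_report"]

CLASS_ORDER = ("uropod", "distal", "proximal", "docked")


@dataclass
class ConditionResults:
    """Collected per-interaction measurements for one condition."""

    dwell_s: list[float] = field(default_factory=list)
    interactions_per_ctl: list[float] = field(default_factory=list)  # per movie
    docking_times_s: list[float | None] = field(default_factory=list)
    closest_approach_classes: list[str] = field(default_factory=list)
    primary_flux_durations_s: list[float] = field(default_factory=list)
    delivered: list[bool] = field(default_factory=list)

    @property
    def stages_present(self) -> list[str]:
        return [k for k in ("dwell_s", "interactions_per_ctl",
                            "docking_times_s", "closest_approach_classes",
                            "primary_flux_durations_s", "delivered")
                if getattr(self, k)]


def condition_report(results: dict[str, ConditionResults],
                     out_dir=None, *,
                     docking_cutoffs_s=(600.0, 750.0, 900.0),
                     make_figures: bool = False) -> pd.DataFrame:
    """Summary table across conditions; optionally CSV + figure files.

    Raises when no condition carries any analysed stage, listing what is
    missing.  Class proportions are reported as percentages summing to 100
    per condition.
    """
    if not results:
        raise ValueError("no conditions analysed: missing all stages "
                         "(dwell, docking, classes, flux, delivery)")
    if all(not r.stages_present for r in results.values()):
        raise ValueError("conditions present but every stage is empty: "
                         "missing dwell, docking, classes, flux, delivery")
    rows = []
    for cond, r in results.items():
        row: dict = {"condition": cond}
        if r.dwell_s:
            d = np.asarray(r.dwell_s)
            row.update(n_interactions=len(d),
                       dwell_median_s=float(np.median(d)),
                       dwell_q1_s=float(np.percentile(d, 25)),
                       dwell_q3_s=float(np.percentile(d, 75)))
        if r.interactions_per_ctl:
            row["interactions_per_ctl_mean"] = float(
                np.mean(r.interactions_per_ctl))
            row["n_movies"] = len(r.interactions_per_ctl)
        if r.docking_times_s:
            times = [t for t in r.docking_times_s if t is not None]
            n = len(r.docking_times_s)
            row["n_conjugates"] = n
            for cut in docking_cutoffs_s:
                row[f"docked_by_{int(cut)}s"] = (
                    sum(1 for t in times if t <= cut) / n)
        if r.closest_approach_classes:
            counts = pd.Series(r.closest_approach_classes).value_counts()
            total = counts.sum()
            for cls in CLASS_ORDER:
                row[f"pct_{cls}"] = 100.0 * counts.get(cls, 0) / total
        if r.primary_flux_durations_s:
            row["primary_flux_median_s"] = float(
                np.median(r.primary_flux_durations_s))
            row["n_fluxes"] = len(r.primary_flux_durations_s)
        if r.delivered:
            row["delivered_fraction"] = float(np.mean(r.delivered))
            row["n_docked"] = len(r.delivered)
        rows.append(row)
    table = pd.DataFrame(rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / "condition_summary.csv", index=False)
        if make_figures:
            _figures(results, out_dir)
    return table


def _figures(results, out_dir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    flux = {c: r.primary_flux_durations_s for c, r in results.items()
            if r.primary_flux_durations_s}
    if flux:
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.violinplot(list(flux.values()), showmedians=True)
        ax.set_xticks(range(1, len(flux) + 1), list(flux))
        ax.set_ylabel("primary Ca$^{2+}$ flux duration (s)")
        fig.tight_layout()
        fig.savefig(out_dir / "primary_flux_violin.png", dpi=150)
        plt.close(fig)
    dwell = {c: r.dwell_s for c, r in results.items() if r.dwell_s}
    if dwell:
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.violinplot(list(dwell.values()), showmedians=True)
        ax.set_xticks(range(1, len(dwell) + 1), list(dwell))
        ax.set_ylabel("dwell time (s)")
        fig.tight_layout()
        fig.savefig(out_dir / "dwell_violin.png", dpi=150)
        plt.close(fig)
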