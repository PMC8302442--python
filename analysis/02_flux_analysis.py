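#!/usr/bin/env python
"""Ca2+ flux structure at trace level: durations, latencies, docking link.

Detects flux events on synthetic whole-cell traces (k = 3 robust z-score),
then relates primary flux duration to the centrosome's closest-approach
class.  Writes results/flux_stats.csv and results/flux_by_class.csv.

Findings with the shipped presets: median primary flux rises with signal
strength (~30 s NP68 -> ~60 s G4 -> ~100 s N4); ~42% of first fluxes start
within 30 s of contact; cells that dock show long fluxes (mean ~207 s,
always >50 s) in every condition - the docked program is conserved, its
trigger rate is not.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from synapse4d import make_preset, simulate_population
from synapse4d.calcium import detect_flux_events, primary_flux_event
from synapse4d.pipeline import calcium_trace_from_values
from synapse4d.presets import CONDITIONS
from synapse4d.protocols import (trace_docked_flux_mean,
                                 trace_onset_latency_fraction)
from synapse4d.simulate import synthesize_calcium_values

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 3026
N = 200


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    rows = []
    rng = np.random.default_rng(SEED)
    for i, cond in enumerate(CONDITIONS):
        preset = make_preset(cond)
        truths = simulate_population(preset, N, 2400.0,
                                     rng_seed=SEED + i, mode="interaction")
        durations = []
        for t in truths:
            vals = synthesize_calcium_values(t, 240, 10.0, rng)
            tr = calcium_trace_from_values(vals, 10.0,
                                           t.principal_episode.start_s)
            try:
                ev = primary_flux_event(detect_flux_events(tr),
                                        tr.first_contact_frame)
            except ValueError:
                continue
            if not ev.censored:
                durations.append(ev.duration_s)
        rows.append({"condition": cond,
                     "primary_flux_median_s": float(np.median(durations)),
                     "primary_flux_mean_s": round(float(np.mean(durations)), 1),
                     "n": len(durations)})
    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "flux_stats.csv", index=False)
    print(table.to_string(index=False))

    frac30 = trace_onset_latency_fraction(N, SEED + 40)
    print(f"\nfirst flux within 30 s of contact (N4 conjugates): "
          f"{100 * frac30:.0f}%")

    mean, summary, long_frac = trace_docked_flux_mean(150, SEED + 50)
    summary.to_csv(RESULTS / "flux_by_class.csv", index=False)
    print(f"docked-group mean primary flux: {mean:.0f} s; "
          f"fraction of docked fluxes >=50 s: {100 * long_frac:.0f}%")
    print(summary.to_string(index=False))


if __name__ == "__main__":
    main()
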