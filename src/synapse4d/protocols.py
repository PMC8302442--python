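"""Canonical desk-scale study protocols over the generate -> measure loop.

Each function runs one complete recovery experiment: simulate a population
under a condition preset, optionally rasterise movies, run the measurement
pipeline, and return the population statistic it recovers.  The analysis
drivers and the acceptance checks call these with their own sample sizes
and seeds; problem sizes here are the package's documented desk-scale
defaults (see docs/methods.md).
"""

from __future__ import annotations

import numpy as np

from . import calcium as ca
from .kinematics import docking_fraction_by
from .params import ImagingParams
from .pipeline import (analyze_interaction_movie, calcium_trace_from_values,
                       trace_from_truth)
from .presets import make_preset
from .render import render_movie
from .simulate import simulate_population, synthesize_calcium_values

__all__ = [
    "flux_movie_params", "docking_movie_params", "delivery_movie_params",
    "rendered_flux_durations", "trace_contact_rate",
    "rendered_docking_fraction", "rendered_delivery_fraction",
    "trace_onset_latency_fraction", "trace_docked_flux_mean",
]

#: movie length (s) per condition for flux-recovery renders: long enough
#: that <~3% of primary fluxes are right-censored
FLUX_MOVIE_DURATION_S = {"N4": 900.0, "T4": 900.0, "G4": 750.0,
                         "NP68": 450.0}


def flux_movie_params(condition: str, frame_interval: float = 5.0,
                      ) -> ImagingParams:
    """Desk-scale geometry for single-interaction Ca2+ movies."""
    duration = FLUX_MOVIE_DURATION_S[condition]
    return ImagingParams(
        voxel_size_xyz=(0.4, 0.4, 0.9),
        frame_interval=frame_interval,
        n_frames=int(round(duration / frame_interval)),
        volume_shape=(9, 56, 56),
        channel_names=("actin", "target", "calcium"),
    )


def docking_movie_params(frame_interval: float = 10.0,
                         duration_s: float = 900.0) -> ImagingParams:
    return ImagingParams(
        voxel_size_xyz=(0.4, 0.4, 0.9),
        frame_interval=frame_interval,
        n_frames=int(round(duration_s / frame_interval)),
        volume_shape=(9, 56, 56),
        channel_names=("actin", "target", "centrosome"),
    )


def delivery_movie_params(frame_interval: float = 10.0,
                          duration_s: float = 900.0) -> ImagingParams:
    p = docking_movie_params(frame_interval, duration_s)
    return p.with_(channel_names=("actin", "target", "centrosome", "granule"))


def _spawn(seed: int, n: int):
    return [int(s.generate_state(1)[0] % (2**31 - 1))
            for s in np.random.SeedSequence(seed).spawn(n)]


def rendered_flux_durations(condition: str, n: int, seed: int, *,
                            frame_interval: float = 5.0,
                            k_flux: float = 3.0) -> np.ndarray:
    """Detected primary flux durations (s) for ``n`` rendered interactions.

    Full route: simulate -> render (default noise) -> segment -> track ->
    extract_trace -> detect_flux_events -> primary flux.  Censored fluxes
    (still above threshold at the movie end) are excluded.
    """
    params = flux_movie_params(condition, frame_interval)
    preset = make_preset(condition)
    truths = simulate_population(preset, n, params.duration, rng_seed=seed,
                                 mode="interaction")
    render_seeds = _spawn(seed + 1, n)
    out = []
    for truth, rseed in zip(truths, render_seeds):
        movie = render_movie([truth], params, rng_seed=rseed)
        res = analyze_interaction_movie(movie, k_flux=k_flux)
        if res.principal_track is None:
            continue
        try:
            ev = ca.primary_flux_event(res.flux_events,
                                       res.principal_track.start_frame)
        except ValueError:
            continue
        if not ev.censored:
            out.append(ev.duration_s)
    return np.asarray(out)


def trace_contact_rate(condition: str, n_ctl: int, seed: int, *,
                       duration_s: float = 2400.0,
                       frame_interval: float = 10.0) -> float:
    """Mean interactions per CTL from a trace-level population."""
    from .kinematics import detect_interactions_from_contact, interactions_per_ctl
    from .simulate import contact_frame_matrix

    preset = make_preset(condition)
    truths = simulate_population(preset, n_ctl, duration_s, rng_seed=seed,
                                 mode="population")
    n_frames = int(round(duration_s / frame_interval))
    contact = contact_frame_matrix(truths, n_frames, frame_interval)
    tracks = detect_interactions_from_contact(contact, frame_interval)
    return interactions_per_ctl(tracks, n_ctl, duration_s)


def rendered_docking_fraction(condition: str, n: int, seed: int, *,
                              t_cutoff_s: float = 600.0,
                              frame_interval: float = 10.0,
                              duration_s: float = 900.0) -> float:
    """Fraction of rendered stable conjugates docked by the cutoff.

    End-to-end: render -> segment -> spot detection -> centrosome_trace ->
    docking_fraction_by.
    """
    params = docking_movie_params(frame_interval, duration_s)
    preset = make_preset(condition)
    truths = simulate_population(preset, n, duration_s, rng_seed=seed,
                                 mode="stable")
    render_seeds = _spawn(seed + 1, n)
    traces = []
    for truth, rseed in zip(truths, render_seeds):
        movie = render_movie([truth], params, rng_seed=rseed)
        res = analyze_interaction_movie(movie)
        if res.centrosome is not None:
            traces.append(res.centrosome)
    return docking_fraction_by(traces, t_cutoff_s)


def rendered_delivery_fraction(n: int, seed: int, *,
                               conditions=("N4", "T4", "G4"),
                               frame_interval: float = 10.0,
                               duration_s: float = 900.0) -> float:
    """Fraction of measured-docked conjugates with concomitant delivery."""
    params = delivery_movie_params(frame_interval, duration_s)
    per = [n // len(conditions)] * len(conditions)
    for i in range(n - sum(per)):
        per[i] += 1
    render_seeds = iter(_spawn(seed + 1, n))
    delivered, docked = 0, 0
    for cond, k in zip(conditions, per):
        preset = make_preset(cond)
        truths = simulate_population(preset, k, duration_s,
                                     rng_seed=seed + sum(ord(c) for c in cond),
                                     mode="docked")
        for truth in truths:
            movie = render_movie([truth], params, rng_seed=next(render_seeds))
            res = analyze_interaction_movie(movie)
            if (res.centrosome is not None
                    and res.centrosome.docking_time_s is not None):
                docked += 1
                if res.delivery is not None and res.delivery.delivered:
                    delivered += 1
    if docked == 0:
        raise RuntimeError("no conjugate docked; cannot form the fraction")
    return delivered / docked


def trace_onset_latency_fraction(n: int, seed: int, *,
                                 condition: str = "N4",
                                 frame_interval: float = 5.0,
                                 duration_s: float = 1200.0,
                                 within_s: float = 30.0) -> float:
    """Fraction of first post-contact fluxes starting within ``within_s``
    of contact (trace level, frame-quantised like the imaging route).

    The population is stable conjugates: the printed latency statistics
    come from tracked conjugates, and transient interactions would distort
    the latency support through dwell truncation.
    """
    preset = make_preset(condition)
    truths = simulate_population(preset, n, duration_s, rng_seed=seed,
                                 mode="stable")
    rng = np.random.default_rng(seed + 7)
    n_frames = int(round(duration_s / frame_interval))
    hits, total = 0, 0
    for truth in truths:
        values = synthesize_calcium_values(truth, n_frames, frame_interval,
                                           rng)
        ep = truth.principal_episode
        trace = calcium_trace_from_values(values, frame_interval, ep.start_s)
        events = ca.detect_flux_events(trace)
        contact_frame = trace.first_contact_frame
        rec = ca.latency_metrics(events, frame_interval,
                                 contact_time_s=contact_frame * frame_interval)
        if rec.contact_to_flux_s is None:
            continue
        total += 1
        if rec.contact_to_flux_s <= within_s:
            hits += 1
    if total == 0:
        raise RuntimeError("no fluxes detected")
    return hits / total


def trace_docked_flux_mean(n: int, seed: int, *,
                           conditions=("N4", "T4", "G4"),
                           frame_interval: float = 10.0,
                           duration_s: float = 2400.0):
    """Docked-group mean primary flux duration from mixed stable
    conjugates, grouped via flux_docking_association.

    Returns ``(docked_mean_s, summary_table, long_flux_fraction)``.
    """
    per = [n // len(conditions)] * len(conditions)
    for i in range(n - sum(per)):
        per[i] += 1
    rng = np.random.default_rng(seed + 13)
    n_frames = int(round(duration_s / frame_interval))
    records = []
    for cond, k in zip(conditions, per):
        preset = make_preset(cond)
        truths = simulate_population(preset, k, duration_s,
                                     rng_seed=seed + sum(ord(c) for c in cond),
                                     mode="stable")
        for truth in truths:
            trace = trace_from_truth(truth, frame_interval)
            values = synthesize_calcium_values(truth, n_frames,
                                               frame_interval, rng)
            ep = truth.principal_episode
            ca_trace = calcium_trace_from_values(values, frame_interval,
                                                 ep.start_s)
            events = ca.detect_flux_events(ca_trace)
            try:
                ev = ca.primary_flux_event(events,
                                           ca_trace.first_contact_frame)
            except ValueError:
                continue
            records.append(ca.AssociationRecord(
                duration_s=ev.duration_s, censored=ev.censored,
                closest_approach_class=trace.closest_approach_class,
                condition=cond))
    summary, long_frac, _ = ca.flux_docking_association(records)
    docked = summary[summary.closest_approach_class == "docked"]
    if docked.empty:
        raise RuntimeError("no docked conjugates in the sample")
    mean = float(np.average(docked["mean"], weights=docked["n"]))
    return mean, summary, long_frac
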