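"""End-to-end measurement pipelines over rendered movies and trace-level
simulations.

These functions wire the object-creation and measurement stages together
for the common single-conjugate movie layout (one CTL, one target per
field) and expose trace-level shortcuts that skip rasterisation but reuse
the same event-detection code paths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import calcium as ca
from . import kinematics as kin
from . import segmentation as seg
from .movie import Movie
from .simulate import GroundTruth

__all__ = [
    "InteractionAnalysis",
    "analyze_interaction_movie",
    "trace_from_truth",
    "calcium_trace_from_values",
]


@dataclass
class InteractionAnalysis:
    """Measured readouts for one conjugate movie."""

    tracks: list[kin.InteractionTrack]
    principal_track: kin.InteractionTrack | None
    centrosome: kin.CentrosomeTrace | None = None
    calcium_trace: ca.CalciumTrace | None = None
    flux_events: list[ca.FluxEvent] = field(default_factory=list)
    delivery: kin.GranuleDeliveryRecord | None = None
    n_ctl: int = 0


def _rear_fraction(pos_um, surface_um, ctl_centroid_um):
    """Fractional position of a point along the synapse->rear cell axis."""
    syn = surface_um.mean(axis=0)
    axis = ctl_centroid_um - syn
    norm = np.linalg.norm(axis)
    if norm < 1e-9:
        return None
    return float(np.dot(pos_um - syn, axis / norm) / (2 * norm))


def analyze_interaction_movie(movie: Movie, *,
                              k_flux: float = 3.0,
                              gap_tolerance_frames: int = 1,
                              centrosome_radius_um: float = 0.5,
                              granule_radius_um: float = 0.35,
                              ) -> InteractionAnalysis:
    """Segment, track and measure a single-conjugate movie.

    Runs whatever stages the movie's channels support: interactions from
    actin+target, centrosome kinematics when a centrosome channel is
    present, Ca2+ events when a calcium channel is present, granule
    delivery when a granule channel is present.
    """
    names = movie.params.channel_names
    ctl_labels = seg.link_labels(seg.segment_cells(movie, "actin"))
    tgt_labels = seg.link_labels(seg.segment_cells(movie, "target"))
    tracks = kin.detect_interactions(ctl_labels, tgt_labels,
                                     gap_tolerance_frames)
    n_ctl = len({i for f in range(ctl_labels.n_frames)
                 for i in np.unique(ctl_labels.labels[f]) if i > 0})
    if not tracks:
        return InteractionAnalysis(tracks=[], principal_track=None,
                                   n_ctl=n_ctl)
    principal = max(tracks, key=lambda t: t.dwell_s)
    frames = range(principal.start_frame, principal.end_frame)

    surfaces = [None] * movie.n_frames
    if "centrosome" in names or "granule" in names:
        for f in frames:
            surf = seg.extract_synapse_surface(
                ctl_labels.labels[f] == principal.ctl_id,
                tgt_labels.labels[f] == principal.target_id,
                ctl_labels.voxel_size_zyx,
                ctl_id=principal.ctl_id, target_id=principal.target_id)
            surfaces[f] = None if surf.is_empty else surf.coords_um

    out = InteractionAnalysis(tracks=tracks, principal_track=principal,
                              n_ctl=n_ctl)

    if "centrosome" in names:
        spots = seg.detect_spots(movie, "centrosome", centrosome_radius_um,
                                 labels=ctl_labels, kind="centrosome")
        positions = [None] * movie.n_frames
        rear = [None] * movie.n_frames
        for f in frames:
            pos = spots.positions_um(f, principal.ctl_id)
            if len(pos):
                positions[f] = pos[0]
                if surfaces[f] is not None:
                    cents = ctl_labels.centroids_um(f)
                    if principal.ctl_id in cents:
                        rear[f] = _rear_fraction(pos[0], surfaces[f],
                                                 cents[principal.ctl_id])
        try:
            out.centrosome = kin.centrosome_trace(
                positions, surfaces, movie.params.frame_interval,
                rear_fractions=rear)
        except ValueError:
            out.centrosome = None

    if "calcium" in names:
        out.calcium_trace = ca.extract_trace(
            movie, "calcium", ctl_labels, principal.ctl_id,
            first_contact_frame=principal.start_frame)
        out.flux_events = ca.detect_flux_events(out.calcium_trace, k_flux)

    if "granule" in names and out.centrosome is not None:
        gspots = seg.detect_spots(movie, "granule", granule_radius_um,
                                  labels=ctl_labels, kind="granule",
                                  max_per_cell=12)
        cspots = seg.detect_spots(movie, "centrosome", centrosome_radius_um,
                                  labels=ctl_labels, kind="centrosome")
        gran = [None] * movie.n_frames
        cen = [None] * movie.n_frames
        for f in frames:
            mine = [s for s in gspots.frames[f]
                    if s.label == principal.ctl_id]
            if mine:
                # near-threshold noise maxima sit far below genuine
                # granule responses; prune relative to the brightest
                top = max(s.intensity for s in mine)
                pos = np.array([s.position_um for s in mine
                                if s.intensity >= 0.1 * top])
            else:
                pos = np.empty((0, 3))
            gran[f] = pos if len(pos) else None
            cp = cspots.positions_um(f, principal.ctl_id)
            cen[f] = cp[0] if len(cp) else None
        sub = slice(principal.start_frame, principal.end_frame)
        out.delivery = kin.granule_centrosome_distances(
            gran[sub], cen[sub], surfaces[sub],
            movie.params.frame_interval)
    return out


def trace_from_truth(truth: GroundTruth, frame_interval: float,
                     ) -> kin.CentrosomeTrace:
    """Frame-sampled centrosome trace straight from latent kinematics.

    Applies the same frame quantisation, docking rule and classification
    as the imaging route, skipping only rasterisation and spot detection.
    """
    ep = truth.principal_episode
    n = max(int(np.floor(ep.dwell_s / frame_interval)) + 1, 1)
    t_rel = np.arange(n) * frame_interval
    dist = np.asarray(truth.centrosome_distance(t_rel), dtype=float)
    rear = 0.85 if truth.rear_position else 0.4
    below = np.flatnonzero(dist < kin.DOCKED_THRESHOLD_UM)
    docking = float(below[0] * frame_interval) if below.size else None
    closest = float(dist.min())
    max_speed = (float(np.abs(np.diff(dist)).max() / frame_interval)
                 if n > 1 else 0.0)
    return kin.CentrosomeTrace(
        distances_um=dist,
        frame_interval=frame_interval,
        contact_start_frame=0,
        docking_time_s=docking,
        closest_approach_um=closest,
        closest_approach_class=kin.classify_closest_approach(closest, rear),
        max_speed_um_per_s=max_speed,
    )


def calcium_trace_from_values(values, frame_interval: float,
                              first_contact_time_s: float) -> ca.CalciumTrace:
    """Build a trace from frame-sampled reporter values (trace level)."""
    first_frame = int(np.ceil(first_contact_time_s / frame_interval - 1e-9))
    return ca.CalciumTrace.from_values(values, frame_interval,
                                       first_contact_frame=first_frame)
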