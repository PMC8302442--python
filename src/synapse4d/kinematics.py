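"""Interaction-level readouts: dwell, docking, granule delivery.

All distances are Euclidean in physical micrometres (anisotropic voxels are
never resampled; coordinates are converted once).  Frames are 0-based and
intervals half-open ``[start_frame, end_frame)``, so
``dwell = (end - start) * frame_interval``.

Closest-approach classes follow the published convention: docked (<1 um,
strict), proximal (1-5 um, both boundaries inclusive), distal (>5 um), and
"uropod" when the closest approach exceeds 5 um while the centrosome sits in
the rear third of the synapse-to-rear cell axis (the rear-third rule is a
configurable heuristic; no numeric definition of "in the uropod" was ever
published).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "InteractionTrack",
    "CentrosomeTrace",
    "GranuleDeliveryRecord",
    "classify_closest_approach",
    "detect_interactions",
    "detect_interactions_from_contact",
    "interactions_per_ctl",
    "centrosome_trace",
    "docking_fraction_by",
    "granule_centrosome_distances",
    "granule_density_map",
]

DOCKED_THRESHOLD_UM = 1.0
PROXIMAL_MAX_UM = 5.0
DELIVERY_THRESHOLD_UM = 0.5
REAR_THIRD_FRACTION = 2.0 / 3.0


@dataclass(frozen=True)
class InteractionTrack:
    """One maximal CTL-target contact episode."""

    ctl_id: int
    target_id: int
    start_frame: int
    end_frame: int          # exclusive
    frame_interval: float
    stable_min_dwell_s: float = 120.0

    @property
    def dwell_s(self) -> float:
        return (self.end_frame - self.start_frame) * self.frame_interval

    @property
    def stable_conjugate(self) -> bool:
        return self.dwell_s >= self.stable_min_dwell_s


@dataclass
class CentrosomeTrace:
    """Per-frame centrosome-to-synapse distances for one interaction."""

    distances_um: np.ndarray        # nan where no contact / no spot
    frame_interval: float
    contact_start_frame: int
    docking_time_s: float | None    # relative to contact start
    closest_approach_um: float
    closest_approach_class: str
    max_speed_um_per_s: float


@dataclass
class GranuleDeliveryRecord:
    """Granule-centrosome and granule-synapse distances for one CTL."""

    granule_centrosome_um: list[np.ndarray]   # per frame, one row per granule
    granule_synapse_um: list[np.ndarray]
    times_since_contact_s: np.ndarray         # one entry per frame with data
    delivered: bool


def classify_closest_approach(closest_um: float,
                              rear_fraction: float | None = None) -> str:
    """Assign the exclusive closest-approach class for one interaction."""
    if closest_um < DOCKED_THRESHOLD_UM:
        return "docked"
    if closest_um <= PROXIMAL_MAX_UM:
        return "proximal"
    if rear_fraction is not None and rear_fraction >= REAR_THIRD_FRACTION:
        return "uropod"
    return "distal"


# ---------------------------------------------------------------------------
# interaction detection
# ---------------------------------------------------------------------------

def _merge_runs(frames: np.ndarray, gap_tolerance: int):
    """Maximal runs of contact frames, merging gaps <= gap_tolerance."""
    if frames.size == 0:
        return []
    runs = []
    start = prev = int(frames[0])
    for f in frames[1:]:
        if f - prev <= gap_tolerance + 1:
            prev = int(f)
        else:
            runs.append((start, prev + 1))
            start = prev = int(f)
    runs.append((start, prev + 1))
    return runs


def detect_interactions_from_contact(contact: dict, frame_interval: float,
                                     gap_tolerance_frames: int = 1,
                                     ) -> list[InteractionTrack]:
    """Tracks from per-pair boolean contact series.

    ``contact`` maps ``(ctl_id, target_id)`` to a boolean array over frames.
    """
    tracks = []
    for (ctl_id, target_id), series in contact.items():
        frames = np.flatnonzero(np.asarray(series, dtype=bool))
        for start, end in _merge_runs(frames, gap_tolerance_frames):
            tracks.append(InteractionTrack(ctl_id, target_id, start, end,
                                           frame_interval))
    tracks.sort(key=lambda t: (t.ctl_id, t.start_frame, t.target_id))
    return tracks


def detect_interactions(ctl_labels, target_labels,
                        gap_tolerance_frames: int = 1,
                        ) -> list[InteractionTrack]:
    """Tracks from linked CTL and target label volumes.

    Contact means the two instance masks touch after a 1-voxel dilation of
    the target (masks are exclusive, so "overlap" of the original surfaces
    is realised as dilation adjacency).
    """
    if ctl_labels.labels.shape != target_labels.labels.shape:
        raise ValueError("label volumes must share shape and calibration")
    n_frames = ctl_labels.n_frames
    contact: dict[tuple[int, int], np.ndarray] = {}
    for f in range(n_frames):
        ctl_f = ctl_labels.labels[f]
        tgt_f = target_labels.labels[f]
        for tgt_id in np.unique(tgt_f)[1:] if tgt_f.any() else []:
            grown = ndimage.binary_dilation(tgt_f == tgt_id)
            touched = np.unique(ctl_f[grown])
            for ctl_id in touched[touched > 0]:
                key = (int(ctl_id), int(tgt_id))
                if key not in contact:
                    contact[key] = np.zeros(n_frames, dtype=bool)
                contact[key][f] = True
    return detect_interactions_from_contact(
        contact, ctl_labels.frame_interval, gap_tolerance_frames)


def interactions_per_ctl(tracks: list[InteractionTrack], n_ctl: int,
                         duration_s: float | None = None) -> float:
    """Mean number of interactions per CTL for one movie."""
    if n_ctl < 1:
        raise ValueError("n_ctl must be >= 1")
    return len(tracks) / n_ctl


# ---------------------------------------------------------------------------
# centrosome kinematics
# ---------------------------------------------------------------------------

def _nearest_surface_distance(pos_um: np.ndarray,
                              surface_um: np.ndarray) -> float:
    d = surface_um - pos_um[None, :]
    return float(np.sqrt((d * d).sum(axis=1)).min())


def centrosome_trace(positions_um, surfaces_um, frame_interval: float, *,
                     rear_fractions=None,
                     dock_threshold_um: float = DOCKED_THRESHOLD_UM,
                     ) -> CentrosomeTrace:
    """Distance trace, docking time and closest-approach class.

    Parameters
    ----------
    positions_um : sequence over frames of length-3 arrays (z, y, x) in um,
        or None where the centrosome spot is missing.
    surfaces_um : sequence over frames of (N, 3) synapse-surface voxel
        centres in um, or None/empty where the pair is not in contact.
    rear_fractions : optional per-frame fractional position of the
        centrosome along the synapse->rear axis (0 at the synapse pole).

    Raises
    ------
    ValueError
        If no frame has both a centrosome spot and a contact surface.
    """
    n = len(positions_um)
    if len(surfaces_um) != n:
        raise ValueError("positions and surfaces must cover the same frames")
    dist = np.full(n, np.nan)
    for f in range(n):
        pos, surf = positions_um[f], surfaces_um[f]
        if pos is None or surf is None or len(surf) == 0:
            continue
        dist[f] = _nearest_surface_distance(np.asarray(pos, dtype=float),
                                            np.asarray(surf, dtype=float))
    defined = np.flatnonzero(np.isfinite(dist))
    if defined.size == 0:
        raise ValueError("no contact frames with a centrosome spot: "
                         "not an interaction")
    contact_start = int(defined[0])

    below = defined[dist[defined] < dock_threshold_um]
    docking_time = (float((below[0] - contact_start) * frame_interval)
                    if below.size else None)

    i_min = defined[np.argmin(dist[defined])]
    closest = float(dist[i_min])
    rear = None
    if rear_fractions is not None and rear_fractions[i_min] is not None:
        rear = float(rear_fractions[i_min])
    cls = classify_closest_approach(closest, rear)

    # raw finite differences over consecutive defined frames
    max_speed = 0.0
    if defined.size >= 2:
        dd = np.abs(np.diff(dist[defined]))
        consecutive = np.diff(defined) == 1
        if consecutive.any():
            max_speed = float((dd[consecutive] / frame_interval).max())
    return CentrosomeTrace(
        distances_um=dist,
        frame_interval=frame_interval,
        contact_start_frame=contact_start,
        docking_time_s=docking_time,
        closest_approach_um=closest,
        closest_approach_class=cls,
        max_speed_um_per_s=max_speed,
    )


def docking_fraction_by(traces: list[CentrosomeTrace],
                        t_cutoff_s: float) -> float:
    """Fraction of conjugates whose docking time is <= the cutoff."""
    if t_cutoff_s <= 0:
        raise ValueError("t_cutoff_s must be positive")
    if not traces:
        raise ValueError("no traces supplied")
    docked = sum(1 for tr in traces
                 if tr.docking_time_s is not None
                 and tr.docking_time_s <= t_cutoff_s)
    return docked / len(traces)


# ---------------------------------------------------------------------------
# granule delivery
# ---------------------------------------------------------------------------

def granule_centrosome_distances(granule_positions_um, centrosome_positions_um,
                                 surfaces_um, frame_interval: float, *,
                                 delivery_threshold_um: float = DELIVERY_THRESHOLD_UM,
                                 dock_threshold_um: float = DOCKED_THRESHOLD_UM,
                                 ) -> GranuleDeliveryRecord:
    """Pairwise granule distances and the concomitant-delivery flag.

    ``delivered`` is true when, in at least one frame, the centrosome is
    docked (<1 um from the synapse) while >=1 granule lies within the
    delivery threshold (<0.5 um) of the synapse - the same-frame rule.
    """
    n = len(granule_positions_um)
    gc, gs, times = [], [], []
    delivered = False
    for f in range(n):
        gran = granule_positions_um[f]
        cen = centrosome_positions_um[f]
        surf = surfaces_um[f]
        if gran is None or len(gran) == 0 or surf is None or len(surf) == 0:
            continue
        gran = np.asarray(gran, dtype=float)
        surf = np.asarray(surf, dtype=float)
        d_gs = np.sqrt(
            ((gran[:, None, :] - surf[None, :, :]) ** 2).sum(-1)).min(axis=1)
        if cen is not None:
            cen = np.asarray(cen, dtype=float)
            d_gc = np.sqrt(((gran - cen[None, :]) ** 2).sum(axis=1))
            d_cs = _nearest_surface_distance(cen, surf)
            if d_cs < dock_threshold_um and (d_gs < delivery_threshold_um).any():
                delivered = True
        else:
            d_gc = np.full(len(gran), np.nan)
        gc.append(d_gc)
        gs.append(d_gs)
        times.append(f * frame_interval)
    return GranuleDeliveryRecord(
        granule_centrosome_um=gc,
        granule_synapse_um=gs,
        times_since_contact_s=np.asarray(times, dtype=float),
        delivered=delivered,
    )


def granule_density_map(records: list[GranuleDeliveryRecord],
                        time_bin_s: float, distance_bin_um: float, *,
                        t_max_s: float | None = None,
                        d_max_um: float | None = None) -> np.ndarray:
    """Normalised 2D density of (time since contact, granule-centrosome
    distance); the maximum bin is exactly 1."""
    ts, ds = [], []
    for rec in records:
        t0 = rec.times_since_contact_s[0] if rec.times_since_contact_s.size else 0.0
        for t, row in zip(rec.times_since_contact_s, rec.granule_centrosome_um):
            good = np.isfinite(row)
            ts.extend([t - t0] * int(good.sum()))
            ds.extend(row[good].tolist())
    if not ds:
        raise ValueError("no granule-centrosome distance observations")
    ts, ds = np.asarray(ts), np.asarray(ds)
    if t_max_s is None:
        t_max_s = max(ts.max(), time_bin_s)
    if d_max_um is None:
        d_max_um = max(ds.max(), distance_bin_um)
    t_edges = np.arange(0.0, t_max_s + time_bin_s, time_bin_s)
    d_edges = np.arange(0.0, d_max_um + distance_bin_um, distance_bin_um)
    hist, _, _ = np.histogram2d(ts, ds, bins=(t_edges, d_edges))
    return hist / hist.max()
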