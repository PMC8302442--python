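"""Trace-level generative model of CTL-target killing choreography.

``simulate_population`` draws, per CTL, a schedule of contact episodes and -
for the principal episode - the latent kinematic and signalling state that
the imaging pipeline later has to recover: a piecewise-linear centrosome
distance-to-synapse profile, Ca2+ flux events, uropod retraction and
polarisation onsets, and the granule-delivery outcome.  Everything is
expressed in physical units (micrometres, seconds) and is independent of any
rendering geometry, so populations can be analysed at "trace level" without
rasterising movies.

The event ordering within a cell follows the observed choreography:
contact -> first Ca2+ flux -> uropod retraction -> start of centrosome
polarisation -> docking (<1 um) -> granule delivery (<0.5 um).  The
centrosome approach is biphasic: a rapid traverse at the shared approach
speed down to ~2.2 um, a membrane-proximal hold, and a final approach that
crosses the 1 um docking threshold exactly at the drawn docking time.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .kinematics import classify_closest_approach
from .presets import STABLE_CONJUGATE_MIN_DWELL_S, ConditionPreset

__all__ = [
    "Episode",
    "GroundTruth",
    "simulate_population",
    "synthesize_calcium_values",
    "contact_frame_matrix",
]

#: distance (um) at which the docked centrosome settles against the membrane
DOCKED_REST_UM = 0.35
#: membrane-proximal hold distance between the rapid and final approach
HOLD_UM = 2.2
#: minimum gap (s) between successive contact episodes of one CTL
MIN_GAP_S = 25.0
#: reference observation window (s) for contacts_per_ctl_mean
REFERENCE_WINDOW_S = 2400.0


@dataclass(frozen=True)
class Episode:
    start_s: float
    end_s: float
    target_id: int

    @property
    def dwell_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class GroundTruth:
    """Latent state of one simulated CTL (the generator's sidecar record)."""

    ctl_id: int
    condition: str
    episodes: list[Episode]
    principal: int                       # index into episodes
    stable: bool
    docked: bool
    docking_time_s: float | None         # relative to principal episode start
    closest_approach_um: float | None
    closest_approach_class: str | None
    rear_position: bool
    d0_um: float
    profile_t: np.ndarray                # knot times, rel. principal start
    profile_d: np.ndarray                # knot distances, um
    flux_events_true: list[tuple[float, float]]   # absolute (onset, end) s
    uropod_retraction_s: float | None    # absolute s
    polarisation_start_s: float | None   # absolute s
    delivered: bool | None
    n_granules: int = 8
    granule_cluster_radius_um: float = 1.5
    depletion_fraction: float | None = None

    @property
    def principal_episode(self) -> Episode:
        return self.episodes[self.principal]

    def centrosome_distance(self, t_rel) -> np.ndarray:
        """Distance to synapse (um) at time(s) ``t_rel`` after contact."""
        t = np.clip(np.asarray(t_rel, dtype=float), 0.0,
                    self.principal_episode.dwell_s)
        return np.interp(t, self.profile_t, self.profile_d)

    def flux_state(self, t_abs) -> np.ndarray:
        """Boolean Ca2+-elevated state at absolute time(s) ``t_abs``."""
        t = np.asarray(t_abs, dtype=float)
        state = np.zeros(t.shape, dtype=bool)
        for onset, end in self.flux_events_true:
            state |= (t >= onset) & (t < end)
        return state

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["episodes"] = [dataclasses.asdict(e) for e in self.episodes]
        d["profile_t"] = np.asarray(self.profile_t).tolist()
        d["profile_d"] = np.asarray(self.profile_d).tolist()
        d["flux_events_true"] = [list(e) for e in self.flux_events_true]
        return d


# ---------------------------------------------------------------------------
# episode scheduling
# ---------------------------------------------------------------------------

def _draw_dwell(preset: ConditionPreset, stable: bool,
                rng: np.random.Generator) -> float:
    dist = preset.dwell_time_dist
    lo = dist.low if dist.low is not None else 0.0
    if stable:
        trunc = dataclasses.replace(
            dist, low=max(lo, STABLE_CONJUGATE_MIN_DWELL_S))
    else:
        trunc = dataclasses.replace(
            dist, high=STABLE_CONJUGATE_MIN_DWELL_S)
    return float(trunc.sample(rng))


def _schedule_episodes(preset, duration_s, rng):
    """Poisson number of non-overlapping episodes packed into the movie."""
    lam = preset.contacts_per_ctl_mean * duration_s / REFERENCE_WINDOW_S
    k = int(rng.poisson(lam))
    if k == 0:
        return [], [], []
    stable = rng.random(k) < preset.p_stable_conjugate
    dock_intent = stable & (rng.random(k) < preset.p_dock)
    dwells = np.array([_draw_dwell(preset, s, rng) for s in stable])
    dock_raw = np.full(k, np.nan)
    for i in np.flatnonzero(dock_intent):
        dock_raw[i] = preset.docking_time_dist.sample(rng)
        dwells[i] = max(dwells[i], dock_raw[i] + 120.0)
    budget = duration_s - k * MIN_GAP_S
    if budget <= 0:  # pathologically short movie: single clipped episode
        return ([Episode(0.0, duration_s, 0)], [bool(stable[0])],
                [dock_raw[0] if dock_intent[0] else None])
    total = dwells.sum()
    if total > budget:
        dwells *= budget / total
    free = budget - dwells.sum()
    gaps = MIN_GAP_S + free * rng.dirichlet(np.ones(k + 1))[:k]
    episodes, t = [], 0.0
    for i in range(k):
        t += gaps[i]
        episodes.append(Episode(t, min(t + dwells[i], duration_s), i))
        t += dwells[i]
    docks = [dock_raw[i] if dock_intent[i] else None for i in range(k)]
    stables = [bool(s) and episodes[i].dwell_s >= STABLE_CONJUGATE_MIN_DWELL_S
               for i, s in enumerate(stable)]
    return episodes, stables, docks


# ---------------------------------------------------------------------------
# kinematic profile of the principal episode
# ---------------------------------------------------------------------------

def _docked_profile(d0, dock_raw, polar_rel, length, v, polar_floor=4.0):
    """Knots for a docking cell; 1 um crossing lands at the docking time.

    When the drawn docking time is too close to the polarisation onset for
    the travel at speed ``v``, the crossing shifts late rather than letting
    polarisation precede the Ca2+ flux (rare; keeps the event order).
    """
    travel1 = (d0 - HOLD_UM) / v
    t_cross = (HOLD_UM - 1.0) / v          # hold -> threshold, 24 s at default v
    t_rest = (HOLD_UM - DOCKED_REST_UM) / v
    polar_rel = min(polar_rel,
                    max(dock_raw - t_cross - travel1 - 2.0, polar_floor))
    dock_eff = max(dock_raw, polar_rel + travel1 + t_cross)
    end_t = max(length, dock_eff - t_cross + t_rest + 1.0)
    knots_t = [0.0, polar_rel, polar_rel + travel1,
               dock_eff - t_cross, dock_eff - t_cross + t_rest, end_t]
    knots_d = [d0, d0, HOLD_UM, HOLD_UM, DOCKED_REST_UM, DOCKED_REST_UM]
    return np.array(knots_t), np.array(knots_d), polar_rel


def _nondock_profile(d0, c, polar_rel, length, v, rng):
    """Knots for a non-docking cell: approach to ``c``, hold, withdraw."""
    t_a = min(polar_rel, 0.4 * length)
    travel = max(d0 - c, 0.0) / v
    if t_a + travel > 0.85 * length:       # short episode: shallower approach
        c = max(c, d0 - v * max(0.85 * length - t_a, 0.0))
        travel = max(d0 - c, 0.0) / v
    hold = rng.uniform(30.0, 120.0)
    t1, t2 = t_a + travel, t_a + travel + hold
    t3 = t2 + travel
    knots_t = [0.0, t_a, t1, t2, t3, max(length, t3 + 1.0)]
    knots_d = [d0, d0, c, c, d0, d0]
    return np.array(knots_t), np.array(knots_d), c


def _first_crossing(tk, dk, threshold, length):
    """First time the piecewise-linear profile drops below ``threshold``."""
    if len(tk) == 0:
        return None
    if dk[0] < threshold:
        return 0.0
    for i in range(len(tk) - 1):
        if dk[i + 1] < threshold:
            frac = (dk[i] - threshold) / (dk[i] - dk[i + 1])
            t = tk[i] + frac * (tk[i + 1] - tk[i])
            return float(t) if t <= length else None
    return None


def _profile_min(tk, dk, length):
    pts = np.clip(np.append(tk, length), 0.0, length)
    return float(np.interp(pts, tk, dk).min())


# ---------------------------------------------------------------------------
# per-cell assembly
# ---------------------------------------------------------------------------

def _make_truth(ctl_id, preset, episodes, stables, docks, rng,
                duration_s) -> GroundTruth:
    # principal episode: first stable one, else the longest
    stable_idx = [i for i, s in enumerate(stables) if s]
    if stable_idx:
        p = stable_idx[0]
    else:
        p = int(np.argmax([e.dwell_s for e in episodes]))
    ep = episodes[p]
    length = ep.dwell_s
    dock_raw = docks[p]
    dock_intent = dock_raw is not None
    v = preset.approach_speed_um_s

    # flux / uropod / polarisation ordering
    onset_rel = min(float(preset.flux_onset_latency_dist.sample(rng)),
                    0.8 * length)
    duration_dist = (preset.flux_duration_docked_dist if dock_intent
                     else preset.flux_duration_nondocked_dist)
    primary_dur = float(duration_dist.sample(rng))
    uropod_rel = onset_rel + float(preset.uropod_latency_dist.sample(rng))
    polar_rel = max(onset_rel + float(preset.polarisation_latency_dist.sample(rng)),
                    uropod_rel + 2.0)

    rear = False
    if dock_intent:
        d0 = float(rng.uniform(4.5, 5.8))
        tk, dk, polar_rel = _docked_profile(
            d0, dock_raw, polar_rel, length, v,
            polar_floor=onset_rel + 4.0)
        # keep the observed order: flux -> uropod retraction -> polarisation
        uropod_rel = min(uropod_rel, polar_rel - 2.0)
        uropod_rel = max(uropod_rel, onset_rel + 1.0)
    else:
        cls = rng.choice(("proximal", "distal", "uropod"),
                         p=preset.nondock_class_probs)
        if cls == "proximal":
            d0 = float(rng.uniform(4.5, 5.8))
            c = float(rng.uniform(1.6, 4.5))
        else:
            d0 = float(rng.uniform(5.3, 6.1))
            c = d0 - float(rng.uniform(0.0, min(0.5, d0 - 5.2)))
            rear = cls == "uropod"
        tk, dk, c = _nondock_profile(d0, c, polar_rel, length, v, rng)

    dock_realized = _first_crossing(tk, dk, 1.0, length)
    closest = _profile_min(tk, dk, length)
    cls_realized = classify_closest_approach(
        closest, rear_fraction=(0.85 if rear else 0.4))
    docked = dock_realized is not None

    # flux events (absolute movie time); oscillations after the primary
    events = [(ep.start_s + onset_rel, ep.start_s + onset_rel + primary_dur)]
    t_cursor = onset_rel + primary_dur
    for _ in range(int(rng.poisson(0.8))):
        t_cursor += float(rng.uniform(25.0, 70.0))
        if t_cursor > length + 100.0:
            break
        extra = float(np.exp(np.log(25.0) + 0.5 * rng.standard_normal()))
        events.append((ep.start_s + t_cursor, ep.start_s + t_cursor + extra))
        t_cursor += extra

    delivered = None
    if docked:
        delivered = bool(rng.random() < preset.p_concomitant_delivery_given_dock)

    return GroundTruth(
        ctl_id=ctl_id,
        condition=preset.condition_name,
        episodes=episodes,
        principal=p,
        stable=stables[p],
        docked=docked,
        docking_time_s=dock_realized,
        closest_approach_um=closest,
        closest_approach_class=cls_realized,
        rear_position=rear,
        d0_um=d0,
        profile_t=tk,
        profile_d=dk,
        flux_events_true=events,
        uropod_retraction_s=(ep.start_s + uropod_rel
                             if uropod_rel <= length else None),
        polarisation_start_s=ep.start_s + polar_rel,
        delivered=delivered,
        n_granules=preset.n_granules,
        granule_cluster_radius_um=preset.granule_cluster_radius_um,
    )


def simulate_population(preset: ConditionPreset, n_ctl: int, duration_s: float,
                        rng_seed: int, *, mode: str = "population",
                        ) -> list[GroundTruth]:
    """Simulate ``n_ctl`` CTLs for ``duration_s`` seconds at trace level.

    Parameters
    ----------
    mode
        ``"population"`` - each CTL carries a Poisson schedule of contact
        episodes against distinct targets (the 40-min dish experiment).
        ``"interaction"`` - exactly one episode per CTL, stable or transient
        per the preset (one movie per interaction).
        ``"stable"`` - one episode, conditioned on being a stable conjugate.
        ``"docked"`` - one episode, conditioned on centrosome docking.

    Returns
    -------
    list of :class:`GroundTruth`, one per CTL, reproducible for a fixed
    seed (bit-identical latent values).
    """
    if n_ctl < 1:
        raise ValueError("n_ctl must be >= 1")
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if mode not in ("population", "interaction", "stable", "docked"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "docked" and preset.p_dock == 0:
        raise ValueError(f"preset {preset.condition_name} never docks")

    streams = [np.random.default_rng(s)
               for s in np.random.SeedSequence(rng_seed).spawn(n_ctl)]
    truths = []
    for ctl_id, rng in enumerate(streams):
        if mode == "population":
            episodes, stables, docks = _schedule_episodes(
                preset, duration_s, rng)
            if not episodes:
                truths.append(GroundTruth(
                    ctl_id=ctl_id, condition=preset.condition_name,
                    episodes=[], principal=-1, stable=False, docked=False,
                    docking_time_s=None, closest_approach_um=None,
                    closest_approach_class=None, rear_position=False,
                    d0_um=np.nan, profile_t=np.array([]),
                    profile_d=np.array([]), flux_events_true=[],
                    uropod_retraction_s=None, polarisation_start_s=None,
                    delivered=None))
                continue
        else:
            if mode == "interaction":
                stable = bool(rng.random() < preset.p_stable_conjugate)
            else:
                stable = True
            if mode == "docked":
                dock = True
            else:
                dock = stable and bool(rng.random() < preset.p_dock)
            dwell = _draw_dwell(preset, stable, rng)
            dock_raw = None
            if dock:
                dock_raw = float(preset.docking_time_dist.sample(rng))
                dwell = max(dwell, dock_raw + 120.0)
            start = float(rng.uniform(25.0, 50.0))
            episodes = [Episode(start, min(start + dwell, duration_s), 0)]
            stables = [stable]
            docks = [dock_raw]
        truths.append(_make_truth(ctl_id, preset, episodes, stables, docks,
                                  rng, duration_s))
    return truths


# ---------------------------------------------------------------------------
# trace-level bridges to the measurement pipeline
# ---------------------------------------------------------------------------

def synthesize_calcium_values(truth: GroundTruth, n_frames: int,
                              frame_interval: float,
                              rng: np.random.Generator, *,
                              baseline: float = 100.0,
                              amplitude: float = 250.0,
                              noise_sd: float = 0.35) -> np.ndarray:
    """Frame-sampled whole-cell Ca2+ reporter intensity for one CTL.

    ``noise_sd`` is the noise of the whole-cell *mean* readout: averaging
    shot noise over the cell volume leaves sub-photon fluctuations, which
    is what the rendered pipeline route empirically shows (~0.36).
    """
    t = np.arange(n_frames) * frame_interval
    values = baseline + amplitude * truth.flux_state(t).astype(float)
    return values + rng.normal(0.0, noise_sd, size=n_frames)


def contact_frame_matrix(truths: list[GroundTruth], n_frames: int,
                         frame_interval: float,
                         ) -> dict[tuple[int, int], np.ndarray]:
    """Frame-sampled contact booleans per (ctl, target) pair.

    The half-open episode convention applies: frame ``k`` is a contact frame
    when ``start <= k * dt < end``.
    """
    t = np.arange(n_frames) * frame_interval
    out = {}
    for truth in truths:
        for ep in truth.episodes:
            key = (truth.ctl_id, ep.target_id)
            out[key] = (t >= ep.start_s) & (t < ep.end_s)
    return out
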