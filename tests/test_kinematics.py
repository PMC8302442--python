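"""Interaction tracks, centrosome traces, delivery filter, density maps."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from synapse4d.kinematics import (GranuleDeliveryRecord,
                                  classify_closest_approach,
                                  centrosome_trace,
                                  detect_interactions_from_contact,
                                  docking_fraction_by, granule_centrosome_distances,
                                  granule_density_map, interactions_per_ctl)


def _series(frames, n=40):
    s = np.zeros(n, dtype=bool)
    s[list(frames)] = True
    return s


class TestDetectInteractions:
    def test_contiguous_run_dwell(self):
        # contact in frames 3..10 inclusive, 10 s interval -> 80 s
        tracks = detect_interactions_from_contact(
            {(1, 1): _series(range(3, 11))}, 10.0)
        assert len(tracks) == 1
        t = tracks[0]
        assert (t.start_frame, t.end_frame) == (3, 11)
        assert t.dwell_s == 80.0

    def test_no_contact_no_track(self):
        assert detect_interactions_from_contact({(1, 1): _series([])},
                                                10.0) == []

    def test_gap_merging(self):
        # frames {2,3,5,6} with tolerance 1 -> one merged run spanning 2..6
        tracks = detect_interactions_from_contact(
            {(1, 1): _series([2, 3, 5, 6])}, 10.0, gap_tolerance_frames=1)
        assert len(tracks) == 1
        assert (tracks[0].start_frame, tracks[0].end_frame) == (2, 7)

    def test_gap_beyond_tolerance_splits(self):
        tracks = detect_interactions_from_contact(
            {(1, 1): _series([2, 3, 6, 7])}, 10.0, gap_tolerance_frames=1)
        assert len(tracks) == 2

    def test_dwell_conservation_without_merging(self):
        rng = np.random.default_rng(9)
        contact = {(1, k): rng.random(60) > 0.5 for k in range(5)}
        tracks = detect_interactions_from_contact(contact, 10.0,
                                                  gap_tolerance_frames=0)
        frames_in_tracks = sum(t.end_frame - t.start_frame for t in tracks)
        assert frames_in_tracks == sum(s.sum() for s in contact.values())

    def test_interactions_per_ctl(self):
        tracks = detect_interactions_from_contact(
            {(c, t): _series([5 + t]) for c in (1, 2, 3) for t in range(4)},
            10.0)
        assert interactions_per_ctl(tracks, 3) == 4.0
        assert interactions_per_ctl([], 3) == 0.0


class TestClassification:
    @pytest.mark.parametrize("closest,rear,expected", [
        (0.7, 0.4, "docked"),
        (3.0, 0.4, "proximal"),
        (1.0, 0.4, "proximal"),      # boundary: strict < 1 for docked
        (5.0, 0.4, "proximal"),      # boundary: 5 um still proximal
        (5.5, 0.4, "distal"),
        (5.5, 0.85, "uropod"),       # rear-third rule
        (5.5, None, "distal"),
    ])
    def test_class_boundaries(self, closest, rear, expected):
        assert classify_closest_approach(closest, rear) == expected

    @given(closest=st.floats(0.01, 12.0),
           rear=st.one_of(st.none(), st.floats(0.0, 1.2)))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_partition_exhaustive_exclusive(self, closest, rear):
        cls = classify_closest_approach(closest, rear)
        assert cls in ("docked", "proximal", "distal", "uropod")
        assert (cls == "docked") == (closest < 1.0)


class TestCentrosomeTrace:
    def _plane(self, x=10.0):
        yy, zz = np.meshgrid(np.arange(5.0), np.arange(5.0))
        return np.stack([zz.ravel(), yy.ravel(),
                         np.full(yy.size, x)], axis=1)

    def test_held_below_threshold_is_docked(self):
        surf = self._plane()
        pos = [np.array([2.0, 2.0, 10.0 - 0.7])] * 5
        tr = centrosome_trace(pos, [surf] * 5, 10.0)
        assert tr.closest_approach_class == "docked"
        assert tr.docking_time_s == 0.0

    def test_max_speed_finite_differences(self):
        # distances 10, 8, 6, 4 um at 10 s interval -> 0.2 um/s
        surf = self._plane()
        pos = [np.array([2.0, 2.0, 10.0 - d]) for d in (10, 8, 6, 4)]
        tr = centrosome_trace(pos, [surf] * 4, 10.0)
        assert tr.max_speed_um_per_s == pytest.approx(0.2)
        assert tr.closest_approach_um == pytest.approx(4.0)
        assert tr.closest_approach_class == "proximal"

    def test_no_contact_frames_raises(self):
        with pytest.raises(ValueError, match="not an interaction"):
            centrosome_trace([None] * 3, [None] * 3, 10.0)

    def test_docking_time_relative_to_contact_start(self):
        surf = self._plane()
        surfaces = [None, None, surf, surf, surf]
        pos = [None, None, np.array([2.0, 2.0, 7.0]),
               np.array([2.0, 2.0, 8.5]), np.array([2.0, 2.0, 9.5])]
        tr = centrosome_trace(pos, surfaces, 10.0)
        assert tr.contact_start_frame == 2
        assert tr.docking_time_s == 20.0  # frame 4, two frames after contact


class TestDockingFraction:
    def test_all_docked_at_zero(self):
        traces = [_mk_trace(0.0)] * 5
        assert docking_fraction_by(traces, 1.0) == 1.0

    def test_none_docked(self):
        traces = [_mk_trace(None)] * 5
        assert docking_fraction_by(traces, 600.0) == 0.0

    def test_monotone_in_cutoff(self):
        rng = np.random.default_rng(3)
        traces = [_mk_trace(float(rng.uniform(0, 900))
                            if rng.random() < 0.7 else None)
                  for _ in range(50)]
        cuts = np.linspace(10, 1000, 12)
        fracs = [docking_fraction_by(traces, c) for c in cuts]
        assert all(a <= b + 1e-12 for a, b in zip(fracs, fracs[1:]))


def _mk_trace(docking_time):
    from synapse4d.kinematics import CentrosomeTrace
    return CentrosomeTrace(
        distances_um=np.array([2.0]), frame_interval=10.0,
        contact_start_frame=0, docking_time_s=docking_time,
        closest_approach_um=0.5 if docking_time is not None else 2.0,
        closest_approach_class=("docked" if docking_time is not None
                                else "proximal"),
        max_speed_um_per_s=0.05)


class TestGranuleDelivery:
    def _surface(self):
        yy, zz = np.meshgrid(np.arange(5.0), np.arange(5.0))
        return np.stack([zz.ravel(), yy.ravel(),
                         np.full(yy.size, 10.0)], axis=1)

    def test_same_frame_rule_fires(self):
        surf = self._surface()
        cen = [np.array([2.0, 2.0, 9.6])]       # 0.4 um from synapse
        gran = [np.array([[2.0, 2.0, 9.7]])]    # 0.3 um from synapse
        rec = granule_centrosome_distances(gran, cen, [surf], 10.0)
        assert rec.delivered

    def test_undocked_centrosome_blocks_delivery(self):
        surf = self._surface()
        cen = [np.array([2.0, 2.0, 8.0])]       # 2 um: not docked
        gran = [np.array([[2.0, 2.0, 9.9]])]    # granule at the synapse
        rec = granule_centrosome_distances(gran, cen, [surf], 10.0)
        assert not rec.delivered

    def test_coincident_granule_distance_zero(self):
        surf = self._surface()
        cen = [np.array([2.0, 2.0, 8.0])]
        gran = [np.array([[2.0, 2.0, 8.0]])]
        rec = granule_centrosome_distances(gran, cen, [surf], 10.0)
        assert rec.granule_centrosome_um[0][0] == pytest.approx(0.0)


class TestDensityMap:
    def _rec(self, times, dists):
        return GranuleDeliveryRecord(
            granule_centrosome_um=[np.atleast_1d(d) for d in dists],
            granule_synapse_um=[np.atleast_1d(d) for d in dists],
            times_since_contact_s=np.asarray(times, dtype=float),
            delivered=False)

    def test_single_bin_is_one(self):
        rec = self._rec([0.0, 0.0], [1.0, 1.2])
        m = granule_density_map([rec], 60.0, 2.0)
        assert m.max() == 1.0
        assert (m == 1.0).sum() == 1
        assert m.sum() == 1.0

    def test_uniform_bins_all_one(self):
        rec = self._rec([10.0, 70.0, 10.0, 70.0], [0.5, 0.5, 2.5, 2.5])
        m = granule_density_map([rec], 60.0, 2.0, t_max_s=120.0,
                                d_max_um=4.0)
        assert np.all(m[m > 0] == 1.0)
        assert (m > 0).sum() == 4

    def test_tight_cluster_has_lower_entropy(self):
        """Strong-signal granules keep uniform centrosome distances: the
        density map concentrates (lower entropy) versus a weak-signal
        spread."""
        rng = np.random.default_rng(8)
        times = np.repeat(np.arange(0, 600, 20.0), 8)

        def rec(spread):
            d = np.abs(rng.normal(1.2, spread, size=times.size))
            return self._rec(times, list(d))

        def entropy(m):
            p = m[m > 0] / m[m > 0].sum()
            return -(p * np.log(p)).sum()

        m_tight = granule_density_map([rec(0.15)], 60.0, 0.5, d_max_um=6.0)
        m_wide = granule_density_map([rec(1.2)], 60.0, 0.5, d_max_um=6.0)
        assert entropy(m_tight) < entropy(m_wide)

    def test_no_observations_raises(self):
        with pytest.raises(ValueError):
            granule_density_map([], 60.0, 1.0)
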