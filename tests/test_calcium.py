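"""Ca2+ trace extraction and flux-event detection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from synapse4d.calcium import (AssociationRecord, CalciumTrace,
                               detect_flux_events, flux_docking_association,
                               latency_metrics, primary_flux_duration,
                               primary_flux_event)


def _trace(values, dt=5.0, contact=None):
    return CalciumTrace.from_values(np.asarray(values, dtype=float), dt,
                                    first_contact_frame=contact)


def _square(n, onset, end, base=100.0, amp=200.0):
    v = np.full(n, base)
    v[onset:end] = base + amp
    return v


class TestDetection:
    def test_flat_trace_no_events(self):
        assert detect_flux_events(_trace([100.0] * 40)) == []

    def test_square_pulse_duration(self):
        # above threshold from frame 10, back at frame 30, 5 s -> 100 s
        ev = detect_flux_events(_trace(_square(50, 10, 30)))
        assert len(ev) == 1
        assert (ev[0].onset_frame, ev[0].end_frame) == (10, 30)
        assert ev[0].duration_s == 100.0
        assert not ev[0].censored

    def test_two_excursions_first_primary(self):
        v = _square(60, 10, 20) + _square(60, 35, 45) - 100.0
        ev = detect_flux_events(_trace(v, contact=5))
        assert len(ev) == 2
        assert ev[0].is_primary and not ev[1].is_primary

    def test_unterminated_event_censored(self):
        ev = detect_flux_events(_trace(_square(40, 30, 40)))
        assert ev[0].censored
        assert ev[0].end_frame == 40

    def test_nan_frames_not_interpolated(self):
        v = _square(40, 10, 30)
        v[15] = np.nan
        ev = detect_flux_events(_trace(v))
        # nan terminates; two sub-events, durations still frame multiples
        assert len(ev) == 2

    @given(k=st.floats(1.0, 8.0), k2=st.floats(0.0, 6.0))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_raising_threshold_never_extends_events(self, k, k2):
        # the above-threshold set shrinks with k: total detected duration
        # is non-increasing and every high-k event nests inside a low-k one
        # (a noise dip may *split* an event, so the count alone need not
        # decrease)
        rng = np.random.default_rng(17)
        v = 100 + 5 * rng.standard_normal(80)
        v[20:40] += 60
        v[55:60] += 25
        tr = _trace(v)
        lo, hi = sorted([k, k + k2])
        ev_lo = detect_flux_events(tr, lo)
        ev_hi = detect_flux_events(tr, hi)
        assert (sum(e.duration_s for e in ev_hi)
                <= sum(e.duration_s for e in ev_lo))
        for e in ev_hi:
            assert any(a.onset_frame <= e.onset_frame
                       and e.end_frame <= a.end_frame for a in ev_lo)

    def test_durations_are_frame_interval_multiples(self):
        rng = np.random.default_rng(21)
        v = 100 + 3 * rng.standard_normal(100)
        v[30:52] += 80
        for ev in detect_flux_events(_trace(v, dt=7.5)):
            assert ev.duration_s % 7.5 == pytest.approx(0.0)


class TestPrimarySelection:
    def test_event_before_contact_excluded(self):
        v = _square(60, 5, 15) + _square(60, 30, 40) - 100.0
        events = detect_flux_events(_trace(v))
        ev = primary_flux_event(events, first_contact_frame=20)
        assert ev.onset_frame == 30
        assert primary_flux_duration(events, 20) == 50.0

    def test_no_post_contact_event_raises(self):
        events = detect_flux_events(_trace(_square(40, 5, 10)))
        with pytest.raises(ValueError):
            primary_flux_event(events, first_contact_frame=20)


class TestBackground:
    def test_background_from_precontact_frames(self):
        v = np.concatenate([np.full(10, 80.0), np.full(30, 300.0)])
        tr = _trace(v, contact=10)
        assert tr.background == pytest.approx(80.0)

    def test_fallback_first_three_frames(self):
        v = np.concatenate([np.full(3, 90.0), np.full(30, 300.0)])
        tr = _trace(v, contact=1)
        assert tr.background == pytest.approx(90.0)

    def test_spread_positive(self):
        tr = _trace([100.0] * 20)
        assert tr.background_spread > 0


class TestLatencies:
    def test_flux_to_docking(self):
        # flux onset at 50 s, docking at 478 s -> 428 s
        v = _square(120, 10, 40)
        events = detect_flux_events(_trace(v, contact=8))
        rec = latency_metrics(events, 5.0, contact_time_s=40.0,
                              docking_time_s=478.0)
        assert rec.contact_to_flux_s == pytest.approx(10.0)
        assert rec.flux_to_docking_s == pytest.approx(428.0)

    def test_absent_events_reported_absent(self):
        v = _square(120, 10, 40)
        events = detect_flux_events(_trace(v, contact=8))
        rec = latency_metrics(events, 5.0, contact_time_s=40.0)
        assert rec.flux_to_docking_s is None
        assert rec.flux_to_uropod_retraction_s is None

    def test_event_before_reference_warns_absent(self, caplog):
        v = _square(120, 10, 40)
        events = detect_flux_events(_trace(v, contact=8))
        with caplog.at_level("WARNING"):
            rec = latency_metrics(events, 5.0, contact_time_s=40.0,
                                  uropod_retraction_s=20.0)
        assert rec.flux_to_uropod_retraction_s is None
        assert any("precedes" in r.message for r in caplog.records)


class TestAssociation:
    def _rec(self, dur, cls, cond="N4", censored=False):
        return AssociationRecord(dur, censored, cls, cond)

    def test_docked_group_mean_recovered(self):
        recs = [self._rec(207.0, "docked") for _ in range(10)]
        recs += [self._rec(60.0, "proximal") for _ in range(5)]
        summary, frac, violations = flux_docking_association(recs)
        docked = summary[summary.closest_approach_class == "docked"]
        assert docked["mean"].iloc[0] == pytest.approx(207.0)
        assert frac == 1.0
        assert violations == []

    def test_short_docked_flux_flagged_not_error(self):
        recs = [self._rec(40.0, "docked"), self._rec(207.0, "docked")]
        summary, frac, violations = flux_docking_association(recs)
        assert len(violations) == 1
        assert frac == pytest.approx(0.5)

    def test_empty_class_absent_row(self):
        recs = [self._rec(60.0, "proximal")]
        summary, frac, _ = flux_docking_association(recs)
        assert "docked" not in set(summary.closest_approach_class)
        assert np.isnan(frac)

    def test_censored_excluded_by_default(self):
        recs = [self._rec(100.0, "docked", censored=True),
                self._rec(200.0, "docked")]
        summary, _, _ = flux_docking_association(recs)
        assert summary.n.iloc[0] == 1
        summary2, _, _ = flux_docking_association(recs,
                                                  include_censored=True)
        assert summary2.n.iloc[0] == 2
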