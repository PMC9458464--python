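"""Trace preprocessing, rupture detection/classification, re-rupture statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import curve_fit

from conftest import classifier_performance, fisher_two_sided_oracle
from nerupture import synthetic
from nerupture.rupture import (
    RuptureEvent,
    align_recovery,
    build_rerupture_table,
    detect_ruptures,
    fisher_exact_2x2,
    preprocess_trace,
    rerupture_intervals,
    track_nuclei,
)


def make_label_movie(positions_per_frame, shape=(80, 80), radius=5):
    """Label maps from per-frame lists of (label, y, x)."""
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    movie = []
    for frame in positions_per_frame:
        lbl = np.zeros(shape, dtype=np.int32)
        for lab, y, x in frame:
            lbl[(yy - y) ** 2 + (xx - x) ** 2 <= radius**2] = lab
        movie.append(lbl)
    return movie


class TestTracking:
    def test_static_nuclei_full_identity_tracks(self):
        frames = [[(1, 20, 20), (2, 60, 60)]] * 6
        tracks = track_nuclei(make_label_movie(frames))
        assert tracks.groupby("track_id").size().tolist() == [6, 6]
        assert (tracks[tracks.track_id == 1].label == 1).all()

    def test_drift_within_gate_keeps_tracks(self):
        frames = [[(1, 20 + 2 * f, 20), (2, 60, 20 + 2 * f)] for f in range(8)]
        tracks = track_nuclei(make_label_movie(frames), max_displacement=10)
        assert tracks.groupby("track_id").size().tolist() == [8, 8]

    def test_disappearance_truncates_track(self):
        frames = [[(1, 20, 20), (2, 60, 60)]] * 3 + [[(2, 60, 60)]] * 3
        tracks = track_nuclei(make_label_movie(frames))
        lengths = tracks.groupby("track_id").size()
        assert sorted(lengths.tolist()) == [3, 6]

    def test_mean_intensity_extracted(self):
        frames = [[(1, 20, 20)]] * 4
        movie = make_label_movie(frames)
        images = [np.full((80, 80), 10.0 * (f + 1)) for f in range(4)]
        tracks = track_nuclei(movie, images=images)
        assert tracks.mean_intensity.tolist() == [10.0, 20.0, 30.0, 40.0]


class TestPreprocess:
    def test_constant_trace_normalizes_to_one(self):
        t = preprocess_trace(np.full(30, 110.0), background=10.0)
        np.testing.assert_allclose(t.normalized, 1.0)

    def test_reference_window_mean_is_one(self):
        rng = np.random.default_rng(0)
        raw = 100 + rng.normal(0, 5, 50)
        t = preprocess_trace(raw, background=0.0, rupture_onset=20)
        assert t.normalized[15:20].mean() == pytest.approx(1.0)

    def test_negative_values_not_clipped(self):
        raw = np.array([100.0] * 10 + [5.0] * 5)
        t = preprocess_trace(raw, background=50.0)
        assert (t.normalized[-5:] < 0).all()

    def test_nonpositive_reference_flagged(self):
        t = preprocess_trace(np.full(20, 5.0), background=10.0)
        assert not t.usable and t.normalized is None


class TestDetect:
    def test_constant_trace_no_events(self):
        assert detect_ruptures(np.ones(100)) == []

    def test_programmed_major_event_recovered(self):
        spec = synthetic.SyntheticTraceSpec(
            n_frames=160, events=((50, 0.5, 1.0, 10.0),), noise_sd=0.01, seed=3
        )
        trace, _ = synthetic.generate_rupture_trace(spec)
        t = preprocess_trace(trace, spec.background)
        events = detect_ruptures(t.normalized)
        assert len(events) == 1
        ev = events[0]
        assert ev.classification == "major"
        assert abs(ev.onset_frame - 50) <= 2
        assert ev.magnitude == pytest.approx(0.5, abs=0.05)

    @pytest.mark.parametrize(
        "loss,expected", [(0.2, "minor"), (0.29, "minor"), (0.31, "major")]
    )
    def test_classification_boundary(self, loss, expected):
        spec = synthetic.SyntheticTraceSpec(
            n_frames=120, events=((40, loss, 1.0, 10.0),), noise_sd=0.0
        )
        trace, _ = synthetic.generate_rupture_trace(spec)
        t = preprocess_trace(trace, spec.background)
        events = detect_ruptures(t.normalized)
        assert [e.classification for e in events] == [expected]

    def test_detection_performance_on_noisy_traces(self):
        sens, prec = classifier_performance(n_traces=50, seed=99)
        assert sens >= 0.95 and prec >= 0.95


class TestAlignRecovery:
    def _events_and_traces(self, n, tau, noise, seed0):
        traces, events = [], []
        for k in range(n):
            spec = synthetic.SyntheticTraceSpec(
                n_frames=150, events=((30, 0.5, 1.0, tau),),
                noise_sd=noise, seed=seed0 + k,
            )
            trace, _ = synthetic.generate_rupture_trace(spec)
            t = preprocess_trace(trace, spec.background)
            evs = detect_ruptures(t.normalized)
            traces.append(t.normalized)
            events.append(evs[0])
        return traces, events

    def test_identical_events_zero_sd(self):
        traces, events = self._events_and_traces(3, 10.0, 0.0, 0)
        curve = align_recovery(traces, events, window=30)
        np.testing.assert_allclose(curve.sd.iloc[1:], 0.0, atol=1e-12)
        assert curve.frame_offset.iloc[0] == 0

    def test_recovery_time_constant_recovered(self):
        traces, events = self._events_and_traces(50, 10.0, 0.01, 400)
        curve = align_recovery(traces, events, window=80)
        nadir = int(curve["mean"].idxmin())
        seg = curve.iloc[nadir:]
        t = (seg.frame_offset - seg.frame_offset.iloc[0]).to_numpy(float)

        def model(t, tau, depth):
            return 1.0 - depth * np.exp(-t / tau)

        popt, _ = curve_fit(model, t, seg["mean"], p0=(5.0, 0.5))
        assert popt[0] == pytest.approx(10.0, rel=0.10)

    def test_single_event_sd_missing(self):
        traces, events = self._events_and_traces(1, 10.0, 0.0, 7)
        curve = align_recovery(traces, events, window=10)
        assert curve.sd.isna().all()


def ev(onset, major=True):
    return RuptureEvent(
        onset_frame=onset, nadir_frame=onset + 3,
        magnitude=0.5 if major else 0.1,
        classification="major" if major else "minor",
        recovered_frame=onset + 20, baseline=1.0,
    )


class TestReRupture:
    def test_interval_binning_arithmetic(self):
        events = [[ev(0), ev(10, major=False)]]
        intervals, hist = rerupture_intervals(events, [200], frame_interval_min=3.0)
        assert intervals == [30.0]
        assert hist.counts[2] == 1  # [30, 45)

    def test_no_next_event_goes_to_overflow(self):
        intervals, hist = rerupture_intervals([[ev(0)]], [36])
        assert hist.overflow == 1 and hist.counts.sum() == 0

    def test_short_follow_up_excluded(self):
        intervals, hist = rerupture_intervals([[ev(0)]], [21])
        assert hist.total == 0 and intervals == []

    @given(
        st.lists(
            st.tuples(st.integers(0, 150), st.booleans()), min_size=0, max_size=6
        )
    )
    @settings(deadline=None, max_examples=50)
    def test_histogram_conserves_qualifying_majors(self, raw_events):
        events = []
        seen = set()
        for o, m in sorted(raw_events):
            if o not in seen:
                events.append(ev(o, major=m))
                seen.add(o)
        length = 200
        qualifying = sum(
            1 for e in events if e.is_major and (length - 1 - e.onset_frame) >= 30
        )
        _, hist = rerupture_intervals([events], [length])
        assert hist.total == qualifying


class TestFisherExact:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ([[1, 1], [1, 1]], 1.0),
            ([[3, 1], [1, 3]], 34 / 70),
            ([[0, 5], [5, 0]], 2 / 252),
        ],
    )
    def test_known_values(self, table, expected):
        assert fisher_exact_2x2(table) == pytest.approx(expected, rel=1e-12)

    def test_zero_margin_convention(self):
        assert fisher_exact_2x2([[0, 0], [3, 4]]) == 1.0

    @given(st.tuples(*[st.integers(0, 10)] * 4))
    @settings(deadline=None, max_examples=200)
    def test_matches_enumeration_oracle(self, cells):
        a, b, c, d = cells
        table = [[a, b], [c, d]]
        if min(a + b, c + d, a + c, b + d) == 0:
            assert fisher_exact_2x2(table) == 1.0
        else:
            oracle = float(fisher_two_sided_oracle(table))
            assert fisher_exact_2x2(table) == pytest.approx(oracle, rel=1e-9)

    def test_rerupture_table_construction(self):
        table = build_rerupture_table([100.0, np.inf, 30.0], [10.0, 20.0])
        np.testing.assert_array_equal(table, [[2, 1], [0, 2]])
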