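"""Thresholding, segmentation, event FRET, population fits, QC."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aptakinetics import (
    BindingSegment,
    FluorescenceTrace,
    analyze_trace,
    fit_fret_peak,
    fit_fret_populations,
    qc_filter,
    segment_trace,
    threshold_total_intensity,
)
from aptakinetics.segmentation import estimate_background, event_fret


def _trace(total: np.ndarray, split: float = 0.5) -> FluorescenceTrace:
    total = np.asarray(total, dtype=float)
    return FluorescenceTrace("m", 0.1, (1 - split) * total, split * total)


class TestThreshold:
    def test_two_level_signal_threshold_is_midpoint(self):
        s = np.tile([200.0, 1200.0], 50)
        assert threshold_total_intensity(_trace(s)) == pytest.approx(700.0)

    def test_constant_signal_flags_no_binding(self):
        assert threshold_total_intensity(_trace(np.full(100, 500.0))) is None

    def test_pure_noise_flags_no_binding(self, rng):
        s = rng.normal(200.0, 30.0, 2000)
        assert threshold_total_intensity(_trace(s)) is None

    def test_noisy_two_level_misclassification_below_0p1pct(self, rng):
        # oracle: classify by distance to the true level means
        levels = rng.random(3000) < 0.3
        s = np.where(levels, rng.normal(1000, 50, 3000), rng.normal(200, 30, 3000))
        thr = threshold_total_intensity(_trace(s))
        assert thr is not None
        oracle = np.abs(s - 1000) < np.abs(s - 200)
        mismatch = np.mean((s > thr) != oracle)
        assert mismatch < 1e-3

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError, match="10 frames"):
            threshold_total_intensity(_trace(np.arange(5.0)))

    @given(shift=st.floats(-500.0, 500.0))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_affine_shift_moves_threshold_by_shift(self, shift):
        s = np.tile([200.0, 1200.0], 50)
        base = threshold_total_intensity(_trace(s))
        shifted = threshold_total_intensity(
            FluorescenceTrace("m", 0.1, 0.5 * s + shift / 2, 0.5 * s + shift / 2)
        )
        assert shifted == pytest.approx(base + shift, abs=1e-9)


class TestSegmentation:
    def test_min_frames_boundary_run_of_3_dropped_4_kept(self):
        s = np.full(30, 200.0)
        s[5:8] = 1200.0  # 3 frames: dropped
        s[15:19] = 1200.0  # 4 frames: kept
        seg = segment_trace(_trace(s), 700.0, min_frames=4)
        assert [(x.start_frame, x.end_frame) for x in seg.segments] == [(15, 19)]
        assert seg.subthreshold_runs == ((5, 8),)

    def test_all_frames_below_threshold_gives_zero_segments(self):
        seg = segment_trace(_trace(np.full(50, 200.0)), 700.0)
        assert seg.segments == ()

    def test_none_threshold_is_event_free(self):
        seg = segment_trace(_trace(np.full(50, 200.0)), None)
        assert seg.segments == () and seg.threshold is None

    def test_segments_match_ground_truth_run_length_encoding(
        self, noiseless_ensemble
    ):
        # oracle: run-length encode the frame-discretized hidden state;
        # exact mid-level threshold on the noiseless render
        cfg, traces, truth = noiseless_ensemble
        mid = 2 * cfg.background_mean + cfg.total_intensity / 2
        for trace in traces:
            m = truth[trace.molecule_id]
            occ = m.path.frame_occupancy(cfg.n_frames, cfg.frame_interval)
            high = occ > 0.5
            padded = np.diff(np.r_[0, high.astype(np.int8), 0])
            runs = list(zip(np.flatnonzero(padded == 1),
                            np.flatnonzero(padded == -1)))
            expected = [(a, b) for a, b in runs if b - a >= 4]
            seg = analyze_trace(trace, threshold=mid)
            got = [(s.start_frame, s.end_frame) for s in seg.segments]
            assert got == expected


class TestEventFret:
    def test_exact_arithmetic(self):
        tr = FluorescenceTrace("m", 0.1, np.full(10, 62.0), np.full(10, 38.0))
        assert event_fret(tr, BindingSegment(0, 10)) == pytest.approx(0.38)

    def test_donor_only_event_is_zero(self):
        tr = FluorescenceTrace("m", 0.1, np.full(10, 100.0), np.zeros(10))
        assert event_fret(tr, BindingSegment(0, 10)) == 0.0

    def test_equal_channels_give_half(self):
        tr = FluorescenceTrace("m", 0.1, np.full(10, 50.0), np.full(10, 50.0))
        assert event_fret(tr, BindingSegment(0, 10)) == pytest.approx(0.5)

    def test_nonpositive_frames_excluded_then_error(self):
        tr = FluorescenceTrace("m", 0.1, np.zeros(5), np.zeros(5))
        with pytest.raises(ValueError, match="positive total intensity"):
            event_fret(tr, BindingSegment(0, 5))

    def test_background_subtraction_recovers_true_fret(self, rng):
        # bound frames at E=0.4 on top of background 100 per channel
        n = 200
        donor = np.full(n, 100.0)
        acceptor = np.full(n, 100.0)
        donor[50:100] += 600.0
        acceptor[50:100] += 400.0
        tr = FluorescenceTrace("m", 0.1, donor, acceptor)
        thr = threshold_total_intensity(tr)
        bg = estimate_background(tr, thr)
        assert bg == pytest.approx((100.0, 100.0))
        assert event_fret(tr, BindingSegment(50, 100), bg) == pytest.approx(0.4)


class TestFretPopulations:
    def test_two_iid_populations_recovered(self, rng):
        # generator parameters are the oracle
        e = np.concatenate(
            [rng.normal(0.0, 0.05, 500), rng.normal(0.38, 0.14, 500)]
        )
        model = fit_fret_populations(e)
        assert len(model.components) == 2
        means = sorted(c[1] for c in model.components)
        assert means[0] == pytest.approx(0.0, abs=0.02)
        assert means[1] == pytest.approx(0.38, abs=0.02)

    def test_single_component_mean_is_sample_mean(self, rng):
        e = rng.normal(0.4, 0.1, 300)
        model = fit_fret_populations(e, max_components=1)
        assert len(model.components) == 1
        assert model.components[0][1] == pytest.approx(e.mean(), abs=1e-6)

    def test_weights_sum_to_one(self, rng):
        e = np.concatenate([rng.normal(0.05, 0.04, 300), rng.normal(0.5, 0.1, 300)])
        model = fit_fret_populations(e)
        assert sum(c[0] for c in model.components) == pytest.approx(1.0)

    def test_too_few_events_rejected(self):
        with pytest.raises(ValueError, match="20 events"):
            fit_fret_populations([0.4] * 10)

    def test_truncated_peak_fit_unbiased(self, rng):
        # events above the donor-only cut only; plain mean would be biased
        e = rng.normal(0.38, 0.14, 4000)
        mu, sd = fit_fret_peak(e, donor_only_cut=0.15)
        naive = e[e >= 0.15].mean()
        assert abs(mu - 0.38) < 0.01
        assert naive - 0.38 > 0.01  # the bias the MLE removes
        assert sd == pytest.approx(0.14, abs=0.015)


class TestQcFilter:
    def _seg(self, n_events):
        segs = tuple(BindingSegment(10 * i, 10 * i + 5) for i in range(n_events))
        from aptakinetics import SegmentedTrace

        return SegmentedTrace("m", 700.0, segs, (), 1000)

    def test_boundary_nine_rejected_ten_kept(self):
        kept, counts = qc_filter([self._seg(9), self._seg(10)], min_events=10)
        assert counts == {"kept": 1, "rejected": 1}
        assert kept[0].n_events == 10

    def test_empty_input(self):
        kept, counts = qc_filter([], min_events=10)
        assert kept == [] and counts == {"kept": 0, "rejected": 0}
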