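"""Dwell extraction, truncated-exponential fitting, rate arithmetic."""

import numpy as np
import pytest

from aptakinetics import (
    BindingSegment,
    ExponentialFit,
    SegmentedTrace,
    analyze_trace,
    estimate_kinetics,
    extract_dwells,
    fit_bound_dwells,
    fit_unbound_dwells,
    qc_filter,
    rates,
    summarize_replicates,
)
from aptakinetics.kinetics import fit_exponential


def _segtrace(spans, n_total=1000, short=()):
    segs = tuple(BindingSegment(a, b) for a, b in spans)
    return SegmentedTrace("m", 700.0, segs, tuple(short), n_total)


class TestExtractDwells:
    def test_gap_of_20_frames_is_2s_unbound_dwell(self):
        d = extract_dwells([_segtrace([(100, 110), (130, 140)])], 5e-9, 0.1)
        interior = d.unbound[~d.unbound_censored]
        assert list(interior) == [pytest.approx(2.0)]

    def test_segment_at_frame_zero_is_censored(self):
        d = extract_dwells([_segtrace([(0, 10), (50, 60)])], 5e-9, 0.1)
        assert d.bound_censored.tolist() == [True, False]

    def test_subthreshold_run_splits_the_gap(self):
        # a discarded 2-frame event inside a gap yields two unbound dwells
        d = extract_dwells(
            [_segtrace([(100, 110), (160, 170)], short=[(130, 132)])], 5e-9, 0.1
        )
        interior = sorted(d.unbound[~d.unbound_censored])
        assert interior == [pytest.approx(2.0), pytest.approx(2.8)]
        d_merged = extract_dwells(
            [_segtrace([(100, 110), (160, 170)], short=[(130, 132)])],
            5e-9, 0.1, split_gaps_at_subthreshold=False,
        )
        assert list(d_merged.unbound[~d_merged.unbound_censored]) == [
            pytest.approx(5.0)
        ]

    def test_interior_dwells_match_ground_truth_within_one_frame(
        self, noiseless_ensemble
    ):
        cfg, traces, truth = noiseless_ensemble
        mid = 2 * cfg.background_mean + cfg.total_intensity / 2
        segs = [analyze_trace(t, threshold=mid) for t in traces]
        d = extract_dwells(segs, cfg.c, cfg.frame_interval)
        got = np.sort(d.bound[~d.bound_censored])
        expected = []
        for m in truth.molecules:
            ivs = list(m.path.intervals())
            for i, (state, t0, t1) in enumerate(ivs):
                if state and 0 < i < len(ivs) - 1 and (t1 - t0) >= 0.35:
                    expected.append(t1 - t0)
        expected = np.sort(expected)
        # same dwell count up to filter-boundary cases (true durations just
        # at the 4-frame cut land on either side depending on frame phase)
        assert abs(len(got) - len(expected)) <= 0.05 * len(expected)
        # interior quantiles of the two multisets agree to one frame
        qs = np.linspace(0.1, 0.9, 9)
        dq = np.abs(np.quantile(got, qs) - np.quantile(expected, qs))
        assert np.all(dq <= cfg.frame_interval + 1e-9)


class TestExponentialFit:
    def test_truncated_mle_unbiased_at_n_10000(self):
        # memorylessness oracle: E[X | X > t] = t + 1/lambda
        rng = np.random.default_rng(123)
        x = rng.exponential(2.0, 40_000)
        x = x[x >= 0.4][:10_000]
        fit = fit_exponential(x, np.zeros(len(x), bool), truncation=0.4)
        se = fit.mean_dwell / np.sqrt(fit.n_used)
        assert abs(fit.mean_dwell - 2.0) < 3 * se

    def test_zero_truncation_equals_sample_mean(self):
        x = np.array([1.0, 2.0, 3.0] * 20)
        fit = fit_exponential(x, np.zeros(len(x), bool), truncation=0.0)
        assert fit.mean_dwell == pytest.approx(2.0)

    def test_too_few_dwells_errors_naming_side(self):
        with pytest.raises(ValueError, match="bound"):
            fit_exponential(
                np.ones(10), np.zeros(10, bool), min_n=50, side="bound"
            )

    def test_frame_quantized_truncation_exactly_unbiased(self):
        # sampling oracle: exponential dwells detected as >=0.5-occupancy
        # frame counts, kept at n >= 4; the (min_frames - 0.5)*dt rule
        # recovers the true mean
        rng = np.random.default_rng(5)
        tau, dt = 1.0 / 0.7, 0.1
        t = rng.exponential(tau, 200_000)
        phase = rng.uniform(0, dt, len(t))
        # frames with >half coverage for a dwell [phase, phase + t)
        n_frames = np.floor((phase + t) / dt + 0.5) - np.floor(phase / dt + 0.5)
        kept = n_frames >= 4
        durations = n_frames[kept] * dt
        fit = fit_exponential(
            durations, np.zeros(kept.sum(), bool), truncation=3.5 * dt
        )
        assert abs(fit.mean_dwell - tau) < 0.01 * tau

    def test_histogram_mode_close_to_mle(self):
        rng = np.random.default_rng(8)
        x = rng.exponential(2.0, 5000)
        mle = fit_exponential(x, np.zeros(len(x), bool))
        hist = fit_exponential(x, np.zeros(len(x), bool), method="histogram")
        assert hist.mean_dwell == pytest.approx(mle.mean_dwell, rel=0.1)


class TestRates:
    def test_reciprocal_and_ratio(self):
        fb = ExponentialFit(1.429, 0.01, 1000, 0.35)
        fu = ExponentialFit(2.857, 0.02, 1000, 0.05)
        est = rates(fb, fu, 5e-9)
        assert est.k_off == pytest.approx(0.6998, abs=1e-3)
        assert est.k_on == pytest.approx(7.0e7, rel=1e-3)
        assert est.K_d == pytest.approx(10e-9, rel=2e-3)

    def test_kd_identity_holds_by_construction(self):
        fb = ExponentialFit(1.0, 0.1, 100, 0.0)
        fu = ExponentialFit(4.0, 0.1, 100, 0.0)
        est = rates(fb, fu, 3e-9)
        assert est.K_d == pytest.approx(est.k_off / est.k_on, rel=1e-12)

    def test_replicate_summary_hand_arithmetic(self):
        ests = [
            rates(ExponentialFit(1 / k, 0.1, 100, 0), ExponentialFit(2.0, 0.1, 100, 0), 5e-9)
            for k in (0.6, 0.7, 0.8)
        ]
        s = summarize_replicates(ests)
        assert s.k_off_mean == pytest.approx(0.7)
        assert s.k_off_sd == pytest.approx(0.1)
        assert s.sd_defined

    def test_identical_replicates_sd_zero(self):
        est = rates(
            ExponentialFit(1.0, 0.1, 100, 0), ExponentialFit(2.0, 0.1, 100, 0), 5e-9
        )
        s = summarize_replicates([est, est, est])
        assert s.k_off_sd == pytest.approx(0.0)

    def test_single_replicate_sd_undefined(self):
        est = rates(
            ExponentialFit(1.0, 0.1, 100, 0), ExponentialFit(2.0, 0.1, 100, 0), 5e-9
        )
        s = summarize_replicates([est])
        assert not s.sd_defined and np.isnan(s.k_off_sd)

    def test_empty_replicates_rejected(self):
        with pytest.raises(ValueError):
            summarize_replicates([])


class TestEndToEnd:
    def test_discretization_bias_small_for_long_dwells(self, small_ensemble):
        # mean bound dwell 14 frames; recovered k_off within 5% of truth
        cfg, traces, _ = small_ensemble
        kept, _ = qc_filter([analyze_trace(t) for t in traces])
        est = estimate_kinetics(kept, cfg.c, cfg.frame_interval)
        assert est.k_off == pytest.approx(cfg.k_off, rel=0.05)

    def test_kon_recovery_uses_subthreshold_runs(self, small_ensemble):
        # with fast k_off the literal kept-segment gaps overestimate tau_ub
        cfg, traces, _ = small_ensemble
        kept, _ = qc_filter([analyze_trace(t) for t in traces])
        est_split = estimate_kinetics(kept, cfg.c, cfg.frame_interval)
        est_merged = estimate_kinetics(
            kept, cfg.c, cfg.frame_interval, split_gaps_at_subthreshold=False
        )
        assert est_split.k_on == pytest.approx(cfg.k_on, rel=0.10)
        assert est_merged.k_on < est_split.k_on  # known bias direction
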