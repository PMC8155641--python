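import numpy as np
import pytest

from spikeconn import RawTrace, SimConfig, render_trace, simulate_poisson_train
from spikeconn import spike_detection as sd
from oracles import min_window_std_brute


def _trace(values, frame_rate=500.0):
    return RawTrace(values=np.asarray(values, float), frame_rate=frame_rate)


def _make_labels(labels):
    """Build FrameLabels from an int array, padding the subthreshold class
    (from trailing baseline frames) to satisfy the size-ordering invariant."""
    labels = np.asarray(labels, int).copy()
    n_spike = (labels == sd.SPIKE).sum()
    n_sub = (labels == sd.SUBTHRESHOLD).sum()
    if n_sub < n_spike:
        base_idx = np.flatnonzero(labels == sd.BASELINE)
        labels[base_idx[-(n_spike - n_sub):]] = sd.SUBTHRESHOLD
    sizes = {cat: int((labels == cat).sum())
             for cat in (sd.BASELINE, sd.SUBTHRESHOLD, sd.SPIKE)}
    return sd.FrameLabels(labels=labels, cluster_sizes=sizes)


class TestClusterFrames:
    def test_separable_levels_assigned_by_size(self):
        # 980 baseline-level frames, 15 intermediate, 5 bright
        rng = np.random.default_rng(1)
        values = np.concatenate([
            rng.normal(100, 0.5, 980), np.full(15, 115.0), np.full(5, 160.0)])
        rng.shuffle(values)
        labels = sd.cluster_frames(_trace(values), seed=0)
        assert (labels.labels == sd.SPIKE).sum() == 5
        assert values[labels.labels == sd.SPIKE].min() == 160.0
        assert (labels.labels == sd.BASELINE).sum() == 980
        assert (labels.labels == sd.SUBTHRESHOLD).sum() == 15

    def test_constant_trace_degenerate(self):
        with pytest.raises(sd.DegenerateTraceError):
            sd.cluster_frames(_trace(np.full(100, 5.0)))

    def test_too_short_trace_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            sd.cluster_frames(_trace(np.arange(10.0)))

    def test_partition_and_size_ordering(self, flat_trace):
        labels = sd.cluster_frames(flat_trace, seed=0)
        sizes = labels.cluster_sizes
        assert sum(sizes.values()) == len(flat_trace)
        assert sizes[sd.BASELINE] >= sizes[sd.SUBTHRESHOLD] >= sizes[sd.SPIKE]

    def test_deterministic_given_seed(self, flat_trace):
        l1 = sd.cluster_frames(flat_trace, seed=3)
        l2 = sd.cluster_frames(flat_trace, seed=3)
        np.testing.assert_array_equal(l1.labels, l2.labels)


class TestExtractEvents:
    def test_runs_merge_into_single_events(self):
        values = np.full(100, 10.0)
        labels = np.zeros(100, int)
        labels[[10, 11, 50]] = sd.SPIKE
        values[11] = 20.0  # peak of the first run
        events = sd.extract_events(_trace(values), _make_labels(labels))
        assert [e.onset_frame for e in events] == [10, 50]
        assert events[0].peak_frame == 11
        assert events[0].peak_time == 22.0  # 11 frames * 2 ms

    def test_three_consecutive_frames_one_event(self):
        labels = np.zeros(100, int)
        labels[40:43] = sd.SPIKE
        events = sd.extract_events(_trace(np.ones(100)), _make_labels(labels))
        assert len(events) == 1

    def test_no_spike_frames_empty_list(self):
        events = sd.extract_events(_trace(np.ones(50)), _make_labels(np.zeros(50, int)))
        assert events == []

    def test_edge_runs_flagged(self):
        labels = np.zeros(60, int)
        labels[0] = sd.SPIKE
        labels[59] = sd.SPIKE
        labels[30] = sd.SPIKE
        events = sd.extract_events(_trace(np.ones(60)), _make_labels(labels))
        assert [e.edge for e in events] == [True, False, True]

    def test_peak_tie_takes_first_frame(self):
        values = np.ones(50)
        labels = np.zeros(50, int)
        labels[20:23] = sd.SPIKE
        values[20:23] = 5.0  # flat run
        events = sd.extract_events(_trace(values), _make_labels(labels))
        assert events[0].peak_frame == 20


class TestScoreEvents:
    def test_amplitude_and_snr_definitions(self):
        # baseline level 100, one spike frame at 110
        rng = np.random.default_rng(5)
        values = 100.0 + rng.normal(0, 0.5, 1000)
        values[500] = 110.0
        labels = np.zeros(1000, int)
        labels[500] = sd.SPIKE
        events = sd.extract_events(_trace(values), _make_labels(labels))
        scored, noise = sd.score_events(_trace(values), _make_labels(labels), events)
        amp = scored[0].amplitude_dff
        assert amp == pytest.approx(0.1, rel=0.02)
        assert scored[0].snr == pytest.approx(amp / noise.sigma)

    def test_snr_is_amplitude_over_sigma(self):
        assert 0.09 / 0.005 == pytest.approx(18.0)  # the definitional identity
        rng = np.random.default_rng(6)
        values = 100.0 + rng.normal(0, 0.5, 500)
        values[100] = 109.0
        labels = np.zeros(500, int)
        labels[100] = sd.SPIKE
        events = sd.extract_events(_trace(values), _make_labels(labels))
        scored, noise = sd.score_events(_trace(values), _make_labels(labels), events)
        assert scored[0].snr == pytest.approx(scored[0].amplitude_dff / noise.sigma)

    def test_sliding_minimum_finds_quiet_segment(self):
        # noisier second half: the window minimum should report the quiet sigma
        rng = np.random.default_rng(2)
        dff_noise = np.concatenate([rng.normal(0, 0.01, 500), rng.normal(0, 0.03, 500)])
        values = 100.0 * (1.0 + dff_noise)
        labels = np.zeros(1000, int)
        labels[[3, 700]] = sd.SPIKE
        values[[3, 700]] = 120.0
        trace = _trace(values)
        events = sd.extract_events(trace, _make_labels(labels))
        scored, noise = sd.score_events(trace, _make_labels(labels), events,
                                        noise_window=100)
        assert noise.sigma == pytest.approx(0.01, rel=0.15)

    def test_sigma_matches_bruteforce_window_enumeration(self):
        rng = np.random.default_rng(3)
        values = 100.0 + rng.normal(0, 1.0, 400)
        raw = np.zeros(400, int)
        raw[50] = sd.SPIKE
        labels = _make_labels(raw)
        trace = _trace(values)
        events = sd.extract_events(trace, labels)
        scored, noise = sd.score_events(trace, labels, events, noise_window=60)
        dff = sd.to_dff(trace, labels)
        baseline_dff = dff[labels.labels == sd.BASELINE]
        assert noise.sigma == pytest.approx(
            min_window_std_brute(baseline_dff, 60), abs=1e-12)

    def test_too_few_baseline_frames_rejected(self):
        labels = np.concatenate([np.full(90, sd.BASELINE), np.full(85, sd.SUBTHRESHOLD),
                                 np.full(75, sd.SPIKE)])
        with pytest.raises(ValueError, match="baseline frames"):
            sd.score_events(_trace(np.random.default_rng(0).normal(100, 1, 250)),
                            _make_labels(labels), [], noise_window=100)

    def test_nonpositive_baseline_rejected(self):
        rng = np.random.default_rng(4)
        values = rng.normal(-5.0, 0.5, 300)  # over-subtracted background
        labels = np.zeros(300, int)
        labels[100] = sd.SPIKE
        trace = _trace(values)
        events = sd.extract_events(trace, _make_labels(labels))
        with pytest.raises(ValueError):
            sd.score_events(trace, _make_labels(labels), events)


class TestApplyThreshold:
    def _events(self, snrs):
        return [sd.SpikeEvent(onset_frame=i, peak_frame=i, peak_time=float(i),
                              amplitude_dff=0.1, snr=s) for i, s in enumerate(snrs)]

    def test_filters_by_snr(self):
        train = sd.apply_threshold(self._events([18.0, 10.0, 25.0]), 16.0, 1000.0)
        assert train.n_spikes == 2

    def test_near_zero_threshold_keeps_all(self):
        train = sd.apply_threshold(self._events([18.0, 10.0, 25.0]), 1e-9, 1000.0)
        assert train.n_spikes == 3

    def test_zero_survivors_is_valid_quiescent_train(self):
        train = sd.apply_threshold(self._events([1.0, 2.0]), 50.0, 1000.0)
        assert train.n_spikes == 0
        assert train.duration == 1000.0

    def test_unscored_events_rejected(self):
        ev = sd.SpikeEvent(onset_frame=0, peak_frame=0, peak_time=0.0)
        with pytest.raises(ValueError, match="scored"):
            sd.apply_threshold([ev], 5.0, 1000.0)


class TestEndToEndDetection:
    def test_recovers_rendered_spikes(self):
        """Rendered transients at the assay's typical SNR are recovered
        within one frame, with no spurious detections."""
        cfg = SimConfig(rate=2.0, duration=20_000.0, seed=42)
        train = simulate_poisson_train(cfg, neuron_id=1)
        trace, truth = render_trace(train, cfg)
        detected, events, noise = sd.detect_spikes(trace, 16.0, seed=0)
        det_frames = np.round(detected.times * cfg.frame_rate / 1000).astype(int)
        assert len(det_frames) > 0
        matched = sum(any(abs(d - t) <= 1 for d in det_frames) for t in truth)
        assert matched >= 0.95 * len(truth)
        false = sum(not any(abs(d - t) <= 1 for t in truth) for d in det_frames)
        assert false == 0

    def test_polarity_inversion_recovers_negative_spikes(self):
        cfg = SimConfig(rate=2.0, duration=10_000.0, seed=9)
        train = simulate_poisson_train(cfg, neuron_id=1)
        trace, truth = render_trace(train, cfg)
        flipped = RawTrace(values=200.0 - trace.values, frame_rate=trace.frame_rate)
        detected, _, _ = sd.detect_spikes(flipped, 16.0, seed=0, polarity=-1)
        det_frames = np.round(detected.times * cfg.frame_rate / 1000).astype(int)
        matched = sum(any(abs(d - t) <= 1 for d in det_frames) for t in truth)
        assert matched >= 0.9 * len(truth)
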