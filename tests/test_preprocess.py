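"""Signal conditioning and epoching rules."""

import numpy as np
import pytest

from gazesync.preprocess import (
    EpochSet,
    bandpass_filter,
    extract_event_epochs,
    interpolate_bad_channels,
    match_condition_counts,
    reject_highpower_segments,
    robust_average_reference,
    segment_by_gaze_state,
)
from gazesync.simulate import DyadRecording, GazeEvent, SimulationConfig, simulate_dyad

from conftest import timeline_from_spans

FS = 512.0


def _sine(freq, dur=10.0, fs=FS):
    t = np.arange(int(dur * fs)) / fs
    return np.sin(2 * np.pi * freq * t)


class TestBandpassFilter:
    def test_passband_amplitude_preserved(self):
        y = bandpass_filter(_sine(10.0), FS)
        mid = y[len(y) // 4 : -len(y) // 4]
        assert abs(np.abs(mid).max() - 1.0) < 0.05

    def test_slow_drift_attenuated_20db(self):
        y = bandpass_filter(_sine(0.2, dur=40.0), FS)
        mid = y[len(y) // 4 : -len(y) // 4]
        assert np.abs(mid).max() < 0.1  # >= 20 dB down

    def test_idempotent_on_inband_content(self):
        x = _sine(8.0) + 0.5 * _sine(4.0)
        once = bandpass_filter(x, FS)
        twice = bandpass_filter(once, FS)
        mid = slice(len(x) // 4, -len(x) // 4)
        assert np.abs(once[mid] - twice[mid]).max() < 0.02

    def test_rejects_edge_above_nyquist(self):
        with pytest.raises(ValueError):
            bandpass_filter(_sine(10.0), FS, low=1.0, high=FS / 2)


class TestRobustAverageReference:
    def test_identical_channels_become_zero(self, rng):
        x = np.tile(rng.standard_normal(1000), (5, 1))
        assert np.allclose(robust_average_reference(x), 0.0)

    def test_invariant_to_common_offset(self, rng):
        x = rng.standard_normal((6, 500))
        np.testing.assert_allclose(
            robust_average_reference(x + 42.0), robust_average_reference(x), atol=1e-12
        )

    def test_median_resists_one_extreme_channel(self, rng):
        x = rng.standard_normal((9, 2000))
        x[0] *= 100.0
        med_ref = robust_average_reference(x)
        mean_ref = x - x.mean(axis=0, keepdims=True)
        # good channels should be perturbed less by the robust reference
        good = slice(1, None)
        assert np.abs(med_ref[good] - x[good]).mean() < np.abs(mean_ref[good] - x[good]).mean()

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError):
            robust_average_reference(np.zeros((1, 100)))


def _correlated_channels(rng, n_ch=12, n=5000):
    sources = rng.standard_normal((4, n))
    mixing = rng.uniform(0.3, 1.0, (n_ch, 4))
    return mixing @ sources + 0.2 * rng.standard_normal((n_ch, n))


class TestInterpolateBadChannels:
    def test_noise_channel_flagged_and_replaced(self, rng):
        x = _correlated_channels(rng)
        x[3] = rng.standard_normal(x.shape[1])
        cleaned, flagged = interpolate_bad_channels(x)
        assert flagged == [3]
        assert np.corrcoef(cleaned[3], np.median(np.delete(x, 3, 0), axis=0))[0, 1] > 0.9

    def test_clean_data_nothing_flagged(self, rng):
        _, flagged = interpolate_bad_channels(_correlated_channels(rng))
        assert flagged == []

    def test_majority_bad_aborts(self, rng):
        x = rng.standard_normal((6, 2000))  # fully independent channels
        with pytest.raises(ValueError):
            interpolate_bad_channels(x)


class TestRejectHighpowerSegments:
    def test_clean_noise_keeps_everything(self, rng):
        x = rng.standard_normal((8, int(30 * FS)))
        mask, frac = reject_highpower_segments(x, FS)
        assert frac == 0.0 and mask.all()

    def test_amplified_segment_on_80pct_channels_masked(self, rng):
        x = rng.standard_normal((10, int(30 * FS)))
        w = int(FS)
        x[:8, 5 * w : 6 * w] *= 10.0
        mask, frac = reject_highpower_segments(x, FS)
        assert not mask[5 * w : 6 * w].any()
        assert mask[: 5 * w].all() and mask[6 * w :].all()

    def test_amplified_on_half_channels_not_masked(self, rng):
        x = rng.standard_normal((10, int(30 * FS)))
        w = int(FS)
        x[:5, 5 * w : 6 * w] *= 10.0
        mask, frac = reject_highpower_segments(x, FS)
        assert mask.all()


def _index_dyad(duration=20.0):
    """Dyad whose samples encode their own index (for slice arithmetic)."""
    n = int(duration * FS)
    ramp = np.arange(n, dtype=float)
    data = np.tile(ramp, (32, 1))
    cfg = SimulationConfig(seed=0, duration=duration)
    tl_i = timeline_from_spans("infant", [("puppet", duration)])
    tl_a = timeline_from_spans("adult", [("partner", duration)])
    return DyadRecording(data, data + 0.5, list(cfg.channel_labels), FS,
                         [], {"infant": tl_i, "adult": tl_a})


class TestExtractEventEpochs:
    def test_slice_index_arithmetic(self):
        dyad = _index_dyad()
        ev = [GazeEvent(10.0, "infant", "nonmutual", "puppet")]
        epo_i, epo_a, dropped = extract_event_epochs(dyad, ev)
        assert dropped == []
        assert epo_i.data.shape == (1, 32, 2560)
        assert epo_i.data[0, 0, 0] == 3840  # sample index 10*512 - 2.5*512
        assert epo_i.data[0, 0, -1] == 6399
        assert epo_i.onset_index == 1280

    def test_zero_events_gives_valid_empty_set(self):
        epo_i, epo_a, dropped = extract_event_epochs(_index_dyad(), [])
        assert epo_i.n_trials == 0 and epo_a.n_trials == 0

    def test_shared_clock_contract(self):
        dyad = _index_dyad()
        evs = [GazeEvent(t, "infant", "nonmutual", "puppet") for t in (5.0, 10.0, 14.0)]
        epo_i, epo_a, _ = extract_event_epochs(dyad, evs)
        assert epo_i.n_trials == epo_a.n_trials == 3
        np.testing.assert_array_equal(epo_i.times, epo_a.times)
        np.testing.assert_allclose(epo_a.data - epo_i.data, 0.5)

    def test_edge_event_dropped(self):
        dyad = _index_dyad()
        evs = [GazeEvent(1.0, "infant", "nonmutual", "puppet"),
               GazeEvent(10.0, "infant", "nonmutual", "puppet")]
        epo_i, _, dropped = extract_event_epochs(dyad, evs)
        assert epo_i.n_trials == 1
        assert dropped[0][1] == "edge"

    def test_masked_event_dropped(self):
        dyad = _index_dyad()
        mask = np.ones(dyad.n_samples, bool)
        mask[int(11 * FS) : int(12 * FS)] = False
        evs = [GazeEvent(10.0, "infant", "nonmutual", "puppet"),
               GazeEvent(16.0, "infant", "nonmutual", "puppet")]
        epo_i, _, dropped = extract_event_epochs(dyad, evs, mask=mask)
        assert epo_i.n_trials == 1
        assert dropped[0][1] == "masked"


class TestSegmentByGazeState:
    def test_hand_built_mutual_episode(self):
        tl_i = timeline_from_spans("infant", [("puppet", 3.0), ("partner", 4.0), ("inattentive", 3.0)])
        tl_a = timeline_from_spans("adult", [("partner", 5.0), ("puppet", 5.0)])
        n = int(10 * FS)
        data = np.zeros((32, n))
        cfg = SimulationConfig(seed=0, duration=10.0)
        dyad = DyadRecording(data, data.copy(), list(cfg.channel_labels), FS,
                             [], {"infant": tl_i, "adult": tl_a})
        segs = segment_by_gaze_state(dyad)
        # mutual overlap is 3..5 s -> 2 s within one frame
        assert abs(segs["mutual"].total_seconds - 2.0) <= 1.0 / 50
        # nonmutual: adult-only 0..3 s plus infant-only 5..7 s
        assert abs(segs["nonmutual"].total_seconds - 5.0) <= 2.0 / 50

    def test_no_overlap_gives_empty_mutual(self):
        tl_i = timeline_from_spans("infant", [("puppet", 10.0)])
        tl_a = timeline_from_spans("adult", [("partner", 10.0)])
        n = int(10 * FS)
        cfg = SimulationConfig(seed=0, duration=10.0)
        dyad = DyadRecording(np.zeros((32, n)), np.zeros((32, n)),
                             list(cfg.channel_labels), FS, [],
                             {"infant": tl_i, "adult": tl_a})
        segs = segment_by_gaze_state(dyad)
        assert segs["mutual"].n_segments == 0
        assert segs["nonmutual"].total_seconds > 9.5

    def test_masked_look_excluded(self):
        tl_i = timeline_from_spans("infant", [("partner", 10.0)])
        tl_a = timeline_from_spans("adult", [("partner", 4.0), ("puppet", 6.0)])
        n = int(10 * FS)
        cfg = SimulationConfig(seed=0, duration=10.0)
        dyad = DyadRecording(np.zeros((32, n)), np.zeros((32, n)),
                             list(cfg.channel_labels), FS, [],
                             {"infant": tl_i, "adult": tl_a})
        mask = np.ones(n, bool)
        mask[: int(4 * FS)] = False  # kill the mutual episode
        segs = segment_by_gaze_state(dyad, mask=mask)
        assert segs["mutual"].n_segments == 0
        assert segs["nonmutual"].n_segments == 1


class TestMatchConditionCounts:
    def _epochs(self, n, tag=0.0):
        data = np.full((n, 2, int(5 * FS)), tag) + np.arange(n)[:, None, None]
        return EpochSet(data, (-2.5, 2.5), FS)

    def test_truncates_larger_epochset_in_order(self):
        a, b = match_condition_counts(self._epochs(12), self._epochs(7))
        assert a.n_trials == b.n_trials == 7
        np.testing.assert_array_equal(a.data[:, 0, 0], np.arange(7))

    def test_equal_sizes_unchanged(self):
        a, b = match_condition_counts(self._epochs(5), self._epochs(5))
        assert a.n_trials == b.n_trials == 5

    def test_idempotent(self):
        a1, b1 = match_condition_counts(self._epochs(12), self._epochs(7))
        a2, b2 = match_condition_counts(a1, b1)
        np.testing.assert_array_equal(a1.data, a2.data)

    def test_segment_sets_truncated_to_min_total_samples(self):
        tl_i = timeline_from_spans("infant", [("partner", 6.0), ("puppet", 4.0)])
        tl_a = timeline_from_spans("adult", [("partner", 8.0), ("puppet", 2.0)])
        n = int(10 * FS)
        cfg = SimulationConfig(seed=0, duration=10.0)
        dyad = DyadRecording(np.zeros((32, n)), np.zeros((32, n)),
                             list(cfg.channel_labels), FS, [],
                             {"infant": tl_i, "adult": tl_a})
        segs = segment_by_gaze_state(dyad)
        mut, non = match_condition_counts(segs["mutual"], segs["nonmutual"])
        assert mut.total_samples == non.total_samples
        a2, b2 = match_condition_counts(mut, non)
        assert a2.total_samples == mut.total_samples


class TestPipelineConditioning:
    def test_masking_conservation_end_to_end(self):
        """Samples rejected by the power rule never reach epochs/segments."""
        dyad = simulate_dyad(SimulationConfig(seed=11, duration=40.0))
        # inject a gross oscillatory artifact with channel-varying gain (a
        # pure offset would not change epoch variance, and a common-mode
        # burst is removed by the median reference — both rightly survive)
        w = int(FS)
        tt = np.arange(w) / FS
        gains = np.linspace(100.0, 900.0, 32)[:, None]
        dyad.infant[:, 10 * w : 11 * w] += gains * np.sin(2 * np.pi * 7 * tt)
        from gazesync.preprocess import preprocess_recording

        clean, mask, info = preprocess_recording(dyad)
        assert not mask[10 * w : 11 * w].any()
        epo_i, _, dropped = extract_event_epochs(clean, dyad.events, mask=mask)
        for ev in epo_i.events:
            s0 = int(round(ev.onset_time * FS)) - 1280
            assert mask[s0 : s0 + 2560].all()
        segs = segment_by_gaze_state(clean, mask=mask)
        for st in segs.values():
            for a, b_ in zip(st.infant, st.adult):
                assert a.shape == b_.shape

    def test_time_sample_round_trip(self):
        for t in (0.1, 1.2345, 17.77):
            s = int(round(t * FS))
            assert abs(s / FS - t) < 1.0 / FS
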