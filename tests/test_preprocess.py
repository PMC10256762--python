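"""Filtering, segmentation, fiducials, features, smoothing, normalization."""

import numpy as np
import pytest
from scipy import signal as sps

from taylorbp.preprocess import (BeatRecord, NormStats, SignalTrace,
                                 compute_features, extract_fiducials,
                                 fit_normalization, load_store,
                                 lowpass_filter, moving_average_beats,
                                 preprocess_subject, resample_and_pad,
                                 save_store, segment_beats)
from taylorbp.simulate import SimConfig, generate_subject


class TestLowpass:
    def test_dc_input_passes_with_unit_gain(self):
        trace = SignalTrace(samples=np.full(1000, 2.5), fs=250.0)
        out = lowpass_filter(trace)
        assert out.fs == trace.fs and len(out.samples) == 1000
        assert np.allclose(out.samples, 2.5, atol=1e-9)

    @pytest.mark.parametrize("freq, bound, kind", [
        (50.0, 0.05, "stop"),   # well above cutoff: < 5 % leakage
        (1.0, 0.02, "pass"),    # passband tone preserved within 2 %
    ])
    def test_tone_attenuation_matches_design(self, freq, bound, kind):
        # oracle: the designed filter's squared magnitude response
        # (forward-backward application) evaluated at the tone frequency
        fs = 250.0
        t = np.arange(int(20 * fs)) / fs
        tone = np.sin(2 * np.pi * freq * t)
        out = lowpass_filter(SignalTrace(samples=tone, fs=fs)).samples
        mid = slice(len(t) // 4, 3 * len(t) // 4)  # avoid edge transients
        gain = out[mid].std() / tone[mid].std()
        b, a = sps.butter(2, 6.0, fs=fs)
        _, h = sps.freqz(b, a, worN=[freq], fs=fs)
        expected = np.abs(h[0]) ** 2
        assert gain == pytest.approx(expected, abs=0.005)
        if kind == "stop":
            assert gain < bound
        else:
            assert abs(gain - 1.0) < bound

    def test_low_sampling_rate_rejected(self):
        with pytest.raises(ValueError, match="too low"):
            lowpass_filter(SignalTrace(samples=np.zeros(100), fs=10.0))


class TestSegmentation:
    def test_constant_signal_yields_no_beats(self):
        trace = SignalTrace(samples=np.ones(5000), fs=250.0)
        onsets, windows = segment_beats(trace)
        assert len(onsets) == 0 and windows == []

    def test_aperiodic_noise_yields_warning_and_no_beats(self):
        rng = np.random.default_rng(0)
        trace = SignalTrace(samples=rng.normal(size=5000), fs=250.0)
        with pytest.warns(UserWarning, match="periodicity"):
            onsets, _ = segment_beats(lowpass_filter(trace))
        assert len(onsets) == 0

    def test_windows_are_disjoint_ordered_halfopen(self, clean_subject):
        _, trace, _ = clean_subject
        onsets, windows = segment_beats(lowpass_filter(trace))
        starts = np.array([a for a, _ in windows])
        ends = np.array([b for _, b in windows])
        assert np.all(np.diff(starts) > 0)
        assert np.array_equal(ends[:-1], starts[1:])

    def test_onsets_match_simulator_truth_within_one_sample(
            self, clean_subject):
        config, trace, state = clean_subject
        onsets, _ = segment_beats(lowpass_filter(trace))
        true_idx = np.round(state.onset_s * config.fs).astype(int)
        for o in onsets:
            assert np.abs(true_idx - o).min() <= 1

    def test_identical_beats_share_boundary_at_zero_crossing(self):
        # 4 identical 1 s beats; the two record-edge beats are excluded,
        # leaving exactly 2 windows with the shared onset as boundary
        config = SimConfig(sessions=(("recovery", 4.0, 120.0),), hr0=60.0,
                           noise_sd=0.0)
        trace, state = generate_subject(config)
        onsets, windows = segment_beats(lowpass_filter(trace))
        assert len(windows) == 2
        (a1, b1), (a2, b2) = windows
        assert b1 == a2  # half-open [onset, next onset) convention
        assert abs(b1 - 500) <= 1  # the shared 2 s zero-crossing


class TestFiducials:
    @pytest.fixture(scope="class")
    def one_beat(self, clean_subject):
        config, trace, state = clean_subject
        filt = lowpass_filter(trace)
        onsets, windows = segment_beats(filt)
        a, b = windows[10]
        return (config, state, filt.samples[a:b], trace.samples[a:b],
                a / config.fs)

    def test_landmark_times_match_simulator_within_one_sample(self, one_beat):
        config, state, beat, raw, t0 = one_beat
        fids = extract_fiducials(beat, config.fs, t_start=t0, raw=raw)
        j = np.argmin(np.abs(state.onset_s - t0))
        tol = 1.0 / config.fs
        assert fids.t("B") == pytest.approx(state.t_b[j], abs=tol)
        assert fids.t("F") == pytest.approx(state.t_f[j], abs=tol)
        assert fids.feature_complete

    def test_times_increase_in_label_order(self, one_beat):
        config, _, beat, raw, t0 = one_beat
        fids = extract_fiducials(beat, config.fs, t_start=t0, raw=raw)
        times = [fids.t(l) for l in "ABCDEFGHJ" if fids.points.get(l)]
        assert np.all(np.diff(times) > 0)

    def test_time_shift_equivariance(self, one_beat):
        config, _, beat, raw, _ = one_beat
        f0 = extract_fiducials(beat, config.fs, t_start=0.0, raw=raw)
        f1 = extract_fiducials(beat, config.fs, t_start=5.0, raw=raw)
        for lbl in "ABCFJ":
            assert f1.t(lbl) - f0.t(lbl) == pytest.approx(5.0)

    def test_monotone_beat_flagged_feature_incomplete(self):
        t = np.linspace(0, 1, 250)
        mono = -np.sin(np.pi * t)  # single systolic lobe, no reflection
        fids = extract_fiducials(mono, 250.0)
        assert not fids.feature_complete
        with pytest.raises(ValueError, match="incomplete"):
            compute_features(fids)


class TestFeatures:
    def make_fids(self, dz_a=0.8, dz_c=0.3, t_b=0.10, t_f=0.30, t_j=1.0):
        from taylorbp.preprocess import FiducialSet
        points = {l: None for l in "ABCDEFGHJ"}
        points.update({"A": (0.0, dz_a), "B": (t_b, 0.5), "C": (0.15, dz_c),
                       "F": (t_f, 0.4), "J": (t_j, 0.8)})
        return FiducialSet(points=points, feature_complete=True)

    def test_formula_values(self):
        u = compute_features(self.make_fids())
        assert u[0] == pytest.approx(0.5)          # 0.8 - 0.3
        assert u[1] == pytest.approx(5.0)          # 1/(0.30-0.10)
        assert u[2] == pytest.approx(60.0)         # 60/1.0

    def test_inverted_timing_rejected(self):
        # label-order validation refuses t_F <= t_B at construction
        with pytest.raises(ValueError, match="label order"):
            self.make_fids(t_f=0.05)
        # and the feature formulas guard it independently
        fids = self.make_fids()
        fids.points["F"] = (0.05, 0.4)
        with pytest.raises(ValueError, match="t_F"):
            compute_features(fids)


class TestMovingAverage:
    def make(self, us, n_x=4):
        return [BeatRecord(x=np.full(n_x, float(i)), u=np.array([u, 1.0, 60.0]),
                           y=np.array([100.0 + u, 70.0, 30.0 + u]),
                           session="s", index=i, onset_s=float(i))
                for i, u in enumerate(us)]

    def test_three_beats_average_to_one(self):
        out = moving_average_beats(self.make([1.0, 2.0, 3.0]))
        assert len(out) == 1
        assert out[0].u[0] == pytest.approx(2.0)
        assert out[0].y[0] == pytest.approx(102.0)

    @pytest.mark.parametrize("n, expected", [(3, 1), (5, 2), (7, 3), (8, 3)])
    def test_stride_two_window_count(self, n, expected):
        out = moving_average_beats(self.make(list(range(n))))
        assert len(out) == expected

    def test_windows_share_exactly_one_beat(self):
        out = moving_average_beats(self.make([0, 1, 2, 3, 4]))
        # windows {0,1,2} and {2,3,4}: means 1 and 3
        assert [o.u[0] for o in out] == [1.0, 3.0]

    def test_identical_beats_are_fixed_point(self):
        out = moving_average_beats(self.make([2.0] * 7))
        assert len(out) == 3
        for o in out:
            assert o.u[0] == pytest.approx(2.0)

    def test_fewer_than_three_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            moving_average_beats(self.make([1.0, 2.0]))

    def test_commutes_with_label_averaging(self):
        recs = self.make([1.0, 4.0, 2.0, 8.0, 5.0])
        out = moving_average_beats(recs)
        direct = [np.mean([recs[i].y[0] for i in w])
                  for w in ((0, 1, 2), (2, 3, 4))]
        assert [o.y[0] for o in out] == pytest.approx(direct)


class TestResample:
    def test_one_second_beat_gives_30_samples_plus_padding(self):
        beat = np.ones(250)
        x = resample_and_pad(beat, 250.0, 30.0, n_pad=40)
        assert len(x) == 40
        assert np.allclose(x[:30], 1.0)
        assert np.allclose(x[30:], 0.0)

    def test_overlong_beat_rejected_with_required_n(self):
        with pytest.raises(ValueError, match="N >= 60"):
            resample_and_pad(np.ones(500), 250.0, 30.0, n_pad=40)

    def test_resampled_beat_tracks_dense_original(self, clean_subject):
        config, trace, _ = clean_subject
        beat = trace.samples[1000:1230]
        x = resample_and_pad(beat, config.fs, 30.0)
        t30 = np.arange(len(x)) / 30.0
        dense = np.interp(t30, np.arange(len(beat)) / config.fs, beat)
        assert np.corrcoef(x, dense)[0, 1] > 0.99


class TestNormalization:
    def test_round_trip_identity(self):
        rng = np.random.default_rng(1)
        u = rng.normal(size=(50, 3))
        y = rng.normal(size=(50, 3)) * 10 + 120
        stats = fit_normalization(u, y)
        assert np.allclose(stats.invert_u(stats.apply_u(u)), u, atol=1e-10)
        assert np.allclose(stats.invert_y(stats.apply_y(y)), y, atol=1e-10)

    def test_normalized_columns_standardized(self):
        rng = np.random.default_rng(2)
        u = rng.normal(size=(200, 3)) * 5 + 3
        stats = fit_normalization(u, rng.normal(size=(200, 3)))
        z = stats.apply_u(u)
        assert np.allclose(z.mean(axis=0), 0, atol=1e-8)
        assert np.allclose(z.std(axis=0), 1, atol=1e-8)

    def test_midpoint_maps_to_zero(self):
        u = np.array([[0.0], [10.0]])
        stats = fit_normalization(u, np.array([[0.0], [10.0]]))
        assert stats.apply_u([[5.0]])[0, 0] == pytest.approx(0.0)

    def test_zero_variance_channel_rejected(self):
        u = np.ones((10, 3))
        with pytest.raises(ValueError, match="zero-variance"):
            fit_normalization(u, np.random.default_rng(0).normal(size=(10, 3)))


class TestPipeline:
    def test_features_within_two_percent_of_truth(self, clean_subject):
        config, trace, state = clean_subject
        from tests.conftest import labels_frame
        ds = preprocess_subject(trace, labels_frame(state), smooth=False)
        # match each beat to the simulator truth by onset time
        for i in range(ds.n_beats):
            j = np.argmin(np.abs(state.onset_s - ds.onset_s[i]))
            truth = np.array([state.u1[j], state.u2[j], state.u3[j]])
            assert np.all(np.abs(ds.u[i] - truth) / np.abs(truth) < 0.02)

    def test_beat_count_matches_simulator(self, clean_subject):
        config, trace, state = clean_subject
        from tests.conftest import labels_frame
        ds = preprocess_subject(trace, labels_frame(state), smooth=False)
        # interior beats all found (the two record-edge beats may be lost)
        assert state.n_beats - 2 <= ds.n_beats <= state.n_beats

    def test_store_round_trip(self, clean_dataset, tmp_path):
        ds = clean_dataset
        stats = fit_normalization(ds.u, ds.y, ds.x)
        save_store(tmp_path / "store.h5", {"s1": ds}, stats)
        subjects, back = load_store(tmp_path / "store.h5")
        assert np.array_equal(subjects["s1"].x, ds.x)
        assert np.array_equal(subjects["s1"].u, ds.u)
        assert list(subjects["s1"].session) == list(ds.session)
        assert np.allclose(back.u_mean, stats.u_mean)
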