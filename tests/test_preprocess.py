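import numpy as np
import pytest

from synergait import (FilterSpec, combine_bilateral_events, detect_events_from_grf,
                       downsample_series, emg_envelope)
from synergait.events_types import GaitEventList


class TestEmgEnvelope:
    def test_zero_input_gives_zero_envelope(self):
        env = emg_envelope(np.zeros((4, 8000)), fs=2000.0)
        assert np.allclose(env, 0.0)

    def test_sine_envelope_settles_at_rectified_mean(self):
        # full-wave-rectified A*sin has mean 2A/pi; the 5 Hz low-pass keeps
        # just that DC level away from the edges
        fs, A = 2000.0, 2.0
        t = np.arange(int(4 * fs)) / fs
        env = emg_envelope(A * np.sin(2 * np.pi * 50 * t), fs)
        mid = env[int(fs) : -int(fs)]
        assert np.allclose(mid, 2 * A / np.pi, rtol=0.02)

    def test_zero_phase_time_reversal_symmetry(self, rng):
        # away from the filter edge transients the forward-backward
        # pipeline commutes with time reversal
        x = rng.standard_normal(8000)
        fwd = emg_envelope(x, 2000.0)
        rev = emg_envelope(x[::-1].copy(), 2000.0)
        assert np.allclose(fwd[2000:-2000], rev[::-1][2000:-2000], atol=1e-5)

    def test_scale_equivariance(self, rng):
        x = rng.standard_normal((2, 4000))
        assert np.allclose(emg_envelope(3.5 * x, 2000.0), 3.5 * emg_envelope(x, 2000.0))

    def test_burst_peak_is_not_delayed(self):
        # zero-lag filtering: envelope peak aligns with the burst center
        fs = 2000.0
        n = 8000
        x = np.zeros(n)
        center = 4000
        burst = np.sin(2 * np.pi * 80 * np.arange(800) / fs)
        window = np.hanning(800)
        x[center - 400 : center + 400] = burst * window
        env = emg_envelope(x, fs)
        assert abs(int(np.argmax(env)) - center) < 50

    def test_low_fs_rejected(self):
        with pytest.raises(ValueError, match="cutoffs"):
            emg_envelope(np.zeros((1, 4000)), fs=500.0)

    def test_all_nan_channel_rejected(self):
        x = np.zeros((2, 4000))
        x[1] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            emg_envelope(x, 2000.0)


class TestFilterSpec:
    def test_invalid_configurations_rejected(self):
        with pytest.raises(ValueError):
            FilterSpec("bandpass", (20.0,))
        with pytest.raises(ValueError):
            FilterSpec("lowpass", (5.0,), order=0)
        with pytest.raises(ValueError):
            FilterSpec("highpass", (5.0,))


class TestGrfEventDetection:
    def test_detects_simulated_contacts_within_one_sample(self, short_recording):
        rec = short_recording
        det = detect_events_from_grf(rec.grf_ipsi, rec.fs, 20.0)
        for etype in ("IC", "FC"):
            truth = rec.truth_events.times(etype)
            got = det.times(etype)
            assert len(got) == len(truth)
            assert np.max(np.abs(got - truth)) <= 1.5 / rec.fs

    def test_zero_grf_gives_empty_list(self):
        assert len(detect_events_from_grf(np.zeros(4000), 2000.0, 20.0)) == 0

    def test_threshold_above_max_gives_empty_list(self, short_recording):
        rec = short_recording
        det = detect_events_from_grf(rec.grf_ipsi, rec.fs, rec.grf_ipsi.max() + 1)
        assert len(det) == 0

    def test_short_blips_are_debounced(self):
        fs = 2000.0
        grf = np.zeros(8000)
        grf[2000:4000] = 500.0    # real stance, 1 s
        grf[5000:5020] = 500.0    # 10 ms blip, below the 50 ms debounce
        det = detect_events_from_grf(grf, fs, 20.0)
        assert [e.type for e in det] == ["IC", "FC"]
        assert det.times("IC")[0] == pytest.approx(1.0, abs=1e-3)

    def test_detection_matches_truth_across_random_conditions(self):
        # median timing error at most one sample over varied gait conditions
        from synergait import SimConfig, simulate_recording

        errs = []
        for seed in range(12):
            rng = np.random.default_rng(seed)
            cfg = SimConfig(
                duration_s=5.0,
                seed=seed,
                duty_factor=float(rng.uniform(0.55, 0.68)),
                mean_cycle_s=float(rng.uniform(0.9, 1.3)),
                cycle_sd_s=float(rng.uniform(0.0, 0.05)),
            )
            rec = simulate_recording(cfg)
            det = detect_events_from_grf(rec.grf_ipsi, rec.fs, cfg.grf_threshold_N)
            for etype in ("IC", "FC"):
                t, g = rec.truth_events.times(etype), det.times(etype)
                assert len(t) == len(g)
                errs.extend(np.abs(t - g))
        assert np.median(errs) <= 1.0 / 2000.0


class TestBilateralMerge:
    def test_contra_events_relabel_at_cycle_fractions(self, exact_recording):
        rec = exact_recording
        ipsi = detect_events_from_grf(rec.grf_ipsi, rec.fs, 20.0)
        contra = detect_events_from_grf(rec.grf_contra, rec.fs, 20.0)
        merged = combine_bilateral_events(ipsi, contra)
        ic = merged.times("IC")
        cycle = ic[1] - ic[0]
        for start in ic[:-1]:
            ofc = merged.times("OFC")
            oic = merged.times("OIC")
            in_cycle_ofc = ofc[(ofc >= start) & (ofc < start + cycle)]
            in_cycle_oic = oic[(oic >= start) & (oic < start + cycle)]
            assert len(in_cycle_ofc) == 1 and len(in_cycle_oic) == 1
            assert (in_cycle_ofc[0] - start) / cycle == pytest.approx(0.10, abs=0.002)
            assert (in_cycle_oic[0] - start) / cycle == pytest.approx(0.50, abs=0.002)

    def test_empty_contralateral_gives_no_opposite_events(self, exact_recording):
        rec = exact_recording
        ipsi = detect_events_from_grf(rec.grf_ipsi, rec.fs, 20.0)
        merged = combine_bilateral_events(ipsi, GaitEventList([]))
        assert len(merged.times("OIC")) == 0 and len(merged.times("OFC")) == 0


class TestDownsample:
    @pytest.mark.parametrize("n,factor,expected", [(120000, 5, 24000), (10, 1, 10), (11, 3, 4)])
    def test_stride_lengths(self, n, factor, expected):
        assert len(downsample_series(np.arange(n), factor)) == expected

    def test_identity_and_constants(self):
        x = np.arange(20.0)
        assert np.array_equal(downsample_series(x, 1), x)
        assert np.all(downsample_series(np.full(100, 7.0), 5) == 7.0)

    def test_nonpositive_factor_rejected(self):
        with pytest.raises(ValueError):
            downsample_series(np.arange(10), 0)
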