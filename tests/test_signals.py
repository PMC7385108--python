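"""Feature-extraction pipeline: filters, fiducials, QC, and ground truth."""

import numpy as np
import pytest

from cardioema import signals, synthdata
from conftest import make_beats


def rms(x):
    return float(np.sqrt(np.mean(np.square(x))))


class TestFilterEcg:
    fs = 500.0
    t = np.arange(0, 20, 1 / 500.0)

    def test_dc_removed(self):
        out = signals.filter_ecg(np.full(self.t.size, 100.0), self.fs)
        assert abs(out.mean()) < 1e-6 * 100.0

    @pytest.mark.parametrize("freq,predicate", [
        (60.0, lambda ratio: ratio < 0.05),   # mains noise rejected
        (10.0, lambda ratio: ratio > 0.90),   # QRS band preserved
    ])
    def test_band_edges(self, freq, predicate):
        x = np.sin(2 * np.pi * freq * self.t)
        out = signals.filter_ecg(x, self.fs)
        # ignore filtfilt edge transients
        core = slice(2000, -2000)
        assert predicate(rms(out[core]) / rms(x[core]))

    def test_low_fs_rejected(self):
        with pytest.raises(ValueError):
            signals.filter_ecg(np.zeros(1000), 80.0)


class TestDetectRPeaks:
    def test_noise_free_recovery_within_one_sample(self, steady_recording,
                                                   steady_beats):
        truth = steady_recording.truth["r_peak_times"]
        det = steady_beats.r_peak_times
        assert det.size == truth.size
        assert np.abs(det - truth).max() <= 1.0 / steady_recording.fs + 1e-9

    def test_constant_ibi_recovered(self, steady_beats):
        assert np.all(np.abs(steady_beats.ibi - 1000.0) <= 2.0)

    def test_sensitivity_under_noise(self):
        # 5-minute record, additive noise at 10% of R amplitude
        rec = synthdata.generate_raw_recording(
            synthdata.make_ibi_trajectory(300.0, 900.0, rsa_amplitude_ms=40.0),
            seed=1, ecg_noise_sd=80.0)
        ecg = signals.filter_ecg(rec.ecg, rec.fs)
        beats = signals.detect_r_peaks(ecg, rec.fs)
        truth = rec.truth["r_peak_times"]
        hits = sum(np.abs(beats.r_peak_times - t).min() < 0.05 for t in truth)
        assert hits / truth.size >= 0.99

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError):
            signals.detect_r_peaks(np.zeros(100), 500.0)

    def test_flat_signal_warns_empty(self):
        with pytest.warns(UserWarning):
            beats = signals.detect_r_peaks(np.zeros(10_000), 500.0)
        assert beats.r_peak_times.size == 0


class TestQcIbi:
    @pytest.mark.parametrize("ibi,expect_rejected", [
        ([1000.0, 250.0, 1000.0], [False, True, False]),
        ([1000.0, 2100.0, 1000.0], [False, True, False]),
        ([1000.0] * 5, [False] * 5),
    ])
    def test_range_rule(self, ibi, expect_rejected):
        # the ectopy rule compares against the last *accepted* IBI, so the
        # return to baseline after an excluded artifact is itself accepted
        out = signals.qc_ibi(make_beats(ibi))
        np.testing.assert_array_equal(out.quality == "rejected",
                                      expect_rejected)

    def test_ectopic_jump_rejected(self):
        out = signals.qc_ibi(make_beats([1000, 1000, 600, 1000, 1000]))
        assert out.quality[1] == "ok"
        assert out.quality[2] == "rejected"
        assert out.reasons[2] == "ectopic-delta"


class TestComputeRsa:
    def _beats(self, amp, freq=0.25, dur=60.0):
        return make_beats(synthdata.make_ibi_trajectory(
            dur, 1000.0, rsa_amplitude_ms=amp, rsa_freq_hz=freq))

    def test_doubling_amplitude_adds_ln4(self):
        lo = signals.compute_rsa(self._beats(50.0), (0, 60))
        hi = signals.compute_rsa(self._beats(100.0), (0, 60))
        assert hi - lo == pytest.approx(np.log(4.0), abs=0.05)

    def test_constant_ibi_hits_floor(self):
        v = signals.compute_rsa(make_beats([1000.0] * 60), (0, 60))
        assert v == pytest.approx(np.log(1e-12))

    def test_out_of_band_modulation_matches_periodogram_oracle(self):
        # 0.05 Hz modulation lies below the 0.12-0.4 Hz band; the remaining
        # band power is spectral leakage, reproduced by an independent
        # periodogram computed from the ground-truth IBI trajectory
        ibi = synthdata.make_ibi_trajectory(120.0, 1000.0,
                                            rsa_amplitude_ms=50.0,
                                            rsa_freq_hz=0.05)
        beats = make_beats(ibi)
        v = signals.compute_rsa(beats, (0, 120))
        in_band = signals.compute_rsa(self._beats(50.0, dur=120.0), (0, 120))
        oracle = _periodogram_band_power_oracle(beats, (0, 120))
        assert v == pytest.approx(oracle, abs=0.1)
        assert in_band - v > 3.0  # leakage is orders of magnitude below band

    def test_rsa_monotone_in_amplitude(self):
        vals = [signals.compute_rsa(self._beats(a), (0, 60))
                for a in (10.0, 25.0, 50.0, 100.0)]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_too_few_beats_is_missing(self):
        assert np.isnan(signals.compute_rsa(make_beats([1000.0] * 4), (0, 6)))


def _periodogram_band_power_oracle(beats, window):
    """Independent RSA oracle: same definition, separate implementation."""
    from numpy.fft import rfft, rfftfreq
    idx = beats.accepted_beat_indices()
    t = beats.r_peak_times[idx]
    sel = (t >= window[0]) & (t < window[1])
    t, v = t[sel], beats.ibi[idx[sel] - 1]
    from scipy.interpolate import CubicSpline
    grid = np.arange(t[0], t[-1], 0.25)
    x = CubicSpline(t, v)(grid)
    # linear detrend by least squares
    A = np.column_stack([grid, np.ones_like(grid)])
    x = x - A @ np.linalg.lstsq(A, x, rcond=None)[0]
    # periodic Hamming taper, written out
    w = 0.54 - 0.46 * np.cos(2 * np.pi * np.arange(x.size) / x.size)
    X = rfft(x * w)
    f = rfftfreq(x.size, 0.25)
    # one-sided power spectral density, window-power normalized
    psd = (np.abs(X) ** 2) / (4.0 * (w ** 2).sum())
    psd[1:-1] *= 2
    m = (f >= 0.12) & (f <= 0.4)
    return float(np.log(max(np.trapezoid(psd[m], f[m]), 1e-12)))


class TestEnsembles:
    def test_overlapping_count(self):
        rec = synthdata.generate_raw_recording(np.full(11, 1000.0))
        beats = make_beats(np.full(10, 1000.0), start_s=0.5)
        ens = signals.build_ensembles(rec.dzdt, beats, rec.fs)
        assert len(ens) == 10 - 8 + 1

    def test_average_of_identical_beats_equals_one_beat(self, steady_recording,
                                                        steady_beats):
        rec = steady_recording
        ens = signals.build_ensembles(rec.dzdt, steady_beats, rec.fs)
        r = int(round(steady_beats.r_peak_times[8] * rec.fs))
        single = rec.dzdt[r - 125: r + 251]
        np.testing.assert_allclose(ens[0].window, single, atol=1e-9)
        assert ens[0].window.size == round(0.75 * rec.fs) + 1

    def test_too_few_beats_warns_empty(self):
        rec = synthdata.generate_raw_recording(np.full(8, 1000.0))
        beats = make_beats(np.full(7, 1000.0), start_s=0.5)
        with pytest.warns(UserWarning):
            assert signals.build_ensembles(rec.dzdt, beats, rec.fs) == []


class TestFiducials:
    def _ensembles(self, pep=100.0, lvet=300.0):
        p = synthdata.IcgParams(pep_ms=pep, lvet_ms=lvet)
        rec = synthdata.generate_raw_recording(np.full(30, 1000.0),
                                               icg_params=p)
        ecg = signals.filter_ecg(rec.ecg, rec.fs)
        beats = signals.qc_ibi(signals.detect_r_peaks(ecg, rec.fs))
        return signals.build_ensembles(rec.dzdt, beats, rec.fs), rec.fs

    @pytest.mark.parametrize("pep,lvet", [(100.0, 300.0), (60.0, 250.0),
                                          (140.0, 330.0)])
    def test_b_and_x_within_two_samples(self, pep, lvet):
        ens, fs = self._ensembles(pep, lvet)
        e = ens[0]
        b = signals.detect_b_point(e, fs)
        assert b is not None
        assert abs((b - e.r_index) * 1000 / fs - pep) <= 2 * 1000 / fs
        e.b_index = b
        x = signals.detect_x_point(e, fs)
        assert x is not None
        assert abs((x - b) * 1000 / fs - lvet) <= 2 * 1000 / fs

    def test_featureless_ramp_has_no_b_point(self):
        e = signals.EnsembleICG(anchor_time=0.0,
                                window=np.linspace(0, 1, 376),
                                n_beats=8, r_index=125, ibi_ms=1000.0)
        assert signals.detect_b_point(e, 500.0) is None

    def test_truncated_x_absent(self):
        # notch pushed beyond the +500 ms window edge
        ens, fs = self._ensembles(pep=180.0, lvet=480.0)
        e = ens[0]
        e.b_index = signals.detect_b_point(e, fs)
        assert signals.detect_x_point(e, fs) is None

    def test_early_b_detected_then_rejected_by_range(self):
        ens, fs = self._ensembles(pep=25.0)
        e = ens[0]
        e.b_index = signals.detect_b_point(e, fs)
        assert e.b_index is not None
        e.x_index = signals.detect_x_point(e, fs)
        iv = signals.compute_systolic_intervals([e], fs)[0]
        assert iv.quality == "rejected" and iv.reason == "pep-out-of-range"


class TestCorrectBPoints:
    def test_spike_replaced_toward_trend(self):
        b = np.linspace(100.0, 110.0, 20)
        b[10] += 40.0
        out = signals.correct_b_points(b)
        trend = np.linspace(100.0, 110.0, 20)[10]
        assert abs(out[10] - trend) < 5.0
        clean = np.delete(np.arange(20), 10)
        np.testing.assert_allclose(out[clean], b[clean])

    def test_smooth_series_unchanged(self):
        b = 100.0 + 3 * np.sin(np.arange(25) / 4.0)
        np.testing.assert_array_equal(signals.correct_b_points(b), b)

    def test_adjacent_outliers_both_corrected(self):
        b = np.linspace(100.0, 110.0, 24)
        b[11] += 35.0
        b[12] += 38.0
        out = signals.correct_b_points(b)
        trend = np.linspace(100.0, 110.0, 24)
        assert abs(out[11] - trend[11]) < 6.0
        assert abs(out[12] - trend[12]) < 6.0

    def test_short_series_returned_with_warning(self):
        b = np.array([100.0, 101.0, 140.0])
        with pytest.warns(UserWarning):
            np.testing.assert_array_equal(signals.correct_b_points(b), b)


class TestSystolicIntervalsAndVolumes:
    def _ens(self, ibi=1000.0):
        w = np.zeros(376)
        return signals.EnsembleICG(anchor_time=0.0, window=w, n_beats=8,
                                   r_index=125, ibi_ms=ibi)

    def test_interval_arithmetic(self):
        e = self._ens()
        e.b_index, e.x_index = 125 + 50, 125 + 200
        iv = signals.compute_systolic_intervals([e], 500.0)[0]
        assert iv.pep == pytest.approx(100.0)
        assert iv.lvet == pytest.approx(300.0)
        assert iv.quality == "ok"

    def test_gradient_flag(self):
        e1, e2 = self._ens(), self._ens()
        e1.b_index, e1.x_index = 125 + 50, 125 + 200
        e2.b_index, e2.x_index = 125 + 68, 125 + 218  # PEP 136: jump of 36 ms
        iv = signals.compute_systolic_intervals([e1, e2], 500.0)
        assert iv[0].quality == "ok"
        assert iv[1].quality == "rejected" and iv[1].reason == "gradient"

    def test_missing_fiducial_rejected(self):
        e = self._ens()
        iv = signals.compute_systolic_intervals([e], 500.0)[0]
        assert iv.quality == "rejected" and iv.reason == "fiducial-missing"

    def test_kubicek_arithmetic(self):
        e = self._ens()
        e.window[200] = 1.0  # dzdt_max = 1.0 ohm/s
        params = signals.KubicekParams(rho=135.0, L=30.0, z0=30.0)
        iv = signals.SystolicIntervals(pep=100.0, lvet=300.0)
        sv, co = signals.compute_sv_co(e, iv, params)
        assert sv == pytest.approx(40.5)
        assert co == pytest.approx(40.5 * 60 / 1000.0)

    def test_sv_scales_with_electrode_distance_squared(self):
        e = self._ens()
        e.window[200] = 1.0
        iv = signals.SystolicIntervals(pep=100.0, lvet=300.0)
        sv1, _ = signals.compute_sv_co(e, iv, signals.KubicekParams(L=30.0))
        sv2, _ = signals.compute_sv_co(e, iv, signals.KubicekParams(L=60.0))
        assert sv2 == pytest.approx(4 * sv1)

    def test_co_identity(self):
        e = self._ens(ibi=800.0)
        e.window[200] = 1.3
        iv = signals.SystolicIntervals(pep=90.0, lvet=280.0)
        sv, co = signals.compute_sv_co(e, iv, signals.KubicekParams())
        assert co == sv * (60000.0 / 800.0) / 1000.0

    def test_invalid_z0(self):
        with pytest.raises(ValueError):
            signals.KubicekParams(z0=0.0)


class TestExtractFeatures:
    def test_scripted_recovery(self, steady_recording):
        fv = signals.extract_features(steady_recording, (0.0, 30.0))
        assert fv.ibi == pytest.approx(1000.0, abs=2.0)
        assert fv.pep == pytest.approx(100.0, abs=4.0)
        assert fv.lvet == pytest.approx(300.0, abs=4.0)
        sv_truth = 135.0 * 1.0 * 0.3 * 1.0  # rho (L/Z0)^2 LVET dzdt_max
        assert fv.sv == pytest.approx(sv_truth, rel=0.05)
        assert fv.co == pytest.approx(sv_truth * 60 / 1000, rel=0.05)

    def test_windows_deterministic(self, steady_recording):
        a = signals.extract_features(steady_recording, (5.0, 35.0))
        b = signals.extract_features(steady_recording, (5.0, 35.0))
        np.testing.assert_array_equal(a.as_array(), b.as_array())

    def test_out_of_bounds_window(self, steady_recording):
        with pytest.raises(ValueError):
            signals.extract_features(steady_recording, (40.0, 120.0))

    def test_rejected_beats_never_enter_means(self):
        # poison one IBI with an out-of-range sentinel; the window mean must
        # equal the mean of accepted values only
        ibi = np.full(40, 1000.0)
        beats = make_beats(ibi)
        beats.ibi[10] = 2500.0  # sentinel
        out = signals.qc_ibi(beats)
        sel = out.accepted_beat_indices()
        t = out.r_peak_times[sel]
        vals = out.ibi[sel - 1]
        m = vals[(t >= 0) & (t < 45)].mean()
        assert m == pytest.approx(1000.0)
        assert 2500.0 not in vals
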