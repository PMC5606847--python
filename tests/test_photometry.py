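import numpy as np
import pytest

import shockresp as sr


def trace(time, f, channel=470):
    return sr.FluorescenceTrace(np.asarray(time, float), np.asarray(f, float), channel)


class TestDemultiplex:
    def test_alternating_channels_split_at_half_rate(self):
        rec, _ = sr.gen_photometry(duration_s=2.0, noise_sd=0.0, seed=0)
        sig, ref = sr.demultiplex(rec)
        assert sig.channel == 470 and ref.channel == 405
        assert 1.0 / np.median(np.diff(sig.time)) == pytest.approx(20.0)
        assert 1.0 / np.median(np.diff(ref.time)) == pytest.approx(20.0)

    def test_missing_channel_rejected(self):
        rec = sr.PhotometryRecording(
            np.arange(4) * 0.05, np.full(4, 470), np.ones(4)
        )
        with pytest.raises(sr.InsufficientDataError):
            sr.demultiplex(rec)

    def test_shuffled_rows_equal_sorted_input(self, tmp_path):
        rec, _ = sr.gen_photometry(duration_s=2.0, seed=1)
        perm = np.random.default_rng(0).permutation(rec.sample_times.size)
        path = tmp_path / "p.csv"
        import pandas as pd

        pd.DataFrame(
            {
                "time_s": rec.sample_times[perm],
                "channel": rec.channel_labels[perm],
                "fluorescence": rec.fluorescence[perm],
            }
        ).to_csv(path, index=False)
        back = sr.read_photometry(path)
        s1, r1 = sr.demultiplex(rec)
        s2, r2 = sr.demultiplex(back)
        np.testing.assert_allclose(s1.fluorescence, s2.fluorescence)
        np.testing.assert_allclose(r1.fluorescence, r2.fluorescence)


class TestComputeDff:
    def test_step_response(self):
        t = np.arange(0.0, 20.0, 0.05)
        f = np.where(t < 10.0, 2.0, 3.0)
        dff = sr.compute_dff(trace(t, f), baseline_window=(0.0, 10.0))
        assert dff.f0 == 2.0
        assert dff.dff[0] == 0.0
        assert dff.dff[-1] == pytest.approx(0.5)

    def test_identity_when_f_equals_f0(self):
        t = np.arange(0.0, 12.0, 0.05)
        dff = sr.compute_dff(trace(t, np.full(t.size, 7.0)))
        np.testing.assert_allclose(dff.dff, 0.0)

    def test_median_f0_robust_to_outlier(self):
        t = np.array([0.0, 1.0, 2.0, 12.0])
        f = np.array([1.0, 2.0, 100.0, 4.0])
        dff = sr.compute_dff(trace(t, f), baseline_window=(0.0, 10.0))
        assert dff.f0 == 2.0
        assert dff.dff[-1] == pytest.approx(1.0)  # (4 - 2)/2

    def test_nonpositive_f0_rejected(self):
        t = np.arange(0.0, 12.0, 0.5)
        with pytest.raises(sr.ShockrespError):
            sr.compute_dff(trace(t, np.full(t.size, -1.0)))

    def test_invariant_under_multiplicative_rescaling(self):
        t = np.arange(0.0, 15.0, 0.05)
        f = 2.0 + np.sin(t)
        d1 = sr.compute_dff(trace(t, f))
        d2 = sr.compute_dff(trace(t, 37.5 * f))
        np.testing.assert_allclose(d1.dff, d2.dff, atol=1e-12)


class TestIsosbesticCorrection:
    def test_identical_traces_cancel(self):
        t = np.arange(0.0, 15.0, 0.05)
        f = 5.0 + np.sin(t)
        d = sr.compute_dff(trace(t, f))
        corrected = sr.isosbestic_correct(d, sr.compute_dff(trace(t, f, 405)))
        np.testing.assert_allclose(corrected.dff, 0.0, atol=1e-12)

    def test_additive_equal_dff_artifact_cancels_exactly(self):
        kwargs = dict(
            transient_times=[15.0, 25.0],
            artifact_times=[20.0],
            artifact_amplitude=0.4,
            noise_sd=0.0,
            duration_s=40.0,
            sampling="simultaneous",
        )
        rec, _ = sr.gen_photometry(seed=2, **kwargs)
        clean_kwargs = {**kwargs, "artifact_times": [], "artifact_amplitude": 0.0}
        rec_clean, _ = sr.gen_photometry(seed=2, **clean_kwargs)
        _, _, corrected = sr.process_recording(rec)
        _, _, clean = sr.process_recording(rec_clean)
        assert np.abs(corrected.dff - clean.dff).max() <= 1e-9

    def test_gain_mismatch_leaves_bounded_residual(self):
        amp, gain = 0.4, 0.8
        rec, _ = sr.gen_photometry(
            transient_times=[],
            artifact_times=[20.0],
            artifact_amplitude=amp,
            noise_sd=0.0,
            duration_s=40.0,
            sampling="simultaneous",
            gain_mismatch=gain,
            seed=3,
        )
        _, _, corrected = sr.process_recording(rec)
        # residual bounded by the artifact amplitude times the gain mismatch
        assert np.abs(corrected.dff).max() <= amp * (1 - gain) + 1e-9
        assert np.abs(corrected.dff).max() > 0.5 * amp * (1 - gain)

    def test_interleaved_artifact_nearly_cancels(self):
        rec, _ = sr.gen_photometry(
            transient_times=[],
            artifact_times=[20.0],
            artifact_amplitude=0.4,
            noise_sd=0.0,
            duration_s=40.0,
            sampling="interleaved",
            seed=4,
        )
        d470, _, corrected = sr.process_recording(rec)
        assert np.abs(d470.dff).max() == pytest.approx(0.4, rel=0.01)
        assert np.abs(corrected.dff).max() < 0.02  # interpolation residual only


class TestEventTriggeredAverage:
    def test_identical_transients_average_with_zero_sem(self):
        ev = [12.0, 22.0, 32.0]
        rec, _ = sr.gen_photometry(
            transient_times=ev, noise_sd=0.0, duration_s=45.0, tau_decay_s=0.3, seed=5
        )
        _, _, corrected = sr.process_recording(rec)
        eta = sr.event_triggered_average(
            corrected, sr.EventSeries(np.array(ev), 0.5, 0.3), 2.0, 5.0
        )
        assert eta.n_events == 3
        assert eta.peak == pytest.approx(0.5, rel=0.02)
        assert np.abs(eta.sem_dff).max() < 1e-9

    def test_null_events_average_near_zero(self):
        rec, _ = sr.gen_photometry(
            transient_times=[], noise_sd=0.05, duration_s=60.0, seed=6
        )
        _, _, corrected = sr.process_recording(rec)
        eta = sr.event_triggered_average(
            corrected, sr.EventSeries(np.array([20.0, 30.0, 40.0]), 0.5, 0.3), 2.0, 5.0
        )
        assert np.abs(eta.mean_dff).max() < 0.01

    def test_out_of_range_event_excluded_with_warning(self, caplog):
        rec, _ = sr.gen_photometry(transient_times=[15.0], duration_s=30.0, seed=7)
        _, _, corrected = sr.process_recording(rec)
        with caplog.at_level("WARNING", logger="shockresp"):
            eta = sr.event_triggered_average(
                corrected,
                sr.EventSeries(np.array([15.0, 29.5]), 0.4, 0.3),
                2.0,
                5.0,
            )
        assert eta.n_events == 1
        assert any("excluded" in r.message for r in caplog.records)

    def test_periodic_signal_eta_equals_one_cycle(self):
        period = 4.0
        t = np.arange(0.0, 60.0, 0.05)
        dff = sr.DffTrace(t, np.sin(2 * np.pi * t / period), 1.0, "corrected")
        events = sr.EventSeries(np.arange(12.0, 48.0, period), 0.5, 0.3)
        eta = sr.event_triggered_average(dff, events, 0.0, period)
        expected = np.sin(2 * np.pi * eta.lag / period)
        np.testing.assert_allclose(eta.mean_dff, expected, atol=1e-9)

    def test_peak_sem_matches_closed_form(self):
        # additive noise sigma in each channel -> corrected noise sigma*sqrt(2);
        # SEM at a fixed lag ~ sigma_corr/sqrt(n)
        sigma_raw, f0, n_ev = 0.5, 100.0, 40
        ev = list(12.0 + 6.0 * np.arange(n_ev))
        rec, _ = sr.gen_photometry(
            transient_times=ev,
            noise_sd=sigma_raw,
            f0=f0,
            duration_s=12.0 + 6.0 * n_ev + 10.0,
            seed=8,
        )
        _, _, corrected = sr.process_recording(rec)
        eta = sr.event_triggered_average(
            corrected, sr.EventSeries(np.array(ev), 0.5, 0.3), 2.0, 3.0
        )
        peak_idx = int(np.argmax(eta.mean_dff))
        expected_sem = (sigma_raw / f0) * np.sqrt(2) / np.sqrt(n_ev)
        assert eta.sem_dff[peak_idx] == pytest.approx(expected_sem, rel=0.6)
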