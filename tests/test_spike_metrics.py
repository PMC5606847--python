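import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import shockresp as sr
from conftest import make_train
from _oracles import brute_force_bursts


def random_trains(min_spikes=0, max_spikes=200):
    """Spike trains with ISIs spanning sub- and supra-threshold scales."""
    return (
        st.lists(
            st.floats(0.0005, 0.2),  # ISIs from 0.5 ms to 200 ms
            min_size=min_spikes,
            max_size=max_spikes,
        )
        .map(lambda isis: np.cumsum(np.asarray(isis)))
        .map(lambda t: make_train(t, t_stop=float(t[-1]) + 1.0 if t.size else 1.0))
    )


class TestFiringRate:
    def test_count_over_time(self, train_factory):
        train = train_factory(np.linspace(0.1, 4.9, 10), t_stop=5.0)
        assert sr.mean_firing_rate(train, (0.0, 5.0)) == pytest.approx(2.0)

    def test_empty_train_is_zero(self):
        train = sr.SpikeTrain(np.array([]), 0.0, 5.0)
        assert sr.mean_firing_rate(train) == 0.0

    def test_zero_length_window_rejected(self, train_factory):
        train = train_factory([0.1, 0.2], t_stop=1.0)
        with pytest.raises(sr.ShockrespError):
            sr.mean_firing_rate(train, (0.5, 0.5))

    def test_poisson_rate_estimate(self):
        train, _ = sr.gen_spike_train("irregular", 10.0, 600.0, seed=7)
        assert sr.mean_firing_rate(train) == pytest.approx(10.0, abs=0.5)


class TestCoefficientOfVariation:
    def test_regular_train_has_zero_cv(self, train_factory):
        train = train_factory(np.arange(1, 100) * 0.05)
        assert sr.coefficient_of_variation(train) == pytest.approx(0.0, abs=1e-12)

    def test_poisson_cv_near_one(self):
        train, _ = sr.gen_spike_train("irregular", 10.0, 600.0, seed=11)
        assert sr.coefficient_of_variation(train) == pytest.approx(1.0, abs=0.05)

    def test_gamma_shape_ten_cv(self, rng):
        # 1/sqrt(shape) closed form for a gamma renewal process
        isis = rng.gamma(10.0, 1.0 / (10.0 * 10.0), size=6000)
        train = make_train(np.cumsum(isis))
        assert sr.coefficient_of_variation(train) == pytest.approx(
            1.0 / np.sqrt(10.0), abs=0.05
        )

    def test_too_few_isis_rejected(self, train_factory):
        with pytest.raises(sr.InsufficientDataError):
            sr.coefficient_of_variation(train_factory([0.1, 0.2]))

    @given(
        isis=st.lists(st.floats(0.001, 1.0), min_size=3, max_size=100),
        c=st.floats(0.01, 100.0),
    )
    def test_cv_invariant_under_time_rescaling(self, isis, c):
        times = np.cumsum(np.asarray(isis))
        cv1 = sr.coefficient_of_variation(make_train(times))
        cv2 = sr.coefficient_of_variation(make_train(c * times))
        assert cv1 == pytest.approx(cv2, rel=1e-9)


class TestBurstDetection:
    def test_manual_trace_single_burst(self, train_factory):
        # ISIs 5, 3, 32 ms: burst = first three spikes, 75% of 4 spikes
        train = train_factory([0.0, 0.005, 0.008, 0.040])
        seg = sr.detect_bursts(train)
        assert seg.bursts == [(0, 3)]
        assert seg.percent_in_bursts == pytest.approx(75.0)

    def test_manual_trace_burst_continues_under_end_threshold(self, train_factory):
        # ISIs 5, 7, 6, 32, 250 ms: burst spans the first four spikes
        train = train_factory([0.100, 0.105, 0.112, 0.118, 0.150, 0.400])
        seg = sr.detect_bursts(train)
        assert seg.bursts == [(0, 4)]
        assert seg.percent_in_bursts == pytest.approx(100.0 * 4 / 6, abs=0.1)

    def test_slow_regular_train_has_no_bursts(self, train_factory):
        train = train_factory(np.arange(100) * 0.050)
        seg = sr.detect_bursts(train)
        assert seg.n_bursts == 0
        assert seg.percent_in_bursts == 0.0

    def test_empty_train_empty_segmentation(self):
        seg = sr.detect_bursts(sr.SpikeTrain(np.array([]), 0.0, 1.0))
        assert seg.bursts == [] and seg.percent_in_bursts == 0.0

    @given(train=random_trains())
    def test_agrees_with_brute_force_oracle(self, train):
        seg = sr.detect_bursts(train)
        assert seg.bursts == brute_force_bursts(train.spike_times)

    @given(train=random_trains(min_spikes=2))
    def test_burst_invariants(self, train):
        seg = sr.detect_bursts(train)
        isis_ms = train.isis() * 1000.0
        prev_stop = 0
        for start, stop in seg.bursts:
            assert stop - start >= 2
            assert start >= prev_stop  # disjoint and ordered
            assert isis_ms[start] < seg.start_isi_threshold
            assert np.all(isis_ms[start + 1 : stop - 1] <= seg.end_isi_threshold)
            if stop - 1 < isis_ms.size:  # ISI following the burst terminates it
                assert isis_ms[stop - 1] > seg.end_isi_threshold
            prev_stop = stop


class TestAutocorrelogram:
    def test_periodic_train_peaks_at_multiples(self, train_factory):
        train = train_factory(np.arange(50) * 0.1)  # 100 ms ISIs
        acg = sr.autocorrelogram(train)
        counts = acg.counts
        peak_bins = {10, 20, 30}  # lags 100, 200, 300 ms -> bins [100,110) etc.
        for b in peak_bins:
            assert counts[b] > 0
        assert counts[5] == 0  # no pairs at 50-60 ms

    def test_single_pair(self, train_factory):
        train = train_factory([0.0, 0.030])
        acg = sr.autocorrelogram(train)
        assert acg.counts.sum() == 1
        assert acg.counts[3] == 1  # [30, 40) ms

    def test_bin_must_divide_max_lag(self, train_factory):
        with pytest.raises(sr.ShockrespError):
            sr.autocorrelogram(train_factory([0.0, 0.1]), bin_ms=7.0, max_lag_ms=2000.0)

    def test_poisson_acg_is_flat(self):
        train, _ = sr.gen_spike_train("irregular", 10.0, 600.0, seed=21)
        acg = sr.autocorrelogram(train)
        counts = acg.counts[1:]  # skip the refractory bin
        mean = counts.mean()
        z = (counts - mean) / np.sqrt(mean)
        assert np.abs(z).max() < 4.0

    @given(train=random_trains(min_spikes=2, max_spikes=100))
    def test_total_count_equals_pairs_within_max_lag(self, train):
        acg = sr.autocorrelogram(train, max_lag_ms=500.0)
        t = train.spike_times
        pairs = sum(
            1
            for i in range(t.size)
            for j in range(i + 1, t.size)
            if 0 < (t[j] - t[i]) * 1000.0 <= 500.0
        )
        assert acg.counts.sum() == pairs


class TestFiringModeClassifier:
    def test_constant_isi_train_is_regular(self, train_factory):
        train, _ = sr.gen_spike_train("regular", 5.0, 600.0, seed=31)
        assert sr.classify_firing_mode(sr.autocorrelogram(train)) == "regular"

    def test_refractory_poisson_is_irregular(self):
        train, _ = sr.gen_spike_train("irregular", 10.0, 600.0, seed=32)
        assert sr.classify_firing_mode(sr.autocorrelogram(train)) == "irregular"

    def test_burst_firing_is_bursting(self):
        train, _ = sr.gen_spike_train("bursting", 0.5, 600.0, seed=33)
        assert sr.classify_firing_mode(sr.autocorrelogram(train)) == "bursting"

    def test_empty_acg_rejected(self):
        acg = sr.Autocorrelogram(np.arange(0.0, 2010.0, 10.0), np.zeros(200, int))
        with pytest.raises(sr.InsufficientDataError):
            sr.classify_firing_mode(acg)

    def test_mode_recovery_on_generated_trains(self):
        """Generator ground truth recovered on >=90% of 150 trains (50/mode)."""
        ok = n = 0
        for mode, rate in [("regular", 5.0), ("irregular", 10.0), ("bursting", 0.5)]:
            for s in range(50):
                train, _ = sr.gen_spike_train(mode, rate, 600.0, 5000 + s)
                label = sr.classify_firing_mode(sr.autocorrelogram(train))
                ok += label == mode
                n += 1
        assert ok / n >= 0.90


class TestSummary:
    def test_summary_bundles_all_metrics(self):
        train, _ = sr.gen_spike_train("bursting", 0.5, 300.0, seed=41)
        s = sr.summarize_spontaneous_activity(train)
        assert s.mode_label == "bursting"
        assert s.percent_spikes_in_bursts > 50.0
        assert s.firing_rate_hz > 0
        assert s.n_spikes == train.n_spikes
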