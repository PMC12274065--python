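import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from thalamostate.io_formats import EpochSet, SpikeTrain
from thalamostate.spike_analysis import (
    Autocorrelogram,
    autocorrelogram,
    burst_index,
    bursting_ratio_index,
    classify_cell_type,
    detect_bursts,
    peristimulus_histogram,
    state_firing_metrics,
    zscore_vs_wake,
)
from thalamostate.stim_protocols import tonic_protocol
from thalamostate.synthetic import default_wt_params, gen_spike_train, gen_waveform_widths

from conftest import brute_force_bursts, random_train


class TestAutocorrelogram:
    def test_two_spikes_single_count_in_5ms_bin(self):
        acg = autocorrelogram(SpikeTrain("u", [1.000, 1.005]))
        assert acg.counts[4] == 1  # bin centered at 5 ms
        assert acg.counts.sum() == 1

    def test_regular_20ms_comb(self):
        train = SpikeTrain("u", np.arange(200) * 0.020)
        acg = autocorrelogram(train, max_lag_ms=100)
        hot = np.flatnonzero(acg.counts)
        np.testing.assert_array_equal(acg.lags_ms[hot], [20, 40, 60, 80, 100])

    def test_poisson_counts_flat_across_lags(self):
        # aggregate over many seeds: Poisson autocorrelation has no structure
        total = np.zeros(100)
        for seed in range(100):
            rng = np.random.default_rng(seed)
            t = np.cumsum(rng.exponential(1 / 20.0, 2000))
            total += autocorrelogram(SpikeTrain("u", t)).counts
        dev = np.abs(total - total.mean()) / total.mean()
        assert dev.max() < 0.1

    def test_fewer_than_two_spikes_rejected(self):
        with pytest.raises(ValueError, match="2 spikes"):
            autocorrelogram(SpikeTrain("u", [1.0]))


class TestBurstIndex:
    def test_flat_acg_scores_zero(self):
        assert burst_index(Autocorrelogram(np.full(100, 7))) == 0.0

    def test_zero_baseline_scores_plus_one(self):
        counts = np.zeros(100)
        counts[4] = 100  # peak at 5 ms, empty 40-50 ms baseline
        assert burst_index(Autocorrelogram(counts)) == 1.0

    def test_suppressed_peak_scores_minus_half(self):
        counts = np.zeros(100)
        counts[4] = 10
        counts[39:50] = 20  # bins centered 40..50 ms
        assert burst_index(Autocorrelogram(counts)) == pytest.approx(-0.5)

    def test_degenerate_acg_warns_and_returns_zero(self):
        counts = np.zeros(100)
        counts[70] = 3  # nothing in either analysis window
        with pytest.warns(UserWarning, match="degenerate"):
            assert burst_index(Autocorrelogram(counts)) == 0.0

    @given(
        st.lists(st.integers(min_value=0, max_value=1000), min_size=60, max_size=120)
    )
    @settings(max_examples=100, derandomize=True)
    def test_bounded_in_unit_interval(self, counts):
        acg = Autocorrelogram(np.asarray(counts))
        if not (np.max(counts[:10]) == 0 and np.sum(counts[39:50]) == 0):
            assert -1.0 <= burst_index(acg) <= 1.0


class TestBurstingRatioIndex:
    def test_flat_acg_gives_9_over_50(self):
        # 9 bins strictly below 10 ms vs 50 bins strictly above 50 ms
        assert bursting_ratio_index(Autocorrelogram(np.full(100, 5))) == pytest.approx(
            0.18
        )

    def test_only_short_lags_gives_inf(self):
        counts = np.zeros(100)
        counts[2] = 10
        with pytest.warns(UserWarning):
            assert bursting_ratio_index(Autocorrelogram(counts)) == math.inf

    def test_no_short_lags_gives_zero(self):
        counts = np.zeros(100)
        counts[80] = 10
        assert bursting_ratio_index(Autocorrelogram(counts)) == 0.0


class TestDetectBursts:
    def test_three_spike_burst_plus_tonic(self):
        b = detect_bursts(SpikeTrain("u", [1.000, 1.004, 1.008, 2.000]))
        assert b.n_bursts == 1
        assert b.spike_counts[0] == 3
        assert b.tonic_spike_times_s.tolist() == [2.000]

    def test_insufficient_pre_silence_rejects_run(self):
        # 30 ms before the short-ISI pair is below the 50 ms requirement
        b = detect_bursts(SpikeTrain("u", [1.000, 1.030, 1.038]))
        assert b.n_bursts == 0

    def test_slow_train_has_no_bursts(self):
        b = detect_bursts(SpikeTrain("u", np.arange(10) * 1.0))
        assert b.n_bursts == 0
        assert b.tonic_spike_times_s.size == 10

    def test_train_start_counts_as_silence(self):
        b = detect_bursts(SpikeTrain("u", [0.001, 0.005]))
        assert b.n_bursts == 1

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            train = random_train(rng)
            got = detect_bursts(train)
            expected = brute_force_bursts(train.spike_times_s)
            assert got.n_bursts == len(expected)
            for onset, (i, j) in zip(got.onsets_s, expected):
                assert onset == train.spike_times_s[i]

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=50, derandomize=True)
    def test_partition_is_exact(self, seed):
        train = random_train(np.random.default_rng(seed))
        b = detect_bursts(train)
        assert b.n_burst_spikes + b.tonic_spike_times_s.size == train.n_spikes
        merged = np.sort(
            np.concatenate([b.tonic_spike_times_s] + b.burst_spike_times_s)
        )
        np.testing.assert_array_equal(merged, train.spike_times_s)


class TestStateFiringMetrics:
    def test_pure_tonic_rates(self):
        train = SpikeTrain("u", np.linspace(0, 59.5, 120))
        epochs = EpochSet([0.0], [60.0], ["wake"])
        m = state_firing_metrics(train, detect_bursts(train), epochs)
        row = m.iloc[0]
        assert row["tonic_rate_hz"] == pytest.approx(2.0)
        assert row["burst_spike_rate_hz"] == 0.0
        assert not row["is_bursting"]

    def test_burst_event_rate_and_flag(self):
        # 12 bursts in 10 min -> 1.2/min -> 12 per 10 min > 1: bursting
        spikes = []
        for k in range(12):
            t0 = 25.0 + 50.0 * k
            spikes += [t0, t0 + 0.004]
        train = SpikeTrain("u", spikes)
        epochs = EpochSet([0.0], [600.0], ["NREM"])
        m = state_firing_metrics(train, detect_bursts(train), epochs)
        row = m.iloc[0]
        assert row["burst_event_rate_per_min"] == pytest.approx(1.2)
        assert row["is_bursting"]

    def test_rate_partition_identity(self):
        es = EpochSet([0.0], [600.0], ["NREM"])
        train, _ = gen_spike_train(4, es, default_wt_params())
        m = state_firing_metrics(train, detect_bursts(train), es).iloc[0]
        assert m["total_rate_hz"] == pytest.approx(
            m["tonic_rate_hz"] + m["burst_spike_rate_hz"], abs=1e-9
        )

    def test_recovery_of_generator_truth(self):
        es = EpochSet([0.0], [600.0], ["NREM"])
        train, truth = gen_spike_train(5, es, default_wt_params())
        m = state_firing_metrics(train, detect_bursts(train), es).iloc[0]
        assert m["burst_event_rate_per_min"] == pytest.approx(
            truth.n_bursts / 10.0, abs=1e-9
        )

    def test_zero_duration_state_omitted(self):
        train = SpikeTrain("u", [1.0, 2.0])
        epochs = EpochSet([0.0], [60.0], ["wake"])
        m = state_firing_metrics(train, detect_bursts(train), epochs)
        assert list(m["state"]) == ["wake"]  # no fabricated rows for absent states

    def test_event_counted_in_onset_epoch(self):
        # burst straddles an epoch boundary; the event belongs to the onset side
        train = SpikeTrain("u", [9.998, 10.002, 10.006])
        epochs = EpochSet([0.0, 10.0], [10.0, 20.0], ["wake", "NREM"])
        m = state_firing_metrics(train, detect_bursts(train), epochs)
        by_state = m.set_index("state")
        assert by_state.loc["wake", "burst_event_rate_per_min"] > 0
        assert by_state.loc["NREM", "burst_event_rate_per_min"] == 0


class TestCellType:
    @pytest.mark.parametrize(
        "width,expected",
        [(300.0, "RS"), (200.0, "NS"), (250.0, "NS"), (None, "unclassified")],
    )
    def test_width_rule(self, width, expected):
        assert classify_cell_type(width) == expected

    def test_fixture_population_fraction(self):
        widths = gen_waveform_widths(0, 36, 3)
        labels = [classify_cell_type(w) for w in widths]
        assert labels.count("RS") / len(labels) == pytest.approx(36 / 39)
        assert round(100 * labels.count("RS") / len(labels), 1) == 92.3


def _train_with_bin_rates(wake_rates_hz, target_rate_hz, bin_s=10.0):
    """Regular spikes at the given per-bin rates in wake, then the target."""
    times = []
    for k, r in enumerate(wake_rates_hz):
        t0 = k * bin_s
        n = int(round(r * bin_s))
        if n:
            times.extend(t0 + np.arange(n) * (bin_s / n))
    t0 = len(wake_rates_hz) * bin_s
    n = int(round(target_rate_hz * 100.0))
    if n:
        times.extend(t0 + np.arange(n) * (100.0 / n))
    return SpikeTrain("u", np.array(times)), t0


class TestZScore:
    def _epochs(self, wake_end, target_end):
        wake = EpochSet([0.0], [wake_end], ["wake"])
        target = EpochSet([wake_end], [target_end], ["fLOM"])
        return wake, target

    def test_decrease_when_three_sds_below(self):
        rates = [8, 12] * 10  # mean 10 Hz, SD ~2 across 10 s bins
        train, t0 = _train_with_bin_rates(rates, 4.0)
        wake, target = self._epochs(t0, t0 + 100.0)
        zc = zscore_vs_wake(train, wake, target)
        assert zc.z == pytest.approx((4 - 10) / np.std([8, 12] * 10, ddof=1), rel=1e-2)
        assert zc.label == "decrease"

    def test_no_change_at_wake_mean(self):
        train, t0 = _train_with_bin_rates([8, 12] * 10, 10.0)
        wake, target = self._epochs(t0, t0 + 100.0)
        zc = zscore_vs_wake(train, wake, target)
        assert abs(zc.z) < 0.2
        assert zc.label == "no_change"

    def test_increase_above_196(self):
        rates = [8, 12] * 10
        sd = np.std(rates, ddof=1)
        target = 10.0 + 2.05 * sd
        train, t0 = _train_with_bin_rates(rates, target)
        wake, targ = self._epochs(t0, t0 + 100.0)
        zc = zscore_vs_wake(train, wake, targ)
        assert zc.label == "increase"

    def test_label_breakpoints_exact(self):
        from thalamostate.spike_analysis import Z_THRESHOLD

        assert Z_THRESHOLD == 1.96
        # z exactly at the threshold is "no change" (strict inequalities)
        rates = [8, 12] * 10
        sd = np.std(rates, ddof=1)
        train, t0 = _train_with_bin_rates(rates, 10.0 + 1.96 * sd)
        wake, targ = self._epochs(t0, t0 + 100.0)
        assert zscore_vs_wake(train, wake, targ).label == "no_change"

    def test_zero_variance_wake_undefined(self):
        train, t0 = _train_with_bin_rates([10] * 20, 5.0)
        wake, targ = self._epochs(t0, t0 + 100.0)
        with pytest.warns(UserWarning, match="zero variance"):
            assert zscore_vs_wake(train, wake, targ).label == "undefined"

    def test_insufficient_wake_occupancy_rejected(self):
        train, t0 = _train_with_bin_rates([10] * 5, 5.0)
        wake = EpochSet([0.0], [50.0], ["wake"])
        targ = EpochSet([50.0], [150.0], ["fLOM"])
        with pytest.raises(ValueError, match="10"):
            zscore_vs_wake(train, wake, targ)


class TestPeristimulus:
    def test_perfect_following_at_5ms(self):
        pulses = tonic_protocol(ipi_ms=50, width_ms=6.25, duration_s=10.0)
        train = SpikeTrain("u", pulses.onsets_s + 0.005)
        res = peristimulus_histogram(train, pulses)
        assert res.fidelity == 1.0
        assert res.latency_ms == pytest.approx(5.0)
        assert res.jitter_ms == pytest.approx(0.0, abs=1e-9)

    def test_silent_neuron(self):
        pulses = tonic_protocol(ipi_ms=50, width_ms=6.25, duration_s=1.0)
        train = SpikeTrain("u", [100.0, 101.0])
        res = peristimulus_histogram(train, pulses)
        assert res.fidelity == 0.0
        assert math.isnan(res.latency_ms)

    def test_half_responsive(self):
        pulses = tonic_protocol(ipi_ms=50, width_ms=6.25, duration_s=10.0)
        train = SpikeTrain("u", pulses.onsets_s[::2] + 0.003)
        res = peristimulus_histogram(train, pulses)
        assert res.fidelity == pytest.approx(0.5)

    def test_empty_window_rejected(self):
        pulses = tonic_protocol(duration_s=1.0)
        with pytest.raises(ValueError, match="window"):
            peristimulus_histogram(SpikeTrain("u", [0.1, 0.2]), pulses, window_ms=0)
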