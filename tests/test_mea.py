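"""MEA filtering, spike detection, burst and network-burst analysis."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from axonsynkit import mea
from axonsynkit import synthetic as syn
from axonsynkit.config import PRESETS

FS = 20_000.0


def _sine(freq, fs=FS, dur=2.0, amp=1.0):
    t = np.arange(int(dur * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t)


def _attenuation_db(freq):
    x = _sine(freq)
    y = mea.filter_trace(x, FS)
    core = slice(int(0.5 * FS), int(1.5 * FS))  # avoid edge transients
    return 20 * np.log10(np.abs(y[core]).max() / np.abs(x[core]).max())


class TestFilterTrace:
    def test_10hz_attenuated_beyond_20db(self):
        assert _attenuation_db(10.0) < -20.0

    def test_50hz_notch_attenuates_beyond_20db(self):
        assert _attenuation_db(50.0) < -20.0

    def test_1khz_passband_within_5pct(self):
        x = _sine(1000.0)
        y = mea.filter_trace(x, FS)
        core = slice(int(0.5 * FS), int(1.5 * FS))
        assert np.abs(y[core]).max() == pytest.approx(1.0, rel=0.05)

    def test_matches_analytic_butterworth_magnitudes(self):
        # passband edges behave like the design equations say they should
        from scipy import signal
        for freq, order, kind in ((100.0, 2, "hp"), (3500.0, 4, "lp")):
            got = 10 ** (_attenuation_db(freq) / 20)
            # at the corner, each Butterworth contributes 1/sqrt(2);
            # filtfilt squares the magnitude response
            assert got == pytest.approx(0.5, rel=0.1)

    def test_length_preserved_and_low_fs_rejected(self):
        x = _sine(500.0, dur=0.5)
        assert mea.filter_trace(x, FS).size == x.size
        with pytest.raises(ValueError):
            mea.filter_trace(x, 5000.0)


class TestDetectSpikes:
    def test_embedded_spikes_recovered(self):
        rng = np.random.default_rng(0)
        times = np.sort(rng.uniform(0.1, 59.9, 100))
        times = times[np.concatenate([[True], np.diff(times) > 0.01])]
        trace = syn.render_spike_trace(times, 60.0, FS, noise_sd=5.0, seed=1)
        det = mea.detect_spikes(mea.filter_trace(trace, FS), FS)
        assert det.size >= 0.99 * times.size
        assert det.size <= 1.05 * times.size

    def test_noise_only_false_positive_rate_near_analytic_tail(self):
        # 5-sigma two-sided Gaussian tail is ~5.7e-7 per sample
        rng = np.random.default_rng(2)
        trace = rng.normal(0, 1.0, int(120 * FS))
        det = mea.detect_spikes(trace, FS)
        n = trace.size
        p_tail = 2 * (1 - 0.9999997133484281)  # 2*(1-Phi(5))
        expected = n * p_tail
        assert det.size <= max(10 * expected, 10)

    def test_zero_trace_no_spikes_with_warning(self):
        with pytest.warns(UserWarning):
            assert mea.detect_spikes(np.zeros(1000), FS).size == 0


def _train(times, duration=600.0, e=0):
    return syn.SpikeTrain(e, np.asarray(times, dtype=float), duration)


def _well(trains, duration=600.0):
    full = list(trains) + [
        _train([], duration, e) for e in range(len(trains), 12)
    ]
    for e, tr in enumerate(full):
        tr.electrode_id = e
    return syn.WellRecording("w", 21, full, duration_s=duration)


class TestActiveElectrodes:
    def test_strictly_greater_than_10_per_min(self):
        just_over = _train(np.linspace(0.1, 599, 101), e=0)
        exactly = _train(np.linspace(0.1, 599, 100), e=1)
        w = _well([just_over, exactly])
        assert mea.active_electrodes(w) == {0}

    def test_silent_well_empty_set(self):
        assert mea.active_electrodes(_well([])) == set()


class TestMeanFiringRate:
    def test_mean_over_active_only(self):
        a = _train(np.linspace(0.001, 599.9, 600), e=0)     # 1 Hz
        b = _train(np.linspace(0.001, 599.9, 1800), e=1)    # 3 Hz
        w = _well([a, b])
        assert mea.mean_firing_rate(w) == pytest.approx(2.0)

    def test_no_active_flagged_zero(self):
        with pytest.warns(UserWarning):
            assert mea.mean_firing_rate(_well([])) == 0.0


def _burst_oracle(t, isi=0.05, quiet=0.1, minsp=3):
    """Independent re-derivation: split at long gaps, seed inside clusters."""
    t = np.asarray(t)
    out = []
    if t.size < 2:
        return out
    gaps = np.diff(t)
    cluster_starts = np.concatenate([[0], np.nonzero(gaps > quiet)[0] + 1])
    cluster_ends = np.concatenate([np.nonzero(gaps > quiet)[0], [t.size - 1]])
    for s, e in zip(cluster_starts, cluster_ends):
        seed = next((i for i in range(s, e) if t[i + 1] - t[i] <= isi), None)
        if seed is not None and e - seed + 1 >= minsp:
            out.append((float(t[seed]), float(t[e]), int(e - seed + 1)))
    return out


class TestDetectBursts:
    def test_worked_example_simple_burst(self):
        tr = _train([0.0, 0.03, 0.06, 0.09, 0.5])
        (b,) = mea.detect_bursts(tr)
        assert (b.t_start, b.t_end, b.n_spikes) == (0.0, 0.09, 4)

    def test_slow_train_has_no_bursts(self):
        tr = _train(np.arange(0, 10, 0.2))
        assert mea.detect_bursts(tr) == []

    def test_mid_burst_gap_between_join_and_quiet_continues(self):
        # gap of 0.08 s: larger than the 50 ms join but within the 100 ms
        # termination window, so the burst continues
        tr = _train([0.0, 0.03, 0.11, 0.14, 0.17, 0.8])
        (b,) = mea.detect_bursts(tr)
        assert (b.t_start, b.t_end, b.n_spikes) == (0.0, 0.17, 5)

    def test_spike_in_burst_uniqueness_and_disjoint_intervals(self, rng):
        t = np.sort(rng.uniform(0, 20, 400))
        t = t[np.concatenate([[True], np.diff(t) > 1e-5])]
        bursts = mea.detect_bursts(_train(t, duration=25.0))
        for a, b in zip(bursts, bursts[1:]):
            assert a.t_end < b.t_start
        total = sum(b.n_spikes for b in bursts)
        in_any = sum(((t >= b.t_start) & (t <= b.t_end)).sum() for b in bursts)
        assert total == in_any

    @given(st.lists(st.floats(0.0, 5.0), min_size=0, max_size=50))
    @settings(max_examples=300, deadline=None)
    def test_equals_brute_force_interval_scan(self, raw):
        t = np.unique(np.round(np.asarray(raw, dtype=float), 6))
        t = t[t < 6.0]
        tr = _train(t, duration=6.0)
        mine = [(b.t_start, b.t_end, b.n_spikes)
                for b in mea.detect_bursts(tr)]
        assert mine == _burst_oracle(t)


class TestNetworkBursts:
    def test_four_electrode_overlap_detected(self):
        bursts = {e: [mea.Burst(e, 0.10, 0.20, 5)] for e in range(4)}
        (nb,) = mea.detect_network_bursts(bursts)
        assert nb.t_start == pytest.approx(0.10)
        assert nb.duration_s == pytest.approx(0.10)
        assert nb.electrode_ids == frozenset(range(4))

    def test_three_electrodes_insufficient(self):
        bursts = {e: [mea.Burst(e, 0.10, 0.20, 5)] for e in range(3)}
        assert mea.detect_network_bursts(bursts) == []

    def test_monotone_in_min_electrodes(self):
        rng = np.random.default_rng(3)
        bursts = {
            e: [mea.Burst(e, t, t + rng.uniform(0.05, 0.3), 4)
                for t in np.sort(rng.uniform(0, 50, 20))]
            for e in range(12)
        }
        counts = [len(mea.detect_network_bursts(bursts, min_electrodes=m))
                  for m in (2, 4, 6, 8)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_generator_network_events_recovered(self):
        p = PRESETS["WT"].replace(mfr_base=1.0, burst_rate=0.5,
                                  netburst_rate=2.0)
        tot_true = tot_det = 0
        for s in range(10):
            w = syn.gen_mea_recording(p, duration_s=600.0, seed=s)
            by_e = {tr.electrode_id: mea.detect_bursts(tr)
                    for tr in w.electrodes}
            tot_det += len(mea.detect_network_bursts(by_e))
            tot_true += len(w.truth["network_events"])
        assert tot_det == pytest.approx(tot_true, rel=0.1)


class TestSummarizeWell:
    def test_silent_well_all_zero(self):
        with pytest.warns(UserWarning):
            s = mea.summarize_well(_well([]))
        assert (s.n_active, s.mfr, s.burst_freq, s.nb_freq) == (0, 0.0, 0.0, 0.0)

    def test_burst_frequency_arithmetic(self):
        spikes = np.concatenate([
            [10.0, 10.02, 10.04, 10.06],
            [300.0, 300.02, 300.04],
            np.linspace(20, 590, 120),
        ])
        tr = _train(np.unique(spikes), e=0)
        s = mea.summarize_well(_well([tr]))
        assert s.burst_freq == pytest.approx(0.2)  # 2 bursts / 10 min

    def test_mfr_invariant_to_electrode_relabeling(self, rng):
        trains = [_train(np.sort(rng.uniform(0, 600, 400)), e=e)
                  for e in range(12)]
        w1 = _well(trains)
        rev = [_train(trains[11 - e].spike_times, e=e) for e in range(12)]
        w2 = _well(rev)
        assert mea.mean_firing_rate(w1) == pytest.approx(
            mea.mean_firing_rate(w2))
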