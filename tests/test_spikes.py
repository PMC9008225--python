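import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from holomea.layout import MEALayout
from holomea.network import NetworkGroundTruth
from holomea.recording import RawRecording
from holomea.simulate import SimConfig, render_extracellular, spike_waveform
from holomea.spikes import (
    activity_metrics,
    assign_units,
    detect_bursts,
    detect_spikes,
    extract_snippets,
    highpass,
    robust_sigma,
    select_active_electrodes,
)

FS = 25_000.0


def make_rec(signals, fs=FS):
    signals = np.atleast_2d(signals)
    ids = [f"ch{i}" for i in range(signals.shape[0])]
    return RawRecording(signals, fs, ids)


# ---------------------------------------------------------------------------
# filtering

class TestHighpass:
    def test_dc_is_rejected(self):
        rec = make_rec(np.full(int(2 * FS), 7.3))
        out = highpass(rec)
        assert np.abs(out.signals).max() < 1e-6
        assert out.n_samples == rec.n_samples

    def test_10hz_attenuated_below_5pct(self):
        t = np.arange(int(4 * FS)) / FS
        rec = make_rec(np.sin(2 * np.pi * 10 * t))
        out = highpass(rec)
        mid = out.signals[0][int(FS) : -int(FS)]  # ignore filter edges
        assert np.abs(mid).max() < 0.05

    def test_1khz_passband_preserved_within_5pct(self):
        t = np.arange(int(4 * FS)) / FS
        rec = make_rec(np.sin(2 * np.pi * 1000 * t))
        out = highpass(rec)
        mid = out.signals[0][int(FS) : -int(FS)]
        assert abs(np.abs(mid).max() - 1.0) < 0.05

    def test_cutoff_above_nyquist_rejected(self):
        rec = make_rec(np.zeros(int(2 * FS)))
        with pytest.raises(ValueError):
            highpass(rec, cutoff_hz=FS / 2)


# ---------------------------------------------------------------------------
# detection

class TestDetectSpikes:
    def test_all_zero_signal_yields_empty_train(self):
        trains = detect_spikes(make_rec(np.zeros(int(2 * FS))))
        assert len(trains["ch0"]) == 0

    def test_pure_noise_has_at_most_two_false_events(self):
        rng = np.random.default_rng(7)
        x = rng.normal(0, 1.0, int(10 * FS))
        trains = detect_spikes(make_rec(x), k_sigma=5.0)
        assert len(trains["ch0"]) <= 2

    def test_injected_8sigma_templates_recovered(self):
        rng = np.random.default_rng(8)
        noise_sd = 2.0
        x = rng.normal(0, noise_sd, int(10 * FS))
        wf = spike_waveform(FS)
        peak = int(round(0.55e-3 * FS))
        true_times = np.arange(0.5, 9.5, 0.25)
        for t in true_times:
            i = int(round(t * FS)) - peak
            x[i : i + len(wf)] += 8 * noise_sd * wf
        trains = detect_spikes(make_rec(x), k_sigma=5.0)
        det = trains["ch0"].timestamps_s
        matched = [np.abs(det - t).min() < 2e-4 for t in true_times]
        assert all(matched)

    def test_debounce_collapses_one_waveform_to_one_event(self):
        x = np.zeros(int(2 * FS))
        wf = spike_waveform(FS)
        x[10_000 : 10_000 + len(wf)] += 100 * wf
        x += np.random.default_rng(0).normal(0, 1.0, x.size)
        trains = detect_spikes(make_rec(x))
        assert len(trains["ch0"]) == 1
        assert trains["ch0"].polarity[0] == -1

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError, match="1 s"):
            detect_spikes(make_rec(np.zeros(100)))

    def test_robust_sigma_of_gaussian_noise(self):
        x = np.random.default_rng(3).normal(0, 2.5, 200_000)
        assert abs(robust_sigma(x) - 2.5) < 0.05


def test_detection_false_positive_rate_on_noise_montecarlo():
    """<= 1 false event per 10 s channel at 5 sigma, 20 repetitions."""
    rng = np.random.default_rng(55)
    counts = []
    for _ in range(20):
        x = rng.normal(0, 1.0, int(10 * FS))
        trains = detect_spikes(make_rec(x), k_sigma=5.0)
        counts.append(len(trains["ch0"]))
    assert np.mean(counts) <= 1.0


def test_end_to_end_recovery_within_30um():
    """Detection after rendering recovers >= 95% of ground-truth spikes of
    units lying within 30 um of an electrode at default SNR."""
    layout = MEALayout(2, 2, 150.0, 30.0)
    net = NetworkGroundTruth(
        neuron_positions=[[10.0, 0.0], [150.0, 170.0]],
        edges=np.empty((0, 2)),
        weights=[],
        delays_ms=[],
        expresses_opsin=[True, True],
        amplitudes=np.array([200.0, 200.0]),
    )
    cfg = SimConfig(duration_s=30.0, spont_rate_hz=1.5, burst_rate_hz=0.0)
    rng = np.random.default_rng(21)
    times = np.sort(rng.uniform(0.2, 29.8, 45))
    spikes = pd.DataFrame(
        {"time_s": np.concatenate([times, times + 0.003]),
         "neuron": [0] * 45 + [1] * 45,
         "source": "spont"}
    ).sort_values("time_s")
    rec = render_extracellular(spikes, net, layout, cfg, seed=22)
    trains = detect_spikes(highpass(rec))
    d = np.linalg.norm(layout.electrode_centers - np.array([10.0, 0.0]), axis=1)
    near = layout.electrode_ids[int(np.argmin(d))]
    det = trains[near].timestamps_s
    recovered = np.mean([np.abs(det - t).min() < 5e-4 for t in times])
    assert recovered >= 0.95


# ---------------------------------------------------------------------------
# unit assignment

class TestAssignUnits:
    def test_exact_template_match(self):
        wf = spike_waveform(FS)
        from holomea.spikes import SpikeTrain

        trains = {"e": SpikeTrain("e", np.array([0.1, 0.2]))}
        snips = {"e": np.stack([3 * wf, 3 * wf])}
        templates = {"e": {"A": 3 * wf, "B": 0.5 * wf}}
        table = assign_units(trains, snips, templates)
        assert list(table["unit"]) == ["A", "A"]

    def test_two_amplitude_classes_separate_perfectly(self):
        wf = spike_waveform(FS)
        from holomea.spikes import SpikeTrain

        n = 10
        amps = np.array([1.0, 4.0] * (n // 2))
        trains = {"e": SpikeTrain("e", np.arange(n) * 0.01 + 0.01)}
        snips = {"e": np.stack([a * wf for a in amps])}
        templates = {"e": {"small": 1.0 * wf, "big": 4.0 * wf}}
        table = assign_units(trains, snips, templates)
        expect = ["small" if a == 1.0 else "big" for a in amps]
        assert list(table["unit"]) == expect

    def test_empty_spike_list_gives_empty_table(self):
        from holomea.spikes import SpikeTrain

        trains = {"e": SpikeTrain("e", np.array([]))}
        table = assign_units(trains, {"e": np.empty((0, 50))},
                             {"e": {"A": np.zeros(50)}})
        assert table.empty

    def test_template_length_mismatch_raises(self):
        from holomea.spikes import SpikeTrain

        trains = {"e": SpikeTrain("e", np.array([0.1]))}
        with pytest.raises(ValueError, match="length"):
            assign_units(trains, {"e": np.zeros((1, 50))},
                         {"e": {"A": np.zeros(40)}})

    def test_snippet_extraction_is_peak_aligned(self):
        x = np.zeros(int(FS))
        wf = spike_waveform(FS)
        start = 12_000
        x[start : start + len(wf)] += wf
        t_peak = (start + np.argmin(wf)) / FS
        snips = extract_snippets(x, FS, np.array([t_peak]))
        assert np.allclose(snips[0], wf, atol=1e-12)


# ---------------------------------------------------------------------------
# bursts

from oracles import burst_oracle  # noqa: E402


class TestDetectBursts:
    def test_five_spike_burst_hand_trace(self):
        t = np.array([0, 5, 10, 15, 20]) / 1e3
        bs = detect_bursts(t)
        assert bs.n_bursts == 1
        s, e, n = bs.bursts[0]
        assert n == 5
        assert np.isclose(e - s, 0.020)
        assert bs.pct_spikes_in_bursts == 100.0

    def test_sparse_train_has_no_bursts(self):
        bs = detect_bursts(np.array([0, 30, 60]) / 1e3)
        assert bs.n_bursts == 0

    def test_empty_train(self):
        bs = detect_bursts(np.array([]))
        assert bs.n_bursts == 0
        assert bs.pct_spikes_in_bursts == 0.0

    def test_burst_frequency_never_exceeds_spike_frequency(self):
        rng = np.random.default_rng(17)
        t = np.sort(rng.uniform(0, 10, 300))
        bs = detect_bursts(t, train_duration_s=10.0)
        assert bs.burst_frequency_hz <= len(t) / 10.0
        assert 0.0 <= bs.pct_spikes_in_bursts <= 100.0

    @given(st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_bruteforce_oracle_on_random_trains(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(0, 200))
        # mix of dense clusters and sparse background to exercise all rules
        t = np.sort(np.concatenate([
            rng.uniform(0, 2.0, n // 2),
            np.repeat(rng.uniform(0, 2.0, max(n // 20, 1)), 5)
            + rng.uniform(0, 0.03, ((n // 20) if n >= 20 else 1) * 5),
        ]))
        got = detect_bursts(t).bursts
        want = burst_oracle(t)
        assert len(got) == len(want)
        for (s1, e1, n1), (s2, e2, n2) in zip(got, want):
            assert np.isclose(s1, s2) and np.isclose(e1, e2) and n1 == n2


# ---------------------------------------------------------------------------
# activity metrics

class TestActivityMetrics:
    def test_spontaneous_rate(self):
        table = pd.DataFrame({
            "time_s": np.linspace(0.5, 9.5, 10),
            "electrode": "e1", "unit": "u1",
        })
        out = activity_metrics(table, [(0.0, 10.0)])
        assert np.isclose(out.loc[0, "rate_hz"], 1.0)

    def test_spikes_outside_windows_do_not_count(self):
        table = pd.DataFrame({
            "time_s": [0.5, 1.5], "electrode": "e1", "unit": "u1"})
        out = activity_metrics(table, [(2.0, 2.075)])
        assert out.loc[0, "rate_hz"] == 0.0

    def test_one_spike_per_75ms_window_is_13hz(self):
        windows = [(i * 1.0, i * 1.0 + 0.075) for i in range(20)]
        table = pd.DataFrame({
            "time_s": [w[0] + 0.01 for w in windows],
            "electrode": "e1", "unit": "u1",
        })
        out = activity_metrics(table, windows)
        assert np.isclose(out.loc[0, "rate_hz"], 1 / 0.075, rtol=1e-6)

    def test_invalid_window_rejected(self):
        table = pd.DataFrame({"time_s": [0.1], "electrode": "e", "unit": "u"})
        with pytest.raises(ValueError):
            activity_metrics(table, [(1.0, 1.0)])


class TestSelectActiveElectrodes:
    def test_low_rate_everywhere_excluded(self):
        rates = pd.DataFrame({"s1": [0.1], "s2": [0.1], "s3": [0.1]},
                             index=["e1"])
        kept, _ = select_active_electrodes(rates)
        assert kept == []

    def test_transiently_active_retained_with_zeros(self):
        rates = pd.DataFrame({"s1": [0.5], "s2": [0.6], "s3": [0.0]},
                             index=["e1"])
        kept, zeroed = select_active_electrodes(rates)
        assert kept == ["e1"]
        assert zeroed.loc["e1", "s3"] == 0.0
        assert zeroed.loc["e1", "s1"] == 0.5

    def test_all_silent_array(self):
        rates = pd.DataFrame(np.zeros((5, 3)),
                             index=[f"e{i}" for i in range(5)],
                             columns=["s1", "s2", "s3"])
        kept, zeroed = select_active_electrodes(rates)
        assert kept == [] and zeroed.empty

    def test_single_session_rejected(self):
        rates = pd.DataFrame({"s1": [1.0]}, index=["e1"])
        with pytest.raises(ValueError):
            select_active_electrodes(rates)
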