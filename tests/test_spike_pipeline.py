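from dataclasses import replace

import numpy as np
import pytest

from clampkit import CellRecording, StepProtocol, Sweep, wt_params
from clampkit.spike_pipeline import (
    DetectionError,
    classify_spikes,
    detect_spikes,
    evoked_spikes,
    fi_curve,
    rheobase_features,
)
from clampkit.synthetic_cells import simulate_current_clamp

from _oracles import brute_force_spikes

SR = 10_000.0
ONSET, OFFSET = 0.020, 0.080  # 60 ms step inside a 100 ms sweep


def make_sweep(samples, command=100.0, onset=ONSET, offset=OFFSET):
    return Sweep(
        samples=np.asarray(samples, dtype=float), sampling_rate=SR,
        command_level=command, step_onset=onset, step_offset=offset,
        holding_level=0.0, mode="current_clamp",
    )


def insert_triangle(v, start_idx, baseline=-65.0, peak=15.0, slope_mv_per_ms=40.0):
    """Symmetric triangular spike: both limbs exceed the slope criteria."""
    per_sample = slope_mv_per_ms / (SR / 1000.0)
    n_limb = int(round((peak - baseline) / per_sample))
    up = np.linspace(baseline, peak, n_limb + 1)
    down = np.linspace(peak, baseline, n_limb + 1)[1:]
    tri = np.concatenate([up, down])
    v[start_idx : start_idx + tri.size] = tri
    return start_idx, start_idx + n_limb  # upcross index, peak index


class TestDetectTrivialCases:
    def test_constant_trace_has_no_spikes(self):
        assert detect_spikes(make_sweep(np.full(1000, -65.0))) == []

    def test_sub_criterion_ramp_is_not_a_spike(self):
        """A 25 mV/ms rise to +20 mV never crosses the 30 mV/ms criterion."""
        v = np.full(1000, -65.0)
        n = int(round(85.0 / 2.5))  # 2.5 mV per sample = 25 mV/ms
        v[300 : 300 + n] = -65.0 + 2.5 * np.arange(n)
        v[300 + n : 300 + 2 * n] = v[300 + n - 1] - 2.5 * np.arange(n)
        assert detect_spikes(make_sweep(v)) == []

    def test_subzero_peak_is_rejected(self):
        v = np.full(1000, -65.0)
        insert_triangle(v, 400, peak=-5.0)
        assert detect_spikes(make_sweep(v)) == []

    def test_single_triangle_is_one_spike_with_exact_peak(self):
        v = np.full(1000, -65.0)
        ui, pi = insert_triangle(v, 400)
        (ev,) = detect_spikes(make_sweep(v))
        assert ev.peak_time == pytest.approx(pi / SR)
        assert ev.peak_voltage == pytest.approx(15.0)
        assert ev.upcross_time == pytest.approx(ui / SR)

    def test_slow_repolarization_fails_pairing_window(self):
        """Fast rise but a 10 mV/ms fall: no qualifying down-slope, no event."""
        v = np.full(2000, -65.0)
        up = np.linspace(-65.0, 15.0, 21)  # 40 mV/ms
        down = 15.0 - 1.0 * np.arange(1, 81)  # 10 mV/ms
        v[500:521] = up
        v[521:601] = down
        assert detect_spikes(make_sweep(v)) == []

    def test_voltage_clamp_sweep_is_rejected(self):
        sw = Sweep(samples=np.zeros(1000), sampling_rate=SR, command_level=10.0,
                   step_onset=ONSET, step_offset=OFFSET, holding_level=-60.0,
                   mode="voltage_clamp")
        with pytest.raises(DetectionError):
            detect_spikes(sw)


class TestDetectAgainstBruteForceOracle:
    def test_simulated_noisy_sweeps_agree_with_exhaustive_scan(
        self, short_cc_protocol
    ):
        params = wt_params()
        mismatches = 0
        total_events = 0
        for seed in range(3):
            sweeps, _ = simulate_current_clamp(params, short_cc_protocol, seed=seed)
            for sw in sweeps:
                got = [
                    (int(round(e.upcross_time * sw.sampling_rate)),
                     int(round(e.peak_time * sw.sampling_rate)))
                    for e in detect_spikes(sw)
                ]
                want = brute_force_spikes(sw.samples, sw.sampling_rate)
                total_events += len(want)
                if got != want:
                    mismatches += 1
        assert mismatches == 0
        assert total_events > 100  # the comparison actually exercised spikes

    def test_pathological_random_walks_agree_with_exhaustive_scan(self):
        rng = np.random.default_rng(7)
        for _ in range(40):
            v = -60.0 + np.cumsum(rng.normal(0.0, 2.5, size=400))
            sw = make_sweep(v, onset=0.005, offset=0.035)
            got = [
                (int(round(e.upcross_time * SR)), int(round(e.peak_time * SR)))
                for e in detect_spikes(sw)
            ]
            assert got == brute_force_spikes(v, SR)


class TestClassification:
    def test_window_boundaries(self):
        v = np.full(2000, -65.0)
        on_i, off_i = int(ONSET * SR), int(OFFSET * SR)
        insert_triangle(v, 50)          # before onset -> spontaneous
        insert_triangle(v, on_i)        # at onset -> evoked (half-open)
        insert_triangle(v, off_i)       # at offset -> rebound
        sw = make_sweep(v, command=100.0, offset=OFFSET)
        labels = [e.classification for e in classify_spikes(detect_spikes(sw), sw)]
        assert labels == ["spontaneous", "evoked", "rebound"]

    def test_spike_during_hyperpolarizing_step_is_not_evoked(self):
        v = np.full(2000, -65.0)
        insert_triangle(v, int(0.05 * SR))  # inside the step window
        sw = make_sweep(v, command=-100.0)
        (ev,) = classify_spikes(detect_spikes(sw), sw)
        assert ev.classification == "rebound"
        assert evoked_spikes(sw) == []


def _recording_with_counts(counts_per_rep, amp=100.0):
    """One amplitude; rep r carries counts_per_rep[r] evoked triangles."""
    proto = StepProtocol(
        mode="current_clamp", holding_level=0.0, pre_duration=ONSET,
        step_duration=OFFSET - ONSET, post_duration=0.020,
        amplitudes=(amp,), repetitions=len(counts_per_rep),
    )
    sweeps = []
    for rep, k in enumerate(counts_per_rep):
        v = np.full(1000, -65.0)
        for j in range(k):
            insert_triangle(v, int(ONSET * SR) + 10 + 60 * j)
        sweeps.append(replace(make_sweep(v, command=amp), repetition_index=rep))
    return CellRecording(
        cell_id="c", genotype="WT", treatment="vehicle", condition="from_rest",
        resting_potential=-65.0, sweeps={"current_steps": sweeps},
        protocols={"current_steps": proto},
    )


class TestFICurve:
    def test_mean_count_and_proportions(self):
        rec = _recording_with_counts([2, 2, 3, 2, 3])
        fi = fi_curve(rec)
        assert fi.spike_count.tolist() == [pytest.approx(2.4)]
        assert fi.p_one_or_more.tolist() == [1.0]
        assert fi.p_exactly_one.tolist() == [0.0]

    def test_exactly_one_proportion(self):
        fi = fi_curve(_recording_with_counts([0, 1, 1, 2]))
        assert fi.p_one_or_more.tolist() == [0.75]
        assert fi.p_exactly_one.tolist() == [0.5]

    def test_missing_repetition_warns(self):
        rec = _recording_with_counts([1, 1, 1])
        rec.sweeps["current_steps"].pop()
        with pytest.warns(UserWarning):
            fi = fi_curve(rec)
        assert fi.spike_count.tolist() == [1.0]


class TestRheobaseFeatures:
    def test_triangle_geometry_is_recovered_exactly(self):
        """40 mV/ms symmetric triangle from -65 to +15: threshold at the
        corner (-65 mV), amplitude 80 mV, half-width 2 ms."""
        rec = _recording_with_counts([1])
        # let the trace dip just below threshold after the spike so the
        # spike end (first sample back below threshold) is defined
        sw = rec.sweeps["current_steps"][0]
        v = sw.samples.copy()
        after = int(ONSET * SR) + 10 + 41  # one sample past the falling limb
        v[after:] = -66.0
        rec.sweeps["current_steps"][0] = replace(sw, samples=v)
        rb = rheobase_features(rec)
        assert rb is not None
        fs = rb.first_spike
        assert fs.threshold_voltage == pytest.approx(-65.0)
        assert fs.amplitude == pytest.approx(80.0)
        assert fs.width == pytest.approx(2.0, abs=1e-6)
        assert fs.latency == pytest.approx((10 + 1) / SR * 1000.0 - 0.0, abs=0.2)
        assert fs.latency > 0
        assert fs.end_time is not None and fs.end_time > fs.peak_time

    def test_never_firing_cell_returns_none(self):
        rec = _recording_with_counts([0, 0])
        assert rheobase_features(rec) is None

    def test_lowest_firing_amplitude_wins(self):
        low = _recording_with_counts([1], amp=40.0)
        high = _recording_with_counts([1], amp=120.0)
        proto = StepProtocol(
            mode="current_clamp", holding_level=0.0, pre_duration=ONSET,
            step_duration=OFFSET - ONSET, post_duration=0.020,
            amplitudes=(40.0, 120.0), repetitions=1,
        )
        merged = CellRecording(
            cell_id="c", genotype="WT", treatment="vehicle",
            condition="from_rest", resting_potential=-65.0,
            sweeps={"current_steps": low.sweeps["current_steps"]
                    + high.sweeps["current_steps"]},
            protocols={"current_steps": proto},
        )
        rb = rheobase_features(merged)
        assert rb.rheobase_current == 40.0

    def test_width_undefined_when_voltage_never_recrosses_threshold(self):
        v = np.full(1000, -65.0)
        # rising limb then a plateau above threshold to the end of the sweep,
        # with one fast partial repolarization to satisfy the down-slope
        up = np.linspace(-65.0, 15.0, 21)
        start = int(ONSET * SR) + 10
        v[start : start + 21] = up
        v[start + 21 : start + 31] = np.linspace(15.0, -20.0, 10)
        v[start + 31 :] = -20.0  # stays above the -65 mV threshold forever
        rec = _recording_with_counts([0])
        rec.sweeps["current_steps"][0] = replace(
            rec.sweeps["current_steps"][0], samples=v
        )
        rb = rheobase_features(rec)
        assert rb is not None
        assert rb.first_spike.end_time is None
        assert rb.first_spike.width is None

    def test_rheobase_increases_with_spike_threshold(self, short_cc_protocol):
        params = replace(wt_params(), noise_sd_mV=0.0, noise_sd_pA=0.0)
        rheos = []
        for thr in (-45.0, -35.0):
            sweeps, _ = simulate_current_clamp(
                replace(params, spike_threshold=thr), short_cc_protocol, seed=0
            )
            rec = CellRecording(
                cell_id="c", genotype="WT", treatment="vehicle",
                condition="from_rest", resting_potential=params.v_rest,
                sweeps={"current_steps": list(sweeps)},
                protocols={"current_steps": short_cc_protocol},
            )
            rb = rheobase_features(rec)
            rheos.append(rb.rheobase_current)
        assert rheos[0] < rheos[1]
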