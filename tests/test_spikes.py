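"""Spike detection, waveform geometry, rheobase aggregation, accommodation."""

from __future__ import annotations

import numpy as np
import pytest

from stepclamp.spikes import (
    ACCOM_LATE_RANGES,
    DetectorConfig,
    SpikeTrain,
    accommodation_summary,
    ap_threshold,
    ap_waveform,
    count_aps,
    delay_to_first_spike,
    detect_spikes,
    firing_indicator,
    firing_probability,
    fraction_summary,
    instantaneous_frequencies,
    measure_rheobase,
    measure_waveform,
    parametric_ap_trace,
)
from stepclamp.synthetic import NeuronParams, sample_params, simulate_cell, default_cohort_spec
from stepclamp.trace_io import StepProtocol, Sweep

from conftest import build_recording

FS = 10_000.0


def spiky_rec(protocol: StepProtocol, peaks_by_key: dict, baseline=-70.0):
    """Recording whose (amplitude, trial) sweeps carry parametric APs at the
    requested peak times (seconds from sweep start)."""
    def fn(amp, trial):
        peaks = peaks_by_key.get((amp, trial), [])
        return parametric_ap_trace(peaks, fs_hz=protocol.sampling_rate_hz,
                                   dur_s=protocol.total_s, baseline_mV=baseline)
    return build_recording(protocol, fn)


class TestDetector:
    def test_flat_trace_has_no_spikes(self):
        train = detect_spikes(np.full(5000, -70.0), FS)
        assert len(train) == 0

    def test_three_parametric_aps_found_at_construction_times(self):
        peaks = [0.05, 0.10, 0.20]
        v = parametric_ap_trace(peaks, dur_s=0.3)
        train = detect_spikes(v, FS)
        assert len(train) == 3
        assert np.allclose(train.peak_times(), peaks, atol=1e-4)
        for sp in train.spikes:
            assert sp.threshold_time_s < sp.peak_time_s
            assert sp.threshold_mV < sp.peak_mV

    def test_parametric_threshold_recovered(self):
        v = parametric_ap_trace([0.05], threshold_mV=-45.0)
        train = detect_spikes(v, FS)
        assert train.spikes[0].threshold_mV == pytest.approx(-45.0, abs=0.5)

    def test_count_matches_simulator_event_log(self, wt_cell_with_events):
        """Detector vs the integrator's own emitted spike markers, all sweeps."""
        rec, events = wt_cell_with_events
        for sweep in rec:
            train = detect_spikes(sweep)
            assert len(train) == len(events[(sweep.amplitude_pA, sweep.trial)]), (
                sweep.amplitude_pA, sweep.trial)

    def test_time_translation_invariance(self):
        v = parametric_ap_trace([0.10], dur_s=0.3)
        shifted = np.concatenate([np.full(1000, -70.0), v])  # +100 ms
        t1 = detect_spikes(v, FS).peak_times()
        t2 = detect_spikes(shifted, FS).peak_times()
        assert np.allclose(t2 - t1, 0.1, atol=1e-9)

    def test_voltage_offset_invariance_with_floor_disabled(self):
        cfg = DetectorConfig(peak_floor_mV=None)
        v = parametric_ap_trace([0.05, 0.15], dur_s=0.3)
        t1 = detect_spikes(v, FS, cfg)
        t2 = detect_spikes(v - 80.0, FS, cfg)
        assert len(t1) == len(t2) == 2
        assert np.allclose(t1.peak_times(), t2.peak_times())

    def test_adex_threshold_matches_rate_crossing_closed_form(self):
        """Detected threshold sits where dV/dt first reaches the detector
        rate: V ~ VT + DeltaT*ln(C*theta/(gL*DeltaT)), not at VT itself."""
        spec = default_cohort_spec(n_cells=10, seed=3)
        proto = StepProtocol(amplitudes_pA=(300.0,), n_trials=1)
        for i in range(10):
            p = sample_params(spec, "Wt-like", i)
            rec = simulate_cell(p, proto, seed=1)
            det = detect_spikes(rec.sweeps[0]).spikes[0].threshold_mV
            pred = p.VT_mV + p.DeltaT_mV * np.log(
                20.0 * p.C_pF / (p.gL_nS * p.DeltaT_mV))
            assert det == pytest.approx(pred, abs=2.5)
            assert det > p.VT_mV


class TestWaveform:
    def test_triangle_geometry(self):
        """Linear rise 0.5 ms / decay 1.0 ms from -45 to +35: amplitude 80,
        half-width 0.25 + 0.50 = 0.75 ms, rise 0.8*0.5 = 0.40 ms."""
        v = parametric_ap_trace([0.05], threshold_mV=-45.0, peak_mV=35.0,
                                rise_ms=0.5, decay_ms=1.0)
        train = detect_spikes(v, FS)
        wf = measure_waveform(v, FS, train.spikes[0])
        assert wf.amplitude_mV == pytest.approx(80.0, abs=1.0)
        assert wf.halfwidth_ms == pytest.approx(0.75, abs=0.1)
        assert wf.rise_ms == pytest.approx(0.40, abs=0.1)
        assert wf.decay_ms == pytest.approx(0.80, abs=0.1)

    def test_ahp_relative_to_threshold(self):
        # baseline above the trough, as for the depolarized membrane during a step
        v = parametric_ap_trace([0.05], threshold_mV=-45.0, trough_mV=-52.0,
                                baseline_mV=-50.0)
        train = detect_spikes(v, FS)
        wf = measure_waveform(v, FS, train.spikes[0])
        assert wf.ahp_mV == pytest.approx(7.0, abs=0.1)

    @pytest.mark.parametrize("rise,decay", [(0.3, 0.6), (0.5, 1.5)])
    def test_asymmetric_shapes_match_closed_form(self, rise, decay):
        thr, pk = -48.0, 30.0
        v = parametric_ap_trace([0.05], threshold_mV=thr, peak_mV=pk,
                                rise_ms=rise, decay_ms=decay)
        wf = measure_waveform(v, FS, detect_spikes(v, FS).spikes[0])
        # one sample period (0.1 ms) of slack on every timing metric
        assert wf.halfwidth_ms == pytest.approx(0.5 * (rise + decay), abs=0.1)
        assert wf.rise_ms == pytest.approx(0.8 * rise, abs=0.1)
        assert wf.decay_ms == pytest.approx(0.8 * decay, abs=0.1)


PROTO3 = StepProtocol(amplitudes_pA=(100.0, 200.0, 300.0, 400.0),
                      pre_step_s=0.1, step_dur_s=0.4, post_step_s=0.1,
                      n_trials=3)


class TestRheobase:
    def test_all_trials_agree(self):
        peaks = {(300.0, t): [0.15, 0.2] for t in (1, 2, 3)}
        peaks.update({(400.0, t): [0.15, 0.2, 0.25, 0.3, 0.35] for t in (1, 2, 3)})
        rec = spiky_rec(PROTO3, peaks)
        assert measure_rheobase(rec) == 300.0

    def test_mean_of_per_trial_minima(self):
        """Trials firing first at 200, 300, 300 pA give rheobase 266.7."""
        peaks = {(200.0, 1): [0.15], (300.0, 1): [0.15],
                 (300.0, 2): [0.15], (300.0, 3): [0.15]}
        rec = spiky_rec(PROTO3, peaks)
        assert measure_rheobase(rec) == pytest.approx(800.0 / 3.0, abs=1e-9)

    def test_silent_cell_is_nan(self):
        rec = spiky_rec(PROTO3, {})
        assert np.isnan(measure_rheobase(rec))


class TestCountsAndProbability:
    def test_silent_cell_all_zero(self):
        rec = spiky_rec(PROTO3, {})
        assert all(v == 0.0 for v in count_aps(rec).values())

    def test_trial_averaged_count(self):
        peaks = {(200.0, 1): [0.12, 0.15, 0.2, 0.3],
                 (200.0, 2): [0.12, 0.15, 0.2, 0.3, 0.35],
                 (200.0, 3): [0.12, 0.15, 0.2, 0.3, 0.35, 0.4]}
        rec = spiky_rec(PROTO3, peaks)
        assert count_aps(rec)[200.0] == pytest.approx(5.0)

    def test_counts_nondecreasing_with_amplitude_on_model_cell(
            self, wt_cell_with_events):
        rec, _ = wt_cell_with_events
        counts = count_aps(rec)
        amps = sorted(a for a in counts if a > 0)
        vals = [counts[a] for a in amps]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_majority_vs_any_trial_rule(self):
        rec1 = spiky_rec(PROTO3, {(100.0, 1): [0.15]})
        assert firing_indicator(rec1, 100.0, rule="majority") == 0
        assert firing_indicator(rec1, 100.0, rule="any") == 1
        rec2 = spiky_rec(PROTO3, {(100.0, 1): [0.15], (100.0, 2): [0.15]})
        assert firing_indicator(rec2, 100.0, rule="majority") == 1

    def test_group_fractions_from_tallies(self):
        k, n, pct = fraction_summary([1] * 9 + [0] * 13)
        assert (k, n) == (9, 22)
        assert pct == pytest.approx(40.909, abs=0.001)
        _, _, pct_tg = fraction_summary([1] * 9 + [0] * 4)
        assert pct_tg == pytest.approx(69.231, abs=0.001)
        assert fraction_summary([1, 1, 1])[2] == 100.0

    def test_firing_probability_over_recordings(self):
        recs = [spiky_rec(PROTO3, {(100.0, t): [0.15] for t in (1, 2, 3)}),
                spiky_rec(PROTO3, {})]
        ind, frac = firing_probability(recs, 100.0)
        assert ind == [1, 0] and frac == 0.5


class TestDelay:
    @pytest.mark.parametrize("delay", [0.150, 0.230])
    def test_constructed_delay(self, delay):
        peaks = {(200.0, t): [PROTO3.pre_step_s + delay] for t in (1, 2, 3)}
        rec = spiky_rec(PROTO3, peaks)
        assert delay_to_first_spike(rec, 200.0) == pytest.approx(delay, abs=2e-4)

    def test_silent_amplitude_is_nan(self):
        rec = spiky_rec(PROTO3, {(300.0, 1): [0.2]})
        assert np.isnan(delay_to_first_spike(rec, 100.0))

    def test_delay_decreases_with_amplitude_on_model_cell(self):
        p = NeuronParams()
        proto = StepProtocol(amplitudes_pA=(200.0, 300.0, 400.0), n_trials=1)
        rec = simulate_cell(p, proto, seed=0)
        d = [delay_to_first_spike(rec, a) for a in (200.0, 300.0, 400.0)]
        assert d[0] > d[1] > d[2]


class TestInstFreqAndAccommodation:
    def test_reciprocal_intervals(self):
        f = instantaneous_frequencies(np.array([0.0, 0.010, 0.030]))
        assert np.allclose(f, [100.0, 50.0])

    def test_periodic_train(self):
        t = np.arange(10) * 0.025
        assert np.allclose(instantaneous_frequencies(t), 40.0)

    def test_fewer_than_two_spikes_empty(self):
        assert instantaneous_frequencies(np.array([0.1])).size == 0

    def test_constant_frequency_late_mean(self):
        s = accommodation_summary(np.full(25, 100.0), (15, 20))
        assert s.late_mean_Hz == pytest.approx(100.0)
        assert (s.f1_Hz, s.f2_Hz, s.f3_Hz) == (100.0, 100.0, 100.0)

    def test_geometric_decay_matches_direct_summation(self):
        f = 100.0 * 0.9 ** np.arange(25)          # f_i = 100*0.9^(i-1)
        expect = float(np.mean(f[14:20]))          # direct summation oracle
        s = accommodation_summary(f, (15, 20))
        assert s.late_mean_Hz == pytest.approx(expect, abs=1e-12)
        assert s.late_mean_Hz == pytest.approx(17.866, abs=0.001)

    def test_short_train_has_missing_late_mean(self):
        f = instantaneous_frequencies(np.linspace(0, 0.5, 10))  # 9 intervals
        assert np.isnan(accommodation_summary(f, (15, 20)).late_mean_Hz)

    def test_adaptation_makes_first_interval_fastest(self, wt_cell_with_events):
        rec, events = wt_cell_with_events
        for amp in (200.0, 300.0):
            f = instantaneous_frequencies(events[(amp, 1)])
            assert f[0] > f[-1]


class TestFirstAPSelection:
    def test_threshold_and_relative_threshold(self):
        peaks = {(300.0, t): [0.15] for t in (1, 2, 3)}
        rec = spiky_rec(PROTO3, peaks)
        thr, rel = ap_threshold(rec, rmp_mV=-80.0)
        assert thr == pytest.approx(-45.0, abs=0.5)
        assert rel == pytest.approx(35.0, abs=0.5)

    def test_waveform_comes_from_rheobase_sweep(self):
        peaks = {(300.0, 1): [0.15], (400.0, 1): [0.15]}
        rec = spiky_rec(PROTO3, peaks)
        wf = ap_waveform(rec)
        assert wf is not None and wf.amplitude_mV == pytest.approx(80.0, abs=1.0)

    def test_silent_cell_yields_none(self):
        rec = spiky_rec(PROTO3, {})
        assert ap_waveform(rec) is None
        thr, rel = ap_threshold(rec, rmp_mV=-80.0)
        assert np.isnan(thr) and np.isnan(rel)
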