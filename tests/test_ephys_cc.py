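"""Tests for current-clamp analysis: RMP, spike detection, AP features,
rheobase, excitability classification and agonist scoring."""

import numpy as np
import pytest

from drgsens import ephys_cc as cc
from drgsens import synth
from drgsens.traces import (
    CURRENT_CLAMP,
    VOLTAGE_CLAMP,
    CurrentStepProtocol,
    MembraneTrace,
    ModeError,
    StimulusEpoch,
)

FS = 20_000.0


def flat_trace(mv=-60.0, duration_s=1.0, epochs=()):
    n = int(duration_s * FS)
    return MembraneTrace(np.full(n, mv), FS, CURRENT_CLAMP, list(epochs))


class TestMeasureRMP:
    def test_constant_trace_identity(self):
        assert cc.measure_rmp(flat_trace(-50.0), (0.0, 0.5)) == -50.0

    def test_noisy_trace_recovers_mean(self, rng):
        n = int(5 * FS)
        tr = MembraneTrace(-60.0 + rng.normal(0, 2.0, n), FS, CURRENT_CLAMP)
        se = 2.0 / np.sqrt(n)
        assert abs(cc.measure_rmp(tr, (0.0, 5.0)) + 60.0) < 5 * se

    def test_window_overlapping_stimulus_rejected(self):
        tr = flat_trace(epochs=[StimulusEpoch(0.2, 0.4, 100.0, "step")])
        with pytest.raises(cc.PreconditionError):
            cc.measure_rmp(tr, (0.1, 0.3))


class TestDetectSpikes:
    def test_flat_trace_has_no_spikes(self):
        assert cc.detect_spikes(flat_trace()) == []

    def test_voltage_clamp_trace_rejected(self):
        tr = MembraneTrace(np.zeros(100), FS, VOLTAGE_CLAMP)
        with pytest.raises(ModeError):
            cc.detect_spikes(tr)

    def test_planted_spikes_detected_at_exact_times(self):
        p = synth.EphysSimParams(noise_sd_mV=0.0, spontaneous_rate_hz=0.0)
        wave = p.spike_template.waveform(p.rmp_mV, FS)
        base = np.full(int(2 * FS), p.rmp_mV)
        onsets = [0.2, 0.8, 1.5]
        peak_offset = int(np.argmax(wave))
        for t in onsets:
            i = int(round(t * FS))
            base[i:i + wave.size] += wave
        tr = MembraneTrace(base, FS, CURRENT_CLAMP)
        events = cc.detect_spikes(tr)
        assert len(events) == 3
        for ev, onset in zip(events, onsets):
            true_peak = (int(round(onset * FS)) + peak_offset) / FS
            assert abs(ev.peak_time_s - true_peak) <= 1.0 / FS
            assert ev.threshold_crossing_time_s < ev.peak_time_s
            assert ev.trough_mV < ev.peak_mV

    def test_matches_crossing_oracle_on_noisy_sweeps(self):
        # independent oracle: upward crossings of the overshoot level
        # separated by at least the template refractory period
        def oracle(v, level, refractory_samples):
            ups = np.flatnonzero((v[:-1] < level) & (v[1:] >= level)) + 1
            kept = []
            for i in ups:
                if not kept or i - kept[-1] >= refractory_samples:
                    kept.append(i)
            return len(kept)

        tpl = synth.SpikeTemplate()
        refr = int(round(tpl.duration_ms / 1000.0 * FS))
        for seed in range(20):
            p = synth.EphysSimParams(
                spontaneous_rate_hz=2.0, noise_sd_mV=0.5, seed=seed)
            traces, _ = synth.simulate_current_clamp(p, duration_s=2.0)
            v = traces[0].samples
            assert len(cc.detect_spikes(traces[0])) == oracle(v, cc.OVERSHOOT_MV, refr)


class TestAPFeatures:
    def test_amplitude_from_rmp_arithmetic(self):
        p = synth.EphysSimParams(rmp_mV=-60.0,
                                 spike_template=synth.SpikeTemplate(peak_mV=40.0))
        wave = p.spike_template.waveform(-60.0, FS)
        base = np.full(int(0.5 * FS), -60.0)
        base[1000:1000 + wave.size] += wave
        tr = MembraneTrace(base, FS, CURRENT_CLAMP)
        spike = cc.detect_spikes(tr)[0]
        feats = cc.extract_ap_features(tr, spike, -60.0)
        assert feats.amplitude_mV == pytest.approx(100.0, abs=0.5)

    def test_triangular_spike_half_width_geometry(self):
        # symmetric triangle of 4-ms base rising from RMP: width at half
        # amplitude is 2 ms
        rmp = -60.0
        n_half = int(0.002 * FS)
        up = np.linspace(rmp, 40.0, n_half + 1)
        tri = np.concatenate([up, up[-2::-1]])
        base = np.full(int(0.2 * FS), rmp)
        base[1000:1000 + tri.size] = tri
        tr = MembraneTrace(base, FS, CURRENT_CLAMP)
        spike = cc.detect_spikes(tr)[0]
        feats = cc.extract_ap_features(tr, spike, rmp)
        assert feats.hpd_ms == pytest.approx(2.0, abs=2000.0 / FS)

    def test_hpd_matches_template_half_width(self):
        # generator template tuned to a 3.1-ms half-peak duration
        p = synth.EphysSimParams(noise_sd_mV=0.0, rheobase_pA=100.0)
        assert p.spike_template.half_width_ms(p.rmp_mV) == pytest.approx(3.1, abs=0.02)
        sweeps, _ = synth.simulate_current_clamp(p, protocol=CurrentStepProtocol())
        spike = cc.detect_spikes(sweeps[0])[0]
        feats = cc.extract_ap_features(sweeps[0], spike, p.rmp_mV)
        assert feats.hpd_ms == pytest.approx(
            p.spike_template.half_width_ms(p.rmp_mV), abs=1500.0 / FS)

    def test_ahp_amplitude_and_duration(self):
        p = synth.EphysSimParams(noise_sd_mV=0.0, rheobase_pA=100.0)
        sweeps, _ = synth.simulate_current_clamp(p, protocol=CurrentStepProtocol())
        spike = cc.detect_spikes(sweeps[0])[0]
        feats = cc.extract_ap_features(sweeps[0], spike, p.rmp_mV)
        assert feats.ahp_amplitude_mV == pytest.approx(
            p.spike_template.ahp_depth_mV, abs=0.3)
        assert feats.ahp_duration_ms > 0

    def test_truncated_spike_marks_features_unavailable(self):
        p = synth.EphysSimParams(noise_sd_mV=0.0)
        wave = p.spike_template.waveform(p.rmp_mV, FS)
        peak_offset = int(np.argmax(wave))
        # spike rises at the very end of the trace: peak present, AHP cut off
        n = int(0.1 * FS)
        base = np.full(n, p.rmp_mV)
        i0 = n - peak_offset - 5
        seg = wave[: n - i0]
        base[i0:] += seg
        tr = MembraneTrace(base, FS, CURRENT_CLAMP)
        events = cc.detect_spikes(tr)
        assert len(events) == 1
        feats = cc.extract_ap_features(tr, events[0], p.rmp_mV)
        assert np.isnan(feats.hpd_ms) or np.isnan(feats.ahp_duration_ms)

    def test_time_shift_invariance(self):
        # prepending quiet samples shifts event times but not features
        p = synth.EphysSimParams(noise_sd_mV=0.0)
        wave = p.spike_template.waveform(p.rmp_mV, FS)
        base = np.full(int(0.3 * FS), p.rmp_mV)
        base[2000:2000 + wave.size] += wave
        shifted = np.concatenate([np.full(4321, p.rmp_mV), base])
        f0 = cc.extract_ap_features(
            (t0 := MembraneTrace(base, FS, CURRENT_CLAMP)),
            cc.detect_spikes(t0)[0], p.rmp_mV)
        f1 = cc.extract_ap_features(
            (t1 := MembraneTrace(shifted, FS, CURRENT_CLAMP)),
            cc.detect_spikes(t1)[0], p.rmp_mV)
        assert f1.amplitude_mV == pytest.approx(f0.amplitude_mV, abs=1e-9)
        assert f1.hpd_ms == pytest.approx(f0.hpd_ms, abs=1e-9)
        assert f1.ahp_amplitude_mV == pytest.approx(f0.ahp_amplitude_mV, abs=1e-9)
        assert f1.ahp_duration_ms == pytest.approx(f0.ahp_duration_ms, abs=1e-9)


class TestRheobase:
    def test_planted_rheobase_snaps_to_grid(self):
        protocol = CurrentStepProtocol()
        p = synth.EphysSimParams(rheobase_pA=300.0, noise_sd_mV=0.5, seed=4)
        sweeps, _ = synth.simulate_current_clamp(p, protocol=protocol)
        res = cc.find_rheobase(sweeps)
        assert res.reached
        assert res.level_pA == pytest.approx(
            protocol.levels_pA[protocol.levels_pA >= 300.0][0])
        assert res.first_spike is not None

    def test_lowest_level_rheobase(self):
        p = synth.EphysSimParams(rheobase_pA=100.0, noise_sd_mV=0.5, seed=1)
        sweeps, _ = synth.simulate_current_clamp(p, protocol=CurrentStepProtocol())
        assert cc.find_rheobase(sweeps).level_pA == pytest.approx(100.0)

    def test_no_spikes_yields_sentinel(self):
        p = synth.EphysSimParams(rheobase_pA=5000.0, noise_sd_mV=0.0)
        sweeps, _ = synth.simulate_current_clamp(p, protocol=CurrentStepProtocol())
        res = cc.find_rheobase(sweeps)
        assert not res.reached and res.level_pA is None

    def test_monotone_adding_spike_to_lower_sweep(self):
        # planting a spike in a lower-current sweep can only lower rheobase
        protocol = CurrentStepProtocol()
        p = synth.EphysSimParams(rheobase_pA=500.0, noise_sd_mV=0.0)
        sweeps, _ = synth.simulate_current_clamp(p, protocol=protocol)
        before = cc.find_rheobase(sweeps).level_pA
        wave = p.spike_template.waveform(p.rmp_mV, FS)
        target = sweeps[2]  # level below planted rheobase
        i0 = target.index(target.epochs[0].start_s) + 50
        target.samples[i0:i0 + wave.size] += wave
        after = cc.find_rheobase(sweeps).level_pA
        assert after <= before
        assert after == pytest.approx(target.epochs[0].level)


class TestClassification:
    def test_flat_trace_not_spontaneous(self):
        assert cc.classify_spontaneous(flat_trace(-48.0, 2.0)) is False

    def test_single_planted_spike_is_spontaneous(self):
        p = synth.EphysSimParams(noise_sd_mV=0.0)
        wave = p.spike_template.waveform(p.rmp_mV, FS)
        base = np.full(int(2 * FS), p.rmp_mV)
        base[5000:5000 + wave.size] += wave
        assert cc.classify_spontaneous(MembraneTrace(base, FS, CURRENT_CLAMP)) is True

    def test_spontaneous_cohort_recovery(self):
        hits = 0
        n = 40
        for seed in range(n):
            planted = seed % 2 == 0  # planted 50% spontaneously active
            p = synth.EphysSimParams(
                spontaneous_rate_hz=0.5 if planted else 0.0,
                noise_sd_mV=0.5, seed=seed)
            traces, _ = synth.simulate_current_clamp(p, duration_s=30.0,
                                                     sampling_rate_hz=5000.0)
            hits += cc.classify_spontaneous(traces[0]) == planted
        assert hits >= n - 1  # rate 0.5 Hz over 30 s: miss probability ~ 0

    def test_multiple_firing_classification(self):
        single = synth.EphysSimParams(rheobase_pA=400.0, noise_sd_mV=0.5, seed=2)
        sweeps, _ = synth.simulate_current_clamp(single, protocol=CurrentStepProtocol())
        assert cc.classify_multiple_firing(sweeps) is False
        multi = synth.EphysSimParams(
            rheobase_pA=400.0, noise_sd_mV=0.5, evoked_spikes_per_step=4, seed=2)
        sweeps, _ = synth.simulate_current_clamp(multi, protocol=CurrentStepProtocol())
        assert cc.classify_multiple_firing(sweeps) is True


class TestAgonistResponse:
    def _pair(self, responder, seed=0, rate=0.0):
        p = synth.EphysSimParams(spontaneous_rate_hz=rate, noise_sd_mV=0.5, seed=seed)
        return synth.simulate_agonist_pair(p, responder, evoked_spikes=4)

    def test_delta_rate_arithmetic(self):
        base, ag = self._pair(True)
        res = cc.score_agonist_response(base, ag, "capsaicin_1uM")
        assert res.baseline_spike_count == 0
        assert res.agonist_spike_count == 4
        assert res.delta_spike_rate_hz == pytest.approx(0.4)
        assert res.above_baseline is True

    def test_tie_is_not_above_baseline(self):
        base, ag = self._pair(False)
        res = cc.score_agonist_response(base, ag, "capsaicin_1uM")
        assert res.delta_spike_rate_hz == 0.0
        assert res.above_baseline is False

    def test_mismatched_durations_rejected(self):
        base, _ = self._pair(True)
        short = MembraneTrace(base.samples[: base.n_samples // 2],
                              base.sampling_rate_hz, CURRENT_CLAMP)
        with pytest.raises(cc.PreconditionError):
            cc.score_agonist_response(base, short, "capsaicin_1uM")

    def test_cohort_recovery_of_planted_responders(self, rng):
        # planted 12/16 responders recovered exactly for quiescent neurons
        labels = synth.planted_labels(rng, 16, 0.75)
        above = 0
        for i, responder in enumerate(labels):
            base, ag = self._pair(bool(responder), seed=100 + i)
            above += cc.score_agonist_response(base, ag, "capsaicin_1uM").above_baseline
        assert above == 12
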