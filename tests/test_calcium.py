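"""Tests for the Ca2+-imaging ROI pipeline: background subtraction, KCl
normalisation, responder classification and exclusion accounting."""

import numpy as np
import pandas as pd
import pytest

from drgsens import calcium as ca
from drgsens import synth


def std_protocol(agonists=("capsaicin_1uM",)):
    return ca.PerfusionProtocol.standard(agonists=agonists)


def make_roi(values, roi_id="r0", background=False):
    return ca.ROITimeSeries(roi_id=roi_id, values=np.asarray(values, float),
                            is_background=background)


class TestSubtractBackground:
    def test_background_equal_to_roi_zeroes_series(self):
        roi = make_roi(np.arange(10.0))
        bg = make_roi(np.arange(10.0), "bg", background=True)
        assert np.all(ca.subtract_background(roi, bg).values == 0.0)

    def test_zero_background_is_identity(self):
        roi = make_roi(np.arange(10.0))
        out = ca.subtract_background(roi, make_roi(np.zeros(10)))
        assert np.array_equal(out.values, roi.values)

    def test_constant_background_shifts_series(self):
        roi = make_roi(np.arange(10.0))
        out = ca.subtract_background(roi, make_roi(np.full(10, 3.0)))
        assert np.array_equal(out.values, np.arange(10.0) - 3.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ca.AlignmentError):
            ca.subtract_background(make_roi(np.zeros(10)), make_roi(np.zeros(9)))


class TestSelectKClPositive:
    def test_flat_roi_excluded_and_transient_retained(self):
        protocol = std_protocol()
        n = int(protocol.duration_s) + 1
        flat = make_roi(np.zeros(n), "flat")
        rng = np.random.default_rng(0)
        noisy = rng.normal(0, 1.0, n)
        kcl = protocol.kcl_event
        i0 = int(kcl.onset_s)
        responding = noisy.copy()
        responding[i0:i0 + 10] += 20.0  # 20x noise excursion
        kept = ca.select_kcl_positive(
            [flat, make_roi(responding, "resp")], protocol)
        assert [r.roi_id for r in kept] == ["resp"]

    def test_simulated_dish_fully_retained(self):
        cp = synth.CalciumSimParams(n_rois=30, responder_fraction=0.5, seed=3)
        rois, _ = synth.simulate_calcium(cp)
        bg = next(r for r in rois if r.is_background)
        cells = [ca.subtract_background(r, bg) for r in rois if not r.is_background]
        kept = ca.select_kcl_positive(cells, cp.protocol)
        assert len(kept) == 30


class TestComputeResponse:
    def _roi_with_transients(self, protocol, agonist_amp, kcl_amp, latency_s=5):
        n = int(protocol.duration_s) + 1
        v = np.zeros(n)
        ev = protocol.agonist_events[0]
        kcl = protocol.kcl_event
        v[int(ev.onset_s) + latency_s] = agonist_amp
        v[int(kcl.onset_s) + 5] = kcl_amp
        return make_roi(v)

    def test_half_kcl_transient_gives_half_dff(self):
        protocol = std_protocol()
        roi = self._roi_with_transients(protocol, 25.0, 50.0)
        resp = ca.compute_response(roi, protocol, protocol.agonist_events[0])
        assert resp.dff_max == pytest.approx(0.5)
        assert resp.peak_latency_s == pytest.approx(5.0)

    def test_flat_event_gives_zero_dff(self):
        protocol = std_protocol()
        roi = self._roi_with_transients(protocol, 0.0, 50.0)
        resp = ca.compute_response(roi, protocol, protocol.agonist_events[0])
        assert resp.dff_max == pytest.approx(0.0)

    def test_kcl_negative_roi_excluded(self):
        protocol = std_protocol()
        roi = make_roi(np.zeros(int(protocol.duration_s) + 1))
        resp = ca.compute_response(roi, protocol, protocol.agonist_events[0])
        assert resp.exclusion_reason == "kcl_negative"
        assert ca.classify_responder(resp).responder is False

    def test_kcl_event_self_normalises_to_unity(self):
        cp = synth.CalciumSimParams(n_rois=5, responder_fraction=1.0, seed=8)
        rois, _ = synth.simulate_calcium(cp)
        bg = next(r for r in rois if r.is_background)
        for roi in rois:
            if roi.is_background:
                continue
            sub = ca.subtract_background(roi, bg)
            resp = ca.compute_response(sub, cp.protocol, cp.protocol.kcl_event)
            assert resp.dff_max == pytest.approx(1.0)

    def test_generator_amplitude_recovered(self):
        cp = synth.CalciumSimParams(n_rois=20, responder_fraction=1.0,
                                    amplitude_rel_kcl=0.3, seed=4)
        rois, _ = synth.simulate_calcium(cp)
        bg = next(r for r in rois if r.is_background)
        for roi in rois:
            if roi.is_background:
                continue
            sub = ca.subtract_background(roi, bg)
            resp = ca.compute_response(sub, cp.protocol, cp.protocol.agonist_events[0])
            assert resp.dff_max == pytest.approx(0.3, abs=0.01)


class TestClassifyResponder:
    def _resp(self, dff, latency):
        return ca.CalciumResponse(roi_id="r", agonist="capsaicin_1uM",
                                  dff_max=dff, peak_latency_s=latency,
                                  responder=False, exclusion_reason="none")

    @pytest.mark.parametrize(
        "dff, latency, responder, reason",
        [
            (0.0005, 5.0, False, "below_threshold"),
            (0.4, 35.0, False, "late_peak"),
            (0.001, 5.0, True, "none"),     # threshold boundary kept
            (0.4, 30.0, True, "none"),      # latency boundary kept
            (0.4, 30.0001, False, "late_peak"),
            (0.0009999, 5.0, False, "below_threshold"),
        ],
    )
    def test_rule_boundaries(self, dff, latency, responder, reason):
        out = ca.classify_responder(self._resp(dff, latency))
        assert out.responder is responder
        assert out.exclusion_reason == reason


class TestDishPipeline:
    def test_scale_invariance_of_calls(self):
        cp = synth.CalciumSimParams(n_rois=20, responder_fraction=0.5, seed=6)
        rois, _ = synth.simulate_calcium(cp)
        bg = next(r for r in rois if r.is_background)
        cells = [r for r in rois if not r.is_background]
        base = ca.analyze_dish(cells, bg, cp.protocol)
        scaled_cells = [
            ca.ROITimeSeries(r.roi_id, r.values * 3.7, frame_rate_hz=r.frame_rate_hz)
            for r in cells
        ]
        scaled_bg = ca.ROITimeSeries("bg", bg.values * 3.7, is_background=True)
        scaled = ca.analyze_dish(scaled_cells, scaled_bg, cp.protocol)
        assert list(base["responder"]) == list(scaled["responder"])
        assert np.allclose(base["dff_max"], scaled["dff_max"])

    def test_exclusion_accounting_conserves_rois(self):
        cp = synth.CalciumSimParams(n_rois=40, responder_fraction=0.3, seed=7)
        rois, _ = synth.simulate_calcium(cp)
        bg = next(r for r in rois if r.is_background)
        cells = [ca.subtract_background(r, bg) for r in rois if not r.is_background]
        retained = ca.select_kcl_positive(cells, cp.protocol)
        excluded = len(cells) - len(retained)
        responses = ca.analyze_dish(
            [r for r in rois if not r.is_background], bg, cp.protocol)
        # every retained ROI classified exactly once per agonist event
        assert len(responses) == len(retained) * len(cp.protocol.agonist_events)
        assert excluded + len(retained) == 40
        responders = responses["responder"].sum()
        nonresponders = (~responses["responder"]).sum()
        assert responders + nonresponders == len(responses)

    def test_planted_responders_recovered_exactly(self):
        cp = synth.CalciumSimParams(
            n_rois=109, responder_fraction=48 / 109, seed=9,
            protocol=ca.PerfusionProtocol.standard(("capsaicin_1uM",)))
        rois, truth = synth.simulate_calcium(cp)
        bg = next(r for r in rois if r.is_background)
        responses = ca.analyze_dish(
            [r for r in rois if not r.is_background], bg, cp.protocol)
        assert responses["responder"].sum() == 48


class TestSummarize:
    def test_reported_fractions(self):
        df = pd.DataFrame({
            "side": ["Ctrl"] * 141 + ["OD"] * 109,
            "agonist": "capsaicin_1uM",
            "responder": [True] * 35 + [False] * 106 + [True] * 48 + [False] * 61,
        })
        out = ca.summarize_proportions(df).set_index("side")
        assert out.loc["Ctrl", "fraction"] == pytest.approx(0.248, abs=5e-4)
        assert out.loc["OD", "fraction"] == pytest.approx(48 / 109)

    def test_zero_responders(self):
        df = pd.DataFrame({"side": ["Ctrl"] * 10, "agonist": "a", "responder": False})
        out = ca.summarize_proportions(df)
        assert out["fraction"].iloc[0] == 0.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            ca.summarize_proportions(pd.DataFrame(columns=["side", "agonist", "responder"]))
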