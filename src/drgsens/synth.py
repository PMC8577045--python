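"""Ground-truth-labelled synthetic data for every pipeline stage.

Current-clamp sweeps use a template action potential (piecewise-exponential
rise and fall plus an afterhyperpolarization undershoot) inserted into a
flat resting potential with optional Gaussian noise — sufficient to exercise
every analysis operator without a biophysical membrane model.  Voltage-clamp
sweeps carry a transient inward and a delayed sustained outward component
whose peak amplitudes follow generating Boltzmann activation curves, plus a
constant offset ("leak") that the 100-ms baseline subtraction removes
exactly.  Ca2+ ROI series are baselines with agonist/KCl transients under
the standard perfusion timing; IHC tables are two-component gray-value
mixtures with planted positive fractions.

All randomness flows from one ``numpy.random.Generator`` seeded per call;
identical parameters and seed give bit-identical outputs.  Planted labels
use exact rounded counts (``round(fraction * n)``, shuffled) so recovered
proportions are exactly the planted ones up to classification error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calcium import (
    ABMEATP,
    CAPSAICIN,
    KCL,
    CalciumProtocolError,
    PerfusionProtocol,
    ROITimeSeries,
)
from .traces import (
    CURRENT_CLAMP,
    VOLTAGE_CLAMP,
    CurrentStepProtocol,
    MembraneTrace,
    StimulusEpoch,
    VoltageStepProtocol,
)

DEFAULT_EPHYS_FS_HZ = 20_000.0   # ephys sampling rate
DEFAULT_CALCIUM_FS_HZ = 1.0      # imaging frame rate


class SimulationParameterError(ValueError):
    pass


# --------------------------------------------------------------------------
# distribution specs

@dataclass(frozen=True)
class ConstantSpec:
    value: float

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return np.full(size, self.value, dtype=float)

    def quantile(self, q: float) -> float:
        return self.value


@dataclass(frozen=True)
class NormalSpec:
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise SimulationParameterError("sd must be nonnegative")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return rng.normal(self.mean, self.sd, size)

    def quantile(self, q: float) -> float:
        from scipy.special import ndtri
        return self.mean + self.sd * float(ndtri(q))


@dataclass(frozen=True)
class UniformSpec:
    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.high >= self.low:
            raise SimulationParameterError("high must be >= low")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return rng.uniform(self.low, self.high, size)

    def quantile(self, q: float) -> float:
        return self.low + q * (self.high - self.low)


@dataclass(frozen=True)
class LogNormalSpec:
    """Parameterised by the median and the log-space sigma."""

    median: float
    sigma: float

    def __post_init__(self) -> None:
        if self.median <= 0 or self.sigma < 0:
            raise SimulationParameterError("median must be positive, sigma nonnegative")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return rng.lognormal(math.log(self.median), self.sigma, size)

    def quantile(self, q: float) -> float:
        from scipy.special import ndtri
        return float(math.exp(math.log(self.median) + self.sigma * float(ndtri(q))))


def as_spec(x):
    if hasattr(x, "sample"):
        return x
    return ConstantSpec(float(x))


# --------------------------------------------------------------------------
# spike template

@dataclass(frozen=True)
class SpikeTemplate:
    """Template AP waveform: exponential rise to the peak, exponential fall
    into the AHP undershoot, exponential recovery back to rest.

    Segment time constants are one third of the segment duration, and each
    segment is normalised to hit its endpoint exactly, so the waveform is
    continuous and reaches ``peak_mV`` at ``rise_ms`` and the AHP floor at
    ``rise_ms + fall_ms``.
    """

    rise_ms: float = 2.0
    fall_ms: float = 8.5
    peak_mV: float = 53.3
    ahp_depth_mV: float = 14.0
    ahp_recovery_ms: float = 10.0

    def __post_init__(self) -> None:
        for name in ("rise_ms", "fall_ms", "ahp_recovery_ms"):
            if not getattr(self, name) > 0:
                raise SimulationParameterError(f"{name} must be positive")
        if self.ahp_depth_mV < 0:
            raise SimulationParameterError("ahp_depth_mV must be nonnegative")

    @property
    def duration_ms(self) -> float:
        return self.rise_ms + self.fall_ms + self.ahp_recovery_ms

    def waveform(self, rmp_mV: float, sampling_rate_hz: float) -> np.ndarray:
        """Deviation from RMP, sampled from spike onset to full recovery."""
        if self.peak_mV <= rmp_mV:
            raise SimulationParameterError("peak_mV must exceed rmp_mV")
        amp = self.peak_mV - rmp_mV
        depth = self.ahp_depth_mV
        n = int(round(self.duration_ms / 1000.0 * sampling_rate_hz)) + 1
        t = np.arange(n) / sampling_rate_hz * 1000.0  # ms from onset
        out = np.zeros(n)
        norm = 1.0 - math.exp(-3.0)

        rise = t < self.rise_ms
        tau_r = self.rise_ms / 3.0
        out[rise] = amp * (1.0 - np.exp(-t[rise] / tau_r)) / norm

        fall = (t >= self.rise_ms) & (t < self.rise_ms + self.fall_ms)
        u = t[fall] - self.rise_ms
        tau_f = self.fall_ms / 3.0
        out[fall] = -depth + (amp + depth) * (np.exp(-u / tau_f) - math.exp(-3.0)) / norm

        rec = t >= self.rise_ms + self.fall_ms
        w = t[rec] - self.rise_ms - self.fall_ms
        tau_a = self.ahp_recovery_ms / 3.0
        out[rec] = -depth * (np.exp(-w / tau_a) - math.exp(-3.0)) / norm
        return out

    def half_width_ms(self, rmp_mV: float, resolution_hz: float = 1e6) -> float:
        """Numeric width of the template at RMP + amplitude/2."""
        wave = self.waveform(rmp_mV, resolution_hz)
        half = (self.peak_mV - rmp_mV) / 2.0
        above = np.flatnonzero(wave >= half)
        return (above[-1] - above[0] + 1) / resolution_hz * 1000.0


# --------------------------------------------------------------------------
# current clamp

@dataclass(frozen=True)
class EphysSimParams:
    """Ground truth for one simulated neuron's current-clamp behaviour."""

    rmp_mV: float = -48.3
    spike_template: SpikeTemplate = field(default_factory=SpikeTemplate)
    spontaneous_rate_hz: float = 0.0
    rheobase_pA: float = 100.0
    noise_sd_mV: float = 0.0
    capacitance_pF: float = 71.0
    evoked_spikes_per_step: int = 1
    evoked_latency_ms: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spike_template.peak_mV <= self.rmp_mV:
            raise SimulationParameterError("spike peak must exceed RMP")
        if self.spontaneous_rate_hz < 0:
            raise SimulationParameterError("spontaneous_rate_hz must be >= 0")
        if not self.rheobase_pA > 0:
            raise SimulationParameterError("rheobase_pA must be positive")
        if self.noise_sd_mV < 0:
            raise SimulationParameterError("noise_sd_mV must be >= 0")
        if not self.capacitance_pF > 0:
            raise SimulationParameterError("capacitance_pF must be positive")
        if self.evoked_spikes_per_step < 1:
            raise SimulationParameterError("evoked_spikes_per_step must be >= 1")


def _insert_spikes(
    base: np.ndarray,
    onsets_s: Sequence[float],
    wave: np.ndarray,
    fs: float,
    peak_offset: int,
) -> list[float]:
    """Add the template at each onset; return the peak times actually emitted
    (spikes whose peak would fall outside the trace are dropped)."""
    peak_times = []
    for t in onsets_s:
        i0 = int(round(t * fs))
        if i0 < 0 or i0 + peak_offset >= base.size:
            continue
        i1 = min(base.size, i0 + wave.size)
        base[i0:i1] += wave[: i1 - i0]
        peak_times.append((i0 + peak_offset) / fs)
    return peak_times


def _spontaneous_onsets(
    rng: np.random.Generator,
    rate_hz: float,
    duration_s: float,
    refractory_s: float,
) -> list[float]:
    """Renewal process: inter-event interval = absolute refractory plus an
    exponential with the stated rate (mean count ~ T / (refractory + 1/rate))."""
    if rate_hz <= 0:
        return []
    onsets = []
    t = float(rng.exponential(1.0 / rate_hz))
    while t < duration_s:
        onsets.append(t)
        t += refractory_s + float(rng.exponential(1.0 / rate_hz))
    return onsets


def simulate_current_clamp(
    params: EphysSimParams,
    protocol: CurrentStepProtocol | None = None,
    duration_s: float = 10.0,
    sampling_rate_hz: float = DEFAULT_EPHYS_FS_HZ,
    rng: np.random.Generator | None = None,
    metadata: dict | None = None,
) -> tuple[list[MembraneTrace], list[np.ndarray]]:
    """Simulate current-clamp sweeps with ground-truth spike times.

    With a :class:`CurrentStepProtocol`, one sweep per injection level is
    produced (20-ms pre, the 80-ms step, 100-ms post); levels at or above the
    neuron's rheobase evoke ``evoked_spikes_per_step`` spikes spread through
    the step.  Without a protocol, a single zero-injection recording of
    ``duration_s`` is produced whose spontaneous spikes follow a Poisson-like
    renewal process with an absolute refractory equal to the template
    duration.

    Returns the sweeps and, aligned with them, arrays of ground-truth spike
    peak times (seconds).
    """
    if not sampling_rate_hz > 0:
        raise SimulationParameterError("sampling rate must be positive")
    rng = np.random.default_rng(params.seed) if rng is None else rng
    fs = sampling_rate_hz
    tpl = params.spike_template
    wave = tpl.waveform(params.rmp_mV, fs)
    peak_offset = int(np.argmax(wave))
    meta = dict(metadata or {})

    traces: list[MembraneTrace] = []
    truths: list[np.ndarray] = []
    if protocol is not None:
        pre_s, post_s = 0.020, 0.100
        step_s = protocol.step_duration_ms / 1000.0
        n = int(round((pre_s + step_s + post_s) * fs))
        for level in protocol.levels_pA:
            base = np.full(n, params.rmp_mV)
            onsets: list[float] = []
            if level >= params.rheobase_pA - 1e-9:
                k = params.evoked_spikes_per_step
                interval_ms = (protocol.step_duration_ms - tpl.rise_ms - params.evoked_latency_ms) / k
                onsets = [
                    pre_s + (params.evoked_latency_ms + j * interval_ms) / 1000.0
                    for j in range(k)
                ]
            peak_times = _insert_spikes(base, onsets, wave, fs, peak_offset)
            if params.noise_sd_mV > 0:
                base = base + rng.normal(0.0, params.noise_sd_mV, n)
            traces.append(MembraneTrace(
                samples=base, sampling_rate_hz=fs, mode=CURRENT_CLAMP,
                epochs=[StimulusEpoch(pre_s, pre_s + step_s, float(level), "step")],
                metadata=meta,
            ))
            truths.append(np.asarray(peak_times))
    else:
        n = int(round(duration_s * fs))
        base = np.full(n, params.rmp_mV)
        onsets = _spontaneous_onsets(
            rng, params.spontaneous_rate_hz, duration_s, tpl.duration_ms / 1000.0
        )
        peak_times = _insert_spikes(base, onsets, wave, fs, peak_offset)
        if params.noise_sd_mV > 0:
            base = base + rng.normal(0.0, params.noise_sd_mV, n)
        traces.append(MembraneTrace(
            samples=base, sampling_rate_hz=fs, mode=CURRENT_CLAMP,
            epochs=[], metadata=meta,
        ))
        truths.append(np.asarray(peak_times))
    return traces, truths


def simulate_agonist_pair(
    params: EphysSimParams,
    responder: bool,
    evoked_spikes: int = 4,
    application_s: float = 10.0,
    sampling_rate_hz: float = DEFAULT_EPHYS_FS_HZ,
    rng: np.random.Generator | None = None,
    metadata: dict | None = None,
) -> tuple[MembraneTrace, MembraneTrace]:
    """Baseline (pH 7.4 wash) and agonist-application traces for one neuron.

    Both are zero-injection recordings of ``application_s``; a responder's
    agonist trace carries ``evoked_spikes`` extra spikes spread through the
    application on top of any spontaneous activity.
    """
    rng = np.random.default_rng(params.seed) if rng is None else rng
    fs = sampling_rate_hz
    tpl = params.spike_template
    wave = tpl.waveform(params.rmp_mV, fs)
    peak_offset = int(np.argmax(wave))
    n = int(round(application_s * fs))
    meta = dict(metadata or {})
    refractory_s = tpl.duration_ms / 1000.0

    out = []
    for is_agonist in (False, True):
        base = np.full(n, params.rmp_mV)
        onsets = _spontaneous_onsets(rng, params.spontaneous_rate_hz, application_s, refractory_s)
        if is_agonist and responder:
            spacing = (application_s - 2 * refractory_s) / max(evoked_spikes, 1)
            onsets = sorted(onsets + [refractory_s + j * spacing for j in range(evoked_spikes)])
        _insert_spikes(base, onsets, wave, fs, peak_offset)
        if params.noise_sd_mV > 0:
            base = base + rng.normal(0.0, params.noise_sd_mV, n)
        out.append(MembraneTrace(
            samples=base, sampling_rate_hz=fs, mode=CURRENT_CLAMP, epochs=[],
            metadata=meta,
        ))
    return out[0], out[1]


def planted_labels(rng: np.random.Generator, n: int, fraction: float) -> np.ndarray:
    """Exactly round(fraction * n) True labels, randomly placed."""
    if not 0.0 <= fraction <= 1.0:
        raise SimulationParameterError("fraction must lie in [0, 1]")
    k = int(round(fraction * n))
    labels = np.zeros(n, dtype=bool)
    labels[:k] = True
    rng.shuffle(labels)
    return labels


# --------------------------------------------------------------------------
# voltage clamp

@dataclass(frozen=True)
class BoltzmannComponent:
    i_max_pA: float
    v_half_mV: float
    slope_k_mV: float

    def __post_init__(self) -> None:
        if self.slope_k_mV == 0:
            raise SimulationParameterError("slope k must be nonzero")

    def peak_pA(self, v: float) -> float:
        return self.i_max_pA / (1.0 + math.exp((self.v_half_mV - v) / self.slope_k_mV))


@dataclass(frozen=True)
class VCSimParams:
    """Generating model for voltage-clamp sweeps.

    ``leak_pA`` is a constant offset current (pipette/amplifier offset); it
    is identical at every potential and is removed exactly by the 100-ms
    baseline subtraction.
    """

    inward: BoltzmannComponent | None = BoltzmannComponent(-2000.0, -20.0, 6.0)
    outward: BoltzmannComponent | None = BoltzmannComponent(4000.0, 0.0, 12.0)
    leak_pA: float = 0.0
    inward_tau_ms: float = 1.0
    outward_tau_ms: float = 5.0
    noise_sd_pA: float = 0.0
    capacitance_pF: float = 71.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("inward_tau_ms", "outward_tau_ms"):
            if not getattr(self, name) > 0:
                raise SimulationParameterError(f"{name} must be positive")
        if self.noise_sd_pA < 0:
            raise SimulationParameterError("noise_sd_pA must be >= 0")
        if not self.capacitance_pF > 0:
            raise SimulationParameterError("capacitance_pF must be positive")


def simulate_voltage_clamp(
    params: VCSimParams,
    protocol: VoltageStepProtocol | None = None,
    sampling_rate_hz: float = DEFAULT_EPHYS_FS_HZ,
    rng: np.random.Generator | None = None,
    metadata: dict | None = None,
) -> tuple[list[MembraneTrace], dict]:
    """Simulate voltage-clamp sweeps (current in pA) and return ground truth.

    The inward component is a fast alpha-function transient (unit peak at
    ``inward_tau_ms``); the outward component activates with a delayed
    sigmoidal (1 - exp(-t/tau))^4 time course, so the within-step minimum and
    maximum recover the generating Boltzmann peak amplitudes to well under a
    percent.  Ground truth holds the generating components in density units
    (pA/pF).
    """
    protocol = protocol or VoltageStepProtocol()
    rng = np.random.default_rng(params.seed) if rng is None else rng
    fs = sampling_rate_hz
    pre_s = protocol.pre_ms / 1000.0
    test_s = protocol.test_ms / 1000.0
    post_s = protocol.inter_ms / 1000.0
    n = int(round((pre_s + test_s + post_s) * fs))
    i_pre, i_test = int(round(pre_s * fs)), int(round((pre_s + test_s) * fs))
    t_test_ms = (np.arange(i_test - i_pre) / fs) * 1000.0

    alpha = (t_test_ms / params.inward_tau_ms) * np.exp(1.0 - t_test_ms / params.inward_tau_ms)
    alpha[0] = 0.0
    sigmoid = (1.0 - np.exp(-t_test_ms / params.outward_tau_ms)) ** 4

    traces = []
    for level in protocol.test_levels_mV:
        samples = np.full(n, params.leak_pA)
        active = np.zeros(i_test - i_pre)
        if params.inward is not None:
            active += params.inward.peak_pA(float(level)) * alpha
        if params.outward is not None:
            active += params.outward.peak_pA(float(level)) * sigmoid
        samples[i_pre:i_test] += active
        if params.noise_sd_pA > 0:
            samples = samples + rng.normal(0.0, params.noise_sd_pA, n)
        traces.append(MembraneTrace(
            samples=samples, sampling_rate_hz=fs, mode=VOLTAGE_CLAMP,
            epochs=[
                StimulusEpoch(0.0, pre_s, protocol.pre_mV, "pre"),
                StimulusEpoch(pre_s, pre_s + test_s, float(level), "test"),
                StimulusEpoch(pre_s + test_s, pre_s + test_s + post_s, protocol.hold_mV, "post"),
            ],
            metadata=dict(metadata or {}),
        ))

    cap = params.capacitance_pF
    truth = {"capacitance_pF": cap, "leak_pA": params.leak_pA}
    for name, comp in (("inward", params.inward), ("outward", params.outward)):
        if comp is not None:
            truth[name] = {
                "i_max_pA_per_pF": comp.i_max_pA / cap,
                "v_half_mV": comp.v_half_mV,
                "slope_k_mV": comp.slope_k_mV,
            }
    return traces, truth


# --------------------------------------------------------------------------
# calcium imaging

@dataclass(frozen=True)
class CalciumSimParams:
    """Generating model for one imaging dish.

    ``responder_fraction`` maps agonist name to the planted responder
    fraction (a bare float applies to every agonist); ``amplitude_rel_kcl``
    is the responders' transient amplitude relative to the KCl transient
    (constant or distribution over (0, 1]).
    """

    n_rois: int = 100
    responder_fraction: Mapping[str, float] | float = 0.3
    amplitude_rel_kcl: object = 0.5
    tau_rise_s: float = 2.0
    tau_decay_s: float = 10.0
    baseline_drift_per_s: float = 0.0
    # mean-gray noise; small relative to kcl_amplitude so that instrument
    # noise stays below the 0.001 dF/Fmax exclusion threshold, as the rule's
    # usability on real traces presumes
    noise_sd: float = 0.005
    kcl_amplitude: float = 50.0
    baseline_level: float = 100.0
    background_level: float = 20.0
    protocol: PerfusionProtocol = field(default_factory=PerfusionProtocol.standard)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rois < 1:
            raise SimulationParameterError("n_rois must be >= 1")
        if not self.kcl_amplitude > 0:
            raise SimulationParameterError("kcl_amplitude must be positive")
        if self.noise_sd < 0:
            raise SimulationParameterError("noise_sd must be >= 0")
        for name in ("tau_rise_s", "tau_decay_s"):
            if not getattr(self, name) > 0:
                raise SimulationParameterError(f"{name} must be positive")
        fracs = self.fraction_for
        for ev in self.protocol.agonist_events:
            f = fracs(ev.agonist)
            if not 0.0 <= f <= 1.0:
                raise SimulationParameterError("responder fractions must lie in [0, 1]")

    def fraction_for(self, agonist: str) -> float:
        if isinstance(self.responder_fraction, Mapping):
            return float(self.responder_fraction.get(agonist, 0.0))
        return float(self.responder_fraction)


def _transient_kernel(tau_rise_s: float, tau_decay_s: float, fs: float) -> np.ndarray:
    """(1 - exp(-t/tr)) * exp(-t/td), normalised to unit peak."""
    t = np.arange(0.0, 6.0 * tau_decay_s + tau_rise_s, 1.0 / fs)
    k = (1.0 - np.exp(-t / tau_rise_s)) * np.exp(-t / tau_decay_s)
    peak = float(np.max(k))
    if peak <= 0:
        raise SimulationParameterError("degenerate transient kernel")
    return k / peak


def simulate_calcium(
    params: CalciumSimParams,
    rng: np.random.Generator | None = None,
    metadata: dict | None = None,
) -> tuple[list[ROITimeSeries], pd.DataFrame]:
    """Simulate a dish of ROI series plus one background ROI.

    Every cell ROI responds to the terminal KCl application; planted
    responders additionally carry an agonist transient starting at the
    application onset (peaking a few seconds later, well inside the 30-s
    acceptance window).  Returns the ROI list (background included, flagged)
    and a ground-truth table (roi_id, agonist, responder, amplitude_rel).
    """
    if params.protocol.events[-1].agonist != KCL:
        raise CalciumProtocolError("protocol must end with the KCl application")
    rng = np.random.default_rng(params.seed) if rng is None else rng
    fs = DEFAULT_CALCIUM_FS_HZ
    n_frames = int(round(params.protocol.duration_s * fs)) + 1
    t = np.arange(n_frames) / fs
    kernel = _transient_kernel(params.tau_rise_s, params.tau_decay_s, fs)
    meta = dict(metadata or {})
    amp_spec = as_spec(params.amplitude_rel_kcl)

    background = np.full(n_frames, params.background_level)
    if params.noise_sd > 0:
        background = background + rng.normal(0.0, params.noise_sd, n_frames)

    agonists = [ev.agonist for ev in params.protocol.agonist_events]
    labels = {
        ag: planted_labels(rng, params.n_rois, params.fraction_for(ag)) for ag in agonists
    }
    amplitudes = {
        ag: np.clip(amp_spec.sample(rng, params.n_rois), 1e-3, 1.0) for ag in agonists
    }

    rois: list[ROITimeSeries] = []
    truth_rows = []
    for i in range(params.n_rois):
        values = background + params.baseline_level + params.baseline_drift_per_s * t
        for ev in params.protocol.events:
            i0 = int(round(ev.onset_s * fs))
            if ev.agonist == KCL:
                amp = params.kcl_amplitude
            elif labels[ev.agonist][i]:
                amp = amplitudes[ev.agonist][i] * params.kcl_amplitude
            else:
                continue
            i1 = min(n_frames, i0 + kernel.size)
            values[i0:i1] += amp * kernel[: i1 - i0]
        if params.noise_sd > 0:
            values = values + rng.normal(0.0, params.noise_sd, n_frames)
        roi_id = f"roi{i:04d}"
        rois.append(ROITimeSeries(
            roi_id=roi_id, values=values, is_background=False,
            frame_rate_hz=fs, metadata=dict(meta),
        ))
        for ag in agonists:
            truth_rows.append({
                "roi_id": roi_id,
                "agonist": ag,
                "responder": bool(labels[ag][i]),
                "amplitude_rel": float(amplitudes[ag][i]) if labels[ag][i] else 0.0,
            })
    rois.append(ROITimeSeries(
        roi_id="background", values=background, is_background=True,
        frame_rate_hz=fs, metadata=dict(meta),
    ))
    return rois, pd.DataFrame(truth_rows)


# --------------------------------------------------------------------------
# immunohistochemistry

@dataclass(frozen=True)
class IHCSimParams:
    """Two-component gray-value mixture over sections of a stained DRG.

    ``negative_gray`` is the between-section background-staining distribution.
    Section backgrounds are stratified draws from it — one per quantile bin,
    in shuffled order, plus a small ``background_jitter_sd`` — emulating the
    systematic staining/sectioning gradient across serial sections; negative
    neurons sit at their section's background plus a small within-section
    jitter (``within_section_sd``).  This is the structure the
    distribution-of-minima threshold presumes: the least-stained neuron per
    section estimates that section's background, and the spread of the minima
    reflects section-to-section staining variability, so the derived
    mean + 2 SD threshold clears every section's unstained population.
    Positive neurons draw independently from ``positive_gray``, which must be
    stochastically larger.
    """

    n_sections: int = 3
    neurons_per_section: int = 300
    positive_fraction: float = 0.3
    negative_gray: object = UniformSpec(20.0, 40.0)
    background_jitter_sd: float = 0.25
    within_section_sd: float = 0.25
    positive_gray: object = NormalSpec(120.0, 15.0)
    area_distribution: object = LogNormalSpec(700.0, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sections < 1 or self.neurons_per_section < 1:
            raise SimulationParameterError("need >= 1 section and >= 1 neuron per section")
        if not 0.0 <= self.positive_fraction <= 1.0:
            raise SimulationParameterError("positive_fraction must lie in [0, 1]")
        if self.within_section_sd < 0:
            raise SimulationParameterError("within_section_sd must be >= 0")


def simulate_ihc(
    params: IHCSimParams,
    rng: np.random.Generator | None = None,
    animal_id: str = "A1",
    side: str = "Ctrl",
    stain: str = "P2X3",
) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-neuron IHC records with ground-truth positivity labels.

    Each section plants exactly ``round(positive_fraction * neurons_per_
    section)`` positive neurons; negative neurons sit at the section's
    background level (one draw from ``negative_gray``) plus within-section
    jitter, positives draw from ``positive_gray``; gray values are clipped at
    zero, areas come from the area distribution.
    """
    rng = np.random.default_rng(params.seed) if rng is None else rng
    neg = as_spec(params.negative_gray)
    pos = as_spec(params.positive_gray)
    area = as_spec(params.area_distribution)

    qs = (np.arange(params.n_sections) + 0.5) / params.n_sections
    backgrounds = np.array([neg.quantile(float(q)) for q in qs])
    rng.shuffle(backgrounds)
    backgrounds = backgrounds + rng.normal(0.0, params.background_jitter_sd, backgrounds.size)

    rows = []
    all_labels = []
    for s in range(params.n_sections):
        m = params.neurons_per_section
        labels = planted_labels(rng, m, params.positive_fraction)
        negative_gray = backgrounds[s] + rng.normal(0.0, params.within_section_sd, m)
        gray = np.where(labels, pos.sample(rng, m), negative_gray)
        gray = np.clip(gray, 0.0, None)
        areas = np.clip(area.sample(rng, m), 1.0, None)
        for j in range(m):
            rows.append({
                "neuron_id": f"{animal_id}_{stain}_{side}_s{s}_n{j}",
                "section_id": f"{animal_id}_{stain}_{side}_s{s}",
                "animal_id": animal_id,
                "side": side,
                "stain": stain,
                "mean_gray": float(gray[j]),
                "area_um2": float(areas[j]),
            })
        all_labels.append(labels)
    return pd.DataFrame(rows), np.concatenate(all_labels)
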