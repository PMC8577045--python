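"""Current-clamp analysis: AP detection, feature extraction, excitability
classification and agonist-evoked response scoring.

Spike detection uses a Schmitt-trigger on membrane potential: an event fires
when the potential rises above the overshoot level (default -10 mV) having
previously been below a re-arm level, with a minimum inter-peak interval.
The AP threshold crossing is located with a dV/dt criterion (default 10 V/s).

Per-spike features follow the conventions for nociceptor recordings:
amplitude from resting membrane potential (RMP) to peak; half-peak duration
(HPD) as the spike width at RMP + amplitude/2; afterhyperpolarization (AHP)
amplitude as RMP minus the post-spike trough; AHP duration from the
post-spike downward RMP crossing until the potential recovers to within 80%
of the AHP depth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .traces import (
    CURRENT_CLAMP,
    CurrentStepProtocol,
    MembraneTrace,
    ModeError,
)

DVDT_THRESHOLD_V_PER_S = 10.0
OVERSHOOT_MV = -10.0
MIN_INTERVAL_MS = 2.0
REARM_BELOW_OVERSHOOT_MV = 5.0   # hysteresis: must dip this far below overshoot to re-arm
AHP_SEARCH_MS = 100.0            # trough searched this far past the peak
AHP_RECOVERY_FRACTION = 0.8      # recovered once within 80% of AHP depth of RMP


class PreconditionError(ValueError):
    pass


@dataclass(frozen=True)
class SpikeEvent:
    peak_time_s: float
    peak_mV: float
    threshold_crossing_time_s: float
    trough_mV: float
    trough_time_s: float


@dataclass(frozen=True)
class APFeatures:
    """Features of a single action potential; NaN marks a feature that could
    not be measured (e.g., spike truncated at the trace edge)."""

    amplitude_mV: float
    hpd_ms: float
    ahp_amplitude_mV: float
    ahp_duration_ms: float


@dataclass(frozen=True)
class AgonistResponse:
    agonist: str
    baseline_spike_count: int
    agonist_spike_count: int
    application_s: float
    delta_spike_rate_hz: float
    above_baseline: bool


@dataclass(frozen=True)
class RheobaseResult:
    """Lowest spiking step level; ``level_pA`` is None when no step evoked a
    spike ("not reached")."""

    level_pA: float | None
    sweep_index: int | None
    first_spike: SpikeEvent | None

    @property
    def reached(self) -> bool:
        return self.level_pA is not None


def measure_rmp(trace: MembraneTrace, window_s: tuple[float, float]) -> float:
    """Mean membrane potential over a zero-injection window."""
    t0, t1 = window_s
    if not t1 > t0:
        raise PreconditionError("window must have positive length")
    for ep in trace.epochs:
        if ep.level != 0.0 and ep.start_s < t1 and ep.end_s > t0:
            raise PreconditionError("RMP window overlaps a stimulus epoch")
    vals = trace.window(t0, t1)
    if vals.size == 0:
        raise PreconditionError("RMP window contains no samples")
    return float(np.mean(vals))


def detect_spikes(
    trace: MembraneTrace,
    dvdt_threshold_V_per_s: float = DVDT_THRESHOLD_V_PER_S,
    overshoot_mV: float = OVERSHOOT_MV,
    min_interval_ms: float = MIN_INTERVAL_MS,
) -> list[SpikeEvent]:
    """Detect action potentials in a current-clamp sweep.

    Events are time-ordered; each event's threshold crossing precedes its
    peak.  The trough is the minimum within ``AHP_SEARCH_MS`` after the peak
    (bounded by the next spike).
    """
    if trace.mode != CURRENT_CLAMP:
        raise ModeError("spike detection requires a current-clamp trace")
    v = trace.samples
    fs = trace.sampling_rate_hz
    n = v.size
    if n < 2:
        return []
    refractory = max(1, int(round(min_interval_ms * fs / 1000.0)))
    rearm_level = overshoot_mV - REARM_BELOW_OVERSHOOT_MV
    # dV/dt in V/s: mV per sample * samples per second / 1000
    dvdt = np.empty_like(v)
    dvdt[1:] = np.diff(v) * fs / 1000.0
    dvdt[0] = dvdt[1]

    peak_indices: list[int] = []
    armed = v[0] < rearm_level
    i = 1
    while i < n:
        if armed and v[i] >= overshoot_mV and v[i - 1] < overshoot_mV:
            # fire: peak is the max until v drops back below the re-arm level
            j = i
            while j < n and v[j] >= rearm_level:
                j += 1
            seg_end = j if j > i else i + 1
            peak = i + int(np.argmax(v[i:seg_end]))
            if not peak_indices or peak - peak_indices[-1] >= refractory:
                peak_indices.append(peak)
            armed = False
            i = seg_end
            continue
        if not armed and v[i] < rearm_level:
            armed = True
        i += 1

    events: list[SpikeEvent] = []
    for k, p in enumerate(peak_indices):
        # threshold crossing: last upward dV/dt crossing before the peak
        lookback = int(round(20e-3 * fs))
        lo = max(0, p - lookback)
        if k > 0:
            lo = max(lo, peak_indices[k - 1])
        seg = dvdt[lo: p + 1]
        cross = np.flatnonzero((seg[1:] >= dvdt_threshold_V_per_s) & (seg[:-1] < dvdt_threshold_V_per_s))
        thr_idx = lo + 1 + int(cross[-1]) if cross.size else lo
        if thr_idx >= p:
            thr_idx = max(lo, p - 1)
        hi = min(n, p + int(round(AHP_SEARCH_MS * fs / 1000.0)))
        if k + 1 < len(peak_indices):
            hi = min(hi, peak_indices[k + 1])
        trough = p + int(np.argmin(v[p:hi])) if hi > p else p
        events.append(SpikeEvent(
            peak_time_s=p / fs,
            peak_mV=float(v[p]),
            threshold_crossing_time_s=thr_idx / fs,
            trough_mV=float(v[trough]),
            trough_time_s=trough / fs,
        ))
    return events


def _interp_crossing(t0: float, v0: float, t1: float, v1: float, level: float) -> float:
    if v1 == v0:
        return t1
    return t0 + (level - v0) * (t1 - t0) / (v1 - v0)


def extract_ap_features(
    trace: MembraneTrace,
    spike: SpikeEvent,
    rmp_mV: float,
    amplitude_from: str = "rmp",
) -> APFeatures:
    """Measure amplitude, HPD, AHP amplitude and AHP duration for one spike.

    ``amplitude_from="threshold"`` measures amplitude from the threshold
    voltage instead of the RMP (the default matches reported magnitudes of
    roughly 100 mV for DRG neurons with RMP near -48 mV).
    """
    v = trace.samples
    fs = trace.sampling_rate_hz
    p = trace.index(spike.peak_time_s)
    p = min(p, v.size - 1)
    if amplitude_from == "threshold":
        ref = float(v[trace.index(spike.threshold_crossing_time_s)])
    elif amplitude_from == "rmp":
        ref = rmp_mV
    else:
        raise ValueError("amplitude_from must be 'rmp' or 'threshold'")
    amplitude = float(v[p]) - ref
    half = rmp_mV + (float(v[p]) - rmp_mV) / 2.0

    # half-peak duration: interpolated crossings of the half level either side
    hpd_ms = float("nan")
    left = None
    for i in range(p, 0, -1):
        if v[i - 1] < half <= v[i]:
            left = _interp_crossing((i - 1) / fs, v[i - 1], i / fs, v[i], half)
            break
    right = None
    for i in range(p, v.size - 1):
        if v[i] >= half > v[i + 1]:
            right = _interp_crossing(i / fs, v[i], (i + 1) / fs, v[i + 1], half)
            break
    if left is not None and right is not None:
        hpd_ms = (right - left) * 1000.0

    ahp_amplitude = rmp_mV - spike.trough_mV
    ahp_duration_ms = float("nan")
    if ahp_amplitude > 0:
        # downward RMP crossing after the peak
        tr = trace.index(spike.trough_time_s)
        down = None
        for i in range(p, tr + 1):
            if i + 1 < v.size and v[i] >= rmp_mV > v[i + 1]:
                down = _interp_crossing(i / fs, v[i], (i + 1) / fs, v[i + 1], rmp_mV)
                break
        recover_level = rmp_mV - (1.0 - AHP_RECOVERY_FRACTION) * ahp_amplitude
        up = None
        for i in range(tr, v.size - 1):
            if v[i] < recover_level <= v[i + 1]:
                up = _interp_crossing(i / fs, v[i], (i + 1) / fs, v[i + 1], recover_level)
                break
        if down is not None and up is not None:
            ahp_duration_ms = (up - down) * 1000.0
    return APFeatures(
        amplitude_mV=amplitude,
        hpd_ms=hpd_ms,
        ahp_amplitude_mV=ahp_amplitude,
        ahp_duration_ms=ahp_duration_ms,
    )


def _step_epoch(sweep: MembraneTrace):
    steps = [ep for ep in sweep.epochs if ep.level != 0.0]
    if len(steps) != 1:
        raise PreconditionError("sweep must carry exactly one current-step epoch")
    return steps[0]


def find_rheobase(
    sweeps: Sequence[MembraneTrace],
    **detect_kwargs,
) -> RheobaseResult:
    """Lowest injected current level whose step window contains a spike.

    The first spike of that sweep is designated for feature extraction.
    Returns a not-reached sentinel (``level_pA=None``) if no sweep spikes.
    """
    if not sweeps:
        raise PreconditionError("no sweeps given")
    order = sorted(range(len(sweeps)), key=lambda i: _step_epoch(sweeps[i]).level)
    for i in order:
        sweep = sweeps[i]
        step = _step_epoch(sweep)
        spikes = [
            s for s in detect_spikes(sweep, **detect_kwargs)
            if step.start_s <= s.peak_time_s < step.end_s
        ]
        if spikes:
            return RheobaseResult(level_pA=step.level, sweep_index=i, first_spike=spikes[0])
    return RheobaseResult(level_pA=None, sweep_index=None, first_spike=None)


def classify_spontaneous(trace: MembraneTrace, **detect_kwargs) -> bool:
    """True iff a zero-injection recording contains at least one spike."""
    for ep in trace.epochs:
        if ep.level != 0.0:
            raise PreconditionError("spontaneous-activity trace must have no current injection")
    return len(detect_spikes(trace, **detect_kwargs)) >= 1


def classify_multiple_firing(sweeps: Sequence[MembraneTrace], **detect_kwargs) -> bool:
    """True iff any current step evokes two or more spikes within its window."""
    for sweep in sweeps:
        step = _step_epoch(sweep)
        n = sum(
            step.start_s <= s.peak_time_s < step.end_s
            for s in detect_spikes(sweep, **detect_kwargs)
        )
        if n >= 2:
            return True
    return False


def score_agonist_response(
    baseline_trace: MembraneTrace,
    agonist_trace: MembraneTrace,
    agonist: str,
    application_s: float = 10.0,
    **detect_kwargs,
) -> AgonistResponse:
    """Delta spike rate: (agonist spikes - baseline spikes) / application time.

    The baseline trace is the pH 7.4 perfusion window immediately preceding
    the application; both traces must be zero-injection current clamp and of
    equal duration.
    """
    for tr in (baseline_trace, agonist_trace):
        if tr.mode != CURRENT_CLAMP:
            raise ModeError("agonist scoring requires current-clamp traces")
        for ep in tr.epochs:
            if ep.level != 0.0:
                raise PreconditionError("agonist scoring requires zero-injection traces")
    if abs(baseline_trace.duration_s - agonist_trace.duration_s) > 1.0 / baseline_trace.sampling_rate_hz:
        raise PreconditionError("baseline and agonist traces must have matching durations")
    nb = len(detect_spikes(baseline_trace, **detect_kwargs))
    na = len(detect_spikes(agonist_trace, **detect_kwargs))
    return AgonistResponse(
        agonist=agonist,
        baseline_spike_count=nb,
        agonist_spike_count=na,
        application_s=application_s,
        delta_spike_rate_hz=(na - nb) / application_s,
        above_baseline=na > nb,
    )
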