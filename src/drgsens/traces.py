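"""Membrane-trace containers and stimulus protocols.

A :class:`MembraneTrace` holds one sweep of membrane potential (current clamp,
mV) or membrane current (voltage clamp, pA) sampled at a fixed rate, together
with the stimulus epochs applied during the sweep and per-neuron metadata
(neuron, animal, side, weeks after the osteochondral defect).

Time is in seconds from the first sample; all windows are closed-open
``[start, end)`` on sample indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CURRENT_CLAMP = "current_clamp"
VOLTAGE_CLAMP = "voltage_clamp"

_EPS = 1e-9


class ProtocolError(ValueError):
    """A trace does not carry the stimulus epochs an operation requires."""


class ModeError(ValueError):
    """An operation received a trace recorded in the wrong clamp mode."""


@dataclass(frozen=True)
class StimulusEpoch:
    """One stimulus interval: injected current (pA) or command voltage (mV)."""

    start_s: float
    end_s: float
    level: float
    label: str = ""

    def __post_init__(self) -> None:
        if not (self.end_s > self.start_s >= 0.0):
            raise ValueError(
                f"epoch must satisfy end > start >= 0, got [{self.start_s}, {self.end_s})"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class MembraneTrace:
    """One recorded sweep.

    samples
        mV in current clamp, pA in voltage clamp.
    epochs
        Non-overlapping stimulus intervals inside the sweep. Regions not
        covered by any epoch are zero-injection (current clamp) or holding
        potential (voltage clamp).
    """

    samples: np.ndarray
    sampling_rate_hz: float
    mode: str = CURRENT_CLAMP
    epochs: list[StimulusEpoch] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if not self.sampling_rate_hz > 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.mode not in (CURRENT_CLAMP, VOLTAGE_CLAMP):
            raise ValueError(f"unknown mode {self.mode!r}")
        self.epochs = sorted(self.epochs, key=lambda e: e.start_s)
        prev_end = 0.0
        for ep in self.epochs:
            if ep.start_s < prev_end - _EPS:
                raise ValueError("epochs overlap")
            if ep.end_s > self.duration_s + _EPS:
                raise ValueError("epoch extends past end of trace")
            prev_end = ep.end_s

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sampling_rate_hz

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sampling_rate_hz

    def index(self, t_s: float) -> int:
        """Sample index of time ``t_s`` (nearest-sample rounding, clipped)."""
        i = int(round(t_s * self.sampling_rate_hz))
        return min(max(i, 0), self.samples.size)

    def window(self, start_s: float, end_s: float) -> np.ndarray:
        """Samples in the closed-open window ``[start_s, end_s)``."""
        return self.samples[self.index(start_s): self.index(end_s)]

    def epoch_by_label(self, label: str) -> StimulusEpoch:
        for ep in self.epochs:
            if ep.label == label:
                return ep
        raise ProtocolError(f"trace has no epoch labelled {label!r}")


@dataclass(frozen=True)
class CurrentStepProtocol:
    """Stepwise current injection: 20 steps of 80 ms from 100 to 1000 pA."""

    start_pA: float = 100.0
    stop_pA: float = 1000.0
    n_steps: int = 20
    step_duration_ms: float = 80.0
    holding_mV: float = -60.0

    def __post_init__(self) -> None:
        if self.n_steps < 2:
            raise ValueError("n_steps must be >= 2")
        if not self.stop_pA > self.start_pA:
            raise ValueError("stop_pA must exceed start_pA")
        if not self.step_duration_ms > 0:
            raise ValueError("step_duration_ms must be positive")

    @property
    def levels_pA(self) -> np.ndarray:
        """Evenly spaced injection levels, inclusive of both ends."""
        return np.linspace(self.start_pA, self.stop_pA, self.n_steps)


@dataclass(frozen=True)
class VoltageStepProtocol:
    """Voltage steps: hold -60, pre-pulse -120 mV for 240 ms, test steps
    -50..+40 mV in 10-mV increments for 40 ms, 200 ms between sweeps."""

    hold_mV: float = -60.0
    pre_mV: float = -120.0
    pre_ms: float = 240.0
    test_start_mV: float = -50.0
    test_stop_mV: float = 40.0
    test_step_mV: float = 10.0
    test_ms: float = 40.0
    inter_ms: float = 200.0

    def __post_init__(self) -> None:
        if not self.test_step_mV > 0:
            raise ValueError("test levels must be strictly increasing")
        if not self.test_stop_mV >= self.test_start_mV:
            raise ValueError("test_stop_mV must be >= test_start_mV")
        for name in ("pre_ms", "test_ms", "inter_ms"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")

    @property
    def test_levels_mV(self) -> np.ndarray:
        n = int(round((self.test_stop_mV - self.test_start_mV) / self.test_step_mV)) + 1
        return self.test_start_mV + self.test_step_mV * np.arange(n)
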