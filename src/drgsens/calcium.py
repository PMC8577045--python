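"""Fluo-4 Ca2+-imaging ROI pipeline.

ROI-level mean-gray time series (1 Hz) are background-subtracted, each
agonist response is normalised to the same cell's peak response to 50 mM KCl
(dF/Fmax), and ROIs are classified as responders with the exclusion rules:
dF/Fmax below 0.001, or a peak later than 30 s after application onset,
excludes the response.

Perfusion design per event: a 10-s wash precedes the 10-s agonist
application, followed by a 90-s wash; a 3-min interval separates events; the
protocol ends with one 50 mM KCl application serving as the positive control.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

KCL = "KCl_50mM"
CAPSAICIN = "capsaicin_1uM"
ABMEATP = "abmeATP_30uM"

RESPONDER_THRESHOLD = 0.001   # dF/Fmax below this is noise
MAX_PEAK_LATENCY_S = 30.0     # peaks later than this after onset are drift


class CalciumProtocolError(ValueError):
    pass


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class PerfusionEvent:
    agonist: str
    onset_s: float
    duration_s: float = 10.0

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass(frozen=True)
class PerfusionProtocol:
    """Ordered agonist applications with exactly one terminal KCl event."""

    events: tuple[PerfusionEvent, ...]
    wash_pre_s: float = 10.0
    wash_post_s: float = 90.0
    inter_event_gap_s: float = 180.0

    def __post_init__(self) -> None:
        if not self.events:
            raise CalciumProtocolError("protocol has no events")
        prev_end = -np.inf
        for ev in self.events:
            if ev.onset_s < prev_end:
                raise CalciumProtocolError("perfusion events overlap or are unordered")
            prev_end = ev.end_s
        n_kcl = sum(ev.agonist == KCL for ev in self.events)
        if n_kcl != 1:
            raise CalciumProtocolError(f"protocol must contain exactly one KCl event, got {n_kcl}")

    @property
    def kcl_event(self) -> PerfusionEvent:
        return next(ev for ev in self.events if ev.agonist == KCL)

    @property
    def agonist_events(self) -> tuple[PerfusionEvent, ...]:
        return tuple(ev for ev in self.events if ev.agonist != KCL)

    @property
    def duration_s(self) -> float:
        return self.events[-1].end_s + self.wash_post_s

    @classmethod
    def standard(cls, agonists: tuple[str, ...] = (CAPSAICIN, ABMEATP)) -> "PerfusionProtocol":
        """Agonists in order, then KCl; spacing per the perfusion design."""
        events = []
        onset = 30.0
        for ag in (*agonists, KCL):
            events.append(PerfusionEvent(agonist=ag, onset_s=onset))
            onset = onset + 10.0 + 90.0 + 180.0
        return cls(events=tuple(events))


@dataclass
class ROITimeSeries:
    """Mean gray value of one ROI per frame, sampled at ``frame_rate_hz``."""

    roi_id: str
    values: np.ndarray
    is_background: bool = False
    frame_rate_hz: float = 1.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if not self.frame_rate_hz > 0:
            raise ValueError("frame_rate_hz must be positive")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) / self.frame_rate_hz

    def index(self, t_s: float) -> int:
        i = int(round(t_s * self.frame_rate_hz))
        return min(max(i, 0), self.values.size)

    def window(self, start_s: float, end_s: float) -> np.ndarray:
        """Frames in the closed-open window [start_s, end_s)."""
        return self.values[self.index(start_s): self.index(end_s)]


@dataclass(frozen=True)
class CalciumResponse:
    roi_id: str
    agonist: str
    dff_max: float
    peak_latency_s: float
    responder: bool
    exclusion_reason: str = "none"  # none | below_threshold | late_peak | kcl_negative

    def __post_init__(self) -> None:
        if self.responder and self.exclusion_reason != "none":
            raise ValueError("responder implies no exclusion reason")


def subtract_background(roi: ROITimeSeries, background: ROITimeSeries) -> ROITimeSeries:
    """Framewise ROI minus background; negative values are permitted."""
    if roi.values.size != background.values.size:
        raise AlignmentError(
            f"length mismatch: ROI {roi.values.size} vs background {background.values.size}"
        )
    return replace(roi, values=roi.values - background.values)


def select_kcl_positive(
    rois: list[ROITimeSeries],
    protocol: PerfusionProtocol,
    k: float = 5.0,
) -> list[ROITimeSeries]:
    """Keep ROIs whose KCl-window excursion exceeds ``k`` baseline-noise SDs.

    Baseline noise is estimated from the wash window immediately preceding the
    KCl application. Emulates the manual step of drawing only KCl-positive
    cells as ROIs.
    """
    kcl = protocol.kcl_event
    kept = []
    for roi in rois:
        if roi.is_background:
            continue
        pre = roi.window(kcl.onset_s - protocol.wash_pre_s, kcl.onset_s)
        if pre.size < 2:
            raise CalciumProtocolError("no pre-KCl wash window in recording")
        block = roi.window(kcl.onset_s, kcl.end_s + protocol.wash_post_s)
        excursion = float(np.max(block) - np.mean(pre)) if block.size else 0.0
        noise_sd = float(np.std(pre, ddof=1))
        if excursion > k * noise_sd and excursion > 0.0:
            kept.append(roi)
    return kept


def compute_response(
    roi: ROITimeSeries,
    protocol: PerfusionProtocol,
    event: PerfusionEvent,
) -> CalciumResponse:
    """dF/Fmax and peak latency for one agonist application.

    F0 is event-local (mean of the 10-s wash preceding the application), so
    slow drift between events does not bias later events.  dF(t) = F(t) - F0
    is searched over the application plus its 90-s wash; Fmax is the peak of
    the KCl event above its own local F0.  dff_max = max dF / Fmax.
    The response is returned unclassified (``responder=False``); apply
    :func:`classify_responder` to obtain the final call.
    """
    kcl = protocol.kcl_event
    f0_kcl = float(np.mean(roi.window(kcl.onset_s - protocol.wash_pre_s, kcl.onset_s)))
    kcl_block = roi.window(kcl.onset_s, kcl.end_s + protocol.wash_post_s)
    fmax = float(np.max(kcl_block) - f0_kcl)
    if fmax <= 0.0:
        return CalciumResponse(
            roi_id=roi.roi_id, agonist=event.agonist, dff_max=float("nan"),
            peak_latency_s=float("nan"), responder=False, exclusion_reason="kcl_negative",
        )
    f0 = float(np.mean(roi.window(event.onset_s - protocol.wash_pre_s, event.onset_s)))
    block = roi.window(event.onset_s, event.end_s + protocol.wash_post_s)
    delta = block - f0
    i_peak = int(np.argmax(delta))
    dff = float(delta[i_peak]) / fmax
    latency = i_peak / roi.frame_rate_hz
    return CalciumResponse(
        roi_id=roi.roi_id, agonist=event.agonist, dff_max=dff,
        peak_latency_s=latency, responder=False, exclusion_reason="none",
    )


def classify_responder(
    resp: CalciumResponse,
    threshold: float = RESPONDER_THRESHOLD,
    max_latency_s: float = MAX_PEAK_LATENCY_S,
) -> CalciumResponse:
    """Responder iff dff_max >= threshold AND peak latency <= max latency.

    Boundary values (dff_max exactly 0.001, latency exactly 30 s) count as
    responders.
    """
    if resp.exclusion_reason == "kcl_negative":
        return resp
    if not resp.dff_max >= threshold:
        return replace(resp, responder=False, exclusion_reason="below_threshold")
    if resp.peak_latency_s > max_latency_s:
        return replace(resp, responder=False, exclusion_reason="late_peak")
    return replace(resp, responder=True, exclusion_reason="none")


def analyze_dish(
    rois: list[ROITimeSeries],
    background: ROITimeSeries,
    protocol: PerfusionProtocol,
    kcl_select_k: float = 5.0,
    threshold: float = RESPONDER_THRESHOLD,
    max_latency_s: float = MAX_PEAK_LATENCY_S,
) -> pd.DataFrame:
    """Full per-dish pipeline: background subtraction, KCl selection,
    per-agonist response computation and classification.

    Returns one row per retained ROI per agonist event, with metadata columns.
    """
    subtracted = [subtract_background(r, background) for r in rois if not r.is_background]
    retained = select_kcl_positive(subtracted, protocol, k=kcl_select_k)
    rows = []
    for roi in retained:
        for event in protocol.agonist_events:
            resp = classify_responder(
                compute_response(roi, protocol, event),
                threshold=threshold, max_latency_s=max_latency_s,
            )
            rows.append({
                "roi_id": resp.roi_id,
                "agonist": resp.agonist,
                "dff_max": resp.dff_max,
                "peak_latency_s": resp.peak_latency_s,
                "responder": resp.responder,
                "exclusion_reason": resp.exclusion_reason,
                **roi.metadata,
            })
    return pd.DataFrame(rows)


def summarize_proportions(
    responses: pd.DataFrame,
    by: tuple[str, ...] = ("side", "agonist"),
) -> pd.DataFrame:
    """Responder counts, totals and fractions per group.

    Raises on an empty input (a fraction over zero ROIs is undefined).
    """
    if responses.empty:
        raise ValueError("no classified responses to summarize")
    grouped = responses.groupby(list(by), observed=True)["responder"]
    out = grouped.agg(responders="sum", total="count").reset_index()
    out["fraction"] = out["responders"] / out["total"]
    return out
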