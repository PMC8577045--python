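"""CSV schemas tying the pipeline stages together.

Everything is plain, diff-able CSV:

* sweeps: ``<prefix>_sweeps.csv`` (sweep_id, time_s, value),
  ``<prefix>_epochs.csv`` (sweep_id, start_s, end_s, level, label) and
  ``<prefix>_meta.csv`` (sweep_id, sampling_rate_hz, mode + metadata columns);
* ROI series: one wide CSV (time_s + one column per roi_id) with a sidecar
  ``<prefix>_rois.csv`` (roi_id, is_background + metadata columns) and a
  protocol CSV (agonist, onset_s, duration_s);
* IHC: one tidy per-neuron CSV.

Units: seconds, mV (current clamp), pA (voltage clamp), um^2.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .calcium import PerfusionEvent, PerfusionProtocol, ROITimeSeries
from .ihc import RECORD_COLUMNS
from .traces import MembraneTrace, StimulusEpoch

log = logging.getLogger("drgsens")

_META_COLUMNS = ("neuron_id", "animal_id", "side", "weeks_post_od")


class FormatError(ValueError):
    pass


# --------------------------------------------------------------------------
# sweeps

def write_sweeps(traces: list[MembraneTrace], prefix: str | Path) -> None:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    sweep_rows, epoch_rows, meta_rows = [], [], []
    for i, tr in enumerate(traces):
        sid = f"sweep{i:04d}"
        sweep_rows.append(pd.DataFrame({
            "sweep_id": sid, "time_s": tr.times, "value": tr.samples,
        }))
        for ep in tr.epochs:
            epoch_rows.append({
                "sweep_id": sid, "start_s": ep.start_s, "end_s": ep.end_s,
                "level": ep.level, "label": ep.label,
            })
        meta_rows.append({
            "sweep_id": sid,
            "sampling_rate_hz": tr.sampling_rate_hz,
            "mode": tr.mode,
            **{k: tr.metadata.get(k, "") for k in _META_COLUMNS},
        })
    pd.concat(sweep_rows, ignore_index=True).to_csv(
        f"{prefix}_sweeps.csv", index=False, float_format="%.17g")
    pd.DataFrame(epoch_rows, columns=["sweep_id", "start_s", "end_s", "level", "label"]).to_csv(
        f"{prefix}_epochs.csv", index=False, float_format="%.17g")
    pd.DataFrame(meta_rows).to_csv(f"{prefix}_meta.csv", index=False)


def read_sweeps(prefix: str | Path) -> list[MembraneTrace]:
    """Read a sweep set written by :func:`write_sweeps`.

    Malformed rows (non-monotone time, unknown mode, overlapping epochs) are
    rejected with a diagnostic naming the sweep.
    """
    sweeps_path = Path(f"{prefix}_sweeps.csv")
    sweeps = pd.read_csv(sweeps_path, float_precision="round_trip")
    if sweeps.empty:
        log.warning("empty sweep file %s", sweeps_path)
        return []
    epochs = pd.read_csv(f"{prefix}_epochs.csv", float_precision="round_trip")
    meta = pd.read_csv(f"{prefix}_meta.csv").set_index("sweep_id")

    traces = []
    for sid, grp in sweeps.groupby("sweep_id", sort=True):
        t = grp["time_s"].to_numpy()
        if np.any(np.diff(t) <= 0):
            raise FormatError(f"{sid}: time_s not strictly increasing")
        if sid not in meta.index:
            raise FormatError(f"{sid}: missing metadata row")
        row = meta.loc[sid]
        mode = str(row["mode"])
        eps = []
        sub = epochs[epochs["sweep_id"] == sid] if not epochs.empty else epochs
        for _, er in sub.iterrows():
            try:
                eps.append(StimulusEpoch(
                    start_s=float(er["start_s"]), end_s=float(er["end_s"]),
                    level=float(er["level"]),
                    label="" if pd.isna(er["label"]) else str(er["label"]),
                ))
            except ValueError as exc:
                raise FormatError(f"{sid}: bad epoch ({exc})") from exc
        md = {}
        for k in _META_COLUMNS:
            if k in row.index and not pd.isna(row[k]) and row[k] != "":
                md[k] = row[k]
        try:
            traces.append(MembraneTrace(
                samples=grp["value"].to_numpy(),
                sampling_rate_hz=float(row["sampling_rate_hz"]),
                mode=mode, epochs=eps, metadata=md,
            ))
        except ValueError as exc:
            raise FormatError(f"{sid}: {exc}") from exc
    return traces


# --------------------------------------------------------------------------
# ROI series

def write_roi_series(rois: list[ROITimeSeries], prefix: str | Path) -> None:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    if not rois:
        raise FormatError("no ROI series to write")
    n = rois[0].values.size
    fs = rois[0].frame_rate_hz
    wide = {"time_s": np.arange(n) / fs}
    side_rows = []
    for roi in rois:
        if roi.values.size != n:
            raise FormatError("ROI series lengths differ")
        wide[roi.roi_id] = roi.values
        side_rows.append({
            "roi_id": roi.roi_id, "is_background": roi.is_background,
            **{k: roi.metadata.get(k, "") for k in ("dish_id", "animal_id", "side")},
        })
    pd.DataFrame(wide).to_csv(f"{prefix}_series.csv", index=False, float_format="%.17g")
    pd.DataFrame(side_rows).to_csv(f"{prefix}_rois.csv", index=False)


def read_roi_series(prefix: str | Path) -> list[ROITimeSeries]:
    wide = pd.read_csv(f"{prefix}_series.csv", float_precision="round_trip")
    side = pd.read_csv(f"{prefix}_rois.csv").set_index("roi_id")
    t = wide["time_s"].to_numpy()
    if t.size < 2:
        raise FormatError("ROI series needs >= 2 frames")
    dt = np.diff(t)
    if np.any(dt <= 0) or not np.allclose(dt, dt[0]):
        raise FormatError("time_s must be uniform and increasing")
    fs = 1.0 / dt[0]
    rois = []
    for col in wide.columns:
        if col == "time_s":
            continue
        if col not in side.index:
            raise FormatError(f"ROI {col!r} missing from sidecar table")
        row = side.loc[col]
        md = {k: row[k] for k in ("dish_id", "animal_id", "side")
              if k in row.index and not pd.isna(row[k]) and row[k] != ""}
        rois.append(ROITimeSeries(
            roi_id=col, values=wide[col].to_numpy(),
            is_background=bool(row["is_background"]), frame_rate_hz=fs, metadata=md,
        ))
    return rois


def write_protocol(protocol: PerfusionProtocol, path: str | Path) -> None:
    rows = [{
        "agonist": ev.agonist, "onset_s": ev.onset_s, "duration_s": ev.duration_s,
        "wash_pre_s": protocol.wash_pre_s, "wash_post_s": protocol.wash_post_s,
    } for ev in protocol.events]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_protocol(path: str | Path) -> PerfusionProtocol:
    df = pd.read_csv(path)
    if df.empty:
        raise FormatError("empty protocol file")
    events = tuple(
        PerfusionEvent(agonist=str(r["agonist"]), onset_s=float(r["onset_s"]),
                       duration_s=float(r["duration_s"]))
        for _, r in df.iterrows()
    )
    return PerfusionProtocol(
        events=events,
        wash_pre_s=float(df["wash_pre_s"].iloc[0]),
        wash_post_s=float(df["wash_post_s"].iloc[0]),
    )


# --------------------------------------------------------------------------
# IHC tables

def write_ihc_records(records: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in RECORD_COLUMNS if c not in records.columns]
    if missing:
        raise FormatError(f"IHC table missing columns {missing}")
    records.to_csv(path, index=False)


def read_ihc_records(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"IHC table missing columns {missing}")
    if (df["area_um2"] <= 0).any():
        raise FormatError("nonpositive neuron area")
    return df
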