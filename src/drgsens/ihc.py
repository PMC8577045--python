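"""Immunohistochemistry scoring by the distribution-of-minima threshold.

Each stained DRG section contributes its least per-neuron mean gray value;
the pooled minima define a background distribution, and any neuron whose mean
gray value exceeds mean(minima) + 2 * SD(minima) is scored positive.  Neuron
cross-sectional areas are binned into small / medium / large categories
(only the 1000 um^2 small-medium boundary is anchored in the literature;
both cutoffs are configurable).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: columns every per-neuron record table must carry
RECORD_COLUMNS = ("neuron_id", "section_id", "animal_id", "side", "stain", "mean_gray", "area_um2")


class IHCError(ValueError):
    pass


@dataclass(frozen=True)
class MinimaDistribution:
    """Per-section minimum gray values and the derived positivity threshold."""

    minima: tuple[float, ...]
    mean: float
    sd: float

    @property
    def threshold(self) -> float:
        return self.mean + 2.0 * self.sd


@dataclass(frozen=True)
class SizeCutoffs:
    """Upper area bounds (um^2) for the small and medium categories."""

    small_max_um2: float = 600.0
    medium_max_um2: float = 1000.0

    def __post_init__(self) -> None:
        if not (0.0 < self.small_max_um2 < self.medium_max_um2):
            raise ValueError("require 0 < small_max < medium_max")


def build_minima_distribution(
    records: pd.DataFrame,
    normalize: bool = False,
) -> MinimaDistribution:
    """Distribution of per-section least mean-gray values.

    ``normalize=True`` min-max rescales gray values within each section before
    pooling the minima (in which case every minimum is 0); the default pools
    raw values.  Requires at least two sections so the SD is defined.  Caller
    is responsible for restricting ``records`` to one scope (typically one
    animal x stain staining batch).
    """
    if records.empty:
        raise IHCError("no records")
    gray = records["mean_gray"]
    if (gray < 0).any():
        raise IHCError("mean_gray must be nonnegative")
    if normalize:
        def _rescale(g: pd.Series) -> pd.Series:
            span = g.max() - g.min()
            return (g - g.min()) / span if span > 0 else g * 0.0
        gray = records.groupby("section_id", observed=True)["mean_gray"].transform(_rescale)
        records = records.assign(mean_gray=gray)
    minima = records.groupby("section_id", observed=True)["mean_gray"].min()
    if len(minima) < 2:
        raise IHCError("need >= 2 sections for a defined SD of the minima")
    return MinimaDistribution(
        minima=tuple(float(v) for v in minima),
        mean=float(minima.mean()),
        sd=float(minima.std(ddof=1)),
    )


def score_positive(records: pd.DataFrame, dist: MinimaDistribution) -> pd.Series:
    """Positive iff mean_gray strictly exceeds the minima threshold."""
    return records["mean_gray"] > dist.threshold


def score_dataset(
    records: pd.DataFrame,
    scope: tuple[str, ...] = ("animal_id", "stain"),
    normalize: bool = False,
) -> pd.DataFrame:
    """Score every neuron, building one minima distribution per scope group.

    The default scope treats each animal x stain combination as one staining
    batch (intensity is batch-dependent); pass ``scope=()`` for a single
    global threshold.
    """
    out = records.copy()
    if scope:
        positive = pd.Series(False, index=out.index)
        for _, idx in out.groupby(list(scope), observed=True).groups.items():
            sub = out.loc[idx]
            dist = build_minima_distribution(sub, normalize=normalize)
            positive.loc[idx] = score_positive(sub, dist)
        out["positive"] = positive
    else:
        dist = build_minima_distribution(out, normalize=normalize)
        out["positive"] = score_positive(out, dist)
    return out


def summarize_positivity(
    scored: pd.DataFrame,
    by: tuple[str, ...] = ("stain", "side"),
) -> pd.DataFrame:
    """Positive counts, totals and fractions per group."""
    if scored.empty:
        raise IHCError("no scored records to summarize")
    grouped = scored.groupby(list(by), observed=True)["positive"]
    out = grouped.agg(positives="sum", total="count").reset_index()
    out["fraction"] = out["positives"] / out["total"]
    return out


def categorize_size(area_um2, cutoffs: SizeCutoffs = SizeCutoffs()):
    """Assign small / medium / large by area; boundaries belong to the
    smaller category (area exactly at small_max is small).

    Accepts a scalar or an array; nonpositive areas are rejected.
    """
    area = np.asarray(area_um2, dtype=float)
    if np.any(area <= 0):
        raise IHCError("areas must be positive")
    cats = np.where(
        area <= cutoffs.small_max_um2, "small",
        np.where(area <= cutoffs.medium_max_um2, "medium", "large"),
    )
    if np.isscalar(area_um2):
        return str(cats.item())
    return pd.Series(cats, index=getattr(area_um2, "index", None), name="size_category")


def size_histogram(
    records: pd.DataFrame,
    bin_width_um2: float = 200.0,
    positive_only: bool = False,
) -> pd.DataFrame:
    """Histogram of neuron cross-sectional areas.

    Bins are [0, w), [w, 2w), ... covering every record; the counts sum to
    the number of records histogrammed.
    """
    if not bin_width_um2 > 0:
        raise IHCError("bin width must be positive")
    sub = records[records["positive"]] if positive_only else records
    areas = sub["area_um2"].to_numpy(dtype=float)
    if areas.size == 0:
        return pd.DataFrame({"bin_left_um2": [], "bin_right_um2": [], "count": []})
    n_bins = int(np.floor(areas.max() / bin_width_um2)) + 1
    edges = bin_width_um2 * np.arange(n_bins + 1)
    counts, _ = np.histogram(areas, bins=edges)
    return pd.DataFrame({
        "bin_left_um2": edges[:-1],
        "bin_right_um2": edges[1:],
        "count": counts,
    })
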