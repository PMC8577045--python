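"""Group statistics: unpaired Student's t-tests and 2x2 Pearson chi-square.

Two-group mean comparisons use the pooled-variance (Student) unpaired t-test,
either from raw samples or from printed ``mean +/- SD, n`` summaries.
Proportion comparisons use the uncorrected Pearson chi-square on a 2x2 table
(df = 1).  P-values are displayed with a truncation (floor) convention —
``p = 0.048`` prints as ``"0.04"`` — while the untruncated value is retained.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps


class StatsError(ValueError):
    pass


class DegenerateTableError(StatsError):
    """A 2x2 table with a zero row or column margin has no defined chi-square."""


@dataclass(frozen=True)
class GroupSummary:
    """Printed summary of one group: mean, SD and sample size."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise StatsError("sd must be nonnegative")
        if int(self.n) != self.n or self.n < 1:
            raise StatsError("n must be a positive integer")

    @classmethod
    def from_samples(cls, x) -> "GroupSummary":
        x = np.asarray(x, dtype=float)
        if x.size < 2:
            raise StatsError("need at least 2 samples")
        return cls(mean=float(np.mean(x)), sd=float(np.std(x, ddof=1)), n=int(x.size))


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts laid out as group (rows) x outcome (columns)::

        a  b      responders / non-responders, group 1
        c  d      responders / non-responders, group 2
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise StatsError(f"count {name} must be a nonnegative integer")
        if self.total < 1:
            raise StatsError("grand total must be >= 1")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def row_totals(self) -> tuple[int, int]:
        return (self.a + self.b, self.c + self.d)

    @property
    def col_totals(self) -> tuple[int, int]:
        return (self.a + self.c, self.b + self.d)

    @classmethod
    def from_proportions(cls, k1: int, n1: int, k2: int, n2: int) -> "ContingencyTable2x2":
        """Build from responder counts ``k`` out of totals ``n`` per group."""
        return cls(a=k1, b=n1 - k1, c=k2, d=n2 - k2)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p_two_sided: float
    method: str
    p_printed: str = field(default="")

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_two_sided <= 1.0):
            raise StatsError("p must lie in [0, 1]")


def format_p(p: float, decimals: int = 2) -> str:
    """Truncate (floor) ``p`` at the given decimal place.

    Truncation, not rounding: 0.0484 at two decimals prints "0.04".  The
    underlying value is not modified; this is a display convention only.
    """
    if not (0.0 <= p <= 1.0):
        raise StatsError("p must lie in [0, 1]")
    if decimals < 0:
        raise StatsError("decimals must be nonnegative")
    scale = 10 ** decimals
    # tiny epsilon guards against 0.03 stored as 0.02999... flooring to 0.02
    truncated = math.floor(p * scale + 1e-12) / scale
    return f"{truncated:.{decimals}f}"


def unpaired_t_summary(
    g1: GroupSummary,
    g2: GroupSummary,
    welch: bool = False,
    p_decimals: int = 2,
) -> TestResult:
    """Two-sided unpaired t-test from group summaries.

    Default is the pooled-variance Student test with df = n1 + n2 - 2;
    ``welch=True`` uses the unequal-variance form with Satterthwaite df.
    Two identical constant groups (both SD 0, equal means) return t = 0, p = 1.
    """
    n1, n2 = g1.n, g2.n
    if n1 < 2 or n2 < 2:
        raise StatsError("t-test requires n >= 2 in each group")
    v1, v2 = g1.sd ** 2, g2.sd ** 2
    if welch:
        se2 = v1 / n1 + v2 / n2
        if se2 == 0.0:
            df = float(n1 + n2 - 2)
        else:
            df = se2 ** 2 / (
                (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
            )
        method = "welch_t"
    else:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se2 = sp2 * (1.0 / n1 + 1.0 / n2)
        df = float(n1 + n2 - 2)
        method = "student_t"
    diff = g1.mean - g2.mean
    if se2 == 0.0:
        t = 0.0 if diff == 0.0 else math.copysign(math.inf, diff)
        p = 1.0 if diff == 0.0 else 0.0
    else:
        t = diff / math.sqrt(se2)
        p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult(
        statistic=t, df=df, p_two_sided=float(p), method=method,
        p_printed=format_p(float(p), p_decimals),
    )


def unpaired_t_samples(x1, x2, welch: bool = False, p_decimals: int = 2) -> TestResult:
    """Two-sided unpaired t-test from raw samples.

    Exactly equivalent to :func:`unpaired_t_summary` applied to each sample's
    mean, SD (ddof = 1) and n.
    """
    return unpaired_t_summary(
        GroupSummary.from_samples(x1), GroupSummary.from_samples(x2),
        welch=welch, p_decimals=p_decimals,
    )


def chi_square_2x2(
    table: ContingencyTable2x2,
    correction: bool = False,
    p_decimals: int = 2,
) -> TestResult:
    """Pearson chi-square on a 2x2 table, df = 1, no continuity correction.

    chi2 = (ad - bc)^2 * N / (r1 * r2 * c1 * c2).  ``correction=True`` applies
    the Yates continuity correction (|ad - bc| reduced by N/2, floored at 0).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    r1, r2 = table.row_totals
    c1, c2 = table.col_totals
    if min(r1, r2, c1, c2) == 0:
        raise DegenerateTableError("zero row or column total")
    n = table.total
    cross = a * d - b * c
    if correction:
        cross_mag = max(abs(cross) - n / 2.0, 0.0)
        method = "chi2_yates"
    else:
        cross_mag = abs(cross)
        method = "chi2"
    chi2 = cross_mag ** 2 * n / (r1 * r2 * c1 * c2)
    p = float(sps.chi2.sf(chi2, 1))
    return TestResult(
        statistic=float(chi2), df=1.0, p_two_sided=p, method=method,
        p_printed=format_p(p, p_decimals),
    )
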