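"""Voltage-clamp analysis: baseline subtraction, step current densities and
single/double Boltzmann fits to current-voltage relations.

Each sweep holds the cell at -120 mV for 240 ms before a 40-ms test step
(-50 to +40 mV in 10-mV increments).  Currents are normalised by subtracting
the mean of the final 100 ms of the -120 mV pre-step; the minimum (inward)
and maximum (outward) current within the test window, divided by the cell
capacitance, give the step current density in pA/pF.  Density-voltage
relations are fit with the Boltzmann activation sigmoid

    I(V) = sum_c Imax_c / (1 + exp((Vhalf_c - V) / k_c))

with one or two components.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .traces import MembraneTrace, ProtocolError

BASELINE_WINDOW_S = 0.100


class FitError(RuntimeError):
    pass


@dataclass(frozen=True)
class IVPoint:
    """Current density at one test voltage, after baseline subtraction."""

    step_mV: float
    inward_density_pA_per_pF: float   # minimum (<= 0 for a passive-corrected sweep)
    outward_density_pA_per_pF: float  # maximum (>= 0)


@dataclass(frozen=True)
class BoltzmannFit:
    """Converged least-squares fit; one dict of (i_max, v_half, slope_k) per
    component, plus the residual sum of squares."""

    components: tuple[dict, ...]
    residual_sum_of_squares: float
    converged: bool

    @property
    def n_components(self) -> int:
        return len(self.components)

    def predict(self, v) -> np.ndarray:
        v = np.asarray(v, dtype=float)
        out = np.zeros_like(v)
        for c in self.components:
            out = out + boltzmann(v, c["i_max_pA_per_pF"], c["v_half_mV"], c["slope_k_mV"])
        return out


def boltzmann(v, i_max: float, v_half: float, k: float):
    """Single Boltzmann activation sigmoid; I(v_half) = i_max / 2."""
    v = np.asarray(v, dtype=float)
    return i_max / (1.0 + np.exp(np.clip((v_half - v) / k, -500.0, 500.0)))


def subtract_baseline(sweep: MembraneTrace, pre_label: str = "pre") -> MembraneTrace:
    """Subtract the mean of the final 100 ms of the -120 mV pre-step epoch."""
    pre = sweep.epoch_by_label(pre_label)
    if pre.duration_s < BASELINE_WINDOW_S:
        raise ProtocolError("pre-step epoch shorter than the 100-ms baseline window")
    baseline = float(np.mean(sweep.window(pre.end_s - BASELINE_WINDOW_S, pre.end_s)))
    return replace(sweep, samples=sweep.samples - baseline)


def compute_current_density(
    sweep: MembraneTrace,
    capacitance_pF: float,
    test_label: str = "test",
) -> IVPoint:
    """Minimum (inward) and maximum (outward) current in the test window,
    divided by cell capacitance.  The sweep must already be
    baseline-subtracted."""
    if not capacitance_pF > 0:
        raise ValueError("capacitance must be positive")
    test = sweep.epoch_by_label(test_label)
    vals = sweep.window(test.start_s, test.end_s)
    if vals.size == 0:
        raise ProtocolError("test window contains no samples")
    return IVPoint(
        step_mV=test.level,
        inward_density_pA_per_pF=float(np.min(vals)) / capacitance_pF,
        outward_density_pA_per_pF=float(np.max(vals)) / capacitance_pF,
    )


def _fit_once(v, y, p0, bounds) -> tuple[np.ndarray, float, bool]:
    def resid(p):
        pred = np.zeros_like(v)
        for j in range(0, p.size, 3):
            pred = pred + boltzmann(v, p[j], p[j + 1], p[j + 2])
        return pred - y

    try:
        res = least_squares(resid, p0, bounds=bounds, max_nfev=5000)
    except ValueError:
        return p0, float("inf"), False
    rss = float(np.sum(res.fun ** 2))
    return res.x, rss, bool(res.success)


def fit_boltzmann(
    points: Sequence[IVPoint],
    branch: str,
    components: int = 1,
    init: Sequence[float] | None = None,
    max_restarts: int = 5,
    seed: int = 0,
) -> BoltzmannFit:
    """Least-squares Boltzmann fit to one branch of an I-V relation.

    branch
        ``"inward"`` fits the inward (minimum) densities, ``"outward"`` the
        outward (maximum) densities.
    init
        Optional flat parameter vector (i_max, v_half, k) per component;
        otherwise Imax starts at the extreme density, Vhalf at the voltage
        nearest half of it, and k at 8 mV, with up to ``max_restarts``
        jittered restarts on non-convergence.

    Returns a fit with ``converged=False`` (never silently) if no start
    converges.
    """
    if branch not in ("inward", "outward"):
        raise ValueError("branch must be 'inward' or 'outward'")
    if components not in (1, 2):
        raise ValueError("components must be 1 or 2")
    min_points = 4 if components == 1 else 7
    pts = sorted(points, key=lambda p: p.step_mV)
    if len(pts) < min_points:
        raise ValueError(f"{components}-component fit needs >= {min_points} points")
    v = np.array([p.step_mV for p in pts], dtype=float)
    y = np.array([
        p.inward_density_pA_per_pF if branch == "inward" else p.outward_density_pA_per_pF
        for p in pts
    ], dtype=float)

    extreme = y[np.argmax(np.abs(y))]
    v_half0 = float(v[np.argmin(np.abs(y - extreme / 2.0))])
    starts: list[np.ndarray] = []
    if init is not None:
        starts.append(np.asarray(init, dtype=float))
    else:
        base1 = np.array([extreme, v_half0, 8.0])
        if components == 1:
            starts.append(base1)
        else:
            # embed the single-component solution, second component small
            p1, _, ok1 = _fit_once(v, y, base1, ([-np.inf] * 3, [np.inf] * 3))
            one = p1 if ok1 else base1
            starts.append(np.array([one[0] * 0.6, one[1] - 10.0, one[2],
                                    one[0] * 0.4, one[1] + 10.0, one[2]]))
            starts.append(np.array([*one, extreme * 1e-3, v_half0 + 20.0, 8.0]))
        rng = np.random.default_rng(seed)
        for _ in range(max_restarts):
            jitter = starts[0] * (1.0 + 0.2 * rng.standard_normal(starts[0].size))
            jitter[2::3] = np.where(jitter[2::3] == 0.0, 8.0, jitter[2::3])
            starts.append(jitter)

    span = float(v.max() - v.min())
    lo = np.tile([-np.inf, v.min() - 2 * span, 0.1], components)
    hi = np.tile([np.inf, v.max() + 2 * span, 10 * span], components)

    best: tuple[np.ndarray, float] | None = None
    for p0 in starts:
        p0c = np.clip(p0, lo + 1e-9, hi - 1e-9)
        p_fit, rss, ok = _fit_once(v, y, p0c, (lo, hi))
        if ok and (best is None or rss < best[1]):
            best = (p_fit, rss)
    if best is None:
        return BoltzmannFit(components=(), residual_sum_of_squares=float("inf"), converged=False)
    p_fit, rss = best
    comps = tuple(
        {
            "i_max_pA_per_pF": float(p_fit[j]),
            "v_half_mV": float(p_fit[j + 1]),
            "slope_k_mV": float(p_fit[j + 2]),
        }
        for j in range(0, p_fit.size, 3)
    )
    return BoltzmannFit(components=comps, residual_sum_of_squares=rss, converged=True)


def compare_iv(
    ctrl_points: dict[float, Sequence[float]],
    od_points: dict[float, Sequence[float]],
    branch_label: str = "",
) -> "pd.DataFrame":
    """Per-voltage two-sided unpaired t-tests on current densities.

    Inputs map step voltage -> per-neuron densities for each group; voltages
    present in both groups are compared.  Singleton groups are rejected (the
    variance is undefined).
    """
    import pandas as pd

    from .stats import unpaired_t_samples

    voltages = sorted(set(ctrl_points) & set(od_points))
    if not voltages:
        raise ValueError("no shared voltages between groups")
    rows = []
    for v in voltages:
        x1, x2 = list(ctrl_points[v]), list(od_points[v])
        res = unpaired_t_samples(x1, x2)
        rows.append({
            "step_mV": v,
            "branch": branch_label,
            "n_ctrl": len(x1),
            "n_od": len(x2),
            "statistic": res.statistic,
            "df": res.df,
            "p_two_sided": res.p_two_sided,
            "p_printed": res.p_printed,
            "method": res.method,
        })
    return pd.DataFrame(rows)
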