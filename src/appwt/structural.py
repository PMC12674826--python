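"""Individual-level structural model.

Appetite trajectory (LCSS appetite item, mm; higher = worse appetite)::

    L(t) = L0 + (exp(SLP*t) - 1) - PMAX * (1 - exp(-Kp*t))

The first exponential carries appetite loss from disease progression or
treatment toxicity (rate ``SLP``, 1/day); the asymptotic exponential
carries recovery / placebo / supportive-care improvement (extent
``PMAX`` mm, onset rate ``Kp`` 1/day).

Body weight follows an indirect-response (turnover) model in which the
appetite score inhibits the zero-order weight input::

    dWT/dt = Kin * (1 - Imax * L(t) / (IC50 + L(t))) - Kout * WT

with ``Kout`` tied to the baseline steady state so that weight is
constant whenever appetite does not change::

    Kout = Kin * (1 - Imax * L0 / (IC50 + L0)) / WT0

``L(t)`` is unbounded analytically; the inhibition term receives the
score clamped to the instrument's 0-100 mm range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp


class ParameterError(ValueError):
    """Structurally invalid parameter combination."""


class SolverError(RuntimeError):
    """ODE integration failed; carries the offending parameter set."""

    def __init__(self, message, params=None):
        super().__init__(message)
        self.params = params


@dataclass(frozen=True)
class AppetiteParameters:
    l0: float   # baseline appetite score, mm in [0, 100]
    slp: float  # appetite loss rate, 1/day, >= 0
    pmax: float  # maximal appetite improvement, mm >= 0
    kp: float   # improvement onset rate, 1/day, >= 0

    def __post_init__(self):
        for name, v in (("L0", self.l0), ("SLP", self.slp), ("PMAX", self.pmax), ("Kp", self.kp)):
            if not math.isfinite(v):
                raise ParameterError(f"{name} must be finite, got {v}")
        if not (0.0 <= self.l0 <= 100.0):
            raise ParameterError(f"L0 must lie in [0, 100] mm, got {self.l0}")
        if self.slp < 0:
            raise ParameterError(f"SLP (appetite loss rate) must be >= 0, got {self.slp}")
        if self.pmax < 0:
            raise ParameterError(f"PMAX must be >= 0, got {self.pmax}")
        if self.kp < 0:
            raise ParameterError(f"Kp must be >= 0, got {self.kp}")


@dataclass(frozen=True)
class WeightParameters:
    wt0: float   # baseline weight, kg > 0
    kin: float   # zero-order weight input, kg/day > 0
    imax: float  # maximal inhibition, in [0, 1]
    ic50: float  # score giving half-maximal inhibition, mm > 0

    def __post_init__(self):
        if not (self.wt0 > 0):
            raise ParameterError(f"WT0 must be > 0 kg, got {self.wt0}")
        if not (self.kin > 0):
            raise ParameterError(f"Kin must be > 0 kg/day, got {self.kin}")
        if not (0.0 <= self.imax <= 1.0):
            raise ParameterError(f"Imax must lie in [0, 1], got {self.imax}")
        if not (self.ic50 > 0):
            raise ParameterError(f"IC50 must be > 0 mm, got {self.ic50}")


@dataclass(frozen=True)
class IndividualParameters:
    appetite: AppetiteParameters
    weight: WeightParameters

    @classmethod
    def from_dict(cls, d: dict) -> "IndividualParameters":
        return cls(
            appetite=AppetiteParameters(l0=d["L0"], slp=d["SLP"], pmax=d["PMAX"], kp=d["Kp"]),
            weight=WeightParameters(wt0=d["WT0"], kin=d["Kin"], imax=d["Imax"], ic50=d["IC50"]),
        )

    def as_dict(self) -> dict:
        a, w = self.appetite, self.weight
        return {"L0": a.l0, "SLP": a.slp, "PMAX": a.pmax, "Kp": a.kp,
                "WT0": w.wt0, "Kin": w.kin, "Imax": w.imax, "IC50": w.ic50}

    @property
    def kout(self) -> float:
        return derive_kout(self)


def clamp_score(score):
    """Clamp an analytic appetite score to the 0-100 mm instrument range."""
    return np.clip(score, 0.0, 100.0)


def appetite_at(params: AppetiteParameters, t):
    """Unclamped appetite trajectory L(t); exact at t = 0 (returns L0)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("appetite trajectory is defined for t >= 0 only")
    out = params.l0 + np.expm1(params.slp * t) - params.pmax * (-np.expm1(-params.kp * t))
    return float(out) if out.ndim == 0 else out


def inhibition(score, weight_params: WeightParameters):
    """Fractional inhibition of weight input at a (clamped) appetite score."""
    L = clamp_score(score)
    return weight_params.imax * L / (weight_params.ic50 + L)


def derive_kout(params: IndividualParameters) -> float:
    """Steady-state turnover rate (1/day) from the baseline constraint."""
    a, w = params.appetite, params.weight
    inh0 = w.imax * a.l0 / (w.ic50 + a.l0)
    if inh0 >= 1.0:
        raise ParameterError(
            f"baseline inhibition {inh0:.3f} >= 1 gives non-positive Kout "
            f"(Imax={w.imax}, L0={a.l0}, IC50={w.ic50})"
        )
    return w.kin * (1.0 - inh0) / w.wt0


def _input_rate(params: IndividualParameters, t):
    """Weight input rate Kin * (1 - inhibition(L(t))), kg/day."""
    L = clamp_score(appetite_at(params.appetite, t))
    return params.weight.kin * (1.0 - inhibition(L, params.weight))


def weight_trajectory(
    params: IndividualParameters,
    t_grid: Sequence[float],
    rtol: float = 1e-10,
    atol: float = 1e-12,
    method: str = "ivp",
    step: float = 0.5,
) -> np.ndarray:
    """Body weight (kg) at each time of ``t_grid`` (days, starting at 0).

    ``method="ivp"`` integrates the turnover ODE with an adaptive
    solver (LSODA); ``method="exact"`` exploits the linearity of the
    ODE given L(t) and applies an exact exponential-integrator update on
    a refined grid (piecewise-linear input), which is much faster and is
    what the fitting and simulation layers use internally.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size == 0:
        raise ValueError("t_grid must be a non-empty 1-D array")
    if t_grid[0] != 0.0:
        raise ValueError("t_grid must start at 0")
    if np.any(np.diff(t_grid) < 0):
        raise ValueError("t_grid must be ordered")
    kout = derive_kout(params)
    wt0 = params.weight.wt0

    if t_grid[-1] == 0.0:
        return np.full_like(t_grid, wt0)

    if method == "exact":
        return _weight_exact(params, t_grid, kout, step)
    if method != "ivp":
        raise ValueError(f"unknown method {method!r}")

    def rhs(t, y):
        return _input_rate(params, t) - kout * y

    sol = solve_ivp(
        rhs, (0.0, float(t_grid[-1])), [wt0], t_eval=t_grid,
        method="LSODA", rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise SolverError(f"weight ODE integration failed: {sol.message}",
                          params=params.as_dict())
    return sol.y[0]


def _weight_exact(params: IndividualParameters, t_eval: np.ndarray, kout: float,
                  step: float) -> np.ndarray:
    """Exact exponential-integrator solution on a refined grid.

    Given L(t), the turnover ODE is linear:
    WT(t) = e^{-k t} (WT0 + \\int_0^t e^{k s} In(s) ds).  The input In is
    interpolated linearly between grid nodes, for which the integral has
    a closed form per step.  Accumulation is segmented so that e^{k t}
    cannot overflow for long horizons or fast turnover.
    """
    tmax = float(t_eval[-1])
    grid = np.unique(np.concatenate([np.arange(0.0, tmax + step, step), t_eval]))
    grid = grid[grid <= tmax + 1e-12]
    rate = _input_rate(params, grid)
    dt = np.diff(grid)
    k = kout
    e = np.exp(-k * dt)
    a = rate[:-1]
    b = np.where(dt > 0, np.diff(rate) / np.where(dt > 0, dt, 1.0), 0.0)
    # per-step forced response: int_0^h e^{-k(h-s)} (a + b s) ds
    c = a * (1.0 - e) / k + b * (dt - (1.0 - e) / k) / k

    wt = np.empty_like(grid)
    wt[0] = params.weight.wt0
    n = len(grid)
    start = 0
    max_span = 250.0  # cap on k*(t - t_seg) per segment to avoid overflow
    while start < n - 1:
        span = np.searchsorted(k * (grid - grid[start]), max_span)
        end = int(min(max(span, start + 2), n))
        kt = k * (grid[start:end] - grid[start])
        growth = np.exp(kt[1:])  # e^{k (t_j - t_start)} at right edges
        s = np.cumsum(growth * c[start:end - 1])
        wt[start + 1:end] = np.exp(-kt[1:]) * wt[start] + s / growth
        start = end - 1

    idx = np.searchsorted(grid, t_eval)
    return wt[idx]


def weight_at(params: IndividualParameters, times, step: float = 0.5) -> np.ndarray:
    """Weight at arbitrary non-negative times via the exact-grid path."""
    times = np.atleast_1d(np.asarray(times, dtype=float))
    if np.any(times < 0):
        raise ValueError("times must be >= 0")
    order = np.argsort(times)
    t_sorted = times[order]
    grid = np.concatenate([[0.0], t_sorted]) if t_sorted[0] > 0 else t_sorted
    vals = weight_trajectory(params, grid, method="exact", step=step)
    if t_sorted[0] > 0:
        vals = vals[1:]
    out = np.empty_like(vals)
    out[order] = vals
    return out


def export_trajectory(params: IndividualParameters, t_grid, path, step: float = 0.5) -> None:
    """Write (time, appetite, weight) on a grid as CSV."""
    import pandas as pd

    t_grid = np.asarray(t_grid, dtype=float)
    appetite = clamp_score(appetite_at(params.appetite, t_grid))
    weight = weight_trajectory(params, t_grid, method="exact", step=step)
    pd.DataFrame({"time": t_grid, "appetite": appetite, "weight": weight}).to_csv(path, index=False)
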