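"""Deterministic single-lineage growth simulation across cell cycles.

A lineage is integrated with a stiff-capable adaptive method; division is
event-located at the instant the total cell volume reaches twice its value
at birth, whereupon every molecular pool is halved.  From the resulting
trajectory the module extracts the exponential growth rate (log-linear fit
with division discontinuities removed), the cell-to-nucleus volume ratio,
and — in the quiescent regime — the constant-volume fixed point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.stats import linregress

from .model import (STATE_FIELDS, CellState, GrowthMode, KineticParameters,
                    NumericalStateError, rhs_array)

__all__ = [
    "DivisionEvent",
    "Trajectory",
    "GrowthSummary",
    "simulate_generations",
    "fit_growth_rate",
    "cn_ratio",
    "CNSummary",
    "summarize_growth",
    "quiescent_steady_state",
]


@dataclass(frozen=True)
class DivisionEvent:
    time: float
    volume: float  # total cell volume immediately before halving


@dataclass
class Trajectory:
    """Time series of one simulated lineage.

    ``states`` has one row per time point in ``STATE_FIELDS`` order;
    ``cycle`` labels each sample with its generation index.  Volumes are
    derived from counts via the conversion factors.
    """

    t: np.ndarray
    states: np.ndarray
    cycle: np.ndarray
    divisions: list[DivisionEvent]
    params: KineticParameters
    mode: GrowthMode
    divided: bool = True

    @property
    def V_C(self) -> np.ndarray:
        return self.states[:, 1:4].sum(axis=1) / self.params.r1

    @property
    def V_N(self) -> np.ndarray:
        return self.states[:, 4:7].sum(axis=1) / self.params.r2

    @property
    def V_cell(self) -> np.ndarray:
        return self.V_C + self.V_N

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(STATE_FIELDS))
        df.insert(0, "t", self.t)
        df["V_C"] = self.V_C
        df["V_N"] = self.V_N
        df["V_cell"] = self.V_cell
        df["CN_ratio"] = df["V_cell"] / df["V_N"]
        df["cycle"] = self.cycle
        return df

    def final_state(self) -> CellState:
        return CellState.from_array(self.states[-1])


@dataclass
class GrowthSummary:
    """Derived scalars of one growth simulation."""

    growth_rate: float | None = None        # λ, 1/h
    doubling_time: float | None = None      # ln2/λ when λ > 0
    cn_steady: float | None = None
    cn_is_steady: bool = False
    cn_cycle_min: float | None = None
    cn_cycle_max: float | None = None
    steady_volume: float | None = None      # quiescent only, μm^3
    converged: bool = False

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


def simulate_generations(initial: CellState, params: KineticParameters,
                         mode: GrowthMode, n_generations: int = 8,
                         max_cycle_hours: float = 200.0,
                         samples_per_cycle: int = 60,
                         rtol: float = 1e-8, atol: float = 1e-10
                         ) -> Trajectory:
    """Integrate ``n_generations`` cell cycles with division at doubling.

    Division is located by a root of V_cell(t) - 2*V_cell(birth); at each
    event all seven pools are halved exactly.  If the volume never doubles
    within ``max_cycle_hours`` (shrinking cells, quiescence) the run stops
    there and the trajectory is flagged ``divided=False``.
    """
    if n_generations < 1:
        raise ValueError("n_generations must be >= 1")
    initial.validate()
    params.validate()
    y = initial.as_array()
    t0 = 0.0
    ts, ys, cyc = [], [], []
    divisions: list[DivisionEvent] = []
    divided = True

    def f(t, yy):
        return rhs_array(yy, params, mode)

    for gen in range(n_generations):
        v_birth = (y[1:4].sum() / params.r1 + y[4:7].sum() / params.r2)

        def doubled(t, yy, vb=v_birth):
            return (yy[1:4].sum() / params.r1
                    + yy[4:7].sum() / params.r2) - 2.0 * vb

        doubled.terminal = True
        doubled.direction = 1
        t_eval = np.linspace(t0, t0 + max_cycle_hours,
                             samples_per_cycle * 10)
        sol = solve_ivp(f, (t0, t0 + max_cycle_hours), y, method="LSODA",
                        events=doubled, dense_output=True,
                        rtol=rtol, atol=atol)
        if not sol.success:
            raise NumericalStateError(f"integration failed in generation "
                                      f"{gen}: {sol.message}")
        t_end = sol.t[-1]
        grid = np.linspace(t0, t_end, samples_per_cycle, endpoint=False)
        seg = sol.sol(grid)
        if np.any(seg < -atol):
            raise NumericalStateError("negative molecular count during "
                                      f"generation {gen}")
        ts.append(grid)
        ys.append(seg.T)
        cyc.append(np.full(grid.size, gen))
        if sol.t_events[0].size:
            td = float(sol.t_events[0][0])
            y_pre = sol.y_events[0][0]
            v_pre = (y_pre[1:4].sum() / params.r1
                     + y_pre[4:7].sum() / params.r2)
            ts.append(np.array([td]))
            ys.append(y_pre[None, :])
            cyc.append(np.array([gen]))
            divisions.append(DivisionEvent(td, float(v_pre)))
            y = y_pre / 2.0
            t0 = td
        else:
            divided = False
            break

    t = np.concatenate(ts)
    states = np.vstack(ys)
    cycle = np.concatenate(cyc)
    return Trajectory(t=t, states=states, cycle=cycle, divisions=divisions,
                      params=params, mode=mode, divided=divided)


def _log_volume_continuous(traj: Trajectory) -> np.ndarray:
    """log V_cell with the division discontinuities stitched out."""
    v = traj.V_cell
    if np.any(v <= 0):
        raise ValueError("non-positive cell volume in trajectory")
    logv = np.log(v)
    out = logv.copy()
    offset = 0.0
    boundaries = np.flatnonzero(np.diff(traj.cycle) != 0) + 1
    for b in boundaries:
        offset += logv[b - 1] - logv[b]
        out[b:] = logv[b:] + offset
    return out


def fit_growth_rate(traj: Trajectory, discard_cycles: int = 3) -> float:
    """Exponential rate λ from a log-linear fit of total cell volume.

    The first ``discard_cycles`` generations are dropped as transient.
    For non-dividing trajectories the fit uses the final half of the
    samples instead.
    """
    logv = _log_volume_continuous(traj)
    n_cycles = int(traj.cycle[-1]) + 1
    if traj.divided and n_cycles - discard_cycles >= 2:
        keep = traj.cycle >= discard_cycles
    else:
        keep = np.arange(traj.t.size) >= traj.t.size // 2
    res = linregress(traj.t[keep], logv[keep])
    return float(res.slope)


def summarize_growth(traj: Trajectory, discard_cycles: int = 3
                     ) -> GrowthSummary:
    """λ, doubling time and C/N summary of a dividing-lineage trajectory."""
    lam = fit_growth_rate(traj, discard_cycles)
    _, cn = cn_ratio(traj)
    return GrowthSummary(
        growth_rate=lam,
        doubling_time=float(np.log(2) / lam) if lam > 0 else None,
        cn_steady=cn.steady, cn_is_steady=cn.is_steady,
        cn_cycle_min=cn.cycle_min, cn_cycle_max=cn.cycle_max,
        converged=traj.divided)


@dataclass(frozen=True)
class CNSummary:
    steady: float
    is_steady: bool
    cycle_min: float
    cycle_max: float


def cn_ratio(traj: Trajectory, drift_tol: float = 1e-4
             ) -> tuple[np.ndarray, CNSummary]:
    """C/N ratio series V_cell/V_N and its steady (final-cycle) summary.

    The steady value is the time-average over the final full cycle; the
    ``is_steady`` flag requires the relative drift of that mean across
    the last two cycles to fall below ``drift_tol`` per hour.  In the
    transporter-limited (poor) regime the ratio oscillates within each
    cycle, so the per-cycle min/max are reported alongside.
    """
    V_N = traj.V_N
    if np.any(V_N <= 0):
        raise ValueError("nuclear volume must be positive")
    series = traj.V_cell / V_N
    last = int(traj.cycle[-1])
    m_last = traj.cycle == last
    steady = float(np.mean(series[m_last]))
    cyc_min = float(series[m_last].min())
    cyc_max = float(series[m_last].max())
    is_steady = False
    if last >= 1:
        m_prev = traj.cycle == last - 1
        prev = float(np.mean(series[m_prev]))
        dt_hours = float(np.mean(traj.t[m_last]) - np.mean(traj.t[m_prev]))
        if dt_hours > 0:
            drift = abs(steady - prev) / (abs(steady) * dt_hours)
            is_steady = drift < drift_tol
    return series, CNSummary(steady, is_steady, cyc_min, cyc_max)


def quiescent_steady_state(initial: CellState, params: KineticParameters,
                           mode: GrowthMode, horizon: float = 200.0,
                           tol: float = 1e-6, chunk: float = 20.0
                           ) -> tuple[CellState, GrowthSummary]:
    """Integrate a quiescent cell to its constant-volume fixed point.

    Convergence requires the largest relative rate |dX/dt|/X across pools
    to drop below ``tol`` (1/h).  A partial result with ``converged=False``
    is returned when the horizon is exhausted first.
    """
    if mode.regime != "quiescent":
        raise ValueError("quiescent_steady_state requires a quiescent mode")
    y = initial.as_array()
    t = 0.0
    converged = False
    while t < horizon:
        t_next = min(t + chunk, horizon)
        sol = solve_ivp(lambda tt, yy: rhs_array(yy, params, mode),
                        (t, t_next), y, method="LSODA",
                        rtol=1e-10, atol=1e-12)
        if not sol.success:
            raise NumericalStateError(f"integration failed: {sol.message}")
        y = sol.y[:, -1]
        t = t_next
        dy = rhs_array(y, params, mode)
        rel = np.max(np.abs(dy) / np.maximum(np.abs(y), 1e-12))
        if rel < tol:
            converged = True
            break
    state = CellState.from_array(y)
    V_C = y[1:4].sum() / params.r1
    V_N = y[4:7].sum() / params.r2
    summary = GrowthSummary(growth_rate=0.0 if converged else None,
                            cn_steady=(V_C + V_N) / V_N,
                            cn_is_steady=converged,
                            steady_volume=V_C + V_N,
                            converged=converged)
    return state, summary
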