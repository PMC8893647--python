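"""Parameter scans, RP/R-ratio curves, and normalized sensitivity gradients.

Scans re-simulate the lineage at each grid point and record the growth
rate λ and the steady C/N ratio.  The gradient analysis differentiates a
response (λ, C/N, or the quiescent steady volume) with respect to
parameters normalized by their baseline values (so a component of 0.1
means "a 1% parameter change moves the response by 0.1%·response-scale"),
and scales the resulting vector to unit Euclidean length — the form
usually displayed as a radar chart.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import CellState, GrowthMode, KineticParameters
from .growth import (cn_ratio, fit_growth_rate, quiescent_steady_state,
                     simulate_generations)

__all__ = [
    "ScanResult",
    "GradientProfile",
    "scan",
    "normalized_gradient",
    "rp_r_curve",
    "DEFAULT_GRADIENT_PARAMS",
    "QUIESCENT_GRADIENT_PARAMS",
]

#: Parameters the gradient is taken over.  The degradation pairs move
#: together (d1 ≡ d1C = d1N etc.), matching how they are calibrated.
DEFAULT_GRADIENT_PARAMS = ("s1", "s2", "s3", "t1", "t2", "t3", "t4", "t5",
                           "d1", "d2", "d3")

#: In the quiescent regime the bimolecular degradation coefficients are
#: inactive; the single first-order rate d takes their place.
QUIESCENT_GRADIENT_PARAMS = ("s1", "s2", "s3", "t1", "t2", "t3", "t4", "t5",
                             "d")

_PAIRED = {"d1": ("d1C", "d1N"), "d2": ("d2C", "d2N"), "d3": ("d3C", "d3N")}


def _apply(params: KineticParameters, mode: GrowthMode, name: str,
           value: float) -> tuple[KineticParameters, GrowthMode]:
    """Set one scan/gradient parameter, resolving paired and mode-owned names.

    ``t1`` refers to the uptake coefficient in the rich regime and to the
    constant uptake rate t̄1 in the poor/quiescent regimes.  ``s3`` in the
    quiescent regime refers to the overridden assembly coefficient.
    """
    if name in _PAIRED:
        kw = {k: value for k in _PAIRED[name]}
        return params.replace(**kw), mode
    if name == "t1" and mode.regime != "rich":
        return params, GrowthMode(mode.regime, t1_bar_const=value,
                                  d_quiescent=mode.d_quiescent,
                                  s3_override=mode.s3_override)
    if name == "s3" and mode.regime == "quiescent":
        return params, GrowthMode(mode.regime,
                                  t1_bar_const=mode.t1_bar_const,
                                  d_quiescent=mode.d_quiescent,
                                  s3_override=value)
    if name == "d" and mode.regime == "quiescent":
        return params, GrowthMode(mode.regime,
                                  t1_bar_const=mode.t1_bar_const,
                                  d_quiescent=value,
                                  s3_override=mode.s3_override)
    return params.replace(**{name: value}), mode


def _baseline(params: KineticParameters, mode: GrowthMode, name: str) -> float:
    if name in _PAIRED:
        return getattr(params, _PAIRED[name][0])
    if name == "t1" and mode.regime != "rich":
        return mode.t1_bar_const
    if name == "s3" and mode.regime == "quiescent":
        return mode.s3_override
    if name == "d" and mode.regime == "quiescent":
        return mode.d_quiescent
    return getattr(params, name)


@dataclass
class ScanResult:
    """Response surface of λ and steady C/N over a parameter grid."""

    param: str | tuple[str, str]
    grid: np.ndarray                    # (n,) or (n, 2)
    growth_rate: np.ndarray
    cn: np.ndarray
    rp_r: np.ndarray | None = None
    ok: np.ndarray | None = None        # convergence flag per point
    regime: str = "rich"

    def to_frame(self) -> pd.DataFrame:
        if isinstance(self.param, tuple):
            df = pd.DataFrame(self.grid, columns=list(self.param))
        else:
            df = pd.DataFrame({self.param: self.grid})
        df["growth_rate"] = self.growth_rate
        df["cn_ratio"] = self.cn
        if self.rp_r is not None:
            df["rp_r"] = self.rp_r
        if self.ok is not None:
            df["converged"] = self.ok
        return df


def _simulate_point(initial: CellState, params: KineticParameters,
                    mode: GrowthMode, n_generations: int,
                    discard_cycles: int, max_cycle_hours: float
                    ) -> tuple[float, float, float]:
    """(λ, steady C/N, cycle-averaged RP/R) at one parameter point."""
    traj = simulate_generations(initial, params, mode,
                                n_generations=n_generations,
                                max_cycle_hours=max_cycle_hours,
                                rtol=1e-7, atol=1e-9)
    lam = fit_growth_rate(traj, discard_cycles)
    _, cn = cn_ratio(traj)
    m = traj.cycle == traj.cycle[-1]
    rp = traj.states[m, 2] + traj.states[m, 5]
    r = traj.states[m, 3] + traj.states[m, 6]
    rp_r = float(np.mean(rp / r))
    return lam, cn.steady, rp_r


def scan(param: str | tuple[str, str], grid, initial: CellState,
         params: KineticParameters, mode: GrowthMode | None = None,
         n_generations: int = 7, discard_cycles: int = 3,
         max_cycle_hours: float = 50.0, constraint: str | None = None
         ) -> ScanResult:
    """Sweep one parameter (or a 2-D (t4, t5)-style pair) and record λ, C/N.

    ``constraint="fixed_total"`` (1-D scans of s1 or s2 only) holds s1+s2
    at its baseline value while the scanned coefficient varies, so the
    sweep explores the ribosomal/non-ribosomal synthesis allocation.
    Non-convergent points are flagged in ``ok`` rather than raised.
    """
    mode = mode or GrowthMode.rich()
    if constraint not in (None, "fixed_total"):
        raise ValueError(f"unknown constraint {constraint!r}")
    is_2d = isinstance(param, tuple)
    grid = np.asarray(grid, dtype=float)
    if np.any(grid <= 0):
        raise ValueError("scan grid must be positive")
    points = grid if is_2d else grid[:, None]
    names = param if is_2d else (param,)
    total = params.s1 + params.s2 if constraint == "fixed_total" else None

    lams = np.full(len(points), np.nan)
    cns = np.full(len(points), np.nan)
    rprs = np.full(len(points), np.nan)
    ok = np.zeros(len(points), dtype=bool)
    for i, pt in enumerate(points):
        p_i, m_i = params, mode
        for name, value in zip(names, pt):
            p_i, m_i = _apply(p_i, m_i, name, value)
        if constraint == "fixed_total":
            other = "s2" if param == "s1" else "s1"
            if pt[0] >= total:
                continue
            p_i = p_i.replace(**{other: total - pt[0]})
        try:
            lams[i], cns[i], rprs[i] = _simulate_point(
                initial, p_i, m_i, n_generations, discard_cycles,
                max_cycle_hours)
            ok[i] = True
        except Exception:
            ok[i] = False
    return ScanResult(param=param, grid=grid, growth_rate=lams, cn=cns,
                      rp_r=rprs, ok=ok, regime=mode.regime)


def rp_r_curve(tuning: str, grid, initial: CellState,
               params: KineticParameters, mode: GrowthMode | None = None,
               **kwargs) -> ScanResult:
    """λ as a function of the steady RP/R ratio, tuned via d3, s3 or t2.

    The free-ribosomal-protein to mature-ribosome ratio is a proxy for
    assembly imbalance (e.g. aneuploidy); it cannot be set directly, so it
    is swept through a parameter that controls it.
    """
    if tuning not in ("d3", "s3", "t2"):
        raise ValueError("tuning parameter must be one of d3, s3, t2")
    return scan(tuning, grid, initial, params, mode, **kwargs)


@dataclass
class GradientProfile:
    """Unit-length normalized-parameter sensitivity vector."""

    response: str                       # "growth_rate" | "cn" | "steady_volume"
    params: tuple[str, ...]
    components: np.ndarray              # signed, unit Euclidean norm
    raw: np.ndarray                     # d(response)/d(normalized parameter)
    regime: str
    step: float

    @property
    def signs(self) -> np.ndarray:
        return np.sign(self.raw)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"parameter": self.params,
                             "component": self.components,
                             "raw_gradient": self.raw})

    def by_param(self) -> dict[str, float]:
        return dict(zip(self.params, self.components))


def normalized_gradient(initial: CellState, params: KineticParameters,
                        mode: GrowthMode | None = None,
                        response: str = "growth_rate",
                        param_names: tuple[str, ...] = DEFAULT_GRADIENT_PARAMS,
                        rel_step: float = 0.01,
                        n_generations: int = 7, discard_cycles: int = 3,
                        horizon: float = 200.0) -> GradientProfile:
    """Central-difference gradient of a response w.r.t. normalized parameters.

    Each parameter is perturbed by ±``rel_step`` of its baseline value;
    the derivative is taken with respect to s̄ = s/s⁰ so components are
    comparable across parameters of different units, then the vector is
    scaled to unit length.  For the quiescent regime the responses are the
    steady-state volume or C/N ratio; for growing regimes λ or C/N.
    """
    mode = mode or GrowthMode.rich()
    quiescent = mode.regime == "quiescent"
    if quiescent and param_names is DEFAULT_GRADIENT_PARAMS:
        param_names = QUIESCENT_GRADIENT_PARAMS
    if quiescent and response == "growth_rate":
        raise ValueError("growth_rate is not defined at a quiescent fixed "
                         "point; use steady_volume or cn")
    if response not in ("growth_rate", "cn", "steady_volume"):
        raise ValueError(f"unknown response {response!r}")

    def evaluate(p, m) -> float:
        if quiescent:
            _, summ = quiescent_steady_state(initial, p, m, horizon=horizon)
            return summ.steady_volume if response == "steady_volume" \
                else summ.cn_steady
        lam, cn, _ = _simulate_point(initial, p, m, n_generations,
                                     discard_cycles, max_cycle_hours=50.0)
        return lam if response == "growth_rate" else cn

    raw = np.zeros(len(param_names))
    for i, name in enumerate(param_names):
        x0 = _baseline(params, mode, name)
        hi = evaluate(*_apply(params, mode, name, x0 * (1 + rel_step)))
        lo = evaluate(*_apply(params, mode, name, x0 * (1 - rel_step)))
        # d(response)/d(x/x0) by central differences
        raw[i] = (hi - lo) / (2 * rel_step)
    norm = np.linalg.norm(raw)
    if norm == 0:
        raise ValueError("gradient vanished; increase rel_step")
    return GradientProfile(response=response, params=tuple(param_names),
                           components=raw / norm, raw=raw,
                           regime=mode.regime, step=rel_step)
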