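"""Stochastic population simulation with a volume-dependent division hazard.

Each cell in the ensemble advances by the deterministic growth kinetics;
division is stochastic, driven by the hazard k(V) = ω(V)/(1 − CDF_ω(V))
derived from a division-volume distribution ω, and applied per step as a
survival probability over the volume increment traversed.  Dividing cells
split into two daughters with a noisy symmetric fraction applied
identically to every molecular pool.  The non-ribosomal proteome can be
resolved into two species whose synthesis coefficients may be constant or
regulated by the partner species' abundance, which reshapes the joint
(P1, P2) distribution across the population.

This module doubles as the package's synthetic single-cell data generator:
ensemble snapshots are plain tables, one row per cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.stats import linregress, norm

from .model import GrowthMode, KineticParameters, CellState
from .params import OrganismFixture

__all__ = [
    "DivisionRule",
    "RegulationSpec",
    "PopulationEnsemble",
    "PopulationSummary",
    "division_hazard",
    "sample_division_deltas",
    "step_population",
    "run_population",
    "POP_FIELDS",
]

#: Column order of the population state table (two non-ribosomal species).
POP_FIELDS = ("A_C", "P1_C", "P2_C", "RP_C", "R_C",
              "P1_N", "P2_N", "RP_N", "R_N")


@dataclass(frozen=True)
class DivisionRule:
    """Division-volume distribution ω(V) and partition-noise scale.

    ``pdf`` is any density over cytoplasmic volume (μm^3); its CDF is
    precomputed by trapezoidal quadrature on a cached grid over
    ``support``.  ``sigma_div`` is the standard deviation of the relative
    volume difference between the two daughters, ΔV_new/V_div.
    """

    grid: np.ndarray
    pdf_grid: np.ndarray
    cdf_grid: np.ndarray
    sigma_div: float = 0.125

    @classmethod
    def from_pdf(cls, pdf, support: tuple[float, float],
                 sigma_div: float = 0.125, n_grid: int = 2048
                 ) -> "DivisionRule":
        lo, hi = support
        if not hi > lo >= 0:
            raise ValueError("support must satisfy 0 <= lo < hi")
        grid = np.linspace(lo, hi, n_grid)
        try:
            pdf_grid = np.asarray(pdf(grid), dtype=float)
        except (TypeError, ValueError):
            pdf_grid = np.asarray([pdf(v) for v in grid], dtype=float)
        pdf_grid = np.clip(pdf_grid, 0, None)
        cdf_grid = cumulative_trapezoid(pdf_grid, grid, initial=0.0)
        total = cdf_grid[-1]
        if not np.isclose(total, 1.0, atol=5e-3):
            raise ValueError(f"pdf integrates to {total:.4f}, not 1")
        return cls(grid=grid, pdf_grid=pdf_grid / total,
                   cdf_grid=cdf_grid / total, sigma_div=sigma_div)

    @classmethod
    def normal(cls, mean: float, cv: float = 0.1,
               sigma_div: float = 0.125) -> "DivisionRule":
        """Normal ω truncated to positive support (the default choice).

        With ``mean = 2 * V_C(birth)`` this reproduces division at volume
        doubling in the zero-noise limit.
        """
        sd = cv * mean
        lo = max(mean - 6 * sd, 0.0)
        hi = mean + 6 * sd
        dist = norm(loc=mean, scale=sd)
        mass = dist.cdf(hi) - dist.cdf(lo)
        return cls.from_pdf(lambda v: dist.pdf(v) / mass, (lo, hi),
                            sigma_div=sigma_div)


def division_hazard(V, rule: DivisionRule):
    """Hazard k(V) = ω(V)/(1 − CDF_ω(V)), per μm^3 of volume growth.

    Zero below ω's support; infinite once essentially all division mass
    has been passed (certain-division regime).
    """
    V = np.asarray(V, dtype=float)
    pdf = np.interp(V, rule.grid, rule.pdf_grid, left=0.0, right=0.0)
    cdf = np.interp(V, rule.grid, rule.cdf_grid, left=0.0, right=1.0)
    surv = 1.0 - cdf
    eps = 1e-12
    out = np.where(surv > eps, pdf / np.maximum(surv, eps), np.inf)
    out = np.where(V >= rule.grid[-1], np.inf, out)
    return out if out.ndim else float(out)


def sample_division_deltas(rng: np.random.Generator, n: int,
                           sigma_div: float = 0.125) -> np.ndarray:
    """Relative daughter-volume differences δ = ΔV_new/V_div ~ N(0, σ).

    δ is truncated to (−1, 1) by resampling so both daughter fractions
    (1±δ)/2 remain in (0, 1).
    """
    delta = rng.normal(0.0, sigma_div, size=n)
    bad = np.abs(delta) >= 1.0
    while np.any(bad):
        delta[bad] = rng.normal(0.0, sigma_div, size=int(bad.sum()))
        bad = np.abs(delta) >= 1.0
    return delta


@dataclass(frozen=True)
class RegulationSpec:
    """Synthesis-coefficient structure of the two non-ribosomal species.

    Species 2's coefficient is the affine form ``s12_const + s12_slope*P1``
    clamped at zero (P1 in 10^6 molecules); with ``n_species=1`` the model
    reduces exactly to the single-species kinetics.
    """

    n_species: int = 1
    s11: float | None = None            # None: use params.s1
    s12_const: float = 0.0
    s12_slope: float = 0.0

    @classmethod
    def single(cls) -> "RegulationSpec":
        return cls(n_species=1)

    @classmethod
    def equal(cls, s: float = 77.5) -> "RegulationSpec":
        return cls(2, s11=s, s12_const=s)

    @classmethod
    def unequal(cls, s11: float = 65.0, s12: float = 90.0
                ) -> "RegulationSpec":
        return cls(2, s11=s11, s12_const=s12)

    @classmethod
    def enhance(cls, s11: float = 65.0, slope: float = 6.0
                ) -> "RegulationSpec":
        """P1 enhances P2 synthesis: s12 = slope * P1."""
        return cls(2, s11=s11, s12_slope=slope)

    @classmethod
    def suppress(cls, s11: float = 65.0, const: float = 145.0,
                 slope: float = -5.0) -> "RegulationSpec":
        """P1 suppresses P2 synthesis: s12 = const + slope*P1, clamped ≥ 0."""
        return cls(2, s11=s11, s12_const=const, s12_slope=slope)

    def coefficients(self, P1: np.ndarray, params: KineticParameters
                     ) -> tuple[np.ndarray, np.ndarray]:
        s11 = np.full_like(P1, self.s11 if self.s11 is not None else params.s1)
        if self.n_species == 1:
            return s11, np.zeros_like(P1)
        s12 = np.clip(self.s12_const + self.s12_slope * P1, 0.0, None)
        return s11, s12


@dataclass
class PopulationEnsemble:
    """A set of cells, their ages and lineages, and the division log."""

    states: np.ndarray                  # (n_cells, 9) in POP_FIELDS order
    age: np.ndarray
    lineage: np.ndarray
    time: float
    rng: np.random.Generator
    params: KineticParameters
    mode: GrowthMode
    n_divisions: int = 0
    division_deltas: list = field(default_factory=list)
    division_volumes: list = field(default_factory=list)
    subsample_factor: float = 1.0

    @property
    def n_cells(self) -> int:
        return self.states.shape[0]

    def volumes(self) -> tuple[np.ndarray, np.ndarray]:
        V_C = self.states[:, 1:5].sum(axis=1) / self.params.r1
        V_N = self.states[:, 5:9].sum(axis=1) / self.params.r2
        return V_C, V_N

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(POP_FIELDS))
        V_C, V_N = self.volumes()
        df["V_C"] = V_C
        df["V_N"] = V_N
        df["age"] = self.age
        df["lineage"] = self.lineage
        return df


def _population_rhs(Y: np.ndarray, params: KineticParameters,
                    mode: GrowthMode, reg: RegulationSpec) -> np.ndarray:
    """Two-species growth kinetics, vectorised over cells (rows of Y).

    Both species share the transport and degradation coefficients of the
    non-ribosomal pool; regulation enters through synthesis only.  Summing
    the species recovers the single-species kinetics exactly.
    """
    p = mode.effective_params(params)
    A, P1C, P2C, RPC, RC, P1N, P2N, RPN, RN = Y.T
    PC = P1C + P2C
    PN = P1N + P2N
    V_C = (PC + RPC + RC) / p.r1
    V_N = (PN + RPN + RN) / p.r2
    f_C = V_C / (V_C + V_N)
    s11, s12 = reg.coefficients(P1C, p)

    aa_flux = A * RC / V_C
    t1_bar = p.t1 * PC if mode.regime == "rich" else mode.t1_bar_const
    net_P1 = (p.t4 * P1C / V_C - p.t5 * P1N / V_N) * PC
    net_P2 = (p.t4 * P2C / V_C - p.t5 * P2N / V_N) * PC
    rp_in = p.t2 * RPC * PC / V_C
    r_out = p.t3 * RN * PC / V_N

    dA = f_C * t1_bar - (s11 + s12 + p.s2) * aa_flux
    dP1C = s11 * aa_flux / p.n1 - net_P1
    dP2C = s12 * aa_flux / p.n1 - net_P2
    dRPC = p.s2 * aa_flux / p.n2 - rp_in
    dRC = r_out
    dP1N = net_P1
    dP2N = net_P2
    dRPN = rp_in - p.s3 * RPN
    dRN = p.s3 / p.n3 * RPN - r_out

    if mode.regime == "quiescent":
        d = mode.d_quiescent
        dA += f_C * (p.n1 * d * (PC + PN) + p.n2 * d * (RPC + RPN))
        dP1C -= d * P1C
        dP2C -= d * P2C
        dP1N -= d * P1N
        dP2N -= d * P2N
        dRPC += p.n3 * d * RC - d * RPC
        dRPN += p.n3 * d * RN - d * RPN
        dRC -= d * RC
        dRN -= d * RN
    else:
        deg_P1C = p.d1C * P1C * PC / V_C
        deg_P2C = p.d1C * P2C * PC / V_C
        deg_P1N = p.d1N * P1N * PN / V_N
        deg_P2N = p.d1N * P2N * PN / V_N
        deg_RPC = p.d2C * RPC * PC / V_C
        deg_RPN = p.d2N * RPN * PN / V_N
        dis_C = p.d3C * RC * PC / V_C
        dis_N = p.d3N * RN * PN / V_N
        dA += f_C * (p.n1 * (deg_P1C + deg_P2C + deg_P1N + deg_P2N)
                     + p.n2 * (deg_RPC + deg_RPN))
        dP1C -= deg_P1C
        dP2C -= deg_P2C
        dP1N -= deg_P1N
        dP2N -= deg_P2N
        dRPC += p.n3 * dis_C - deg_RPC
        dRPN += p.n3 * dis_N - deg_RPN
        dRC -= dis_C
        dRN -= dis_N
    return np.stack([dA, dP1C, dP2C, dRPC, dRC, dP1N, dP2N, dRPN, dRN],
                    axis=1)


def step_population(ensemble: PopulationEnsemble, rule: DivisionRule,
                    reg: RegulationSpec, dt: float = 0.02
                    ) -> PopulationEnsemble:
    """Advance every cell by one explicit-Euler step and apply divisions.

    Each cell divides during the step with probability
    1 − exp(−k(V_C)·ΔV_C), where ΔV_C is the cytoplasmic volume increment
    traversed in the step; daughters receive fractions (1±δ)/2 of every
    pool, δ ~ N(0, σ_div) truncated to (−1, 1), and both are retained.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    ens = ensemble
    Y = ens.states
    V_C0 = Y[:, 1:5].sum(axis=1) / ens.params.r1
    Y_new = Y + dt * _population_rhs(Y, ens.params, ens.mode, reg)
    if np.any(Y_new < 0):
        # protect against Euler overshoot of tiny pools
        if np.any(Y_new < -1e-6 * np.maximum(Y, 1.0)):
            raise FloatingPointError("negative molecular count in Euler step")
        Y_new = np.clip(Y_new, 0.0, None)
    V_C1 = Y_new[:, 1:5].sum(axis=1) / ens.params.r1
    dV = np.clip(V_C1 - V_C0, 0.0, None)
    k = np.asarray(division_hazard(V_C1, rule))
    p_div = np.where(np.isinf(k), 1.0, 1.0 - np.exp(-k * dV))
    u = ens.rng.uniform(size=Y_new.shape[0])
    dividing = u < p_div

    age = ens.age + dt
    n_div = int(dividing.sum())
    deltas = list(ens.division_deltas)
    volumes = list(ens.division_volumes)
    if n_div:
        delta = sample_division_deltas(ens.rng, n_div, rule.sigma_div)
        deltas.extend(delta.tolist())
        volumes.extend(V_C1[dividing].tolist())
        mothers = Y_new[dividing]
        f = (1.0 + delta)[:, None] / 2.0
        d1 = mothers * f
        d2 = mothers * (1.0 - f)
        Y_new = np.vstack([Y_new[~dividing], d1, d2])
        lin = ens.lineage
        age = np.concatenate([age[~dividing],
                              np.zeros(n_div), np.zeros(n_div)])
        lineage = np.concatenate([lin[~dividing], lin[dividing],
                                  lin[dividing]])
    else:
        lineage = ens.lineage
    return replace(ens, states=Y_new, age=age, lineage=lineage,
                   time=ens.time + dt, n_divisions=ens.n_divisions + n_div,
                   division_deltas=deltas, division_volumes=volumes)


@dataclass
class PopulationSummary:
    """Distribution summaries of a final ensemble."""

    n_cells: int
    n_divisions: int
    time: float
    volume_mean: float
    volume_cv: float
    volume_hist: tuple[np.ndarray, np.ndarray]
    division_delta_std: float | None
    slope: float | None = None          # P2 vs P1 regression slope
    intercept: float | None = None
    r_value: float | None = None
    linear_sse: float | None = None
    quadratic_sse: float | None = None
    curvature: float | None = None      # quadratic coefficient of a degree-2 fit
    better_fit: str | None = None

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "volume_hist"}
        counts, edges = self.volume_hist
        d["volume_hist_counts"] = counts.tolist()
        d["volume_hist_edges"] = edges.tolist()
        return d


def _proteome_fits(P1: np.ndarray, P2: np.ndarray) -> dict:
    res = linregress(P1, P2)
    # equal-dof candidate laws: a + b·P1 versus a + b·P1² (within one
    # cycle the regulated species follows offset-plus-quadratic exactly)
    X_lin = np.column_stack([np.ones_like(P1), P1])
    X_quad = np.column_stack([np.ones_like(P1), P1 ** 2])
    sse = []
    for X in (X_lin, X_quad):
        coef, *_ = np.linalg.lstsq(X, P2, rcond=None)
        sse.append(float(np.sum((P2 - X @ coef) ** 2)))
    lin_sse, quad_sse = sse
    curvature = float(np.polyfit(P1, P2, 2)[0])
    return {"slope": float(res.slope), "intercept": float(res.intercept),
            "r_value": float(res.rvalue), "linear_sse": lin_sse,
            "quadratic_sse": quad_sse, "curvature": curvature,
            "better_fit": "quadratic" if quad_sse < lin_sse else "linear"}


def initialize_ensemble(fixture_state: CellState, params: KineticParameters,
                        mode: GrowthMode, n_cells: int,
                        rng: np.random.Generator,
                        reg: RegulationSpec) -> PopulationEnsemble:
    """N cells at uniformly spread sizes between 1× and 2× the newborn state.

    One shared uniform scale factor per cell multiplies every pool, so the
    initial composition is preserved and only cell size varies.  With two
    species the non-ribosomal pool starts split evenly between them.
    """
    base = fixture_state.as_array()
    if reg.n_species == 2:
        y9 = np.array([base[0], base[1] / 2, base[1] / 2, base[2], base[3],
                       base[4] / 2, base[4] / 2, base[5], base[6]])
    else:
        y9 = np.array([base[0], base[1], 0.0, base[2], base[3],
                       base[4], 0.0, base[5], base[6]])
    scale = rng.uniform(1.0, 2.0, size=n_cells)
    states = y9[None, :] * scale[:, None]
    return PopulationEnsemble(
        states=states, age=np.zeros(n_cells),
        lineage=np.arange(n_cells), time=0.0, rng=rng,
        params=params, mode=mode)


def run_population(fixture: OrganismFixture, regime: str = "rich",
                   reg: RegulationSpec | None = None,
                   n_cells: int = 200, horizon: float = 12.0,
                   dt: float = 0.02, seed: int = 0,
                   rule: DivisionRule | None = None,
                   max_cells: int = 2000
                   ) -> tuple[PopulationEnsemble, PopulationSummary]:
    """Evolve an ensemble to its steady size/proteome distribution.

    The population grows roughly exponentially; whenever it exceeds
    ``max_cells`` it is randomly subsampled back to half that, with the
    cumulative factor recorded on the ensemble.
    """
    reg = reg or RegulationSpec.single()
    mode = fixture.mode(regime)
    params = fixture.parameters
    if rule is None:
        V_C_birth = (fixture.initial_state.P_C + fixture.initial_state.RP_C
                     + fixture.initial_state.R_C) / params.r1
        rule = DivisionRule.normal(mean=2.0 * V_C_birth)
    rng = np.random.default_rng(seed)
    ens = initialize_ensemble(fixture.initial_state, params, mode,
                              n_cells, rng, reg)
    n_steps = int(round(horizon / dt))
    for _ in range(n_steps):
        ens = step_population(ens, rule, reg, dt)
        if ens.n_cells > max_cells:
            keep = ens.rng.choice(ens.n_cells, size=max_cells // 2,
                                  replace=False)
            factor = ens.n_cells / keep.size
            ens = replace(ens, states=ens.states[keep], age=ens.age[keep],
                          lineage=ens.lineage[keep],
                          subsample_factor=ens.subsample_factor * factor)

    V_C, V_N = ens.volumes()
    V = V_C + V_N
    counts, edges = np.histogram(V, bins=40)
    summary = PopulationSummary(
        n_cells=ens.n_cells, n_divisions=ens.n_divisions, time=ens.time,
        volume_mean=float(V.mean()), volume_cv=float(V.std() / V.mean()),
        volume_hist=(counts, edges),
        division_delta_std=(float(np.std(ens.division_deltas))
                            if ens.division_deltas else None))
    if reg.n_species == 2:
        fits = _proteome_fits(ens.states[:, 1], ens.states[:, 2])
        for k, v in fits.items():
            setattr(summary, k, v)
    return ens, summary
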