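"""Core state, parameters, volume law, and governing fluxes.

The model tracks seven molecular pools of a eukaryotic cell — the free
cytoplasmic amino-acid pool, non-ribosomal proteins, free ribosomal
proteins and mature ribosomes, each resolved into cytoplasmic and nuclear
compartments.  Ribosomal proteins are synthesised in the cytoplasm,
imported into the nucleus, assembled n3-at-a-time into mature ribosomes,
and the ribosomes are exported back to the cytoplasm where they carry out
translation.  Compartment volumes are slaved to macromolecule counts
through a fixed conversion factor (a consequence of ionic/osmotic
homeostasis), so the cell and nuclear volumes are derived quantities,
never independent state.

Units throughout: molecular counts in units of 10^6 molecules, volumes in
μm^3, time in hours.  With this convention the shipped parameter tables
apply verbatim.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

__all__ = [
    "STATE_FIELDS",
    "CellState",
    "KineticParameters",
    "GrowthMode",
    "FluxBreakdown",
    "DegenerateVolumeError",
    "NumericalStateError",
    "compartment_volumes",
    "synthesis_fluxes",
    "transport_fluxes",
    "degradation_fluxes",
    "rhs",
    "rhs_array",
]

#: Canonical ordering of the state vector.
STATE_FIELDS = ("A_C", "P_C", "RP_C", "R_C", "P_N", "RP_N", "R_N")


class DegenerateVolumeError(ValueError):
    """A compartment volume is zero where the kinetics divide by it."""


class NumericalStateError(RuntimeError):
    """A derivative or state became non-finite during integration."""


@dataclass(frozen=True)
class CellState:
    """Molecular counts of one cell, in units of 10^6 molecules.

    Attributes
    ----------
    A_C : cytoplasmic free amino acids
    P_C, P_N : cytoplasmic / nuclear non-ribosomal proteins
    RP_C, RP_N : cytoplasmic / nuclear free ribosomal proteins
    R_C, R_N : cytoplasmic / nuclear mature ribosomes
    """

    A_C: float
    P_C: float
    RP_C: float
    R_C: float
    P_N: float
    RP_N: float
    R_N: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in STATE_FIELDS], dtype=float)

    @classmethod
    def from_array(cls, y: np.ndarray) -> "CellState":
        return cls(**dict(zip(STATE_FIELDS, map(float, y))))

    def validate(self) -> None:
        y = self.as_array()
        if not np.all(np.isfinite(y)):
            raise NumericalStateError(f"non-finite state: {self}")
        if np.any(y < 0):
            raise ValueError(f"negative molecular count in state: {self}")

    def replace(self, **kwargs) -> "CellState":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class KineticParameters:
    """Rate coefficients, stoichiometries and count→volume conversion.

    s1, s2 : synthesis coefficients of non-ribosomal / ribosomal protein
        (μm^3/10^6 h); s3 : ribosome assembly coefficient (1/h).
    n1, n2 : amino acids per non-ribosomal / ribosomal protein; n3 :
        ribosomal proteins per mature ribosome.
    t1 : amino-acid import coefficient in the rich regime (1/h);
        t2–t5 : nuclear-envelope transport coefficients (μm^3/10^6 h) for
        ribosomal-protein import, ribosome export, and non-ribosomal
        protein import/export.
    d1C/d1N, d2C/d2N, d3C/d3N : degradation (non-ribosomal, ribosomal) and
        ribosome-disassembly coefficients per compartment (μm^3/10^6 h).
    r1, r2 : macromolecule-count-to-volume conversion factors for the
        cytoplasm and nucleus (10^6/μm^3).
    """

    s1: float
    s2: float
    s3: float
    n1: float
    n2: float
    n3: float
    t1: float
    t2: float
    t3: float
    t4: float
    t5: float
    d1C: float
    d1N: float
    d2C: float
    d2N: float
    d3C: float
    d3N: float
    r1: float
    r2: float

    def validate(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"parameter {f.name} must be positive, got {v}")

    def replace(self, **kwargs) -> "KineticParameters":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "KineticParameters":
        names = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: float(v) for k, v in d.items() if k in names})


@dataclass(frozen=True)
class GrowthMode:
    """Growth regime and its mode-specific parameter overrides.

    rich : amino-acid uptake is cargo-saturated, t̄1 = t1·P_C.
    poor : uptake is transporter-saturated, t̄1 = t1_bar_const.
    quiescent : constant uptake plus first-order degradation of every pool
        at rate ``d_quiescent`` and a reduced assembly coefficient
        ``s3_override``.
    """

    regime: str = "rich"
    t1_bar_const: float | None = None
    d_quiescent: float | None = None
    s3_override: float | None = None

    def __post_init__(self):
        if self.regime not in ("rich", "poor", "quiescent"):
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.regime in ("poor", "quiescent") and self.t1_bar_const is None:
            raise ValueError(f"{self.regime} regime requires t1_bar_const")
        if self.regime == "quiescent":
            if not (self.d_quiescent and self.d_quiescent > 0):
                raise ValueError("quiescent regime requires d_quiescent > 0")
            if not (self.s3_override and self.s3_override > 0):
                raise ValueError("quiescent regime requires s3_override > 0")

    @classmethod
    def rich(cls) -> "GrowthMode":
        return cls("rich")

    @classmethod
    def poor(cls, t1_bar_const: float) -> "GrowthMode":
        return cls("poor", t1_bar_const=t1_bar_const)

    @classmethod
    def quiescent(cls, t1_bar_const: float, d_quiescent: float,
                  s3_override: float) -> "GrowthMode":
        return cls("quiescent", t1_bar_const=t1_bar_const,
                   d_quiescent=d_quiescent, s3_override=s3_override)

    def effective_params(self, params: KineticParameters) -> KineticParameters:
        """Parameters with the quiescent s3 override applied."""
        if self.regime == "quiescent":
            return params.replace(s3=self.s3_override)
        return params


@dataclass(frozen=True)
class FluxBreakdown:
    """One derivative contribution per state field (10^6 molecules/h)."""

    A_C: float = 0.0
    P_C: float = 0.0
    RP_C: float = 0.0
    R_C: float = 0.0
    P_N: float = 0.0
    RP_N: float = 0.0
    R_N: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in STATE_FIELDS], dtype=float)

    def __add__(self, other: "FluxBreakdown") -> "FluxBreakdown":
        return FluxBreakdown(*(self.as_array() + other.as_array()))


def compartment_volumes(state: CellState,
                        params: KineticParameters) -> tuple[float, float]:
    """Cytoplasmic and nuclear volumes implied by macromolecule counts.

    V_C = (P_C + R_C + RP_C)/r1 and V_N = (P_N + R_N + RP_N)/r2: each
    compartment's water content tracks its impermeable-macromolecule
    count, so volume is proportional to the protein + ribosome number.
    Free amino acids equilibrate across the envelope and do not count.
    """
    V_C = (state.P_C + state.R_C + state.RP_C) / params.r1
    V_N = (state.P_N + state.R_N + state.RP_N) / params.r2
    return float(V_C), float(V_N)


def _require_volumes(state: CellState, params: KineticParameters,
                     need_c: bool = True, need_n: bool = True) -> tuple[float, float]:
    V_C, V_N = compartment_volumes(state, params)
    if need_c and V_C <= 0:
        raise DegenerateVolumeError("cytoplasmic volume is zero")
    if need_n and V_N <= 0:
        raise DegenerateVolumeError("nuclear volume is zero")
    return V_C, V_N


def synthesis_fluxes(state: CellState,
                     params: KineticParameters) -> FluxBreakdown:
    """Translation and ribosome-assembly contributions.

    Translation is a sequential assembly carried out by cytoplasmic
    ribosomes, so production of each protein class is bimolecular in the
    amino-acid pool and the ribosome pool, divided by the compartment
    volume; each protein consumes n1 (or n2) amino acids.  In the nucleus
    RP_N is consumed at rate s3·RP_N and yields mature ribosomes
    n3-at-a-time.
    """
    if state.A_C * state.R_C != 0:
        V_C, _ = _require_volumes(state, params, need_n=False)
        aa_flux = state.A_C * state.R_C / V_C
    else:
        aa_flux = 0.0
    return FluxBreakdown(
        A_C=-(params.s1 + params.s2) * aa_flux,
        P_C=params.s1 * aa_flux / params.n1,
        RP_C=params.s2 * aa_flux / params.n2,
        RP_N=-params.s3 * state.RP_N,
        R_N=params.s3 / params.n3 * state.RP_N,
    )


def transport_fluxes(state: CellState, params: KineticParameters,
                     mode: GrowthMode) -> FluxBreakdown:
    """Amino-acid import and nuclear-envelope exchange.

    Carrier-mediated fluxes scale with the cytoplasmic protein pool P_C
    (transporter abundance) and the cargo concentration.  Imported amino
    acids partition between compartments by volume; only the cytoplasmic
    fraction V_C/(V_C+V_N) is tracked.  Every nuclear-envelope flux is
    antisymmetric between the two compartments.
    """
    t1_bar = (params.t1 * state.P_C if mode.regime == "rich"
              else mode.t1_bar_const)
    if not state.as_array().any():
        # empty cell: every carrier-mediated flux vanishes with its pools
        if t1_bar == 0:
            return FluxBreakdown()
        raise DegenerateVolumeError("constant uptake into a zero-volume cell")
    V_C, V_N = _require_volumes(state, params)
    net_P = (params.t4 * state.P_C / V_C
             - params.t5 * state.P_N / V_N) * state.P_C
    rp_in = params.t2 * state.RP_C * state.P_C / V_C
    r_out = params.t3 * state.R_N * state.P_C / V_N
    return FluxBreakdown(
        A_C=V_C / (V_C + V_N) * t1_bar,
        P_C=-net_P, P_N=net_P,
        RP_C=-rp_in, RP_N=rp_in,
        R_N=-r_out, R_C=r_out,
    )


def degradation_fluxes(state: CellState, params: KineticParameters,
                       mode: GrowthMode) -> FluxBreakdown:
    """Protein degradation and ribosome disassembly.

    Growing regimes: degradation is assisted by a machinery pool that
    scales with the compartment's non-ribosomal protein count, giving
    bimolecular terms (e.g. d1C·P_C²/V_C).  Disassembly of a ribosome
    returns its n3 ribosomal proteins; degraded protein is recycled to the
    amino-acid pool, of which the V_C/(V_C+V_N) fraction stays in the
    modeled cytoplasmic pool.

    Quiescent regime: proteasome/lysosome capacity is assumed saturating,
    so every degradation and disassembly term becomes first-order at the
    single rate d_quiescent while the same mass-flow structure is kept
    (disassembly still returns n3 ribosomal proteins; degraded protein is
    still recycled to amino acids).
    """
    if not state.as_array().any():
        return FluxBreakdown()
    if mode.regime == "quiescent":
        d = mode.d_quiescent
        V_C, V_N = _require_volumes(state, params)
        dis_C = d * state.R_C
        dis_N = d * state.R_N
        recycled = (params.n1 * d * (state.P_C + state.P_N)
                    + params.n2 * d * (state.RP_C + state.RP_N))
        return FluxBreakdown(
            A_C=V_C / (V_C + V_N) * recycled,
            P_C=-d * state.P_C,
            P_N=-d * state.P_N,
            RP_C=params.n3 * dis_C - d * state.RP_C,
            RP_N=params.n3 * dis_N - d * state.RP_N,
            R_C=-dis_C,
            R_N=-dis_N,
        )

    V_C, V_N = _require_volumes(state, params)
    deg_PC = params.d1C * state.P_C ** 2 / V_C
    deg_PN = params.d1N * state.P_N ** 2 / V_N
    deg_RPC = params.d2C * state.RP_C * state.P_C / V_C
    deg_RPN = params.d2N * state.RP_N * state.P_N / V_N
    dis_C = params.d3C * state.R_C * state.P_C / V_C
    dis_N = params.d3N * state.R_N * state.P_N / V_N
    recycled = params.n1 * (deg_PC + deg_PN) + params.n2 * (deg_RPC + deg_RPN)
    return FluxBreakdown(
        A_C=V_C / (V_C + V_N) * recycled,
        P_C=-deg_PC,
        P_N=-deg_PN,
        RP_C=params.n3 * dis_C - deg_RPC,
        RP_N=params.n3 * dis_N - deg_RPN,
        R_C=-dis_C,
        R_N=-dis_N,
    )


def rhs(state: CellState, params: KineticParameters,
        mode: GrowthMode) -> FluxBreakdown:
    """Full time derivative: synthesis + transport + degradation."""
    p = mode.effective_params(params)
    total = (synthesis_fluxes(state, p)
             + transport_fluxes(state, p, mode)
             + degradation_fluxes(state, p, mode))
    if not np.all(np.isfinite(total.as_array())):
        raise NumericalStateError(f"non-finite derivative at state {state}")
    return total


def rhs_array(y: np.ndarray, params: KineticParameters,
              mode: GrowthMode) -> np.ndarray:
    """Vectorised right-hand side on raw state arrays.

    ``y`` has shape (7,) or (7, n) in the field order of ``STATE_FIELDS``.
    This is the hot path used by the integrators; ``rhs`` on ``CellState``
    is the reference implementation and the two are cross-checked in the
    test suite.
    """
    p = mode.effective_params(params)
    A, PC, RPC, RC, PN, RPN, RN = y
    V_C = (PC + RPC + RC) / p.r1
    V_N = (PN + RPN + RN) / p.r2
    f_C = V_C / (V_C + V_N)
    with np.errstate(divide="ignore", invalid="ignore"):
        aa_flux = np.where(V_C > 0, A * RC / np.where(V_C > 0, V_C, 1.0), 0.0)
        t1_bar = p.t1 * PC if mode.regime == "rich" else mode.t1_bar_const
        net_P = (p.t4 * PC / V_C - p.t5 * PN / V_N) * PC
        rp_in = p.t2 * RPC * PC / V_C
        r_out = p.t3 * RN * PC / V_N

        dA = f_C * t1_bar - (p.s1 + p.s2) * aa_flux
        dPC = p.s1 * aa_flux / p.n1 - net_P
        dRPC = p.s2 * aa_flux / p.n2 - rp_in
        dRC = r_out
        dPN = net_P
        dRPN = rp_in - p.s3 * RPN
        dRN = p.s3 / p.n3 * RPN - r_out

        if mode.regime == "quiescent":
            d = mode.d_quiescent
            dA += f_C * (p.n1 * d * (PC + PN) + p.n2 * d * (RPC + RPN))
            dPC -= d * PC
            dPN -= d * PN
            dRPC += p.n3 * d * RC - d * RPC
            dRPN += p.n3 * d * RN - d * RPN
            dRC -= d * RC
            dRN -= d * RN
        else:
            deg_PC = p.d1C * PC ** 2 / V_C
            deg_PN = p.d1N * PN ** 2 / V_N
            deg_RPC = p.d2C * RPC * PC / V_C
            deg_RPN = p.d2N * RPN * PN / V_N
            dis_C = p.d3C * RC * PC / V_C
            dis_N = p.d3N * RN * PN / V_N
            dA += f_C * (p.n1 * (deg_PC + deg_PN) + p.n2 * (deg_RPC + deg_RPN))
            dPC -= deg_PC
            dPN -= deg_PN
            dRPC += p.n3 * dis_C - deg_RPC
            dRPN += p.n3 * dis_N - deg_RPN
            dRC -= dis_C
            dRN -= dis_N
    return np.stack([dA, dPC, dRPC, dRC, dPN, dRPN, dRN])
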