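"""Synthesis of the reference-tracking controllers as reaction networks.

Three closed-loop configurations are supported:

``full_ff``
    Inverse-feedforward branch (gain alpha, gain delta, Subtraction I,
    Division; 10 reactions) plus the PI feedback chain (13 reactions) and
    the process (3 reactions): 26 reactions total.  The feedforward branch
    computes ``x4 = alpha*r / (beta - delta*r)``, the exact steady-state
    inverse of the process.
``simplified_ff``
    The feedforward branch collapsed, via a first-order Taylor expansion of
    the inverse law at ``r* = 0``, to a single gain ``x4 = (alpha/beta) * r``
    (2 reactions): 18 reactions total.
``pi_only``
    The PI feedback chain alone driving the process (16 reactions); the
    feedforward input of Summation II is inert at zero.  This configuration
    demonstrates the failure mode of one-sided error computation.

The reference ``r`` and the Subtraction I source ``beta`` are clamped
species supplied as inputs at simulation time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

from .crn import CRN, combine
from .operators import (
    make_division,
    make_gain,
    make_integrator,
    make_proportional,
    make_subtraction_onesided,
    make_summation3,
)
from .plant import InversionConstants, ProcessParams, inversion_constants, make_process

__all__ = [
    "Mode",
    "ControllerConfig",
    "TaylorFF",
    "ClosedLoopCircuit",
    "ff_law",
    "taylor_ff",
    "build_full_ff",
    "build_simplified_ff",
    "build_pi_chain",
    "assemble",
    "count_reactions",
    "percent_reduction",
]

Mode = Literal["full_ff", "simplified_ff", "pi_only"]
MODES: tuple[str, ...] = ("full_ff", "simplified_ff", "pi_only")


@dataclass(frozen=True)
class ControllerConfig:
    """Controller rates and gains; defaults are the nominal design values."""

    g_Ga: float = 1.0    # feedforward gain-alpha operator rate
    g_Gd: float = 1.0    # feedforward gain-delta operator rate
    g_SbI: float = 1.0   # Subtraction I rate
    g_D: float = 1.0     # Division rate
    g_GKP: float = 1.0   # proportional operator rate
    KP: float = 0.02     # proportional gain
    KI: float = 2.5e-8   # integral gain
    g_SmI: float = 0.0004  # Summation I rate
    g_SbII: float = 3.0  # Subtraction II rate (error computation)
    g_SmII: float = 1.0  # Summation II rate (control signal)
    g_G: float = 1.0     # simplified feedforward gain operator rate

    def __post_init__(self):
        for name in self.__dataclass_fields__:
            if getattr(self, name) <= 0:
                raise ValueError(f"controller rate {name} must be > 0")

    def scaled(self, **factors: float) -> "ControllerConfig":
        """Return a copy with the named rates multiplied by the given factors."""
        return replace(
            self, **{name: getattr(self, name) * f for name, f in factors.items()}
        )


@dataclass(frozen=True)
class TaylorFF:
    """Polynomial coefficients of the inverse law expanded at ``r* = 0``."""

    Gamma1: float  # linear coefficient, alpha/beta
    Gamma2: float  # quadratic coefficient, alpha*delta/beta**2
    order: int = 2

    def __post_init__(self):
        if self.Gamma1 <= 0 or self.Gamma2 < 0:
            raise ValueError("Taylor coefficients must be positive (Gamma2 >= 0)")


def ff_law(r: float, inv: InversionConstants) -> float:
    """Exact inverse-feedforward law ``u = alpha*r / (beta - delta*r)``."""
    if r < 0:
        raise ValueError("reference must be non-negative")
    if r >= inv.feasible_max:
        raise ValueError(
            f"reference {r} is not invertible: must be below beta/delta = "
            f"{inv.feasible_max}"
        )
    return inv.alpha * r / (inv.beta - inv.delta * r)


def taylor_ff(inv: InversionConstants) -> TaylorFF:
    """Taylor coefficients of :func:`ff_law` at ``r* = 0`` (quadratic order)."""
    return TaylorFF(
        Gamma1=inv.alpha / inv.beta,
        Gamma2=inv.alpha * inv.delta / inv.beta**2,
    )


def build_full_ff(cfg: ControllerConfig, inv: InversionConstants) -> CRN:
    """Full feedforward branch: 10 reactions computing ``x4 = u(r)``.

    Cascade: gain alpha (r -> x1), gain delta (r -> x2), Subtraction I
    (beta - x2 -> x3, intermediate xs), Division (x1 / x3 -> x4).
    """
    return combine(
        make_gain(inv.alpha, cfg.g_Ga, "r", "x1", label="gain_alpha"),
        make_gain(inv.delta, cfg.g_Gd, "r", "x2", label="gain_delta"),
        make_subtraction_onesided(cfg.g_SbI, "beta", "x2", "x3", "xs", label="subtraction_I"),
        make_division(cfg.g_D, "x1", "x3", "x4", label="division"),
        clamped={"r", "beta"},
    )


def build_simplified_ff(cfg: ControllerConfig, Gamma1: float) -> CRN:
    """Simplified feedforward branch: a single gain, ``x4 = Gamma1 * r``."""
    if Gamma1 < 0:
        raise ValueError("Gamma1 must be >= 0")
    crn = make_gain(Gamma1, cfg.g_G, "r", "x4", label="gain_Gamma")
    return combine(crn, clamped={"r"})


def build_pi_chain(cfg: ControllerConfig) -> CRN:
    """PI feedback chain: 13 reactions.

    Subtraction II computes the (one-sided) error ``x7 = r - x6``
    (intermediate xt), the integrator and proportional operators produce x8
    and x9, Summation I merges them into x10, and Summation II merges the
    feedforward and feedback contributions into the control signal x5.
    """
    return combine(
        make_integrator(cfg.KI, "x7", "x8", label="integrator"),
        make_proportional(cfg.KP, cfg.g_GKP, "x7", "x9", label="proportional"),
        make_summation3(cfg.g_SmI, "x8", "x9", "x10", label="summation_I"),
        make_subtraction_onesided(cfg.g_SbII, "r", "x6", "x7", "xt", label="subtraction_II"),
        make_summation3(cfg.g_SmII, "x4", "x10", "x5", label="summation_II"),
        clamped={"r"},
    )


#: Wiring map common to all modes.
WIRING = {
    "reference": "r",
    "control": "x5",
    "output": "x6",
    "ff_out": "x4",
    "pi_out": "x10",
    "error": "x7",
}


@dataclass
class ClosedLoopCircuit:
    """Assembled controller + process network with wiring metadata."""

    crn: CRN
    mode: str
    cfg: ControllerConfig
    params: ProcessParams
    retroactivity: bool
    blocks: dict[str, int]
    wiring: dict[str, str] = field(default_factory=lambda: dict(WIRING))

    @property
    def reaction_count(self) -> int:
        return self.crn.n_reactions

    @property
    def inv(self) -> InversionConstants:
        return inversion_constants(self.params)

    def initial_state(self) -> dict[str, float]:
        """Unexcited initial condition: all species zero, enzyme at xT."""
        return {"xe": self.params.xT}

    def inputs(self, reference) -> dict[str, object]:
        """Clamped-species input map for a given reference (value or callable)."""
        ins: dict[str, object] = {"r": reference}
        if "beta" in self.crn.clamped:
            ins["beta"] = self.inv.beta
        return ins


def assemble(
    mode: Mode,
    cfg: ControllerConfig | None = None,
    params: ProcessParams | None = None,
    *,
    retroactivity: bool = False,
) -> ClosedLoopCircuit:
    """Wire controller and process into a closed loop.

    Reaction counts: 26 (``full_ff``), 18 (``simplified_ff``), 16
    (``pi_only``).  With ``retroactivity=True`` the process consumes the
    control species x5 instead of reading a buffered copy, adding the
    ``-kr1*x5*xe`` term to the Summation II ODE.
    """
    cfg = cfg or ControllerConfig()
    params = params or ProcessParams()
    inv = inversion_constants(params)

    blocks: dict[str, int] = {}
    parts: list[CRN] = []
    if mode == "full_ff":
        ff = build_full_ff(cfg, inv)
        parts.append(ff)
        blocks["feedforward"] = ff.n_reactions
    elif mode == "simplified_ff":
        ff = build_simplified_ff(cfg, taylor_ff(inv).Gamma1)
        parts.append(ff)
        blocks["feedforward"] = ff.n_reactions
    elif mode == "pi_only":
        blocks["feedforward"] = 0
    else:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")

    pi = build_pi_chain(cfg)
    process = make_process(params, inp="x5", out="x6", consume_input=retroactivity)
    parts += [pi, process]
    blocks["pi_feedback"] = pi.n_reactions
    blocks["process"] = process.n_reactions

    crn = combine(*parts)
    return ClosedLoopCircuit(
        crn=crn,
        mode=mode,
        cfg=cfg,
        params=params,
        retroactivity=retroactivity,
        blocks=blocks,
    )


@dataclass(frozen=True)
class CountReport:
    total: int
    blocks: dict[str, int]

    def to_dict(self) -> dict:
        return {"total": self.total, "blocks": dict(self.blocks)}


def count_reactions(circuit: ClosedLoopCircuit) -> CountReport:
    """Total reaction count with a per-block breakdown."""
    return CountReport(total=circuit.reaction_count, blocks=dict(circuit.blocks))


def percent_reduction(n_before: int, n_after: int) -> int:
    """Percent reduction ``(a - b)/a * 100`` rounded to the nearest integer."""
    if n_before <= 0:
        raise ValueError("n_before must be positive")
    return round(100.0 * (n_before - n_after) / n_before)
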