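"""Compilation of abstract reactions into DNA strand-displacement programs.

Each unimolecular source reaction ``X -> products`` (rate k) becomes two
implementation steps with fresh auxiliary species G, O, T:

    X + G -> O          (rate q, with q * C_max = k)
    O + T -> products   (rate q_max)

Each bimolecular source reaction ``X + Y -> products`` (rate k) becomes
three steps with auxiliaries L, H, B, O, T, the first reversible:

    X + L <-> H + B     (forward q = k, backward q_max)
    Y + H -> O          (rate q_max)
    O + T -> products   (rate q_max)

Auxiliary buffers (G, T, L, B) start at ``C_max``; transient intermediates
(H, O) start at zero.  In the limit of large ``C_max`` (relative to signal
concentrations) and large ``q_max`` the implementation reproduces the source
kinetics: the binding rate constant is ``k_b = q * C_max``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .crn import CRN, Reaction, build_crn

__all__ = [
    "DSDParams",
    "CompiledReaction",
    "DSDProgram",
    "compile_unimolecular",
    "compile_bimolecular",
    "compile_crn_dsd",
    "default_dsd_params",
]

#: Buffer level below which the large-C_max operating regime is violated.
DEPLETION_FRACTION = 0.5


@dataclass(frozen=True)
class DSDParams:
    """Auxiliary concentration and maximum strand-displacement rate."""

    c_max: float
    q_max: float

    def __post_init__(self):
        if self.c_max <= 0 or self.q_max <= 0:
            raise ValueError("c_max and q_max must be > 0")


def default_dsd_params(crn: CRN, signal_scale: float = 1.0) -> DSDParams:
    """Defaults: C_max = 1e4 x signal scale, q_max = 1e3 x the largest rate."""
    max_rate = max((r.rate_value for r in crn.reactions), default=1.0) or 1.0
    return DSDParams(c_max=1e4 * signal_scale, q_max=1e3 * max_rate)


@dataclass(frozen=True)
class CompiledReaction:
    """Implementation steps and auxiliaries for one source reaction."""

    source: Reaction
    steps: tuple[Reaction, ...]
    auxiliaries: dict[str, float]  # name -> initial concentration
    q: float
    k_b: float


def _expand(reactants: dict[str, int]) -> list[str]:
    out: list[str] = []
    for name, coeff in reactants.items():
        out.extend([name] * coeff)
    return out


def compile_unimolecular(rxn: Reaction, params: DSDParams, tag: str) -> CompiledReaction:
    """Two-step implementation of a unimolecular reaction."""
    if rxn.order != 1:
        raise ValueError(f"expected a unimolecular reaction, got order {rxn.order}")
    (x,) = _expand(rxn.reactants)
    G, O, T = f"G_{tag}", f"O_{tag}", f"T_{tag}"
    q = rxn.rate_value / params.c_max
    if q > params.q_max:
        raise ValueError(
            f"required partial displacement rate q={q} exceeds q_max={params.q_max}"
        )
    steps = (
        Reaction({x: 1, G: 1}, {O: 1}, f"q_{tag}", q),
        Reaction({O: 1, T: 1}, dict(rxn.products), f"qmax_{tag}", params.q_max),
    )
    aux = {G: params.c_max, O: 0.0, T: params.c_max}
    return CompiledReaction(rxn, steps, aux, q=q, k_b=q * params.c_max)


def compile_bimolecular(rxn: Reaction, params: DSDParams, tag: str) -> CompiledReaction:
    """Three-step implementation of a bimolecular reaction (first reversible)."""
    if rxn.order != 2:
        raise ValueError(f"expected a bimolecular reaction, got order {rxn.order}")
    x, y = _expand(rxn.reactants)
    L, H, B, O, T = (f"{a}_{tag}" for a in "LHBOT")
    q = rxn.rate_value
    if q > params.q_max:
        raise ValueError(
            f"required partial displacement rate q={q} exceeds q_max={params.q_max}"
        )
    steps = (
        Reaction({x: 1, L: 1}, {H: 1, B: 1}, f"q_{tag}", q),
        Reaction({H: 1, B: 1}, {x: 1, L: 1}, f"qmax_{tag}_rev", params.q_max),
        Reaction({y: 1, H: 1}, {O: 1}, f"qmax_{tag}", params.q_max),
        Reaction({O: 1, T: 1}, dict(rxn.products), f"qmax_{tag}", params.q_max),
    )
    aux = {L: params.c_max, H: 0.0, B: params.c_max, O: 0.0, T: params.c_max}
    return CompiledReaction(rxn, steps, aux, q=q, k_b=q * params.c_max)


@dataclass
class DSDProgram:
    """Full strand-displacement implementation of a reaction network."""

    compiled: tuple[CompiledReaction, ...]
    params: DSDParams
    clamped: frozenset[str] = field(default_factory=frozenset)

    @property
    def reactions(self) -> tuple[Reaction, ...]:
        return tuple(step for c in self.compiled for step in c.steps)

    @property
    def auxiliaries(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for c in self.compiled:
            out.update(c.auxiliaries)
        return out

    @property
    def n_steps(self) -> int:
        """Implementation reaction count: 2 per unimolecular, 3 per bimolecular.

        The reversible first bimolecular step counts as one reaction.
        """
        return sum(2 if c.source.order == 1 else 3 for c in self.compiled)

    @property
    def n_auxiliaries(self) -> int:
        return len(self.auxiliaries)

    def buffers(self) -> tuple[str, ...]:
        """Consumed-only auxiliary buffers (monitored for depletion)."""
        return tuple(
            name
            for name, conc in self.auxiliaries.items()
            if conc > 0 and name.split("_")[0] in ("G", "T", "L")
        )

    def to_crn(self) -> CRN:
        """Simulation network; auxiliaries are ordinary dynamic species."""
        return build_crn(self.reactions, clamped=self.clamped)

    def initial_state(self, signals: dict[str, float] | None = None) -> dict[str, float]:
        state = dict(self.auxiliaries)
        state.update(signals or {})
        return state

    def depleted_buffers(self, traj) -> list[str]:
        """Buffers that fell below half of C_max during a simulation."""
        out = []
        for name in self.buffers():
            if name in traj.species and traj[name].min() < DEPLETION_FRACTION * self.params.c_max:
                out.append(name)
        return out


def compile_crn_dsd(crn: CRN, params: DSDParams) -> DSDProgram:
    """Compile every reaction of a network; rejects other molecularities."""
    compiled = []
    for j, rxn in enumerate(crn.reactions):
        tag = str(j)
        if rxn.order == 1:
            compiled.append(compile_unimolecular(rxn, params, tag))
        elif rxn.order == 2:
            compiled.append(compile_bimolecular(rxn, params, tag))
        else:
            from .crn import format_reaction

            raise ValueError(
                f"reaction {j} ({format_reaction(rxn)}) has molecularity "
                f"{rxn.order}; only unimolecular and bimolecular reactions "
                "can be compiled"
            )
    return DSDProgram(tuple(compiled), params, clamped=crn.clamped)
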