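"""Chemical reaction networks and their compilation to mass-action ODE systems.

A reaction network is a list of :class:`Reaction` objects over named species.
Compilation produces a :class:`MassActionSystem` whose right-hand side is
``dx/dt = P f(x)``, where ``P`` is the stoichiometric matrix over the
*dynamic* (non-clamped) species and ``f`` evaluates generalised mass-action
rate laws.  Clamped species act as constant (or piecewise-constant) sources:
they contribute to reaction rates but carry no state equation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "Reaction",
    "CRN",
    "MassActionSystem",
    "Trajectory",
    "PiecewiseConstant",
    "SimulationError",
    "SteadyStateResult",
    "build_crn",
    "combine",
    "stoichiometric_matrix",
    "mass_action_rates",
    "compile_crn",
    "simulate",
    "steady_state",
]


class SimulationError(RuntimeError):
    """Raised when the ODE integrator fails; carries the last valid time."""

    def __init__(self, message: str, last_time: float | None = None):
        super().__init__(message)
        self.last_time = last_time


def _as_count_map(side: Mapping[str, int] | Iterable[str]) -> dict[str, int]:
    """Normalise a reaction side to ``{species: positive int coefficient}``."""
    if isinstance(side, Mapping):
        out = dict(side)
    else:
        out = {}
        for name in side:
            out[name] = out.get(name, 0) + 1
    for name, coeff in out.items():
        if not isinstance(name, str) or not name:
            raise ValueError(f"species names must be non-empty strings, got {name!r}")
        if not isinstance(coeff, (int, np.integer)) or coeff <= 0:
            raise ValueError(
                f"stoichiometric coefficient of {name!r} must be a positive "
                f"integer, got {coeff!r}"
            )
    return out


@dataclass(frozen=True)
class Reaction:
    """A single chemical reaction ``reactants -> products`` with a named rate.

    Parameters
    ----------
    reactants, products :
        Either a ``{species: coefficient}`` mapping or an iterable of species
        names (repetition encodes multiplicity).  Empty means the empty set.
    rate_name :
        Identifier of the rate constant (used for reporting and perturbation
        bookkeeping).
    rate_value :
        Non-negative rate constant.
    """

    reactants: Mapping[str, int]
    products: Mapping[str, int]
    rate_name: str
    rate_value: float

    def __post_init__(self):
        object.__setattr__(self, "reactants", _as_count_map(self.reactants))
        object.__setattr__(self, "products", _as_count_map(self.products))
        if not self.rate_name:
            raise ValueError("rate_name must be a non-empty identifier")
        if not math.isfinite(self.rate_value) or self.rate_value < 0:
            raise ValueError(
                f"rate constant {self.rate_name!r} must be finite and >= 0, "
                f"got {self.rate_value!r}"
            )

    @property
    def order(self) -> int:
        """Total molecularity (number of reactant molecules)."""
        return sum(self.reactants.values())

    @property
    def species(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for name in (*self.reactants, *self.products):
            seen.setdefault(name)
        return tuple(seen)

    def net_change(self, name: str) -> int:
        """Net production of *name*; catalytic appearances cancel to zero."""
        return self.products.get(name, 0) - self.reactants.get(name, 0)


@dataclass(frozen=True)
class CRN:
    """A reaction network: ordered species, ordered reactions, clamped set.

    Species order is the insertion order of first appearance, which makes
    compiled matrices reproducible.  ``clamped`` species are held at a
    constant (externally supplied) concentration.
    """

    species: tuple[str, ...]
    reactions: tuple[Reaction, ...]
    clamped: frozenset[str]

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def dynamic_species(self) -> tuple[str, ...]:
        return tuple(s for s in self.species if s not in self.clamped)

    def index(self, name: str) -> int:
        return self.species.index(name)


def build_crn(
    reactions: Sequence[Reaction],
    clamped: Iterable[str] = (),
    *,
    allow_higher_order: bool = False,
) -> CRN:
    """Assemble a :class:`CRN` with deterministic species ordering.

    Reactions with more than two reactant molecules are rejected unless
    ``allow_higher_order`` is set.  Every clamped name must occur in some
    reaction.
    """
    reactions = tuple(reactions)
    species: dict[str, None] = {}
    for rxn in reactions:
        if rxn.order > 2 and not allow_higher_order:
            raise ValueError(
                f"reaction {format_reaction(rxn)} has molecularity {rxn.order}; "
                "only unimolecular and bimolecular reactions are supported "
                "(pass allow_higher_order=True to override)"
            )
        for name in rxn.species:
            species.setdefault(name)
    clamped = frozenset(clamped)
    unknown = clamped - species.keys()
    if unknown:
        raise ValueError(f"clamped species not present in any reaction: {sorted(unknown)}")
    return CRN(tuple(species), reactions, clamped)


def combine(*crns: CRN, clamped: Iterable[str] = ()) -> CRN:
    """Concatenate reaction networks, preserving reaction and species order.

    The clamped set is the union of the parts plus any extra names given.
    """
    reactions: list[Reaction] = []
    clamp: set[str] = set(clamped)
    for crn in crns:
        reactions.extend(crn.reactions)
        clamp |= crn.clamped
    return build_crn(reactions, clamp, allow_higher_order=True)


def stoichiometric_matrix(crn: CRN) -> np.ndarray:
    """Integer matrix of net production; rows are dynamic species."""
    dyn = crn.dynamic_species
    P = np.zeros((len(dyn), crn.n_reactions), dtype=int)
    row = {name: i for i, name in enumerate(dyn)}
    for j, rxn in enumerate(crn.reactions):
        for name in rxn.species:
            if name in row:
                P[row[name], j] = rxn.net_change(name)
    return P


def _exponent_matrix(crn: CRN) -> np.ndarray:
    E = np.zeros((crn.n_reactions, crn.n_species), dtype=int)
    col = {name: i for i, name in enumerate(crn.species)}
    for j, rxn in enumerate(crn.reactions):
        for name, coeff in rxn.reactants.items():
            E[j, col[name]] = coeff
    return E


def mass_action_rates(crn: CRN, x: Sequence[float]) -> np.ndarray:
    """Mass-action rate vector at full concentration state *x*.

    ``rate_j = k_j * prod_i x_i**nu_ij`` with reactant multiplicities as
    exponents.  Negative concentrations are rejected.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (crn.n_species,):
        raise ValueError(f"state must have length {crn.n_species}, got {x.shape}")
    if np.any(x < 0):
        raise ValueError("negative concentrations are not allowed")
    E = _exponent_matrix(crn)
    k = np.array([r.rate_value for r in crn.reactions])
    with np.errstate(invalid="ignore"):
        return k * np.prod(x[None, :] ** E, axis=1)


@dataclass
class Trajectory:
    """Simulated time course: a strictly increasing grid and per-species series.

    ``values`` has one column per entry of ``species`` (clamped species are
    included, evaluated from their input functions).  Concentrations are
    clipped at zero on output; the largest clipped undershoot is recorded in
    ``metadata['clip_magnitude']``.
    """

    t: np.ndarray
    species: tuple[str, ...]
    values: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.values[:, self.species.index(name)]

    def at(self, name: str, time: float) -> float:
        """Linearly interpolated concentration of *name* at *time*."""
        return float(np.interp(time, self.t, self[name]))

    def final(self, name: str) -> float:
        return float(self[name][-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.species)).assign(t=self.t)[
            ["t", *self.species]
        ]

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


class PiecewiseConstant:
    """Piecewise-constant time function defined by ``(start_time, value)`` pairs."""

    def __init__(self, segments: Sequence[tuple[float, float]]):
        segments = [(float(t0), float(v)) for t0, v in segments]
        if not segments:
            raise ValueError("at least one segment is required")
        starts = [t0 for t0, _ in segments]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("segment start times must be strictly increasing")
        self.segments = segments

    @property
    def breakpoints(self) -> tuple[float, ...]:
        return tuple(t0 for t0, _ in self.segments[1:])

    def __call__(self, t: float) -> float:
        value = self.segments[0][1]
        for t0, v in self.segments:
            if t >= t0:
                value = v
            else:
                break
        return value


def _as_input_fn(value) -> Callable[[float], float]:
    if callable(value):
        return value
    return lambda t, v=float(value): v


class MassActionSystem:
    """Compiled ODE right-hand side ``dx/dt = P f(x)`` for a CRN.

    State variables are the dynamic (non-clamped) species in network order.
    Clamped species are supplied at simulation time as constants or callables
    of time via ``inputs``.
    """

    def __init__(self, crn: CRN):
        self.crn = crn
        self.state_names: tuple[str, ...] = crn.dynamic_species
        self.clamped_names: tuple[str, ...] = tuple(
            s for s in crn.species if s in crn.clamped
        )
        self.P = stoichiometric_matrix(crn)
        self._E = _exponent_matrix(crn)
        self._k = np.array([r.rate_value for r in crn.reactions])
        self._dyn_idx = np.array(
            [i for i, s in enumerate(crn.species) if s not in crn.clamped], dtype=int
        )
        self._clamp_idx = np.array(
            [i for i, s in enumerate(crn.species) if s in crn.clamped], dtype=int
        )

    @property
    def n_states(self) -> int:
        return len(self.state_names)

    def full_state(self, x_dyn: np.ndarray, clamped_values: np.ndarray) -> np.ndarray:
        x = np.empty(self.crn.n_species)
        x[self._dyn_idx] = x_dyn
        x[self._clamp_idx] = clamped_values
        return x

    def rates(self, x_full: np.ndarray) -> np.ndarray:
        x = np.maximum(x_full, 0.0)
        return self._k * np.prod(x[None, :] ** self._E, axis=1)

    def rhs(self, t: float, x_dyn: np.ndarray, input_fns: Mapping[str, Callable]) -> np.ndarray:
        clamped = np.array([input_fns[name](t) for name in self.clamped_names])
        return self.P @ self.rates(self.full_state(x_dyn, clamped))

    def initial_state(self, x0: Mapping[str, float] | Sequence[float] | None) -> np.ndarray:
        if x0 is None:
            return np.zeros(self.n_states)
        if isinstance(x0, Mapping):
            unknown = set(x0) - set(self.state_names)
            if unknown:
                raise ValueError(f"unknown species in initial state: {sorted(unknown)}")
            return np.array([float(x0.get(s, 0.0)) for s in self.state_names])
        x0 = np.asarray(x0, dtype=float)
        if x0.shape != (self.n_states,):
            raise ValueError(f"initial state must have length {self.n_states}")
        return x0


def compile_crn(crn: CRN) -> MassActionSystem:
    """Compile a network to its generalised mass-action ODE system."""
    return MassActionSystem(crn)


def simulate(
    system: MassActionSystem,
    x0: Mapping[str, float] | Sequence[float] | None = None,
    inputs: Mapping[str, float | Callable[[float], float]] | None = None,
    t_end: float = 1.0,
    t_grid: Sequence[float] | None = None,
    *,
    method: str = "LSODA",
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate the system with a stiff-capable implicit solver.

    Piecewise-constant inputs exposing ``breakpoints`` cause the integration
    to be restarted at each discontinuity.  Reported concentrations are
    clipped at zero; the clip magnitude is logged in the metadata.
    """
    inputs = dict(inputs or {})
    missing = set(system.clamped_names) - inputs.keys()
    if missing:
        raise ValueError(f"missing input functions for clamped species: {sorted(missing)}")
    input_fns = {name: _as_input_fn(v) for name, v in inputs.items()}

    x = system.initial_state(x0)
    if np.any(x < 0):
        raise ValueError("initial concentrations must be non-negative")

    if t_grid is None:
        t_grid = np.linspace(0.0, t_end, 201)
    t_grid = np.asarray(t_grid, dtype=float)
    t_end = float(t_grid[-1])

    breaks = sorted(
        {
            float(b)
            for v in inputs.values()
            if hasattr(v, "breakpoints")
            for b in v.breakpoints
            if t_grid[0] < b < t_end
        }
    )
    legs = list(zip([t_grid[0], *breaks], [*breaks, t_end]))

    ts: list[np.ndarray] = []
    xs: list[np.ndarray] = []
    for t_a, t_b in legs:
        sel = (t_grid >= t_a) & (t_grid <= t_b)
        t_eval = np.unique(np.concatenate([[t_a], t_grid[sel], [t_b]]))
        sol = solve_ivp(
            system.rhs,
            (t_a, t_b),
            x,
            args=(input_fns,),
            method=method,
            rtol=rtol,
            atol=atol,
            t_eval=t_eval,
        )
        if not sol.success:
            last = float(sol.t[-1]) if sol.t.size else t_a
            raise SimulationError(f"integrator failed: {sol.message}", last_time=last)
        keep = np.isin(sol.t, t_grid[sel])
        ts.append(sol.t[keep])
        xs.append(sol.y[:, keep].T)
        x = sol.y[:, -1]

    t_all = np.concatenate(ts)
    x_all = np.concatenate(xs, axis=0)
    # drop duplicated grid points at leg boundaries
    t_all, idx = np.unique(t_all, return_index=True)
    x_all = x_all[idx]

    clip = float(max(0.0, -x_all.min())) if x_all.size else 0.0
    x_all = np.clip(x_all, 0.0, None)

    clamped_cols = np.column_stack(
        [[input_fns[name](t) for t in t_all] for name in system.clamped_names]
    ) if system.clamped_names else np.empty((len(t_all), 0))

    species = (*system.state_names, *system.clamped_names)
    values = np.column_stack([x_all, clamped_cols])
    meta = {
        "method": method,
        "rtol": rtol,
        "atol": atol,
        "clip_magnitude": clip,
        "final_state": dict(zip(system.state_names, x.tolist())),
    }
    return Trajectory(t=t_all, species=species, values=values, metadata=meta)


@dataclass
class SteadyStateResult:
    state: dict[str, float]
    converged: bool
    derivatives: dict[str, float]
    horizon: float

    def __getitem__(self, name: str) -> float:
        return self.state[name]


def steady_state(
    system: MassActionSystem,
    x0: Mapping[str, float] | Sequence[float] | None = None,
    inputs: Mapping[str, float] | None = None,
    horizon: float = 100.0,
    tol: float = 1e-6,
    **sim_kwargs,
) -> SteadyStateResult:
    """Long-horizon integration followed by a derivative test.

    The system is integrated to ``horizon`` under constant inputs and flagged
    converged iff every ``|dx_i/dt| < tol * (1 + |x_i|)``.  Motifs without a
    finite fixed point (e.g. a one-sided subtraction with non-positive
    difference) are flagged as not converged rather than raising.
    """
    traj = simulate(system, x0, inputs, t_end=horizon, **sim_kwargs)
    x = np.array([traj.final(s) for s in system.state_names])
    input_fns = {name: _as_input_fn(v) for name, v in (inputs or {}).items()}
    dxdt = system.rhs(horizon, x, input_fns)
    converged = bool(np.all(np.abs(dxdt) < tol * (1.0 + np.abs(x))))
    return SteadyStateResult(
        state=dict(zip(system.state_names, x.tolist())),
        converged=converged,
        derivatives=dict(zip(system.state_names, dxdt.tolist())),
        horizon=float(horizon),
    )


def format_reaction(rxn: Reaction) -> str:
    """Render a reaction in the plain-text list grammar."""

    def side(counts: Mapping[str, int]) -> str:
        if not counts:
            return "empty"
        terms = []
        for name, coeff in counts.items():
            terms.append(name if coeff == 1 else f"{coeff} {name}")
        return " + ".join(terms)

    return (
        f"{side(rxn.reactants)} -> {side(rxn.products)} "
        f"@ {rxn.rate_name}={rxn.rate_value:.12g}"
    )
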