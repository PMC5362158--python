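"""Closed-loop tracking experiments and robustness / sensitivity analyses.

The analyses operate on :class:`ClosedLoopModel`, a hand-written split-rate
ODE form of the closed loop in which every *occurrence* of a rate constant
in the ODE terms is an independently perturbable parameter (e.g. the
Subtraction II rate appears in five terms and yields five parameters
``gSbII1..gSbII5``).  At nominal values the model is identical, term by
term, to the generalised mass-action compilation of the assembled circuit;
the test suite asserts that identity to 1e-12 relative.

Steady-state tracking quality is quantified by the relative error
``100 * (y_hat(T) - target) / y_hat(T)`` evaluated at the end of each
reference segment (by default ``T = 40000`` with target 4, and
``T = 80000`` with target 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .controller import ControllerConfig, Mode, taylor_ff
from .crn import PiecewiseConstant, Trajectory
from .plant import ProcessParams, inversion_constants

__all__ = [
    "ReferenceSignal",
    "ClosedLoopModel",
    "PerturbationSpec",
    "EnvelopeReport",
    "run_tracking",
    "relative_ess",
    "chernoff_sample_size",
    "monte_carlo_robustness",
    "sensitivity_sweep",
    "process_regime_sweep",
    "default_reference",
    "UNBOUNDED_INTERMEDIATES",
]

#: One-sided-subtraction intermediates; unbounded by design when the
#: subtraction saturates, hence excluded from the divergence test.
UNBOUNDED_INTERMEDIATES = ("xt", "xs")


@dataclass(frozen=True)
class ReferenceSignal:
    """Piecewise-constant reference: ``(start_time, value)`` segments."""

    segments: tuple[tuple[float, float], ...] = ((0.0, 4.0), (40000.0, 1.0))
    t_end: float = 80000.0

    def __post_init__(self):
        if not self.segments:
            raise ValueError("reference needs at least one segment")
        starts = [t for t, _ in self.segments]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("segment start times must be strictly increasing")
        if any(v < 0 for _, v in self.segments):
            raise ValueError("reference values must be non-negative")

    def as_function(self) -> PiecewiseConstant:
        return PiecewiseConstant(self.segments)

    def value(self, t: float) -> float:
        return self.as_function()(t)

    @property
    def breakpoints(self) -> tuple[float, ...]:
        return tuple(t for t, _ in self.segments[1:])

    def evaluation_points(self) -> list[tuple[float, float]]:
        """``(time, target)`` pairs at the end of each segment."""
        ends = [*self.breakpoints, self.t_end]
        return [(t_eval, v) for t_eval, (_, v) in zip(ends, self.segments)]


def default_reference() -> ReferenceSignal:
    """Step-up/step-down experiment: r=4 on [0, 40000), r=1 on [40000, 80000]."""
    return ReferenceSignal()


# ---------------------------------------------------------------------------
# Split-rate closed-loop models
# ---------------------------------------------------------------------------

_FULL_STATES = (
    "x1", "x2", "x3", "xs", "x4", "x7", "xt", "x8", "x9", "x10",
    "x5", "xi", "x6", "xe",
)
_FULL_PARAMS = (
    "gGa1", "gGa2", "gGd1", "gGd2",
    "gSbI1", "gSbI2", "gSbI3", "gSbI4", "gSbI5",
    "gD1", "gD2",
    "KI", "gGKP1", "gGKP2", "KP",
    "gSmI1", "gSmI2", "gSmI3",
    "gSbII1", "gSbII2", "gSbII3", "gSbII4", "gSbII5",
    "gSmII1", "gSmII2", "gSmII3",
    "kr1", "kr2", "kr3",
)

_SIMP_STATES = ("x4", "x7", "xt", "x8", "x9", "x10", "x5", "xi", "x6", "xe")
_SIMP_PARAMS = (
    "gG1", "gG2",
    "KI", "gGKP1", "gGKP2", "KP",
    "gSmI1", "gSmI2", "gSmI3",
    "gSbII1", "gSbII2", "gSbII3", "gSbII4", "gSbII5",
    "gSmII1", "gSmII2", "gSmII3",
    "kr1", "kr2", "kr3",
)

_PI_STATES = ("x7", "xt", "x8", "x9", "x10", "x5", "xi", "x6", "xe")
_PI_PARAMS = (
    "KI", "gGKP1", "gGKP2", "KP",
    "gSmI1", "gSmI2", "gSmI3",
    "gSbII1", "gSbII2", "gSbII3", "gSbII4", "gSbII5",
    "gSmII2", "gSmII3",
    "kr1", "kr2", "kr3",
)


class ClosedLoopModel:
    """Fast split-rate ODE model of an assembled closed loop.

    Parameters are exposed as a flat vector ``p_nominal`` indexed by
    ``param_names``; the right-hand side has signature ``rhs(t, x, p, r)``
    with ``r`` the instantaneous reference value.  The controller-side
    inversion constants (alpha, beta, delta and the simplified gain Gamma1)
    are computed once from the *design* process parameters and are not
    themselves perturbed: perturbing ``kr1..kr3`` therefore represents plant
    model mismatch, exactly as in the robustness analyses.
    """

    def __init__(
        self,
        mode: Mode,
        cfg: ControllerConfig | None = None,
        params: ProcessParams | None = None,
        *,
        retroactivity: bool = False,
        design_params: ProcessParams | None = None,
    ):
        self.mode = mode
        self.cfg = cfg = cfg or ControllerConfig()
        self.params = params = params or ProcessParams()
        self.retroactivity = retroactivity
        inv = inversion_constants(design_params or params)
        self.inv = inv
        self.Gamma1 = taylor_ff(inv).Gamma1

        if mode == "full_ff":
            self.state_names = _FULL_STATES
            self.param_names = _FULL_PARAMS
        elif mode == "simplified_ff":
            self.state_names = _SIMP_STATES
            self.param_names = _SIMP_PARAMS
        elif mode == "pi_only":
            self.state_names = _PI_STATES
            self.param_names = _PI_PARAMS
        else:
            raise ValueError(f"unknown mode {mode!r}")

        nominal = {
            "gGa1": cfg.g_Ga, "gGa2": cfg.g_Ga,
            "gGd1": cfg.g_Gd, "gGd2": cfg.g_Gd,
            "gSbI1": cfg.g_SbI, "gSbI2": cfg.g_SbI, "gSbI3": cfg.g_SbI,
            "gSbI4": cfg.g_SbI, "gSbI5": cfg.g_SbI,
            "gD1": cfg.g_D, "gD2": cfg.g_D,
            "gG1": cfg.g_G, "gG2": cfg.g_G,
            "KI": cfg.KI, "gGKP1": cfg.g_GKP, "gGKP2": cfg.g_GKP, "KP": cfg.KP,
            "gSmI1": cfg.g_SmI, "gSmI2": cfg.g_SmI, "gSmI3": cfg.g_SmI,
            "gSbII1": cfg.g_SbII, "gSbII2": cfg.g_SbII, "gSbII3": cfg.g_SbII,
            "gSbII4": cfg.g_SbII, "gSbII5": cfg.g_SbII,
            "gSmII1": cfg.g_SmII, "gSmII2": cfg.g_SmII, "gSmII3": cfg.g_SmII,
            "kr1": params.kr1, "kr2": params.kr2, "kr3": params.kr3,
        }
        self.p_nominal = np.array([nominal[name] for name in self.param_names])
        self.rhs = self._make_rhs()

    def param_index(self, name: str) -> int:
        return self.param_names.index(name)

    def perturbed(self, **factors: float) -> np.ndarray:
        """Nominal parameter vector with named entries scaled by factors."""
        p = self.p_nominal.copy()
        for name, f in factors.items():
            p[self.param_index(name)] *= f
        return p

    def output_index(self) -> int:
        return self.state_names.index("x6")

    def initial_state(self) -> np.ndarray:
        x = np.zeros(len(self.state_names))
        x[self.state_names.index("xe")] = self.params.xT
        return x

    def _make_rhs(self) -> Callable:
        alpha, beta, delta = self.inv.alpha, self.inv.beta, self.inv.delta
        Gamma1 = self.Gamma1
        retro = self.retroactivity

        if self.mode == "full_ff":

            def rhs(t, x, p, r):
                x1, x2, x3, xs, x4, x7, xt, x8, x9, x10, x5, xi, x6, xe = x
                (gGa1, gGa2, gGd1, gGd2,
                 gSbI1, gSbI2, gSbI3, gSbI4, gSbI5,
                 gD1, gD2, KI, gGKP1, gGKP2, KP,
                 gSmI1, gSmI2, gSmI3,
                 gSbII1, gSbII2, gSbII3, gSbII4, gSbII5,
                 gSmII1, gSmII2, gSmII3, kr1, kr2, kr3) = p
                bind = kr1 * x5 * xe
                return (
                    gGa1 * alpha * r - gGa2 * x1,
                    gGd1 * delta * r - gGd2 * x2,
                    gSbI1 * beta - gSbI2 * xs * x3 - gSbI3 * x3,
                    gSbI4 * x2 - gSbI5 * xs * x3,
                    gD1 * x1 - gD2 * x3 * x4,
                    gSbII1 * r - gSbII2 * xt * x7 - gSbII3 * x7,
                    gSbII4 * x6 - gSbII5 * xt * x7,
                    KI * x7,
                    gGKP1 * KP * x7 - gGKP2 * x9,
                    gSmI1 * x8 + gSmI2 * x9 - gSmI3 * x10,
                    gSmII1 * x4 + gSmII2 * x10 - gSmII3 * x5 - (bind if retro else 0.0),
                    bind - kr2 * xi,
                    kr2 * xi - kr3 * x6,
                    kr2 * xi - bind,
                )

        elif self.mode == "simplified_ff":

            def rhs(t, x, p, r):
                x4, x7, xt, x8, x9, x10, x5, xi, x6, xe = x
                (gG1, gG2, KI, gGKP1, gGKP2, KP,
                 gSmI1, gSmI2, gSmI3,
                 gSbII1, gSbII2, gSbII3, gSbII4, gSbII5,
                 gSmII1, gSmII2, gSmII3, kr1, kr2, kr3) = p
                bind = kr1 * x5 * xe
                return (
                    gG1 * Gamma1 * r - gG2 * x4,
                    gSbII1 * r - gSbII2 * xt * x7 - gSbII3 * x7,
                    gSbII4 * x6 - gSbII5 * xt * x7,
                    KI * x7,
                    gGKP1 * KP * x7 - gGKP2 * x9,
                    gSmI1 * x8 + gSmI2 * x9 - gSmI3 * x10,
                    gSmII1 * x4 + gSmII2 * x10 - gSmII3 * x5 - (bind if retro else 0.0),
                    bind - kr2 * xi,
                    kr2 * xi - kr3 * x6,
                    kr2 * xi - bind,
                )

        else:  # pi_only: the feedforward input of Summation II is inert zero

            def rhs(t, x, p, r):
                x7, xt, x8, x9, x10, x5, xi, x6, xe = x
                (KI, gGKP1, gGKP2, KP,
                 gSmI1, gSmI2, gSmI3,
                 gSbII1, gSbII2, gSbII3, gSbII4, gSbII5,
                 gSmII2, gSmII3, kr1, kr2, kr3) = p
                bind = kr1 * x5 * xe
                return (
                    gSbII1 * r - gSbII2 * xt * x7 - gSbII3 * x7,
                    gSbII4 * x6 - gSbII5 * xt * x7,
                    KI * x7,
                    gGKP1 * KP * x7 - gGKP2 * x9,
                    gSmI1 * x8 + gSmI2 * x9 - gSmI3 * x10,
                    gSmII2 * x10 - gSmII3 * x5 - (bind if retro else 0.0),
                    bind - kr2 * xi,
                    kr2 * xi - kr3 * x6,
                    kr2 * xi - bind,
                )

        return rhs


def run_tracking(
    model: ClosedLoopModel,
    ref: ReferenceSignal | None = None,
    *,
    p: np.ndarray | None = None,
    n_points: int = 401,
    method: str = "LSODA",
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Simulate the closed loop under a piecewise-constant reference.

    Integration restarts at each reference step.  The returned trajectory
    carries all model states (including the feedforward and PI contributions
    x4 and x10 where present) plus an ``r`` column.
    """
    ref = ref or default_reference()
    p = model.p_nominal if p is None else np.asarray(p, dtype=float)
    x = model.initial_state()

    bounds = [t for t, _ in ref.segments] + [ref.t_end]
    grid = np.unique(np.concatenate([np.linspace(bounds[0], ref.t_end, n_points), bounds]))

    ts: list[np.ndarray] = []
    xs: list[np.ndarray] = []
    for (t_a, r_val), t_b in zip(ref.segments, bounds[1:]):
        t_eval = grid[(grid >= t_a) & (grid <= t_b)]
        sol = solve_ivp(
            model.rhs, (t_a, t_b), x, args=(p, r_val),
            method=method, rtol=rtol, atol=atol, t_eval=t_eval,
        )
        if not sol.success:
            from .crn import SimulationError

            last = float(sol.t[-1]) if sol.t.size else t_a
            raise SimulationError(f"integrator failed: {sol.message}", last_time=last)
        ts.append(sol.t)
        xs.append(sol.y.T)
        x = sol.y[:, -1]

    t_all = np.concatenate(ts)
    x_all = np.concatenate(xs, axis=0)
    t_all, idx = np.unique(t_all, return_index=True)
    x_all = x_all[idx]

    clip = float(max(0.0, -x_all.min()))
    x_all = np.clip(x_all, 0.0, None)
    r_col = np.array([ref.value(t) for t in t_all])
    return Trajectory(
        t=t_all,
        species=(*model.state_names, "r"),
        values=np.column_stack([x_all, r_col]),
        metadata={"mode": model.mode, "clip_magnitude": clip, "rtol": rtol, "atol": atol},
    )


def relative_ess(traj: Trajectory, ref: ReferenceSignal | None = None) -> tuple[float, ...]:
    """Signed relative steady-state errors, in percent, per reference segment.

    ``e = 100 * (y_hat(T) - target) / y_hat(T)`` at the end time of each
    segment.  A vanishing output at an evaluation point yields ``nan``
    (undefined).  For the default reference the result is ``(e_U, e_D)``.
    """
    ref = ref or default_reference()
    out = []
    for t_eval, target in ref.evaluation_points():
        if t_eval > traj.t[-1] + 1e-9:
            raise ValueError(f"trajectory does not cover evaluation time {t_eval}")
        y = traj.at("x6", t_eval)
        out.append(100.0 * (y - target) / y if abs(y) > 1e-12 else float("nan"))
    return tuple(out)


def chernoff_sample_size(accuracy: float, confidence: float) -> int:
    """Smallest N with ``N >= ln(2/(1-confidence)) / (2*accuracy**2)``."""
    if not 0 < accuracy < 1:
        raise ValueError("accuracy must be in (0, 1)")
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")
    return math.ceil(math.log(2.0 / (1.0 - confidence)) / (2.0 * accuracy**2))


@dataclass(frozen=True)
class PerturbationSpec:
    """Multiplicative perturbation ``theta * (1 + scale * Delta)``.

    ``Delta`` is drawn independently per split parameter from the uniform
    distribution on [-1, 1].
    """

    scale: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.scale <= 1:
            raise ValueError("scale must be in [0, 1] so perturbed rates stay >= 0")

    def draw(self, rng: np.random.Generator, p_nominal: np.ndarray) -> np.ndarray:
        delta = rng.uniform(-1.0, 1.0, size=p_nominal.shape)
        return p_nominal * (1.0 + self.scale * delta)


@dataclass
class EnvelopeReport:
    """Monte Carlo output envelope and per-run divergence flags."""

    t: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    nominal: np.ndarray
    n_runs: int
    scale: float
    seed: int
    diverged: list[int] = field(default_factory=list)

    @property
    def n_diverged(self) -> int:
        return len(self.diverged)

    def width(self) -> np.ndarray:
        return self.hi - self.lo

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.t, "min": self.lo, "max": self.hi,
                             "nominal": self.nominal})

    def summary(self) -> dict:
        return {
            "n_runs": self.n_runs,
            "scale": self.scale,
            "seed": self.seed,
            "n_diverged": self.n_diverged,
            "diverged_runs": list(self.diverged),
            "max_width": float(self.width().max()),
        }


def monte_carlo_robustness(
    model: ClosedLoopModel,
    spec: PerturbationSpec,
    n: int,
    *,
    ref: ReferenceSignal | None = None,
    n_points: int = 201,
    divergence_bound: float = 1e6,
    exclude: Iterable[str] = UNBOUNDED_INTERMEDIATES,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> EnvelopeReport:
    """N tracking simulations with independently resampled split parameters.

    The envelope is the pointwise min/max of the output over all
    non-divergent runs.  A run is flagged divergent when the solver fails or
    any checked state exceeds ``divergence_bound``; the one-sided subtraction
    intermediates are excluded from the check by default because they grow
    without bound whenever the subtraction saturates (by design, not
    instability).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ref = ref or default_reference()
    rng = np.random.default_rng(spec.seed)
    checked = [i for i, s in enumerate(model.state_names) if s not in set(exclude)]
    out_idx = model.output_index()

    nominal = run_tracking(model, ref, n_points=n_points, rtol=rtol, atol=atol)
    t_grid = nominal.t
    y_nom = nominal["x6"]

    lo = np.full_like(y_nom, np.inf)
    hi = np.full_like(y_nom, -np.inf)
    diverged: list[int] = []
    for run in range(n):
        p = spec.draw(rng, model.p_nominal)
        try:
            traj = run_tracking(model, ref, p=p, n_points=n_points, rtol=rtol, atol=atol)
        except Exception:
            diverged.append(run)
            continue
        states = traj.values[:, : len(model.state_names)]
        if np.max(np.abs(states[:, checked])) > divergence_bound:
            diverged.append(run)
            continue
        y = np.interp(t_grid, traj.t, states[:, out_idx])
        lo = np.minimum(lo, y)
        hi = np.maximum(hi, y)

    return EnvelopeReport(
        t=t_grid, lo=lo, hi=hi, nominal=y_nom, n_runs=n,
        scale=spec.scale, seed=spec.seed, diverged=diverged,
    )


DEFAULT_FACTORS: tuple[float, ...] = tuple(
    round(0.5 + 0.1 * i, 10) for i in range(16)
)  # 0.5 .. 2.0 step 0.1


def sensitivity_sweep(
    model: ClosedLoopModel,
    parameters: Sequence[str] | None = None,
    factors: Sequence[float] = DEFAULT_FACTORS,
    *,
    ref: ReferenceSignal | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> pd.DataFrame:
    """One-at-a-time sweep: max signed relative error over the factor grid.

    Each split parameter in turn is multiplied by every factor while all
    others stay nominal.  The report gives, per parameter, the maximum of
    the signed step-up and step-down errors over the factors (the printed
    convention: upward output excursions cannot be corrected by the
    one-sided error and dominate the maxima).
    """
    ref = ref or default_reference()
    parameters = list(parameters) if parameters is not None else list(model.param_names)
    rows = []
    for name in parameters:
        idx = model.param_index(name)
        e_first = []
        e_last = []
        for f in factors:
            p = model.p_nominal.copy()
            p[idx] *= f
            traj = run_tracking(model, ref, p=p, n_points=51, rtol=rtol, atol=atol)
            errs = relative_ess(traj, ref)
            e_first.append(errs[0])
            e_last.append(errs[-1])
        rows.append(
            {"parameter": name, "e_U": max(e_first), "e_D": max(e_last)}
        )
    return pd.DataFrame(rows).set_index("parameter")


# ---------------------------------------------------------------------------
# Process-parameter regime sweep
# ---------------------------------------------------------------------------

_RANGE = {"kr1": (1e-9, 1e6), "kr2": (1e-2, 1e2), "kr3": (1e-5, 1e-3)}

#: Controller adjustments per sign pattern, mirroring the design remarks:
#: increase feedforward rates when binding is very slow, decrease the PI
#: gains when binding is very fast.  Magnitudes are implementation choices.
DEFAULT_ADJUSTMENTS: dict[str, dict[tuple[str, str, str], dict]] = {
    "full_ff": {
        ("-", "-", "+"): {"ff_scale": 1e8, "remark": "Increase reaction rates gamma"},
        ("-", "+", "+"): {"ff_scale": 1e8, "remark": "Increase reaction rates gamma"},
        ("+", "-", "+"): {"kp_scale": 1e-8, "ki_scale": 1e-8, "remark": "Decrease KP and KI"},
        ("+", "+", "+"): {"kp_scale": 1e-8, "ki_scale": 1e-8, "remark": "Decrease KP and KI"},
    },
    "simplified_ff": {
        ("-", "-", "+"): {"kp_scale": 1e2, "ki_scale": 1e2, "remark": "Increase KP and KI"},
        ("-", "+", "+"): {"remark": "No change to existing parameters"},
        ("+", "-", "+"): {"kp_scale": 1e-8, "ki_scale": 1e-8, "remark": "Decrease KP and KI"},
        ("+", "+", "+"): {"kp_scale": 1e-8, "ki_scale": 1e-8, "remark": "Decrease KP and KI"},
    },
}


def _adjusted_config(cfg: ControllerConfig, mode: str, adj: dict) -> ControllerConfig:
    factors: dict[str, float] = {}
    if "ff_scale" in adj:
        if mode == "full_ff":
            factors.update(
                g_Ga=adj["ff_scale"], g_Gd=adj["ff_scale"],
                g_SbI=adj["ff_scale"], g_D=adj["ff_scale"],
            )
        else:
            factors.update(g_G=adj["ff_scale"])
    if "kp_scale" in adj:
        factors.update(KP=adj["kp_scale"])
    if "ki_scale" in adj:
        factors.update(KI=adj["ki_scale"])
    return cfg.scaled(**factors) if factors else cfg


def process_regime_sweep(
    mode: Mode,
    cfg: ControllerConfig | None = None,
    *,
    scenarios: Sequence[tuple[str, str, str]] | None = None,
    adjustments: dict | None = None,
    threshold: float = 10.0,
    ref: ReferenceSignal | None = None,
    xT: float = 5.5,
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> pd.DataFrame:
    """Tracking verdicts over the extreme corners of the process-rate ranges.

    Each scenario sets (kr1, kr2, kr3) to range endpoints (``-`` = minimum,
    ``+`` = maximum); the feedforward controller is re-designed for the
    scenario's process (inversion constants recomputed) and the listed
    controller adjustments applied.  A scenario tracks (verdict Y) iff both
    relative steady-state errors are within ``threshold`` percent.
    """
    cfg = cfg or ControllerConfig()
    ref = ref or default_reference()
    if scenarios is None:
        scenarios = [
            (s1, s2, s3) for s1 in "-+" for s2 in "-+" for s3 in "-+"
        ]
        # mirror the report layout: slow-degradation rows first
        scenarios.sort(key=lambda s: (s[2], s[0], s[1]))
    adj_table = (
        adjustments if adjustments is not None else DEFAULT_ADJUSTMENTS.get(mode, {})
    )

    rows = []
    for signs in scenarios:
        kr = {
            name: _RANGE[name][0 if sign == "-" else 1]
            for name, sign in zip(("kr1", "kr2", "kr3"), signs)
        }
        params = ProcessParams(xT=xT, **kr)
        adj = adj_table.get(tuple(signs), {})
        scen_cfg = _adjusted_config(cfg, mode, adj)
        model = ClosedLoopModel(mode, scen_cfg, params)
        try:
            traj = run_tracking(model, ref, n_points=51, rtol=rtol, atol=atol)
            errs = relative_ess(traj, ref)
            tracks = all(abs(e) <= threshold for e in errs)
            e_first, e_last = errs[0], errs[-1]
        except Exception:
            tracks, e_first, e_last = False, float("nan"), float("nan")
        rows.append(
            {
                "scenario": "".join(signs),
                "kr1": kr["kr1"],
                "kr2": kr["kr2"],
                "kr3": kr["kr3"],
                "e_U": e_first,
                "e_D": e_last,
                "tracks": "Y" if tracks else "N",
                "remark": adj.get("remark", ""),
            }
        )
    return pd.DataFrame(rows).set_index("scenario")
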