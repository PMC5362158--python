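"""The enzymatic reaction process: model, inversion constants, retroactivity.

The process is the three-reaction catalytic chain

    input + enzyme -> complex        (binding, kr1)
    complex -> output + enzyme       (catalysis, kr2)
    output -> 0                      (degradation, kr3)

Total enzyme ``xT = enzyme + complex`` is conserved.  The steady-state
input-output map inverts to ``input = alpha*output / (beta - delta*output)``
with ``alpha = kr2*kr3``, ``beta = kr1*kr2*xT`` and ``delta = kr1*kr3``;
feasible outputs satisfy ``output < beta/delta``.

By default the process reads its input *catalytically* (ideal modularity:
the upstream module's output is buffered and not consumed).  With
``consume_input=True`` the binding reaction consumes the input species, which
adds the retroactivity term ``-kr1*input*enzyme`` to the upstream ODE.
"""

from __future__ import annotations

from dataclasses import dataclass

from .crn import CRN, Reaction, build_crn

__all__ = [
    "ProcessParams",
    "InversionConstants",
    "make_process",
    "inversion_constants",
    "LITERATURE_RANGES",
]

#: Literature ranges for the process rates (binding, catalytic, degradation).
LITERATURE_RANGES = {
    "kr1": (1e-9, 1e6),
    "kr2": (1e-2, 1e2),
    "kr3": (1e-5, 1e-3),
}


@dataclass(frozen=True)
class ProcessParams:
    """Process rates and total enzyme concentration (all strictly positive)."""

    kr1: float = 0.005
    kr2: float = 1.6
    kr3: float = 0.0008
    xT: float = 5.5

    def __post_init__(self):
        for name in ("kr1", "kr2", "kr3", "xT"):
            if getattr(self, name) <= 0:
                raise ValueError(f"process parameter {name} must be > 0")


@dataclass(frozen=True)
class InversionConstants:
    """Constants of the steady-state inverse map."""

    alpha: float
    beta: float
    delta: float

    def __post_init__(self):
        if min(self.alpha, self.beta, self.delta) <= 0:
            raise ValueError("inversion constants must be > 0")

    @property
    def feasible_max(self) -> float:
        """Upper bound on trackable outputs, ``beta/delta = kr2*xT/kr3``."""
        return self.beta / self.delta


def inversion_constants(params: ProcessParams) -> InversionConstants:
    return InversionConstants(
        alpha=params.kr2 * params.kr3,
        beta=params.kr1 * params.kr2 * params.xT,
        delta=params.kr1 * params.kr3,
    )


def make_process(
    params: ProcessParams,
    inp: str = "x5",
    out: str = "x6",
    complex_species: str = "xi",
    enzyme: str = "xe",
    *,
    consume_input: bool = False,
) -> CRN:
    """Build the three-reaction process network.

    The enzyme species should be initialised at ``params.xT`` (and the
    complex at zero); the network conserves their sum.  ``consume_input``
    switches from the buffered (ideal-modularity) reading of the input to the
    mass-action one that exerts retroactivity on the upstream module.
    """
    binding_products = {complex_species: 1} if consume_input else {complex_species: 1, inp: 1}
    return build_crn(
        [
            Reaction({inp: 1, enzyme: 1}, binding_products, "kr1", params.kr1),
            Reaction({complex_species: 1}, {out: 1, enzyme: 1}, "kr2", params.kr2),
            Reaction({out: 1}, {}, "kr3", params.kr3),
        ]
    )
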