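"""Biomolecular arithmetic operator motifs as reaction networks.

Each factory returns a :class:`~crnctrl.crn.CRN` implementing an arithmetic
primitive whose equilibrium realises the stated contract for constant
non-negative inputs.  Single-rail motifs can never settle at a negative
output (mass action keeps concentrations non-negative), which is why the
subtraction motif is one-sided: its output clips at zero and its
intermediate species has no finite fixed point when the difference is not
positive.  The dual-rail motifs encode a signal as the difference of a
``+`` and a ``-`` species with a fast annihilation reaction (``eta >> gamma``)
and support signed results at the cost of nine reactions each.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

from .crn import CRN, Reaction, build_crn

__all__ = [
    "OperatorKind",
    "OperatorSpec",
    "REACTION_COUNTS",
    "make_gain",
    "make_summation3",
    "make_subtraction_onesided",
    "make_division",
    "make_integrator",
    "make_proportional",
    "make_dualrail",
]

OperatorKind = Literal[
    "gain",
    "summation3",
    "subtraction_onesided",
    "division",
    "integrator",
    "proportional",
    "summation_dualrail",
    "subtraction_dualrail",
]

#: Number of reactions used by each operator motif.
REACTION_COUNTS: dict[str, int] = {
    "gain": 2,
    "summation3": 3,
    "subtraction_onesided": 4,
    "division": 2,
    "integrator": 1,
    "proportional": 2,
    "summation_dualrail": 9,
    "subtraction_dualrail": 9,
}

#: Default ratio eta/gamma for dual-rail annihilation.
DEFAULT_ETA_RATIO = 1000.0

#: Ratio below which the dual-rail contract is considered degraded.
MIN_ETA_RATIO = 100.0


def _rate(label: str, name: str) -> str:
    return f"{label}/{name}" if label else name


def make_gain(k: float, gamma: float, inp: str, out: str, label: str = "") -> CRN:
    """Gain operator: equilibrium ``out = k * inp``.

    Reactions: ``inp -> inp + out`` at rate ``k*gamma`` and ``out -> 0`` at
    ``gamma``, i.e. ``d(out)/dt = gamma * (k*inp - out)``.
    """
    if k < 0:
        raise ValueError("gain constant k must be >= 0")
    if gamma <= 0:
        raise ValueError("rate gamma must be > 0")
    g = _rate(label, "gamma")
    return build_crn(
        [
            Reaction({inp: 1}, {inp: 1, out: 1}, _rate(label, "k_gamma"), k * gamma),
            Reaction({out: 1}, {}, g, gamma),
        ]
    )


def make_summation3(gamma: float, in1: str, in2: str, out: str, label: str = "") -> CRN:
    """Three-reaction summation: equilibrium ``out = in1 + in2``."""
    if gamma <= 0:
        raise ValueError("rate gamma must be > 0")
    g = _rate(label, "gamma")
    return build_crn(
        [
            Reaction({in1: 1}, {in1: 1, out: 1}, g, gamma),
            Reaction({in2: 1}, {in2: 1, out: 1}, g, gamma),
            Reaction({out: 1}, {}, g, gamma),
        ]
    )


def make_subtraction_onesided(
    gamma: float, in1: str, in2: str, out: str, itd: str, label: str = ""
) -> CRN:
    """One-sided subtraction: ``out -> max(0, in1 - in2)`` at equilibrium.

    Four reactions.  ``itd`` is the intermediate that sequesters the output;
    when ``in1 <= in2`` the motif has no finite fixed point and ``itd``
    drifts while ``out`` clips at zero.
    """
    if gamma <= 0:
        raise ValueError("rate gamma must be > 0")
    g = _rate(label, "gamma")
    return build_crn(
        [
            Reaction({in1: 1}, {in1: 1, out: 1}, g, gamma),
            Reaction({itd: 1, out: 1}, {}, g, gamma),
            Reaction({in2: 1}, {in2: 1, itd: 1}, g, gamma),
            Reaction({out: 1}, {}, g, gamma),
        ]
    )


def make_division(gamma: float, num: str, den: str, out: str, label: str = "") -> CRN:
    """Two-reaction division: equilibrium ``out = num / den`` for ``den > 0``."""
    if gamma <= 0:
        raise ValueError("rate gamma must be > 0")
    g = _rate(label, "gamma")
    return build_crn(
        [
            Reaction({num: 1}, {num: 1, out: 1}, g, gamma),
            Reaction({den: 1, out: 1}, {den: 1}, g, gamma),
        ]
    )


def make_integrator(KI: float, inp: str, out: str, label: str = "") -> CRN:
    """Pure integrator: single reaction giving ``d(out)/dt = KI * inp``."""
    if KI <= 0:
        raise ValueError("integral gain KI must be > 0")
    return build_crn([Reaction({inp: 1}, {inp: 1, out: 1}, _rate(label, "KI"), KI)])


def make_proportional(KP: float, gamma: float, inp: str, out: str, label: str = "") -> CRN:
    """Proportional operator; structurally a gain with ``k = KP``."""
    return make_gain(KP, gamma, inp, out, label=label)


def make_dualrail(
    kind: Literal["summation", "subtraction"],
    gamma: float,
    eta: float,
    in1p: str,
    in1m: str,
    in2p: str,
    in2m: str,
    outp: str,
    outm: str,
    label: str = "",
) -> CRN:
    """Dual-rail summation or subtraction over ``(+, -)`` encoded signals.

    Nine reactions.  For subtraction the second input's rails are crossed, so
    at equilibrium ``(outp - outm) = (in1p - in1m) - (in2p - in2m)``
    regardless of sign.  Requires a fast annihilation rate ``eta >> gamma``;
    a degraded ratio triggers a warning, not an error.
    """
    if kind not in ("summation", "subtraction"):
        raise ValueError(f"unknown dual-rail kind {kind!r}")
    if gamma <= 0:
        raise ValueError("rate gamma must be > 0")
    if eta < MIN_ETA_RATIO * gamma:
        warnings.warn(
            f"dual-rail contract degraded: eta={eta} < {MIN_ETA_RATIO}*gamma; "
            "annihilation may be too slow for accurate signed arithmetic",
            stacklevel=2,
        )
    g = _rate(label, "gamma")
    h = _rate(label, "eta")
    # second input feeds the crossed rails for subtraction
    to_p, to_m = (in2p, in2m) if kind == "summation" else (in2m, in2p)
    return build_crn(
        [
            Reaction({in1p: 1}, {in1p: 1, outp: 1}, g, gamma),
            Reaction({in1m: 1}, {in1m: 1, outm: 1}, g, gamma),
            Reaction({in1p: 1, in1m: 1}, {}, h, eta),
            Reaction({to_p: 1}, {to_p: 1, outp: 1}, g, gamma),
            Reaction({to_m: 1}, {to_m: 1, outm: 1}, g, gamma),
            Reaction({in2p: 1, in2m: 1}, {}, h, eta),
            Reaction({outp: 1}, {}, g, gamma),
            Reaction({outm: 1}, {}, g, gamma),
            Reaction({outp: 1, outm: 1}, {}, h, eta),
        ]
    )


@dataclass
class OperatorSpec:
    """Declarative description of an operator instance.

    ``build()`` dispatches to the corresponding factory.  ``inputs`` and
    ``output`` name the wiring species; dual-rail kinds expect rail pairs
    ``(in1p, in1m, in2p, in2m)`` and ``output=(outp, outm)``.
    """

    kind: OperatorKind
    gamma: float = 1.0
    k: float | None = None
    eta: float | None = None
    inputs: tuple[str, ...] = ()
    output: str | tuple[str, str] = ""
    intermediate: str = ""
    label: str = ""

    n_reactions: int = field(init=False)

    def __post_init__(self):
        if self.kind not in REACTION_COUNTS:
            raise ValueError(f"unknown operator kind {self.kind!r}")
        self.n_reactions = REACTION_COUNTS[self.kind]
        if self.kind.endswith("_dualrail"):
            eta = self.eta if self.eta is not None else DEFAULT_ETA_RATIO * self.gamma
            if eta < MIN_ETA_RATIO * self.gamma:
                warnings.warn(
                    "dual-rail operator specified with eta < "
                    f"{MIN_ETA_RATIO}*gamma (eta={eta}, gamma={self.gamma})",
                    stacklevel=2,
                )
            self.eta = eta

    def build(self) -> CRN:
        if self.kind == "gain":
            (inp,) = self.inputs
            return make_gain(self.k, self.gamma, inp, self.output, label=self.label)
        if self.kind == "proportional":
            (inp,) = self.inputs
            return make_proportional(self.k, self.gamma, inp, self.output, label=self.label)
        if self.kind == "summation3":
            in1, in2 = self.inputs
            return make_summation3(self.gamma, in1, in2, self.output, label=self.label)
        if self.kind == "subtraction_onesided":
            in1, in2 = self.inputs
            return make_subtraction_onesided(
                self.gamma, in1, in2, self.output, self.intermediate, label=self.label
            )
        if self.kind == "division":
            num, den = self.inputs
            return make_division(self.gamma, num, den, self.output, label=self.label)
        if self.kind == "integrator":
            (inp,) = self.inputs
            return make_integrator(self.k, inp, self.output, label=self.label)
        # dual-rail kinds
        in1p, in1m, in2p, in2m = self.inputs
        outp, outm = self.output
        return make_dualrail(
            self.kind.removesuffix("_dualrail"),
            self.gamma,
            self.eta,
            in1p,
            in1m,
            in2p,
            in2m,
            outp,
            outm,
            label=self.label,
        )
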