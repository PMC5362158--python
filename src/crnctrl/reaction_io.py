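"""Plain-text reaction-list parsing and serialization.

Grammar, one reaction per line::

    # comment
    clamp: r, beta
    xin + xe -> xi @ kr1=0.005
    xo -> empty @ g=1.0
    x2 -> x2 + xs @ gSbI=1.0
    2 A -> B @ k=0.1

``empty``, ``0`` and the empty-set symbol denote an empty side.  Coefficients
may be written as a leading integer (``2 A``) or by repetition (``A + A``).
Round-tripping through :func:`serialize_reaction_list` preserves species,
reactions, rates and the clamped set.
"""

from __future__ import annotations

import re

from .crn import CRN, Reaction, build_crn, format_reaction

__all__ = ["parse_reaction_list", "serialize_reaction_list", "ReactionParseError"]

_EMPTY_TOKENS = {"empty", "0", "∅"}
_TERM_RE = re.compile(r"^(?:(\d+)\s*\*?\s*)?([A-Za-z_][\w.+\-/]*)$")


class ReactionParseError(ValueError):
    """Malformed reaction-list input; carries the offending line number."""

    def __init__(self, message: str, line_no: int):
        super().__init__(f"line {line_no}: {message}")
        self.line_no = line_no


def _parse_side(text: str, line_no: int) -> dict[str, int]:
    text = text.strip()
    if text in _EMPTY_TOKENS:
        return {}
    counts: dict[str, int] = {}
    for raw in text.split("+"):
        term = raw.strip()
        if not term:
            raise ReactionParseError("empty term in reaction side", line_no)
        m = _TERM_RE.match(term)
        if not m:
            raise ReactionParseError(f"cannot parse species term {term!r}", line_no)
        coeff = int(m.group(1)) if m.group(1) else 1
        name = m.group(2)
        counts[name] = counts.get(name, 0) + coeff
    return counts


def parse_reaction_list(text: str, *, allow_higher_order: bool = False) -> CRN:
    """Parse a reaction-list document into a :class:`CRN`.

    Raises :class:`ReactionParseError` with a line number on any malformed
    line; molecularity violations surface from :func:`build_crn`.
    """
    reactions: list[Reaction] = []
    clamped: set[str] = set()
    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.lower().startswith("clamp:"):
            names = [n.strip() for n in line.split(":", 1)[1].split(",") if n.strip()]
            if not names:
                raise ReactionParseError("clamp directive lists no species", line_no)
            clamped.update(names)
            continue
        if "@" not in line:
            raise ReactionParseError("missing '@ rate_name=value' clause", line_no)
        body, rate_part = line.rsplit("@", 1)
        if "->" not in body:
            raise ReactionParseError("missing '->' arrow", line_no)
        lhs, rhs = body.split("->", 1)
        if "=" not in rate_part:
            raise ReactionParseError("rate clause must be 'name=value'", line_no)
        rate_name, rate_text = (s.strip() for s in rate_part.split("=", 1))
        if not rate_name:
            raise ReactionParseError("empty rate name", line_no)
        try:
            rate_value = float(rate_text)
        except ValueError:
            raise ReactionParseError(f"invalid rate value {rate_text!r}", line_no) from None
        try:
            reactions.append(
                Reaction(
                    _parse_side(lhs, line_no),
                    _parse_side(rhs, line_no),
                    rate_name,
                    rate_value,
                )
            )
        except ValueError as exc:
            raise ReactionParseError(str(exc), line_no) from None
    try:
        return build_crn(reactions, clamped, allow_higher_order=allow_higher_order)
    except ValueError as exc:
        raise ReactionParseError(str(exc), 0) from None


def serialize_reaction_list(crn: CRN) -> str:
    """Render a network in the reaction-list grammar (round-trip stable)."""
    lines = []
    if crn.clamped:
        ordered = [s for s in crn.species if s in crn.clamped]
        lines.append("clamp: " + ", ".join(ordered))
    lines.extend(format_reaction(rxn) for rxn in crn.reactions)
    return "\n".join(lines) + "\n"
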