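"""Stoichiometric network domain model and Metatool-dialect reader/writer.

A metabolic network is a list of metabolites (internal species must be
mass-balanced at steady state, external species are sources/sinks), a list of
reactions with signed rational stoichiometry (negative = consumed, positive =
produced) and a reversibility flag per reaction.  The internal stoichiometric
matrix ``S`` has one row per *internal* metabolite and one column per
reaction, in declaration order.

The text dialect follows the classic METATOOL input format: five sections
headed ``-ENZREV``, ``-ENZIRREV``, ``-METINT``, ``-METEXT`` and ``-CAT``,
with one equation per line in the last section::

    -ENZREV
    PGI

    -ENZIRREV
    Glc_up PFK

    -METINT
    G6P F6P

    -METEXT
    Glc_ext

    -CAT
    Glc_up : Glc_ext = G6P .
    PGI : G6P = F6P .
    PFK : F6P = .

Coefficients may be integers, decimals (converted exactly) or ``p/q``
rationals.  ``=``, ``<=>``, ``<->``, ``=>`` and ``->`` are all accepted as
the equation arrow; ``#`` starts a comment; a trailing ``.`` is optional.
Whitespace is insignificant.  Metabolite classification is authoritative from
-METINT/-METEXT, never inferred from topology.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicNetwork",
    "MetatoolParseError",
    "parse_metatool",
    "read_metatool",
    "write_metatool",
    "validate_network",
]

SECTIONS = ("-ENZREV", "-ENZIRREV", "-METINT", "-METEXT", "-CAT")

_ARROWS = ("<=>", "<->", "=>", "->", "=")


class MetatoolParseError(ValueError):
    """Raised on malformed Metatool input; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class Metabolite:
    id: str
    is_external: bool = False


@dataclass(frozen=True)
class Reaction:
    """A reaction with signed stoichiometry over metabolite ids.

    Direction convention: as written, the left side is consumed (negative
    coefficients).  ``reversible`` means the flux may be negative.
    """

    id: str
    stoichiometry: dict[str, Fraction] = field(hash=False)
    reversible: bool = False

    def __post_init__(self):
        clean = {m: Fraction(c) for m, c in self.stoichiometry.items() if c != 0}
        if not clean:
            raise ValueError(f"reaction {self.id!r} has no nonzero coefficient")
        object.__setattr__(self, "stoichiometry", clean)


class MetabolicNetwork:
    """Ordered metabolites + reactions with an internal stoichiometric matrix."""

    def __init__(self, metabolites: list[Metabolite], reactions: list[Reaction]):
        met_ids = [m.id for m in metabolites]
        if len(set(met_ids)) != len(met_ids):
            raise ValueError("duplicate metabolite ids")
        rxn_ids = [r.id for r in reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            raise ValueError("duplicate reaction ids")
        known = set(met_ids)
        for r in reactions:
            missing = set(r.stoichiometry) - known
            if missing:
                raise ValueError(
                    f"reaction {r.id!r} references undeclared metabolites: {sorted(missing)}"
                )
        self.metabolites = list(metabolites)
        self.reactions = list(reactions)

    # -- queries -----------------------------------------------------------
    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def internal_metabolites(self) -> list[Metabolite]:
        return [m for m in self.metabolites if not m.is_external]

    @property
    def external_metabolites(self) -> list[Metabolite]:
        return [m for m in self.metabolites if m.is_external]

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def n_reversible(self) -> int:
        return sum(r.reversible for r in self.reactions)

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolites)

    @property
    def n_internal(self) -> int:
        return len(self.internal_metabolites)

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def stoichiometric_matrix(self) -> list[list[Fraction]]:
        """Internal stoichiometric matrix S (rows = internal metabolites)."""
        rows = []
        for m in self.internal_metabolites:
            rows.append([r.stoichiometry.get(m.id, Fraction(0)) for r in self.reactions])
        return rows

    def stoichiometric_array(self) -> np.ndarray:
        return np.array(
            [[float(c) for c in row] for row in self.stoichiometric_matrix()], dtype=float
        ).reshape(self.n_internal, self.n_reactions)

    def summary(self) -> dict:
        return {
            "n_reactions": self.n_reactions,
            "n_reversible": self.n_reversible,
            "n_metabolites": self.n_metabolites,
            "n_internal": self.n_internal,
            "n_external": self.n_metabolites - self.n_internal,
        }

    def summary_json(self) -> str:
        return json.dumps(self.summary(), indent=2)

    def __eq__(self, other):
        if not isinstance(other, MetabolicNetwork):
            return NotImplemented
        return (
            self.metabolites == other.metabolites
            and [(r.id, r.stoichiometry, r.reversible) for r in self.reactions]
            == [(r.id, r.stoichiometry, r.reversible) for r in other.reactions]
        )

    def __repr__(self):
        return (
            f"MetabolicNetwork({self.n_reactions} reactions, "
            f"{self.n_reversible} reversible, {self.n_metabolites} metabolites, "
            f"{self.n_internal} internal)"
        )


# -- parsing ---------------------------------------------------------------


def _parse_coefficient(tok: str, lineno: int) -> Fraction:
    try:
        return Fraction(tok)
    except ValueError:
        raise MetatoolParseError(f"bad coefficient {tok!r}", lineno) from None


_TERM_RE = re.compile(r"^(?:(\d+(?:\.\d+)?|\d+/\d+)\s+)?(\S+)$")


def _parse_side(side: str, lineno: int) -> dict[str, Fraction]:
    terms: dict[str, Fraction] = {}
    side = side.strip()
    if not side:
        return terms
    for chunk in side.split("+"):
        chunk = chunk.strip()
        if not chunk:
            raise MetatoolParseError("empty term", lineno)
        m = _TERM_RE.match(chunk)
        if not m:
            raise MetatoolParseError(f"cannot parse term {chunk!r}", lineno)
        coef_tok, met = m.groups()
        coef = _parse_coefficient(coef_tok, lineno) if coef_tok else Fraction(1)
        terms[met] = terms.get(met, Fraction(0)) + coef
    return terms


def parse_metatool(text: str) -> MetabolicNetwork:
    """Parse a Metatool-dialect document into a :class:`MetabolicNetwork`."""
    sections: dict[str, list[tuple[int, str]]] = {s: [] for s in SECTIONS}
    headers_seen: set[str] = set()
    current: str | None = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("-"):
            header = line.split()[0]
            if header not in sections:
                raise MetatoolParseError(f"unknown section header {header!r}", lineno)
            current = header
            headers_seen.add(header)
            rest = line[len(header):].strip()
            if rest:
                sections[current].append((lineno, rest))
            continue
        if current is None:
            raise MetatoolParseError(f"content before any section header: {line!r}", lineno)
        sections[current].append((lineno, line))

    if current is None:
        raise MetatoolParseError("document contains no Metatool sections", 1)
    for s in SECTIONS:
        if s not in headers_seen:
            raise MetatoolParseError(f"missing section {s}", 1)

    def tokens(sec: str) -> list[tuple[int, str]]:
        out = []
        for lineno, line in sections[sec]:
            for tok in line.split():
                out.append((lineno, tok))
        return out

    rev = tokens("-ENZREV")
    irrev = tokens("-ENZIRREV")
    rxn_flags: dict[str, bool] = {}
    for lineno, name in rev + [(l, n) for l, n in irrev]:
        if name in rxn_flags:
            raise MetatoolParseError(f"duplicate reaction id {name!r}", lineno)
        rxn_flags[name] = False
    for _, name in rev:
        rxn_flags[name] = True

    metabolites: list[Metabolite] = []
    met_seen: set[str] = set()
    for sec, ext in (("-METINT", False), ("-METEXT", True)):
        for lineno, name in tokens(sec):
            if name in met_seen:
                raise MetatoolParseError(f"duplicate metabolite id {name!r}", lineno)
            met_seen.add(name)
            metabolites.append(Metabolite(name, is_external=ext))

    stoich: dict[str, dict[str, Fraction]] = {}
    order: list[str] = []
    for lineno, line in sections["-CAT"]:
        if ":" not in line:
            raise MetatoolParseError(f"equation missing ':' separator: {line!r}", lineno)
        name, eq = line.split(":", 1)
        name = name.strip()
        if name not in rxn_flags:
            raise MetatoolParseError(f"unknown reaction name {name!r} in -CAT", lineno)
        if name in stoich:
            raise MetatoolParseError(f"duplicate equation for reaction {name!r}", lineno)
        eq = eq.strip()
        if eq.endswith("."):
            eq = eq[:-1].strip()
        for arrow in _ARROWS:
            if arrow in eq:
                lhs, rhs = eq.split(arrow, 1)
                break
        else:
            raise MetatoolParseError(f"equation has no arrow: {eq!r}", lineno)
        coeffs: dict[str, Fraction] = {}
        for met, c in _parse_side(lhs, lineno).items():
            coeffs[met] = coeffs.get(met, Fraction(0)) - c
        for met, c in _parse_side(rhs, lineno).items():
            coeffs[met] = coeffs.get(met, Fraction(0)) + c
        for met in coeffs:
            if met not in met_seen:
                raise MetatoolParseError(
                    f"metabolite {met!r} not declared in -METINT or -METEXT", lineno
                )
        if not any(c != 0 for c in coeffs.values()):
            raise MetatoolParseError(f"reaction {name!r} has empty stoichiometry", lineno)
        stoich[name] = coeffs
        order.append(name)

    missing = [n for n in rxn_flags if n not in stoich]
    if missing:
        raise MetatoolParseError(f"reactions declared but lacking a -CAT equation: {missing}", 1)

    # reaction order follows -CAT order (the only place stoichiometry lives)
    reactions = [Reaction(n, stoich[n], reversible=rxn_flags[n]) for n in order]
    return MetabolicNetwork(metabolites, reactions)


def read_metatool(path) -> MetabolicNetwork:
    with open(path, encoding="utf-8") as fh:
        return parse_metatool(fh.read())


# -- writing ---------------------------------------------------------------


def _fmt_coeff(c: Fraction) -> str:
    return str(c.numerator) if c.denominator == 1 else f"{c.numerator}/{c.denominator}"


def _fmt_side(terms: list[tuple[str, Fraction]]) -> str:
    parts = []
    for met, c in terms:
        parts.append(met if c == 1 else f"{_fmt_coeff(c)} {met}")
    return " + ".join(parts)


def write_metatool(network: MetabolicNetwork) -> str:
    """Serialize a network to the Metatool dialect (round-trips exactly)."""
    lines: list[str] = []
    lines.append("-ENZREV")
    lines.append(" ".join(r.id for r in network.reactions if r.reversible))
    lines.append("")
    lines.append("-ENZIRREV")
    lines.append(" ".join(r.id for r in network.reactions if not r.reversible))
    lines.append("")
    lines.append("-METINT")
    lines.append(" ".join(m.id for m in network.internal_metabolites))
    lines.append("")
    lines.append("-METEXT")
    lines.append(" ".join(m.id for m in network.external_metabolites))
    lines.append("")
    lines.append("-CAT")
    for r in network.reactions:
        lhs = [(m, -c) for m, c in r.stoichiometry.items() if c < 0]
        rhs = [(m, c) for m, c in r.stoichiometry.items() if c > 0]
        lines.append(f"{r.id} : {_fmt_side(lhs)} = {_fmt_side(rhs)} .")
    return "\n".join(lines).rstrip() + "\n"


# -- diagnostics -----------------------------------------------------------


def validate_network(network: MetabolicNetwork) -> dict[str, list]:
    """Structural diagnostics (not failures): dead ends, unused metabolites,
    duplicate stoichiometries.

    An internal metabolite is a dead end when, over all reactions touching
    it, it can only ever be produced or only ever be consumed (reversible
    reactions can do both).
    """
    produced: set[str] = set()
    consumed: set[str] = set()
    touched: set[str] = set()
    for r in network.reactions:
        for met, c in r.stoichiometry.items():
            touched.add(met)
            if r.reversible:
                produced.add(met)
                consumed.add(met)
            elif c > 0:
                produced.add(met)
            else:
                consumed.add(met)
    dead_ends = [
        m.id
        for m in network.internal_metabolites
        if m.id in touched and (m.id not in produced or m.id not in consumed)
    ]
    unused = [m.id for m in network.metabolites if m.id not in touched]
    sigs: dict[tuple, list[str]] = {}
    for r in network.reactions:
        key = tuple(sorted(r.stoichiometry.items()))
        sigs.setdefault(key, []).append(r.id)
    duplicates = [ids for ids in sigs.values() if len(ids) > 1]
    return {
        "dead_end_internal": dead_ends,
        "unused_metabolites": unused,
        "duplicate_reactions": duplicates,
    }
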