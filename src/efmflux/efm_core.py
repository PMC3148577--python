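"""Elementary flux mode enumeration.

An elementary flux mode (EFM) of a network with internal stoichiometric
matrix ``S`` is a flux vector ``e`` satisfying

* steady state: ``S @ e == 0`` exactly,
* feasibility: ``e_j >= 0`` for every irreversible reaction ``j``,
* non-decomposability: the columns of ``S`` restricted to the support of
  ``e`` have rank ``|support| - 1`` (equivalently, the support carries a
  one-dimensional kernel).

Enumeration uses the nullspace-initialized double description method in the
METATOOL style: reversible reactions are split into forward/backward halves,
the kernel of the split matrix seeds the lineality space, and the
nonnegativity constraints are processed one reaction at a time.  Candidate
rays generated from positive/negative pairs are admitted by the algebraic
rank (face-dimension) adjacency test, which stays correct even if redundant
rays are present.  All arithmetic is exact (``fractions.Fraction``); modes
are stored in canonical coprime-integer form.

A fully reversible mode and its negation count as a single EFM, and futile
two-cycles created by splitting a reversible reaction are discarded — the
METATOOL counting convention.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np

from ._rational import ZERO, Matrix, Row, is_zero, matvec, nullspace, primitive, rank
from .netio import MetabolicNetwork, Metabolite, Reaction

__all__ = [
    "FluxMode",
    "EFMSet",
    "ModeCountExceeded",
    "split_reversible",
    "enumerate_efms",
    "is_elementary",
    "brute_force_efms",
]

DEFAULT_MODE_CEILING = 500_000


class ModeCountExceeded(RuntimeError):
    """Enumeration aborted because the mode-count ceiling was hit."""


@dataclass(frozen=True)
class FluxMode:
    """A single elementary mode: exact coefficients over the reaction index."""

    coefficients: tuple[Fraction, ...]

    @property
    def support(self) -> frozenset[int]:
        return frozenset(j for j, c in enumerate(self.coefficients) if c != 0)

    def __len__(self):
        return len(self.coefficients)


class EFMSet:
    """A set of elementary modes over a shared reaction index.

    The conceptual object is the N x P matrix of modes (N rows of modes,
    P reaction columns).  ``label`` carries provenance (e.g. a substrate
    subset name).
    """

    def __init__(self, reaction_ids: Sequence[str], modes: Iterable[FluxMode], label: str = ""):
        self.reaction_ids = tuple(reaction_ids)
        self.modes = list(modes)
        self.label = label
        for m in self.modes:
            if len(m) != len(self.reaction_ids):
                raise ValueError("mode length does not match reaction index")

    def __len__(self):
        return len(self.modes)

    def __iter__(self):
        return iter(self.modes)

    @property
    def n_modes(self) -> int:
        return len(self.modes)

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    def column(self, reaction_id: str) -> int:
        try:
            return self.reaction_ids.index(reaction_id)
        except ValueError:
            raise KeyError(reaction_id) from None

    def as_array(self) -> np.ndarray:
        """Float N x P view of the mode matrix."""
        return np.array(
            [[float(c) for c in m.coefficients] for m in self.modes], dtype=float
        ).reshape(len(self.modes), len(self.reaction_ids))

    def as_l1_normalized(self) -> np.ndarray:
        a = self.as_array()
        norms = np.abs(a).sum(axis=1, keepdims=True)
        return a / norms

    # -- TSV round trip ----------------------------------------------------
    def to_tsv(self) -> str:
        buf = io.StringIO()
        if self.label:
            buf.write(f"# label: {self.label}\n")
        buf.write("\t".join(self.reaction_ids) + "\n")
        for m in self.modes:
            buf.write("\t".join(str(c) for c in m.coefficients) + "\n")
        return buf.getvalue()

    @classmethod
    def from_tsv(cls, text: str) -> "EFMSet":
        label = ""
        lines = [ln for ln in text.splitlines() if ln.strip()]
        rows = []
        header: list[str] | None = None
        for ln in lines:
            if ln.startswith("#"):
                if "label:" in ln:
                    label = ln.split("label:", 1)[1].strip()
                continue
            if header is None:
                header = ln.split("\t")
            else:
                rows.append(tuple(Fraction(tok) for tok in ln.split("\t")))
        if header is None:
            raise ValueError("empty EFM table")
        return cls(header, [FluxMode(r) for r in rows], label=label)

    def __repr__(self):
        lab = f" {self.label!r}" if self.label else ""
        return f"EFMSet({self.n_modes} modes x {self.n_reactions} reactions{lab})"


# -- preprocessing ---------------------------------------------------------


def split_reversible(network: MetabolicNetwork):
    """Split every reversible reaction into irreversible forward/backward halves.

    Returns ``(split_network, mapping)`` where ``mapping[k] = (orig_index,
    sign)`` recombines split column ``k`` into the original reaction index:
    ``v_orig[j] = sum(sign * v_split[k] for k mapping to j)``.
    """
    reactions: list[Reaction] = []
    mapping: list[tuple[int, int]] = []
    for j, r in enumerate(network.reactions):
        if r.reversible:
            reactions.append(Reaction(r.id + "__fwd", dict(r.stoichiometry), reversible=False))
            mapping.append((j, +1))
            neg = {m: -c for m, c in r.stoichiometry.items()}
            reactions.append(Reaction(r.id + "__bwd", neg, reversible=False))
            mapping.append((j, -1))
        else:
            reactions.append(Reaction(r.id, dict(r.stoichiometry), reversible=False))
            mapping.append((j, +1))
    return MetabolicNetwork(list(network.metabolites), reactions), mapping


# -- double description ----------------------------------------------------


def _extreme_rays_nonneg(S: Matrix, m: int, ceiling: int) -> list[Row]:
    """Extreme rays of the pointed cone {v in R^m : S v = 0, v >= 0}.

    Double description seeded with the kernel of S as the lineality space;
    the nonnegativity constraints are processed coordinate by coordinate.
    """
    lineality: list[Row] = nullspace(S, m)
    rays: list[Row] = []
    processed: list[int] = []

    def face_dim(zero_set: list[int]) -> int:
        aug = [row[:] for row in S]
        for z in zero_set:
            unit = [ZERO] * m
            unit[z] = Fraction(1)
            aug.append(unit)
        return m - rank(aug)

    for j in range(m):
        pivot = next((l for l in lineality if l[j] != 0), None)
        if pivot is not None:
            pj = pivot[j]
            lineality = [
                [a - (l[j] / pj) * b for a, b in zip(l, pivot)]
                for l in lineality
                if l is not pivot
            ]
            projected = [
                primitive([a - (w[j] / pj) * b for a, b in zip(w, pivot)]) for w in rays
            ]
            r0 = pivot if pj > 0 else [-a for a in pivot]
            projected.append(primitive(r0))
            seen: dict[tuple, Row] = {}
            for w in projected:
                if not is_zero(w):
                    seen.setdefault(tuple(w), w)
            rays = list(seen.values())
        else:
            pos = [w for w in rays if w[j] > 0]
            neg = [w for w in rays if w[j] < 0]
            zero = [w for w in rays if w[j] == 0]
            new_rays = pos + zero
            lin_dim = len(lineality)
            for p in pos:
                for n in neg:
                    tight = [
                        k for k in processed if p[k] == 0 and n[k] == 0
                    ]
                    # algebraic adjacency: the minimal face containing both
                    # rays must have dimension lineality + 2
                    if face_dim(tight) != lin_dim + 2:
                        continue
                    combo = [p[j] * b - n[j] * a for a, b in zip(p, n)]
                    new_rays.append(primitive(combo))
            # dedupe (combinations of different pairs can coincide)
            seen: dict[tuple, Row] = {}
            for w in new_rays:
                seen.setdefault(tuple(w), w)
            rays = list(seen.values())
            if len(rays) > ceiling:
                raise ModeCountExceeded(
                    f"intermediate ray count {len(rays)} exceeds ceiling {ceiling}"
                )
        processed.append(j)
    return rays


def _canonicalize(v: Row, reversible: Sequence[bool]) -> tuple[Fraction, ...] | None:
    """Coprime-integer canonical form; None for the zero vector.

    Sign convention: irreversible coefficients must be nonnegative; a mode
    whose support is fully reversible is oriented so its first nonzero
    coefficient is positive (a reversible mode and its negation are one EFM).
    """
    if is_zero(v):
        return None
    v = primitive(v)
    support_irrev = [j for j, c in enumerate(v) if c != 0 and not reversible[j]]
    if support_irrev:
        if any(v[j] < 0 for j in support_irrev):
            if all(v[j] <= 0 for j in support_irrev):
                v = [-a for a in v]
            # mixed signs on irreversible support cannot be canonicalized;
            # caller filters by feasibility
    else:
        first = next(c for c in v if c != 0)
        if first < 0:
            v = [-a for a in v]
    return tuple(v)


def _sorted_modes(modes: Iterable[tuple[Fraction, ...]]) -> list[FluxMode]:
    uniq = sorted(set(modes), key=lambda t: (sum(c != 0 for c in t), t))
    return [FluxMode(t) for t in uniq]


def enumerate_efms(
    network: MetabolicNetwork,
    max_modes: int = DEFAULT_MODE_CEILING,
    label: str = "",
) -> EFMSet:
    """Enumerate all elementary flux modes of a network.

    Raises :class:`ModeCountExceeded` if the (intermediate or final) mode
    count exceeds ``max_modes``.
    """
    if network.n_reactions == 0:
        return EFMSet([], [], label=label)
    split, mapping = split_reversible(network)
    S_split = split.stoichiometric_matrix()
    m = split.n_reactions
    rays = _extreme_rays_nonneg(S_split, m, max_modes)

    reversible = [r.reversible for r in network.reactions]
    P = network.n_reactions
    S = network.stoichiometric_matrix()
    out: set[tuple[Fraction, ...]] = set()
    for ray in rays:
        v: Row = [ZERO] * P
        for k, (j, sign) in enumerate(mapping):
            if ray[k] != 0:
                v[j] += sign * ray[k]
        canon = _canonicalize(v, reversible)
        if canon is None:
            continue  # futile two-cycle collapsed to zero
        # final elementarity guard: support must carry rank |support| - 1
        support = [j for j, c in enumerate(canon) if c != 0]
        sub = [[row[j] for j in support] for row in S]
        if rank(sub) != len(support) - 1:
            continue
        out.add(canon)
        if len(out) > max_modes:
            raise ModeCountExceeded(f"mode count exceeds ceiling {max_modes}")
    return EFMSet(network.reaction_ids, _sorted_modes(out), label=label)


# -- verification ----------------------------------------------------------


@dataclass(frozen=True)
class ElementarityResult:
    ok: bool
    reason: str

    def __bool__(self):
        return self.ok


def is_elementary(network: MetabolicNetwork, flux_vector: Sequence) -> ElementarityResult:
    """Check the three defining conditions for a flux vector.

    Steady state (``S e = 0`` in exact arithmetic), feasibility
    (nonnegative flux through irreversible reactions) and
    non-decomposability (rank of S restricted to the support equals
    ``|support| - 1``).
    """
    P = network.n_reactions
    if len(flux_vector) != P:
        raise ValueError(f"expected a vector of length {P}, got {len(flux_vector)}")
    v = [Fraction(x) if not isinstance(x, float) else Fraction(x).limit_denominator(10**9)
         for x in flux_vector]
    if is_zero(v):
        return ElementarityResult(False, "zero vector (empty support)")
    S = network.stoichiometric_matrix()
    if not is_zero(matvec(S, v)):
        return ElementarityResult(False, "not at steady state (S e != 0)")
    for j, r in enumerate(network.reactions):
        if not r.reversible and v[j] < 0:
            return ElementarityResult(False, f"negative flux through irreversible {r.id!r}")
    support = [j for j, c in enumerate(v) if c != 0]
    sub = [[row[j] for j in support] for row in S]
    if rank(sub) != len(support) - 1:
        return ElementarityResult(False, "decomposable (support rank != |support| - 1)")
    return ElementarityResult(True, "elementary")


# -- brute-force oracle ----------------------------------------------------


def brute_force_efms(
    network: MetabolicNetwork, max_columns: int = 18, label: str = ""
) -> EFMSet:
    """Exhaustive EFM enumeration over all support subsets.

    Independent oracle for :func:`enumerate_efms`: a subset T of reactions
    carries an elementary mode iff S restricted to T has a one-dimensional
    kernel whose vector is nonzero on all of T and sign-feasible.  Exponential
    in the reaction count; refuses networks with more than ``max_columns``
    reactions.
    """
    P = network.n_reactions
    if P > max_columns:
        raise ValueError(f"{P} reactions exceeds brute-force limit {max_columns}")
    S = network.stoichiometric_matrix()
    reversible = [r.reversible for r in network.reactions]
    found: set[tuple[Fraction, ...]] = set()
    for mask in range(1, 1 << P):
        support = [j for j in range(P) if mask >> j & 1]
        sub = [[row[j] for j in support] for row in S]
        kern = nullspace(sub, len(support))
        if len(kern) != 1:
            continue
        k = kern[0]
        if any(c == 0 for c in k):
            continue
        v: Row = [ZERO] * P
        for idx, j in enumerate(support):
            v[j] = k[idx]
        feasible = all(v[j] >= 0 for j in support if not reversible[j])
        feasible_neg = all(-v[j] >= 0 for j in support if not reversible[j])
        if not feasible and not feasible_neg:
            continue
        if not feasible:
            v = [-a for a in v]
        canon = _canonicalize(v, reversible)
        if canon is not None:
            found.add(canon)
    return EFMSet(network.reaction_ids, _sorted_modes(found), label=label)
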