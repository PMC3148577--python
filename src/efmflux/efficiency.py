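"""The coefficient of flux efficiency.

Each elementary mode row ``e_i`` of an EFM matrix is turned into a row of
flux efficiencies by dividing every coefficient by the mode's total absolute
flux (the proxy for the enzyme investment needed to establish the mode):

    eps_ij = e_ij / sum_l |e_il|

The per-reaction coefficient of flux efficiency is the average of these
shares over the whole EFM set (size N), with the forward (positive) and
backward (negative) directions of reversible reactions averaged separately:

    eps_j+ = (1/N) * sum_i max(eps_ij, 0)
    eps_j- = (1/N) * sum_i min(eps_ij, 0)
    eps_j  = eps_j+ + eps_j-

No growth or ATP objective enters: the coefficient is determined from the
EFM matrix alone.  A reaction used by no mode has efficiency zero; a reaction
that occurs frequently in short modes gets a large coefficient.

All values are exact rationals internally; ``as_frame`` gives a float view.
The averaging denominator is N (all modes) by default; dividing by the number
of modes that actually use the reaction is available as
``average_over="active_modes"`` for sensitivity analyses.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import pandas as pd

from .efm_core import EFMSet

__all__ = [
    "EfficiencyMatrix",
    "EfficiencyVector",
    "efficiency_matrix",
    "flux_efficiency",
    "efficiency_from_modes",
]


@dataclass(frozen=True)
class EfficiencyMatrix:
    """N x P matrix of per-mode flux-efficiency shares (exact rationals).

    Every row with nonempty support has unit L1 norm; zeros and signs match
    the underlying EFM matrix entry-for-entry.
    """

    reaction_ids: tuple[str, ...]
    rows: tuple[tuple[Fraction, ...], ...]

    @property
    def n_modes(self) -> int:
        return len(self.rows)

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [[float(c) for c in row] for row in self.rows],
            columns=list(self.reaction_ids),
            dtype=float,
        )


@dataclass(frozen=True)
class EfficiencyVector:
    """Per-reaction flux efficiency, split into forward/backward components."""

    reaction_ids: tuple[str, ...]
    forward: tuple[Fraction, ...]
    backward: tuple[Fraction, ...]
    n_modes_using: tuple[int, ...]
    n_modes: int
    label: str = ""

    @property
    def net(self) -> tuple[Fraction, ...]:
        return tuple(f + b for f, b in zip(self.forward, self.backward))

    def __getitem__(self, reaction_id: str) -> Fraction:
        return self.net[self.reaction_ids.index(reaction_id)]

    def as_series(self) -> pd.Series:
        return pd.Series([float(x) for x in self.net], index=list(self.reaction_ids), name="eps")

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "reaction_id": list(self.reaction_ids),
                "eps_forward": [float(x) for x in self.forward],
                "eps_backward": [float(x) for x in self.backward],
                "eps_net": [float(x) for x in self.net],
                "n_modes_using": list(self.n_modes_using),
            }
        )

    def to_tsv(self) -> str:
        buf = io.StringIO()
        if self.label:
            buf.write(f"# label: {self.label}\n")
        buf.write(f"# n_modes: {self.n_modes}\n")
        self.as_frame().to_csv(buf, sep="\t", index=False)
        return buf.getvalue()


def efficiency_matrix(efmset: EFMSet) -> EfficiencyMatrix:
    """Transform an EFM matrix into the efficiency matrix (per-mode L1 shares)."""
    if efmset.n_modes == 0:
        raise ValueError("cannot build an efficiency matrix from an empty EFM set")
    rows = []
    for mode in efmset:
        total = sum(abs(c) for c in mode.coefficients)
        rows.append(tuple(c / total for c in mode.coefficients))
    return EfficiencyMatrix(tuple(efmset.reaction_ids), tuple(rows))


def flux_efficiency(
    eff_matrix: EfficiencyMatrix,
    average_over: str = "all_modes",
    label: str = "",
) -> EfficiencyVector:
    """Average the efficiency matrix into per-reaction coefficients.

    ``average_over="all_modes"`` divides by N (the default reading);
    ``"active_modes"`` divides by the number of modes using each reaction.
    """
    if average_over not in ("all_modes", "active_modes"):
        raise ValueError(f"unknown average_over {average_over!r}")
    N = eff_matrix.n_modes
    if N == 0:
        raise ValueError("efficiency undefined for an empty mode set")
    forward: list[Fraction] = []
    backward: list[Fraction] = []
    using: list[int] = []
    for j in range(eff_matrix.n_reactions):
        col = [row[j] for row in eff_matrix.rows]
        nz = sum(1 for c in col if c != 0)
        denom = N if average_over == "all_modes" else max(nz, 1)
        forward.append(sum((c for c in col if c > 0), Fraction(0)) / denom)
        backward.append(sum((c for c in col if c < 0), Fraction(0)) / denom)
        using.append(nz)
    return EfficiencyVector(
        reaction_ids=tuple(eff_matrix.reaction_ids),
        forward=tuple(forward),
        backward=tuple(backward),
        n_modes_using=tuple(using),
        n_modes=N,
        label=label,
    )


def efficiency_from_modes(
    efmset: EFMSet, average_over: str = "all_modes", label: str | None = None
) -> EfficiencyVector:
    """Convenience: EFM set straight to the per-reaction efficiency vector."""
    return flux_efficiency(
        efficiency_matrix(efmset),
        average_over=average_over,
        label=efmset.label if label is None else label,
    )
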