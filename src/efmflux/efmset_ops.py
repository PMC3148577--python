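"""Operations on EFM sets: substrate filtering, usage counts, knockouts.

Condition-specific subsets are built the way the study defines them: a
"mineral-nitrogen" style subset keeps modes that take up the sugar but touch
none of the amino-acid uptakes ({required active: sugar uptake, forbidden:
amino-acid uptakes}); an "at least one uptake" subset only requires some
uptake reaction in the support.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .efm_core import EFMSet
from .netio import MetabolicNetwork

__all__ = ["SubstrateFilter", "filter_modes", "count_modes_using", "knockout"]


@dataclass(frozen=True)
class SubstrateFilter:
    """Keep modes using >= 1 of ``required_active`` (if nonempty) and none of
    ``forbidden``."""

    required_active: frozenset[str] = field(default_factory=frozenset)
    forbidden: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        object.__setattr__(self, "required_active", frozenset(self.required_active))
        object.__setattr__(self, "forbidden", frozenset(self.forbidden))
        overlap = self.required_active & self.forbidden
        if overlap:
            raise ValueError(f"reactions both required and forbidden: {sorted(overlap)}")


def _columns(efmset: EFMSet, ids) -> list[int]:
    return [efmset.column(rid) for rid in ids]


def filter_modes(efmset: EFMSet, flt: SubstrateFilter, label: str = "") -> EFMSet:
    """Select the sub-EFMset matching a substrate-usage filter.

    Raises ``KeyError`` for a filter id absent from the reaction index.
    Idempotent; never enlarges the set.
    """
    req = _columns(efmset, sorted(flt.required_active))
    forb = _columns(efmset, sorted(flt.forbidden))
    kept = []
    for mode in efmset:
        sup = mode.support
        if req and not any(j in sup for j in req):
            continue
        if any(j in sup for j in forb):
            continue
        kept.append(mode)
    return EFMSet(efmset.reaction_ids, kept, label=label or efmset.label)


def count_modes_using(efmset: EFMSet, reaction_id: str) -> int:
    """Number of modes with nonzero flux through ``reaction_id``."""
    j = efmset.column(reaction_id)
    return sum(1 for mode in efmset if j in mode.support)


def knockout(network: MetabolicNetwork, reaction_id: str) -> MetabolicNetwork:
    """Remove one reaction from the network (for robustness re-enumeration).

    Every elementary mode of the reduced network is a mode of the original
    with zero flux at the removed reaction; knockouts never create modes.
    """
    if reaction_id not in network.reaction_ids:
        raise KeyError(reaction_id)
    reactions = [r for r in network.reactions if r.id != reaction_id]
    return MetabolicNetwork(list(network.metabolites), reactions)
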