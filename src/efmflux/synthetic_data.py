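"""Synthetic networks and flux data with known elementary-mode structure.

Three generators make every pipeline stage testable without the original
supplementary inputs:

* motif networks (chains and parallel-branch blocks) whose EFM count is the
  product of the branch counts — an analytic ground truth;
* seeded sparse random networks for oracle cross-checks;
* synthetic flux tables built as nonnegative combinations of elementary
  modes with multiplicative lognormal noise, emulating the statistical
  structure of 13C-MFA flux maps (steady-state consistent, sign-preserving,
  error proportional to the flux).

The module also packages two fixture networks standing in for the study
systems: a TCA-centred plant embryo core network with glucose, glutamine and
alanine uptakes, and a bacterial central-carbon network (glycolysis, a
lumped pentose phosphate shunt, TCA, lysine synthesis) with interchangeable
sugar uptake.  Both are SYNTHETIC stand-ins written from the biology the
study describes, not transcriptions of its supplementary files, and their
mode counts are fixture properties of this package only.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np

from .comparison import FluxTable
from .efm_core import EFMSet
from .netio import MetabolicNetwork, Metabolite, Reaction

__all__ = [
    "SyntheticSpec",
    "make_motif_network",
    "make_random_network",
    "make_flux_table",
    "efficiency_weights",
    "chain_network",
    "diamond_network",
    "plant_core_network",
    "plant_condition_dataset",
    "bacterial_network",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """A stated world for a synthetic experiment.

    ``blocks``: parallel-branch counts of the motif network (1 = plain chain
    link).  ``noise``: relative standard deviation of the multiplicative
    measurement noise (default 0.05, a typical relative error for
    well-determined central-metabolism fluxes).  Identical seeds give
    identical outputs everywhere.
    """

    blocks: tuple[int, ...] = (1,)
    reversible_fraction: float = 0.0
    noise: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if any(b < 1 for b in self.blocks):
            raise ValueError("branch counts must be >= 1")
        if not 0 <= self.reversible_fraction <= 1:
            raise ValueError("reversible_fraction must be in [0, 1]")
        if self.noise < 0:
            raise ValueError("noise must be >= 0")


# -- motif networks --------------------------------------------------------


def make_motif_network(blocks: Sequence[int]) -> tuple[MetabolicNetwork, int]:
    """Serial chain of parallel-branch blocks with an analytic EFM count.

    A block of ``k`` parallel branches multiplies the mode count by ``k``;
    plain chain links (k = 1) contribute a factor of one.  Returns the
    network together with the expected count (the product of the blocks).
    All reactions are irreversible.
    """
    blocks = tuple(int(b) for b in blocks)
    if any(b < 1 for b in blocks):
        raise ValueError("branch counts must be >= 1")
    n_nodes = len(blocks) + 1
    mets = [Metabolite("SRC_ext", True)] + [
        Metabolite(f"M{i}", False) for i in range(n_nodes)
    ] + [Metabolite("SNK_ext", True)]
    reactions = [Reaction("uptake", {"SRC_ext": Fraction(-1), "M0": Fraction(1)})]
    for b, k in enumerate(blocks):
        for i in range(k):
            name = f"B{b}_{i + 1}" if k > 1 else f"C{b}"
            reactions.append(
                Reaction(name, {f"M{b}": Fraction(-1), f"M{b + 1}": Fraction(1)})
            )
    reactions.append(
        Reaction("output", {f"M{n_nodes - 1}": Fraction(-1), "SNK_ext": Fraction(1)})
    )
    expected = 1
    for k in blocks:
        expected *= k
    return MetabolicNetwork(mets, reactions), expected


def chain_network() -> MetabolicNetwork:
    """Toy fixture: Glc_ext -> Glc -> Pyr -> Pyr_ext (one mode, (1,1,1))."""
    mets = [
        Metabolite("Glc_ext", True),
        Metabolite("Glc", False),
        Metabolite("Pyr", False),
        Metabolite("Pyr_ext", True),
    ]
    rxns = [
        Reaction("Glc_up", {"Glc_ext": Fraction(-1), "Glc": Fraction(1)}),
        Reaction("Glyc", {"Glc": Fraction(-1), "Pyr": Fraction(1)}),
        Reaction("Pyr_out", {"Pyr": Fraction(-1), "Pyr_ext": Fraction(1)}),
    ]
    return MetabolicNetwork(mets, rxns)


def diamond_network() -> MetabolicNetwork:
    """Toy fixture: two parallel routes A->B->D and A->C->D (two modes)."""
    mets = [Metabolite(m, False) for m in "ABCD"] + [
        Metabolite("IN_ext", True),
        Metabolite("OUT_ext", True),
    ]
    rxns = [
        Reaction("r_in", {"IN_ext": Fraction(-1), "A": Fraction(1)}),
        Reaction("r_ab", {"A": Fraction(-1), "B": Fraction(1)}),
        Reaction("r_ac", {"A": Fraction(-1), "C": Fraction(1)}),
        Reaction("r_bd", {"B": Fraction(-1), "D": Fraction(1)}),
        Reaction("r_cd", {"C": Fraction(-1), "D": Fraction(1)}),
        Reaction("r_out", {"D": Fraction(-1), "OUT_ext": Fraction(1)}),
    ]
    return MetabolicNetwork(mets, rxns)


# -- random networks -------------------------------------------------------


def make_random_network(
    n_internal: int,
    n_reactions: int,
    reversible_fraction: float = 0.3,
    seed: int = 0,
) -> MetabolicNetwork:
    """Seeded sparse random network with one uptake and one output reaction.

    Interior reactions convert 1-2 internal metabolites into 1-2 others with
    coefficients in {1, 2}; a ``reversible_fraction`` of them is reversible.
    ``n_reactions`` counts all reactions including the two exchanges, so
    ``n_reactions >= n_internal + 1`` is recommended for a nontrivial kernel.
    """
    if n_internal < 1 or n_reactions < 2:
        raise ValueError("need at least one internal metabolite and two reactions")
    rng = np.random.default_rng(seed)
    internal = [f"M{i}" for i in range(n_internal)]
    mets = [Metabolite(m, False) for m in internal] + [
        Metabolite("SRC_ext", True),
        Metabolite("SNK_ext", True),
    ]
    reactions = [
        Reaction(
            "uptake",
            {"SRC_ext": Fraction(-1), internal[int(rng.integers(n_internal))]: Fraction(1)},
        )
    ]
    for k in range(n_reactions - 2):
        n_sub = int(rng.integers(1, min(2, n_internal) + 1))
        n_prod = int(rng.integers(1, min(2, n_internal) + 1))
        picks = rng.choice(n_internal, size=min(n_sub + n_prod, n_internal), replace=False)
        subs = picks[:n_sub]
        prods = picks[n_sub:]
        if len(prods) == 0:  # tiny networks: recycle a substrate slot
            subs, prods = picks[:1], picks[1:] if len(picks) > 1 else picks[:1]
        stoich: dict[str, Fraction] = {}
        for i in subs:
            stoich[internal[int(i)]] = stoich.get(internal[int(i)], Fraction(0)) - Fraction(
                int(rng.integers(1, 3))
            )
        for i in prods:
            stoich[internal[int(i)]] = stoich.get(internal[int(i)], Fraction(0)) + Fraction(
                int(rng.integers(1, 3))
            )
        if all(c == 0 for c in stoich.values()):
            stoich[internal[int(subs[0])]] = Fraction(-1)
            stoich["SNK_ext"] = Fraction(1)
        rev = bool(rng.random() < reversible_fraction)
        reactions.append(Reaction(f"R{k}", stoich, reversible=rev))
    reactions.append(
        Reaction(
            "output",
            {internal[int(rng.integers(n_internal))]: Fraction(-1), "SNK_ext": Fraction(1)},
        )
    )
    return MetabolicNetwork(mets, reactions)


# -- flux tables -----------------------------------------------------------


def efficiency_weights(efmset: EFMSet) -> np.ndarray:
    """Mode weights that make the noiseless flux vector equal the net
    flux-efficiency vector of the set (w_i = 1 / (N * ||e_i||_1))."""
    if efmset.n_modes == 0:
        raise ValueError("empty EFM set")
    norms = np.abs(efmset.as_array()).sum(axis=1)
    return 1.0 / (efmset.n_modes * norms)


def make_flux_table(
    efmset: EFMSet,
    weights: Sequence[float],
    noise: float = 0.0,
    seed: int = 0,
    condition: str = "synthetic",
) -> FluxTable:
    """Synthetic flux table: F = sum_i w_i e_i with multiplicative noise.

    ``weights`` are nonnegative, one per mode.  Each reaction's flux is
    multiplied by a mean-one lognormal factor of relative standard deviation
    ``noise``; the ``se`` column is ``noise * |F|``.  Noiseless tables
    satisfy S @ F = 0 exactly.
    """
    w = np.asarray(weights, dtype=float)
    if w.shape != (efmset.n_modes,):
        raise ValueError(f"expected {efmset.n_modes} weights, got {w.shape}")
    if np.any(w < 0):
        raise ValueError("mode weights must be nonnegative")
    if noise < 0:
        raise ValueError("noise must be >= 0")
    F = w @ efmset.as_array()
    if noise > 0:
        rng = np.random.default_rng(seed)
        sigma = np.sqrt(np.log1p(noise**2))
        factors = rng.lognormal(mean=-sigma**2 / 2, sigma=sigma, size=F.shape)
        F = F * factors
    import pandas as pd

    return FluxTable(
        pd.DataFrame(
            {
                "reaction_id": list(efmset.reaction_ids),
                "flux": F,
                "se": noise * np.abs(F),
            }
        ),
        condition=condition,
    )


# -- packaged stand-in networks -------------------------------------------


def plant_core_network() -> MetabolicNetwork:
    """SYNTHETIC stand-in for a TCA-centred plant embryo core network.

    Glucose, glutamine and alanine uptakes feed a TCA cycle with the usual
    anaplerotic (PEP carboxylase, malic enzyme) and nitrogen-assimilation
    (glutamate dehydrogenase, glutamate synthase, transaminases) reactions,
    plus outputs toward fatty acids, protein amino acids and vacuolar
    malate.  Written from the biology of heterotrophic embryos, not
    transcribed from any supplementary file; nitrogen atoms are not
    balanced (only carbon skeletons are modelled).
    """
    F = Fraction
    internal = ["PEP", "Pyr", "AcCoA", "OAA", "Cit", "aKG", "Mal", "Glu", "Gln", "Ala", "Asp"]
    external = [
        "Glc_ext", "Gln_ext", "Ala_ext", "CO2_ext", "FA_ext",
        "GluP_ext", "AlaP_ext", "Asp_ext", "Mal_ext",
    ]
    mets = [Metabolite(m, False) for m in internal] + [Metabolite(m, True) for m in external]
    rxns = [
        Reaction("Glc_up", {"Glc_ext": F(-1), "PEP": F(2)}),
        Reaction("Vpk", {"PEP": F(-1), "Pyr": F(1)}),
        Reaction("Vpepc", {"PEP": F(-1), "CO2_ext": F(-1), "OAA": F(1)}),
        Reaction("Vpdh", {"Pyr": F(-1), "AcCoA": F(1), "CO2_ext": F(1)}),
        Reaction("Vcs", {"AcCoA": F(-1), "OAA": F(-1), "Cit": F(1)}),
        Reaction("Vidh", {"Cit": F(-1), "aKG": F(1), "CO2_ext": F(1)}),
        Reaction("Vakgdh", {"aKG": F(-1), "Mal": F(1), "CO2_ext": F(1)}),
        Reaction("Vfum", {"Mal": F(-1), "OAA": F(1)}, reversible=True),
        Reaction("Vme", {"Mal": F(-1), "Pyr": F(1), "CO2_ext": F(1)}),
        Reaction("Vcl", {"Cit": F(-1), "AcCoA": F(1), "OAA": F(1)}),
        Reaction("FA_out", {"AcCoA": F(-2), "FA_ext": F(1)}),
        Reaction("gln_up", {"Gln_ext": F(-1), "Gln": F(1)}),
        Reaction("Vgs", {"Gln": F(-1), "aKG": F(-1), "Glu": F(2)}),
        Reaction("Vgdh", {"aKG": F(-1), "Glu": F(1)}, reversible=True),
        Reaction("ala_up", {"Ala_ext": F(-1), "Ala": F(1)}),
        Reaction("Vala", {"Pyr": F(-1), "Glu": F(-1), "Ala": F(1), "aKG": F(1)},
                 reversible=True),
        Reaction("Vasp", {"OAA": F(-1), "Glu": F(-1), "Asp": F(1), "aKG": F(1)},
                 reversible=True),
        Reaction("Glu_out", {"Glu": F(-1), "GluP_ext": F(1)}),
        Reaction("Ala_out", {"Ala": F(-1), "AlaP_ext": F(1)}),
        Reaction("Asp_out", {"Asp": F(-1), "Asp_ext": F(1)}),
        Reaction("Mal_out", {"Mal": F(-1), "Mal_ext": F(1)}),
    ]
    return MetabolicNetwork(mets, rxns)


def plant_condition_dataset(noise: float = 0.05, seed: int = 0, weight_spread: float = 0.3):
    """Two-condition synthetic experiment over the plant stand-in network.

    The organic-nitrogen condition (reference) draws its fluxes from the
    modes using at least one uptake ("Naa"-style subset); the
    mineral-nitrogen condition from the sugar-only modes ("Nm"-style).
    Mode weights start from the efficiency-consistent values (which make the
    noiseless flux vector equal the subset's efficiency vector) and are
    perturbed by a mean-one lognormal factor of sd ``weight_spread``,
    emulating condition-specific regulation the structure alone cannot see.
    Measurement noise is multiplicative lognormal of relative sd ``noise``.

    Returns a dict with the network, the full/filtered mode sets, the two
    efficiency vectors and the two flux tables.
    """
    from .efficiency import efficiency_from_modes
    from .efm_core import enumerate_efms
    from .efmset_ops import SubstrateFilter, filter_modes

    net = plant_core_network()
    modes = enumerate_efms(net, label="plant_all")
    naa = filter_modes(modes, SubstrateFilter({"Glc_up", "gln_up", "ala_up"}), label="Naa")
    nm = filter_modes(modes, SubstrateFilter({"Glc_up"}, {"gln_up", "ala_up"}), label="Nm")
    rng = np.random.default_rng(seed)
    w_naa = efficiency_weights(naa) * rng.lognormal(0.0, weight_spread, naa.n_modes)
    w_nm = efficiency_weights(nm) * rng.lognormal(0.0, weight_spread, nm.n_modes)
    return {
        "network": net,
        "modes": modes,
        "naa": naa,
        "nm": nm,
        "eff_ref": efficiency_from_modes(naa),
        "eff_alt": efficiency_from_modes(nm),
        "flux_ref": make_flux_table(naa, w_naa, noise=noise, seed=seed + 1,
                                    condition="organicN"),
        "flux_alt": make_flux_table(nm, w_nm, noise=noise, seed=seed + 2,
                                    condition="mineralN"),
    }


_SUGAR_UPTAKES = {
    "glucose": Reaction("Glc_up", {"Glc_ext": Fraction(-1), "G6P": Fraction(1)}),
    "fructose": Reaction("Fru_up", {"Fru_ext": Fraction(-1), "F6P": Fraction(1)}),
    "sucrose": Reaction("Suc_up", {"Suc_ext": Fraction(-1), "G6P": Fraction(1),
                                   "F6P": Fraction(1)}),
}


def bacterial_network(substrate: str = "glucose") -> MetabolicNetwork:
    """SYNTHETIC stand-in for a bacterial central-carbon network.

    Glycolysis with a reversible phosphoglucose isomerase, a lumped oxidative
    pentose phosphate shunt (3 G6P -> 2 F6P + triose + 3 CO2), pyruvate
    carboxylase anaplerosis, a lumped TCA cycle and lysine/lactate outputs.
    ``substrate`` selects the sugar uptake ('glucose', 'fructose' or
    'sucrose'); fructose enters below PGI, so feeding the pentose phosphate
    shunt on fructose forces PGI to run gluconeogenically.  Not a
    transcription of any supplementary file.
    """
    if substrate not in _SUGAR_UPTAKES:
        raise ValueError(f"unknown substrate {substrate!r}")
    F = Fraction
    internal = ["G6P", "F6P", "T", "Pyr", "AcCoA", "OAA"]
    sugar_ext = {"glucose": "Glc_ext", "fructose": "Fru_ext", "sucrose": "Suc_ext"}
    external = [sugar_ext[substrate], "CO2_ext", "Lys_ext", "Lac_ext"]
    mets = [Metabolite(m, False) for m in internal] + [Metabolite(m, True) for m in external]
    rxns = [
        _SUGAR_UPTAKES[substrate],
        Reaction("PGI", {"G6P": F(-1), "F6P": F(1)}, reversible=True),
        Reaction("PFK", {"F6P": F(-1), "T": F(2)}),
        Reaction("G6Pdh", {"G6P": F(-3), "F6P": F(2), "T": F(1), "CO2_ext": F(3)}),
        Reaction("Pyk", {"T": F(-1), "Pyr": F(1)}),
        Reaction("Pdh", {"Pyr": F(-1), "AcCoA": F(1), "CO2_ext": F(1)}),
        Reaction("PC", {"Pyr": F(-1), "CO2_ext": F(-1), "OAA": F(1)}),
        Reaction("TCA", {"AcCoA": F(-1), "CO2_ext": F(2)}),
        Reaction("AspK", {"OAA": F(-1), "Pyr": F(-1), "Lys_ext": F(1)}),
        Reaction("Lac_out", {"Pyr": F(-1), "Lac_ext": F(1)}),
    ]
    return MetabolicNetwork(mets, rxns)
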