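"""Elementary-mode enumeration against hand results and the brute-force oracle."""

from fractions import Fraction

import numpy as np
import pytest

from efmflux import (
    EFMSet,
    FluxMode,
    Metabolite,
    MetabolicNetwork,
    ModeCountExceeded,
    Reaction,
    brute_force_efms,
    enumerate_efms,
    is_elementary,
    split_reversible,
)
from efmflux._rational import is_zero, matvec, rank
from efmflux.synthetic_data import make_motif_network, make_random_network


def as_int_tuples(efmset):
    return {tuple(int(c) for c in m.coefficients) for m in efmset}


def test_chain_single_mode(chain):
    modes = enumerate_efms(chain)
    assert as_int_tuples(modes) == {(1, 1, 1)}


def test_diamond_two_modes(diamond):
    modes = enumerate_efms(diamond)
    assert as_int_tuples(modes) == {
        (1, 1, 0, 1, 0, 1),
        (1, 0, 1, 0, 1, 1),
    }
    assert as_int_tuples(brute_force_efms(diamond)) == as_int_tuples(modes)


def test_parallel_branches_k_modes():
    net, expected = make_motif_network([3])
    assert expected == 3
    assert enumerate_efms(net).n_modes == 3


def test_no_internal_metabolites_every_reaction_is_a_mode(minimal_doc):
    from efmflux import parse_metatool

    net = parse_metatool(minimal_doc)
    modes = enumerate_efms(net)
    assert as_int_tuples(modes) == {(1,)}


def test_reversible_exchange_counted_once():
    # a single reversible conversion between two external pools is one EFM,
    # reported in canonical (first-nonzero-positive) orientation
    net = MetabolicNetwork(
        [Metabolite("A", True), Metabolite("B", True)],
        [Reaction("R1", {"A": Fraction(-1), "B": Fraction(1)}, reversible=True)],
    )
    modes = enumerate_efms(net)
    assert as_int_tuples(modes) == {(1,)}


def test_futile_two_cycle_discarded():
    # an isolated reversible internal interconversion supports no steady flow
    net = MetabolicNetwork(
        [Metabolite("A", False), Metabolite("B", False)],
        [Reaction("R1", {"A": Fraction(-1), "B": Fraction(1)}, reversible=True)],
    )
    assert enumerate_efms(net).n_modes == 0


def test_reversible_internal_cycle_modes():
    # two antiparallel routes between internal A and B: the cycle through
    # the reversible reaction run backward plus the irreversible one forward
    net = MetabolicNetwork(
        [Metabolite("A", False), Metabolite("B", False),
         Metabolite("X", True), Metabolite("Y", True)],
        [
            Reaction("in", {"X": Fraction(-1), "A": Fraction(1)}),
            Reaction("r1", {"A": Fraction(-1), "B": Fraction(1)}, reversible=True),
            Reaction("r2", {"A": Fraction(-1), "B": Fraction(1)}),
            Reaction("out", {"B": Fraction(-1), "Y": Fraction(1)}),
        ],
    )
    modes = enumerate_efms(net)
    assert as_int_tuples(modes) == as_int_tuples(brute_force_efms(net))
    # two throughput paths and one internal cycle (r2 forward, r1 backward)
    assert (0, -1, 1, 0) in as_int_tuples(modes)
    assert modes.n_modes == 3


def test_split_reversible_column_count(plant):
    split, mapping = split_reversible(plant)
    assert split.n_reactions == plant.n_reactions + plant.n_reversible
    assert split.n_reversible == 0
    # recombination mapping covers every original reaction
    assert {j for j, _ in mapping} == set(range(plant.n_reactions))


def test_split_identity_when_all_irreversible(diamond):
    split, mapping = split_reversible(diamond)
    assert split.n_reactions == diamond.n_reactions
    assert mapping == [(j, 1) for j in range(diamond.n_reactions)]


def test_is_elementary_cases(chain, diamond):
    assert is_elementary(chain, [1, 1, 1])
    res = is_elementary(chain, [0, 0, 0])
    assert not res and "empty support" in res.reason
    # the sum of the two diamond modes is steady and feasible but decomposable
    res = is_elementary(diamond, [2, 1, 1, 1, 1, 2])
    assert not res and "decomposable" in res.reason
    with pytest.raises(ValueError):
        is_elementary(chain, [1, 1])


def test_mode_invariants_on_fixture(plant, plant_modes):
    S = plant.stoichiometric_matrix()
    irrev = [j for j, r in enumerate(plant.reactions) if not r.reversible]
    for mode in plant_modes:
        v = list(mode.coefficients)
        assert is_zero(matvec(S, v))
        assert all(v[j] >= 0 for j in irrev)
        support = sorted(mode.support)
        sub = [[row[j] for j in support] for row in S]
        assert rank(sub) == len(support) - 1
        # canonical integer form
        assert all(c.denominator == 1 for c in mode.coefficients)


def test_no_signed_support_inclusion(plant_modes):
    sigs = [
        frozenset((j, c > 0) for j, c in enumerate(m.coefficients) if c != 0)
        for m in plant_modes
    ]
    for i, a in enumerate(sigs):
        for b in sigs[i + 1:]:
            assert not (a < b or b < a)


def test_deterministic_output_order(plant):
    a = enumerate_efms(plant).to_tsv()
    b = enumerate_efms(plant).to_tsv()
    assert a == b


def test_mode_ceiling_aborts():
    net, expected = make_motif_network([3, 3, 3])
    with pytest.raises(ModeCountExceeded):
        enumerate_efms(net, max_modes=10)
    assert enumerate_efms(net).n_modes == expected == 27


def test_brute_force_refuses_large_networks():
    net = make_random_network(5, 25, 0.0, seed=0)
    with pytest.raises(ValueError, match="brute-force"):
        brute_force_efms(net, max_columns=18)


@pytest.mark.parametrize("seed", range(25))
def test_enumerate_matches_oracle_random(seed):
    rng = np.random.default_rng(seed + 10_000)
    net = make_random_network(
        int(rng.integers(2, 5)), int(rng.integers(5, 10)),
        reversible_fraction=0.4, seed=seed,
    )
    assert as_int_tuples(enumerate_efms(net)) == as_int_tuples(brute_force_efms(net))


def test_tsv_roundtrip(plant_modes):
    again = EFMSet.from_tsv(plant_modes.to_tsv())
    assert again.reaction_ids == plant_modes.reaction_ids
    assert [m.coefficients for m in again] == [m.coefficients for m in plant_modes]
    assert again.label == plant_modes.label


def test_l1_normalized_view(plant_modes):
    a = plant_modes.as_l1_normalized()
    np.testing.assert_allclose(np.abs(a).sum(axis=1), 1.0)


def test_rank_helper_matches_sympy():
    import sympy

    rng = np.random.default_rng(3)
    for _ in range(10):
        m = rng.integers(-3, 4, size=(4, 6))
        ours = rank([[Fraction(int(x)) for x in row] for row in m])
        assert ours == sympy.Matrix(m.tolist()).rank()
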