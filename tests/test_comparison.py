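"""Relative differences, exclusion rules, Wilcoxon test and sign concordance."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import rankdata

from efmflux import (
    FluxTable,
    SubstrateFilter,
    compare_conditions,
    enumerate_efms,
    filter_modes,
    relative_difference,
    sign_concordance,
    wilcoxon_paired,
)
from efmflux.efficiency import efficiency_from_modes
from efmflux.synthetic_data import efficiency_weights, make_flux_table


# -- relative difference ---------------------------------------------------


@pytest.mark.parametrize(
    "ref, alt, expected",
    [(2, 3, 0.5), (5, 5, 0.0), (-2, -1, 0.5), (-2, -4, -1.0), (4, 2, -0.5)],
)
def test_relative_difference_values(ref, alt, expected):
    assert relative_difference(ref, alt) == pytest.approx(expected)


def test_relative_difference_zero_reference():
    with pytest.raises(ValueError):
        relative_difference(0.0, 1.0)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    ref=st.floats(-100, 100).filter(lambda x: abs(x) > 1e-6),
    alt=st.floats(-100, 100),
    scale=st.floats(0.01, 100),
)
def test_relative_difference_scale_invariance(ref, alt, scale):
    assert relative_difference(scale * ref, scale * alt) == pytest.approx(
        relative_difference(ref, alt), rel=1e-9, abs=1e-9
    )


# -- Wilcoxon --------------------------------------------------------------


def exact_signflip_pvalue(d):
    """Independent oracle: full enumeration of the 2^n sign assignments of
    the signed-rank statistic (tie-free |d| assumed)."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    dist = []
    for signs in itertools.product((0, 1), repeat=len(d)):
        dist.append(sum(r for s, r in zip(signs, ranks) if s))
    dist = np.asarray(dist)
    p = 2 * min((dist <= w_obs).mean(), (dist >= w_obs).mean())
    return min(p, 1.0)


def test_wilcoxon_one_signed_n5():
    stat, p = wilcoxon_paired([1, 2, 3, 4, 5], [0, 0, 0, 0, 0])
    assert p == pytest.approx(0.0625)
    assert p == pytest.approx(exact_signflip_pvalue([1, 2, 3, 4, 5]))


def test_wilcoxon_identical_vectors_convention():
    with pytest.warns(UserWarning, match="zero"):
        stat, p = wilcoxon_paired([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert p == 1.0


@pytest.mark.parametrize("n", range(3, 11))
def test_wilcoxon_matches_signflip_enumeration(n):
    rng = np.random.default_rng(n)
    for _ in range(5):
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        _, p = wilcoxon_paired(x, y)
        assert p == pytest.approx(exact_signflip_pvalue(x - y), abs=1e-12)


def test_wilcoxon_large_n_uses_normal_approximation():
    rng = np.random.default_rng(1)
    x = rng.normal(size=40)
    y = rng.normal(size=40)
    _, p = wilcoxon_paired(x, y)
    assert 0 < p <= 1


def test_wilcoxon_input_validation():
    with pytest.raises(ValueError):
        wilcoxon_paired([1, 2], [1])
    with pytest.raises(ValueError):
        wilcoxon_paired([], [])


# -- flux tables -----------------------------------------------------------


def test_flux_table_tsv_roundtrip():
    t = FluxTable.from_mapping({"a": 1.0, "b": -2.0}, condition="ref", se={"a": 0.1})
    again = FluxTable.from_tsv(__import__("io").StringIO(t.to_tsv()))
    assert again.condition == "ref"
    assert list(again.data["reaction_id"]) == ["a", "b"]
    assert again.data["flux"].tolist() == [1.0, -2.0]


def test_flux_table_rejects_duplicates_and_negative_se():
    import pandas as pd

    with pytest.raises(ValueError, match="duplicate"):
        FluxTable(pd.DataFrame({"reaction_id": ["a", "a"], "flux": [1, 2]}))
    with pytest.raises(ValueError, match="negative"):
        FluxTable(pd.DataFrame({"reaction_id": ["a"], "flux": [1], "se": [-1]}))


# -- compare_conditions ----------------------------------------------------


@pytest.fixture(scope="module")
def plant_conditions(plant_modes):
    naa = filter_modes(
        plant_modes, SubstrateFilter({"Glc_up", "gln_up", "ala_up"}), label="Naa"
    )
    nm = filter_modes(
        plant_modes,
        SubstrateFilter({"Glc_up"}, {"gln_up", "ala_up"}),
        label="Nm",
    )
    eff = (efficiency_from_modes(naa), efficiency_from_modes(nm))
    tables = (
        make_flux_table(naa, efficiency_weights(naa), condition="organicN"),
        make_flux_table(nm, efficiency_weights(nm), condition="mineralN"),
    )
    return tables, eff


def test_identical_conditions_all_zero(plant_conditions):
    (t_ref, _), (e_ref, _) = plant_conditions
    cmp_ = compare_conditions(t_ref, t_ref, e_ref, e_ref)
    sub = cmp_.compared
    assert (sub["dF"] == 0).all()
    assert (sub["dEps"] == 0).all()
    n_conc, n_total, discordant = sign_concordance(cmp_)
    assert (n_conc, discordant) == (n_total, [])


def test_noiseless_construction_perfect_concordance(plant_conditions):
    """Flux tables built so the flux vector equals the efficiency vector make
    DeltaF track Delta_eps exactly: perfect sign concordance."""
    (t_ref, t_alt), (e_ref, e_alt) = plant_conditions
    cmp_ = compare_conditions(t_ref, t_alt, e_ref, e_alt)
    n_conc, n_total, discordant = sign_concordance(cmp_)
    assert discordant == []
    assert n_conc == n_total > 10
    np.testing.assert_allclose(
        cmp_.compared["dF"], cmp_.compared["dEps"], atol=1e-9
    )


def test_zero_reference_excluded(plant_conditions):
    (t_ref, t_alt), (e_ref, e_alt) = plant_conditions
    cmp_ = compare_conditions(t_ref, t_alt, e_ref, e_alt)
    excluded = dict(zip(cmp_.excluded["reaction_id"], cmp_.excluded["reason"]))
    # the pure citrate cycle reaction carries no flux in the reference set
    assert "Vcl" in excluded and "zero reference" in excluded["Vcl"]


def test_unpaired_reactions_autoexcluded():
    t_ref = FluxTable.from_mapping({"shared": 2.0, "only_ref": 1.0}, condition="ref")
    t_alt = FluxTable.from_mapping({"shared": 3.0, "only_alt": 1.0}, condition="alt")
    eff = _tiny_eff({"shared": 0.5, "only_ref": 0.1, "only_alt": 0.1})
    cmp_ = compare_conditions(t_ref, t_alt, eff, eff)
    reasons = dict(zip(cmp_.frame["reaction_id"], cmp_.frame["reason"]))
    assert "unpaired" in reasons["only_ref"]
    assert "unpaired" in reasons["only_alt"]
    assert list(cmp_.compared["reaction_id"]) == ["shared"]


def test_error_bar_rule():
    t_ref = FluxTable.from_mapping(
        {"good": 2.0, "noisy": 1.0}, condition="ref", se={"good": 0.2, "noisy": 4.0}
    )
    t_alt = FluxTable.from_mapping({"good": 3.0, "noisy": 2.0}, condition="alt")
    eff = _tiny_eff({"good": 0.5, "noisy": 0.5})
    cmp_ = compare_conditions(t_ref, t_alt, eff, eff)
    reasons = dict(zip(cmp_.frame["reaction_id"], cmp_.frame["reason"]))
    assert "error bars" in reasons["noisy"]
    assert list(cmp_.compared["reaction_id"]) == ["good"]
    # a looser threshold admits the noisy reaction
    loose = compare_conditions(t_ref, t_alt, eff, eff, error_bar_threshold=10.0)
    assert list(loose.compared["reaction_id"]) == ["good", "noisy"]


def test_output_flux_exclusion_switch():
    t_ref = FluxTable.from_mapping({"Vx": 2.0, "Asp_out": 1.0}, condition="ref")
    t_alt = FluxTable.from_mapping({"Vx": 3.0, "Asp_out": 2.0}, condition="alt")
    eff = _tiny_eff({"Vx": 0.5, "Asp_out": 0.2})
    with_outputs = compare_conditions(t_ref, t_alt, eff, eff, include_outputs=True)
    assert "Asp_out" in list(with_outputs.compared["reaction_id"])
    without = compare_conditions(t_ref, t_alt, eff, eff, include_outputs=False)
    assert "Asp_out" not in list(without.compared["reaction_id"])
    assert "output" in dict(zip(without.frame["reaction_id"], without.frame["reason"]))["Asp_out"]


def test_sign_convention_zero_vs_nonzero():
    t_ref = FluxTable.from_mapping({"flat": 2.0, "moves": 2.0}, condition="ref")
    t_alt = FluxTable.from_mapping({"flat": 2.0, "moves": 4.0}, condition="alt")
    eff_ref = _tiny_eff({"flat": 0.5, "moves": 0.5})
    eff_alt = _tiny_eff({"flat": 0.5, "moves": 0.5})  # dEps = 0 for both
    cmp_ = compare_conditions(t_ref, t_alt, eff_ref, eff_alt)
    n_conc, n_total, discordant = sign_concordance(cmp_)
    # (0, 0) concordant; (nonzero, 0) discordant
    assert n_total == 2 and n_conc == 1 and discordant == ["moves"]


def test_exclusions_logged_in_report(plant_conditions):
    (t_ref, t_alt), (e_ref, e_alt) = plant_conditions
    cmp_ = compare_conditions(t_ref, t_alt, e_ref, e_alt)
    text = cmp_.to_tsv()
    assert "# reference: organicN" in text
    assert "error_bar_threshold" in text
    payload = __import__("json").loads(cmp_.to_json())
    assert payload["n_compared"] == len(cmp_.compared)
    assert "wilcoxon" in payload


def _tiny_eff(values):
    """Degenerate single-mode efficiency vector for plumbing tests."""
    from fractions import Fraction

    from efmflux.efficiency import EfficiencyVector

    ids = tuple(values)
    fwd = tuple(Fraction(v).limit_denominator(10**6) for v in values.values())
    return EfficiencyVector(
        reaction_ids=ids,
        forward=fwd,
        backward=tuple(Fraction(0) for _ in ids),
        n_modes_using=tuple(1 for _ in ids),
        n_modes=1,
    )
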