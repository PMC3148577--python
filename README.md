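# efmflux

Elementary flux mode (EFM) analysis for small stoichiometric metabolic
networks, and a pipeline for testing whether the *structure* of a network
predicts how its measured fluxes shift when the environment changes.

¹³C metabolic flux analysis gives a snapshot of the fluxes a cell actually
runs; EFM analysis gives the complete catalogue of minimal steady-state
pathways the network *could* run. This package connects the two through the
**coefficient of flux efficiency**: each elementary mode `e_i` distributes
one unit of efficiency over its reactions in proportion to its flux shares,

    ε_ij = e_ij / Σ_l |e_il|,

and a reaction's coefficient is the average share over all `N` modes of the
condition-specific mode set, with forward and backward use of reversible
reactions split:

    ε_j = (1/N) Σ_i max(ε_ij, 0)  +  (1/N) Σ_i min(ε_ij, 0).

No growth or ATP objective is involved. To compare two conditions
(e.g. a different carbon or nitrogen source), the relative difference
`Δx = (x_alt − x_ref)/|x_ref|` is computed for both the measured fluxes
(ΔF) and the efficiencies (Δε) of each paired reaction; agreement is
assessed by sign concordance and a paired Wilcoxon signed-rank test.

The library covers: a Metatool-dialect reader/writer, exact
(rational-arithmetic) EFM enumeration by the nullspace-initialized double
description method with a brute-force oracle, efficiency coefficients,
substrate-based mode filtering and reaction knockouts, the condition
comparison with its exclusion rules, and seeded synthetic data generators
(networks with analytically known mode counts, flux tables built from mode
combinations). See `docs/methods.md` for the model and all conventions.

## Worked example

```python
from efmflux import (enumerate_efms, filter_modes, SubstrateFilter,
                     compare_conditions, sign_concordance)
from efmflux.efficiency import efficiency_from_modes
from efmflux.synthetic_data import plant_core_network, plant_condition_dataset

net = plant_core_network()          # packaged synthetic plant-embryo fixture
modes = enumerate_efms(net)
print(net)
print(modes.n_modes, "elementary modes")

nm = filter_modes(modes, SubstrateFilter({"Glc_up"}, {"gln_up", "ala_up"}))
naa = filter_modes(modes, SubstrateFilter({"Glc_up", "gln_up", "ala_up"}))
print(nm.n_modes, "sugar-only modes;", naa.n_modes, "modes using >=1 uptake")

ds = plant_condition_dataset(noise=0.05, seed=1)   # two-condition synthetic data
cmp_ = compare_conditions(ds["flux_ref"], ds["flux_alt"],
                          ds["eff_ref"], ds["eff_alt"], sign_tolerance=1e-9)
print(sign_concordance(cmp_))
```

prints

```
MetabolicNetwork(21 reactions, 4 reversible, 20 metabolites, 11 internal)
39 elementary modes
11 sugar-only modes; 38 modes using >=1 uptake
(20, 20, [])
```

i.e. the fixture network has 39 elementary modes, of which 11 run on sugar
alone and 38 use at least one uptake, and on the seeded two-condition
synthetic dataset all 20 comparable reactions change their flux in the
direction their efficiency coefficient predicts (no discordant reactions).

## Analysis pipeline

The study-style analysis is a sequence of thin drivers over the library,
writing tables under `results/`:

```bash
python analysis/01_build_networks.py        # networks + diagnostics -> Metatool files
python analysis/02_enumerate_efms.py        # EFM matrices + count table (oracle-checked)
python analysis/03_flux_efficiency.py       # efficiency vectors per condition set
python analysis/04_compare_conditions.py    # DeltaF vs Delta_eps, concordance, Wilcoxon
python analysis/05_knockout_robustness.py   # single-reaction knockout scan
```

The original study's supplementary networks and measured flux tables are
not distributed here; the pipeline runs on packaged synthetic stand-in
networks (clearly labelled as such in their docstrings) and seeded
synthetic flux data, so every number it prints is reproducible from this
repository alone.

A command-line interface mirrors the pipeline for ad-hoc use:

```bash
efmflux enumerate results/networks/plant_core.dat --out modes.tsv
efmflux filter modes.tsv --require Glc_up --forbid gln_up,ala_up
efmflux compare flux_ref.tsv flux_alt.tsv modes_ref.tsv modes_alt.tsv
```

## Acceptance script

`scripts/acceptance.py` re-runs the package's main computation from scratch
— network construction, oracle-checked enumeration, mode subsetting,
efficiency coefficients, the seeded synthetic comparison and a knockout —
and writes its result JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
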