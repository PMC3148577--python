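# Methods

## The model

A metabolic network is given by its internal stoichiometric matrix `S`
(rows = internal metabolites, columns = reactions, exact rational entries)
and a reversibility flag per reaction. External metabolites (nutrients,
sinks, stored products) are exempt from mass balance; which metabolites are
external is declared in the input, never inferred from topology.

An **elementary flux mode** (EFM) is a flux vector `e` over the reactions
satisfying three conditions, all checked in exact arithmetic:

1. *steady state*: `S·e = 0`;
2. *feasibility*: `e_j ≥ 0` for every irreversible reaction `j`;
3. *non-decomposability*: the columns of `S` restricted to `supp(e)` have
   rank `|supp(e)| − 1`, i.e. the support carries a one-dimensional kernel.

The EFMs are the extreme rays of the flux cone, up to two conventions we
adopt from the METATOOL lineage: a futile two-cycle arising from the
forward/backward halves of a split reversible reaction is not a mode, and a
mode whose support is fully reversible counts once (its negation is the
same pathway run backwards).

## Enumeration

`efm_core.enumerate_efms` uses the nullspace-initialized double description
method:

1. every reversible reaction is split into irreversible forward and
   backward halves;
2. the rational kernel of the split matrix seeds the lineality space of the
   cone `{v : Sv = 0}`;
3. the constraints `v_j ≥ 0` are processed one column at a time. While the
   lineality space still has a component along `v_j`, the constraint is
   absorbed by a pivot (one lineality vector becomes a ray). Afterwards,
   new candidate rays come from positive/negative ray pairs.

Pair admission uses the *algebraic* adjacency test: a pair `(p, n)` spawns
a ray only if the minimal face containing both — the kernel of `S`
augmented with unit rows for every processed coordinate at which both rays
vanish — has dimension `dim(lineality) + 2`. Unlike combinatorial
support-counting, this test remains correct in the presence of redundant
intermediate rays; a final elementarity filter (condition 3 above) on the
recombined vectors provides a second guarantee.

All arithmetic is over `fractions.Fraction`; modes are canonicalized to
coprime integers with the sign fixed by the irreversible entries (or, for
fully reversible modes, by making the first nonzero entry positive) and
sorted by support size, then lexicographically — the output order is
deterministic across runs. A mode-count ceiling (default 500 000) aborts
enumeration of combinatorial blow-ups with a clear error.

The independent oracle, `brute_force_efms`, enumerates *all* support
subsets of the original (unsplit) network and keeps those whose restricted
matrix has a one-dimensional, fully nonzero, sign-feasible kernel. The two
routes are compared exactly on hundreds of seeded random networks in the
test suite. The small rational linear algebra (rank, nullspace) is
implemented directly in `_rational.py` because it sits in the enumeration
inner loop; it is cross-checked against sympy in the tests.

## The coefficient of flux efficiency

Each mode row `e_i` is converted to a row of flux shares

    ε_ij = e_ij / Σ_l |e_il|

so every mode distributes one unit of "efficiency mass" over its reactions
— the L1 denominator is the proxy for the total enzyme investment needed to
establish the mode. The per-reaction coefficient averages these shares over
the whole mode set of size `N`, with forward and backward use of reversible
reactions averaged separately:

    ε_j⁺ = (1/N) Σ_i max(ε_ij, 0),   ε_j⁻ = (1/N) Σ_i min(ε_ij, 0),
    ε_j  = ε_j⁺ + ε_j⁻.

No growth or ATP objective enters anywhere. Two readings of the averaging
denominator are defensible; we divide by `N` (all modes, including those
not using `j`) by default and expose `average_over="active_modes"` as a
documented alternative. Consequences that the tests pin down: a reaction in
no mode has ε = 0; short modes weight their reactions more than long ones;
Σ_j (ε_j⁺ − ε_j⁻) = 1 exactly; ε is invariant under rescaling any mode.

## Comparing conditions

For a quantity measured under a reference and an alternative condition,

    Δ = (alt − ref) / |ref|,

undefined when `ref = 0` (the pair is excluded, with the reason logged).
`compare_conditions` pairs reactions by id across two flux tables and two
efficiency vectors and applies, in order: unpaired ids (which removes
substrate-specific uptake reactions automatically), the optional output-flux
exclusion (id suffix `_out`; off for the plant comparison, on for the
bacterial one, matching how such outputs are normalised in practice), the
error-bar rule (`se/|F|` above 300 % in either condition), and the
zero-reference rules.

Agreement is assessed two ways. *Sign concordance* counts pairs with
`sign(ΔF) = sign(Δε)`, where zero is its own category: (0, 0) is
concordant, (0, x≠0) is discordant. Because fluxes normally arrive through
floating point, `sign_tolerance` (default 0, i.e. exact zeros only) lets
callers treat |Δ| below a threshold as "no change"; the synthetic analyses
use 1e-9. The *Wilcoxon paired signed-rank test* is applied to the
differences ΔF − Δε (scipy's implementation behind our interface): exact
null distribution when n ≤ 25 and the nonzero differences are tie-free,
normal approximation with tie and continuity correction otherwise, zeros
dropped by default (`pratt` available), and the all-zero case returns p = 1
by convention with a warning. The test suite validates the p-values against
a full 2^n sign-flip enumeration for n ≤ 10.

## Synthetic data: what it emulates and what it does not

The original study inputs (five curated networks and the matching
¹³C-measured flux tables) are not distributed here, so the package ships
generators plus two fixture networks written from the biology the study
describes — a bacterial central-carbon network with interchangeable sugar
uptake (glucose enters at G6P, fructose below the isomerase so that feeding
the pentose phosphate shunt forces PGI to run gluconeogenically, sucrose at
both) and a TCA-centred plant embryo network with glucose, glutamine and
alanine uptakes and outputs toward fatty acids, protein amino acids and
vacuolar malate. Both docstrings mark them as synthetic stand-ins; their
mode counts (9/6/9 and 39, with sugar-only subset 11 and any-uptake subset
38) are properties of these fixtures, not of the published networks.

Synthetic flux tables are nonnegative combinations of a condition's
elementary modes — so noiseless tables satisfy `S·F = 0` exactly —
multiplied reaction-wise by a mean-one lognormal factor. Defaults, chosen
once: measurement noise 5 % relative sd (typical of well-determined central
fluxes); condition-specific mode-weight spread 0.3 (lognormal sd), standing
in for the regulation that network structure alone cannot see. Base weights
`w_i = 1/(N·‖e_i‖₁)` make the noiseless flux vector equal the subset's net
efficiency vector, which is the cleanest way to state "the efficiency
structure drives the fluxes". Multiplicative noise was chosen over additive
to preserve flux directions, as ¹³C-MFA magnitudes are positive along a
direction.

A green test on this synthetic world establishes that the machinery is
correct and that the comparison recovers structure-driven changes; it does
not establish anything about the published biological measurements, and it
does not emulate isotopomer dynamics, cofactor balancing in the plant
fixture, or correlated measurement errors.

One statistical caveat the acceptance test respects: the weight-spread
perturbations are correlated across reactions (they act through shared
modes), so a single draw's Wilcoxon p rejects at well above the usual
intuition. The null-design check therefore asserts the *median* p over
several seeds under zero weight spread, where ΔF − Δε is pure measurement
noise.

## Numerical and design choices

- Exact rationals everywhere inside enumeration and efficiency; floats only
  at the flux-table/comparison boundary.
- Metatool dialect: section order -ENZREV, -ENZIRREV, -METINT, -METEXT,
  -CAT; arrows `=`, `<=>`, `<->`, `=>`, `->` all accepted; `#` comments;
  integer, decimal (converted exactly) and `p/q` coefficients; the writer
  emits integers or `p/q` so round trips are exact.
- Knockout analyses re-enumerate the reduced network; the tests verify this
  equals selecting the original modes with zero at the removed reaction.
- Tie-break in mode output order: support size, then lexicographic by
  coefficient tuple over the reaction index.

## Known limitations

- Enumeration is pure Python over exact rationals: comfortable for networks
  up to a few dozen reactions and a few thousand modes, not for
  genome-scale models (no network compression is performed).
- The brute-force oracle is exponential and refuses networks with more than
  18 reactions.
- The Wilcoxon exact path requires tie-free nonzero differences; ties fall
  back to the corrected normal approximation regardless of n.
- The pooled Wilcoxon across both organisms treats all pairs as exchangeable,
  ignoring the system-level grouping.
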