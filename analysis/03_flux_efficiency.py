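"""Compute flux-efficiency coefficients for the condition-specific EFM sets.

Builds the five working EFM sets — the three bacterial sets (one per sugar)
and the two plant substrate subsets: the sugar-only modes ("Nm", mineral
nitrogen) and the modes using at least one uptake ("Naa", organic
nitrogen) — and computes the per-reaction coefficient of flux efficiency
(forward/backward split and net) for each.
"""

import argparse
from pathlib import Path

from efmflux import EFMSet, SubstrateFilter, filter_modes
from efmflux.efficiency import efficiency_from_modes


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", default="results", type=Path)
    args = ap.parse_args()
    modedir = args.outdir / "modes"
    effdir = args.outdir / "efficiency"
    effdir.mkdir(parents=True, exist_ok=True)

    plant = EFMSet.from_tsv((modedir / "plant_core_modes.tsv").read_text())
    sets = {
        "Sg": EFMSet.from_tsv((modedir / "bacterial_glucose_modes.tsv").read_text()),
        "Sf": EFMSet.from_tsv((modedir / "bacterial_fructose_modes.tsv").read_text()),
        "Ss": EFMSet.from_tsv((modedir / "bacterial_sucrose_modes.tsv").read_text()),
        "Nm": filter_modes(
            plant, SubstrateFilter({"Glc_up"}, {"gln_up", "ala_up"}), label="Nm"
        ),
        "Naa": filter_modes(
            plant, SubstrateFilter({"Glc_up", "gln_up", "ala_up"}), label="Naa"
        ),
    }
    for name, efmset in sets.items():
        if name in ("Nm", "Naa"):
            (modedir / f"plant_{name}_modes.tsv").write_text(efmset.to_tsv())
        eff = efficiency_from_modes(efmset, label=name)
        (effdir / f"{name}_efficiency.tsv").write_text(eff.to_tsv())
        top = eff.as_frame().nlargest(3, "eps_net")[["reaction_id", "eps_net"]]
        tops = ", ".join(f"{r}={v:.3f}" for r, v in top.itertuples(index=False))
        print(f"{name}: {efmset.n_modes} modes; highest efficiencies: {tops}")

    print(f"\nwrote efficiency tables to {effdir}/")


if __name__ == "__main__":
    main()
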