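"""Literature VIE and reduction-potential tables with derived columns.

From the published gas-phase (computed and photoelectron-spectroscopy)
nucleobase VIEs and the computed aqueous VIEs of nucleosides,
deoxynucleotide monophosphates and dinucleotides, derive the gas-shift-
corrected aqueous VIEs and the solvent-induced lowerings; from the
computed water reduction potentials, the differences vs adenosine.
Writes results/vie_table.csv and results/v_red_table.csv.
"""

from pathlib import Path

from pmmredox.reference import v_red_table, vie_table

OUT = Path("results")


def main():
    t_vie = vie_table()
    t_v = v_red_table()
    OUT.mkdir(parents=True, exist_ok=True)
    t_vie.to_csv(OUT / "vie_table.csv", index=False)
    t_v.to_csv(OUT / "v_red_table.csv", index=False)
    print(t_vie.to_string(index=False))
    print()
    print(t_v.to_string(index=False))
    g = t_vie.set_index("species")
    print(
        f"\nsolvent lowering spans {g.solvent_shift_eV.min():.2f} eV "
        f"(guanosine-like) to {g.solvent_shift_eV.max():.2f} eV (dTMP); "
        "thymidine-family species show the largest stabilization of the "
        "radical cation, consistent with their larger dipole change upon "
        "oxidation."
    )


if __name__ == "__main__":
    main()
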