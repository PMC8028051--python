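"""Literature reference values for DNA nucleoside/nucleotide oxidation.

Inputs for the reporting layer: gas-phase vertical ionization energies of
the four nucleobases (B3LYP-level computed values and photoelectron-
spectroscopy experimental values), PMM aqueous computed VIEs for
nucleosides, deoxynucleotide monophosphates and di-homonucleotides, and
computed aqueous standard reduction potentials of the deoxynucleosides
(V vs SHE). From these the package derives the gas-shift-corrected
aqueous VIEs, the solvent-induced VIE lowerings, VIE spacings between
species, and reduction-potential differences relative to adenosine.

All energies in eV, potentials in V.
"""

from __future__ import annotations

import pandas as pd

from .errors import PmmRedoxError
from .redox import gas_shift_correction

# base of each (deoxy)nucleoside / nucleotide / dinucleotide
BASE_OF = {
    "guanosine": "guanine", "adenosine": "adenine",
    "thymidine": "thymine", "cytidine": "cytosine",
    "dGMP": "guanine", "dAMP": "adenine", "dTMP": "thymine", "dCMP": "cytosine",
    "GG(5')": "guanine", "GG(3')": "guanine",
    "AA(5')": "adenine", "AA(3')": "adenine",
    "TT(5')": "thymine", "TT(3')": "thymine",
    "CC(5')": "cytosine", "CC(3')": "cytosine",
}

# gas-phase VIEs of the isolated nucleobases, eV
GAS_VIE_CALC = {"guanine": 7.92, "adenine": 8.21, "thymine": 8.97,
                "cytosine": 8.71}
GAS_VIE_EXP = {"guanine": 8.24, "adenine": 8.44, "thymine": 9.14,
               "cytosine": 8.94}

# aqueous computed VIEs (PMM over MD ensembles), eV
AQ_VIE_CALC = {
    "guanosine": 7.66, "adenosine": 7.94, "thymidine": 8.29, "cytidine": 8.26,
    "dGMP": 7.57, "dAMP": 7.86, "dTMP": 8.22, "dCMP": 8.17,
    "GG(5')": 7.59, "GG(3')": 7.56, "AA(5')": 7.85, "AA(3')": 7.79,
    "TT(5')": 8.27, "TT(3')": 8.28, "CC(5')": 8.23, "CC(3')": 8.20,
}

# computed aqueous standard reduction potentials of deoxynucleosides, V vs SHE
V_RED_WATER = {"guanosine": 1.05, "adenosine": 1.26, "thymidine": 1.73,
               "cytidine": 1.87}


def _base(species: str) -> str:
    try:
        return BASE_OF[species]
    except KeyError:
        raise PmmRedoxError(f"unknown species {species!r}") from None


def corrected_aqueous_vie(species: str) -> float:
    """Aqueous VIE with the gas-phase exp-minus-calc shift of its base."""
    b = _base(species)
    return gas_shift_correction(
        AQ_VIE_CALC[species], GAS_VIE_CALC[b], GAS_VIE_EXP[b]
    )


def solvent_vie_shift(species: str) -> float:
    """Gas-phase computed VIE minus aqueous computed VIE (solvent lowering)."""
    return GAS_VIE_CALC[_base(species)] - AQ_VIE_CALC[species]


def vie_spacing(species_a: str, species_b: str) -> float:
    """Aqueous computed VIE difference a minus b."""
    return AQ_VIE_CALC[species_a] - AQ_VIE_CALC[species_b]


def delta_v_red(species: str, relative_to: str = "adenosine") -> float:
    """Reduction-potential difference vs a reference nucleoside, V."""
    return V_RED_WATER[species] - V_RED_WATER[relative_to]


def vie_table() -> pd.DataFrame:
    """Aqueous VIE table: computed, corrected, and solvent lowering."""
    rows = []
    for sp in AQ_VIE_CALC:
        b = _base(sp)
        rows.append(
            {
                "species": sp,
                "base": b,
                "gas_vie_calc_eV": GAS_VIE_CALC[b],
                "gas_vie_exp_eV": GAS_VIE_EXP[b],
                "aq_vie_calc_eV": AQ_VIE_CALC[sp],
                "aq_vie_corr_eV": round(corrected_aqueous_vie(sp), 10),
                "solvent_shift_eV": round(solvent_vie_shift(sp), 10),
            }
        )
    return pd.DataFrame(rows)


def v_red_table(relative_to: str = "adenosine") -> pd.DataFrame:
    """Water reduction potentials with differences vs a reference."""
    rows = [
        {
            "species": sp,
            "V_red_V": v,
            f"delta_vs_{relative_to}_V": round(delta_v_red(sp, relative_to), 10),
        }
        for sp, v in V_RED_WATER.items()
    ]
    return pd.DataFrame(rows)
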