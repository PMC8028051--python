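"""Redox thermodynamics of the synthetic chromophore.

Turns the per-frame gap ensembles into the vertical and adiabatic
ionization energies, the mean-of-bounds oxidation free energy, and the
standard reduction potential vs SHE, with block-averaged statistical
errors and the gas-phase shift correction. Writes results/redox_summary.json.
"""

import importlib.util
import json
from pathlib import Path

from pmmredox import PmmConfig, gap_series, redox_estimate

_step02 = importlib.util.spec_from_file_location(
    "step02", Path(__file__).with_name("02_perturbed_energies.py")
)
step02 = importlib.util.module_from_spec(_step02)
_step02.loader.exec_module(step02)

OUT = Path("results")


def main():
    pair, ens = step02.load_inputs()
    cfg = PmmConfig()
    est = redox_estimate(
        gap_series(ens["reduced"], pair, "vertical", cfg),
        gap_series(ens["reduced"], pair, "adiabatic", cfg),
        gap_series(ens["oxidized"], pair, "adiabatic", cfg),
        gas_calc=pair.gas_vie_calc, gas_exp=pair.gas_vie_exp,
    )
    path = OUT / "redox_summary.json"
    with open(path, "w") as fh:
        json.dump({k: (round(v, 4) if isinstance(v, float) else v)
                   for k, v in est.to_dict().items()}, fh, indent=1)
        fh.write("\n")
    print(
        f"VIE {est.vie:.4f} +- {est.err_vie:.4f} eV, "
        f"AIE {est.aie:.4f} eV, dA {est.delta_A:.4f} +- "
        f"{est.err_delta_A:.4f} eV, reorganization "
        f"{est.reorganization:.4f} eV"
    )
    print(
        f"V_red {est.V_red:.4f} +- {est.err_V_red:.4f} V vs SHE "
        f"(gas shift applied: {est.shift_applied:.4f} eV) -> {path}"
    )
    if est.reorganization < 0:
        print("warning: negative reorganization energy — sampling suspect")


if __name__ == "__main__":
    main()
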