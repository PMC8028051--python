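"""Unperturbed quantum-center model.

A quantum center (QC) — here typically a nucleobase — is described by a
set of gas-phase electronic states computed once, independently of any
environment: state energies, per-state atomic partial charges, permanent
dipoles and the transition-dipole matrix, together with the QC geometry.
These unperturbed properties are the only electronic-structure input the
perturbed-matrix engine consumes.

Units follow the package convention (nm, e, e*nm, eV); the loader accepts
dipoles in debye and converts them (1 D = 0.0208194 e*nm).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .constants import DEBYE_TO_E_NM
from .errors import StateSetParseError, ValidationError

STATESET_DIALECT = "stateset-v1"

CHARGE_SUM_TOL = 1e-6


@dataclass
class ElectronicState:
    """One electronic state: energy, per-atom charges, permanent dipole.

    ``energy`` is in eV, either relative to the species ground state or on
    an absolute scale shared between species (the owning set's
    ``energy_reference`` flag says which). ``atomic_charges`` carry one
    value per QC atom (e) and must sum to the species total charge;
    ``atomic_dipoles`` is an optional reserved per-atom dipole block (e*nm)
    that the default engine does not read.
    """

    index: int
    energy: float
    atomic_charges: np.ndarray
    permanent_dipole: np.ndarray
    atomic_dipoles: Optional[np.ndarray] = None

    def __post_init__(self):
        self.atomic_charges = np.asarray(self.atomic_charges, dtype=float)
        self.permanent_dipole = np.asarray(self.permanent_dipole, dtype=float)
        if self.atomic_dipoles is not None:
            self.atomic_dipoles = np.asarray(self.atomic_dipoles, dtype=float)


@dataclass
class ElectronicStateSet:
    """Gas-phase description of one species at one geometry.

    ``geometry`` is a list of ``(atom_label, mass_u, coord_nm)`` tuples;
    ``transition_dipoles`` has shape (n_states, n_states, 3) with the
    permanent dipoles on its diagonal (real symmetric convention — the
    engine is invariant to flipping the sign of any state's row/column
    pair, since transition-dipole phase is not observable).
    """

    species_label: str
    total_charge: int
    geometry: list  # [(label, mass, np.ndarray(3)), ...]
    states: list  # [ElectronicState, ...]
    transition_dipoles: np.ndarray  # (n_states, n_states, 3)
    energy_reference: str = "absolute"  # or "ground"

    def __post_init__(self):
        self.geometry = [
            (str(lbl), float(m), np.asarray(xyz, dtype=float))
            for lbl, m, xyz in self.geometry
        ]
        self.transition_dipoles = np.asarray(self.transition_dipoles, dtype=float)

    # -- convenience views ------------------------------------------------
    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def n_atoms(self) -> int:
        return len(self.geometry)

    @property
    def atom_labels(self) -> list:
        return [lbl for lbl, _, _ in self.geometry]

    @property
    def masses(self) -> np.ndarray:
        return np.array([m for _, m, _ in self.geometry], dtype=float)

    @property
    def coords(self) -> np.ndarray:
        return np.array([xyz for _, _, xyz in self.geometry], dtype=float)

    @property
    def energies(self) -> np.ndarray:
        return np.array([s.energy for s in self.states], dtype=float)

    @property
    def state_charges(self) -> np.ndarray:
        """(n_states, n_atoms) per-state atomic charges."""
        return np.array([s.atomic_charges for s in self.states], dtype=float)

    def validate(self) -> None:
        """Check every invariant; raise ValidationError listing all failures."""
        fails = []
        if self.n_states < 1:
            fails.append("n_states must be >= 1")
        if self.n_atoms < 1:
            fails.append("geometry must contain at least one atom")
        if self.energy_reference not in ("absolute", "ground"):
            fails.append(
                f"energy_reference must be 'absolute' or 'ground', "
                f"got {self.energy_reference!r}"
            )
        for st in self.states:
            if st.atomic_charges.shape != (self.n_atoms,):
                fails.append(
                    f"state {st.index}: {st.atomic_charges.size} atomic charges "
                    f"for {self.n_atoms} atoms"
                )
                continue
            qsum = float(st.atomic_charges.sum())
            if abs(qsum - self.total_charge) > CHARGE_SUM_TOL:
                fails.append(
                    f"state {st.index}: atomic charges sum to {qsum:.8f}, "
                    f"expected total charge {self.total_charge}"
                )
        if self.states:
            e0 = self.states[0].energy
            for st in self.states[1:]:
                if st.energy < e0 - 1e-12:
                    fails.append(
                        f"state {st.index} energy {st.energy} below ground "
                        f"state energy {e0}"
                    )
        td = self.transition_dipoles
        if td.shape != (self.n_states, self.n_states, 3):
            fails.append(
                f"transition_dipoles shape {td.shape} != "
                f"({self.n_states}, {self.n_states}, 3)"
            )
        else:
            if not np.allclose(td, np.swapaxes(td, 0, 1), atol=1e-10):
                fails.append("transition_dipoles not symmetric")
            for i, st in enumerate(self.states):
                if not np.allclose(td[i, i], st.permanent_dipole, atol=1e-10):
                    fails.append(
                        f"transition_dipoles diagonal [{i}][{i}] differs from "
                        f"state {i} permanent_dipole"
                    )
        if fails:
            raise ValidationError(fails)


@dataclass
class RedoxSpeciesPair:
    """Reduced species plus its radical cation, vertical and adiabatic.

    ``ox_vertical`` holds the cation's states at the *neutral* geometry
    (electron removed with nuclei frozen), ``ox_adiabatic`` at the
    cation-relaxed geometry. ``gas_vie_calc`` is the unperturbed computed
    vertical ionization energy; ``gas_vie_exp``, when known, feeds the
    gas-shift correction.
    """

    red: ElectronicStateSet
    ox_vertical: ElectronicStateSet
    ox_adiabatic: ElectronicStateSet
    gas_vie_calc: float
    gas_vie_exp: Optional[float] = None

    def validate(self) -> None:
        fails = []
        for name, ss in (
            ("red", self.red),
            ("ox_vertical", self.ox_vertical),
            ("ox_adiabatic", self.ox_adiabatic),
        ):
            try:
                ss.validate()
            except ValidationError as exc:
                fails.extend(f"{name}: {f}" for f in exc.failures)
        if self.ox_vertical.atom_labels != self.red.atom_labels or not np.allclose(
            self.ox_vertical.coords, self.red.coords, atol=1e-10
        ):
            fails.append("ox_vertical geometry differs from red geometry")
        for name, ss in (("ox_vertical", self.ox_vertical),
                         ("ox_adiabatic", self.ox_adiabatic)):
            if ss.total_charge != self.red.total_charge + 1:
                fails.append(
                    f"{name}.total_charge {ss.total_charge} != red.total_charge + 1"
                )
        if fails:
            raise ValidationError(fails)


def center_of_mass(stateset: ElectronicStateSet) -> np.ndarray:
    """Mass-weighted mean of the QC geometry, nm."""
    m = stateset.masses
    if stateset.n_atoms == 0:
        raise ValidationError("geometry is empty")
    if np.any(m <= 0) or m.sum() <= 0:
        raise ValidationError("all atomic masses must be > 0")
    return m @ stateset.coords / m.sum()


# ---------------------------------------------------------------------------
# Serialization: a versioned JSON-compatible schema ("stateset-v1").
# Keys: dialect, species_label, total_charge, energy_reference, dipole_unit,
# geometry [[label, mass, [x,y,z]], ...], states [{index, energy,
# atomic_charges, permanent_dipole, atomic_dipoles?}, ...],
# transition_dipoles [n][n][3].
# ---------------------------------------------------------------------------

def _require(doc: dict, key: str):
    if key not in doc:
        raise StateSetParseError(f"missing required field {key!r}")
    return doc[key]


def load_stateset(path, dialect: str = STATESET_DIALECT) -> ElectronicStateSet:
    """Load and validate an ElectronicStateSet from a schema file."""
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise StateSetParseError(f"not valid JSON: {exc}") from exc
    if not isinstance(doc, dict):
        raise StateSetParseError("top level must be an object")
    file_dialect = doc.get("dialect", STATESET_DIALECT)
    if file_dialect != dialect:
        raise StateSetParseError(
            f"dialect {file_dialect!r} does not match requested {dialect!r}"
        )
    dip_scale = 1.0
    unit = doc.get("dipole_unit", "e_nm")
    if unit == "debye":
        dip_scale = DEBYE_TO_E_NM
    elif unit != "e_nm":
        raise StateSetParseError(f"dipole_unit must be 'e_nm' or 'debye', got {unit!r}")
    try:
        geometry = [
            (str(g[0]), float(g[1]), np.array(g[2], dtype=float))
            for g in _require(doc, "geometry")
        ]
    except (TypeError, ValueError, IndexError) as exc:
        raise StateSetParseError(f"bad geometry entry: {exc}") from exc
    states = []
    for k, sdoc in enumerate(_require(doc, "states")):
        try:
            states.append(
                ElectronicState(
                    index=int(sdoc.get("index", k)),
                    energy=float(_require(sdoc, "energy")),
                    atomic_charges=np.array(
                        _require(sdoc, "atomic_charges"), dtype=float
                    ),
                    permanent_dipole=dip_scale
                    * np.array(_require(sdoc, "permanent_dipole"), dtype=float),
                    atomic_dipoles=(
                        dip_scale * np.array(sdoc["atomic_dipoles"], dtype=float)
                        if "atomic_dipoles" in sdoc
                        else None
                    ),
                )
            )
        except (TypeError, ValueError) as exc:
            raise StateSetParseError(f"bad field in states[{k}]: {exc}") from exc
    try:
        td = dip_scale * np.array(_require(doc, "transition_dipoles"), dtype=float)
    except (TypeError, ValueError) as exc:
        raise StateSetParseError(f"bad transition_dipoles: {exc}") from exc
    ss = ElectronicStateSet(
        species_label=str(_require(doc, "species_label")),
        total_charge=int(_require(doc, "total_charge")),
        geometry=geometry,
        states=states,
        transition_dipoles=td,
        energy_reference=str(doc.get("energy_reference", "absolute")),
    )
    ss.validate()
    return ss


def write_stateset(stateset: ElectronicStateSet, path) -> None:
    """Serialize a state set to the stateset-v1 schema (dipoles in e*nm)."""
    doc = {
        "dialect": STATESET_DIALECT,
        "species_label": stateset.species_label,
        "total_charge": stateset.total_charge,
        "energy_reference": stateset.energy_reference,
        "dipole_unit": "e_nm",
        "geometry": [
            [lbl, m, list(map(float, xyz))] for lbl, m, xyz in stateset.geometry
        ],
        "states": [
            {
                "index": st.index,
                "energy": st.energy,
                "atomic_charges": st.atomic_charges.tolist(),
                "permanent_dipole": st.permanent_dipole.tolist(),
                **(
                    {"atomic_dipoles": st.atomic_dipoles.tolist()}
                    if st.atomic_dipoles is not None
                    else {}
                ),
            }
            for st in stateset.states
        ],
        "transition_dipoles": stateset.transition_dipoles.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")
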