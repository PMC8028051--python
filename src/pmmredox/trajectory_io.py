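"""Frame ensembles: classical configurations of QC atoms plus point charges.

Two plain-text inputs are supported:

* a concatenated GRO-style coordinate series (fixed-column Gromacs layout,
  one block per frame) with a separate charge table mapping atom names to
  partial charges, and
* a self-contained XYZQ dialect: per frame, a count line, a comment line
  carrying ``box_edge=<nm>``, then ``label x y z q`` records, whitespace
  separated, coordinates in nm, charges in e.

No wrapping is applied on read; periodic boundaries enter only through
:func:`minimum_image` inside the electrostatics.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .errors import PmmRedoxError, ValidationError


@dataclass
class Frame:
    """One classical configuration.

    ``qc_coords`` are the quantum-center atom positions (nm), ordered as
    in the species geometry; the environment is a flat list of point
    charges with a group id (solvent molecule, counterion, ...).
    """

    box_edge: float
    qc_coords: np.ndarray  # (n_qc, 3)
    env_coords: np.ndarray  # (n_env, 3)
    env_charges: np.ndarray  # (n_env,)
    env_groups: np.ndarray  # (n_env,) int
    index: int = 0

    def __post_init__(self):
        self.qc_coords = np.asarray(self.qc_coords, dtype=float).reshape(-1, 3)
        self.env_coords = np.asarray(self.env_coords, dtype=float).reshape(-1, 3)
        self.env_charges = np.asarray(self.env_charges, dtype=float).reshape(-1)
        self.env_groups = np.asarray(self.env_groups, dtype=int).reshape(-1)
        if self.box_edge <= 0:
            raise ValidationError(f"box_edge must be > 0, got {self.box_edge}")
        for name, arr in (("qc_coords", self.qc_coords),
                          ("env_coords", self.env_coords),
                          ("env_charges", self.env_charges)):
            if not np.all(np.isfinite(arr)):
                raise ValidationError(f"non-finite values in {name}")
        if not (len(self.env_coords) == len(self.env_charges) == len(self.env_groups)):
            raise ValidationError("env arrays have inconsistent lengths")

    @property
    def n_qc(self) -> int:
        return len(self.qc_coords)

    @property
    def n_env(self) -> int:
        return len(self.env_coords)


@dataclass
class FrameEnsemble:
    """Ordered frames sampled in one charge state of the QC."""

    label: str  # "reduced" | "oxidized"
    temperature: float
    frames: list
    charge_map_id: str = ""
    variable_composition: bool = False
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.label not in ("reduced", "oxidized"):
            raise ValidationError(
                f"ensemble label must be 'reduced' or 'oxidized', got {self.label!r}"
            )

    def __len__(self) -> int:
        return len(self.frames)

    def validate(self) -> None:
        if not self.frames:
            raise ValidationError("ensemble has no frames")
        n_qc = self.frames[0].n_qc
        comp = None if self.variable_composition else _group_multiset(self.frames[0])
        for f in self.frames:
            if f.n_qc != n_qc:
                raise ValidationError(
                    f"frame {f.index}: QC atom count {f.n_qc} != {n_qc}"
                )
            if comp is not None and _group_multiset(f) != comp:
                raise ValidationError(
                    f"frame {f.index}: environment group composition differs "
                    "(set variable_composition=True to allow)"
                )


def _group_multiset(frame: Frame):
    ids, counts = np.unique(frame.env_groups, return_counts=True)
    return tuple(sorted(counts.tolist()))


def minimum_image(displacement, box_edge: float) -> np.ndarray:
    """Wrap each displacement component into (-box_edge/2, box_edge/2].

    Idempotent; works on arrays of any shape whose last axis is free.
    """
    if box_edge <= 0:
        raise ValidationError(f"box_edge must be > 0, got {box_edge}")
    d = np.asarray(displacement, dtype=float)
    return d - box_edge * np.ceil(d / box_edge - 0.5)


# ---------------------------------------------------------------------------
# Charge tables
# ---------------------------------------------------------------------------

def load_charge_table(path) -> dict:
    """Read a name -> charge (e) map from two-column text or JSON."""
    text = open(path).read()
    stripped = text.lstrip()
    if stripped.startswith("{"):
        table = json.loads(text)
        return {str(k): float(v) for k, v in table.items()}
    table = {}
    for ln, line in enumerate(text.splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise PmmRedoxError(
                f"{path}: line {ln}: expected 'name charge', got {line!r}"
            )
        table[parts[0]] = float(parts[1])
    return table


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def _parse_gro_series(path):
    """Yield (names, resids, coords, box_edge) per frame of a GRO series."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        # title line, then atom count
        try:
            natoms = int(lines[i + 1].strip())
        except (IndexError, ValueError) as exc:
            raise PmmRedoxError(
                f"{path}: expected atom count after title at line {i + 2}"
            ) from exc
        atom_lines = lines[i + 2 : i + 2 + natoms]
        if len(atom_lines) < natoms:
            raise PmmRedoxError(f"{path}: truncated frame starting at line {i + 1}")
        names, resids, coords = [], [], []
        for al in atom_lines:
            names.append(al[10:15].strip())
            resids.append(int(al[0:5]))
            coords.append(
                (float(al[20:28]), float(al[28:36]), float(al[36:44]))
            )
        box_line = lines[i + 2 + natoms].split()
        box_edge = float(box_line[0])
        yield names, np.array(resids), np.asarray(coords, dtype=float), box_edge
        i += natoms + 3


_BOX_RE = re.compile(r"box_edge\s*=\s*([-+0-9.eE]+)")


def _parse_xyzq_series(path):
    """Yield (labels, group_ids, coords, charges, box_edge) per XYZQ frame."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        natoms = int(lines[i].strip())
        m = _BOX_RE.search(lines[i + 1])
        if m is None:
            raise PmmRedoxError(
                f"{path}: comment line of frame at line {i + 1} lacks 'box_edge='"
            )
        box_edge = float(m.group(1))
        labels, coords, charges, groups = [], [], [], []
        for rec in lines[i + 2 : i + 2 + natoms]:
            parts = rec.split()
            if len(parts) < 5:
                raise PmmRedoxError(f"{path}: bad XYZQ record {rec!r}")
            labels.append(parts[0])
            coords.append(tuple(map(float, parts[1:4])))
            charges.append(float(parts[4]))
            groups.append(int(parts[5]) if len(parts) > 5 else 0)
        yield (labels, np.array(groups), np.asarray(coords, dtype=float),
               np.array(charges, dtype=float), box_edge)
        i += natoms + 2


def _resolve_selection(qc_selection, labels) -> np.ndarray:
    """Turn a name list or index list into QC atom indices (file order)."""
    sel = list(qc_selection)
    if all(isinstance(s, (int, np.integer)) for s in sel):
        idx = np.array(sel, dtype=int)
    else:
        names = set(map(str, sel))
        idx = np.array([k for k, lbl in enumerate(labels) if lbl in names], dtype=int)
    if idx.size == 0:
        raise PmmRedoxError(f"qc_selection {qc_selection!r} matched zero atoms")
    return idx


def read_frames(
    coord_path,
    charge_table_path=None,
    qc_selection: Sequence = (),
    label: str = "reduced",
    temperature: float = 300.0,
    fmt: Optional[str] = None,
) -> FrameEnsemble:
    """Read a coordinate series into a FrameEnsemble.

    QC atoms are identified by ``qc_selection`` (atom names or 0-based file
    indices) and carry no charge here — their per-state charges live in the
    ElectronicStateSet. Every remaining atom becomes an environment point;
    for GRO input its charge is looked up by atom name in the charge table
    (an unmapped name is an error naming the atom), for XYZQ input the
    charge column is used directly.
    """
    coord_path = str(coord_path)
    if fmt is None:
        fmt = "xyzq" if coord_path.endswith((".xyzq", ".xyzq.txt")) else "gro"
    frames = []
    if fmt == "gro":
        if charge_table_path is None:
            raise PmmRedoxError("GRO input requires a charge table")
        table = load_charge_table(charge_table_path)
        for fidx, (names, resids, coords, box) in enumerate(
            _parse_gro_series(coord_path)
        ):
            qc_idx = _resolve_selection(qc_selection, names)
            env_mask = np.ones(len(names), dtype=bool)
            env_mask[qc_idx] = False
            env_idx = np.flatnonzero(env_mask)
            charges = []
            for k in env_idx:
                if names[k] not in table:
                    raise PmmRedoxError(
                        f"atom {names[k]!r} (index {k}) missing from charge table"
                    )
                charges.append(table[names[k]])
            frames.append(
                Frame(
                    box_edge=box,
                    qc_coords=coords[qc_idx],
                    env_coords=coords[env_idx],
                    env_charges=np.array(charges, dtype=float),
                    env_groups=resids[env_idx],
                    index=fidx,
                )
            )
        charge_map_id = str(charge_table_path)
    elif fmt == "xyzq":
        for fidx, (labels, groups, coords, charges, box) in enumerate(
            _parse_xyzq_series(coord_path)
        ):
            qc_idx = _resolve_selection(qc_selection, labels)
            env_mask = np.ones(len(labels), dtype=bool)
            env_mask[qc_idx] = False
            env_idx = np.flatnonzero(env_mask)
            frames.append(
                Frame(
                    box_edge=box,
                    qc_coords=coords[qc_idx],
                    env_coords=coords[env_idx],
                    env_charges=charges[env_idx],
                    env_groups=groups[env_idx],
                    index=fidx,
                )
            )
        charge_map_id = "xyzq-inline"
    else:
        raise PmmRedoxError(f"unknown trajectory format {fmt!r}")
    if not frames:
        raise PmmRedoxError(f"{coord_path}: no frames found")
    ens = FrameEnsemble(
        label=label, temperature=temperature, frames=frames,
        charge_map_id=charge_map_id,
    )
    ens.validate()
    return ens


def write_xyzq(ensemble: FrameEnsemble, path, qc_labels: Sequence[str]) -> None:
    """Write an ensemble in the XYZQ dialect (QC atoms first, charge 0)."""
    with open(path, "w") as fh:
        for f in ensemble.frames:
            fh.write(f"{f.n_qc + f.n_env}\n")
            fh.write(f"frame={f.index} box_edge={f.box_edge:.6f} nm\n")
            for lbl, xyz in zip(qc_labels, f.qc_coords):
                fh.write(
                    f"{lbl} {xyz[0]:.6f} {xyz[1]:.6f} {xyz[2]:.6f} 0.0 -1\n"
                )
            for xyz, q, g in zip(f.env_coords, f.env_charges, f.env_groups):
                fh.write(
                    f"ENV {xyz[0]:.6f} {xyz[1]:.6f} {xyz[2]:.6f} {q:.6f} {g}\n"
                )
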