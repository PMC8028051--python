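"""Electrostatic potential and field of environment point charges.

The perturbing environment enters the perturbed Hamiltonian through two
quantities per frame: the Coulomb potential at each QC atom position
(feeding the atom-based diagonal) and the electric field at the QC center
of mass (feeding the dipolar off-diagonal coupling). Bare Coulomb sums
over all points with minimum-image periodic wrapping; no Ewald, no
reaction field, no cutoff by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import D_MIN_DEFAULT, K_E
from .errors import NearSingularityError, ValidationError
from .qc_model import ElectronicStateSet
from .trajectory_io import Frame, minimum_image


@dataclass
class PerturbationSample:
    """Electrostatic perturbation at one frame.

    ``potentials_at_atoms`` in V (one per QC atom), ``field_at_com`` in
    V/nm at ``com``, the instantaneous QC center of mass (nm).
    """

    potentials_at_atoms: np.ndarray
    field_at_com: np.ndarray
    com: np.ndarray

    def __post_init__(self):
        self.potentials_at_atoms = np.asarray(self.potentials_at_atoms, dtype=float)
        self.field_at_com = np.asarray(self.field_at_com, dtype=float)
        self.com = np.asarray(self.com, dtype=float)
        if not (
            np.all(np.isfinite(self.potentials_at_atoms))
            and np.all(np.isfinite(self.field_at_com))
        ):
            raise ValidationError("non-finite perturbation sample")


def _displacements(point, frame: Frame, use_pbc: bool, d_min: float):
    """point-minus-charge displacement vectors and norms, with d_min guard."""
    point = np.asarray(point, dtype=float)
    if frame.n_env == 0:
        return np.zeros((0, 3)), np.zeros(0)
    disp = point[None, :] - frame.env_coords
    if use_pbc:
        disp = minimum_image(disp, frame.box_edge)
    r = np.linalg.norm(disp, axis=1)
    if r.size and r.min() <= d_min:
        k = int(np.argmin(r))
        raise NearSingularityError(
            f"environment charge {k} (q={frame.env_charges[k]:+.3f} e) is "
            f"{r[k]:.4f} nm from the evaluation point in frame {frame.index} "
            f"(d_min={d_min} nm)",
            frame_index=frame.index,
            charge_index=k,
        )
    return disp, r


def potential_at(point, frame: Frame, use_pbc: bool = True,
                 d_min: float = D_MIN_DEFAULT) -> float:
    """Coulomb potential (V) at ``point`` from the frame's environment."""
    _, r = _displacements(point, frame, use_pbc, d_min)
    if r.size == 0:
        return 0.0
    return float(K_E * np.sum(frame.env_charges / r))


def field_at(point, frame: Frame, use_pbc: bool = True,
             d_min: float = D_MIN_DEFAULT) -> np.ndarray:
    """Electric field (V/nm) at ``point`` from the frame's environment."""
    disp, r = _displacements(point, frame, use_pbc, d_min)
    if r.size == 0:
        return np.zeros(3)
    return K_E * np.sum(frame.env_charges[:, None] * disp / r[:, None] ** 3, axis=0)


def sample_perturbation(
    frame: Frame,
    stateset: ElectronicStateSet,
    use_pbc: bool = True,
    d_min: float = D_MIN_DEFAULT,
) -> PerturbationSample:
    """Evaluate the perturbation a frame exerts on a QC.

    QC atom positions are taken from the frame (the classical geometry),
    in the order of the state set's geometry; the field is evaluated at
    the frame-instantaneous center of mass built from the state set's
    masses and the frame coordinates.
    """
    if frame.n_qc != stateset.n_atoms:
        raise ValidationError(
            f"frame has {frame.n_qc} QC atoms, state set expects "
            f"{stateset.n_atoms}"
        )
    m = stateset.masses
    com = m @ frame.qc_coords / m.sum()
    if frame.n_env == 0:
        return PerturbationSample(
            potentials_at_atoms=np.zeros(frame.n_qc),
            field_at_com=np.zeros(3),
            com=com,
        )
    # vectorized over atoms: displacement tensor (n_qc, n_env, 3)
    disp = frame.qc_coords[:, None, :] - frame.env_coords[None, :, :]
    if use_pbc:
        disp = minimum_image(disp, frame.box_edge)
    r = np.linalg.norm(disp, axis=2)
    if r.min() <= d_min:
        a, k = np.unravel_index(int(np.argmin(r)), r.shape)
        raise NearSingularityError(
            f"environment charge {k} (q={frame.env_charges[k]:+.3f} e) is "
            f"{r[a, k]:.4f} nm from QC atom {a} in frame {frame.index} "
            f"(d_min={d_min} nm)",
            frame_index=frame.index,
            charge_index=int(k),
        )
    pots = K_E * (1.0 / r) @ frame.env_charges
    return PerturbationSample(
        potentials_at_atoms=pots,
        field_at_com=field_at(com, frame, use_pbc=use_pbc, d_min=d_min),
        com=com,
    )
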