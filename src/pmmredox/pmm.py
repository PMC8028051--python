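"""Perturbed-matrix-method engine.

Per frame, the electronic Hamiltonian of the quantum center embedded in
the point-charge environment is built in the basis of its unperturbed
states and diagonalized:

* diagonal elements use the atom-based expansion truncated at the atomic
  monopole: ``H[i][i] = E_i + sum_N q_{N,i} * V(R_N)``, with ``V(R_N)``
  the environment potential at atom N and ``q_{N,i}`` state i's partial
  charge on that atom;
* off-diagonal elements use the dipolar approximation centered at the QC
  center of mass: ``H[i][j] = -E(r_0) . mu_ij``.

The per-frame ground state is the lowest eigenvalue — no adiabatic
state-tracking across frames; the minimum ground/first-excited gap is
reported as a crossing diagnostic instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .constants import D_MIN_DEFAULT
from .electrostatics import PerturbationSample, sample_perturbation
from .errors import EmptySeriesError, NearSingularityError, ValidationError
from .qc_model import ElectronicStateSet, RedoxSpeciesPair
from .trajectory_io import FrameEnsemble

SYMMETRY_TOL = 1e-10


@dataclass
class PmmConfig:
    """Engine knobs: periodic boundaries, clash guard, skip policy."""

    use_pbc: bool = True
    d_min: float = D_MIN_DEFAULT
    on_singularity: str = "skip"  # "skip" (log + drop frame) | "error"

    def __post_init__(self):
        if self.on_singularity not in ("skip", "error"):
            raise ValidationError(
                f"on_singularity must be 'skip' or 'error', got "
                f"{self.on_singularity!r}"
            )


@dataclass
class PerturbedState:
    """Eigen-solution of one frame's perturbed Hamiltonian."""

    eigenvalues: np.ndarray  # ascending, eV
    ground_energy: float
    ground_vector: np.ndarray  # unit-norm coefficients over unperturbed states
    frame_index: int = 0
    eigenvectors: Optional[np.ndarray] = None  # columns, same order


@dataclass
class GapSeries:
    """Per-frame oxidized-minus-reduced ground-state energy differences."""

    ensemble_label: str  # "reduced" | "oxidized"
    kind: str  # "vertical" | "adiabatic"
    values: np.ndarray  # eV, one per retained frame
    frame_indices: np.ndarray = None  # original frame indices retained
    skipped: list = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.frame_indices is None:
            self.frame_indices = np.arange(len(self.values))
        self.frame_indices = np.asarray(self.frame_indices, dtype=int)
        if self.ensemble_label not in ("reduced", "oxidized"):
            raise ValidationError(f"bad ensemble_label {self.ensemble_label!r}")
        if self.kind not in ("vertical", "adiabatic"):
            raise ValidationError(f"bad kind {self.kind!r}")


@dataclass
class SeriesResult:
    """Ground-energy series with skip bookkeeping and crossing diagnostics."""

    values: np.ndarray  # eV, retained frames only
    frame_indices: np.ndarray
    skipped: list  # original indices of skipped frames
    min_gap_01: np.ndarray  # first-excited minus ground per retained frame

    @property
    def n_skipped(self) -> int:
        return len(self.skipped)


def build_hamiltonian(
    sample: PerturbationSample, stateset: ElectronicStateSet
) -> np.ndarray:
    """Assemble the perturbed Hamiltonian matrix (eV), exactly symmetric."""
    if sample.potentials_at_atoms.shape != (stateset.n_atoms,):
        raise ValidationError(
            f"perturbation sample has {sample.potentials_at_atoms.size} atom "
            f"potentials, state set has {stateset.n_atoms} atoms"
        )
    diag = stateset.energies + stateset.state_charges @ sample.potentials_at_atoms
    # off-diagonal dipolar coupling: -E . mu_ij
    H = -(stateset.transition_dipoles @ sample.field_at_com)
    np.fill_diagonal(H, diag)
    return 0.5 * (H + H.T)  # exact symmetry despite floating-point assembly


def diagonalize(H: np.ndarray, frame_index: int = 0) -> PerturbedState:
    """Eigen-decompose a symmetric Hamiltonian with a deterministic gauge.

    Eigenvalues ascend; each eigenvector's largest-magnitude coefficient is
    made positive (ties broken toward the lowest basis index), so repeated
    runs and BLAS variants agree in sign.
    """
    H = np.asarray(H, dtype=float)
    if H.ndim != 2 or H.shape[0] != H.shape[1]:
        raise ValidationError(f"Hamiltonian must be square, got {H.shape}")
    if not np.allclose(H, H.T, atol=SYMMETRY_TOL):
        raise ValidationError("Hamiltonian not symmetric within 1e-10 eV")
    w, v = np.linalg.eigh(H)
    order = np.argsort(w, kind="stable")
    w, v = w[order], v[:, order]
    # sign convention per eigenvector
    lead = np.argmax(np.abs(v), axis=0)
    signs = np.sign(v[lead, np.arange(v.shape[1])])
    signs[signs == 0] = 1.0
    v = v * signs[None, :]
    return PerturbedState(
        eigenvalues=w,
        ground_energy=float(w[0]),
        ground_vector=v[:, 0],
        frame_index=frame_index,
        eigenvectors=v,
    )


def perturbed_state(frame, stateset: ElectronicStateSet,
                    config: PmmConfig = PmmConfig()) -> PerturbedState:
    """build_hamiltonian + diagonalize for one frame."""
    sample = sample_perturbation(
        frame, stateset, use_pbc=config.use_pbc, d_min=config.d_min
    )
    return diagonalize(build_hamiltonian(sample, stateset), frame.index)


def ground_energy_series(
    ensemble: FrameEnsemble,
    stateset: ElectronicStateSet,
    config: PmmConfig = PmmConfig(),
) -> SeriesResult:
    """Perturbed ground-state energy per frame, order preserving.

    Near-singular frames are skipped (and counted) or raised, per config.
    """
    if len(ensemble) == 0:
        raise EmptySeriesError("ensemble has no frames")
    values, idx, skipped, gaps01 = [], [], [], []
    for f in ensemble.frames:
        try:
            ps = perturbed_state(f, stateset, config)
        except NearSingularityError:
            if config.on_singularity == "error":
                raise
            skipped.append(f.index)
            continue
        values.append(ps.ground_energy)
        idx.append(f.index)
        gaps01.append(
            float(ps.eigenvalues[1] - ps.eigenvalues[0])
            if len(ps.eigenvalues) > 1
            else np.inf
        )
    if not values:
        raise EmptySeriesError(
            f"all {len(ensemble)} frames skipped as near-singular"
        )
    return SeriesResult(
        values=np.array(values),
        frame_indices=np.array(idx, dtype=int),
        skipped=skipped,
        min_gap_01=np.array(gaps01),
    )


def gap_series(
    ensemble: FrameEnsemble,
    pair: RedoxSpeciesPair,
    kind: str = "vertical",
    config: PmmConfig = PmmConfig(),
    return_table: bool = False,
):
    """Oxidized-minus-reduced perturbed ground-energy series in one ensemble.

    ``kind='vertical'`` uses the cation at the neutral geometry
    (``pair.ox_vertical``); ``kind='adiabatic'`` uses the relaxed cation
    (``pair.ox_adiabatic``). Both species are evaluated on the same frames
    and share one skip set. With ``return_table=True`` also returns the
    per-frame DataFrame (frame_index, E0_red, E0_ox, gap_eV,
    min_gap_01_eV, skipped_flag).
    """
    if kind == "vertical":
        ox = pair.ox_vertical
    elif kind == "adiabatic":
        ox = pair.ox_adiabatic
    else:
        raise ValidationError(f"kind must be 'vertical' or 'adiabatic', got {kind!r}")
    if len(ensemble) == 0:
        raise EmptySeriesError("ensemble has no frames")
    rows, values, idx, skipped = [], [], [], []
    for f in ensemble.frames:
        try:
            ps_red = perturbed_state(f, pair.red, config)
            ps_ox = perturbed_state(f, ox, config)
        except NearSingularityError:
            if config.on_singularity == "error":
                raise
            skipped.append(f.index)
            rows.append((f.index, np.nan, np.nan, np.nan, np.nan, True))
            continue
        gap = ps_ox.ground_energy - ps_red.ground_energy
        mg = min(
            float(ps_red.eigenvalues[1] - ps_red.eigenvalues[0])
            if len(ps_red.eigenvalues) > 1 else np.inf,
            float(ps_ox.eigenvalues[1] - ps_ox.eigenvalues[0])
            if len(ps_ox.eigenvalues) > 1 else np.inf,
        )
        values.append(gap)
        idx.append(f.index)
        rows.append(
            (f.index, ps_red.ground_energy, ps_ox.ground_energy, gap, mg, False)
        )
    if not values:
        raise EmptySeriesError(f"all {len(ensemble)} frames skipped as near-singular")
    series = GapSeries(
        ensemble_label=ensemble.label,
        kind=kind,
        values=np.array(values),
        frame_indices=np.array(idx, dtype=int),
        skipped=skipped,
    )
    if return_table:
        table = pd.DataFrame(
            rows,
            columns=[
                "frame_index", "E0_red", "E0_ox", "gap_eV",
                "min_gap_01_eV", "skipped_flag",
            ],
        )
        return series, table
    return series
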