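"""Redox thermodynamics from energy-gap ensembles.

The oxidation free energy of a solvated chromophore is bracketed by the
ensemble averages of the (adiabatic) oxidized-minus-reduced ground-state
energy gap taken in the two equilibrium ensembles:

    <dE>_ox  <=  dA  <=  <dE>_red

and, assuming the ionic-relaxation free energies of the two end states
cancel, estimated by the mean of the bounds

    dA = ( <dE>_red + <dE>_ox ) / 2,

which is exact when both gap distributions are Gaussian with equal
variance (linear response). The vertical ionization energy is the
average vertical gap in the reduced ensemble; the reduction potential on
the SHE scale follows from the per-electron free energy,
V_red = dA / n - V_SHE (per-electron eV is numerically V, so the Faraday
constant never appears). Statistical errors come from block averaging
over three contiguous trajectory subparts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .constants import V_SHE_DEFAULT
from .errors import PmmRedoxError, ValidationError
from .pmm import GapSeries, PmmConfig, build_hamiltonian, diagonalize
from .electrostatics import sample_perturbation
from .qc_model import RedoxSpeciesPair
from .trajectory_io import Frame, FrameEnsemble, minimum_image


@dataclass
class EnsembleAverages:
    """The two bracketed gap averages entering the mean-of-bounds estimator."""

    mean_gap_red: float
    mean_gap_ox: float
    kind: str
    n_frames_red: int
    n_frames_ox: int

    def __post_init__(self):
        if not (math.isfinite(self.mean_gap_red) and math.isfinite(self.mean_gap_ox)):
            raise ValidationError("ensemble gap means must be finite")
        if self.n_frames_red <= 0 or self.n_frames_ox <= 0:
            raise ValidationError("frame counts must be > 0")

    @classmethod
    def from_series(cls, red: GapSeries, ox: GapSeries) -> "EnsembleAverages":
        if red.ensemble_label != "reduced" or ox.ensemble_label != "oxidized":
            raise ValidationError(
                "expected one reduced-ensemble and one oxidized-ensemble series"
            )
        if red.kind != ox.kind:
            raise ValidationError(
                f"mixed gap kinds: {red.kind!r} vs {ox.kind!r}"
            )
        return cls(
            mean_gap_red=float(np.mean(red.values)),
            mean_gap_ox=float(np.mean(ox.values)),
            kind=red.kind,
            n_frames_red=len(red.values),
            n_frames_ox=len(ox.values),
        )


@dataclass
class RedoxEstimate:
    """Bundle of redox observables with block-averaged errors.

    ``shift_applied`` records the gas-phase correction added to VIE, AIE
    and dA (0 when no experimental gas value was supplied);
    ``ionic_relaxation_assumption`` records that the reduced/oxidized
    ionic-relaxation free energies were assumed to cancel (fixed in v1).
    """

    delta_A: float
    V_red: float
    vie: float
    aie: float
    reorganization: float
    err_vie: float
    err_delta_A: float
    err_V_red: float
    shift_applied: float = 0.0
    n_frames_red: int = 0
    n_frames_ox: int = 0
    n_skipped_red: int = 0
    n_skipped_ox: int = 0
    ionic_relaxation_assumption: bool = field(default=True)

    def to_dict(self) -> dict:
        return {
            "delta_A_eV": self.delta_A,
            "V_red_V": self.V_red,
            "vie_eV": self.vie,
            "aie_eV": self.aie,
            "reorganization_eV": self.reorganization,
            "err_vie_eV": self.err_vie,
            "err_delta_A_eV": self.err_delta_A,
            "err_V_red_V": self.err_V_red,
            "shift_applied_eV": self.shift_applied,
            "n_frames_red": self.n_frames_red,
            "n_frames_ox": self.n_frames_ox,
            "n_skipped_red": self.n_skipped_red,
            "n_skipped_ox": self.n_skipped_ox,
            "ionic_relaxation_assumption": self.ionic_relaxation_assumption,
        }


def vertical_ionization_energy(gaps: GapSeries) -> float:
    """Mean vertical gap in the reduced ensemble (the VIE), eV."""
    if gaps.ensemble_label != "reduced":
        raise ValidationError(
            f"VIE requires the reduced ensemble, got {gaps.ensemble_label!r}"
        )
    if gaps.kind != "vertical":
        raise ValidationError(f"VIE requires vertical gaps, got {gaps.kind!r}")
    return float(np.mean(gaps.values))


def adiabatic_ionization_energy(gaps: GapSeries) -> float:
    """Mean adiabatic gap in the reduced ensemble (the AIE), eV."""
    if gaps.ensemble_label != "reduced":
        raise ValidationError(
            f"AIE requires the reduced ensemble, got {gaps.ensemble_label!r}"
        )
    if gaps.kind != "adiabatic":
        raise ValidationError(f"AIE requires adiabatic gaps, got {gaps.kind!r}")
    return float(np.mean(gaps.values))


def oxidation_free_energy(avg: EnsembleAverages) -> float:
    """Mean-of-bounds oxidation free energy, eV (adiabatic gaps only)."""
    if avg.kind != "adiabatic":
        raise ValidationError(
            f"oxidation free energy requires adiabatic gaps, got {avg.kind!r}"
        )
    return 0.5 * (avg.mean_gap_red + avg.mean_gap_ox)


def reorganization_energy(avg: EnsembleAverages) -> float:
    """Half the spread of the two bounds; >= 0 for equilibrium sampling."""
    return 0.5 * (avg.mean_gap_red - avg.mean_gap_ox)


def reduction_potential(
    delta_A: float, n_electrons: int = 1, v_she: float = V_SHE_DEFAULT
) -> float:
    """Standard reduction potential vs SHE, V.

    ``delta_A`` is the per-molecule oxidation free energy in eV; per
    electron it is numerically a potential in volts, so
    V_red = delta_A/n - V_SHE. A larger oxidation free energy (harder to
    oxidize) gives a larger reduction potential.
    """
    if n_electrons < 1:
        raise ValidationError(f"n_electrons must be >= 1, got {n_electrons}")
    return delta_A / n_electrons - v_she


def gas_shift_correction(value_aq_calc: float, gas_calc: float,
                         gas_exp: float) -> float:
    """Shift an aqueous computed energy by the gas-phase exp-minus-calc gap."""
    for name, v in (("value_aq_calc", value_aq_calc), ("gas_calc", gas_calc),
                    ("gas_exp", gas_exp)):
        if not math.isfinite(v):
            raise ValidationError(f"{name} must be finite")
    return value_aq_calc + (gas_exp - gas_calc)


def block_error(series, n_blocks: int = 3) -> float:
    """Standard error of the mean by block averaging.

    The series is split into ``n_blocks`` contiguous equal-length blocks
    (any remainder at the end is dropped); the sample standard deviation
    of the block means divided by sqrt(n_blocks) is returned.
    """
    x = np.asarray(series, dtype=float)
    if n_blocks < 2:
        raise ValidationError(f"n_blocks must be >= 2, got {n_blocks}")
    if x.size < n_blocks:
        raise ValidationError(
            f"series of length {x.size} shorter than {n_blocks} blocks"
        )
    blen = x.size // n_blocks
    means = x[: n_blocks * blen].reshape(n_blocks, blen).mean(axis=1)
    return float(np.std(means, ddof=1) / math.sqrt(n_blocks))


def redox_estimate(
    vertical_red: GapSeries,
    adiabatic_red: GapSeries,
    adiabatic_ox: GapSeries,
    n_electrons: int = 1,
    v_she: float = V_SHE_DEFAULT,
    n_blocks: int = 3,
    gas_calc: Optional[float] = None,
    gas_exp: Optional[float] = None,
) -> RedoxEstimate:
    """Assemble the full redox summary from three gap series.

    When both gas-phase VIE values are given, the exp-minus-calc shift is
    added to VIE, AIE and dA before converting to a potential (the same
    unperturbed-energy correction for vertical and adiabatic quantities).
    Errors on V_red propagate from dA with slope 1/n; V_SHE is exact.
    """
    vie = vertical_ionization_energy(vertical_red)
    aie = adiabatic_ionization_energy(adiabatic_red)
    avg = EnsembleAverages.from_series(adiabatic_red, adiabatic_ox)
    dA = oxidation_free_energy(avg)
    reorg = reorganization_energy(avg)
    shift = 0.0
    if gas_calc is not None and gas_exp is not None:
        shift = gas_exp - gas_calc
    err_vie = block_error(vertical_red.values, n_blocks)
    err_red = block_error(adiabatic_red.values, n_blocks)
    err_ox = block_error(adiabatic_ox.values, n_blocks)
    err_dA = 0.5 * math.hypot(err_red, err_ox)
    return RedoxEstimate(
        delta_A=dA + shift,
        V_red=reduction_potential(dA + shift, n_electrons, v_she),
        vie=vie + shift,
        aie=aie + shift,
        reorganization=reorg,
        err_vie=err_vie,
        err_delta_A=err_dA,
        err_V_red=err_dA / n_electrons,
        shift_applied=shift,
        n_frames_red=len(adiabatic_red.values),
        n_frames_ox=len(adiabatic_ox.values),
        n_skipped_red=len(adiabatic_red.skipped),
        n_skipped_ox=len(adiabatic_ox.skipped),
    )


# ---------------------------------------------------------------------------
# Solvent truncation (convergence-with-system-size) scan
# ---------------------------------------------------------------------------

def _truncated_frame(frame: Frame, keep_groups: np.ndarray) -> Frame:
    mask = np.isin(frame.env_groups, keep_groups)
    return Frame(
        box_edge=frame.box_edge,
        qc_coords=frame.qc_coords,
        env_coords=frame.env_coords[mask],
        env_charges=frame.env_charges[mask],
        env_groups=frame.env_groups[mask],
        index=frame.index,
    )


def _vertical_gap_one_frame(frame, pair, config) -> float:
    s_red = sample_perturbation(frame, pair.red, config.use_pbc, config.d_min)
    e_red = diagonalize(build_hamiltonian(s_red, pair.red)).ground_energy
    s_ox = sample_perturbation(frame, pair.ox_vertical, config.use_pbc, config.d_min)
    e_ox = diagonalize(build_hamiltonian(s_ox, pair.ox_vertical)).ground_energy
    return e_ox - e_red


def _group_center_distances(frame: Frame, masses: np.ndarray):
    """|q|-weighted distance of each solvent group's center from the QC
    center of mass (minimum image). Returns (group_ids, distances)."""
    com = masses @ frame.qc_coords / masses.sum()
    d = np.linalg.norm(minimum_image(frame.env_coords - com, frame.box_edge),
                       axis=1)
    w = np.abs(frame.env_charges)
    group_ids = np.unique(frame.env_groups)
    order = np.argsort(frame.env_groups, kind="stable")
    gsorted = frame.env_groups[order]
    bounds = np.searchsorted(gsorted, group_ids, side="left")
    centers = np.add.reduceat((w * d)[order], bounds) / np.add.reduceat(
        w[order], bounds
    )
    return group_ids, centers


def solvent_truncation_scan(
    ensemble: FrameEnsemble,
    pair: RedoxSpeciesPair,
    radii_or_counts: Sequence,
    config: PmmConfig = PmmConfig(),
) -> pd.DataFrame:
    """Sensitivity of the VIE to dropping the farthest solvent groups.

    Each level is either an ``int`` — remove that many groups, farthest
    first by the |q|-weighted center distance from the QC center of mass
    (minimum image) — or a ``float`` radius in nm: remove every group
    whose center lies beyond it. The per-frame vertical gap is recomputed
    on the truncated frames and its difference to the all-solvent
    reference summarized. Returns one row per level (int level 0 = the
    reference), columns: level, removed (mean over frames for radius
    levels), retained, vie_eV, diff_mean_eV, diff_sd_eV, diff_min_eV,
    diff_max_eV.
    """
    levels = sorted(set(radii_or_counts), key=lambda x: (isinstance(x, float), x))
    if any(isinstance(n, (int, np.integer)) and n < 0 for n in levels):
        raise ValidationError("removal counts must be >= 0")
    masses = pair.red.masses
    ref_gaps = np.array(
        [_vertical_gap_one_frame(f, pair, config) for f in ensemble.frames]
    )
    rows = []
    for level in levels:
        by_radius = isinstance(level, float)
        diffs, gaps, removed = [], [], []
        for f, ref in zip(ensemble.frames, ref_gaps):
            group_ids, centers = _group_center_distances(f, masses)
            if by_radius:
                keep = group_ids[centers <= level]
                n_remove = group_ids.size - keep.size
            else:
                n_remove = int(level)
                if n_remove > group_ids.size:
                    raise PmmRedoxError(
                        f"cannot remove {n_remove} of {group_ids.size} groups"
                    )
                keep = group_ids[np.argsort(centers, kind="stable")][
                    : group_ids.size - n_remove
                ]
            removed.append(n_remove)
            if n_remove == 0:
                gaps.append(ref)
                diffs.append(0.0)
                continue
            g = _vertical_gap_one_frame(_truncated_frame(f, keep), pair, config)
            gaps.append(g)
            diffs.append(g - ref)
        diffs = np.array(diffs)
        n_groups = int(np.unique(ensemble.frames[0].env_groups).size)
        rows.append(
            {
                "level": level,
                "removed": float(np.mean(removed)),
                "retained": n_groups - float(np.mean(removed)),
                "vie_eV": float(np.mean(gaps)),
                "diff_mean_eV": float(diffs.mean()),
                "diff_sd_eV": float(diffs.std(ddof=1)) if len(diffs) > 1 else 0.0,
                "diff_min_eV": float(diffs.min()),
                "diff_max_eV": float(diffs.max()),
            }
        )
    return pd.DataFrame(rows)
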