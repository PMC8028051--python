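"""Synthetic inputs with known answers for every pipeline stage.

The generator stands in for the electronic-structure and molecular-
dynamics inputs the method normally consumes: it fabricates a reduced/
oxidized species pair with a prescribed unperturbed vertical gap,
relaxation energy and dipole-moment change upon oxidation, and samples
classical solvent configurations around it — either independently
(uniform rigid groups outside an exclusion radius; fast, non-responsive)
or by Metropolis Monte Carlo on the point-charge Coulomb energy, which
yields genuinely distinct, physically responsive reduced and oxidized
ensembles. A Gaussian gap-series generator with an analytic free energy
exercises the mean-of-bounds estimator directly.

Defaults emulate a nucleoside-in-water study box: cubic 3.1 nm side,
~1050 three-site water-like charge groups (-0.82/+0.41/+0.41 e) at
300 K, seven electronic states per species.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .constants import DEBYE_TO_E_NM, K_B, K_E
from .errors import PmmRedoxError, ValidationError
from .pmm import GapSeries
from .qc_model import (ElectronicState, ElectronicStateSet, RedoxSpeciesPair,
                       write_stateset)
from .trajectory_io import Frame, FrameEnsemble, minimum_image, write_xyzq

# SPC-like rigid geometry: O at the group center, two H at 0.1 nm, 109.47 deg
_HALF = math.radians(109.47 / 2)
WATER_SITES = (
    (np.zeros(3), -0.82),
    (np.array([0.1 * math.sin(_HALF), 0.0, 0.1 * math.cos(_HALF)]), 0.41),
    (np.array([-0.1 * math.sin(_HALF), 0.0, 0.1 * math.cos(_HALF)]), 0.41),
)


@dataclass
class SolventSpec:
    """Box of rigid point-charge solvent groups around a quantum center."""

    n_groups: int = 1050
    box_edge: float = 3.1  # nm
    site_charges: tuple = WATER_SITES  # ((offset nm, charge e), ...)
    exclusion_radius: float = 0.30  # nm, group center to any QC atom
    hard_core: float = 0.26  # nm, group center to group center (Metropolis)
    temperature: float = 300.0  # K
    seed: int = 0

    def __post_init__(self):
        qtot = sum(q for _, q in self.site_charges)
        if abs(qtot) > 1e-9:
            raise ValidationError(
                f"solvent group charges must sum to 0, got {qtot}"
            )
        if self.n_groups < 0 or self.box_edge <= 0:
            raise ValidationError("n_groups >= 0 and box_edge > 0 required")

    @property
    def offsets(self) -> np.ndarray:
        return np.array([o for o, _ in self.site_charges], dtype=float)

    @property
    def charges(self) -> np.ndarray:
        return np.array([q for _, q in self.site_charges], dtype=float)


@dataclass
class GaussianGapSpec:
    """Two Gaussian gap ensembles with a known mean-of-bounds answer."""

    mean_red: float = 6.0
    mean_ox: float = 4.0
    sigma: float = 0.5
    n_samples: int = 10_000
    seed: int = 0

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValidationError(f"sigma must be > 0, got {self.sigma}")
        if self.n_samples < 2:
            raise ValidationError("n_samples must be >= 2")

    @property
    def analytic_delta_A(self) -> float:
        """Exact free energy under equal-variance Gaussian statistics."""
        return 0.5 * (self.mean_red + self.mean_ox)


# ---------------------------------------------------------------------------
# Species pair
# ---------------------------------------------------------------------------

_MASSES = np.array([12.011, 1.008, 15.999, 14.007])
_LABELS = ["C", "H", "O", "N"]


def _random_rotations(rng: np.random.Generator, n: int) -> np.ndarray:
    """n uniform random rotation matrices (quaternion construction)."""
    q = rng.normal(size=(n, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    w, x, y, z = q.T
    return np.stack(
        [
            np.stack([1 - 2 * (y**2 + z**2), 2 * (x * y - z * w), 2 * (x * z + y * w)], -1),
            np.stack([2 * (x * y + z * w), 1 - 2 * (x**2 + z**2), 2 * (y * z - x * w)], -1),
            np.stack([2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x**2 + y**2)], -1),
        ],
        axis=1,
    )


def _state_charges(rng, n_atoms, total, scale=0.25):
    q = rng.normal(scale=scale, size=n_atoms)
    return q + (total - q.sum()) / n_atoms


def _make_stateset(rng, label, total_charge, geometry, ground_energy,
                   excitations, ground_dipole, dipole_scatter=0.02):
    n_states = len(excitations) + 1
    n_atoms = len(geometry)
    energies = np.concatenate([[ground_energy], ground_energy + np.asarray(excitations)])
    states = []
    perms = [np.asarray(ground_dipole, dtype=float)]
    for i in range(1, n_states):
        perms.append(perms[0] + rng.normal(scale=dipole_scatter, size=3))
    td = rng.normal(scale=dipole_scatter, size=(n_states, n_states, 3))
    td = 0.5 * (td + np.swapaxes(td, 0, 1))
    for i in range(n_states):
        td[i, i] = perms[i]
        states.append(
            ElectronicState(
                index=i,
                energy=float(energies[i]),
                atomic_charges=_state_charges(rng, n_atoms, total_charge),
                permanent_dipole=perms[i],
            )
        )
    return ElectronicStateSet(
        species_label=label,
        total_charge=total_charge,
        geometry=geometry,
        states=states,
        transition_dipoles=td,
        energy_reference="absolute",
    )


def make_synthetic_pair(
    n_atoms: int = 12,
    n_states: int = 7,
    dipole_shift: float = 1.8 * DEBYE_TO_E_NM,
    gap0: float = 8.97,
    relaxation: float = 0.30,
    seed: int = 0,
    gas_vie_exp: Optional[float] = None,
) -> RedoxSpeciesPair:
    """Fabricate a valid reduced/oxidized species pair.

    The unperturbed vertical gap is exactly ``gap0`` (eV) and the relaxed
    cation's ground energy sits exactly ``relaxation`` below the vertical
    one; the cation's permanent dipole magnitude exceeds the neutral's by
    ``dipole_shift`` (e*nm; the default mirrors a 1.8 D increase upon
    oxidation). All state-set invariants hold by construction.
    """
    if n_states < 1 or n_atoms < 1:
        raise ValidationError("n_atoms and n_states must be >= 1")
    if relaxation < 0:
        raise ValidationError(f"relaxation must be >= 0, got {relaxation}")
    rng = np.random.default_rng(seed)
    coords = rng.uniform(-0.15, 0.15, size=(n_atoms, 3))
    kinds = rng.integers(0, len(_MASSES), size=n_atoms)
    geometry = [
        (f"{_LABELS[k]}{i+1}", float(_MASSES[k]), coords[i])
        for i, k in enumerate(kinds)
    ]
    # neutral: excitations ~4.5-8 eV; cation: lower-lying excitations
    exc_red = np.sort(rng.uniform(4.5, 8.0, size=n_states - 1))
    exc_ox = np.sort(rng.uniform(0.8, 3.0, size=n_states - 1))
    mu_red = rng.normal(scale=1.0, size=3)
    mu_red *= 3.0 * DEBYE_TO_E_NM / np.linalg.norm(mu_red)  # ~3 D neutral
    mu_ox = mu_red * (np.linalg.norm(mu_red) + dipole_shift) / np.linalg.norm(mu_red)
    red = _make_stateset(rng, "toy_red", 0, geometry, 0.0, exc_red, mu_red)
    ox_v = _make_stateset(rng, "toy_ox_vertical", 1, geometry, gap0, exc_ox, mu_ox)
    geom_ad = [
        (lbl, m, xyz + rng.normal(scale=0.008, size=3))
        for lbl, m, xyz in geometry
    ]
    ox_a = _make_stateset(
        rng, "toy_ox_adiabatic", 1, geom_ad, gap0 - relaxation, exc_ox, mu_ox
    )
    pair = RedoxSpeciesPair(
        red=red, ox_vertical=ox_v, ox_adiabatic=ox_a,
        gas_vie_calc=gap0, gas_vie_exp=gas_vie_exp,
    )
    pair.validate()
    return pair


# ---------------------------------------------------------------------------
# Solvent ensembles
# ---------------------------------------------------------------------------

def _qc_clash(centers, qc_coords, exclusion, box_edge):
    """Boolean mask: group center within the exclusion radius of any QC atom."""
    if len(qc_coords) == 0:
        return np.zeros(len(centers), dtype=bool)
    disp = minimum_image(
        centers[:, None, :] - qc_coords[None, :, :], box_edge
    )
    return (np.linalg.norm(disp, axis=2) < exclusion).any(axis=1)


def _sites_from(centers, rots, offsets, box_edge):
    """(n_groups * n_sites, 3) site coordinates (unwrapped around centers)."""
    return (centers[:, None, :] + np.einsum("nij,sj->nsi", rots, offsets)).reshape(
        -1, 3
    )


def _pair_energy(sites_a, charges_a, sites_b, charges_b, box_edge):
    """Coulomb energy between two site sets, minimum image, eV."""
    if len(sites_a) == 0 or len(sites_b) == 0:
        return 0.0
    disp = minimum_image(sites_a[:, None, :] - sites_b[None, :, :], box_edge)
    r = np.linalg.norm(disp, axis=2)
    return float(K_E * (charges_a @ (1.0 / r) @ charges_b))


def _iid_centers(rng, spec, qc_coords, max_tries=200):
    centers = rng.uniform(0.0, spec.box_edge, size=(spec.n_groups, 3))
    for _ in range(max_tries):
        bad = _qc_clash(centers, qc_coords, spec.exclusion_radius, spec.box_edge)
        if not bad.any():
            return centers
        centers[bad] = rng.uniform(0.0, spec.box_edge, size=(int(bad.sum()), 3))
    raise PmmRedoxError(
        "could not place solvent groups outside the exclusion radius; "
        "the exclusion sphere may not fit in the box"
    )


def _frame_from(centers, rots, spec, qc_coords, index):
    sites = _sites_from(centers, rots, spec.offsets, spec.box_edge)
    n_sites = len(spec.site_charges)
    return Frame(
        box_edge=spec.box_edge,
        qc_coords=qc_coords,
        env_coords=sites,
        env_charges=np.tile(spec.charges, spec.n_groups),
        env_groups=np.repeat(np.arange(spec.n_groups), n_sites),
        index=index,
    )


def generate_solvent_frames(
    spec: SolventSpec,
    qc_geometry,
    n_frames: int,
    mode: str = "iid",
    qc_state_charges=None,
    label: str = "reduced",
    burn_in_sweeps: int = 50,
    stride_sweeps: int = 10,
    trans_step: float = 0.012,  # nm
    max_rot: float = 0.5,  # rad
    max_tries: int = 500,
) -> FrameEnsemble:
    """Sample solvent configurations around a fixed QC geometry.

    ``qc_geometry`` is a geometry list as in ElectronicStateSet (or an
    (n,3) coordinate array). ``mode='iid'`` places groups uniformly with
    uniform orientations, rejecting any inside the exclusion radius —
    fast, but the two redox ensembles are statistically identical.
    ``mode='metropolis'`` runs single-group-move Markov-chain sampling of
    the point-charge Coulomb energy (solvent-solvent + solvent-QC, using
    ``qc_state_charges`` — the ground-state charges of the species whose
    ensemble is being generated) at ``spec.temperature``, with hard-core
    rejection standing in for excluded volume; burn-in and stride are in
    sweeps of ``n_groups`` single-group moves. Fully reproducible from
    ``spec.seed``; the acceptance rate is recorded in
    ``ensemble.metadata['acceptance_rate']``.
    """
    if isinstance(qc_geometry, (list, tuple)) and qc_geometry and isinstance(
        qc_geometry[0], (list, tuple)
    ) and len(qc_geometry[0]) == 3 and isinstance(qc_geometry[0][0], str):
        qc_coords = np.array([xyz for _, _, xyz in qc_geometry], dtype=float)
    else:
        qc_coords = np.asarray(qc_geometry, dtype=float).reshape(-1, 3)
    rng = np.random.default_rng(spec.seed)
    frames = []
    meta = {"mode": mode, "spec_seed": spec.seed}
    if spec.n_groups == 0:
        frames = [
            Frame(
                box_edge=spec.box_edge, qc_coords=qc_coords,
                env_coords=np.zeros((0, 3)), env_charges=np.zeros(0),
                env_groups=np.zeros(0, dtype=int), index=i,
            )
            for i in range(n_frames)
        ]
    elif mode == "iid":
        for i in range(n_frames):
            centers = _iid_centers(rng, spec, qc_coords)
            rots = _random_rotations(rng, spec.n_groups)
            frames.append(_frame_from(centers, rots, spec, qc_coords, i))
    elif mode == "metropolis":
        if qc_state_charges is None:
            raise ValidationError("metropolis mode requires qc_state_charges")
        qc_q = np.asarray(qc_state_charges, dtype=float)
        if qc_q.shape != (len(qc_coords),):
            raise ValidationError("qc_state_charges length must match QC atoms")
        frames, acc = _metropolis_frames(
            rng, spec, qc_coords, qc_q, n_frames,
            burn_in_sweeps, stride_sweeps, trans_step, max_rot, max_tries,
        )
        meta["acceptance_rate"] = acc
    else:
        raise ValidationError(f"mode must be 'iid' or 'metropolis', got {mode!r}")
    ens = FrameEnsemble(
        label=label, temperature=spec.temperature, frames=frames,
        charge_map_id=f"synthetic-{mode}", metadata=meta,
    )
    ens.validate()
    return ens


def _metropolis_frames(rng, spec, qc_coords, qc_q, n_frames,
                       burn_in_sweeps, stride_sweeps, trans_step, max_rot,
                       max_tries):
    n, L = spec.n_groups, spec.box_edge
    n_sites = len(spec.site_charges)
    offsets, gq = spec.offsets, spec.charges
    beta = 1.0 / (K_B * spec.temperature)
    # initial packing: iid placement with hard-core enforcement
    centers = np.empty((n, 3))
    placed = 0
    tries = 0
    while placed < n:
        c = rng.uniform(0.0, L, size=3)
        ok = not _qc_clash(c[None, :], qc_coords, spec.exclusion_radius, L)[0]
        if ok and placed:
            d = np.linalg.norm(minimum_image(centers[:placed] - c, L), axis=1)
            ok = bool(d.min() > spec.hard_core)
        if ok:
            centers[placed] = c
            placed += 1
            tries = 0
        else:
            tries += 1
            if tries > max_tries * n:
                raise PmmRedoxError("infeasible packing: hard cores do not fit")
    rots = _random_rotations(rng, n)
    sites = _sites_from(centers, rots, offsets, L).reshape(n, n_sites, 3)
    all_q = np.tile(gq, n)

    def group_energy(j, c_j, s_j):
        """Coulomb energy of group j with all other groups and the QC."""
        others = np.delete(np.arange(n), j)
        os_ = sites[others].reshape(-1, 3)
        oq = np.tile(gq, n - 1)
        e = _pair_energy(s_j, gq, os_, oq, L)
        e += _pair_energy(s_j, gq, qc_coords, qc_q, L)
        return e

    n_moves = (burn_in_sweeps + stride_sweeps * n_frames) * n
    accepted = 0
    frames = []
    move = 0
    next_snap = burn_in_sweeps * n
    snap = 0
    while move < n_moves:
        j = int(rng.integers(n))
        c_new = (centers[j] + rng.normal(scale=trans_step, size=3)) % L
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        ang = rng.uniform(-max_rot, max_rot)
        K = np.array([[0, -axis[2], axis[1]],
                      [axis[2], 0, -axis[0]],
                      [-axis[1], axis[0], 0]])
        R = np.eye(3) + math.sin(ang) * K + (1 - math.cos(ang)) * (K @ K)
        rot_new = R @ rots[j]
        move += 1
        # hard-core / exclusion rejection
        if _qc_clash(c_new[None, :], qc_coords, spec.exclusion_radius, L)[0]:
            pass
        else:
            others = np.delete(np.arange(n), j)
            d = np.linalg.norm(minimum_image(centers[others] - c_new, L), axis=1)
            if n > 1 and d.min() <= spec.hard_core:
                pass
            else:
                s_new = c_new[None, :] + offsets @ rot_new.T
                e_old = group_energy(j, centers[j], sites[j])
                e_new = group_energy(j, c_new, s_new)
                if e_new <= e_old or rng.random() < math.exp(-beta * (e_new - e_old)):
                    centers[j], rots[j], sites[j] = c_new, rot_new, s_new
                    accepted += 1
        if move >= next_snap and snap < n_frames:
            frames.append(
                Frame(
                    box_edge=L, qc_coords=qc_coords,
                    env_coords=sites.reshape(-1, 3).copy(),
                    env_charges=all_q.copy(),
                    env_groups=np.repeat(np.arange(n), n_sites),
                    index=snap,
                )
            )
            snap += 1
            next_snap += stride_sweeps * n
    return frames, accepted / max(n_moves, 1)


# ---------------------------------------------------------------------------
# Gaussian gap series
# ---------------------------------------------------------------------------

def gaussian_gap_series(spec: GaussianGapSpec, kind: str = "adiabatic"):
    """Seeded Gaussian gap samples for the two ensembles.

    Returns ``(reduced, oxidized)`` GapSeries with means ``spec.mean_red``
    and ``spec.mean_ox`` and common ``spec.sigma``; the exact equal-
    variance free energy is ``spec.analytic_delta_A``.
    """
    rng = np.random.default_rng(spec.seed)
    red = GapSeries(
        ensemble_label="reduced", kind=kind,
        values=rng.normal(spec.mean_red, spec.sigma, size=spec.n_samples),
    )
    ox = GapSeries(
        ensemble_label="oxidized", kind=kind,
        values=rng.normal(spec.mean_ox, spec.sigma, size=spec.n_samples),
    )
    return red, ox


# ---------------------------------------------------------------------------
# Dataset export (files consumable by qc_model / trajectory_io)
# ---------------------------------------------------------------------------

def export_dataset(outdir, pair: RedoxSpeciesPair, ensembles: dict,
                   manifest_extra: Optional[dict] = None) -> dict:
    """Write state sets, XYZQ trajectories and a provenance manifest.

    ``ensembles`` maps a name (e.g. 'reduced') to a FrameEnsemble. Returns
    the manifest dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, ss in (("red", pair.red), ("ox_vertical", pair.ox_vertical),
                     ("ox_adiabatic", pair.ox_adiabatic)):
        p = outdir / f"stateset_{name}.json"
        write_stateset(ss, p)
        paths[name] = p.name
    for name, ens in ensembles.items():
        p = outdir / f"frames_{name}.xyzq"
        write_xyzq(ens, p, qc_labels=pair.red.atom_labels)
        paths[f"frames_{name}"] = p.name
    manifest = {
        "gas_vie_calc": pair.gas_vie_calc,
        "gas_vie_exp": pair.gas_vie_exp,
        "files": paths,
        **(manifest_extra or {}),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
        fh.write("\n")
    return manifest
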