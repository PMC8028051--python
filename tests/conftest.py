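"""Shared fixtures: hand-sized quantum centers, frames and ensembles."""

import numpy as np
import pytest

from pmmredox import (ElectronicState, ElectronicStateSet, Frame,
                      FrameEnsemble, make_synthetic_pair)


@pytest.fixture
def toy_stateset():
    """3-atom, 3-state neutral species with simple printed numbers."""
    td = np.zeros((3, 3, 3))
    td[0, 0] = [0.02, 0.00, 0.00]
    td[1, 1] = [0.00, 0.03, 0.00]
    td[2, 2] = [0.01, 0.01, 0.01]
    td[0, 1] = td[1, 0] = [0.005, -0.002, 0.001]
    td[0, 2] = td[2, 0] = [-0.003, 0.004, 0.002]
    td[1, 2] = td[2, 1] = [0.001, 0.001, -0.006]
    states = [
        ElectronicState(0, 0.0, [0.10, -0.25, 0.15], td[0, 0]),
        ElectronicState(1, 4.5, [-0.05, 0.20, -0.15], td[1, 1]),
        ElectronicState(2, 6.0, [0.30, -0.10, -0.20], td[2, 2]),
    ]
    ss = ElectronicStateSet(
        species_label="toy_base_red",
        total_charge=0,
        geometry=[
            ("C1", 12.011, np.array([0.00, 0.00, 0.00])),
            ("H2", 1.008, np.array([0.10, 0.00, 0.00])),
            ("O3", 15.999, np.array([0.00, 0.12, 0.00])),
        ],
        states=states,
        transition_dipoles=td,
    )
    ss.validate()
    return ss


@pytest.fixture
def toy_pair():
    """Deterministic synthetic redox pair (7 states, 12 atoms)."""
    return make_synthetic_pair(seed=42)


@pytest.fixture
def small_pair():
    """Small, fast pair for per-frame loops."""
    return make_synthetic_pair(n_atoms=4, n_states=3, seed=7)


def make_frame(qc_coords, env, box_edge=3.1, index=0):
    """Frame from a list of (xyz, charge[, group]) environment points."""
    if env:
        coords = np.array([e[0] for e in env], dtype=float)
        charges = np.array([e[1] for e in env], dtype=float)
        groups = np.array([e[2] if len(e) > 2 else i for i, e in enumerate(env)])
    else:
        coords = np.zeros((0, 3))
        charges = np.zeros(0)
        groups = np.zeros(0, dtype=int)
    return Frame(
        box_edge=box_edge,
        qc_coords=np.asarray(qc_coords, dtype=float),
        env_coords=coords,
        env_charges=charges,
        env_groups=groups,
        index=index,
    )


@pytest.fixture
def frame_factory():
    return make_frame


@pytest.fixture
def zero_env_ensemble(toy_stateset):
    frames = [
        make_frame(toy_stateset.coords + 1.0, [], index=i) for i in range(4)
    ]
    return FrameEnsemble(label="reduced", temperature=300.0, frames=frames)
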