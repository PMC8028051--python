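"""Perturbed Hamiltonian construction, diagonalization and gap series."""

import numpy as np
import pytest
import scipy.linalg

from pmmredox import (EmptySeriesError, FrameEnsemble, K_E,
                      PerturbationSample, PmmConfig, ValidationError,
                      build_hamiltonian, diagonalize, gap_series,
                      ground_energy_series, make_synthetic_pair,
                      perturbed_state, sample_perturbation)
from pmmredox.qc_model import ElectronicStateSet
from conftest import make_frame


def _sample(stateset, potentials, field):
    m = stateset.masses
    return PerturbationSample(
        potentials_at_atoms=np.asarray(potentials, dtype=float),
        field_at_com=np.asarray(field, dtype=float),
        com=m @ stateset.coords / m.sum(),
    )


# ---------------------------------------------------------------------------
# build_hamiltonian
# ---------------------------------------------------------------------------

def test_zero_perturbation_gives_unperturbed_diagonal(toy_stateset):
    H = build_hamiltonian(_sample(toy_stateset, np.zeros(3), np.zeros(3)),
                          toy_stateset)
    np.testing.assert_allclose(H, np.diag([0.0, 4.5, 6.0]), atol=1e-14)


def test_uniform_potential_is_a_gauge_shift(toy_stateset):
    # each state's charges sum to the total charge Q, so a constant
    # potential shifts every diagonal by Q*V0 (here Q=0: no shift at all)
    H = build_hamiltonian(_sample(toy_stateset, [7.0] * 3, np.zeros(3)),
                          toy_stateset)
    np.testing.assert_allclose(H, np.diag([0.0, 4.5, 6.0]), atol=1e-12)


def test_hand_summed_construction(toy_stateset):
    # one env charge q at r; element-by-element independent construction
    q, r = 0.8, np.array([1.0, 1.2, 0.9])
    frame = make_frame(toy_stateset.coords + 1.0, [(r, q)], box_edge=100.0)
    s = sample_perturbation(frame, toy_stateset, use_pbc=False)
    H = build_hamiltonian(s, toy_stateset)
    pots = [K_E * q / np.linalg.norm(rc - r) for rc in frame.qc_coords]
    m = toy_stateset.masses
    com = m @ frame.qc_coords / m.sum()
    E = K_E * q * (com - r) / np.linalg.norm(com - r) ** 3
    charges = toy_stateset.state_charges
    energies = [0.0, 4.5, 6.0]
    for i in range(3):
        expected = energies[i] + sum(
            charges[i][n] * pots[n] for n in range(3)
        )
        assert H[i, i] == pytest.approx(expected, rel=1e-12)
        for j in range(3):
            if i != j:
                mu = toy_stateset.transition_dipoles[i, j]
                assert H[i, j] == pytest.approx(-float(E @ mu), rel=1e-10)
    np.testing.assert_array_equal(H, H.T)  # exactly symmetric


# ---------------------------------------------------------------------------
# diagonalize
# ---------------------------------------------------------------------------

def test_diagonal_matrix_eigenpairs():
    ps = diagonalize(np.diag([0.0, 5.0]))
    np.testing.assert_allclose(ps.eigenvalues, [0.0, 5.0])
    np.testing.assert_allclose(ps.ground_vector, [1.0, 0.0])
    assert ps.ground_energy == ps.eigenvalues[0]


def test_two_level_closed_form():
    H = np.array([[0.0, 0.5], [0.5, 1.0]])
    ps = diagonalize(H)
    assert ps.ground_energy == pytest.approx((1 - np.sqrt(2)) / 2, abs=1e-14)
    assert ps.eigenvalues[1] == pytest.approx((1 + np.sqrt(2)) / 2, abs=1e-14)
    assert np.linalg.norm(ps.ground_vector) == pytest.approx(1.0, abs=1e-12)


def test_random_hamiltonians_match_dense_solver_oracle():
    rng = np.random.default_rng(12)
    for _ in range(50):
        A = rng.normal(size=(7, 7))
        H = 0.5 * (A + A.T)
        ps = diagonalize(H)
        w_ref = scipy.linalg.eigh(H, eigvals_only=True)
        np.testing.assert_allclose(ps.eigenvalues, np.sort(w_ref), atol=1e-10)
        # eigenvector property: H v = lambda v, deterministic sign
        np.testing.assert_allclose(
            H @ ps.ground_vector, ps.eigenvalues[0] * ps.ground_vector,
            atol=1e-10,
        )
        assert ps.ground_vector[np.argmax(np.abs(ps.ground_vector))] > 0


def test_nonsymmetric_matrix_rejected():
    with pytest.raises(ValidationError, match="symmetric"):
        diagonalize(np.array([[0.0, 1e-3], [0.0, 1.0]]))


# ---------------------------------------------------------------------------
# ground_energy_series / gap_series
# ---------------------------------------------------------------------------

def test_zero_charge_environment_gives_unperturbed_series(
    zero_env_ensemble, toy_stateset
):
    res = ground_energy_series(zero_env_ensemble, toy_stateset)
    np.testing.assert_allclose(res.values, 0.0, atol=1e-14)
    assert res.n_skipped == 0


def test_series_equals_per_frame_composition(small_pair):
    rng = np.random.default_rng(8)
    frames = [
        make_frame(
            small_pair.red.coords + 1.5,
            [(rng.uniform(0.4, 2.6, 3), q) for q in rng.uniform(-0.5, 0.5, 12)],
            index=i,
        )
        for i in range(10)
    ]
    ens = FrameEnsemble(label="reduced", temperature=300.0, frames=frames,
                        variable_composition=True)
    res = ground_energy_series(ens, small_pair.red)
    expected = [
        perturbed_state(f, small_pair.red).ground_energy for f in frames
    ]
    np.testing.assert_allclose(res.values, expected, atol=1e-14)


def test_transition_dipole_phase_flip_leaves_energies_unchanged(small_pair):
    rng = np.random.default_rng(9)
    frame = make_frame(
        small_pair.red.coords + 1.5,
        [(rng.uniform(0.4, 2.6, 3), q) for q in rng.uniform(-0.8, 0.8, 10)],
    )
    ss = small_pair.red
    e0 = perturbed_state(frame, ss).eigenvalues
    td = ss.transition_dipoles.copy()
    k = 1  # flip the phase of state 1: negate row and column, keep diagonal
    td[k, :] *= -1
    td[:, k] *= -1
    td[k, k] *= -1  # double negation restored: diagonal is physical
    flipped = ElectronicStateSet(
        species_label=ss.species_label, total_charge=ss.total_charge,
        geometry=ss.geometry,
        states=[
            st if i != k else type(st)(
                st.index, st.energy, st.atomic_charges, td[k, k]
            )
            for i, st in enumerate(ss.states)
        ],
        transition_dipoles=td,
    )
    flipped.validate()
    e1 = perturbed_state(frame, flipped).eigenvalues
    np.testing.assert_allclose(e1, e0, atol=1e-12)


def test_gap_series_zero_env_equals_unperturbed_gap(toy_pair):
    frames = [make_frame(toy_pair.red.coords + 1.0, [], index=i)
              for i in range(3)]
    ens = FrameEnsemble(label="reduced", temperature=300.0, frames=frames)
    vert = gap_series(ens, toy_pair, "vertical")
    np.testing.assert_allclose(vert.values, toy_pair.gas_vie_calc, atol=1e-12)
    adia = gap_series(ens, toy_pair, "adiabatic")
    np.testing.assert_allclose(adia.values, toy_pair.gas_vie_calc - 0.30,
                               atol=1e-12)


def test_gauge_shift_moves_gap_by_delta_q_times_constant(toy_pair):
    # adding a constant V0 to every atom potential shifts the red->ox gap
    # by exactly (Q_ox - Q_red) * V0 = V0
    v0 = 2.345
    for ss in (toy_pair.red, toy_pair.ox_vertical):
        H0 = build_hamiltonian(_sample(ss, np.zeros(ss.n_atoms), np.zeros(3)), ss)
        H1 = build_hamiltonian(
            _sample(ss, np.full(ss.n_atoms, v0), np.zeros(3)), ss
        )
        shift = ss.total_charge * v0
        np.testing.assert_allclose(H1, H0 + shift * np.eye(ss.n_states),
                                   atol=1e-10)
    gap0 = (
        diagonalize(build_hamiltonian(
            _sample(toy_pair.ox_vertical, np.zeros(12), np.zeros(3)),
            toy_pair.ox_vertical)).ground_energy
        - diagonalize(build_hamiltonian(
            _sample(toy_pair.red, np.zeros(12), np.zeros(3)),
            toy_pair.red)).ground_energy
    )
    gap1 = (
        diagonalize(build_hamiltonian(
            _sample(toy_pair.ox_vertical, np.full(12, v0), np.zeros(3)),
            toy_pair.ox_vertical)).ground_energy
        - diagonalize(build_hamiltonian(
            _sample(toy_pair.red, np.full(12, v0), np.zeros(3)),
            toy_pair.red)).ground_energy
    )
    assert gap1 - gap0 == pytest.approx(v0, abs=1e-10)


def _rotation(seed):
    rng = np.random.default_rng(seed)
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def test_rigid_rotation_leaves_eigenvalues_unchanged(small_pair):
    rng = np.random.default_rng(10)
    ss = small_pair.red
    env = [(rng.uniform(0.4, 2.6, 3), q) for q in rng.uniform(-0.8, 0.8, 9)]
    frame = make_frame(ss.coords + 1.5, env, box_edge=1e6)
    e0 = perturbed_state(frame, ss, PmmConfig(use_pbc=False)).eigenvalues
    R = _rotation(99)
    ss_rot = ElectronicStateSet(
        species_label=ss.species_label, total_charge=ss.total_charge,
        geometry=[(l, m, R @ xyz) for l, m, xyz in ss.geometry],
        states=[
            type(st)(st.index, st.energy, st.atomic_charges,
                     R @ st.permanent_dipole)
            for st in ss.states
        ],
        transition_dipoles=np.einsum("ab,ijb->ija", R, ss.transition_dipoles),
    )
    frame_rot = make_frame(
        (frame.qc_coords @ R.T), [(R @ r, q) for r, q in env], box_edge=1e6
    )
    e1 = perturbed_state(frame_rot, ss_rot, PmmConfig(use_pbc=False)).eigenvalues
    np.testing.assert_allclose(e1, e0, atol=1e-9)


def test_weak_field_ground_energy_is_first_order_plus_quadratic(toy_stateset):
    # residual after removing the first-order (diagonal) term scales as eps^2
    field = np.array([0.9, -0.4, 0.2])
    pots = np.array([0.5, -0.3, 0.2])

    def residual(eps):
        s = _sample(toy_stateset, eps * pots, eps * field)
        e = diagonalize(build_hamiltonian(s, toy_stateset)).ground_energy
        first = toy_stateset.energies[0] + float(
            toy_stateset.state_charges[0] @ (eps * pots)
        )
        return e - first

    r1, r2 = residual(1e-3), residual(5e-4)
    assert abs(r1) < 1e-4
    assert r1 / r2 == pytest.approx(4.0, rel=0.05)


def test_singular_frames_skipped_and_counted(small_pair):
    good = make_frame(
        small_pair.red.coords + 1.5, [((0.2, 0.2, 0.2), 0.3)], index=0
    )
    clash_pos = tuple(small_pair.red.coords[0] + 1.5 + [0.01, 0, 0])
    bad = make_frame(
        small_pair.red.coords + 1.5, [(clash_pos, 0.3)], index=1
    )
    ens = FrameEnsemble(label="reduced", temperature=300.0,
                        frames=[good, bad], variable_composition=True)
    res = ground_energy_series(ens, small_pair.red, PmmConfig())
    assert res.skipped == [1] and len(res.values) == 1
    with pytest.raises(Exception):
        ground_energy_series(
            ens, small_pair.red, PmmConfig(on_singularity="error")
        )
    only_bad = FrameEnsemble(label="reduced", temperature=300.0, frames=[bad])
    with pytest.raises(EmptySeriesError):
        ground_energy_series(only_bad, small_pair.red, PmmConfig())


def test_gap_series_matches_two_ground_series(small_pair):
    rng = np.random.default_rng(11)
    frames = [
        make_frame(
            small_pair.red.coords + 1.5,
            [(rng.uniform(0.4, 2.6, 3), q) for q in rng.uniform(-0.5, 0.5, 15)],
            index=i,
        )
        for i in range(50)
    ]
    ens = FrameEnsemble(label="reduced", temperature=300.0, frames=frames,
                        variable_composition=True)
    gaps, table = gap_series(ens, small_pair, "vertical", return_table=True)
    red = ground_energy_series(ens, small_pair.red)
    ox = ground_energy_series(ens, small_pair.ox_vertical)
    np.testing.assert_allclose(gaps.values, ox.values - red.values, atol=1e-13)
    assert list(table.columns) == [
        "frame_index", "E0_red", "E0_ox", "gap_eV", "min_gap_01_eV",
        "skipped_flag",
    ]
    assert not table.skipped_flag.any()
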