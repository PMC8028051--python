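"""Redox thermodynamics: estimators, corrections, errors, truncation scan."""

import numpy as np
import pytest

from pmmredox import (EnsembleAverages, FrameEnsemble, GapSeries, PmmConfig,
                      SolventSpec, ValidationError, block_error, gap_series,
                      gas_shift_correction, generate_solvent_frames,
                      make_synthetic_pair, oxidation_free_energy,
                      redox_estimate, reduction_potential,
                      reorganization_energy, solvent_truncation_scan,
                      vertical_ionization_energy)
from pmmredox.errors import PmmRedoxError


def _series(values, label="reduced", kind="vertical"):
    return GapSeries(ensemble_label=label, kind=kind, values=np.array(values))


# ---------------------------------------------------------------------------
# VIE / mean-of-bounds / reduction potential
# ---------------------------------------------------------------------------

def test_vie_is_the_mean_of_vertical_gaps():
    assert vertical_ionization_energy(_series([8.0, 8.0, 8.0])) == 8.0
    assert vertical_ionization_energy(_series([7.5, 8.5])) == 8.0
    rng = np.random.default_rng(0)
    x = rng.normal(8.0, 0.3, size=1000)
    assert vertical_ionization_energy(_series(x)) == pytest.approx(
        sum(x) / len(x), abs=1e-12
    )


def test_vie_rejects_wrong_ensemble_or_kind():
    with pytest.raises(ValidationError):
        vertical_ionization_energy(_series([8.0], label="oxidized"))
    with pytest.raises(ValidationError):
        vertical_ionization_energy(_series([8.0], kind="adiabatic"))


def test_oxidation_free_energy_is_mean_of_bounds():
    avg = EnsembleAverages(5.0, 5.0, "adiabatic", 10, 10)
    assert oxidation_free_energy(avg) == 5.0
    avg = EnsembleAverages(6.0, 4.0, "adiabatic", 10, 10)
    assert oxidation_free_energy(avg) == 5.0
    assert reorganization_energy(avg) == 1.0


def test_oxidation_free_energy_rejects_vertical_kind():
    with pytest.raises(ValidationError, match="adiabatic"):
        oxidation_free_energy(EnsembleAverages(6.0, 4.0, "vertical", 1, 1))


def test_mixed_kinds_rejected():
    with pytest.raises(ValidationError, match="kind"):
        EnsembleAverages.from_series(
            _series([5.0], kind="adiabatic"),
            _series([5.0], label="oxidized", kind="vertical"),
        )


@pytest.mark.parametrize(
    "delta_A, n, v_she, expected",
    [
        (4.281, 1, 4.281, 0.0),
        (5.331, 1, 4.281, 1.05),
        (8.562, 2, 4.281, 0.0),
    ],
)
def test_reduction_potential_convention(delta_A, n, v_she, expected):
    assert reduction_potential(delta_A, n, v_she) == pytest.approx(
        expected, abs=1e-12
    )


def test_reduction_potential_is_affine_in_delta_A():
    rng = np.random.default_rng(1)
    for n in (1, 2, 3):
        a, b = rng.uniform(3, 9, 2)
        lhs = reduction_potential(a + b, n) - reduction_potential(a, n)
        assert lhs == pytest.approx(b / n, abs=1e-12)
    with pytest.raises(ValidationError):
        reduction_potential(5.0, 0)


def test_gas_shift_correction_examples():
    assert gas_shift_correction(7.66, 7.92, 8.24) == pytest.approx(7.98)
    assert gas_shift_correction(8.29, 8.97, 9.14) == pytest.approx(8.46)
    assert gas_shift_correction(5.0, 8.0, 8.0) == 5.0


# ---------------------------------------------------------------------------
# block averaging
# ---------------------------------------------------------------------------

def test_block_error_constant_series_is_zero():
    assert block_error(np.full(30, 2.5)) == 0.0


def test_block_error_hand_computed():
    # three blocks with means 1, 2, 3: sd = 1, sem = 1/sqrt(3)
    series = np.concatenate([np.full(4, 1.0), np.full(4, 2.0), np.full(4, 3.0)])
    assert block_error(series, 3) == pytest.approx(1 / np.sqrt(3), abs=1e-12)
    # remainder frames at the end are dropped
    assert block_error(np.append(series, 99.0), 3) == pytest.approx(
        1 / np.sqrt(3), abs=1e-12
    )


def test_block_error_too_short_rejected():
    with pytest.raises(ValidationError):
        block_error([1.0, 2.0], 3)


def test_block_error_sampling_distribution():
    # for iid Gaussian(0, sigma) of length n, the block SEM estimates
    # sigma/sqrt(n); over 200 replicates the mean squared estimate must
    # agree with sigma^2/n within the chi-squared (2 dof) spread
    sigma, n, reps = 0.7, 3000, 200
    rng = np.random.default_rng(2024)
    est2 = [block_error(rng.normal(0, sigma, n)) ** 2 for _ in range(reps)]
    ratio = np.mean(est2) / (sigma**2 / n)
    # relative SE of the mean of chi2_2/2 variables is 1/sqrt(reps) ~ 7%
    assert 0.72 < ratio < 1.28


# ---------------------------------------------------------------------------
# full estimate assembly
# ---------------------------------------------------------------------------

def test_redox_estimate_bundle():
    rng = np.random.default_rng(3)
    vert = _series(rng.normal(9.0, 0.1, 300))
    ad_red = _series(rng.normal(8.7, 0.1, 300), kind="adiabatic")
    ad_ox = _series(rng.normal(8.1, 0.1, 300), label="oxidized",
                    kind="adiabatic")
    est = redox_estimate(vert, ad_red, ad_ox, gas_calc=8.97, gas_exp=9.14)
    shift = 9.14 - 8.97
    assert est.shift_applied == pytest.approx(shift)
    assert est.vie == pytest.approx(np.mean(vert.values) + shift, abs=1e-12)
    assert est.aie == pytest.approx(np.mean(ad_red.values) + shift, abs=1e-12)
    dA = 0.5 * (np.mean(ad_red.values) + np.mean(ad_ox.values)) + shift
    assert est.delta_A == pytest.approx(dA, abs=1e-12)
    assert est.V_red == pytest.approx(dA - 4.281, abs=1e-12)
    assert est.err_V_red == est.err_delta_A
    assert est.reorganization > 0
    assert est.ionic_relaxation_assumption is True


# ---------------------------------------------------------------------------
# solvent truncation scan
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def scan_setup():
    pair = make_synthetic_pair(n_atoms=4, n_states=3, seed=13)
    spec = SolventSpec(n_groups=20, box_edge=1.8, seed=14)
    ens = generate_solvent_frames(
        spec, pair.red.coords + 0.9, n_frames=6, mode="iid"
    )
    return pair, ens


def test_truncation_reference_level_is_exactly_zero(scan_setup):
    pair, ens = scan_setup
    table = solvent_truncation_scan(ens, pair, [0])
    row = table.iloc[0]
    assert row.removed == 0 and row.retained == 20
    assert row.diff_mean_eV == 0.0 and row.diff_sd_eV == 0.0


def test_truncation_matches_brute_force_recomputation(scan_setup):
    pair, ens = scan_setup
    table = solvent_truncation_scan(ens, pair, [0, 5])
    masses = pair.red.masses
    # independent recomputation: drop the 5 farthest groups by center
    # distance, rebuild frames, run the engine end to end
    from pmmredox import Frame, minimum_image

    gaps = []
    for f in ens.frames:
        com = masses @ f.qc_coords / masses.sum()
        d = np.linalg.norm(minimum_image(f.env_coords - com, f.box_edge), axis=1)
        w = np.abs(f.env_charges)
        centers = {
            g: np.average(d[f.env_groups == g], weights=w[f.env_groups == g])
            for g in np.unique(f.env_groups)
        }
        keep = sorted(centers, key=lambda g: centers[g])[:15]
        mask = np.isin(f.env_groups, keep)
        sub = Frame(
            box_edge=f.box_edge, qc_coords=f.qc_coords,
            env_coords=f.env_coords[mask], env_charges=f.env_charges[mask],
            env_groups=f.env_groups[mask], index=f.index,
        )
        ens_sub = FrameEnsemble(label="reduced", temperature=300.0,
                                frames=[sub])
        gaps.append(gap_series(ens_sub, pair, "vertical").values[0])
    assert table.iloc[1].vie_eV == pytest.approx(np.mean(gaps), abs=1e-10)
    assert table.iloc[1].removed == 5


def test_truncation_by_radius_matches_rank_removal(scan_setup):
    # a radius chosen between the k-th and (k+1)-th farthest group centers
    # must remove exactly the same groups as the rank-based count
    pair, ens = scan_setup
    from pmmredox.redox import _group_center_distances

    # use a single frame so one radius separates the same set everywhere
    single = FrameEnsemble(label="reduced", temperature=300.0,
                           frames=[ens.frames[0]])
    _, centers = _group_center_distances(ens.frames[0], pair.red.masses)
    ranked = np.sort(centers)
    radius = float((ranked[-4] + ranked[-3]) / 2)  # cuts off the 3 farthest
    t = solvent_truncation_scan(single, pair, [3, radius])
    by_count = t[t.level == 3].iloc[0]
    by_radius = t[t.level == radius].iloc[0]
    assert by_radius.removed == 3
    assert by_radius.vie_eV == pytest.approx(by_count.vie_eV, abs=1e-12)


def test_truncation_overflow_rejected(scan_setup):
    pair, ens = scan_setup
    with pytest.raises(PmmRedoxError, match="remove"):
        solvent_truncation_scan(ens, pair, [25])
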