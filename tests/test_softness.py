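"""Superposition, RMSF and radial softness prevalence."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

import evbcold as ec
from evbcold.softness import _kabsch


def _rigid_copies(base_traj, seed=0, translate=5.0):
    """Frames that are rigid-body transforms of frame 0."""
    rng = np.random.default_rng(seed)
    frames = [base_traj.coords[0]]
    for _ in range(base_traj.n_frames - 1):
        rot = Rotation.random(random_state=rng).as_matrix()
        shift = rng.uniform(-translate, translate, 3)
        frames.append(base_traj.coords[0] @ rot.T + shift)
    return ec.Trajectory(coords=np.array(frames), atoms=base_traj.atoms)


def test_rigid_motion_removed_by_superposition(aligned_trajectory):
    rigid = _rigid_copies(aligned_trajectory)
    fitted = ec.superpose(rigid)
    values = ec.rmsf(fitted)
    assert values.max() < 1e-8


def test_superposition_idempotent(aligned_trajectory):
    once = ec.superpose(aligned_trajectory)
    twice = ec.superpose(once)
    np.testing.assert_allclose(twice.coords, once.coords, atol=1e-9)


def test_random_rotations_round_trip(aligned_trajectory):
    """Rotating all frames but the first, then superposing, recovers the
    original coordinates."""
    rng = np.random.default_rng(3)
    perturbed = aligned_trajectory.coords.copy()
    for f in range(1, perturbed.shape[0]):
        rot = Rotation.random(random_state=rng).as_matrix()
        perturbed[f] = perturbed[f] @ rot.T + rng.uniform(-3, 3, 3)
    traj = ec.Trajectory(coords=perturbed, atoms=aligned_trajectory.atoms)
    recovered = ec.superpose(traj)
    np.testing.assert_allclose(recovered.coords, aligned_trajectory.coords,
                               atol=1e-6)


def test_rmsf_invariant_under_global_rigid_transform(aligned_trajectory):
    rot = Rotation.from_euler("xyz", [0.3, -1.0, 2.2]).as_matrix()
    moved = ec.Trajectory(coords=aligned_trajectory.coords @ rot.T + 7.0,
                          atoms=aligned_trajectory.atoms)
    a = ec.rmsf(ec.superpose(aligned_trajectory))
    b = ec.rmsf(ec.superpose(moved))
    np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), atol=1e-9)


def test_kabsch_agrees_with_biotite_superimpose():
    """Independent oracle: biotite's superimpose on the same point sets."""
    import biotite.structure as bst
    rng = np.random.default_rng(9)
    ref = rng.uniform(-5, 5, (30, 3))
    rot = Rotation.random(random_state=rng).as_matrix()
    mobile = ref @ rot.T + np.array([1.0, -2.0, 0.5]) \
        + rng.normal(0, 0.1, (30, 3))
    r, mc, rc = _kabsch(mobile, ref)
    ours = (mobile - mc) @ r + rc

    fixed_arr = bst.AtomArray(30)
    fixed_arr.coord = ref
    mob_arr = bst.AtomArray(30)
    mob_arr.coord = mobile
    fitted, _ = bst.superimpose(fixed_arr, mob_arr)
    np.testing.assert_allclose(ours, fitted.coord, atol=1e-6)


def test_static_trajectory_has_zero_rmsf():
    traj = ec.synth_trajectory(6, 10, radial_sigma=lambda r: 0.0 * r, seed=0)
    assert ec.rmsf(traj).max() <= 1e-12  # identical frames, float-mean eps


def test_two_frame_displacement_rmsf_by_hand():
    base = ec.synth_trajectory(4, 2, radial_sigma=lambda r: 0.0 * r, seed=0)
    coords = base.coords.copy()
    coords[0, :, 0] -= 0.4   # +-d about the mean along x
    coords[1, :, 0] += 0.4
    traj = ec.Trajectory(coords=coords, atoms=base.atoms)
    values = ec.rmsf(traj)
    np.testing.assert_allclose(values.to_numpy(), 0.4, atol=1e-12)


def test_single_frame_rmsf_rejected():
    traj = ec.synth_trajectory(4, 2, seed=0)
    one = ec.Trajectory(coords=traj.coords[:1], atoms=traj.atoms)
    with pytest.raises(ec.SoftnessError):
        ec.rmsf(one)


def test_isotropic_gaussian_rmsf_matches_sigma_sqrt3():
    """The generated frames are already aligned, so the RMSF statistic
    can be checked directly against its sigma*sqrt(3) expectation (with
    few residues, superposition itself would absorb ~6/(3*n_res) of the
    variance; the superposed variant is exercised elsewhere)."""
    sigma = 0.5
    traj = ec.synth_trajectory(20, 4000, radial_sigma=lambda r: sigma + 0 * r,
                               seed=2)
    values = ec.rmsf(traj)
    assert values.mean() == pytest.approx(sigma * np.sqrt(3), rel=0.03)


def test_degenerate_collinear_selection_rejected():
    coords = np.zeros((3, 4, 3))
    coords[:, :, 0] = np.arange(4)  # all atoms on the x axis
    atoms = pd.DataFrame({"res_id": [1, 2, 3, 4], "res_name": "ALA",
                          "atom_name": "CA", "chain": "A", "backbone": True})
    with pytest.raises(ec.SoftnessError, match="degenerate"):
        ec.superpose(ec.Trajectory(coords=coords, atoms=atoms))


# -------------------------------------------------------------- selection

def test_selection_expressions(aligned_trajectory):
    traj = aligned_trajectory
    ca = ec.select(traj, "name CA")
    assert ca.sum() == 12
    sub = ec.select(traj, "resi 2-4 and name CA N")
    assert sub.sum() == 6
    assert ec.select(traj, "chain A").all()
    with pytest.raises(ec.SoftnessError):
        ec.select(traj, "altloc A")


def test_active_site_center_examples(aligned_trajectory):
    traj = aligned_trajectory
    single = ec.active_site_center(traj, "resi 3 and name CA")
    mean = traj.mean_structure()[ec.select(traj, "resi 3 and name CA")]
    np.testing.assert_allclose(single, mean[0])
    # two atoms at +-x about their midpoint
    coords = np.zeros((2, 2, 3))
    coords[:, 0, 0], coords[:, 1, 0] = -1.5, 1.5
    atoms = pd.DataFrame({"res_id": [1, 2], "res_name": "GLY",
                          "atom_name": "CA", "chain": "A", "backbone": True})
    pair = ec.Trajectory(coords=coords, atoms=atoms)
    np.testing.assert_allclose(ec.active_site_center(pair, "name CA"),
                               [0.0, 0.0, 0.0], atol=1e-12)
    with pytest.raises(ec.SoftnessError):
        ec.active_site_center(traj, "resi 99")


# ------------------------------------------------------------- prevalence

def test_handcrafted_six_residue_shell_counts():
    """3 residues in the first shell (one mobile), 3 in the second (all
    mobile): 33.33% and 100%."""
    values = pd.Series([1.5, 0.2, 0.3, 1.2, 1.3, 1.4], index=range(1, 7))
    dist = pd.Series([1.0, 2.0, 3.0, 6.0, 7.0, 8.0], index=range(1, 7))
    prof = ec.shell_prevalence(values, dist, threshold=1.1, shell_width=5.0)
    assert prof.prevalence[0] == pytest.approx(100.0 / 3)
    assert prof.prevalence[1] == pytest.approx(100.0)


def test_threshold_extremes():
    values = pd.Series([0.5, 0.9, 1.0], index=[1, 2, 3])
    dist = pd.Series([1.0, 6.0, 11.0], index=[1, 2, 3])
    low = ec.shell_prevalence(values, dist, threshold=0.0)
    assert np.nanmin(low.prevalence) == 100.0
    high = ec.shell_prevalence(values, dist, threshold=2.0)
    assert np.nanmax(high.prevalence) == 0.0


@settings(max_examples=25)
@given(th=st.lists(st.floats(0, 2), min_size=2, max_size=5))
def test_prevalence_monotone_in_threshold(th):
    rng = np.random.default_rng(1)
    values = pd.Series(rng.uniform(0, 2, 40), index=range(1, 41))
    dist = pd.Series(rng.uniform(0, 20, 40), index=range(1, 41))
    prev = [ec.shell_prevalence(values, dist, threshold=t).prevalence
            for t in sorted(th)]
    for a, b in zip(prev, prev[1:]):
        ok = ~np.isnan(a)
        assert np.all(b[ok] <= a[ok] + 1e-12)


def test_stiff_core_soft_surface_pattern():
    """Radially increasing mobility yields non-decreasing prevalence with
    shell distance and a mobile outer rim."""
    traj = ec.synth_trajectory(60, 500, radial_sigma="salmon_like", seed=6)
    fitted = ec.superpose(traj)
    values = ec.rmsf(fitted)
    center = ec.active_site_center(fitted, "resi 1 and name CA")
    prof = ec.shell_prevalence(values, ec.residue_distances(fitted, center))
    occ = prof.prevalence[prof.occupied]
    assert occ[0] == 0.0 and occ[-1] == 100.0
    assert np.all(np.diff(occ) >= -1e-9)


def test_empty_shells_flagged_not_valued():
    values = pd.Series([0.5, 1.5], index=[1, 2])
    dist = pd.Series([1.0, 16.0], index=[1, 2])
    prof = ec.shell_prevalence(values, dist, shell_width=5.0)
    assert not prof.occupied[1] and np.isnan(prof.prevalence[1])
    assert prof.occupied[0] and prof.occupied[3]


def test_invalid_shell_width_rejected():
    values = pd.Series([0.5], index=[1])
    dist = pd.Series([1.0], index=[1])
    with pytest.raises(ec.SoftnessError):
        ec.shell_prevalence(values, dist, shell_width=0.0)
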