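"""RMSF/RMSD computations, replica aggregation and variant comparison."""

import numpy as np
import pytest
from scipy import stats
from scipy.spatial.transform import Rotation

from asase.flexibility import (
    AnalysisError,
    aggregate_replicas,
    compare_flexibility,
    compute_rmsd_trace,
    compute_rmsf,
)
from asase.structure_io import Trajectory
from asase.synthetic import TrajectorySpec, generate_trajectory


def make_traj(coords, replica_id="r1"):
    coords = np.asarray(coords, dtype=float)
    n_atoms = coords.shape[1]
    return Trajectory(
        replica_id=replica_id,
        atom_names=["CA"] * n_atoms,
        residue_numbers=np.arange(1, n_atoms + 1),
        residue_names=["ALA"] * n_atoms,
        frame_times=50.0 * np.arange(coords.shape[0]),
        coords=coords,
    )


def base_structure(n_atoms=12, seed=0):
    return np.random.default_rng(seed).uniform(-10, 10, (n_atoms, 3))


# ---------------------------------------------------------------------------
# RMSF
# ---------------------------------------------------------------------------

def test_static_trajectory_has_zero_rmsf():
    ref = base_structure()
    traj = make_traj(np.repeat(ref[None], 5, axis=0))
    _, rmsf = compute_rmsf(traj)
    assert np.allclose(rmsf, 0.0, atol=1e-12)


def test_rigid_rotations_superpose_away():
    """Frames that are rigid-body copies of one structure have ~zero RMSF
    after superposition."""
    ref = base_structure()
    rng = np.random.default_rng(1)
    frames = [ref]
    for _ in range(9):
        rot = Rotation.from_euler("xyz", rng.uniform(-np.pi, np.pi, 3))
        frames.append(rot.apply(ref) + rng.uniform(-20, 20, 3))
    _, rmsf = compute_rmsf(make_traj(np.stack(frames)))
    assert np.all(rmsf < 1e-6)


def test_rmsf_needs_two_frames():
    traj = make_traj(base_structure()[None])
    with pytest.raises(AnalysisError, match="2 frames"):
        compute_rmsf(traj)


def test_rmsf_selection_must_match():
    traj = make_traj(np.repeat(base_structure()[None], 3, axis=0))
    with pytest.raises(AnalysisError, match="selection"):
        compute_rmsf(traj, selection="CB")


def test_rmsf_invariant_to_joint_rigid_motion():
    tset = generate_trajectory(TrajectorySpec(n_residues=10, n_frames=50, seed=4))
    traj = tset.trajectories[0]
    _, before = compute_rmsf(traj)
    rot = Rotation.from_euler("zyx", [0.3, -1.1, 2.0])
    moved = make_traj(rot.apply(traj.coords.reshape(-1, 3)).reshape(traj.coords.shape) + 7.5)
    _, after = compute_rmsf(moved)
    assert np.allclose(before, after, atol=1e-9)


# ---------------------------------------------------------------------------
# replica aggregation
# ---------------------------------------------------------------------------

def test_identical_replicas_have_zero_ci():
    ids = np.arange(1, 6)
    vals = np.linspace(0.2, 1.0, 5)
    prof = aggregate_replicas([(ids, vals)] * 5)
    assert np.allclose(prof.mean_rmsf, vals)
    assert np.allclose(prof.ci_halfwidth, 0.0)


def test_t_interval_closed_form_oracle():
    """Replica values {1..5} A: mean 3, halfwidth t(.975, 4) * sd / sqrt(5)."""
    ids = np.array([1])
    prof = aggregate_replicas([(ids, np.array([float(v)])) for v in range(1, 6)])
    assert prof.mean_rmsf[0] == pytest.approx(3.0)
    sd = np.std([1, 2, 3, 4, 5], ddof=1)
    expected = stats.t.ppf(0.975, df=4) * sd / np.sqrt(5)
    assert prof.ci_halfwidth[0] == pytest.approx(expected, rel=1e-12)
    assert prof.ci_halfwidth[0] == pytest.approx(1.96324, abs=1e-5)


def test_aggregate_matches_vectorized_t_interval_on_random_instances():
    rng = np.random.default_rng(5)
    ids = np.arange(1, 21)
    for _ in range(50):
        n_rep = rng.integers(2, 8)
        mat = rng.uniform(0.1, 2.0, (n_rep, 20))
        prof = aggregate_replicas([(ids, row) for row in mat])
        assert np.allclose(prof.mean_rmsf, mat.mean(axis=0))
        hw = stats.t.ppf(0.975, n_rep - 1) * mat.std(axis=0, ddof=1) / np.sqrt(n_rep)
        assert np.allclose(prof.ci_halfwidth, hw)


def test_aggregate_requires_matching_rosters():
    with pytest.raises(AnalysisError, match="roster"):
        aggregate_replicas([(np.array([1, 2]), np.ones(2)), (np.array([1, 3]), np.ones(2))])


def test_replica_mean_rmsf_tracks_sigma_sqrt3():
    sigma = 0.4
    tset = generate_trajectory(
        TrajectorySpec(n_residues=15, n_frames=800, per_residue_sigma=sigma, n_replicas=5, seed=6)
    )
    prof = aggregate_replicas([compute_rmsf(t, superpose_frames=False) for t in tset.trajectories])
    target = sigma * np.sqrt(3)
    covered = np.abs(prof.mean_rmsf - target) <= np.maximum(prof.ci_halfwidth, 1e-6)
    assert covered.mean() >= 0.8  # 95% CI, 15 residues: allow a few misses


# ---------------------------------------------------------------------------
# variant comparison
# ---------------------------------------------------------------------------

def test_identical_variants_show_no_significance():
    ids = np.arange(1, 11)
    rng = np.random.default_rng(7)
    rows = [(ids, rng.uniform(0.3, 0.8, 10)) for _ in range(5)]
    prof = aggregate_replicas(rows)
    comp = compare_flexibility(prof, prof, alpha=0.05)
    assert np.allclose(comp.mean_diff, 0.0)
    assert not comp.significant.any()
    assert np.all(comp.p_values == 1.0)


def test_halved_sigma_at_one_residue_is_flagged_negative():
    n_res, sigma = 12, 0.5
    sig_mut = np.full(n_res, sigma)
    sig_mut[4] = sigma / 2  # the stiffened residue
    wt = generate_trajectory(
        TrajectorySpec(n_residues=n_res, n_frames=400, per_residue_sigma=sigma,
                       n_replicas=5, seed=8)
    )
    mut = generate_trajectory(
        TrajectorySpec(n_residues=n_res, n_frames=400, per_residue_sigma=tuple(sig_mut),
                       n_replicas=5, seed=9)
    )
    prof_wt = aggregate_replicas([compute_rmsf(t, superpose_frames=False) for t in wt.trajectories])
    prof_mut = aggregate_replicas([compute_rmsf(t, superpose_frames=False) for t in mut.trajectories])
    comp = compare_flexibility(prof_wt, prof_mut, alpha=0.05)
    assert comp.significant[4]
    assert comp.mean_diff[4] < 0  # mutant is less flexible there


def test_alpha_zero_gives_empty_mask():
    ids = np.arange(1, 6)
    rng = np.random.default_rng(10)
    prof_a = aggregate_replicas([(ids, rng.uniform(0.2, 1.0, 5)) for _ in range(4)])
    prof_b = aggregate_replicas([(ids, rng.uniform(0.2, 1.0, 5)) for _ in range(4)])
    comp = compare_flexibility(prof_a, prof_b, alpha=0.0)
    assert not comp.significant.any()


def test_welch_matches_scipy_per_residue():
    rng = np.random.default_rng(11)
    ids = np.arange(1, 9)
    a = rng.uniform(0.2, 1.0, (5, 8))
    b = rng.uniform(0.2, 1.0, (4, 8))
    prof_a = aggregate_replicas([(ids, row) for row in a])
    prof_b = aggregate_replicas([(ids, row) for row in b])
    comp = compare_flexibility(prof_a, prof_b)
    for i in range(8):
        _, p = stats.ttest_ind(b[:, i], a[:, i], equal_var=False)
        assert comp.p_values[i] == pytest.approx(p, rel=1e-12)


def test_bh_correction_never_increases_significance():
    rng = np.random.default_rng(12)
    ids = np.arange(1, 31)
    prof_a = aggregate_replicas([(ids, rng.uniform(0.2, 1.0, 30)) for _ in range(5)])
    prof_b = aggregate_replicas([(ids, rng.uniform(0.2, 1.0, 30)) for _ in range(5)])
    raw = compare_flexibility(prof_a, prof_b)
    adj = compare_flexibility(prof_a, prof_b, bh_correct=True)
    assert adj.significant.sum() <= raw.significant.sum()
    assert np.all(adj.p_values >= raw.p_values - 1e-12)


# ---------------------------------------------------------------------------
# RMSD traces
# ---------------------------------------------------------------------------

def test_rmsd_trace_zero_at_reference_frame():
    tset = generate_trajectory(TrajectorySpec(n_residues=8, n_frames=20, seed=13))
    trace = compute_rmsd_trace(tset.trajectories[0], reference=0)
    assert trace[0] == pytest.approx(0.0, abs=1e-9)
    assert trace.shape == (20,)


def test_pure_translation_gives_zero_rmsd_after_superposition():
    ref = base_structure()
    frames = np.stack([ref, ref + np.array([5.0, -3.0, 2.0])])
    trace = compute_rmsd_trace(make_traj(frames), reference=0)
    assert np.allclose(trace, 0.0, atol=1e-9)


def test_known_uniform_displacement_without_superposition():
    ref = base_structure()
    d = 1.7
    shifted = ref + np.array([d, 0.0, 0.0])
    trace = compute_rmsd_trace(make_traj(np.stack([ref, shifted])),
                               reference=0, superpose_frames=False)
    assert trace[1] == pytest.approx(d, rel=1e-12)
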