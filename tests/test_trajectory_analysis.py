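import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from glycodelta.glycan_annotation import detect_sites
from glycodelta.synthetic_data import (
    SiteSpec,
    SyntheticSpec,
    TrajectorySpec,
    generate_toy_protein,
    generate_trajectory,
    write_trajectory_pdb,
)
from glycodelta.trajectory_analysis import (
    RMSFProfile,
    Trajectory,
    aggregate_replicates,
    load_trajectory,
    max_delta_residue,
    rmsd_series,
    rmsf_profile,
    window_average_structure,
)


def _toy_base(n=30, seed=0):
    model = generate_toy_protein(SyntheticSpec(n_residues=n, seed=seed))
    chain = model.chains[0]
    ids = [r.id for r in chain.residues]
    base = np.array([r.atom("CA").xyz for r in chain.residues])
    return model, ids, base


def _const_traj(base, ids, n_frames=8):
    frames = np.repeat(base[None], n_frames, axis=0)
    return Trajectory(residue_ids=ids, frames=frames,
                      times=0.24 * np.arange(1, n_frames + 1))


class TestLoading:
    def test_multimodel_frame_count(self, tmp_path):
        model, ids, base = _toy_base(12)
        traj = _const_traj(base, ids, n_frames=3)
        path = write_trajectory_pdb(model, traj, tmp_path / "t.pdb")
        loaded = load_trajectory(path)
        assert loaded.n_frames == 3
        assert loaded.n_atoms == 12

    def test_residue_range_restriction(self, tmp_path):
        model, ids, base = _toy_base(20)
        traj = _const_traj(base, ids, n_frames=2)
        path = write_trajectory_pdb(model, traj, tmp_path / "t.pdb")
        loaded = load_trajectory(path, residue_range=(7, 18))
        assert loaded.n_atoms == 12  # inclusive range

    def test_empty_selection_rejected(self, tmp_path):
        model, ids, base = _toy_base(10)
        traj = _const_traj(base, ids, n_frames=2)
        path = write_trajectory_pdb(model, traj, tmp_path / "t.pdb")
        with pytest.raises(ValueError):
            load_trajectory(path, residue_range=(500, 600))

    def test_frame_width_mismatch_rejected(self):
        _, ids, base = _toy_base(10)
        with pytest.raises(ValueError):
            Trajectory(residue_ids=ids, frames=np.zeros((2, 9, 3)),
                       times=np.array([1.0, 2.0]))

    def test_times_strictly_increasing(self):
        _, ids, base = _toy_base(10)
        with pytest.raises(ValueError):
            Trajectory(residue_ids=ids,
                       frames=np.repeat(base[None], 2, axis=0),
                       times=np.array([2.0, 1.0]))


class TestRMSDSeries:
    def test_identical_frames_zero(self):
        _, ids, base = _toy_base(15)
        traj = _const_traj(base, ids)
        series = rmsd_series(traj, base)
        assert all(abs(r) < 1e-9 for _, r in series)

    def test_rigid_motion_removed(self):
        _, ids, base = _toy_base(15)
        frames = []
        for f in range(4):
            rot = Rotation.from_euler("xyz", [10 * f, 5 * f, -3 * f],
                                      degrees=True).as_matrix()
            frames.append(base @ rot.T + np.array([f, -f, 2.0 * f]))
        traj = Trajectory(residue_ids=ids, frames=np.array(frames),
                          times=np.arange(1.0, 5.0))
        assert all(r < 1e-6 for _, r in rmsd_series(traj, base))

    def test_single_displacement_matches_oracle(self):
        from .oracles import grid_superpose_rmsd
        _, ids, base = _toy_base(15)
        frame = base.copy()
        frame[7] += np.array([0.0, 0.0, 2.5])
        traj = Trajectory(residue_ids=ids,
                          frames=np.stack([base, frame]),
                          times=np.array([1.0, 2.0]))
        (_, r0), (_, r1) = rmsd_series(traj, base)
        assert r0 < 1e-9
        assert r1 <= 2.5 / np.sqrt(15) + 1e-9
        assert r1 == pytest.approx(grid_superpose_rmsd(base, frame, polish=True),
                                   abs=1e-3)

    def test_selection_mismatch_rejected(self):
        _, ids, base = _toy_base(15)
        traj = _const_traj(base, ids)
        with pytest.raises(ValueError):
            rmsd_series(traj, base[:-1])


class TestWindowAverage:
    def test_constant_trajectory(self):
        _, ids, base = _toy_base(10)
        traj = _const_traj(base, ids)
        np.testing.assert_allclose(window_average_structure(traj), base,
                                   atol=1e-9)

    def test_two_frame_symmetric_displacement(self):
        # displacement along a pair-stretch mode (zero net translation and
        # torque), so frame fitting stays near identity and the window
        # average lands on the mean structure
        _, ids, base = _toy_base(10)
        u = base[7] - base[2]
        u /= np.linalg.norm(u)
        delta = np.zeros_like(base)
        delta[7] = 0.4 * u
        delta[2] = -0.4 * u
        frames = np.stack([base + delta, base - delta])
        traj = Trajectory(residue_ids=ids, frames=frames,
                          times=np.array([1.0, 2.0]))
        avg = window_average_structure(traj, window_fraction=1.0)
        np.testing.assert_allclose(avg, base, atol=1e-2)

    def test_window_fraction_one_uses_all_frames(self):
        _, ids, base = _toy_base(10)
        traj = _const_traj(base, ids, n_frames=4)
        avg = window_average_structure(traj, window_fraction=1.0)
        np.testing.assert_allclose(avg, base, atol=1e-9)

    def test_tiny_window_rejected(self):
        _, ids, base = _toy_base(10)
        traj = _const_traj(base, ids, n_frames=4)
        with pytest.raises(ValueError):
            window_average_structure(traj, window_fraction=0.1)


class TestRMSF:
    def test_constant_trajectory_zero(self):
        _, ids, base = _toy_base(10)
        profile = rmsf_profile(_const_traj(base, ids))
        assert np.all(profile.values < 1e-9)

    def test_gaussian_noise_recovery(self):
        _, ids, base = _toy_base(30)
        traj = generate_trajectory(TrajectorySpec(
            base=base, residue_ids=ids, sigma=0.5, n_frames=500, seed=8))[0]
        profile = rmsf_profile(traj, window_fraction=1.0)
        assert profile.mean == pytest.approx(0.5 * np.sqrt(3), rel=0.05)

    def test_invariant_under_rigid_transform_of_frames(self):
        _, ids, base = _toy_base(20)
        traj = generate_trajectory(TrajectorySpec(
            base=base, residue_ids=ids, sigma=0.3, n_frames=40, seed=9))[0]
        prof0 = rmsf_profile(traj)
        rot = Rotation.from_euler("y", 55, degrees=True).as_matrix()
        moved = Trajectory(residue_ids=ids,
                           frames=traj.frames @ rot.T + np.array([3.0, 1.0, -2.0]),
                           times=traj.times)
        prof1 = rmsf_profile(moved)
        np.testing.assert_allclose(prof1.values, prof0.values, atol=1e-6)

    def test_variance_conservation(self):
        # mean_j RMSF_j^2 equals the mean squared deviation of the fitted
        # window frames from the reference
        from glycodelta.structure_compare import kabsch_superpose
        _, ids, base = _toy_base(20)
        traj = generate_trajectory(TrajectorySpec(
            base=base, residue_ids=ids, sigma=0.4, n_frames=24, seed=10))[0]
        ref = window_average_structure(traj, window_fraction=0.25)
        profile = rmsf_profile(traj, reference=ref, window_fraction=0.25)
        window = traj.frames[-6:]
        total = 0.0
        for frame in window:
            fitted = kabsch_superpose(ref, frame).transform(frame)
            total += np.mean(np.sum((fitted - ref) ** 2, axis=1))
        total /= len(window)
        assert np.mean(profile.values ** 2) == pytest.approx(total, rel=1e-9)


class TestAggregation:
    def test_equal_replicates(self):
        s = aggregate_replicates([2.0, 2.0, 2.0])
        assert s.mean == 2.0 and s.se == 0.0

    def test_closed_form_se(self):
        s = aggregate_replicates([1.0, 2.0, 3.0])
        assert s.mean == 2.0
        assert s.se == pytest.approx(1.0 / np.sqrt(3))

    def test_single_replicate_flagged(self):
        s = aggregate_replicates([5.0])
        assert s.mean == 5.0 and s.se == 0.0 and s.single_replicate

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_replicates([])


class TestMaxDelta:
    def _profiles_and_model(self):
        spec = SyntheticSpec(n_residues=30, sites=[SiteSpec(residue=5, n_sugars=1)],
                             seed=4)
        model = generate_toy_protein(spec)
        from glycodelta.synthetic_data import attach_mock_glycan
        from glycodelta.glycan_annotation import classify_saccharides
        attach_mock_glycan(model, 5, 1)
        classify_saccharides(model)
        site = detect_sites(model)[0]
        ids = [r.id for r in model.chains[0].amino_acid_residues()]
        return model, site, ids

    def test_identical_profiles_tie_rule(self):
        model, site, ids = self._profiles_and_model()
        prof = RMSFProfile(residue_ids=ids, values=np.ones(len(ids)))
        rid, delta, _ = max_delta_residue(prof, prof, model, site)
        assert delta == 0.0
        assert rid == ids[0]

    def test_planted_maximum_found(self):
        model, site, ids = self._profiles_and_model()
        gp = RMSFProfile(residue_ids=ids, values=np.full(len(ids), 0.5))
        p_vals = np.full(len(ids), 0.6)
        p_vals[22] = 1.4  # planted allosteric hotspot at residue 23
        p = RMSFProfile(residue_ids=ids, values=p_vals)
        rid, delta, distance = max_delta_residue(gp, p, model, site)
        assert rid == (23, "")
        assert delta == pytest.approx(0.9)
        ca_site = model.chains[0].residue(5).atom("CA").xyz
        ca_hot = model.chains[0].residue(23).atom("CA").xyz
        assert distance == pytest.approx(float(np.linalg.norm(ca_site - ca_hot)))

    def test_disjoint_profiles_rejected(self):
        model, site, ids = self._profiles_and_model()
        a = RMSFProfile(residue_ids=ids[:5], values=np.ones(5))
        b = RMSFProfile(residue_ids=[(99, ""), (100, "")], values=np.ones(2))
        with pytest.raises(ValueError):
            max_delta_residue(a, b, model, site)
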