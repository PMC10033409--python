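"""Tests for dihedral featurization, tICA, FES, clustering and loop distances."""

import numpy as np
import numpy.ma as ma
import pytest
from scipy.spatial.transform import Rotation

from icl3kit.ensemble_analysis import (
    CoordinateFrame,
    DihedralTrajectory,
    cluster_states,
    com_distance,
    featurize_dihedrals,
    fit_tica,
    free_energy_surface,
    parse_segment_spec,
    segment_distance_profile,
    subcluster_basin,
)
from icl3kit.synthetic_data import gen_metastable_trajectory


def traj_from(angles, dt=0.02):
    return DihedralTrajectory(angles=np.asarray(angles), frame_interval_ns=dt)


class TestFeaturizeDihedrals:
    def test_periodic_angles_embed_identically(self):
        a = np.deg2rad([[-179.0, 10.0], [181.0, 10.0]])
        feats = featurize_dihedrals(traj_from(a))
        assert feats[0] == pytest.approx(feats[1], abs=1e-12)

    def test_constant_channel_gives_zero_variance_columns(self):
        feats = featurize_dihedrals(traj_from(np.full((50, 1), 0.7)))
        assert np.allclose(feats, 0.0)

    def test_shape_and_centering(self):
        rng = np.random.default_rng(0)
        feats = featurize_dihedrals(traj_from(rng.uniform(-np.pi, np.pi, (1000, 4))))
        assert feats.shape == (1000, 8)
        assert feats.mean(axis=0) == pytest.approx(np.zeros(8), abs=1e-12)

    def test_nonfinite_angles_raise(self):
        with pytest.raises(ValueError):
            traj_from([[np.nan, 0.0], [0.0, 0.0]])


class TestFitTica:
    def test_white_noise_has_no_slow_process(self):
        rng = np.random.default_rng(1)
        feats = rng.normal(size=(10_000, 6))
        proj = fit_tica(feats, lag=1)
        assert np.all(np.abs(proj.eigenvalues) < 0.1)

    def test_planted_two_state_chain_matches_analytic_eigenvalue(self):
        # 2-state chain, stay probabilities 0.99/0.98: second eigenvalue of the
        # transition matrix is 1 - p12 - p21 = 0.97, the lag-1 autocorrelation
        traj, labels, _, _ = gen_metastable_trajectory(
            k_states=2, stay_probabilities=(0.99, 0.98), frames=10_000, seed=5
        )
        proj = fit_tica(featurize_dihedrals(traj), lag=1)
        assert abs(proj.eigenvalues[0] - 0.97) < 0.05
        model = cluster_states(proj.projection[:, :1], 2, seed=0)
        acc = max((model.labels == labels).mean(), (model.labels != labels).mean())
        assert acc > 0.95

    def test_duplicated_feature_columns_leave_projection_unchanged(self):
        traj, _, _, _ = gen_metastable_trajectory(
            k_states=2, stay_probabilities=(0.98, 0.98), frames=3_000, seed=8
        )
        feats = featurize_dihedrals(traj)
        base = fit_tica(feats, lag=1).projection[:, 0]
        dup = fit_tica(np.hstack([feats, feats]), lag=1).projection[:, 0]
        corr = np.corrcoef(base, dup)[0, 1]
        assert abs(corr) > 0.999  # identical up to sign/scale

    def test_eigenvalues_sorted_descending(self):
        rng = np.random.default_rng(2)
        proj = fit_tica(rng.normal(size=(2000, 5)), lag=2)
        assert np.all(np.diff(proj.eigenvalues) <= 1e-12)

    def test_bad_lag_raises(self):
        feats = np.zeros((10, 2))
        with pytest.raises(ValueError):
            fit_tica(feats, lag=10)
        with pytest.raises(ValueError):
            fit_tica(feats, lag=0)


class TestFreeEnergySurface:
    def test_single_occupied_bin_sits_at_zero(self):
        proj = np.zeros((100, 2))
        fes = free_energy_surface(proj, bins=5, range_=((-1, 1), (-1, 1)))
        occupied = fes.free_energy.compressed()
        assert occupied.size == 1 and occupied[0] == 0.0

    def test_mixture_weights_give_closed_form_basin_gap(self):
        # two well-separated Gaussians, weights 0.7/0.3:
        # dF = -ln(0.3/0.7) ~ 0.847 kT between basin minima
        rng = np.random.default_rng(0)
        n = 10**5
        minor = rng.random(n) < 0.3
        x = np.where(minor, rng.normal(5, 0.5, n), rng.normal(0, 0.5, n))
        y = rng.normal(0, 0.5, n)
        fes = free_energy_surface(np.c_[x, y], bins=60)
        centers = 0.5 * (fes.x_edges[:-1] + fes.x_edges[1:])
        f_major = fes.free_energy[centers < 2.5].min()
        f_minor = fes.free_energy[centers >= 2.5].min()
        assert f_minor - f_major == pytest.approx(-np.log(0.3 / 0.7), abs=0.1)

    def test_sample_count_scaling_leaves_f_unchanged(self):
        rng = np.random.default_rng(3)
        proj = rng.normal(size=(4000, 2))
        rng_ = ((-4, 4), (-4, 4))
        fes1 = free_energy_surface(proj, bins=10, range_=rng_)
        fes3 = free_energy_surface(np.tile(proj, (3, 1)), bins=10, range_=rng_)
        assert ma.allclose(fes1.free_energy, fes3.free_energy)

    def test_occupied_minimum_always_zero(self):
        rng = np.random.default_rng(4)
        fes = free_energy_surface(rng.normal(size=(500, 2)), bins=12)
        assert fes.free_energy.min() == 0.0

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            free_energy_surface(np.empty((0, 2)))


class TestClusterStates:
    def test_k1_center_is_data_mean(self):
        rng = np.random.default_rng(5)
        proj = rng.normal(size=(500, 2))
        model = cluster_states(proj, k=1, seed=0)
        assert model.centers[0] == pytest.approx(proj.mean(axis=0), abs=1e-6)

    def test_two_separated_blobs_recovered(self):
        rng = np.random.default_rng(6)
        a = rng.normal(0, 0.3, size=(400, 2))
        b = rng.normal(8, 0.3, size=(400, 2))
        proj = np.vstack([a, b])
        truth = np.repeat([0, 1], 400)
        model = cluster_states(proj, k=2, seed=0)
        acc = max((model.labels == truth).mean(), (model.labels != truth).mean())
        assert acc >= 0.99

    def test_fixed_seed_is_reproducible(self):
        rng = np.random.default_rng(7)
        proj = rng.normal(size=(600, 2))
        m1 = cluster_states(proj, k=4, seed=3)
        m2 = cluster_states(proj, k=4, seed=3)
        assert np.array_equal(m1.labels, m2.labels)
        assert m1.centers == pytest.approx(m2.centers)

    def test_k_exceeding_frames_raises(self):
        with pytest.raises(ValueError):
            cluster_states(np.zeros((3, 2)), k=5)

    def test_basin_subclustering_gives_five_states(self):
        # the 4-basins-plus-split-one workflow yields a 5-state decomposition
        rng = np.random.default_rng(8)
        blobs = [rng.normal(c, 0.3, size=(300, 2)) for c in ((0, 0), (8, 0), (0, 8), (8, 8))]
        blobs[1][:150] += (0, 2.5)  # basin 1 is itself bimodal
        proj = np.vstack(blobs)
        base = cluster_states(proj, k=4, seed=0)
        basin = int(base.labels[450])  # a frame from the bimodal blob
        full = subcluster_basin(proj, base, basin=basin, k_sub=2, seed=0)
        assert len(np.unique(full.labels)) == 5
        outside = base.labels != basin
        assert np.array_equal(full.labels[outside], base.labels[outside])


class TestComDistance:
    def make_frame(self, positions, resid=None, mass=None, resname=None):
        positions = np.asarray(positions, dtype=float)
        resid = resid if resid is not None else np.arange(len(positions))
        return CoordinateFrame(positions=positions, resid=resid, mass=mass,
                               resname=resname)

    def test_two_unit_particles(self):
        frame = self.make_frame([[0, 0, 0], [5, 0, 0]])
        d = com_distance(frame, np.array([True, False]), np.array([False, True]))
        assert d == pytest.approx(5.0)

    def test_mass_weighted_four_particle_oracle(self):
        frame = self.make_frame(
            [[0, 0, 0], [13, 0, 0], [10, 0, 0], [10, 13, 0]],
            mass=[12.0, 1.0, 12.0, 1.0],
        )
        a = np.array([True, True, False, False])
        b = np.array([False, False, True, True])
        com_a = (12 * np.array([0, 0, 0]) + 1 * np.array([13, 0, 0])) / 13
        com_b = (12 * np.array([10, 0, 0]) + 1 * np.array([10, 13, 0])) / 13
        assert com_distance(frame, a, b) == pytest.approx(
            np.linalg.norm(com_a - com_b), abs=1e-12
        )

    def test_invariant_to_rigid_motion_and_symmetric(self):
        rng = np.random.default_rng(9)
        pos = rng.normal(size=(10, 3))
        frame = self.make_frame(pos, mass=rng.uniform(1, 20, 10))
        a = np.arange(10) < 5
        b = ~a
        d0 = com_distance(frame, a, b)
        assert d0 == pytest.approx(com_distance(frame, b, a))
        rot = Rotation.random(rng=42).as_matrix()
        moved = self.make_frame(pos @ rot.T + np.array([3.0, -7.0, 11.0]),
                                mass=frame.mass)
        assert com_distance(moved, a, b) == pytest.approx(d0, abs=1e-9)

    def test_resid_range_selection(self):
        frame = self.make_frame([[0, 0, 0], [6, 0, 0]], resid=np.array([61, 236]))
        assert com_distance(frame, (61, 66), (236, 257)) == pytest.approx(6.0)

    def test_empty_selection_raises(self):
        frame = self.make_frame([[0, 0, 0], [1, 0, 0]])
        with pytest.raises(ValueError):
            com_distance(frame, (100, 110), (0, 1))


class TestSegmentDistanceProfile:
    def test_loop_spec_parses_five_subsegments(self):
        spec = parse_segment_spec("241-HVQ/NLS/QVE/QDG/RT-254")
        assert len(spec.subsegments) == 5
        assert sum(len(s) for s in spec.subsegments) == 14
        assert spec.ranges == [(241, 243), (244, 246), (247, 249), (250, 252), (253, 254)]

    def test_inconsistent_spec_raises(self):
        with pytest.raises(ValueError):
            parse_segment_spec("241-HVQ/NLS-254")  # 6 letters for a 14-residue span

    def make_planted_frames(self, n=30, seed=0):
        """QDG segment planted 8 A from the reference, HVQ at 20 A."""
        rng = np.random.default_rng(seed)
        ref_resid = np.arange(61, 67)
        loop_resid = np.arange(241, 255)
        frames = []
        seg_dist = {tuple(range(241, 244)): 20.0, tuple(range(250, 253)): 8.0}
        for _ in range(n):
            ref = rng.normal(0, 0.2, (6, 3))
            ref -= ref.mean(axis=0)
            loop = rng.normal(0, 0.2, (14, 3))
            loop -= loop.mean(axis=0)
            for resids, dist in seg_dist.items():
                idx = np.isin(loop_resid, resids)
                loop[idx] = loop[idx] - loop[idx].mean(axis=0) + [dist, 0, 0]
            others = ~np.isin(loop_resid, [*range(241, 244), *range(250, 253)])
            loop[others, 0] += 14.0
            frames.append(
                CoordinateFrame(
                    positions=np.vstack([ref, loop]),
                    resid=np.concatenate([ref_resid, loop_resid]),
                )
            )
        return frames

    def test_planted_segment_ordering_recovered(self):
        frames = self.make_planted_frames()
        df = segment_distance_profile(frames, "241-HVQ/NLS/QVE/QDG/RT-254", (61, 66))
        med = df.groupby("subsegment")["distance"].median()
        assert med["QDG250-252"] < med["HVQ241-243"]
        q = df.attrs["quartiles"]
        assert set(q.columns) == {0.25, 0.5, 0.75}

    def test_single_subsegment_equals_com_distance_series(self):
        frames = self.make_planted_frames(n=5)
        df = segment_distance_profile(frames, "241-HVQNLSQVEQDGRT-254", (61, 66))
        direct = [com_distance(f, (241, 254), (61, 66)) for f in frames]
        assert df["distance"].to_numpy() == pytest.approx(direct)

    def test_residue_name_validation(self):
        frame = CoordinateFrame(
            positions=np.zeros((2, 3)),
            resid=np.array([241, 242]),
            resname=np.array(["HIS", "ALA"]),  # spec says H, V
        )
        with pytest.raises(ValueError, match="spec says V"):
            segment_distance_profile([frame], "241-HV-242", (241, 241))


def test_planted_three_state_recovery_pipeline():
    """tICA + k-means recover >= 90% of planted metastable state labels."""
    traj, labels, _, _ = gen_metastable_trajectory(
        k_states=3, stay_probabilities=(0.99, 0.98, 0.99), frames=12_000, seed=13
    )
    proj = fit_tica(featurize_dihedrals(traj), lag=1)
    model = cluster_states(proj.projection, k=3, seed=0)
    from itertools import permutations

    acc = max(
        (np.array(perm)[model.labels] == labels).mean()
        for perm in permutations(range(3))
    )
    assert acc >= 0.90
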