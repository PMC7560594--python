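"""Superposition, RMSD clustering, and internal-coordinate PCA."""

import numpy as np
import pytest

import ncpdyn as nd
from ncpdyn.ensemble import RMSDMatrix, residue_centers


def quaternion_rmsd(p, q):
    """Independent minimum-RMSD oracle (Horn's quaternion method)."""
    p = np.asarray(p, float) - np.mean(p, axis=0)
    q = np.asarray(q, float) - np.mean(q, axis=0)
    s = p.T @ q
    sxx, sxy, sxz = s[0]
    syx, syy, syz = s[1]
    szx, szy, szz = s[2]
    k = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    lam = np.linalg.eigvalsh(k).max()
    msd = (np.sum(p ** 2) + np.sum(q ** 2) - 2 * lam) / len(p)
    return float(np.sqrt(max(msd, 0.0)))


def random_rotation(rng):
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


class TestKabsch:
    def test_identical_structures_rmsd_zero(self):
        x = np.random.default_rng(0).normal(size=(10, 3))
        _, rmsd = nd.kabsch_superpose(x, x)
        assert rmsd <= 1e-10

    def test_rigid_motion_recovered(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(12, 3))
        moved = x @ random_rotation(rng).T + np.array([5.0, -3.0, 2.0])
        aligned, rmsd = nd.kabsch_superpose(moved, x)
        assert rmsd <= 1e-8
        np.testing.assert_allclose(aligned, x, atol=1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_quaternion_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(4, 3))
        b = rng.normal(size=(4, 3))
        _, rmsd = nd.kabsch_superpose(a, b)
        assert rmsd == pytest.approx(quaternion_rmsd(a, b), abs=1e-8)

    def test_too_few_or_collinear_atoms(self):
        with pytest.raises(ValueError):
            nd.kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0], [3.0, 0, 0]])
        with pytest.raises(ValueError, match="collinear"):
            nd.kabsch_superpose(line, line)


class TestPairwiseRMSD:
    def test_identical_frames_all_zero(self, lesioned15):
        traj = nd.Trajectory(lesioned15,
                             np.repeat(lesioned15.coords[None], 6, axis=0))
        mat = nd.pairwise_rmsd(traj)
        assert np.all(mat.condensed <= 1e-6)

    def test_single_frame_is_one_by_one_zero(self, lesioned15):
        traj = nd.Trajectory(lesioned15, lesioned15.coords[None])
        mat = nd.pairwise_rmsd(traj)
        assert mat.full().shape == (1, 1)
        assert mat.full()[0, 0] == 0.0

    def test_matches_per_pair_quaternion_oracle(self, lesioned15, site15):
        flips = [nd.FlipSpec(site=site15.lesion, mode="exact_fraction",
                             fraction=0.5)]
        traj, _ = nd.simulate_flip_dynamics(lesioned15, flips, 12, seed=2,
                                            noise_sigma=0.2)
        sel = nd.select_atoms(traj.topology, chain="A", heavy_only=True)
        mat = nd.pairwise_rmsd(traj, sel).full()
        for i in range(12):
            for j in range(i + 1, 12):
                oracle = quaternion_rmsd(traj.frames[i, sel],
                                         traj.frames[j, sel])
                assert mat[i, j] == pytest.approx(oracle, abs=1e-8)


class TestClustering:
    def _two_state_matrix(self, n_a, n_b, sep=10.0, jitter=0.1, seed=0):
        """Trajectory with two well-separated conformers -> RMSD matrix."""
        rng = np.random.default_rng(seed)
        labels = np.array([0] * n_a + [1] * n_b)
        base = rng.normal(size=(12, 3))
        frames = np.empty((n_a + n_b, 12, 3))
        for t, lab in enumerate(labels):
            conf = base.copy()
            if lab:
                conf[:6] += sep
            frames[t] = conf + rng.normal(0, jitter, (12, 3))
        topo_rows = [("CA", "GLY", "X", i + 1, "C") for i in range(12)]
        from conftest import make_structure
        topo = make_structure(topo_rows, base)
        return nd.pairwise_rmsd(nd.Trajectory(topo, frames))

    def test_identical_frames_single_cluster(self, lesioned15):
        traj = nd.Trajectory(lesioned15,
                             np.repeat(lesioned15.coords[None], 5, axis=0))
        res = nd.cluster_frames(nd.pairwise_rmsd(traj))
        assert res.occupancy == {1: 100.0}

    def test_designed_64_36_split(self):
        mat = self._two_state_matrix(640, 360)
        res = nd.cluster_frames(mat)
        assert sorted(res.occupancy.values(), reverse=True) == [64.0, 36.0]

    def test_designed_996_4_split(self):
        mat = self._two_state_matrix(996, 4)
        res = nd.cluster_frames(mat)
        assert sorted(res.occupancy.values(), reverse=True) == [99.6, 0.4]

    def test_occupancies_sum_to_100(self):
        mat = self._two_state_matrix(30, 20, sep=3.0, jitter=0.5)
        for kwargs in ({}, {"k": 3}, {"epsilon": 1.0}):
            res = nd.cluster_frames(mat, **kwargs)
            assert sum(res.occupancy.values()) == pytest.approx(100.0)

    def test_frame_permutation_equivariance(self):
        mat = self._two_state_matrix(12, 8)
        res = nd.cluster_frames(mat, k=2)
        perm = np.random.default_rng(3).permutation(20)
        from scipy.spatial.distance import squareform
        full = mat.full()[np.ix_(perm, perm)]
        permuted = RMSDMatrix(20, squareform(full, checks=False), "")
        res_p = nd.cluster_frames(permuted, k=2)
        # relabeling frames permutes labels: same partition, co-membership-wise
        a = res.labels[perm]
        b = res_p.labels
        same_a = a[:, None] == a[None, :]
        same_b = b[:, None] == b[None, :]
        np.testing.assert_array_equal(same_a, same_b)

    def test_invalid_parameters(self):
        mat = self._two_state_matrix(5, 5)
        with pytest.raises(ValueError):
            nd.cluster_frames(mat, epsilon=-1.0)
        with pytest.raises(ValueError):
            nd.cluster_frames(mat, k=0)


class TestRepresentativeFrame:
    def test_singleton_is_its_own_medoid(self):
        mat = RMSDMatrix(3, np.array([1.0, 2.0, 3.0]))
        assert nd.representative_frame(np.array([2]), mat) == 2

    def test_three_frame_brute_force(self):
        # condensed order: (0,1)=1.0 (0,2)=4.0 (1,2)=2.0
        mat = RMSDMatrix(3, np.array([1.0, 4.0, 2.0]))
        members = np.array([0, 1, 2])
        means = mat.full()[np.ix_(members, members)].sum(1) / 2
        assert nd.representative_frame(members, mat) == int(np.argmin(means))
        assert nd.representative_frame(members, mat) == 1

    def test_tie_breaks_to_lower_index(self):
        # symmetric 2-frame cluster: both have the same mean RMSD
        mat = RMSDMatrix(2, np.array([1.5]))
        assert nd.representative_frame(np.array([0, 1]), mat) == 0


class TestPairFeatures:
    def test_reciprocal_of_fixed_distance(self):
        from conftest import make_structure
        rows = [("CA", "GLY", "X", 1, "C"), ("CA", "GLY", "X", 2, "C")]
        s = make_structure(rows, [[0.0, 0, 0], [5.0, 0, 0]])
        traj = nd.Trajectory(s, np.repeat(s.coords[None], 4, axis=0))
        feats, pairs = nd.pair_features(traj, [("X", 1), ("X", 2)])
        np.testing.assert_allclose(feats, 0.2)
        assert pairs == [(("X", 1), ("X", 2))]

    def test_pair_order_is_lexicographic(self, static_traj):
        residues = [("A", r) for r in (1, 2, 3, 4)]
        feats, pairs = nd.pair_features(static_traj, residues)
        assert feats.shape == (1, 6)
        assert pairs == [
            (("A", 1), ("A", 2)), (("A", 1), ("A", 3)), (("A", 1), ("A", 4)),
            (("A", 2), ("A", 3)), (("A", 2), ("A", 4)), (("A", 3), ("A", 4)),
        ]

    def test_rigid_body_invariance(self, lesioned15, site15):
        flips = [nd.FlipSpec(site=site15.lesion, mode="exact_fraction",
                             fraction=0.5)]
        traj, _ = nd.simulate_flip_dynamics(lesioned15, flips, 8, seed=4,
                                            noise_sigma=0.1)
        residues = [("A", r) for r in range(5, 10)]
        feats, _ = nd.pair_features(traj, residues)
        rng = np.random.default_rng(9)
        moved = np.empty_like(traj.frames)
        for t in range(traj.n_frames):
            moved[t] = traj.frames[t] @ random_rotation(rng).T \
                + rng.normal(0, 50, 3)
        feats2, _ = nd.pair_features(nd.Trajectory(traj.topology, moved),
                                     residues)
        np.testing.assert_allclose(feats2, feats, atol=1e-8)


class TestPCA:
    def test_rank_one_structure(self):
        rng = np.random.default_rng(0)
        n = 200
        feats = np.tile([0.2, 0.5, 0.1], (n, 1))
        feats[:, 1] += 0.05 * np.sin(np.linspace(0, 20, n))
        model = nd.pca_fit(feats)
        assert np.argmax(np.abs(model.eigenvectors[0])) == 1
        assert model.eigenvalues[1] == pytest.approx(0.0, abs=1e-12)

    def test_trace_conservation(self):
        rng = np.random.default_rng(1)
        feats = rng.normal(size=(50, 8))
        model = nd.pca_fit(feats)
        total_var = feats.var(axis=0, ddof=1).sum()
        assert model.eigenvalues.sum() == pytest.approx(total_var, abs=1e-8)

    def test_two_feature_closed_form(self):
        # covariance [[a, c], [c, b]] -> eigenvalues by the quadratic formula
        x = np.array([[1.0, 2.0], [2.0, 3.0], [3.0, 5.0], [4.0, 4.0]])
        model = nd.pca_fit(x)
        cov = np.cov(x.T, ddof=1)
        a, b, c = cov[0, 0], cov[1, 1], cov[0, 1]
        disc = np.sqrt(((a - b) / 2) ** 2 + c ** 2)
        expected = np.array([(a + b) / 2 + disc, (a + b) / 2 - disc])
        np.testing.assert_allclose(model.eigenvalues, expected, atol=1e-12)

    def test_matches_sklearn_oracle(self):
        sklearn = pytest.importorskip("sklearn.decomposition")
        rng = np.random.default_rng(2)
        feats = rng.normal(size=(40, 15)) * np.linspace(0.1, 2, 15)
        model = nd.pca_fit(feats)
        ref = sklearn.PCA(n_components=15).fit(feats)
        np.testing.assert_allclose(model.eigenvalues,
                                   ref.explained_variance_, atol=1e-8)
        for i in range(5):
            dot = abs(model.eigenvectors[i] @ ref.components_[i])
            assert dot == pytest.approx(1.0, abs=1e-8)

    def test_constant_features_flagged_degenerate(self):
        model = nd.pca_fit(np.ones((10, 3)))
        assert model.degenerate


class TestResidueImportance:
    def _toy_model(self):
        """4 residues, only the (A,B) pair distance varies."""
        rng = np.random.default_rng(0)
        residues = ["A", "B", "C", "D"]
        import itertools
        pairs = list(itertools.combinations(residues, 2))
        n = 300
        feats = np.full((n, len(pairs)), 0.25)
        ab = pairs.index(("A", "B"))
        feats[:, ab] += 0.1 * np.sin(np.linspace(0, 30, n))
        feats += rng.normal(0, 1e-5, feats.shape)
        return nd.pca_fit(feats, pairs)

    def test_sums_to_100(self):
        model = self._toy_model()
        imp = nd.residue_importance(model, n_components=3)
        assert sum(imp.per_residue.values()) == pytest.approx(100.0,
                                                              abs=1e-6)

    def test_varying_pair_splits_importance_evenly(self):
        model = self._toy_model()
        imp = nd.residue_importance(model, n_components=1)
        assert imp.per_residue["A"] == pytest.approx(50.0, abs=1.0)
        assert imp.per_residue["B"] == pytest.approx(50.0, abs=1.0)
        assert imp.per_residue["C"] < 1.0 and imp.per_residue["D"] < 1.0

    def test_too_many_components_rejected(self):
        model = self._toy_model()
        with pytest.raises(ValueError, match="exceeds"):
            nd.residue_importance(model, n_components=100)

    def test_whole_pipeline_rigid_body_invariance(self, lesioned15, site15):
        flips = [nd.FlipSpec(site=site15.lesion, mode="exact_fraction",
                             fraction=0.5)]
        traj, _ = nd.simulate_flip_dynamics(lesioned15, flips, 30, seed=6,
                                            noise_sigma=0.1)
        residues = ([("A", r) for r in range(5, 10)]
                    + [("B", r) for r in range(7, 11)])
        feats, pairs = nd.pair_features(traj, residues)
        model = nd.pca_fit(feats, pairs)
        imp = nd.residue_importance(model, n_components=5)

        rng = np.random.default_rng(8)
        moved = np.empty_like(traj.frames)
        for t in range(traj.n_frames):
            moved[t] = traj.frames[t] @ random_rotation(rng).T \
                + rng.normal(0, 20, 3)
        feats2, pairs2 = nd.pair_features(nd.Trajectory(traj.topology, moved),
                                          residues)
        model2 = nd.pca_fit(feats2, pairs2)
        imp2 = nd.residue_importance(model2, n_components=5)
        np.testing.assert_allclose(model2.eigenvalues, model.eigenvalues,
                                   atol=1e-8)
        for res in imp.per_residue:
            assert imp2.per_residue[res] == pytest.approx(
                imp.per_residue[res], abs=1e-6)
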