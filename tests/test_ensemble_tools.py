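import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from saxsdrive.ensemble_tools import (Ensemble, chi2, cluster, kl_divergence,
                                      maxent_reweight, rmsd_matrix,
                                      superpose_rmsd, theta_lcurve)
from saxsdrive.errors import InputError
from saxsdrive.io_synth import SynthSpec, make_synthetic_target
from saxsdrive.scatter_core import (FormFactorTable, ParticleSystem,
                                    ScatteringProfile, debye_intensity)
from saxsdrive.structure_analysis import radius_of_gyration


class TestChi2:
    def test_identity(self):
        i = np.array([1.0, 2.0, 3.0])
        assert chi2(i, i, np.ones(3)) == 0.0

    def test_hand_case(self):
        # ((10-9)^2 + 0 + (6-7)^2) / 2 = 1.0
        assert chi2(np.array([9.0, 8.0, 7.0]), np.array([10.0, 8.0, 6.0]),
                    np.ones(3)) == pytest.approx(1.0)

    def test_sigma_scaling_law(self):
        rng = np.random.default_rng(0)
        a, b = rng.uniform(1, 2, 10), rng.uniform(1, 2, 10)
        s = rng.uniform(0.1, 0.2, 10)
        assert chi2(a, b, s / 2) == pytest.approx(4 * chi2(a, b, s))

    def test_needs_two_points(self):
        with pytest.raises(InputError):
            chi2(np.array([1.0]), np.array([1.0]), np.array([1.0]))

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 1000))
    def test_nonnegative_and_zero_iff_equal(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.uniform(1, 2, 8), rng.uniform(1, 2, 8)
        s = rng.uniform(0.05, 0.5, 8)
        val = chi2(a, b, s)
        assert val >= 0
        assert (val == 0) == bool(np.array_equal(a, b))


class TestKL:
    def test_identity_and_hand_case(self):
        w = np.array([0.5, 0.5])
        assert kl_divergence(w, w) == 0.0
        got = kl_divergence(w, np.array([0.25, 0.75]))
        assert got == pytest.approx(0.5 * np.log(2) + 0.5 * np.log(2 / 3),
                                    abs=1e-12)
        assert got == pytest.approx(0.1438, abs=5e-5)

    def test_zero_times_log_zero(self):
        assert kl_divergence(np.array([1.0, 0.0]),
                             np.array([0.5, 0.5])) == pytest.approx(np.log(2))

    def test_domain_error(self):
        with pytest.raises(InputError):
            kl_divergence(np.array([0.5, 0.5]), np.array([1.0, 0.0]))

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 1000))
    def test_gibbs_inequality(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.dirichlet(np.ones(6))
        b = rng.dirichlet(np.ones(6))
        assert kl_divergence(a, b) >= -1e-12


def _pool_ensemble(n_frames=10, seed=0, noise_frac=0.0):
    """Pool of bent HJH conformers with per-frame Debye profiles."""
    from saxsdrive.toy_dynamics import bend_arm, build_hjh_toy
    model = build_hjh_toy()
    labels = [model.bead_label] * model.n_beads
    ff = FormFactorTable("constant")
    q = np.linspace(0.01, 0.315, 60)
    angles = np.linspace(0.0, 135.0, n_frames)
    frames = np.array([bend_arm(model, a) for a in angles])
    profiles = np.array([
        debye_intensity(ParticleSystem(f, labels), ff, q).intensity
        for f in frames])
    return Ensemble(frames, q=q, profiles=profiles), q


class TestMaxent:
    def test_uniform_target_keeps_uniform_weights(self):
        ens, q = _pool_ensemble()
        mean = ens.mean_profile()
        target = ScatteringProfile(q, mean, 0.02 * mean)
        w, diag = maxent_reweight(ens, target, theta=1.0)
        assert np.allclose(w, 1.0 / ens.n_frames, atol=1e-6)
        assert diag["chi2"] < 1e-8
        assert diag["kl_uniform"] < 1e-10

    def test_degenerate_target_concentrates_weight(self):
        ens, q = _pool_ensemble()
        k = 7
        target = ScatteringProfile(q, ens.profiles[k],
                                   0.001 * ens.profiles[k])
        w, _ = maxent_reweight(ens, target, theta=0.0)
        assert np.argmax(w) == k
        assert w[k] > 0.9

    def test_dirichlet_weight_recovery(self):
        ens, q = _pool_ensemble()
        rng = np.random.default_rng(42)
        w_true = rng.dirichlet(np.ones(ens.n_frames))
        mean = w_true @ ens.profiles
        target = ScatteringProfile(q, mean, 0.02 * mean)
        w, diag = maxent_reweight(ens, target, theta=0.0)
        assert diag["chi2"] < 1e-6
        rg = np.array([radius_of_gyration(f) for f in ens.frames])
        assert w @ rg == pytest.approx(w_true @ rg, rel=0.01)

    def test_theta_sweep_tradeoff_monotone(self):
        ens, q = _pool_ensemble()
        rng = np.random.default_rng(3)
        w_true = rng.dirichlet(np.ones(ens.n_frames) * 0.5)
        mean = w_true @ ens.profiles
        target = ScatteringProfile(q, mean, 0.02 * mean)
        thetas = np.logspace(-3, 2, 8)
        chis, kls = [], []
        for th in thetas:
            _, diag = maxent_reweight(ens, target, theta=float(th))
            chis.append(diag["chi2"])
            kls.append(diag["kl_uniform"])
        # decreasing theta: chi2 non-increasing, divergence non-decreasing
        assert np.all(np.diff(chis) >= -1e-9)
        assert np.all(np.diff(kls) <= 1e-9)

    def test_lcurve_returns_swept_theta(self):
        ens, q = _pool_ensemble(n_frames=6)
        rng = np.random.default_rng(5)
        w_true = rng.dirichlet(np.ones(6))
        mean = w_true @ ens.profiles
        target = ScatteringProfile(q, mean, 0.02 * mean)
        thetas = np.logspace(-3, 1, 5)
        knee, sweep = theta_lcurve(ens, target, thetas=thetas)
        assert knee in thetas
        assert sweep["chi2"].shape == (5,)


class TestSuperpose:
    def test_identity_and_rigid_motion(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(10, 3))
        assert superpose_rmsd(a, a)[0] == pytest.approx(0.0, abs=1e-12)
        rot = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        b = a @ rot.T + np.array([5.0, -2.0, 1.0])
        assert superpose_rmsd(a, b)[0] == pytest.approx(0.0, abs=1e-10)

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=(8, 3)), rng.normal(size=(8, 3))
        assert superpose_rmsd(a, b)[0] == pytest.approx(
            superpose_rmsd(b, a)[0], rel=1e-12)

    def test_matches_quaternion_oracle(self):
        # independent quaternion-based solution of the same problem
        def quaternion_rmsd(a, b):
            a0 = a - a.mean(axis=0)
            b0 = b - b.mean(axis=0)
            m = b0.T @ a0
            key = np.array([
                [m[0, 0] + m[1, 1] + m[2, 2], m[1, 2] - m[2, 1],
                 m[2, 0] - m[0, 2], m[0, 1] - m[1, 0]],
                [m[1, 2] - m[2, 1], m[0, 0] - m[1, 1] - m[2, 2],
                 m[0, 1] + m[1, 0], m[2, 0] + m[0, 2]],
                [m[2, 0] - m[0, 2], m[0, 1] + m[1, 0],
                 -m[0, 0] + m[1, 1] - m[2, 2], m[1, 2] + m[2, 1]],
                [m[0, 1] - m[1, 0], m[2, 0] + m[0, 2], m[1, 2] + m[2, 1],
                 -m[0, 0] - m[1, 1] + m[2, 2]]])
            lmax = np.linalg.eigvalsh(key)[-1]
            e0 = (np.sum(a0 ** 2) + np.sum(b0 ** 2))
            return np.sqrt(max(0.0, e0 - 2 * lmax) / a.shape[0])

        rng = np.random.default_rng(7)
        for _ in range(5):
            a = rng.normal(size=(10, 3))
            b = rng.normal(size=(10, 3))
            assert superpose_rmsd(a, b)[0] == pytest.approx(
                quaternion_rmsd(a, b), abs=1e-10)

    def test_count_mismatch_rejected(self):
        with pytest.raises(InputError):
            superpose_rmsd(np.zeros((3, 3)), np.zeros((4, 3)))


def _two_blob_frames(seed=0, n_per=20, offset=25.0):
    """Two tight clusters of perturbed conformers, far apart in RMSD."""
    rng = np.random.default_rng(seed)
    base_a = rng.normal(scale=6.0, size=(12, 3))
    base_b = base_a + np.array([offset, 0.0, 0.0]) * np.linspace(
        -1, 1, 12)[:, None]
    frames = []
    for base in (base_a, base_b):
        for _ in range(n_per):
            frames.append(base + rng.normal(scale=0.4, size=base.shape))
    return np.array(frames)


class TestClustering:
    @pytest.mark.parametrize("method", ["gromos", "single_linkage"])
    def test_two_blobs_two_clusters(self, method):
        frames = _two_blob_frames()
        assign = cluster(frames, cutoff=4.0, method=method)
        assert assign.n_clusters == 2
        sizes = np.bincount(assign.labels)
        assert sorted(sizes.tolist()) == [20, 20]
        # members of each blob share a label
        assert len(set(assign.labels[:20])) == 1
        assert len(set(assign.labels[20:])) == 1

    def test_identical_frames_single_cluster(self):
        frames = np.repeat(np.random.default_rng(0).normal(
            size=(1, 5, 3)), 8, axis=0)
        for method in ("gromos", "single_linkage"):
            assign = cluster(frames, cutoff=0.5, method=method)
            assert assign.n_clusters == 1

    def test_gromos_matches_greedy_oracle_on_5_frame_graph(self):
        frames = _two_blob_frames(seed=3, n_per=5, offset=30.0)[:5]
        dmat = rmsd_matrix(frames)
        cutoff = float(np.median(dmat[dmat > 0]))

        # brute-force greedy rule on the neighbour graph
        adj = dmat <= cutoff
        np.fill_diagonal(adj, True)
        remaining = list(range(5))
        expected = {}
        cid = 0
        while remaining:
            counts = [sum(adj[i][j] for j in remaining) for i in remaining]
            center = remaining[int(np.argmax(counts))]
            members = [j for j in remaining if adj[center][j]]
            for m in members:
                expected[m] = cid
            remaining = [j for j in remaining if j not in members]
            cid += 1

        assign = cluster(frames, cutoff=cutoff, method="gromos")
        # same partition (labels may be renumbered canonically)
        for i in range(5):
            for j in range(5):
                assert ((assign.labels[i] == assign.labels[j])
                        == (expected[i] == expected[j]))

    def test_labels_invariant_under_frame_reordering(self):
        frames = _two_blob_frames(seed=5, n_per=8)
        assign = cluster(frames, cutoff=4.0)
        rng = np.random.default_rng(9)
        perm = rng.permutation(len(frames))
        assign_p = cluster(frames[perm], cutoff=4.0)
        # canonical labels: partitions agree after permutation
        for i in range(len(frames)):
            for j in range(len(frames)):
                same = assign.labels[i] == assign.labels[j]
                same_p = assign_p.labels[np.argwhere(perm == i)[0, 0]] == \
                    assign_p.labels[np.argwhere(perm == j)[0, 0]]
                assert same == same_p

    def test_centers_belong_to_their_cluster(self):
        frames = _two_blob_frames(seed=6)
        for method in ("gromos", "single_linkage"):
            assign = cluster(frames, cutoff=4.0, method=method)
            for cid, center in enumerate(assign.centers):
                assert assign.labels[center] == cid

    def test_empty_input_rejected(self):
        with pytest.raises(InputError):
            cluster(np.empty((0, 3, 3)), cutoff=1.0)


class TestEnsembleContainer:
    def test_weight_validation(self):
        frames = np.zeros((3, 2, 3))
        with pytest.raises(InputError):
            Ensemble(frames, weights=np.array([0.5, 0.2, 0.2]))
        with pytest.raises(InputError):
            Ensemble(frames, weights=np.array([-0.1, 0.6, 0.5]))

    def test_synthetic_target_mixture_consistency(self):
        # 50/50 mixture target equals the mean of the two pure profiles
        from saxsdrive.toy_dynamics import bend_arm, build_hjh_toy
        model = build_hjh_toy()
        labels = [model.bead_label] * model.n_beads
        a = ParticleSystem(model.beads.coordinates, labels)
        b = ParticleSystem(bend_arm(model, 90.0), labels)
        spec = SynthSpec(generator="two_state_mixture",
                         mixture_weights=[0.5, 0.5], noise_frac=0.0)
        mix = make_synthetic_target([a, b], spec)
        ff = FormFactorTable("constant")
        ia = debye_intensity(a, ff, mix.q).intensity
        ib = debye_intensity(b, ff, mix.q).intensity
        assert np.allclose(mix.intensity, 0.5 * (ia + ib))
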