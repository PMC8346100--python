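import numpy as np
import pytest

from vdyn import (
    CartesianPCA,
    cross_project,
    explained_variance,
    export_nmd,
    fit_pca,
    make_toy_chain,
    porcupine_vectors,
    project,
    random_orthonormal_modes,
    rmsip,
    sample_gaussian_trajectory,
    select_atoms,
)


def _two_mode_matrix():
    """4 frames in 6 dims with exact sample eigenvalues (3, 1)."""
    e1 = np.eye(6)[0]
    e2 = np.eye(6)[1]
    a = 1.5 * np.array([1, -1, 1, -1])  # ddof=1 variance = 3
    b = (np.sqrt(3) / 2) * np.array([1, 1, -1, -1])  # ddof=1 variance = 1
    return np.outer(a, e1) + np.outer(b, e2)


class TestFitPca:
    def test_single_direction_explains_everything(self):
        direction = np.full(6, 1.0) / np.sqrt(6)
        X = np.outer(np.array([-1.0, 0.5, 2.0, -1.5]), direction)
        decomp = CartesianPCA().fit(X)
        assert decomp.explained_variance_ratio_[0] == pytest.approx(1.0)
        assert abs(decomp.components_[0] @ direction) == pytest.approx(1.0)

    def test_planted_spectrum_recovery(self, planted_trajectory):
        traj, modes, eigenvalues = planted_trajectory
        decomp = fit_pca(traj)
        np.testing.assert_allclose(
            decomp.eigenvalues_[:3], eigenvalues, rtol=0.10
        )
        for k in range(3):
            assert abs(modes[k] @ decomp.components_[k]) >= 0.95

    def test_variance_fractions_sum_to_one(self, planted_trajectory):
        traj, _, _ = planted_trajectory
        decomp = fit_pca(traj)
        assert decomp.explained_variance_ratio_.sum() == pytest.approx(1.0, abs=1e-8)

    def test_eigenvectors_orthonormal_and_sorted(self, planted_trajectory):
        traj, _, _ = planted_trajectory
        decomp = fit_pca(traj)
        gram = decomp.components_ @ decomp.components_.T
        np.testing.assert_allclose(gram, np.eye(gram.shape[0]), atol=1e-8)
        assert np.all(np.diff(decomp.eigenvalues_) <= 1e-12)

    def test_trace_conservation(self, planted_trajectory):
        traj, _, _ = planted_trajectory
        X = traj.xyz.reshape(traj.n_frames, -1)
        total = np.var(X, axis=0, ddof=1).sum()
        decomp = fit_pca(traj)
        assert decomp.eigenvalues_.sum() == pytest.approx(total, rel=1e-6)

    def test_requires_two_frames_and_finite_coordinates(self):
        with pytest.raises(ValueError, match="two frames"):
            CartesianPCA().fit(np.zeros((1, 6)))
        bad = np.zeros((3, 6))
        bad[1, 2] = np.nan
        with pytest.raises(ValueError, match="finite"):
            CartesianPCA().fit(bad)

    def test_deterministic_sign_convention(self, planted_trajectory):
        traj, _, _ = planted_trajectory
        a = fit_pca(traj).components_
        b = fit_pca(traj).components_
        np.testing.assert_array_equal(a, b)
        largest = np.abs(a).argmax(axis=1)
        assert np.all(a[np.arange(a.shape[0]), largest] > 0)

    def test_spectrum_recovery_converges_with_frames(self, toy_chain):
        eigenvalues = np.array([9.0, 4.0, 1.0])
        errors = []
        for n_frames in (500, 2000, 10000):
            per_seed = []
            for seed in (21, 22, 23, 24, 25):
                modes = random_orthonormal_modes(30, 3, seed=seed)
                traj = sample_gaussian_trajectory(
                    toy_chain, modes, eigenvalues, n_frames, seed=seed + 100
                )
                est = fit_pca(traj).eigenvalues_[:3]
                per_seed.append(np.abs(est - eigenvalues).sum())
            errors.append(np.mean(per_seed))
        assert errors[0] > errors[1] > errors[2]


class TestExplainedVariance:
    def test_full_mode_count_is_one(self, planted_trajectory):
        traj, _, _ = planted_trajectory
        decomp = fit_pca(traj)
        assert explained_variance(decomp, len(decomp.eigenvalues_)) == pytest.approx(1.0)

    def test_exact_two_mode_arithmetic(self):
        decomp = CartesianPCA().fit(_two_mode_matrix())
        assert explained_variance(decomp, 1) == pytest.approx(0.75, abs=1e-10)

    def test_planted_cumulative_fraction(self, planted_trajectory):
        traj, _, eigenvalues = planted_trajectory
        decomp = fit_pca(traj)
        planted_fraction = eigenvalues[:2].sum() / eigenvalues.sum()
        assert explained_variance(decomp, 2) == pytest.approx(planted_fraction, rel=0.05)

    def test_k_out_of_range(self, planted_trajectory):
        traj, _, _ = planted_trajectory
        decomp = fit_pca(traj)
        with pytest.raises(ValueError):
            explained_variance(decomp, 0)
        with pytest.raises(ValueError):
            explained_variance(decomp, len(decomp.eigenvalues_) + 1)


class TestProjection:
    def test_mean_projects_to_zero(self, planted_trajectory):
        traj, _, _ = planted_trajectory
        decomp = fit_pca(traj)
        scores = decomp.transform(decomp.mean_[np.newaxis])
        np.testing.assert_allclose(scores, 0.0, atol=1e-8)

    def test_displaced_mean_scores_exactly(self, planted_trajectory):
        traj, _, _ = planted_trajectory
        decomp = fit_pca(traj)
        frame = decomp.mean_ + 2.0 * decomp.components_[0]
        scores = decomp.transform(frame[np.newaxis], pcs=(1, 2, 3))
        np.testing.assert_allclose(scores[0], [2.0, 0.0, 0.0], atol=1e-10)

    def test_self_projection_variance_equals_eigenvalue(self, planted_trajectory):
        traj, _, _ = planted_trajectory
        decomp = fit_pca(traj)
        proj = project(traj, decomp, pcs=(1,))
        assert np.var(proj["pc1"], ddof=1) == pytest.approx(
            decomp.eigenvalues_[0], rel=1e-6
        )
        assert abs(proj["pc1"].mean()) < 1e-8

    def test_reconstruction_with_all_modes(self, planted_trajectory):
        traj, _, _ = planted_trajectory
        decomp = fit_pca(traj)
        X = traj.xyz.reshape(traj.n_frames, -1)
        scores = decomp.transform(X)
        reconstructed = scores @ decomp.components_ + decomp.mean_
        assert np.abs(reconstructed - X).max() < 1e-8

    def test_dimension_mismatch(self, planted_trajectory):
        traj, _, _ = planted_trajectory
        decomp = fit_pca(traj)
        with pytest.raises(ValueError, match="dimension"):
            decomp.transform(np.zeros((1, 12)))


class TestCrossProject:
    def test_reference_mean_maps_to_origin(self, planted_trajectory):
        traj, _, _ = planted_trajectory
        decomp = fit_pca(traj)
        np.testing.assert_allclose(
            cross_project(decomp.mean_, decomp), 0.0, atol=1e-8
        )

    def test_known_combination_recovered_exactly(self, planted_trajectory):
        traj, _, _ = planted_trajectory
        decomp = fit_pca(traj)
        frame = decomp.mean_ + 1.7 * decomp.components_[0] - 0.4 * decomp.components_[1]
        np.testing.assert_allclose(
            cross_project(frame, decomp), [1.7, -0.4], atol=1e-10
        )

    def test_consistent_with_own_projection(self, planted_trajectory):
        traj, _, _ = planted_trajectory
        decomp = fit_pca(traj)
        own = project(traj, decomp, pcs=(1, 2)).iloc[0].to_numpy()
        frame = traj.xyz[traj.equilibration_start].ravel()
        np.testing.assert_allclose(cross_project(frame, decomp), own, atol=1e-10)


class TestRmsip:
    def test_self_overlap_is_one(self, planted_trajectory):
        traj, _, _ = planted_trajectory
        decomp = fit_pca(traj)
        assert rmsip(decomp, decomp, n_modes=3) == pytest.approx(1.0, abs=1e-10)

    def test_orthogonal_subspaces_are_zero(self):
        basis = np.eye(12)
        assert rmsip(basis[:3], basis[3:6], n_modes=3) == 0.0

    def test_symmetric(self):
        a = random_orthonormal_modes(60, 5, seed=1)
        b = random_orthonormal_modes(60, 5, seed=2)
        assert rmsip(a, b, n_modes=5) == pytest.approx(rmsip(b, a, n_modes=5))

    def test_complete_bases_overlap_fully(self):
        a = random_orthonormal_modes(9, 9, seed=3)
        b = random_orthonormal_modes(9, 9, seed=4)
        assert rmsip(a, b, n_modes=9) == pytest.approx(1.0, abs=1e-8)

    def test_random_subspace_baseline(self):
        # E[RMSIP] for random k-subspaces in dimension D is ~sqrt(k/D)
        k, dim, draws = 10, 300, 40
        values = [
            rmsip(
                random_orthonormal_modes(dim, k, seed=2 * i),
                random_orthonormal_modes(dim, k, seed=2 * i + 1),
                n_modes=k,
            )
            for i in range(draws)
        ]
        assert np.mean(values) == pytest.approx(np.sqrt(k / dim), rel=0.2)

    def test_dimension_and_mode_count_validation(self):
        a = random_orthonormal_modes(30, 5, seed=5)
        b = random_orthonormal_modes(33, 5, seed=6)
        with pytest.raises(ValueError, match="dimension"):
            rmsip(a, b, n_modes=5)
        with pytest.raises(ValueError, match="modes"):
            rmsip(a, a[:2], n_modes=5)

    def test_literal_no_sqrt_variant(self):
        a = random_orthonormal_modes(30, 5, seed=7)
        assert rmsip(a, a, n_modes=5, sqrt=False) == pytest.approx(1.0)
        b = random_orthonormal_modes(30, 5, seed=8)
        with_root = rmsip(a, b, n_modes=5)
        without = rmsip(a, b, n_modes=5, sqrt=False)
        assert without == pytest.approx(with_root**2)


class TestPorcupine:
    def test_zero_scale_zero_vectors(self, planted_trajectory):
        traj, _, _ = planted_trajectory
        vectors = porcupine_vectors(fit_pca(traj), mode=1, scale=0.0)
        np.testing.assert_allclose(vectors, 0.0)

    def test_amplitudes_sum_to_scale_squared(self, planted_trajectory):
        traj, _, _ = planted_trajectory
        vectors = porcupine_vectors(fit_pca(traj), mode=1, scale=10.0)
        assert np.sum(vectors**2) == pytest.approx(100.0, rel=1e-10)

    def test_planted_single_mode_is_parallel(self, toy_chain):
        mode = random_orthonormal_modes(30, 1, seed=9)
        traj = sample_gaussian_trajectory(
            toy_chain, mode, np.array([4.0]), 500, seed=10
        )
        vectors = porcupine_vectors(fit_pca(traj), mode=1, scale=1.0)
        cosine = abs(vectors.ravel() @ mode[0])
        assert cosine == pytest.approx(1.0, abs=1e-6)

    def test_mode_out_of_range(self, planted_trajectory):
        traj, _, _ = planted_trajectory
        with pytest.raises(ValueError, match="out of range"):
            porcupine_vectors(fit_pca(traj), mode=0)


def test_nmd_export_round_trips_mode_vectors(tmp_path, toy_chain):
    sel = select_atoms(toy_chain, "ca")
    modes = random_orthonormal_modes(30, 2, seed=11)
    traj = sample_gaussian_trajectory(
        toy_chain, modes, np.array([4.0, 1.0]), 400, seed=12
    )
    decomp = fit_pca(traj, sel)
    path = tmp_path / "modes.nmd"
    export_nmd(path, toy_chain, sel, decomp, modes=(1, 2))
    lines = path.read_text().splitlines()
    mode_lines = [l for l in lines if l.startswith("mode ")]
    assert len(mode_lines) == 2
    vec = np.array(mode_lines[0].split()[3:], dtype=float)
    np.testing.assert_allclose(vec, decomp.components_[0], atol=1e-5)
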