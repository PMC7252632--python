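"""Karhunen-Loeve decomposition: exactness, invariants, recovery."""

import numpy as np
import pytest

import chromsig as cs
from chromsig.fpca import fit_fpca, project, reconstruct
from chromsig.profiles import PROFILE_LEN

T = PROFILE_LEN


def _orthonormal_basis(n_funcs: int) -> np.ndarray:
    """Smooth orthonormal functions on the 400-point grid (sinusoids)."""
    t = np.arange(T)
    basis = np.stack([np.sin(2 * np.pi * (j + 1) * t / T) for j in range(n_funcs)], axis=1)
    q, _ = np.linalg.qr(basis)
    return q


class TestFitExactCases:
    def test_no_variation_gives_zero_spectrum(self):
        Y = np.tile(np.linspace(0, 1, T), (5, 1))
        model = fit_fpca(Y)
        assert model.total_variance == pytest.approx(0, abs=1e-12)
        np.testing.assert_allclose(model.eigenvalues, 0, atol=1e-12)
        np.testing.assert_allclose(model.scores, 0, atol=1e-12)

    def test_rank_one_data_recovers_scores_up_to_sign(self):
        psi = _orthonormal_basis(1)[:, 0]
        c = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        mu = np.linspace(1, 2, T)
        model = fit_fpca(mu + np.outer(c, psi))
        assert model.q == 1
        np.testing.assert_allclose(model.fve[-1], 1.0)
        sign = np.sign(model.scores[4, 0])  # global sign is arbitrary
        np.testing.assert_allclose(sign * model.scores[:, 0], c, atol=1e-10)

    def test_q_from_engineered_spectrum(self):
        # sample eigenvalues exactly (5, 3, 1, 1): cumulative FVE .5/.8/.9/1
        rng = np.random.default_rng(0)
        n = 50
        C = rng.normal(size=(n, 4))
        C -= C.mean(axis=0)
        # whiten the realized sample covariance, then scale to the target
        L = np.linalg.cholesky(np.cov(C, rowvar=False))
        C = C @ np.linalg.inv(L).T * np.sqrt([5.0, 3.0, 1.0, 1.0])
        Y = np.zeros((n, T))
        Y[:, :4] = C  # canonical unit vectors as eigenfunctions
        model = fit_fpca(Y, fve_threshold=0.9)
        assert model.q == 3
        np.testing.assert_allclose(model.eigenvalues, [5, 3, 1], atol=1e-8)

    def test_input_validation(self):
        with pytest.raises(ValueError, match="at least 2"):
            fit_fpca(np.ones((1, T)))
        with pytest.raises(ValueError, match="fve_threshold"):
            fit_fpca(np.random.default_rng(0).normal(size=(5, T)), fve_threshold=1.5)
        with pytest.raises(ValueError, match="log"):
            fit_fpca(cs.ProfileMatrix(np.ones((3, T)), transform_state="raw"))


class TestInvariants:
    @pytest.fixture(scope="class")
    def model(self, sim400):
        matrix, _ = sim400
        return fit_fpca(cs.log_transform(matrix).values)

    def test_total_variance_conserved(self, sim400):
        matrix, _ = sim400
        Y = cs.log_transform(matrix).values
        model = fit_fpca(Y, q_override=Y.shape[1])
        assert model.eigenvalues.sum() == pytest.approx(model.total_variance, rel=1e-8)

    def test_eigenfunctions_orthonormal(self, model):
        gram = model.psi.T @ model.psi
        np.testing.assert_allclose(gram, np.eye(model.q), atol=1e-10)

    def test_eigenvalues_sorted_nonnegative(self, model):
        assert np.all(model.eigenvalues >= 0)
        assert np.all(np.diff(model.eigenvalues) <= 1e-12)

    def test_scores_centred_and_decorrelated(self, model):
        np.testing.assert_allclose(model.scores.mean(axis=0), 0, atol=1e-10)
        cov = np.cov(model.scores, rowvar=False)
        np.testing.assert_allclose(cov, np.diag(model.eigenvalues),
                                   atol=1e-8 * model.total_variance)

    def test_matches_sklearn_pca(self, sim400):
        """Independent route: sklearn PCA on the same centred data."""
        from sklearn.decomposition import PCA

        matrix, _ = sim400
        Y = cs.log_transform(matrix).values
        model = fit_fpca(Y, q_override=5)
        pca = PCA(n_components=5).fit(Y)
        np.testing.assert_allclose(model.eigenvalues, pca.explained_variance_, rtol=1e-8)
        for j in range(5):
            dot = abs(model.psi[:, j] @ pca.components_[j])
            assert dot == pytest.approx(1.0, abs=1e-8)


class TestKLRecovery:
    def test_recovers_generating_eigenfunctions(self):
        """3-component KL model + small noise: eigenfunctions recovered
        with cosine similarity > 0.99 and eigenvalues within sampling
        error at n = 500."""
        rng = np.random.default_rng(7)
        n, sds = 500, np.array([3.0, 2.0, 1.0])
        basis = _orthonormal_basis(3)
        C = rng.normal(size=(n, 3)) * sds
        Y = 1.0 + C @ basis.T + rng.normal(0, 0.05, size=(n, T))
        model = fit_fpca(Y, q_override=3)
        for j in range(3):
            cos = abs(model.psi[:, j] @ basis[:, j])
            assert cos > 0.99
        # lambda_j ~ sd_j^2; chi^2 sampling error ~ lambda*sqrt(2/n), allow 4x
        for lam, sd in zip(model.eigenvalues, sds):
            assert abs(lam - sd**2) < 4 * sd**2 * np.sqrt(2 / n) + 0.05 * T / n + 0.1


class TestProjectReconstruct:
    @pytest.fixture(scope="class")
    def model(self):
        rng = np.random.default_rng(3)
        basis = _orthonormal_basis(4)
        Y = 2.0 + (rng.normal(size=(40, 4)) * [4, 3, 2, 1]) @ basis.T
        return fit_fpca(Y, q_override=4), Y

    def test_mean_projects_to_zero(self, model):
        m, _ = model
        np.testing.assert_allclose(project(m, m.mu), 0, atol=1e-10)

    def test_shifted_mean_projects_to_loading(self, model):
        m, _ = model
        scores = project(m, m.mu + 2 * m.psi[:, 0])
        np.testing.assert_allclose(scores, [2, 0, 0, 0], atol=1e-10)

    def test_training_rows_consistent(self, model):
        m, Y = model
        np.testing.assert_allclose(project(m, Y), m.scores, atol=1e-10)

    def test_projection_identity_in_span(self, model):
        m, Y = model
        y = Y[0]
        np.testing.assert_allclose(reconstruct(m, project(m, y)), y, atol=1e-8)

    def test_residual_nonincreasing_in_q(self, sim400):
        matrix, _ = sim400
        Y = cs.log_transform(matrix).values
        y = Y[0]
        residuals = []
        for q in (1, 3, 5, 10, 50):
            m = fit_fpca(Y, q_override=q)
            residuals.append(np.linalg.norm(y - reconstruct(m, project(m, y))))
        assert all(b <= a + 1e-9 for a, b in zip(residuals, residuals[1:]))

    def test_length_mismatch_errors(self, model):
        m, _ = model
        with pytest.raises(ValueError):
            project(m, np.ones(10))
        with pytest.raises(ValueError):
            reconstruct(m, np.ones(m.q + 1))

    def test_save_load_round_trip(self, model, tmp_path):
        m, _ = model
        m.save(tmp_path / "model.npz")
        loaded = cs.FPCAModel.load(tmp_path / "model.npz")
        np.testing.assert_array_equal(loaded.psi, m.psi)
        assert loaded.q == m.q and loaded.total_variance == m.total_variance
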