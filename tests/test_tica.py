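"""FOBI/JADE rotations, joint diagonalisation and the tWFOBI/tWJADE drivers.

Source-recovery tests use the identifiable regimes of each estimator:
JADE separates any independent non-Gaussian sources, while FOBI
additionally requires distinct kurtosis (row-sum) values, so its recovery
tests use mixed Laplace/uniform/Student-t sources.
"""

import numpy as np
import pytest
from scipy.stats import ortho_group

from tensorica import (
    OmicsTensor,
    center_realisations,
    excess_kurtosis,
    fobi_rotation,
    jade_rotation,
    joint_diagonalize,
    mode_covariance,
    mode_multiply,
    project_mode1,
    rank_components,
    twfobi,
    twjade,
)
from tensorica.tica import TICAModel, _cumulant_matrices

from conftest import make_mixed_tensor, matched_abs_correlations


def md_index(G):
    """Minimum-distance index: 0 iff G is a signed permutation matrix."""
    d = G.shape[0]
    A = np.abs(G)
    perm = A.argmax(axis=1)
    if len(set(perm.tolist())) != d:
        return 1.0
    aligned = np.zeros_like(G)
    for i, j in enumerate(perm):
        aligned[i] = G[i] * np.sign(G[i, j])
    P = np.eye(d)[perm]
    return float(np.linalg.norm(aligned - P) / np.sqrt(d - 1)) if d > 1 else 0.0


class TestExcessKurtosis:
    def test_symmetric_two_point_is_minus_two(self):
        v = np.array([1.0, -1.0] * 50)
        assert excess_kurtosis(v) == pytest.approx(-2.0)

    def test_gaussian_limit(self, rng):
        assert abs(excess_kurtosis(rng.normal(size=200_000))) < 0.1

    def test_laplace_limit(self, rng):
        v = rng.laplace(0, 1, size=500_000)
        assert excess_kurtosis(v) == pytest.approx(3.0, abs=0.2)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            excess_kurtosis(np.ones(10))
        with pytest.raises(ValueError):
            excess_kurtosis(np.array([1.0, 2.0, 3.0]))


class TestJointDiagonalize:
    def test_already_diagonal_gives_identity(self):
        mats = [np.diag([3.0, 1.0, -2.0]), np.diag([0.5, 2.0, 1.0])]
        np.testing.assert_allclose(joint_diagonalize(mats), np.eye(3), atol=1e-12)

    def test_recovers_common_eigenbasis(self, rng):
        V = ortho_group.rvs(4, random_state=rng)
        mats = [V @ np.diag(d) @ V.T for d in ([4.0, 2.0, 1.0, -1.0], [1.0, 3.0, -2.0, 0.5])]
        U = joint_diagonalize(mats)
        assert md_index(U.T @ V) < 1e-8

    def test_single_matrix_matches_eigendecomposition_optimum(self, rng):
        A = rng.normal(size=(5, 5))
        A = A + A.T
        U = joint_diagonalize([A])
        off = lambda M: np.sum(M**2) - np.sum(np.diag(M) ** 2)
        assert off(U.T @ A @ U) < off(np.diag(np.diag(A)) + 0 * A) + 1e-10
        # eigendecomposition achieves zero off-diagonal mass; so must Jacobi
        assert off(U.T @ A @ U) < 1e-10

    def test_off_diagonal_mass_non_increasing_over_sweeps(self, rng):
        mats = [rng.normal(size=(4, 4)) for _ in range(3)]
        mats = [M + M.T for M in mats]
        off = lambda V: sum(
            np.sum((V.T @ M @ V) ** 2) - np.sum(np.diag(V.T @ M @ V) ** 2)
            for M in mats
        )
        prev = off(np.eye(4))
        for sweeps in (1, 2, 3, 5, 10):
            cur = off(joint_diagonalize(mats, max_sweeps=sweeps))
            assert cur <= prev + 1e-10
            prev = cur

    def test_asymmetric_input_rejected(self, rng):
        M = rng.normal(size=(3, 3))
        with pytest.raises(ValueError, match="symmetric"):
            joint_diagonalize([M])


def _whitened_sources(rng, dists, p):
    """Empirically standardised independent source matrix (len(dists), p)."""
    S = np.stack([d(p) for d in dists])
    S -= S.mean(axis=1, keepdims=True)
    S /= S.std(axis=1, keepdims=True)
    return S


class TestFobiRotation:
    def test_reduces_to_classical_fobi_on_vector_data(self, rng):
        # d_other = 1: B must equal the classical E[||x||^2 x x^T] matrix
        S = _whitened_sources(
            rng,
            [
                lambda s: rng.laplace(size=s),
                lambda s: rng.uniform(-1, 1, size=s),
                lambda s: rng.normal(size=s),
            ],
            5000,
        )
        Xw = OmicsTensor(S[:, None, :])  # (3, 1, p)
        U = fobi_rotation(Xw, 1)
        B = np.zeros((3, 3))
        for i in range(S.shape[1]):
            x = S[:, i]
            B += (x @ x) * np.outer(x, x)
        B /= S.shape[1]
        lam, vec = np.linalg.eigh(B)
        vec = vec[:, np.argsort(lam)[::-1]]
        for j in range(3):
            k = np.argmax(np.abs(vec[:, j]))
            if vec[k, j] < 0:
                vec[:, j] = -vec[:, j]
        np.testing.assert_allclose(U, vec, atol=1e-10)

    def test_independent_distinct_kurtosis_fibers_give_identity(self, rng):
        S = _whitened_sources(
            rng,
            [
                lambda s: rng.laplace(size=s),  # kurt 3
                lambda s: rng.normal(size=s),  # kurt 0
                lambda s: rng.uniform(-1, 1, size=s),  # kurt -1.2
            ],
            100_000,
        )
        U = fobi_rotation(OmicsTensor(S[:, None, :]), 1)
        assert md_index(U.T) < 0.05

    def test_gaussian_data_still_orthogonal(self, rng):
        Xw = OmicsTensor(rng.normal(size=(3, 2, 2000)))
        U = fobi_rotation(Xw, 1)
        np.testing.assert_allclose(U.T @ U, np.eye(3), atol=1e-10)

    def test_exactly_tied_spectrum_warns(self):
        Xw = OmicsTensor(np.zeros((3, 2, 10)))
        with pytest.warns(UserWarning, match="tied"):
            fobi_rotation(Xw, 1)


class TestJadeRotation:
    def test_recovers_known_orthogonal_mixing(self, rng):
        S = _whitened_sources(
            rng, [lambda s: rng.laplace(size=s)] * 4, 100_000
        )
        Q = ortho_group.rvs(4, random_state=rng)
        Xw = OmicsTensor(np.einsum("ij,jp->ip", Q, S)[None].transpose(1, 0, 2))
        # tensor (4, 1, p): mode-1 fibers are the mixed vectors
        U = jade_rotation(Xw, 1)
        assert md_index(U.T @ Q) < 0.05

    def test_dimension_one_returns_identity(self, rng):
        Xw = OmicsTensor(rng.normal(size=(1, 3, 500)))
        np.testing.assert_array_equal(jade_rotation(Xw, 1), np.eye(1))

    def test_gaussian_cumulant_matrices_vanish(self, rng):
        N, d = 100_000, 3
        R = rng.normal(size=(N, d))
        R -= R.mean(axis=0)
        R = R @ np.linalg.inv(np.linalg.cholesky((R.T @ R) / N)).T  # exact whiten
        mats = _cumulant_matrices(R)
        # entries of a 4th-moment mean have SE <= sqrt(105/N); 3x Frobenius bound
        bound = 3.0 * d * np.sqrt(105.0 / N)
        assert max(np.linalg.norm(C) for C in mats) < bound

    def test_insufficient_fibers_warn(self, rng):
        Xw = OmicsTensor(rng.normal(size=(4, 1, 10)))
        with pytest.warns(UserWarning, match="pooled fibers"):
            jade_rotation(Xw, 1)


class TestDrivers:
    @pytest.mark.parametrize("fit", [twfobi, twjade], ids=["twfobi", "twjade"])
    def test_source_recovery_identifiable_regime(self, fit):
        # mixed Laplace/uniform/Student-t sources: distinct kurtoses, so
        # both estimators are identifiable
        X, S, _, _ = make_mixed_tensor(seed=21, d1=2, d2=3, p=10000)
        model = fit(X, dims="full")
        corr = matched_abs_correlations(S, model.source.values)
        assert corr.min() > 0.95

    def test_twjade_recovers_iid_laplace_sources(self):
        rng = np.random.default_rng(8)
        S = rng.laplace(0, 1 / np.sqrt(2), (2, 3, 10000))
        O1 = ortho_group.rvs(2, random_state=rng)
        O2 = ortho_group.rvs(3, random_state=rng)
        X = OmicsTensor(np.einsum("ab,bcd,ec->aed", O1, S, O2))
        model = twjade(X, dims="full")
        corr = matched_abs_correlations(S, model.source.values)
        assert corr.min() > 0.95

    @pytest.mark.parametrize("fit", [twfobi, twjade], ids=["twfobi", "twjade"])
    def test_gaussian_only_tensor_gives_small_kurtosis(self, fit):
        rng = np.random.default_rng(0)
        X = OmicsTensor(rng.normal(size=(2, 3, 10000)))
        model = fit(X, dims="full")
        assert np.abs(model.kurtosis).mean() < 0.1
        for W, A in zip(model.unmixing, model.mixing):
            np.testing.assert_allclose(W @ A, np.eye(W.shape[0]), atol=1e-8)

    @pytest.mark.parametrize("fit", [twfobi, twjade], ids=["twfobi", "twjade"])
    def test_deterministic(self, fit, default_dataset):
        m1 = fit(default_dataset.tensor, dims=(2, 6))
        m2 = fit(default_dataset.tensor, dims=(2, 6))
        np.testing.assert_array_equal(m1.source.values, m2.source.values)
        np.testing.assert_array_equal(m1.unmixing[1], m2.unmixing[1])

    def test_source_slices_centered_unit_variance_under_model(self):
        X, S, _, _ = make_mixed_tensor(seed=3, d1=2, d2=3, p=10000)
        model = twjade(X, dims="full")
        assert np.abs(model.source.values.mean(axis=2)).max() < 1e-8
        # variance exact for the last-whitened mode, O(1/sqrt(p)) overall
        assert np.abs(model.source.values.var(axis=2) - 1).max() < 0.05

    def test_source_mode_covariances_near_diagonal(self, default_dataset):
        model = twjade(default_dataset.tensor, dims=(2, 6))
        C2 = mode_covariance(model.source, 2)
        off2 = np.abs(C2 - np.diag(np.diag(C2))).max()
        assert off2 < 1e-6 * np.trace(C2)  # exact: whitening + orthogonal rotation
        C1 = mode_covariance(model.source, 1)
        off1 = np.abs(C1 - np.diag(np.diag(C1))).max()
        assert off1 < 1e-2 * np.trace(C1)  # first-whitened mode: finite-sample

    def test_unmixing_composes_whitening_and_rotation(self, default_dataset):
        X = default_dataset.tensor
        model = twfobi(X, dims=(2, 6))
        Xc, _ = center_realisations(X)
        direct = mode_multiply(
            mode_multiply(Xc, model.unmixing[0], 1), model.unmixing[1], 2
        )
        np.testing.assert_allclose(direct.values, model.source.values, atol=1e-8)

    @pytest.mark.parametrize("fit", [twfobi, twjade], ids=["twfobi", "twjade"])
    def test_equivariance_under_mode2_rotation(self, fit):
        X, S, _, _ = make_mixed_tensor(seed=13, d1=2, d2=3, p=10000)
        rng = np.random.default_rng(99)
        Q = ortho_group.rvs(X.shape[1], random_state=rng)
        m0 = fit(X, dims="full")
        m1 = fit(mode_multiply(X, Q, 2), dims="full")
        corr = matched_abs_correlations(m0.source.values, m1.source.values)
        assert corr.min() > 0.95

    @pytest.mark.parametrize("fit", [twfobi, twjade], ids=["twfobi", "twjade"])
    def test_recovery_error_decreases_with_p(self, fit):
        """Median worst-component mismatch shrinks as p grows."""
        med = []
        for p in (1000, 5000, 20000):
            errs = []
            for seed in range(20):
                X, S, _, _ = make_mixed_tensor(seed=1000 + seed, d1=2, d2=3, p=p)
                model = fit(X, dims="full")
                corr = matched_abs_correlations(S, model.source.values)
                errs.append(1.0 - corr.min())
            med.append(np.median(errs))
        assert med[0] >= med[1] >= med[2]
        assert med[2] < 0.05


class TestRanking:
    def _toy_model(self, kurt, p=200):
        d1, d2 = kurt.shape
        rng = np.random.default_rng(0)
        S = OmicsTensor(rng.normal(size=(d1, d2, p)))
        eye1, eye2 = np.eye(d1), np.eye(d2)
        return TICAModel(
            unmixing=(eye1, eye2),
            mixing=(eye1, eye2),
            source=S,
            offsets=np.zeros((d1, d2)),
            kurtosis=np.asarray(kurt, dtype=float),
            order=np.argsort(-np.asarray(kurt).max(axis=0), kind="stable"),
            whitening=None,
            method="toy",
        )

    def test_equal_kurtoses_keep_natural_order(self):
        model = self._toy_model(np.ones((2, 4)))
        table = rank_components(model)
        assert table[table["mode1_index"] == 0]["component"].tolist() == [0, 1, 2, 3]

    def test_heavy_tailed_component_ranked_first(self, default_dataset):
        model = twfobi(default_dataset.tensor, dims=(2, 6))
        table = rank_components(model)
        first = table.iloc[0]
        assert first["max_kurtosis"] == model.kurtosis.max()
        # simulated JV/IV sources are sparse: top component is heavy-tailed
        assert first["max_kurtosis"] > 1.0

    def test_order_invariant_under_feature_permutation(self, default_dataset):
        X = default_dataset.tensor
        perm = np.random.default_rng(5).permutation(X.shape[2])
        Xp = OmicsTensor(X.values[:, :, perm])
        m0 = twfobi(X, dims=(2, 6))
        m1 = twfobi(Xp, dims=(2, 6))
        np.testing.assert_array_equal(m0.order, m1.order)


class TestProjectMode1:
    def test_identity_mixing_returns_source(self):
        model = TestRanking()._toy_model(np.ones((2, 3)))
        np.testing.assert_array_equal(
            project_mode1(model).values, model.source.values
        )

    def test_known_mixing_matches_contraction_loop(self, rng):
        model = twfobi(
            OmicsTensor(rng.normal(size=(2, 5, 3000))), dims=(2, 3)
        )
        proj = project_mode1(model)
        A1 = model.mixing[0]
        S = model.source.values
        expected = np.zeros_like(proj.values)
        for i1 in range(2):
            for j in range(2):
                expected[i1] += S[j] * A1[i1, j]
        np.testing.assert_allclose(proj.values, expected, atol=1e-12)

    def test_roundtrip_through_unmixing(self, default_dataset):
        model = twjade(default_dataset.tensor, dims=(2, 6))
        proj = project_mode1(model)
        back = mode_multiply(proj, model.unmixing[0], 1)
        np.testing.assert_allclose(back.values, model.source.values, atol=1e-8)

    def test_reduced_mode1_unsupported(self, rng):
        model = twfobi(OmicsTensor(rng.normal(size=(3, 4, 500))), dims=(2, 3))
        with pytest.raises(ValueError, match="unreduced"):
            project_mode1(model)
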