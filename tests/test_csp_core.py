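"""Common-spatial-pattern algebra: covariances, whitening, diagonalization."""

import numpy as np
import pytest
import scipy.linalg

from sccsp import csp_core
from sccsp.errors import DegenerateDataError, RankDeficiencyError

from conftest import random_spd


class TestClassCovariance:
    def test_single_trial_has_unit_trace(self, rng):
        y = rng.standard_normal((4, 100))
        c = csp_core.class_covariance([y])
        assert abs(np.trace(c) - 1.0) < 1e-12

    def test_orthogonal_equal_norm_rows_give_scaled_identity(self, rng):
        # rows of an orthogonal matrix scaled equally: Y Y^T = c I
        q, _ = np.linalg.qr(rng.standard_normal((8, 8)))
        y = q[:4] * 3.0
        c = csp_core.class_covariance([y])
        assert np.abs(c - np.eye(4) / 4).max() < 1e-10

    def test_duplicated_trial_changes_nothing(self, rng):
        y = rng.standard_normal((3, 50))
        assert np.allclose(
            csp_core.class_covariance([y, y]), csp_core.class_covariance([y])
        )

    def test_zero_power_trial_raises(self):
        with pytest.raises(DegenerateDataError, match="trial 1"):
            csp_core.class_covariance([np.ones((2, 10)), np.zeros((2, 10))])


class TestWhiten:
    def test_closed_form_for_scaled_identity(self):
        # whitening I/p is sqrt(p) times an orthogonal (here: permuted identity)
        p = 5
        P = csp_core.whiten(np.eye(p) / p)
        assert np.abs(P @ P.T - p * np.eye(p)).max() < 1e-10
        assert np.abs(P @ (np.eye(p) / p) @ P.T - np.eye(p)).max() < 1e-10

    @pytest.mark.parametrize("seed", range(20))
    def test_whitens_random_spd(self, seed):
        rng = np.random.default_rng(seed)
        c = random_spd(rng, 6)
        P = csp_core.whiten(c)
        assert np.abs(P @ c @ P.T - np.eye(6)).max() < 1e-8

    def test_singular_matrix_raises(self):
        c = np.diag([1.0, 0.0])
        with pytest.raises(RankDeficiencyError, match="ridge"):
            csp_core.whiten(c)


class TestSimultaneousDiagonalize:
    def test_equal_covariances_give_half_eigenvalues(self, rng):
        c = random_spd(rng, 4)
        model = csp_core.simultaneous_diagonalize(c, c)
        assert np.abs(model.D1 - np.eye(4) / 2).max() < 1e-8

    @pytest.mark.parametrize("seed", range(10))
    def test_complementary_diagonals(self, seed):
        rng = np.random.default_rng(seed)
        c1, c2 = random_spd(rng, 5), random_spd(rng, 5)
        m = csp_core.simultaneous_diagonalize(c1, c2)
        z1 = m.K @ c1 @ m.K.T
        z2 = m.K @ c2 @ m.K.T
        # both projected covariances diagonal, diagonals summing to one
        assert np.abs(z1 - np.diag(np.diag(z1))).max() < 1e-8
        assert np.abs(z2 - np.diag(np.diag(z2))).max() < 1e-8
        assert np.abs(np.diag(z1) + np.diag(z2) - 1.0).max() < 1e-8

    def test_commuting_diagonal_case_isolates_channels(self):
        c1 = np.diag([0.9, 0.1])
        c2 = np.diag([0.1, 0.9])
        m = csp_core.simultaneous_diagonalize(c1, c2)
        assert np.abs(np.diag(m.D1) - [0.9, 0.1]).max() < 1e-8
        # first filter row reads channel 1 only, last reads channel 2 only
        assert abs(m.K[0, 1]) < 1e-8 and abs(m.K[0, 0]) > 0
        assert abs(m.K[1, 0]) < 1e-8 and abs(m.K[1, 1]) > 0

    def test_class_swap_antisymmetry(self, rng):
        c1, c2 = random_spd(rng, 4), random_spd(rng, 4)
        m12 = csp_core.simultaneous_diagonalize(c1, c2)
        m21 = csp_core.simultaneous_diagonalize(c2, c1)
        assert np.abs(np.diag(m21.D1)[::-1] + np.diag(m12.D1) - 1.0).max() < 1e-8
        y = rng.standard_normal((4, 200))
        f12 = csp_core.feature(m12, y)
        f21 = csp_core.feature(m21, y)
        assert abs(f12 + f21 - 1.0) < 1e-10

    @pytest.mark.parametrize("p", [2, 3])
    def test_matches_generalized_eigenproblem_oracle(self, rng, p):
        c1, c2 = random_spd(rng, p), random_spd(rng, p)
        m = csp_core.simultaneous_diagonalize(c1, c2)
        evals, evecs = scipy.linalg.eigh(c1, c1 + c2)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        assert np.abs(np.diag(m.D1) - evals).max() < 1e-8
        for i in range(p):
            v = evecs[:, i]
            cos = m.K[i] @ v / (np.linalg.norm(m.K[i]) * np.linalg.norm(v))
            assert abs(abs(cos) - 1.0) < 1e-8  # same direction up to sign
            assert abs(np.linalg.norm(m.K[i]) - np.linalg.norm(v)) < 1e-6


class TestProjectAndFeature:
    def test_identity_and_zero(self, rng):
        c = random_spd(rng, 3)
        m = csp_core.simultaneous_diagonalize(c, c)
        assert np.allclose(csp_core.project(m, np.zeros((3, 10))), 0.0)

    def test_project_matches_bruteforce_product(self, rng):
        c1, c2 = random_spd(rng, 3), random_spd(rng, 3)
        m = csp_core.simultaneous_diagonalize(c1, c2)
        y = rng.standard_normal((3, 7))
        z = csp_core.project(m, y)
        brute = np.zeros_like(z)
        for i in range(3):
            for j in range(7):
                for k in range(3):
                    brute[i, j] += m.K[i, k] * y[k, j]
        assert np.abs(z - brute).max() < 1e-12

    def test_feature_arithmetic(self, rng):
        # identity filter, rows with sample variance ratio 3:1 -> f = 0.75
        eye = csp_core.CSPModel(
            P=np.eye(2), R=np.eye(2), D1=np.eye(2) / 2, D2=np.eye(2) / 2,
            K=np.eye(2), filter_rows_used=(0, 1),
        )
        base = rng.standard_normal(50)
        trial = np.vstack([np.sqrt(3.0) * base, base])
        assert abs(csp_core.feature(eye, trial) - 0.75) < 1e-12
        symmetric = np.vstack([base, base])
        assert csp_core.feature(eye, symmetric) == 0.5
        with_const = np.vstack([base, np.ones(50)])
        assert csp_core.feature(eye, with_const) == 1.0

    def test_feature_invariant_to_trial_scaling(self, rng):
        c1, c2 = random_spd(rng, 4), random_spd(rng, 4)
        m = csp_core.simultaneous_diagonalize(c1, c2)
        y = rng.standard_normal((4, 100))
        assert abs(csp_core.feature(m, y) - csp_core.feature(m, -7.3 * y)) < 1e-10

    def test_feature_vector_extends_scalar(self, rng):
        c1, c2 = random_spd(rng, 4), random_spd(rng, 4)
        m = csp_core.simultaneous_diagonalize(c1, c2)
        y = rng.standard_normal((4, 100))
        v = csp_core.feature_vector(m, y, n_pairs=1)
        assert abs(v.sum() - 1.0) < 1e-12
        assert abs(v[0] - csp_core.feature(m, y)) < 1e-12
        v2 = csp_core.feature_vector(m, y, n_pairs=2)
        assert v2.shape == (4,) and abs(v2.sum() - 1.0) < 1e-12
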