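"""Rate-matrix algebra and the ENS integral."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.linalg import null_space

from ensdist import (
    EdgeProcess,
    ValidationError,
    calibrate,
    ens,
    ens_quadrature,
    ens_stationary,
    f81_closed_form_ens,
    f81_rate_matrix,
    jc_rate_matrix,
    make_rate_matrix,
    solve_ens_duration,
    stationary_distribution,
    substitution_rate,
    transition_matrix,
)
from ensdist.substitution import _ScaledEnsProfile

from conftest import random_distribution, random_rate_matrix

F81_PI = np.array([0.5, 0.2, 0.1, 0.2])


class TestMakeRateMatrix:
    def test_jc_diagonal(self):
        Q = jc_rate_matrix()
        assert np.allclose(np.diag(Q), -1.0)
        assert np.allclose(Q.sum(axis=1), 0.0)

    def test_f81_rows_sum_to_zero(self):
        Q = f81_rate_matrix(F81_PI, alpha=1.0)
        assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-14)

    def test_off_diagonals_preserved(self, rng):
        off = rng.uniform(0.01, 2.0, size=12)
        Q = make_rate_matrix(off)
        flat = [Q[i, j] for i in range(4) for j in range(4) if i != j]
        assert np.allclose(flat, off)
        assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-12)

    @pytest.mark.parametrize(
        "bad",
        [np.full(12, -0.1), np.full(11, 0.5), np.r_[np.full(11, 0.5), np.nan]],
        ids=["negative", "wrong-length", "nan"],
    )
    def test_invalid_input_rejected(self, bad):
        with pytest.raises(ValidationError):
            make_rate_matrix(bad)


class TestStationaryDistribution:
    def test_jc_uniform(self):
        assert np.allclose(stationary_distribution(jc_rate_matrix()), 0.25)

    def test_f81_returns_its_pi(self):
        pi = stationary_distribution(f81_rate_matrix(F81_PI))
        assert np.allclose(pi, F81_PI, atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_null_space_oracle(self, seed):
        rng = np.random.default_rng(seed)
        Q = random_rate_matrix(rng)
        pi = stationary_distribution(Q)
        assert np.linalg.norm(pi @ Q, np.inf) < 1e-10
        ns = null_space(Q.T)
        assert ns.shape[1] == 1
        oracle = ns[:, 0] / ns[:, 0].sum()
        assert np.allclose(pi, oracle, atol=1e-9)

    def test_reducible_generator_rejected(self):
        # two disconnected 2-state blocks: no unique stationary distribution
        Q = np.array(
            [
                [-1.0, 1.0, 0.0, 0.0],
                [1.0, -1.0, 0.0, 0.0],
                [0.0, 0.0, -1.0, 1.0],
                [0.0, 0.0, 1.0, -1.0],
            ]
        )
        with pytest.raises(ValidationError):
            stationary_distribution(Q)


class TestCalibrate:
    def test_jc_already_calibrated(self):
        Q = jc_rate_matrix()
        assert np.allclose(calibrate(Q), Q)

    def test_f81_rate_is_sum_pi_one_minus_pi(self):
        # -sum pi_i Q_ii = alpha * sum pi_i (1 - pi_i) = 0.66 for this pi
        Q = f81_rate_matrix(F81_PI, alpha=1.0)
        assert substitution_rate(Q) == pytest.approx(0.66, abs=1e-12)
        assert np.allclose(calibrate(Q), Q / 0.66)

    @pytest.mark.parametrize("seed", range(3))
    def test_idempotent(self, seed):
        Q = random_rate_matrix(np.random.default_rng(seed))
        once = calibrate(Q)
        assert np.allclose(calibrate(once), once, atol=1e-12)
        assert substitution_rate(once) == pytest.approx(1.0, abs=1e-10)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(c=st.floats(1e-3, 1e3), seed=st.integers(0, 100))
    def test_scale_equivariant(self, c, seed):
        Q = random_rate_matrix(np.random.default_rng(seed))
        assert np.allclose(calibrate(c * Q), calibrate(Q), atol=1e-9)

    def test_zero_rate_rejected(self):
        with pytest.raises(ValidationError):
            calibrate(np.zeros((4, 4)))


class TestTransitionMatrix:
    def test_zero_duration_is_identity(self, rng):
        Q = random_rate_matrix(rng)
        assert np.array_equal(transition_matrix(Q, 0.0), np.eye(4))

    @pytest.mark.parametrize("t", [0.01, 0.3, 1.0, 4.0])
    def test_jc_spectral_form(self, t):
        # JC diagonal: 1/4 + 3/4 exp(-4t/3) for the calibrated generator
        P = transition_matrix(jc_rate_matrix(), t)
        expected_diag = 0.25 + 0.75 * np.exp(-4.0 * t / 3.0)
        assert np.allclose(np.diag(P), expected_diag, atol=1e-12)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_eigendecomposition_oracle(self, seed):
        rng = np.random.default_rng(seed)
        Q = random_rate_matrix(rng)
        t = rng.uniform(0.05, 3.0)
        lam, V = np.linalg.eig(Q)
        oracle = np.real(V @ np.diag(np.exp(lam * t)) @ np.linalg.inv(V))
        assert np.allclose(transition_matrix(Q, t), oracle, atol=1e-9)


class TestEns:
    """The three-route evaluation of the nonstationary ENS."""

    @pytest.mark.parametrize(
        "f0,expected",
        [
            (F81_PI, 0.99),
            ((0.1, 0.3, 0.2, 0.4), 1.09),
            ((0.6, 0.2, 0.1, 0.1), 0.97),
        ],
        ids=["stationary", "understating-start", "overstating-start"],
    )
    def test_f81_worked_example_three_routes(self, f0, expected):
        Q = f81_rate_matrix(F81_PI, alpha=1.0)
        assert round(ens(f0, Q, 1.5), 2) == expected
        assert round(ens_quadrature(f0, Q, 1.5), 2) == expected
        assert round(f81_closed_form_ens(F81_PI, 1.0, 1.5, f0), 2) == expected

    def test_zero_duration(self, rng):
        assert ens(random_distribution(rng), random_rate_matrix(rng), 0.0) == 0.0

    @pytest.mark.parametrize("t", [0.1, 0.7, 2.5])
    def test_calibrated_stationary_equals_duration(self, t, rng):
        Q = calibrate(random_rate_matrix(rng))
        pi = stationary_distribution(Q)
        assert ens(pi, Q, t) == pytest.approx(t, abs=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_monotone_in_duration(self, seed):
        rng = np.random.default_rng(seed)
        Q = random_rate_matrix(rng)
        f0 = random_distribution(rng)
        values = [ens(f0, Q, t) for t in np.linspace(0.0, 4.0, 30)]
        assert np.all(np.diff(values) >= -1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_quadrature_agreement(self, seed):
        rng = np.random.default_rng(seed)
        Q = random_rate_matrix(rng)
        f0 = random_distribution(rng)
        t = rng.uniform(0.05, 5.0)
        assert abs(ens(f0, Q, t) - ens_quadrature(f0, Q, t)) < 1e-6

    @pytest.mark.parametrize("seed", range(5))
    def test_stationary_start_matches_linear_formula(self, seed):
        rng = np.random.default_rng(seed)
        Q = random_rate_matrix(rng)
        pi = stationary_distribution(Q)
        t = rng.uniform(0.1, 3.0)
        assert ens(pi, Q, t) == pytest.approx(ens_stationary(pi, Q, t), abs=1e-10)

    def test_stationary_survives_gamma_rate_mixing(self, rng):
        # iterated expectation over fixed rate multipliers preserves the
        # stationary linear-in-t formula
        from ensdist import discrete_gamma_rates

        Q = calibrate(random_rate_matrix(rng))
        pi = stationary_distribution(Q)
        t = 0.8
        rates = discrete_gamma_rates(0.7, 4)
        mixed = np.mean([ens(pi, Q, t * r) for r in rates])
        assert mixed == pytest.approx(ens_stationary(pi, Q, t), abs=1e-10)


class TestF81ClosedForm:
    @pytest.mark.parametrize("seed", range(8))
    def test_equals_augmented_matrix_route(self, seed):
        rng = np.random.default_rng(seed)
        pi = random_distribution(rng)
        f0 = random_distribution(rng)
        alpha = rng.uniform(0.2, 3.0)
        t = rng.uniform(0.05, 4.0)
        Q = f81_rate_matrix(pi, alpha)
        assert f81_closed_form_ens(pi, alpha, t, f0) == pytest.approx(
            ens(f0, Q, t), abs=1e-10
        )

    def test_uniform_pi_has_no_correction(self, rng):
        # correction vanishes for uniform pi regardless of the start
        pi = np.full(4, 0.25)
        for _ in range(5):
            f0 = random_distribution(rng)
            alpha, t = rng.uniform(0.2, 3.0), rng.uniform(0.1, 3.0)
            assert f81_closed_form_ens(pi, alpha, t, f0) == pytest.approx(
                0.75 * alpha * t, abs=1e-12
            )

    def test_stationary_start_reduces_to_linear_form(self, rng):
        pi = random_distribution(rng)
        assert f81_closed_form_ens(pi, 1.3, 2.0, pi) == pytest.approx(
            ens_stationary(pi, f81_rate_matrix(pi, 1.3), 2.0), abs=1e-12
        )


class TestScaledProfileAndSolve:
    @pytest.mark.parametrize("seed", range(5))
    def test_profile_matches_ens(self, seed):
        rng = np.random.default_rng(seed)
        A = random_rate_matrix(rng)
        f0 = random_distribution(rng)
        profile = _ScaledEnsProfile(f0, A)
        for s in [0.0, 0.05, 0.5, 2.0]:
            assert profile(s) == pytest.approx(ens(f0, A, s), abs=1e-10)

    @pytest.mark.parametrize("target", [0.01, 0.3, 1.5])
    def test_solve_roundtrip(self, target, rng):
        A = random_rate_matrix(rng)
        f0 = random_distribution(rng)
        s = solve_ens_duration(f0, A, target)
        assert ens(f0, A, s) == pytest.approx(target, abs=1e-9)

    def test_zero_target(self, rng):
        assert solve_ens_duration(random_distribution(rng), random_rate_matrix(rng), 0.0) == 0.0


class TestEdgeProcess:
    def test_scaled_product(self, rng):
        Q = random_rate_matrix(rng)
        edge = EdgeProcess(Q, 0.4)
        assert np.allclose(edge.scaled, Q * 0.4)
        assert edge.ens(stationary_distribution(Q)) == pytest.approx(
            ens_stationary(stationary_distribution(Q), Q, 0.4), abs=1e-10
        )

    def test_negative_duration_rejected(self, rng):
        with pytest.raises(ValidationError):
            EdgeProcess(random_rate_matrix(rng), -0.1)
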