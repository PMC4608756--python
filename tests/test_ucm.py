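"""UCM variance decomposition, synergy indices and Fisher Z transform."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from synergy import (
    delta_v,
    fisher_z,
    inverse_fisher_z,
    no_coordination_value,
    null_basis,
    ratio_of_change,
    ucm_decompose,
)


def brute_force_components(trials, A):
    """Oracle: orthogonal part via explicit row-space least squares."""
    T = np.asarray(trials, float)
    A = np.atleast_2d(np.asarray(A, float))
    N, n = T.shape
    d = A.shape[0]
    dev = T - T.mean(axis=0)
    # orthogonal complement of the null space is the row space of A:
    # per trial, solve min ||dev - A.T c|| for c (normal equations)
    C = np.linalg.solve(A @ A.T, A @ dev.T)  # (d, N)
    ort = (A.T @ C).T
    par = dev - ort
    v_ucm = np.sum(par**2) / N / (n - d)
    v_ort = np.sum(ort**2) / N / d
    v_tot = np.sum(dev**2) / N / n
    return v_ucm, v_ort, v_tot


class TestNullBasis:
    def test_two_element_sum_map(self):
        E = null_basis(np.array([[1.0, 1.0]]))
        assert E.shape == (2, 1)
        assert np.allclose(np.abs(E[:, 0]), 1 / np.sqrt(2))
        assert np.allclose(np.array([[1.0, 1.0]]) @ E, 0, atol=1e-14)

    def test_axis_map_leaves_coordinate_plane(self):
        E = null_basis(np.array([[1.0, 0.0, 0.0]]))
        assert E.shape == (3, 2)
        assert np.allclose(E[0, :], 0, atol=1e-14)
        assert np.allclose(E.T @ E, np.eye(2), atol=1e-12)

    def test_random_wide_map_orthonormal(self, rng):
        A = rng.normal(size=(2, 8))
        E = null_basis(A)
        assert E.shape == (8, 6)
        assert np.allclose(A @ E, 0, atol=1e-12)
        assert np.allclose(E.T @ E, np.eye(6), atol=1e-12)

    def test_sign_convention_deterministic(self, rng):
        A = rng.normal(size=(1, 5))
        E = null_basis(A)
        for j in range(E.shape[1]):
            lead = E[:, j][np.abs(E[:, j]) > 1e-12][0]
            assert lead > 0

    def test_rank_deficient_rejected(self):
        with pytest.raises(ValueError):
            null_basis(np.array([[1.0, 1.0, 1.0], [2.0, 2.0, 2.0]]))


class TestUCMDecompose:
    def test_hand_computed_two_muscle_case(self):
        # deviations (+-0.5, -+0.5) lie exactly in the null space of [1, 1]
        res = ucm_decompose(np.array([[1.0, 0.0], [0.0, 1.0]]), [[1.0, 1.0]])
        assert res.v_ucm == pytest.approx(0.5)
        assert res.v_ort == pytest.approx(0.0, abs=1e-15)
        assert res.v_tot == pytest.approx(0.25)
        assert res.delta_v == pytest.approx(2.0)

    def test_row_space_deviations_have_zero_ucm(self):
        res = ucm_decompose(np.array([[1.0, 1.0], [2.0, 2.0]]), [[1.0, 1.0]])
        assert res.v_ucm == pytest.approx(0.0, abs=1e-15)
        assert res.delta_v == pytest.approx(-2.0)

    def test_isotropic_noise_centres_on_zero(self, rng):
        T = rng.standard_normal((100_000, 8))
        A = rng.normal(size=(1, 8))
        res = ucm_decompose(T, A)
        assert abs(res.delta_v) < 0.05

    def test_conservation_identity(self, rng):
        for _ in range(50):
            n = rng.integers(3, 9)
            d = rng.integers(1, min(3, n))
            T = rng.standard_normal((rng.integers(2, 30), n))
            A = rng.normal(size=(d, n))
            r = ucm_decompose(T, A)
            lhs = r.n * r.v_tot
            rhs = (r.n - r.d) * r.v_ucm + r.d * r.v_ort
            assert abs(lhs - rhs) <= 1e-10 * max(abs(lhs), 1e-300)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            n = rng.integers(3, 5)
            d = rng.integers(1, n - 1)
            T = rng.standard_normal((10, n))
            A = rng.normal(size=(d, n))
            r = ucm_decompose(T, A)
            v_ucm, v_ort, v_tot = brute_force_components(T, A)
            assert r.v_ucm == pytest.approx(v_ucm, abs=1e-10)
            assert r.v_ort == pytest.approx(v_ort, abs=1e-10)
            assert r.v_tot == pytest.approx(v_tot, abs=1e-10)

    def test_invariant_to_row_rescaling_of_map(self, rng):
        # any invertible recombination of A's rows spans the same spaces
        T = rng.standard_normal((30, 6))
        A = rng.normal(size=(2, 6))
        R = np.array([[2.0, 1.0], [0.0, -3.0]])
        r1 = ucm_decompose(T, A)
        r2 = ucm_decompose(T, R @ A)
        assert r1.v_ucm == pytest.approx(r2.v_ucm, rel=1e-10)
        assert r1.v_ort == pytest.approx(r2.v_ort, rel=1e-10)

    def test_ddof_option(self, rng):
        T = rng.standard_normal((10, 4))
        A = np.ones((1, 4))
        r0 = ucm_decompose(T, A, ddof=0)
        r1 = ucm_decompose(T, A, ddof=1)
        assert r1.v_tot == pytest.approx(r0.v_tot * 10 / 9)

    def test_single_trial_rejected(self):
        with pytest.raises(ValueError):
            ucm_decompose(np.ones((1, 3)), np.ones((1, 3)))


class TestSynergyIndices:
    def test_equal_components_give_zero(self):
        for v in (0.1, 1.0, 7.3):
            assert delta_v(v, v, v) == 0.0

    def test_bounds_for_eight_muscles_one_torque(self):
        # v_ort = 0: dV = n/(n-d) = 8/7; v_ucm = 0: dV = -n/d = -8
        # via the conservation identity n*v_tot = (n-d)*v_ucm + d*v_ort
        v = 1.0
        assert delta_v(v, 0.0, 7 * v / 8) == pytest.approx(8 / 7)
        assert delta_v(0.0, v, v / 8) == pytest.approx(-8.0)

    def test_zero_total_variance_rejected(self):
        with pytest.raises(ValueError):
            delta_v(0.0, 0.0, 0.0)

    def test_fisher_z_no_coordination_anchor(self):
        assert fisher_z(0.0, 8, 1) == pytest.approx(np.log(7))
        assert round(fisher_z(0.0, 8, 1), 2) == 1.95

    def test_fisher_z_symmetric_case(self):
        assert fisher_z(0.0, 2, 1) == pytest.approx(0.0)

    def test_fisher_z_monotone(self):
        grid = np.linspace(-7.9, 8 / 7 - 0.01, 50)
        vals = [fisher_z(g, 8, 1) for g in grid]
        assert np.all(np.diff(vals) > 0)

    def test_fisher_z_diverges_at_bounds(self):
        with pytest.warns(RuntimeWarning):
            assert fisher_z(8 / 7, 8, 1) == np.inf
        with pytest.warns(RuntimeWarning):
            assert fisher_z(-8.0, 8, 1) == -np.inf

    def test_round_trip_inverse(self, rng):
        for dv in rng.uniform(-7.9, 1.1, 20):
            assert inverse_fisher_z(fisher_z(dv, 8, 1), 8, 1) == pytest.approx(
                dv, abs=1e-12
            )

    def test_no_coordination_value_depends_on_dimensions(self):
        assert no_coordination_value(8, 1) == pytest.approx(np.log(7))
        assert no_coordination_value(2, 1) == 0.0
        assert no_coordination_value(4, 2) == 0.0  # (n/d) == n/(n-d)
        assert no_coordination_value(8, 2) == pytest.approx(np.log(3.0))


class TestPropertyBased:
    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1), n=st.integers(3, 8), d=st.integers(1, 2))
    def test_conservation_holds_for_arbitrary_instances(self, seed, n, d):
        rng = np.random.default_rng(seed)
        T = rng.standard_normal((int(rng.integers(2, 20)), n))
        A = rng.normal(size=(d, n))
        r = ucm_decompose(T, A)
        lhs = n * r.v_tot
        rhs = (n - d) * r.v_ucm + d * r.v_ort
        assert abs(lhs - rhs) <= 1e-10 * max(abs(lhs), 1e-300)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(dv=st.floats(-7.99, 8 / 7 - 1e-3), )
    def test_fisher_z_round_trips(self, dv):
        assert inverse_fisher_z(fisher_z(dv, 8, 1), 8, 1) == pytest.approx(
            dv, abs=1e-9
        )


class TestRatioOfChange:
    def test_identical_changes(self):
        assert ratio_of_change(2.0, 1.5, 2.2, 1.7) == pytest.approx(100.0)

    def test_no_normalized_change(self):
        assert ratio_of_change(2.0, 1.5, 2.0, 2.0) == pytest.approx(0.0)

    def test_partial_change(self):
        assert ratio_of_change(2.0, 1.5, 2.0, 1.6) == pytest.approx(80.0)

    def test_zero_measured_change_rejected(self):
        with pytest.raises(ValueError):
            ratio_of_change(2.0, 2.0, 1.0, 1.5)
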