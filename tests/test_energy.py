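import numpy as np
import pytest
from scipy.special import softmax

from spatialforces.energy import (
    GeneGeneForces,
    ModelConfig,
    empirical_moments,
    expression_gradient,
    flatten_forces,
    force_gradients,
    interaction_energy,
    local_field,
    loss,
    mean_field_log_partition,
)


def _forces(gi, gq, names=None):
    gi = np.asarray(gi, float)
    names = names or [f"g{i}" for i in range(gi.shape[0])]
    return GeneGeneForces(gi, np.asarray(gq, float), names)


ONE_HOT_S = np.eye(2)
SWAP_J = np.array([[0.0, 1.0], [1.0, 0.0]])


class TestLocalField:
    def test_zero_forces_zero_field(self, random_state_5x3, small_slide):
        f = _forces(np.zeros((3, 3)), np.zeros((3, 3)))
        J = np.zeros((5, 5))
        assert np.array_equal(local_field(random_state_5x3, J, f), np.zeros((5, 3)))

    def test_one_hot_cells_neighbor_swap(self):
        # S = I, J swaps the two cells, g_inter swaps the two genes -> Z = I
        f = _forces(SWAP_J, np.zeros((2, 2)))
        assert np.array_equal(local_field(ONE_HOT_S, SWAP_J, f), np.eye(2))

    def test_identity_intra_no_edges_returns_state(self, random_state_5x3):
        f = _forces(np.zeros((3, 3)), np.eye(3))
        Z = local_field(random_state_5x3, np.zeros((5, 5)), f)
        assert np.allclose(Z, random_state_5x3)

    def test_dimension_mismatch_names_operand(self, random_state_5x3):
        f = _forces(np.zeros((4, 4)), np.zeros((4, 4)))
        with pytest.raises(ValueError, match="g_inter"):
            local_field(random_state_5x3, np.zeros((5, 5)), f)
        with pytest.raises(ValueError, match="adjacency"):
            local_field(random_state_5x3, np.zeros((4, 4)),
                        _forces(np.zeros((3, 3)), np.zeros((3, 3))))


class TestInteractionEnergy:
    def test_zero_forces(self, random_state_5x3):
        f = _forces(np.zeros((3, 3)), np.zeros((3, 3)))
        assert interaction_energy(random_state_5x3, np.zeros((5, 5)), f) == 0.0

    def test_one_hot_swap_energy_two(self):
        f = _forces(SWAP_J, np.zeros((2, 2)))
        assert interaction_energy(ONE_HOT_S, SWAP_J, f) == pytest.approx(2.0)

    def test_matches_explicit_double_sum(self, rng):
        S = rng.uniform(0, 1, (5, 3))
        J = (rng.uniform(0, 1, (5, 5)) < 0.4).astype(float)
        J = np.triu(J, 1)
        J = J + J.T
        gi = rng.normal(size=(3, 3))
        gq = rng.normal(size=(3, 3))
        total = 0.0
        for a in range(3):
            for b in range(3):
                for i in range(5):
                    total += S[i, a] * gq[a, b] * S[i, b]
                    for j in range(5):
                        total += S[i, a] * J[i, j] * gi[a, b] * S[j, b]
        assert interaction_energy(S, J, _forces(gi, gq)) == pytest.approx(
            total, abs=1e-10
        )


class TestEmpiricalMoments:
    def test_one_hot_swap(self):
        c_inter, c_intra = empirical_moments(ONE_HOT_S, SWAP_J)
        assert np.array_equal(c_inter, SWAP_J)
        assert np.array_equal(c_intra, np.eye(2))

    def test_no_edges_zero_inter(self, random_state_5x3):
        c_inter, _ = empirical_moments(random_state_5x3, np.zeros((5, 5)))
        assert np.array_equal(c_inter, np.zeros((3, 3)))

    def test_intra_trace_equals_n_cells(self, random_state_5x3):
        _, c_intra = empirical_moments(random_state_5x3, np.zeros((5, 5)))
        assert np.trace(c_intra) == pytest.approx(5.0)


class TestMeanFieldLogPartition:
    def test_uniform_field(self):
        assert mean_field_log_partition(np.zeros((2, 2))) == pytest.approx(
            2 * np.log(2)
        )

    def test_single_cell_closed_form(self):
        assert mean_field_log_partition(np.array([[np.log(2), 0.0]])) == pytest.approx(
            np.log(3)
        )

    def test_shift_identity(self, rng):
        Z = rng.normal(size=(4, 5))
        shifted = Z.copy()
        shifted[2] += 3.7
        assert mean_field_log_partition(shifted) == pytest.approx(
            mean_field_log_partition(Z) + 3.7, abs=1e-9
        )

    def test_stable_at_large_fields(self):
        Z = np.array([[1000.0, 999.0]])
        assert np.isfinite(mean_field_log_partition(Z))
        assert mean_field_log_partition(Z) == pytest.approx(
            1000 + np.log(1 + np.e**-1)
        )

    def test_matches_state_enumeration_oracle(self, rng):
        # brute force: per cell, enumerate the G single-gene candidate
        # states and sum the exponentiated cross-energies explicitly
        S = np.eye(3)[rng.integers(0, 3, size=6)]  # one-hot rows
        gq = rng.normal(size=(3, 3))
        f = _forces(np.zeros((3, 3)), gq)
        Z = local_field(S, np.zeros((6, 6)), f)
        expected = 0.0
        for i in range(6):
            total = 0.0
            for gamma in range(3):
                cross = sum(S[i, a] * gq[a, gamma] for a in range(3))
                total += np.exp(cross)
            expected += np.log(total)
        assert mean_field_log_partition(Z) == pytest.approx(expected, abs=1e-12)


class TestLoss:
    def test_zero_forces_uniform_partition(self, random_state_5x3, rng):
        f = _forces(np.zeros((3, 3)), np.zeros((3, 3)))
        J = np.zeros((5, 5))
        assert loss(random_state_5x3, J, f) == pytest.approx(5 * np.log(3), abs=1e-9)

    def test_zmft_zero_keeps_only_partition(self, random_state_5x3, rng):
        gi, gq = rng.normal(size=(3, 3)), rng.normal(size=(3, 3))
        f = _forces(gi, gq)
        J = np.zeros((5, 5))
        Z = local_field(random_state_5x3, J, f)
        assert loss(random_state_5x3, J, f, zmft_scalar=0.0) == pytest.approx(
            mean_field_log_partition(Z)
        )

    @pytest.mark.parametrize("zmft", [1.0, 0.7])
    def test_finite_difference_moment_matching(self, zmft, rng):
        """The analytic force gradient equals softmax moments minus scaled
        empirical moments, and both match central finite differences."""
        S = rng.uniform(0, 1, (6, 3))
        S /= np.linalg.norm(S, axis=1, keepdims=True)
        J = np.zeros((6, 6))
        pairs = [(0, 1), (1, 2), (3, 4), (4, 5), (0, 5)]
        for i, j in pairs:
            J[i, j] = J[j, i] = 1.0
        gi, gq = rng.normal(size=(3, 3)), rng.normal(size=(3, 3))
        f = _forces(gi, gq)
        grad_i, grad_q = force_gradients(S, J, f, zmft)
        # closed-form moment-matching expression
        Z = local_field(S, J, f)
        P = softmax(Z, axis=1)
        c_inter, c_intra = empirical_moments(S, J)
        assert np.allclose(grad_q, S.T @ P - zmft * c_intra, atol=1e-12)
        assert np.allclose(grad_i, (J @ S).T @ P - zmft * c_inter, atol=1e-12)
        # central finite differences
        eps = 1e-6
        for grad, which in ((grad_i, "g_inter"), (grad_q, "g_intra")):
            num = np.zeros((3, 3))
            for a in range(3):
                for b in range(3):
                    up, dn = [
                        _forces(
                            gi + s * eps * (np.arange(9).reshape(3, 3) == 3 * a + b)
                            if which == "g_inter" else gi,
                            gq + s * eps * (np.arange(9).reshape(3, 3) == 3 * a + b)
                            if which == "g_intra" else gq,
                        )
                        for s in (+1, -1)
                    ]
                    num[a, b] = (loss(S, J, up, zmft) - loss(S, J, dn, zmft)) / (2 * eps)
            assert np.abs(num - grad).max() < 1e-5

    def test_expression_gradient_matches_finite_difference(self, rng):
        S = rng.uniform(0.1, 1, (5, 3))
        S /= np.linalg.norm(S, axis=1, keepdims=True)
        J = np.zeros((5, 5))
        J[0, 1] = J[1, 0] = J[2, 3] = J[3, 2] = 1.0
        f = _forces(rng.normal(size=(3, 3)), rng.normal(size=(3, 3)))
        grad = expression_gradient(S, J, f, 0.8)
        eps = 1e-6
        num = np.zeros_like(S)
        for i in range(5):
            for a in range(3):
                up, dn = S.copy(), S.copy()
                up[i, a] += eps
                dn[i, a] -= eps
                num[i, a] = (loss(up, J, f, 0.8) - loss(dn, J, f, 0.8)) / (2 * eps)
        assert np.abs(num - grad).max() < 1e-5

    def test_cell_permutation_invariance(self, rng, small_slide):
        f = _forces(rng.normal(size=(4, 4)), rng.normal(size=(4, 4)))
        S, J = small_slide.expression, small_slide.adjacency
        perm = rng.permutation(16)
        assert loss(S[perm], J[np.ix_(perm, perm)], f) == pytest.approx(
            loss(S, J, f), abs=1e-9
        )

    def test_gene_permutation_conjugates(self, rng, small_slide):
        gi, gq = rng.normal(size=(4, 4)), rng.normal(size=(4, 4))
        S, J = small_slide.expression, small_slide.adjacency
        perm = rng.permutation(4)
        f = _forces(gi, gq)
        f_p = _forces(gi[np.ix_(perm, perm)], gq[np.ix_(perm, perm)])
        Z = local_field(S, J, f)
        Z_p = local_field(S[:, perm], J, f_p)
        assert np.allclose(Z_p, Z[:, perm], atol=1e-12)
        assert loss(S[:, perm], J, f_p) == pytest.approx(loss(S, J, f), abs=1e-9)


class TestTypes:
    def test_forces_shape_validation(self):
        with pytest.raises(ValueError, match="g_intra"):
            GeneGeneForces(np.zeros((2, 2)), np.zeros((3, 3)), ["a", "b"])

    def test_config_validation(self):
        with pytest.raises(ValueError, match="zmft"):
            ModelConfig(zmft_scalar=1.5)
        with pytest.raises(ValueError, match="epochs"):
            ModelConfig(epochs=0)

    def test_flatten_concatenates_inter_then_intra(self):
        f = _forces([[1.0, 2.0], [3.0, 4.0]], [[5.0, 6.0], [7.0, 8.0]])
        assert flatten_forces(f).tolist() == [1, 2, 3, 4, 5, 6, 7, 8]
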