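"""Recurrent signaling network: activation, propagation, loss terms."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from drugsignet.autodiff import Tensor
from drugsignet.pkn import SignalingNetwork
from drugsignet.signaling import (SignalingParams, bias_projection_losses,
                                  default_target_rho, mml_activation, mml_prime,
                                  project_to_tf, propagate_steady_state,
                                  regularize_weights, sign_constraint_loss,
                                  spectral_radius, spectral_radius_exact,
                                  state_loss)


class TestMML:
    @pytest.mark.parametrize("x,expected", [
        (0.5, 0.5),       # continuity at the knot
        (1.0, 0.75),      # 1 - 0.25/1
        (-1.0, -0.01),    # leak branch
        (0.0, 0.0),
    ])
    def test_values(self, x, expected):
        assert mml_activation(x) == pytest.approx(expected)

    @given(st.floats(-5, 5), st.floats(-5, 5))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_monotone_and_bounded(self, a, b):
        lo, hi = sorted((a, b))
        assert mml_activation(lo) <= mml_activation(hi) + 1e-12
        assert mml_activation(hi) <= 1.0

    def test_continuity_at_knots(self):
        eps = 1e-9
        assert mml_activation(-eps) == pytest.approx(mml_activation(eps), abs=1e-7)
        assert mml_activation(0.5 - eps) == pytest.approx(mml_activation(0.5 + eps), abs=1e-7)

    def test_derivative_matches_finite_difference(self):
        xs = np.array([-2.0, -0.3, 0.1, 0.4, 0.7, 2.0, 10.0])
        num = (mml_activation(xs + 1e-7) - mml_activation(xs - 1e-7)) / 2e-7
        assert np.allclose(mml_prime(xs), num, atol=1e-5)


def _chain_params(weights, bias=0.0):
    """Linear chain T -> ... -> F with given edge weights."""
    n = len(weights) + 1
    nodes = [f"N{i}" for i in range(n)]
    edges = [(nodes[i], nodes[i + 1], 1) for i in range(n - 1)]
    net = SignalingNetwork(nodes, edges, target_nodes=[nodes[0]], tf_nodes=[nodes[-1]])
    sp = SignalingParams.from_network(net, seed=0)
    sp.w.data[:] = weights
    sp.b.data[:] = bias
    return sp


class TestPropagation:
    def test_zero_network_fixed_point_after_one_step(self):
        sp = _chain_params([0.0])
        sp.w.data[:] = 0.0
        h, _, traj = propagate_steady_state(np.zeros((1, 2)), sp)
        assert np.allclose(h.data, 0.0)
        assert traj.converged.all()

    def test_self_loop_geometric_fixed_point(self):
        """w=0.3 self-loop with input 0.1 in the linear regime converges to
        the closed-form geometric-series limit 0.1/(1-0.3)."""
        net = SignalingNetwork(["A", "F"], [("A", "A", 1), ("A", "F", 1)],
                               target_nodes=["A"], tf_nodes=["F"])
        sp = SignalingParams.from_network(net, seed=0)
        sp.w.data[:] = [0.3, 1.0]
        sp.b.data[:] = 0.0
        u = np.zeros((1, 2))
        u[0, 0] = 0.1
        h, _, traj = propagate_steady_state(u, sp)
        assert h.data[0, 0] == pytest.approx(0.1 / 0.7, abs=1e-7)
        assert traj.converged.all()

    def test_two_node_chain_composes_mml(self):
        sp = _chain_params([1.0])
        u = np.zeros((1, 2))
        u[0, 0] = 0.8
        h, _, _ = propagate_steady_state(u, sp)
        assert h.data[0, 1] == pytest.approx(mml_activation(mml_activation(0.8)), abs=1e-7)

    def test_contractive_model_converges_within_120_steps(self):
        rng = np.random.default_rng(4)
        nodes = [f"n{i}" for i in range(12)]
        edges = [(nodes[i], nodes[j], 1) for i in range(12) for j in range(12)
                 if i != j and rng.random() < 0.25]
        net = SignalingNetwork(nodes, edges, target_nodes=[nodes[0]], tf_nodes=[nodes[-1]])
        sp = SignalingParams.from_network(net, seed=4, weight_scale=0.8)
        u = rng.uniform(0, 0.5, (3, 12))
        _, _, traj = propagate_steady_state(u, sp, min_steps=120)
        assert traj.n_steps <= 120 and traj.delta < 1e-6


class TestProjection:
    def test_unit_weight_identity(self):
        steady = np.array([[0.2, 0.7]])
        out = project_to_tf(steady, np.ones(1), np.array([1]))
        assert out.tolist() == [[0.7]]

    def test_scaling(self):
        out = project_to_tf(np.array([[0.5]]), np.array([1.2]), np.array([0]))
        assert out[0, 0] == pytest.approx(0.6)

    def test_zero_weight(self):
        out = project_to_tf(np.array([[0.5, 0.5]]), np.zeros(2), np.array([0, 1]))
        assert np.allclose(out, 0.0)


class TestSpectralRadius:
    def _diag_params(self, value, n=4):
        nodes = [f"n{i}" for i in range(n)] + ["F"]
        edges = [(x, x, 1) for x in nodes[:-1]] + [(nodes[0], "F", 1)]
        net = SignalingNetwork(nodes, edges, target_nodes=[nodes[0]], tf_nodes=["F"])
        sp = SignalingParams.from_network(net, seed=0)
        sp.w.data[:] = [value] * n + [0.0]
        return sp

    def test_zero_weights_zero_rho(self):
        sp = self._diag_params(0.0)
        z = np.full((1, 5), 0.25)  # linear regime: mml' = 1
        rho, loss = spectral_radius(sp, z, seed=0)
        assert rho.item() == pytest.approx(0.0, abs=1e-12)
        assert loss.item() == 0.0

    def test_diagonal_half_is_subcritical(self):
        sp = self._diag_params(0.5)
        z = np.full((1, 5), 0.25)
        rho, loss = spectral_radius(sp, z, seed=0)
        assert rho.item() == pytest.approx(0.5, abs=1e-9)
        assert loss.item() == 0.0  # 0.5 < target_rho ~ 0.8913

    def test_diagonal_095_activates_barrier(self):
        sp = self._diag_params(0.95)
        z = np.full((1, 5), 0.25)
        rho, loss = spectral_radius(sp, z, seed=0)
        assert rho.item() == pytest.approx(0.95, abs=1e-9)
        assert loss.item() == pytest.approx(1e10 * (math.exp(9.5) - 1), rel=1e-6)

    def test_power_iteration_matches_dense_eigen_oracle(self):
        rng = np.random.default_rng(8)
        for trial in range(5):
            n = 30
            nodes = [f"n{i}" for i in range(n)]
            edges = [(nodes[i], nodes[j], 1) for i in range(n) for j in range(n)
                     if rng.random() < 0.2]
            if not edges:
                continue
            net = SignalingNetwork(nodes, edges,
                                   target_nodes=[nodes[0]], tf_nodes=[nodes[-1]])
            sp = SignalingParams.from_network(net, seed=trial)
            z = rng.uniform(-1, 2, (2, n))
            rho, _ = spectral_radius(sp, z, n_iter=200, seed=trial)
            assert rho.item() == pytest.approx(spectral_radius_exact(sp, z), abs=1e-6)

    def test_target_rho_closed_form(self):
        assert default_target_rho() == pytest.approx(math.exp(math.log(1e-6) / 120))
        assert 0 < default_target_rho() < 1


class TestLossTerms:
    def test_sign_constraint_values(self):
        signs = np.array([1.0, 1.0, -1.0])
        assert sign_constraint_loss(np.array([0.5, 0.2, -0.1]), signs) == 0.0
        assert sign_constraint_loss(np.array([-0.4, 0.2, -0.1]), signs) == pytest.approx(0.04)
        assert sign_constraint_loss(np.array([0.0, 0.0, 0.0]), signs) == 0.0

    def test_sign_constraint_zero_iff_no_violation(self):
        signs = np.array([1.0, -1.0])
        w = Tensor(np.array([0.3, 0.4]), requires_grad=True)
        loss = sign_constraint_loss(w, signs)
        assert (loss.item() == 0.0) != bool((np.sign(w.data) * signs < 0).any())

    def test_weight_regularizer_values(self):
        assert regularize_weights(np.array([0.0])) == pytest.approx(2e-6)
        assert regularize_weights(np.array([1.0])) == pytest.approx(1e-6 * (1 + 1 / 1.5))

    def test_weight_regularizer_interior_minimum(self):
        # 1-D grid-search oracle: per-weight term has its minimum away from 0
        grid = np.linspace(-2, 2, 2001)
        term = grid ** 2 + 1 / (grid ** 2 + 0.5)
        best = grid[np.argmin(term)]
        assert abs(best) > 0.5
        assert term.min() < term[1000]  # strictly better than w = 0

    def test_state_loss_constant_states(self):
        h = np.full((4, 3), 0.495)
        expected_per_node = (0.99 ** 2 / 12) ** 2 + 0.495 ** 2 + 0.495 ** 2
        assert state_loss(h).item() == pytest.approx(3 * expected_per_node)

    def test_state_loss_uniform_grid_near_zero(self):
        grid = np.linspace(0.0, 0.99, 400)[:, None]
        assert state_loss(grid).item() < 1e-4

    def test_state_loss_negative_states_penalized_tenfold(self):
        pos = state_loss(np.full((3, 1), 0.2)).item()
        neg = state_loss(np.full((3, 1), -0.2)).item()
        base_pos = (0.2 - 0.495) ** 2 + (0.99 ** 2 / 12) ** 2 + (0.2 - 0.99) ** 2 + 0.2 ** 2
        base_neg = (-0.2 - 0.495) ** 2 + (0.99 ** 2 / 12) ** 2 + (-0.2 - 0.99) ** 2 + 0.2 ** 2
        assert pos == pytest.approx(base_pos)
        assert neg == pytest.approx(10 * base_neg)

    def test_bias_projection_losses(self):
        bias_l, proj_l = bias_projection_losses(np.zeros(3), np.full(2, 1.2))
        assert bias_l.item() == 0.0 and proj_l.item() == 0.0
        _, proj = bias_projection_losses(np.zeros(1), np.array([1.0, 1.4]))
        assert proj.item() == pytest.approx(8e-8)
        b_l, _ = bias_projection_losses(np.array([2.0, -1.0]), np.array([1.2]))
        assert b_l.item() == pytest.approx(5e-6)
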