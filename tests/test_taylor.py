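"""Taylor expansion, next-beat residual and the loss functions."""

import numpy as np
import pytest

from taylorbp.network import ModelConfig, build_model
from taylorbp.taylor import (LossBreakdown, TaylorExpansion,
                             consecutive_pairs, evaluate_taylor, expand,
                             physics_loss, physics_residuals_graph, residual,
                             supervised_loss, total_loss)


class AnalyticModel:
    """Toy model y = c + w.u + u'Qu (ignores x) with exact derivatives."""

    def __init__(self, w, Q=None, c=0.0):
        self.w = np.asarray(w, dtype=float)
        self.Q = None if Q is None else np.asarray(Q, dtype=float)
        self.c = c

    def predict(self, x, u):
        u = np.atleast_2d(u)
        y = self.c + u @ self.w
        if self.Q is not None:
            y = y + np.einsum("bi,ij,bj->b", u, self.Q, u)
        return y

    def grad_wrt_features(self, x, u, order=1):
        u = np.atleast_2d(u)
        g = np.tile(self.w, (len(u), 1))
        if self.Q is not None:
            g = g + u @ (self.Q + self.Q.T)
        if order == 1:
            return g
        H = (np.zeros((len(u), 3, 3)) if self.Q is None
             else np.tile(self.Q + self.Q.T, (len(u), 1, 1)))
        return g, H


@pytest.fixture
def batch():
    rng = np.random.default_rng(0)
    return rng.normal(size=(8, 5)), rng.normal(size=(8, 3))


class TestExpansion:
    def test_anchor_identity(self, batch):
        x, u = batch
        model = AnalyticModel([-2.0, 1.0, 0.5], c=3.0)
        exp = expand(model, x, u, 2)
        assert evaluate_taylor(exp, u[2]) == pytest.approx(exp.base,
                                                          abs=1e-10)

    def test_first_order_exact_on_linear_model(self, batch):
        x, u = batch
        model = AnalyticModel([-2.0, 1.0, 0.5], c=3.0)
        exp = expand(model, x, u, 0)
        for j in range(len(u)):
            assert evaluate_taylor(exp, u[j]) == pytest.approx(
                model.predict(x, u)[j], abs=1e-10)

    def test_order_two_exact_on_quadratic_model(self, batch):
        x, u = batch
        Q = np.array([[0.5, 0.1, 0.0], [0.1, -0.3, 0.2], [0.0, 0.2, 0.4]])
        model = AnalyticModel([1.0, -1.0, 0.5], Q=Q)
        exp = expand(model, x, u, 0, order=2)
        for j in range(len(u)):
            assert evaluate_taylor(exp, u[j]) == pytest.approx(
                model.predict(x, u)[j], abs=1e-9)

    def test_hand_computed_polynomial_values(self):
        exp = TaylorExpansion(index=0, base=100.0,
                              gradient=np.array([-2.0, 1.0, 0.5]),
                              anchor_u=np.zeros(3))
        assert evaluate_taylor(exp, np.zeros(3)) == pytest.approx(100.0)
        assert evaluate_taylor(exp, np.array([1.0, 0, 0])) == pytest.approx(98.0)
        exp2 = TaylorExpansion(index=0, base=100.0,
                               gradient=np.array([-2.0, 1.0, 0.5]),
                               anchor_u=np.zeros(3), order=2,
                               hessian=np.diag([2.0, 0.0, 0.0]))
        assert evaluate_taylor(exp2, np.array([1.0, 0, 0])) == pytest.approx(99.0)

    def test_order_two_requires_symmetric_hessian(self):
        with pytest.raises(ValueError, match="symmetric"):
            TaylorExpansion(index=0, base=0.0, gradient=np.zeros(3),
                            anchor_u=np.zeros(3), order=2,
                            hessian=np.array([[0, 1, 0], [0, 0, 0],
                                              [0, 0, 0.0]]))


class TestResidual:
    def test_identical_consecutive_beats_give_zero(self, batch):
        x, u = batch
        x[3], u[3] = x[2], u[2]
        model = AnalyticModel([1.0, 2.0, 3.0], Q=np.eye(3))
        assert residual(model, x, u, 2) == pytest.approx(0.0, abs=1e-12)

    def test_linear_model_residual_zero_everywhere(self, batch):
        x, u = batch
        model = AnalyticModel([-1.5, 0.3, 2.0], c=7.0)
        for i in range(len(u) - 1):
            assert residual(model, x, u, i) == pytest.approx(0.0, abs=1e-10)

    def test_pure_quadratic_residual_is_delta_squared(self):
        # y = (u1)^2, du1 = delta: first-order residual = delta^2
        model = AnalyticModel([0.0, 0.0, 0.0],
                              Q=np.diag([1.0, 0.0, 0.0]))
        u = np.array([[1.0, 0, 0], [1.3, 0, 0]])
        x = np.zeros((2, 4))
        delta = 0.3
        assert residual(model, x, u, 0) == pytest.approx(delta**2, abs=1e-12)

    def test_non_consecutive_pair_rejected(self, batch):
        x, u = batch
        model = AnalyticModel([1.0, 0, 0])
        with pytest.raises(ValueError, match="consecutive"):
            residual(model, x, u, 0, 2)

    def test_session_boundary_rejected(self, batch):
        x, u = batch
        sessions = np.array(["a"] * 4 + ["b"] * 4)
        model = AnalyticModel([1.0, 0, 0])
        with pytest.raises(ValueError, match="session"):
            residual(model, x, u, 3, 4, sessions=sessions)


class TestLosses:
    def test_physics_loss_zero_for_affine_model(self, batch):
        x, u = batch
        model = AnalyticModel([2.0, -1.0, 0.5], c=1.0)
        assert physics_loss(model, x, u) == pytest.approx(0.0, abs=1e-12)

    def test_order_two_not_worse_than_order_one_on_quadratic(self, batch):
        x, u = batch
        model = AnalyticModel([1.0, 0, 0], Q=np.diag([0.7, 0.2, 0.1]))
        l1 = physics_loss(model, x, u, order=1)
        l2 = physics_loss(model, x, u, order=2)
        assert l2 <= l1
        assert l2 == pytest.approx(0.0, abs=1e-12)  # exact at order 2

    def test_physics_loss_mean_of_squared_residuals(self, batch):
        x, u = batch
        model = AnalyticModel([0.5, 1.0, -2.0], Q=np.eye(3) * 0.3)
        manual = np.mean([residual(model, x, u, i) ** 2
                          for i in range(len(u) - 1)])
        assert physics_loss(model, x, u) == pytest.approx(manual, rel=1e-12)

    def test_physics_loss_ignores_labels(self, batch):
        x, u = batch
        model = AnalyticModel([0.5, 1.0, -2.0], Q=np.eye(3) * 0.3)
        # no label argument exists; removing/relabeling y cannot change it
        assert physics_loss(model, x, u) == physics_loss(model, x, u)

    def test_pairs_respect_session_boundaries(self):
        sessions = np.array(["a", "a", "b", "b", "b"])
        pairs = consecutive_pairs(sessions)
        assert pairs.tolist() == [[0, 1], [2, 3], [3, 4]]

    def test_supervised_loss_examples(self, batch):
        x, u = batch
        model = AnalyticModel([0.0, 0.0, 0.0], c=0.0)
        assert supervised_loss(model, x[:2], u[:2],
                               np.zeros(2)) == pytest.approx(0.0)
        model2 = AnalyticModel([0.0, 0.0, 0.0], c=1.0)
        # preds (1,1), labels (0,2) -> ((1)^2+(1)^2)/2 = 1
        assert supervised_loss(model2, x[:2], u[:2],
                               np.array([0.0, 2.0])) == pytest.approx(1.0)

    def test_supervised_loss_order_invariant(self, batch):
        x, u = batch
        model = AnalyticModel([1.0, 2.0, 3.0])
        y = np.arange(8.0)
        perm = np.random.default_rng(3).permutation(8)
        assert supervised_loss(model, x, u, y) == pytest.approx(
            supervised_loss(model, x[perm], u[perm], y[perm]))

    def test_total_loss_weighting(self):
        assert total_loss(0.5, 0.02) == pytest.approx(0.7)
        assert total_loss(0.5, 0.02, beta=0.0) == pytest.approx(0.5)
        assert total_loss(0.5, 0.02, alpha=0.0) == pytest.approx(0.2)
        with pytest.raises(ValueError):
            total_loss(0.5, 0.02, alpha=-1.0)

    def test_loss_breakdown_total_consistency(self):
        lb = LossBreakdown(conventional=0.5, physics=0.02, alpha=1.0,
                           beta=10.0, n_labeled=10, n_segments=100)
        assert lb.total == pytest.approx(1.0 * 0.5 + 10.0 * 0.02, abs=1e-10)
        with pytest.raises(ValueError):
            LossBreakdown(conventional=-0.1, physics=0.0, alpha=1, beta=1,
                          n_labeled=1, n_segments=2)


class TestGraphPath:
    """The differentiable batch residuals agree with the per-beat API."""

    @pytest.mark.parametrize("activation, order", [
        ("relu", 1), ("tanh", 1), ("tanh", 2),
    ])
    def test_graph_residuals_match_per_beat(self, activation, order):
        rng = np.random.default_rng(5)
        state = build_model(
            ModelConfig(n_wave=12, dense_units=6,
                        dense_activation=activation), seed=8)
        x = rng.normal(size=(6, 12))
        u = rng.normal(size=(6, 3))
        from taylorbp import network
        fw = network.forward_graph(state, x, u)
        pairs = consecutive_pairs(n=6)
        h = physics_residuals_graph(state, fw, u, pairs, order=order)
        for (a, b), hv in zip(pairs, h.data[:, 0]):
            assert hv == pytest.approx(
                residual(state, x, u, int(a), int(b), order=order),
                rel=1e-9, abs=1e-12)

    def test_loss_gradient_matches_finite_differences_on_tiny_model(self):
        # differentiate through the Taylor residual: the whole-loss gradient
        # with respect to every weight against central differences
        rng = np.random.default_rng(9)
        state = build_model(ModelConfig(
            n_wave=9, conv1_filters=2, conv1_kernel=3, conv2_filters=2,
            conv2_kernel=3, pool_size=2, dense_units=2), seed=2)
        n_weights = sum(p.data.size for p in state.params.values())
        assert n_weights <= 50
        x = rng.normal(size=(5, 9))
        u = rng.normal(size=(5, 3))
        y = rng.normal(size=5)
        pairs = consecutive_pairs(n=5)

        def loss_value():
            from taylorbp import network
            fw = network.forward_graph(state, x, u)
            err = fw["y"][np.arange(5)] - y[:, None]
            h = physics_residuals_graph(state, fw, u, pairs)
            return (err * err).mean() + 10.0 * (h * h).mean()

        loss = loss_value()
        loss.backward()
        eps = 1e-6
        for name, p in state.params.items():
            an = p.grad if p.grad is not None else np.zeros_like(p.data)
            it = np.nditer(p.data, flags=["multi_index"])
            while not it.finished:
                idx = it.multi_index
                orig = p.data[idx]
                p.data[idx] = orig + eps
                fp = float(loss_value().data)
                p.data[idx] = orig - eps
                fm = float(loss_value().data)
                p.data[idx] = orig
                fd = (fp - fm) / (2 * eps)
                assert an[idx] == pytest.approx(fd, rel=1e-4, abs=1e-7), name
                it.iternext()
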