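"""Taylor-approximation consistency ("physics") loss.

The cardiovascular relation between the extracted features u and blood
pressure varies slowly between consecutive cardiac cycles.  The network's
own first-order (optionally second-order) Taylor polynomial around beat i,

    P_i(x, u) = f(x_i, u_i) + Σ_k ∂f/∂u^k |_i (u^k - u_i^k)
                [+ 1/2 Δuᵀ H_i Δu],

evaluated at the next beat, should therefore agree with the network's own
prediction there.  The residual

    h_i = f(x_{i+1}, u_{i+1}) - P_i(x_{i+1}, u_{i+1})

vanishes as beat i+1 approaches beat i, and its mean square over all R-1
consecutive same-session pairs is the physics loss — computable without
any labels, which is what lets unlabeled beats shape training.  The total
training loss is α·L_conventional + β·L_physics with defaults α=1, β=10.

Functions taking a ``model`` accept anything that implements
``predict(x, u)`` and ``grad_wrt_features(x, u, order)`` — the CNN
:class:`~taylorbp.network.ModelState` via thin wrappers, or analytic toy
models in tests.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import network
from .autodiff import Tensor

__all__ = [
    "TaylorExpansion", "LossBreakdown", "consecutive_pairs", "expand",
    "evaluate_taylor", "residual", "physics_loss", "supervised_loss",
    "total_loss", "physics_residuals_graph",
]


@dataclasses.dataclass
class TaylorExpansion:
    """First- or second-order expansion of the model around one beat."""

    index: int
    base: float                 # f(x_i, u_i)
    gradient: np.ndarray        # ∂f/∂u at the anchor, shape (M,)
    anchor_u: np.ndarray        # u_i
    order: int = 1
    hessian: np.ndarray | None = None  # (M, M), order 2 only

    def __post_init__(self):
        self.gradient = np.asarray(self.gradient, dtype=float)
        self.anchor_u = np.asarray(self.anchor_u, dtype=float)
        if self.gradient.shape != self.anchor_u.shape:
            raise ValueError("gradient and anchor_u dimensions differ")
        if self.order == 2:
            if self.hessian is None:
                raise ValueError("order-2 expansion requires a Hessian block")
            H = np.asarray(self.hessian, dtype=float)
            if not np.allclose(H, H.T, atol=1e-8):
                raise ValueError("Hessian block must be symmetric")
            self.hessian = H
        elif self.order != 1:
            raise ValueError("order must be 1 or 2")


@dataclasses.dataclass
class LossBreakdown:
    """Loss terms of one optimization step."""

    conventional: float
    physics: float
    alpha: float
    beta: float
    n_labeled: int      # S
    n_segments: int     # R

    def __post_init__(self):
        if self.conventional < 0 or self.physics < 0:
            raise ValueError("losses must be non-negative")

    @property
    def total(self) -> float:
        return self.alpha * self.conventional + self.beta * self.physics


class _StateModel:
    """Adapter giving a ModelState the generic model protocol."""

    def __init__(self, state):
        self.state = state

    def predict(self, x, u):
        return network.predict(self.state, x, u)

    def grad_wrt_features(self, x, u, order=1):
        return network.grad_wrt_features(self.state, x, u, order)


def _as_model(model):
    return _StateModel(model) if isinstance(model, network.ModelState) else model


def consecutive_pairs(sessions=None, n: int | None = None) -> np.ndarray:
    """Indices (i, i+1) of consecutive beats that share a session.

    The slowly-varying premise holds between consecutive cardiac cycles,
    not across recording gaps, so pairs never straddle session boundaries.
    """
    if sessions is None:
        if n is None:
            raise ValueError("need sessions or n")
        sessions = np.zeros(n)
    sessions = np.asarray(sessions)
    idx = np.arange(len(sessions) - 1)
    keep = sessions[:-1] == sessions[1:]
    return np.column_stack([idx[keep], idx[keep] + 1])


# -- per-beat API -------------------------------------------------------------

def expand(model, x: np.ndarray, u: np.ndarray, i: int,
           order: int = 1) -> TaylorExpansion:
    """Capture base value and feature gradient(s) at beat ``i``."""
    model = _as_model(model)
    x = np.atleast_2d(x)
    u = np.atleast_2d(u)
    base = float(model.predict(x[i:i + 1], u[i:i + 1])[0])
    if order == 1:
        g = model.grad_wrt_features(x[i:i + 1], u[i:i + 1], 1)
        return TaylorExpansion(index=i, base=base, gradient=g[0],
                               anchor_u=u[i], order=1)
    g, H = model.grad_wrt_features(x[i:i + 1], u[i:i + 1], 2)
    return TaylorExpansion(index=i, base=base, gradient=g[0],
                           anchor_u=u[i], order=2, hessian=H[0])


def evaluate_taylor(exp: TaylorExpansion, u_next: np.ndarray) -> float:
    """P(u_next) = base + g·Δu [+ ½ Δuᵀ H Δu]."""
    u_next = np.asarray(u_next, dtype=float)
    if u_next.shape != exp.anchor_u.shape:
        raise ValueError("feature dimension mismatch")
    du = u_next - exp.anchor_u
    val = exp.base + float(exp.gradient @ du)
    if exp.order == 2:
        val += 0.5 * float(du @ exp.hessian @ du)
    return val


def residual(model, x: np.ndarray, u: np.ndarray, i: int, j: int | None = None,
             sessions=None, order: int = 1) -> float:
    """h_i = f(x_{i+1}, u_{i+1}) - P_i(x_{i+1}, u_{i+1}).

    Rejects non-consecutive pairs and pairs crossing a session boundary.
    """
    model = _as_model(model)
    x = np.atleast_2d(x)
    u = np.atleast_2d(u)
    if j is None:
        j = i + 1
    if j != i + 1:
        raise ValueError("Taylor residual is defined for consecutive beats")
    if sessions is not None and sessions[i] != sessions[j]:
        raise ValueError("beats belong to different sessions")
    exp = expand(model, x, u, i, order=order)
    f_next = float(model.predict(x[j:j + 1], u[j:j + 1])[0])
    return f_next - evaluate_taylor(exp, u[j])


def physics_loss(model, x: np.ndarray, u: np.ndarray, sessions=None,
                 order: int = 1) -> float:
    """Mean squared residual over all R-1 consecutive pairs (label-free)."""
    x = np.atleast_2d(x)
    u = np.atleast_2d(u)
    R = x.shape[0]
    if R < 2:
        raise ValueError("physics loss requires at least two segments")
    pairs = consecutive_pairs(sessions, n=R)
    if len(pairs) == 0:
        raise ValueError("no within-session consecutive pairs")
    model = _as_model(model)
    hs = [residual(model, x, u, int(a), int(b), order=order)
          for a, b in pairs]
    return float(np.mean(np.square(hs)))


def supervised_loss(model, x: np.ndarray, u: np.ndarray,
                    y_true: np.ndarray) -> float:
    """Mean squared error over the S labeled beats only."""
    y_true = np.asarray(y_true, dtype=float).ravel()
    if len(y_true) == 0:
        raise ValueError("supervised loss requires at least one label")
    model = _as_model(model)
    pred = model.predict(np.atleast_2d(x), np.atleast_2d(u))
    return float(np.mean((pred - y_true) ** 2))


def total_loss(l_conventional: float, l_physics: float, alpha: float = 1.0,
               beta: float = 10.0) -> float:
    if alpha < 0 or beta < 0:
        raise ValueError("loss weights must be non-negative")
    return alpha * l_conventional + beta * l_physics


# -- differentiable batch path (used by the trainer) --------------------------

def physics_residuals_graph(state, fw: dict, u: np.ndarray,
                            pairs: np.ndarray, order: int = 1) -> Tensor:
    """All pair residuals h as one graph tensor of shape (P, 1).

    ``fw`` is the cached full-batch forward pass.  The first-order term is
    g_a · Δu = Σ_j (W2_j σ'(z1_aj)) (W1u Δu)_j, the optional second-order
    term ½ Σ_j (W2_j σ''(z1_aj)) (W1u Δu)_j² — both written with graph
    primitives so the trainer backpropagates through the expansion itself.
    """
    ia, ib = pairs[:, 0], pairs[:, 1]
    du = np.atleast_2d(u)[ib] - np.atleast_2d(u)[ia]  # constants wrt Θ

    sp = network._sigma_prime(state, fw)
    coeff = sp[ia] * state.params["W2"]          # (P, units)
    v = Tensor(du) @ fw["W1u"].T                 # (P, units)
    lin = (coeff * v).sum(axis=1, keepdims=True)
    h = fw["y"][ib] - fw["y"][ia] - lin
    if order == 2:
        spp = network._sigma_second(state, fw)
        if spp is not None:
            quad = ((spp[ia] * state.params["W2"]) * v * v).sum(
                axis=1, keepdims=True) * 0.5
            h = h - quad
    elif order != 1:
        raise ValueError("order must be 1 or 2")
    return h
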