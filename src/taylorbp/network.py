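"""Regression network f_NN(x, u, Θ) and its feature gradients.

Architecture (per-beat scalar regression):

    x (N,) -> Conv1D(32, k=5, ReLU) -> Conv1D(64, k=3, ReLU)
           -> MaxPool1D(3, stride 1) -> flatten
    concat(flatten, u (M,)) -> Dense(60, ReLU) -> Dense(1, linear)

Convolutions use "valid" padding so the flatten width is a deterministic
function of the input length.  The gradient ∂f/∂u is taken with respect to
the feature inputs at the concatenation layer, with x held fixed; because
u only enters through the dense head, that gradient has the closed form

    ∂f/∂u = W2 · diag(σ'(z1)) · W1u

(z1 the dense pre-activation, W1u the feature block of the first dense
weight matrix).  Building this expression out of graph primitives lets a
single reverse sweep differentiate losses that contain ∂f/∂u (the Taylor
residual) with respect to Θ.  For ReLU, σ' is piecewise constant, so the
expression equals the autodiff gradient almost everywhere; a tanh dense
option is provided for experiments needing a smooth (twice-differentiable)
head.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np

from .autodiff import Tensor, conv1d, maxpool1d

__all__ = ["ModelConfig", "ModelState", "build_model", "predict",
           "grad_wrt_features", "forward_graph", "feature_gradient_graph",
           "save_model", "load_model", "parameter_count"]

PARAM_NAMES = ("Wc1", "bc1", "Wc2", "bc2", "W1", "b1", "W2", "b2")


@dataclasses.dataclass(frozen=True)
class ModelConfig:
    n_wave: int                   # input length N (30 Hz padded beats)
    n_features: int = 3           # M
    conv1_filters: int = 32
    conv1_kernel: int = 5
    conv2_filters: int = 64
    conv2_kernel: int = 3
    pool_size: int = 3
    pool_stride: int = 1
    dense_units: int = 60
    dense_activation: str = "relu"   # or "tanh"

    def __post_init__(self):
        for name in ("n_wave", "conv1_filters", "conv1_kernel",
                     "conv2_filters", "conv2_kernel", "pool_size",
                     "pool_stride", "dense_units"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.dense_activation not in ("relu", "tanh"):
            raise ValueError("dense_activation must be 'relu' or 'tanh'")
        if self.flatten_width <= 0:
            raise ValueError(
                f"n_wave={self.n_wave} smaller than the receptive-field "
                "minimum of the conv/pool stack"
            )

    @property
    def conv1_out(self) -> int:
        return self.n_wave - self.conv1_kernel + 1

    @property
    def conv2_out(self) -> int:
        return self.conv1_out - self.conv2_kernel + 1

    @property
    def pool_out(self) -> int:
        return (self.conv2_out - self.pool_size) // self.pool_stride + 1

    @property
    def flatten_width(self) -> int:
        return self.conv2_filters * self.pool_out

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class ModelState:
    """Trainable weights Θ plus the architecture that shapes them."""

    params: dict           # name -> Tensor (requires_grad=True)
    config: ModelConfig
    seed: int

    def copy(self) -> "ModelState":
        return ModelState(
            params={k: Tensor.param(v.data.copy())
                    for k, v in self.params.items()},
            config=self.config, seed=self.seed,
        )


def build_model(config: ModelConfig, seed: int = 0) -> ModelState:
    """Deterministic He/Glorot initialisation under a fixed seed."""
    rng = np.random.default_rng(seed)
    c = config

    def he(shape, fan_in):
        return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)

    dense_in = c.flatten_width + c.n_features
    params = {
        "Wc1": Tensor.param(he((c.conv1_filters, 1, c.conv1_kernel),
                               c.conv1_kernel)),
        "bc1": Tensor.param(np.zeros(c.conv1_filters)),
        "Wc2": Tensor.param(he((c.conv2_filters, c.conv1_filters,
                                c.conv2_kernel),
                               c.conv1_filters * c.conv2_kernel)),
        "bc2": Tensor.param(np.zeros(c.conv2_filters)),
        "W1": Tensor.param(he((c.dense_units, dense_in), dense_in)),
        "b1": Tensor.param(np.zeros(c.dense_units)),
        "W2": Tensor.param(
            rng.normal(0.0, np.sqrt(1.0 / c.dense_units), size=(1, c.dense_units))
        ),
        "b2": Tensor.param(np.zeros(1)),
    }
    return ModelState(params=params, config=config, seed=int(seed))


def parameter_count(config: ModelConfig) -> int:
    c = config
    dense_in = c.flatten_width + c.n_features
    return (c.conv1_filters * 1 * c.conv1_kernel + c.conv1_filters
            + c.conv2_filters * c.conv1_filters * c.conv2_kernel
            + c.conv2_filters
            + c.dense_units * dense_in + c.dense_units
            + 1 * c.dense_units + 1)


# -- forward ------------------------------------------------------------------

def _validate_batch(config: ModelConfig, x: np.ndarray, u: np.ndarray):
    x = np.atleast_2d(np.asarray(x, dtype=float))
    u = np.atleast_2d(np.asarray(u, dtype=float))
    if x.shape[1] != config.n_wave:
        raise ValueError(f"x has length {x.shape[1]}, expected {config.n_wave}")
    if u.shape[1] != config.n_features:
        raise ValueError(f"u has {u.shape[1]} features, expected "
                         f"{config.n_features}")
    if x.shape[0] != u.shape[0]:
        raise ValueError("x and u batch sizes differ")
    return x, u


def forward_graph(state: ModelState, x: np.ndarray, u) -> dict:
    """Full differentiable forward pass.

    Returns the output ``y`` (B, 1) plus the dense pre-/post-activations
    needed to express Taylor terms in closed form.
    """
    c = state.config
    u_t = u if isinstance(u, Tensor) else Tensor(np.atleast_2d(u))
    x, _ = _validate_batch(c, x, u_t.data)
    p = state.params

    h = conv1d(Tensor(x[:, None, :]), p["Wc1"], p["bc1"]).relu()
    h = conv1d(h, p["Wc2"], p["bc2"]).relu()
    h = maxpool1d(h, c.pool_size, c.pool_stride)
    flat = h.reshape(x.shape[0], c.flatten_width)

    W1f = p["W1"][:, : c.flatten_width]
    W1u = p["W1"][:, c.flatten_width:]
    z1 = flat @ W1f.T + u_t @ W1u.T + p["b1"]
    a1 = z1.relu() if c.dense_activation == "relu" else z1.tanh()
    y = a1 @ p["W2"].T + p["b2"]
    return {"y": y, "z1": z1, "a1": a1, "W1u": W1u, "flat": flat}


def _sigma_prime(state: ModelState, fw: dict) -> Tensor:
    """σ'(z1) as a graph node (constant a.e. for ReLU, smooth for tanh)."""
    if state.config.dense_activation == "relu":
        return Tensor((fw["z1"].data > 0).astype(float))
    a1 = fw["a1"]
    return 1.0 - a1 * a1


def _sigma_second(state: ModelState, fw: dict) -> Tensor | None:
    """σ''(z1) as a graph node; None means identically zero (ReLU)."""
    if state.config.dense_activation == "relu":
        return None
    a1 = fw["a1"]
    return -2.0 * a1 * (1.0 - a1 * a1)


def feature_gradient_graph(state: ModelState, fw: dict) -> Tensor:
    """g = ∂f/∂u = (σ'(z1) ⊙ W2) @ W1u as a differentiable expression."""
    sp = _sigma_prime(state, fw)
    return (sp * state.params["W2"]) @ fw["W1u"]


def predict(state: ModelState, x, u) -> np.ndarray:
    """Scalar prediction per beat, in the (normalized) output units."""
    fw = forward_graph(state, x, u)
    return fw["y"].data[:, 0].copy()


def grad_wrt_features(state: ModelState, x, u, order: int = 1):
    """∂f/∂u per beat ((B, M)); with ``order=2`` also the (B, M, M)
    second-derivative block, symmetric by construction."""
    fw = forward_graph(state, x, u)
    g = feature_gradient_graph(state, fw).data.copy()
    if not np.all(np.isfinite(g)):
        raise FloatingPointError(
            f"non-finite feature gradient (|z1| max "
            f"{np.abs(fw['z1'].data).max():.3g})"
        )
    if order == 1:
        return g
    if order != 2:
        raise ValueError("order must be 1 or 2")
    spp = _sigma_second(state, fw)
    W1u = fw["W1u"].data
    if spp is None:
        H = np.zeros((g.shape[0], W1u.shape[1], W1u.shape[1]))
    else:
        q = spp.data * state.params["W2"].data  # (B, units)
        H = np.einsum("bj,jk,jl->bkl", q, W1u, W1u, optimize=True)
    return g, H


# -- persistence --------------------------------------------------------------

def save_model(state: ModelState, path) -> None:
    """Self-describing checkpoint (config JSON + weight arrays)."""
    arrays = {k: v.data for k, v in state.params.items()}
    np.savez(path, __config__=json.dumps(state.config.to_dict()),
             __seed__=state.seed, **arrays)


def load_model(path) -> ModelState:
    with np.load(path, allow_pickle=False) as z:
        config = ModelConfig(**json.loads(str(z["__config__"])))
        seed = int(z["__seed__"])
        params = {k: Tensor.param(z[k].copy()) for k in PARAM_NAMES}
    return ModelState(params=params, config=config, seed=seed)


def describe(state: ModelState) -> str:
    c = state.config
    lines = [
        f"input x: ({c.n_wave},)  features u: ({c.n_features},)",
        f"conv1: {c.conv1_filters} filters, k={c.conv1_kernel}, relu "
        f"-> ({c.conv1_out}, {c.conv1_filters})",
        f"conv2: {c.conv2_filters} filters, k={c.conv2_kernel}, relu "
        f"-> ({c.conv2_out}, {c.conv2_filters})",
        f"maxpool: size {c.pool_size}, stride {c.pool_stride} "
        f"-> ({c.pool_out}, {c.conv2_filters})",
        f"flatten+concat -> ({c.flatten_width + c.n_features},)",
        f"dense1: {c.dense_units} units, {c.dense_activation}",
        "dense2: 1 unit, linear",
        f"parameters: {parameter_count(c)}",
    ]
    return "\n".join(lines)
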