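"""Training loop for the Taylor-consistency PINN and its CNN baseline.

Full-batch Adam (step size 1e-3) minimises α·L_conventional + β·L_physics;
the supervised term uses only the split's labeled beats, the physics term
every within-session consecutive pair, labels never.  Training stops when
the supervised loss reaches the threshold (default 0.01 in normalized
units) or at the epoch cap (a safety net — the threshold may be
unreachable on noisy data, in which case a warning is raised).  With
β = 0 the loop *is* the conventional CNN trainer: the physics term is
skipped entirely and the trajectory is bit-reproducible under a fixed
seed either way.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from . import network
from .splits import SplitSpec, minimal_split
from .taylor import consecutive_pairs, physics_residuals_graph

__all__ = ["TrainConfig", "TrainingDiverged", "Adam", "train",
           "train_conventional", "growing_labels_experiment"]


@dataclasses.dataclass
class TrainConfig:
    alpha: float = 1.0
    beta: float = 10.0
    taylor_order: int = 1
    learning_rate: float = 1e-3
    max_epochs: int = 5000
    sup_loss_threshold: float = 0.01   # normalized units
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8
    seed: int = 0

    def __post_init__(self):
        if self.sup_loss_threshold <= 0:
            raise ValueError("sup_loss_threshold must be positive")
        if self.max_epochs <= 0:
            raise ValueError("max_epochs must bound the runtime")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("loss weights must be non-negative")


class TrainingDiverged(RuntimeError):
    """Raised on non-finite loss; carries the history up to the abort."""

    def __init__(self, message: str, history: pd.DataFrame):
        super().__init__(message)
        self.history = history


class Adam:
    """Adaptive-moment optimizer over a dict of parameter tensors."""

    def __init__(self, params: dict, lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None


def train(state: network.ModelState, x: np.ndarray, u: np.ndarray,
          y_norm: np.ndarray, split: SplitSpec, cfg: TrainConfig,
          sessions=None):
    """Gradient-based minimisation of the total loss.

    ``y_norm`` holds normalized labels (NaN allowed outside the training
    indices; only ``split.train_idx`` entries are read).  Returns
    ``(state, history)`` where history logs per-epoch
    ``step, L_conv, L_phys, L_total``.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    u = np.atleast_2d(np.asarray(u, dtype=float))
    y_norm = np.asarray(y_norm, dtype=float).ravel()
    tr = split.train_idx
    if tr.size == 0:
        raise ValueError("training split is empty")
    y_tr = y_norm[tr]
    if not np.all(np.isfinite(y_tr)):
        raise ValueError("non-finite label inside the training split")
    pairs = consecutive_pairs(sessions, n=x.shape[0])
    use_physics = cfg.beta > 0
    if use_physics and len(pairs) == 0:
        raise ValueError("physics term requested but no consecutive pairs")

    opt = Adam(state.params, cfg.learning_rate, cfg.adam_beta1,
               cfg.adam_beta2, cfg.adam_eps)
    rows = []
    stopped = False
    for epoch in range(cfg.max_epochs):
        opt.zero_grad()
        fw = network.forward_graph(state, x, u)
        err = fw["y"][tr] - y_tr[:, None]
        l_conv = (err * err).mean()
        if use_physics:
            h = physics_residuals_graph(state, fw, u, pairs,
                                        order=cfg.taylor_order)
            l_phys = (h * h).mean()
            loss = cfg.alpha * l_conv + cfg.beta * l_phys
            l_phys_val = float(l_phys.data)
        else:
            loss = cfg.alpha * l_conv
            l_phys_val = 0.0
        l_conv_val = float(l_conv.data)
        rows.append((epoch, l_conv_val, l_phys_val,
                     cfg.alpha * l_conv_val + cfg.beta * l_phys_val))
        if not np.isfinite(rows[-1][3]):
            history = pd.DataFrame(
                rows, columns=["step", "L_conv", "L_phys", "L_total"])
            raise TrainingDiverged(
                f"non-finite loss at epoch {epoch}", history)
        if l_conv_val <= cfg.sup_loss_threshold:
            stopped = True
            break
        loss.backward()
        opt.step()
    if not stopped:
        warnings.warn(
            f"epoch cap {cfg.max_epochs} reached before the supervised "
            f"loss fell below {cfg.sup_loss_threshold}"
        )
    history = pd.DataFrame(rows,
                           columns=["step", "L_conv", "L_phys", "L_total"])
    return state, history


def train_conventional(state, x, u, y_norm, split, cfg: TrainConfig,
                       sessions=None):
    """The conventional-CNN trainer: the same loop with the physics term
    off (β = 0)."""
    cfg = dataclasses.replace(cfg, beta=0.0)
    return train(state, x, u, y_norm, split, cfg, sessions)


def growing_labels_experiment(x, u, y, sessions, cfg: TrainConfig,
                              model_config: network.ModelConfig | None = None,
                              seed: int = 0, bin_width: float = 0.5,
                              max_models: int | None = None,
                              norm_stats=None):
    """Train a model series with 1, 3, 5, ... labels from a 0.5-mmHg-bin pool.

    The pool holds one random labeled beat per populated 0.5-mmHg bin
    (k = 2 x BP range points).  Model m draws the first 1 + 2m points of a
    fixed shuffled pool order, so each model's label set contains the
    previous one's.  Returns a list of dicts with ``label_count``,
    ``train_idx``, trained ``state``, ``history``, per-model test RMSE and
    Pearson r, and the per-beat feature-gradient matrix.
    """
    from scipy.stats import pearsonr

    x = np.atleast_2d(np.asarray(x, dtype=float))
    u = np.atleast_2d(np.asarray(u, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    pool_split = minimal_split(y, bin_width=bin_width, seed=seed)
    rng = np.random.default_rng(seed)
    pool = rng.permutation(pool_split.train_idx)
    counts = list(range(1, len(pool) + 1, 2))
    if max_models is not None:
        counts = counts[:max_models]
    if not counts:
        raise ValueError("label pool is empty")

    y_mean, y_sd = (float(np.nanmean(y)), float(np.nanstd(y)))
    if norm_stats is not None:
        y_mean, y_sd = float(norm_stats.y_mean), float(norm_stats.y_sd)
    y_norm = (y - y_mean) / y_sd

    if model_config is None:
        model_config = network.ModelConfig(n_wave=x.shape[1])
    all_idx = np.flatnonzero(np.isfinite(y))
    results = []
    for m, c in enumerate(counts):
        train_idx = np.sort(pool[:c])
        test_idx = np.setdiff1d(all_idx, train_idx)
        split = SplitSpec(strategy="growing", train_idx=train_idx,
                          test_idx=test_idx, seed=seed)
        state = network.build_model(model_config, seed=cfg.seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            state, history = train(state, x, u, y_norm, split, cfg, sessions)
        pred = network.predict(state, x[test_idx], u[test_idx]) * y_sd + y_mean
        truth = y[test_idx]
        rmse = float(np.sqrt(np.mean((pred - truth) ** 2)))
        r = float(pearsonr(pred, truth)[0]) if len(test_idx) > 2 else np.nan
        grads = network.grad_wrt_features(state, x, u)
        results.append({
            "label_count": c, "train_idx": train_idx, "state": state,
            "history": history, "rmse": rmse, "pearson_r": r,
            "gradients": grads,
        })
    return results
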