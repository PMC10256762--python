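"""Scikit-learn style estimator for Taylor-consistency PINN regression.

:class:`TaylorPINNRegressor` composes with sklearn model selection and
pipelines; the row layout is ``X = [waveform (n_wave cols) | u1 u2 u3]``.
``y`` may contain NaN: those beats are unlabeled and contribute only to
the label-free physics term — this is the transductive, minimal-label
setting the model exists for.  Setting ``beta=0`` turns the estimator
into the conventionally trained CNN with an identical architecture,
initialisation and optimizer trajectory.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from . import network
from .splits import SplitSpec
from .training import TrainConfig, train

__all__ = ["TaylorPINNRegressor"]


class TaylorPINNRegressor(RegressorMixin, BaseEstimator):
    """Beat-to-beat BP regressor trained with a Taylor-consistency loss.

    The architecture is a two-layer 1-D CNN over the beat waveform
    concatenated with three physiological features; training minimises
    ``alpha * MSE(labeled) + beta * mean(h_i^2)`` where ``h_i`` is the
    next-beat Taylor-consistency residual.

    Parameters
    ----------
    n_wave : int or None
        Waveform columns in X; inferred as ``X.shape[1] - 3`` when None.
    alpha, beta : float
        Loss weights; defaults 1 and 10.  ``beta=0`` is the CNN baseline.
    taylor_order : int
        1 (default) or 2 (adds the second-order block to the expansion).
    normalize : bool
        Z-score features/waveform over all rows and the labels over the
        labeled rows inside ``fit`` (predictions are returned in mmHg
        either way).  Set False when the data are already normalized.
    random_state : int
        Seeds initialisation; the whole trajectory is deterministic.

    Attributes
    ----------
    model_state_ : ModelState
        Trained weights and architecture.
    history_ : pandas.DataFrame
        Per-epoch ``step, L_conv, L_phys, L_total``.
    n_iter_ : int
        Epochs actually run.
    stopped_early_ : bool
        True when the supervised-loss threshold was reached.
    """

    def __init__(self, n_wave=None, alpha=1.0, beta=10.0, taylor_order=1,
                 learning_rate=1e-3, max_epochs=5000, sup_loss_threshold=0.01,
                 dense_activation="relu", dense_units=60, conv1_filters=32,
                 conv1_kernel=5, conv2_filters=64, conv2_kernel=3,
                 pool_size=3, pool_stride=1, normalize=True, random_state=0):
        self.n_wave = n_wave
        self.alpha = alpha
        self.beta = beta
        self.taylor_order = taylor_order
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.sup_loss_threshold = sup_loss_threshold
        self.dense_activation = dense_activation
        self.dense_units = dense_units
        self.conv1_filters = conv1_filters
        self.conv1_kernel = conv1_kernel
        self.conv2_filters = conv2_filters
        self.conv2_kernel = conv2_kernel
        self.pool_size = pool_size
        self.pool_stride = pool_stride
        self.normalize = normalize
        self.random_state = random_state

    # -- helpers --------------------------------------------------------------
    def _split_X(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D: [waveform | u1 u2 u3]")
        n_wave = self.n_wave if self.n_wave is not None else X.shape[1] - 3
        if n_wave <= 0 or X.shape[1] != n_wave + 3:
            raise ValueError(
                f"X has {X.shape[1]} columns; expected n_wave+3 "
                f"(n_wave={n_wave})"
            )
        return X[:, :n_wave], X[:, n_wave:], n_wave

    def _norm_inputs(self, xw, u):
        if not self.normalize:
            return xw, u
        xw = (xw - self.x_mean_) / self.x_sd_
        u = (u - self.u_mean_) / self.u_sd_
        return xw, u

    # -- sklearn API ----------------------------------------------------------
    def fit(self, X, y, sessions=None):
        xw, u, n_wave = self._split_X(X)
        y = np.asarray(y, dtype=float).ravel()
        if len(y) != xw.shape[0]:
            raise ValueError("X and y lengths differ")
        labeled = np.isfinite(y)
        if not labeled.any():
            raise ValueError("y has no finite (labeled) entries")

        if self.normalize:
            self.x_mean_, self.x_sd_ = float(xw.mean()), float(xw.std())
            self.u_mean_, self.u_sd_ = u.mean(axis=0), u.std(axis=0)
            self.y_mean_, self.y_sd_ = (float(y[labeled].mean()),
                                        float(y[labeled].std()))
            if self.x_sd_ <= 0 or np.any(self.u_sd_ <= 0) or self.y_sd_ <= 0:
                raise ValueError("zero-variance channel: cannot normalize")
        else:
            self.x_mean_, self.x_sd_ = 0.0, 1.0
            self.u_mean_ = np.zeros(u.shape[1])
            self.u_sd_ = np.ones(u.shape[1])
            self.y_mean_, self.y_sd_ = 0.0, 1.0
        xw_n, u_n = self._norm_inputs(xw, u)
        y_n = (y - self.y_mean_) / self.y_sd_

        config = network.ModelConfig(
            n_wave=n_wave, n_features=u.shape[1],
            conv1_filters=self.conv1_filters, conv1_kernel=self.conv1_kernel,
            conv2_filters=self.conv2_filters, conv2_kernel=self.conv2_kernel,
            pool_size=self.pool_size, pool_stride=self.pool_stride,
            dense_units=self.dense_units,
            dense_activation=self.dense_activation,
        )
        state = network.build_model(config, seed=self.random_state)
        split = SplitSpec(strategy="provided",
                          train_idx=np.flatnonzero(labeled),
                          test_idx=np.array([], dtype=int))
        cfg = TrainConfig(
            alpha=self.alpha, beta=self.beta, taylor_order=self.taylor_order,
            learning_rate=self.learning_rate, max_epochs=self.max_epochs,
            sup_loss_threshold=self.sup_loss_threshold,
            seed=self.random_state,
        )
        state, history = train(state, xw_n, u_n, y_n, split, cfg,
                               sessions=sessions)
        self.model_state_ = state
        self.history_ = history
        self.n_iter_ = len(history)
        self.stopped_early_ = bool(
            history["L_conv"].iloc[-1] <= self.sup_loss_threshold
        )
        self.n_wave_ = n_wave
        return self

    def predict(self, X):
        """BP predictions in mmHg (normalization inverted)."""
        xw, u, _ = self._split_X(X)
        xw, u = self._norm_inputs(xw, u)
        y_n = network.predict(self.model_state_, xw, u)
        return y_n * self.y_sd_ + self.y_mean_

    def feature_gradients(self, X, order: int = 1):
        """∂y/∂u in normalized units (the network's own input space)."""
        xw, u, _ = self._split_X(X)
        xw, u = self._norm_inputs(xw, u)
        return network.grad_wrt_features(self.model_state_, xw, u, order)

    def score(self, X, y, sample_weight=None):
        """R² over the finite entries of ``y``."""
        y = np.asarray(y, dtype=float).ravel()
        mask = np.isfinite(y)
        pred = self.predict(np.asarray(X)[mask])
        ss_res = np.sum((y[mask] - pred) ** 2)
        ss_tot = np.sum((y[mask] - y[mask].mean()) ** 2)
        return 1.0 - ss_res / ss_tot
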