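"""Canonical synthetic study protocols.

These fix the simulated study conditions used throughout the package's
validation experiments, so that tests, scripts and documentation all refer
to the same subjects:

* :func:`linear_subject` — noise-free CPT/recovery with a linear negative
  amplitude coupling; the oracle for segmentation, features and for
  first-order Taylor exactness (the feature-BP map is affine, so a
  perfectly trained first-order PINN can be exact).
* :func:`nonlinear_subject` — a saturating (compliance-like) amplitude
  coupling plus realistic beat-to-beat variability: 10 % amplitude
  jitter, 2 %/3 % HR/delay jitter, respiratory modulation and sensor
  noise.  The variability is deliberately uninformative about BP: it is
  what a conventionally trained network overfits when labels are scarce,
  and what the Taylor-consistency term is designed to resist.

Each runner reports plain dictionaries of numbers so they can be asserted
in tests or serialized by scripts.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .estimator import TaylorPINNRegressor
from .preprocess import BeatDataset, preprocess_subject
from .simulate import SimConfig, generate_subject
from .splits import minimal_split

__all__ = ["linear_subject", "nonlinear_subject", "prepare_dataset",
           "run_minimal_label_comparison", "run_gradient_sign_recovery"]


def linear_subject(seed: int = 3) -> SimConfig:
    """Noise-free single CPT+recovery cycle, linear couplings."""
    return SimConfig(
        sessions=(("cpt", 120.0, 150.0), ("recovery", 120.0, 120.0)),
        noise_sd=0.0, seed=seed,
    )


def nonlinear_subject(seed: int = 0) -> SimConfig:
    """Two CPT/recovery cycles with a saturating amplitude coupling and
    physiological variability (the minimal-label comparison conditions)."""
    return SimConfig(
        sessions=(("cpt", 90.0, 134.0), ("recovery", 90.0, 121.0),
                  ("cpt", 90.0, 132.0), ("recovery", 90.0, 120.0)),
        amp_coupling=-0.012, amp_coupling_kind="saturating",
        noise_sd=0.02, amp_jitter_rel=0.10, hr_jitter_rel=0.02,
        delay_jitter_rel=0.03, amp_resp_rel=0.06, hr_resp_rel=0.04,
        hr_breakpoint=129.0, seed=seed,
    )


def prepare_dataset(config: SimConfig) -> BeatDataset:
    """Simulate one subject and run the full preprocessing pipeline."""
    trace, state = generate_subject(config)
    labels = pd.DataFrame({
        "beat_index": np.arange(state.n_beats),
        "onset_s": state.onset_s,
        "SBP": state.sbp, "DBP": state.dbp, "PP": state.pp,
        "session": state.session,
    })
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return preprocess_subject(trace, labels)


def _fit_and_score(ds: BeatDataset, beta: float, seed: int,
                   max_epochs: int):
    sbp = ds.y[:, 0]
    split = minimal_split(sbp, bin_width=1.0, seed=seed)
    y_fit = np.where(np.isin(np.arange(len(sbp)), split.train_idx),
                     sbp, np.nan)
    X = np.hstack([ds.x, ds.u])
    est = TaylorPINNRegressor(beta=beta, max_epochs=max_epochs,
                              random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit(X, y_fit, sessions=ds.session)
    pred = est.predict(X[split.test_idx])
    rmse = float(np.sqrt(np.mean((pred - sbp[split.test_idx]) ** 2)))
    return est, split, rmse


def run_minimal_label_comparison(seeds=range(5), max_epochs: int = 1200,
                                 subject_seed_base: int = 100) -> dict:
    """PINN (α=1, β=10) vs conventional CNN (β=0) at the same minimal-label
    budget on the nonlinear subject, per seed; reports per-seed RMSE (mmHg)
    and the medians."""
    pinn, cnn, n_labels = [], [], []
    for seed in seeds:
        ds = prepare_dataset(nonlinear_subject(subject_seed_base + seed))
        _, split, rmse_p = _fit_and_score(ds, beta=10.0, seed=seed,
                                          max_epochs=max_epochs)
        _, _, rmse_c = _fit_and_score(ds, beta=0.0, seed=seed,
                                      max_epochs=max_epochs)
        pinn.append(rmse_p)
        cnn.append(rmse_c)
        n_labels.append(split.n_train)
    return {
        "pinn_rmse": pinn, "cnn_rmse": cnn, "n_labels": n_labels,
        "pinn_median": float(np.median(pinn)),
        "cnn_median": float(np.median(cnn)),
    }


def run_gradient_sign_recovery(seed: int = 0, max_epochs: int = 1200) -> dict:
    """Train a PINN with minimal labels on the nonlinear subject (negative
    amplitude coupling) and measure how often the learned ∂y/∂u1 carries
    the configured negative sign on the test beats."""
    ds = prepare_dataset(nonlinear_subject(100 + seed))
    est, split, rmse = _fit_and_score(ds, beta=10.0, seed=seed,
                                      max_epochs=max_epochs)
    X = np.hstack([ds.x, ds.u])
    g = est.feature_gradients(X)
    negative = g[split.test_idx, 0] < 0
    return {
        "fraction_negative": float(np.mean(negative)),
        "n_test": int(len(split.test_idx)),
        "rmse": rmse,
        "history": est.history_,
    }
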