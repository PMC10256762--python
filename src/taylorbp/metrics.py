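"""Evaluation: error metrics, Bland-Altman agreement, AAMI-style grading,
and gradient-interpretation profiles.

Error sign convention throughout: ``error = estimated - true`` (so a
positive Bland-Altman bias means overestimation).  SDE uses the n-1 sample
convention.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats as sstats

from . import network

__all__ = ["MetricsReport", "compute_metrics", "bland_altman", "aami_grade",
           "GradientProfile", "gradient_profile", "sd_avg_across",
           "AAMI_THRESHOLDS"]

# |ME| and SDE ceilings (mmHg) per grade; values follow the cited device
# standard, not measured data here — override via the `thresholds` argument.
AAMI_THRESHOLDS = (("A", 5.0, 8.0), ("B", 6.0, 9.0), ("C", 7.0, 10.0))


@dataclasses.dataclass
class MetricsReport:
    me: float
    sde: float
    rmse: float
    pearson_r: float
    n: int
    scope: str = "per-subject"
    r_defined: bool = True

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def compute_metrics(est, true, scope: str = "per-subject") -> MetricsReport:
    """ME / SDE / RMSE / Pearson r of ``est - true``."""
    est = np.asarray(est, dtype=float).ravel()
    true = np.asarray(true, dtype=float).ravel()
    if est.shape != true.shape or est.size < 2:
        raise ValueError("need two equal-length series of at least 2 points")
    err = est - true
    me = float(err.mean())
    sde = float(err.std(ddof=1))
    rmse = float(np.sqrt(np.mean(err**2)))
    r_defined = bool(est.std() > 0 and true.std() > 0)
    r = float(sstats.pearsonr(est, true)[0]) if r_defined else float("nan")
    return MetricsReport(me=me, sde=sde, rmse=rmse, pearson_r=r,
                         n=est.size, scope=scope, r_defined=r_defined)


def bland_altman(est, true) -> dict:
    """Bias and 1.96-SD limits of agreement, plus plot-ready pairs."""
    est = np.asarray(est, dtype=float).ravel()
    true = np.asarray(true, dtype=float).ravel()
    if est.shape != true.shape or est.size < 2:
        raise ValueError("need two equal-length series of at least 2 points")
    diff = est - true
    bias = float(diff.mean())
    sde = float(diff.std(ddof=1))
    return {
        "bias": bias,
        "loa_lower": bias - 1.96 * sde,
        "loa_upper": bias + 1.96 * sde,
        "mean_pairs": (est + true) / 2.0,
        "diff_pairs": diff,
        "reliable": est.size >= 3,
    }


def aami_grade(report: MetricsReport, thresholds=AAMI_THRESHOLDS):
    """Grade |ME| and SDE against threshold ladders.

    Returns ``(grade, comparisons)``; beats falling outside every listed
    grade get "D".
    """
    if not thresholds:
        raise ValueError("no grading thresholds provided")
    comparisons = []
    for grade, me_max, sde_max in thresholds:
        ok = bool(abs(report.me) <= me_max and report.sde <= sde_max)
        comparisons.append({
            "grade": grade, "me_max": me_max, "sde_max": sde_max,
            "abs_me": abs(report.me), "sde": report.sde, "passed": ok,
        })
        if ok:
            return grade, comparisons
    return "D", comparisons


# -- gradient interpretation --------------------------------------------------

@dataclasses.dataclass
class GradientProfile:
    """Per-beat predictions and feature gradients with session tags."""

    y_nn: np.ndarray       # (n,)
    gradients: np.ndarray  # (n, M)
    session: np.ndarray    # (n,)

    def trend(self, session: str, feature: int) -> dict:
        """Mean gradient at each integer BP value within one session."""
        mask = self.session == session
        if not mask.any():
            raise KeyError(f"no beats in session {session!r}")
        bp = np.round(self.y_nn[mask]).astype(int)
        g = self.gradients[mask, feature]
        return {int(v): float(g[bp == v].mean()) for v in np.unique(bp)}

    @property
    def sessions(self) -> list:
        return sorted(set(self.session.tolist()))


def gradient_profile(model, x, u, sessions, y_nn=None) -> GradientProfile:
    """Per-beat ∂y/∂u profile of a trained model over a dataset."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    u = np.atleast_2d(np.asarray(u, dtype=float))
    if isinstance(model, network.ModelState):
        g = network.grad_wrt_features(model, x, u)
        if y_nn is None:
            y_nn = network.predict(model, x, u)
    else:
        g = model.grad_wrt_features(x, u, 1)
        if y_nn is None:
            y_nn = model.predict(x, u)
    return GradientProfile(y_nn=np.asarray(y_nn, dtype=float).ravel(),
                           gradients=np.asarray(g, dtype=float),
                           session=np.asarray(sessions, dtype=object))


def sd_avg_across(profiles, feature: int, session: str | None = None) -> float:
    """Trend-line spread across a group of models (or sessions).

    For each integer BP value present in every group member's trend, take
    the standard deviation of the trend values across the group, then
    average over BP values.  This is the consistency summary used to judge
    whether independently trained models discover the same feature-BP
    relation.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles to compare")
    trends = []
    for p in profiles:
        sess = session if session is not None else p.sessions[0]
        trends.append(p.trend(sess, feature))
    common = set(trends[0])
    for t in trends[1:]:
        common &= set(t)
    if not common:
        raise ValueError("trend lines share no integer BP values")
    sds = [np.std([t[v] for t in trends], ddof=0) for v in sorted(common)]
    return float(np.mean(sds))
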