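"""Train/test splits over beat-level BP labels.

The minimal-label criterion bins the label range at a fixed width
(default 1 mmHg) and places one uniformly random beat per populated bin in
the training set — e.g. 1000 beats spanning 120-160 mmHg give 40 training
and 960 test samples.  Bin count K follows the label *range* (empty bins
contribute nothing).  Also provided: an out-of-range split (train on the
tails, test on the middle band) and K-fold partitions that can be forced
to contain the minimal-criterion indices.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

__all__ = ["SplitSpec", "minimal_split", "out_of_range_split", "kfold_split"]


@dataclasses.dataclass
class SplitSpec:
    strategy: str
    train_idx: np.ndarray
    test_idx: np.ndarray
    bin_width: float | None = None
    n_bins: int | None = None
    seed: int | None = None

    def __post_init__(self):
        self.train_idx = np.asarray(self.train_idx, dtype=int)
        self.test_idx = np.asarray(self.test_idx, dtype=int)
        if np.intersect1d(self.train_idx, self.test_idx).size:
            raise ValueError("train and test sets overlap")

    @property
    def n_train(self) -> int:
        return len(self.train_idx)

    @property
    def n_test(self) -> int:
        return len(self.test_idx)


def _labeled_indices(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels, dtype=float)
    idx = np.flatnonzero(np.isfinite(labels))
    if idx.size == 0:
        raise ValueError("no labeled beats")
    return idx


def minimal_split(labels, bin_width: float = 1.0, seed: int = 0) -> SplitSpec:
    """One random labeled beat per populated ``bin_width``-mmHg bin."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    labels = np.asarray(labels, dtype=float)
    idx = _labeled_indices(labels)
    vals = labels[idx]
    lo, hi = vals.min(), vals.max()
    span = hi - lo
    n_bins = max(1, int(math.ceil(span / bin_width - 1e-12)))
    bins = np.minimum(((vals - lo) / bin_width).astype(int), n_bins - 1)

    rng = np.random.default_rng(seed)
    train = []
    for b in range(n_bins):
        members = idx[bins == b]
        if members.size:
            train.append(rng.choice(members))
    train = np.sort(np.asarray(train, dtype=int))
    test = np.setdiff1d(idx, train)
    return SplitSpec(strategy="minimal", train_idx=train, test_idx=test,
                     bin_width=bin_width, n_bins=n_bins, seed=seed)


def out_of_range_split(labels, middle_fraction: float = 0.5) -> SplitSpec:
    """Train on the label-value tails, test on the central band.

    The test band covers ``middle_fraction`` of the label range, centred;
    bands are defined on label values, not ranks.
    """
    if not 0 < middle_fraction < 1:
        raise ValueError("middle_fraction must be in (0, 1)")
    labels = np.asarray(labels, dtype=float)
    idx = _labeled_indices(labels)
    vals = labels[idx]
    lo, hi = vals.min(), vals.max()
    if hi <= lo:
        raise ValueError("labels must span a positive range")
    centre = 0.5 * (lo + hi)
    half = 0.5 * middle_fraction * (hi - lo)
    in_band = (vals > centre - half) & (vals < centre + half)
    test, train = idx[in_band], idx[~in_band]
    if test.size == 0 or train.size == 0:
        raise ValueError("out-of-range split produced an empty band")
    return SplitSpec(strategy="out_of_range", train_idx=train, test_idx=test)


def kfold_split(labels, k_folds: int, seed: int = 0,
                forced_train_indices=()) -> list:
    """Random partition into K equal-length sets; each fold's training set
    additionally contains ``forced_train_indices`` (e.g. the minimal-
    criterion beats)."""
    if k_folds < 2:
        raise ValueError("k_folds must be at least 2")
    labels = np.asarray(labels, dtype=float)
    idx = _labeled_indices(labels)
    if k_folds > idx.size:
        raise ValueError("more folds than labeled beats")
    forced = np.asarray(sorted(set(int(i) for i in forced_train_indices)),
                        dtype=int)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(idx)
    folds = np.array_split(perm, k_folds)
    specs = []
    for f in folds:
        test = np.setdiff1d(f, forced)
        train = np.union1d(np.setdiff1d(idx, test), forced)
        specs.append(SplitSpec(strategy=f"kfold{k_folds}", train_idx=train,
                               test_idx=test, seed=seed))
    return specs
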