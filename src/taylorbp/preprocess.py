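"""Bioimpedance preprocessing: filtering, beat segmentation, fiducials,
features, smoothing, resampling and normalization.

The pipeline mirrors standard pulse-waveform practice: a 6 Hz second-order
zero-phase Butterworth low-pass isolates the quasi-periodic volumetric
component; beats are segmented from the peaks of the inverted signal's
first derivative (maximum systolic slope) with the preceding derivative
zero-crossing marking the cycle onset; nine fiducial landmarks A..J are
located per beat on the inverted waveform; three physiological features are
derived per beat:

    u1 = (ΔZ)_A - (ΔZ)_C          amplitude drop (arterial volume proxy)
    u2 = 1 / (t_F - t_B)          inverse systolic-to-reflection delay
                                  (pulse-wave-velocity proxy), 1/s
    u3 = 60 / (t_J - t_A)         beat-to-beat heart rate, bpm

followed by a three-beat moving average with one-beat overlap, 30 Hz
resampling with zero padding, and per-channel z-normalization.
"""

from __future__ import annotations

import dataclasses
import json
import warnings

import h5py
import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "SignalTrace", "FiducialSet", "BeatRecord", "NormStats", "BeatDataset",
    "lowpass_filter", "segment_beats", "extract_fiducials", "compute_features",
    "moving_average_beats", "resample_and_pad", "fit_normalization",
    "preprocess_subject", "save_store", "load_store",
]

FIDUCIAL_LABELS = ("A", "B", "C", "D", "E", "F", "G", "H", "J")

HR_BAND_BPM = (20.0, 250.0)  # plausibility band for beat periodicity


@dataclasses.dataclass
class SignalTrace:
    """Uniformly sampled ΔZ series."""

    samples: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if len(self.samples) and not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs

    def time(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.samples)) / self.fs


@dataclasses.dataclass
class FiducialSet:
    """Nine labelled landmarks of one beat.

    ``points`` maps label -> (t_s, delta_z); entries are None when the
    morphology does not expose the landmark (flagged, never fabricated).
    """

    points: dict
    feature_complete: bool

    def __post_init__(self):
        times = [p[0] for lbl, p in
                 ((l, self.points.get(l)) for l in FIDUCIAL_LABELS)
                 if p is not None]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("fiducial times must increase in label order")

    def t(self, label: str) -> float:
        return self.points[label][0]

    def dz(self, label: str) -> float:
        return self.points[label][1]


@dataclasses.dataclass
class BeatRecord:
    """One (possibly averaged) cardiac cycle ready for the model."""

    x: np.ndarray          # fixed-length waveform (resampled, zero-padded)
    u: np.ndarray          # (u1, u2, u3)
    y: np.ndarray | None   # (SBP, DBP, PP) in mmHg, or None if unlabeled
    session: str
    index: int
    onset_s: float


@dataclasses.dataclass
class NormStats:
    """Per-channel z-score statistics (features, outputs, waveform)."""

    u_mean: np.ndarray
    u_sd: np.ndarray
    y_mean: np.ndarray
    y_sd: np.ndarray
    x_mean: float
    x_sd: float

    def __post_init__(self):
        if np.any(self.u_sd <= 0) or np.any(self.y_sd <= 0) or self.x_sd <= 0:
            raise ValueError("zero-variance channel: cannot normalize")

    def apply_u(self, u):
        return (np.asarray(u) - self.u_mean) / self.u_sd

    def invert_u(self, z):
        return np.asarray(z) * self.u_sd + self.u_mean

    def apply_y(self, y):
        return (np.asarray(y) - self.y_mean) / self.y_sd

    def invert_y(self, z):
        return np.asarray(z) * self.y_sd + self.y_mean

    def apply_x(self, x):
        return (np.asarray(x) - self.x_mean) / self.x_sd

    def invert_x(self, z):
        return np.asarray(z) * self.x_sd + self.x_mean

    def to_dict(self) -> dict:
        return {
            "u_mean": list(map(float, self.u_mean)),
            "u_sd": list(map(float, self.u_sd)),
            "y_mean": list(map(float, self.y_mean)),
            "y_sd": list(map(float, self.y_sd)),
            "x_mean": float(self.x_mean),
            "x_sd": float(self.x_sd),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormStats":
        return cls(
            u_mean=np.asarray(d["u_mean"]), u_sd=np.asarray(d["u_sd"]),
            y_mean=np.asarray(d["y_mean"]), y_sd=np.asarray(d["y_sd"]),
            x_mean=d["x_mean"], x_sd=d["x_sd"],
        )


# -- filtering ----------------------------------------------------------------

def lowpass_filter(trace: SignalTrace, cutoff_hz: float = 6.0,
                   order: int = 2) -> SignalTrace:
    """Zero-phase (forward-backward) Butterworth low-pass.

    Zero-phase application keeps fiducial timing unbiased, which matters
    because u2 is a timing feature.
    """
    if trace.fs <= 2.0 * cutoff_hz:
        raise ValueError(
            f"fs={trace.fs} Hz too low for a {cutoff_hz} Hz low-pass"
        )
    b, a = sps.butter(order, cutoff_hz, btype="low", fs=trace.fs)
    return SignalTrace(samples=sps.filtfilt(b, a, trace.samples),
                       fs=trace.fs, t0=trace.t0)


# -- segmentation -------------------------------------------------------------

def _max_slope_peaks(dw: np.ndarray, fs: float) -> np.ndarray:
    """Most-prominent derivative peaks (maximum systolic slope points) with
    plausible periodicity around the heart rate.

    Two passes: a high prominence bar first isolates the dominant
    (systolic) upstrokes and yields the beat period as the median peak
    interval; the second pass lowers the bar to catch weak beats while a
    minimum separation of 0.6 periods keeps the tallest peak per beat and
    rejects secondary/reflection slopes.
    """
    top = dw.max()
    if top <= 0 or dw.max() - dw.min() <= 0:
        return np.array([], dtype=int)
    min_dist = max(1, int(round(fs * 60.0 / HR_BAND_BPM[1])))
    max_period = fs * 60.0 / HR_BAND_BPM[0]
    coarse, _ = sps.find_peaks(dw, height=0.6 * top, distance=min_dist)
    if len(coarse) < 2:
        return np.array([], dtype=int)
    period = float(np.median(np.diff(coarse)))
    if not (min_dist <= period <= max_period):
        return np.array([], dtype=int)
    peaks, _ = sps.find_peaks(dw, height=0.2 * top,
                              distance=max(1, int(0.6 * period)))
    if len(peaks) < 2:
        return np.array([], dtype=int)
    # final periodicity screen: drop the weaker of any pair closer than
    # half the realised median interval (secondary slopes that slipped in)
    while len(peaks) >= 2:
        med = np.median(np.diff(peaks))
        gaps = np.diff(peaks)
        bad = np.flatnonzero(gaps < 0.5 * med)
        if not len(bad):
            break
        i = bad[0]
        drop = i if dw[peaks[i]] < dw[peaks[i + 1]] else i + 1
        peaks = np.delete(peaks, drop)
    return peaks


def segment_beats(trace: SignalTrace):
    """Segment a (filtered) trace into beat windows.

    Returns ``(onsets, windows)``: onset sample indices and half-open
    ``[onset_i, onset_{i+1})`` windows.  The onset is the derivative
    zero-crossing immediately preceding each maximum-slope point of the
    inverted waveform.  Returns empty arrays (with a warning) when no
    plausibly periodic peaks exist.
    """
    w = -trace.samples  # inverted waveform: systolic deflection positive
    if len(w) < 4:
        return np.array([], dtype=int), []
    dw = np.gradient(w) * trace.fs
    peaks = _max_slope_peaks(dw, trace.fs)
    if len(peaks) == 0:
        warnings.warn("no derivative peaks with plausible periodicity found")
        return np.array([], dtype=int), []

    onsets = []
    for p in peaks:
        i = p
        while i > 0 and dw[i - 1] > 0:
            i -= 1
        if i == 0:
            continue  # no confirmed zero-crossing before the record start
        # dw[i-1] <= 0 < dw[i]: linear sub-sample crossing, then round
        if i > 0 and dw[i] != dw[i - 1]:
            frac = dw[i - 1] / (dw[i - 1] - dw[i])  # in [0, 1]
            i = (i - 1) + int(round(frac))
        onsets.append(i)
    onsets = np.unique(np.asarray(onsets, dtype=int))
    windows = [(int(a), int(b)) for a, b in zip(onsets[:-1], onsets[1:])]
    return onsets, windows


# -- fiducials ----------------------------------------------------------------

def _refine_peak(y: np.ndarray, i: int) -> tuple[float, float]:
    """Sub-sample peak via parabolic interpolation around sample ``i``."""
    if i <= 0 or i >= len(y) - 1:
        return float(i), float(y[i])
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom == 0:
        return float(i), float(y1)
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    return i + delta, float(y1 - 0.25 * (y0 - y2) * delta)


def extract_fiducials(beat: np.ndarray, fs: float, t_start: float = 0.0,
                      raw: np.ndarray | None = None) -> FiducialSet:
    """Locate the nine landmarks A..J on one beat window (ΔZ samples).

    Detection operates on the inverted waveform and its first derivative.
    A = cycle onset (window start); B = maximum systolic slope; C =
    systolic peak; F = reflected-wave peak; J = cycle end (window end).
    D, E, G, H are the intervening extrema of the waveform/derivative and
    are carried as metadata.  A beat without a secondary (reflection)
    deflection is flagged ``feature_complete=False``.

    When the unfiltered window ``raw`` is supplied, landmark *times* are
    located on the (filtered) ``beat`` but *amplitudes* are read off the
    raw waveform, so the low-pass does not attenuate the u1 amplitude
    feature; timing features are unaffected by this choice.
    """
    beat = np.asarray(beat, dtype=float)
    n = len(beat)
    if n < 8:
        raise ValueError("beat window too short for fiducial extraction")
    if raw is not None:
        raw = np.asarray(raw, dtype=float)
        if raw.shape != beat.shape:
            raise ValueError("raw window must match the beat window")
    amp_src = raw if raw is not None else beat
    w = -beat
    dw = np.gradient(w) * fs

    def tp(idx_float: float) -> float:
        return t_start + idx_float / fs

    def amp_at(i: int) -> float:
        """ΔZ amplitude near sample i (parabolic peak on the raw source)."""
        j = int(np.clip(i, 1, n - 2))
        _, v = _refine_peak(-amp_src, j)
        return -v

    points: dict = {lbl: None for lbl in FIDUCIAL_LABELS}
    points["A"] = (tp(0.0), float(amp_src[0]))
    points["J"] = (tp(float(n)), float(amp_src[-1]))

    c_i = int(np.argmax(w))
    if raw is None:
        c_f, c_v = _refine_peak(w, c_i)
        points["C"] = (tp(c_f), -c_v)
    else:
        # re-localise the systolic peak on the raw waveform near c_i
        lo, hi = max(c_i - 5, 0), min(c_i + 6, n)
        cr_i = lo + int(np.argmax(-raw[lo:hi]))
        c_f, c_v = _refine_peak(-raw, cr_i)
        points["C"] = (tp(c_f), -c_v)

    b_i = int(np.argmax(dw[: max(c_i, 1)]))
    b_f, _ = _refine_peak(dw, b_i)
    points["B"] = (tp(b_f), float(amp_src[b_i]))

    # reflection peak: most prominent local max of w after the systolic peak
    feature_complete = False
    if c_i + 2 < n - 2:
        rel, props = sps.find_peaks(
            w[c_i + 1:], prominence=0.02 * (w[c_i] - w.min())
        )
        if len(rel):
            f_i = c_i + 1 + int(rel[np.argmax(props["prominences"])])
            f_f, _ = _refine_peak(w, f_i)
            points["F"] = (tp(f_f), amp_at(f_i))
            feature_complete = True

            e_i = c_i + int(np.argmin(w[c_i:f_i + 1]))
            points["E"] = (tp(float(e_i)), float(amp_src[e_i]))
            d_i = c_i + int(np.argmin(dw[c_i:e_i + 1]))
            points["D"] = (tp(float(d_i)), float(amp_src[d_i]))
            if e_i < f_i:
                g_i = e_i + int(np.argmax(dw[e_i:f_i + 1]))
                points["G"] = (tp(float(g_i)), float(amp_src[g_i]))
            if f_i + 1 < n:
                h_i = f_i + 1 + int(np.argmin(dw[f_i + 1:]))
                points["H"] = (tp(float(h_i)), float(amp_src[h_i]))
    if not feature_complete and c_i + 1 < n:
        d_i = c_i + int(np.argmin(dw[c_i:]))
        points["D"] = (tp(float(d_i)), float(amp_src[d_i]))

    # enforce label-order monotonicity: drop violating metadata points;
    # a violating *required* point makes the beat feature-incomplete
    # (degenerate morphology) rather than fabricating an ordering
    ordered: dict = {}
    last_t = -np.inf
    for lbl in FIDUCIAL_LABELS:
        p = points[lbl]
        if p is None:
            ordered[lbl] = None
        elif p[0] > last_t:
            ordered[lbl] = p
            last_t = p[0]
        else:
            ordered[lbl] = None
            if lbl in ("A", "B", "C", "F", "J"):
                feature_complete = False
    return FiducialSet(points=ordered, feature_complete=feature_complete)


def compute_features(fids: FiducialSet) -> np.ndarray:
    """u = (u1, u2, u3) from the landmark formulas."""
    if not fids.feature_complete or fids.points.get("F") is None:
        raise ValueError("beat is feature-incomplete (no reflected pulse)")
    for lbl in ("A", "B", "C", "F", "J"):
        if fids.points.get(lbl) is None:
            raise ValueError(f"missing required fiducial {lbl}")
    if fids.t("F") <= fids.t("B"):
        raise ValueError("t_F must exceed t_B")
    if fids.t("J") <= fids.t("A"):
        raise ValueError("t_J must exceed t_A")
    u1 = fids.dz("A") - fids.dz("C")
    u2 = 1.0 / (fids.t("F") - fids.t("B"))
    u3 = 60.0 / (fids.t("J") - fids.t("A"))
    return np.array([u1, u2, u3])


# -- smoothing / resampling ---------------------------------------------------

def moving_average_beats(records: list) -> list:
    """Three-beat moving average with one-beat overlap (stride 2).

    Waveforms, features and BP labels are averaged elementwise per window;
    consecutive windows share exactly one beat.  Output length is
    ``(n - 3)//2 + 1``.
    """
    n = len(records)
    if n < 3:
        raise ValueError("moving average requires at least 3 beats")
    out = []
    for j, start in enumerate(range(0, n - 2, 2)):
        grp = records[start:start + 3]
        ys = [r.y for r in grp]
        y = None if any(v is None for v in ys) else np.mean(ys, axis=0)
        out.append(BeatRecord(
            x=np.mean([r.x for r in grp], axis=0),
            u=np.mean([r.u for r in grp], axis=0),
            y=y,
            session=grp[1].session,
            index=j,
            onset_s=grp[1].onset_s,
        ))
    return out


def resample_and_pad(beat: np.ndarray, fs: float, target_fs: float = 30.0,
                     n_pad: int | None = None) -> np.ndarray:
    """Resample one beat to ``target_fs`` then right-pad with zeros to
    ``n_pad`` samples (linear interpolation on the common time axis)."""
    beat = np.asarray(beat, dtype=float)
    dur = len(beat) / fs
    m = int(round(dur * target_fs))
    if n_pad is not None and m > n_pad:
        raise ValueError(
            f"beat needs {m} samples at {target_fs} Hz; N={n_pad} is too "
            f"small (require N >= {m})"
        )
    t_new = np.arange(m) / target_fs
    t_old = np.arange(len(beat)) / fs
    resampled = np.interp(t_new, t_old, beat)
    if n_pad is None:
        return resampled
    return np.pad(resampled, (0, n_pad - m))


# -- normalization ------------------------------------------------------------

def fit_normalization(u: np.ndarray, y: np.ndarray,
                      x: np.ndarray | None = None) -> NormStats:
    """Z-score statistics per feature and per output over a dataset.

    Fit on the full per-subject dataset by default (train-only fitting is
    available simply by passing the training subset).
    """
    u = np.asarray(u, dtype=float)
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if y.shape[0] == 1 and u.shape[0] != 1:
        y = y.T
    x_mean, x_sd = (0.0, 1.0)
    if x is not None:
        x = np.asarray(x, dtype=float)
        x_mean, x_sd = float(x.mean()), float(x.std())
    return NormStats(
        u_mean=u.mean(axis=0), u_sd=u.std(axis=0),
        y_mean=np.nanmean(y, axis=0), y_sd=np.nanstd(y, axis=0),
        x_mean=x_mean, x_sd=x_sd,
    )


# -- end-to-end pipeline ------------------------------------------------------

@dataclasses.dataclass
class BeatDataset:
    """Segmented-beat store for one subject (model-ready arrays)."""

    x: np.ndarray          # (n, N) resampled, padded waveforms
    u: np.ndarray          # (n, 3)
    y: np.ndarray          # (n, 3) SBP/DBP/PP in mmHg (NaN when unlabeled)
    session: np.ndarray    # (n,) tags
    onset_s: np.ndarray    # (n,)
    n_pad: int
    target_fs: float

    @property
    def n_beats(self) -> int:
        return self.x.shape[0]


def _assign_labels(onset_times: np.ndarray, labels: pd.DataFrame | None):
    if labels is None or len(labels) == 0:
        return (np.full((len(onset_times), 3), np.nan),
                np.array(["all"] * len(onset_times), dtype=object))
    lab_t = labels["onset_s"].to_numpy()
    med = np.median(np.diff(lab_t)) if len(lab_t) > 1 else np.inf
    y = np.full((len(onset_times), 3), np.nan)
    tags = np.array(["all"] * len(onset_times), dtype=object)
    for i, t in enumerate(onset_times):
        j = int(np.argmin(np.abs(lab_t - t)))
        if np.abs(lab_t[j] - t) <= 0.5 * med:
            y[i] = labels.iloc[j][["SBP", "DBP", "PP"]].to_numpy(dtype=float)
            tags[i] = str(labels.iloc[j]["session"])
    return y, tags


def preprocess_subject(trace: SignalTrace, labels: pd.DataFrame | None = None,
                       smooth: bool = True, target_fs: float = 30.0,
                       n_pad: int | None = None,
                       lowpass: bool = True) -> BeatDataset:
    """Raw trace + beat labels -> model-ready :class:`BeatDataset`.

    Steps: 6 Hz low-pass, segmentation, fiducials, features, optional
    three-beat average, 30 Hz resampling with zero padding (N defaults to
    the 95th-percentile beat duration), feature plausibility screening.
    Beats with incomplete fiducials or implausible features are dropped.
    """
    filt = lowpass_filter(trace) if lowpass else trace
    onsets, windows = segment_beats(filt)
    if len(windows) == 0:
        raise ValueError("no beats segmented from trace")

    records = []
    for k, (a, b) in enumerate(windows):
        beat = filt.samples[a:b]
        try:
            fids = extract_fiducials(beat, filt.fs,
                                     t_start=filt.t0 + a / filt.fs,
                                     raw=trace.samples[a:b] if lowpass
                                     else None)
            u = compute_features(fids)
        except ValueError:
            continue
        if not (u[1] > 0 and HR_BAND_BPM[0] < u[2] < HR_BAND_BPM[1]):
            continue
        records.append(BeatRecord(
            x=beat, u=u, y=None, session="all", index=k,
            onset_s=filt.t0 + a / filt.fs,
        ))
    if not records:
        raise ValueError("no feature-complete beats in trace")

    onset_arr = np.array([r.onset_s for r in records])
    y, tags = _assign_labels(onset_arr, labels)
    for r, yi, tag in zip(records, y, tags):
        r.y = yi if np.all(np.isfinite(yi)) else None
        r.session = tag

    # fixed-length waveforms first (N from the beat-duration distribution),
    # then the three-beat average on equal-length records
    durations = np.array([len(r.x) for r in records]) / filt.fs
    if n_pad is None:
        n_pad = int(np.ceil(np.percentile(durations, 95) * target_fs))
    resampled = []
    dropped = 0
    for r in records:
        try:
            xr = resample_and_pad(r.x, filt.fs, target_fs, n_pad)
        except ValueError:
            dropped += 1
            continue
        resampled.append(dataclasses.replace(r, x=xr))
    if dropped:
        warnings.warn(f"dropped {dropped} beats longer than N={n_pad} at "
                      f"{target_fs} Hz")
    if smooth:
        resampled = moving_average_beats(resampled)

    xs = [r.x for r in resampled]
    us = [r.u for r in resampled]
    ys = [r.y if r.y is not None else np.full(3, np.nan) for r in resampled]
    sess = [r.session for r in resampled]
    ons = [r.onset_s for r in resampled]
    return BeatDataset(
        x=np.asarray(xs), u=np.asarray(us), y=np.asarray(ys),
        session=np.asarray(sess, dtype=object), onset_s=np.asarray(ons),
        n_pad=int(n_pad), target_fs=float(target_fs),
    )


# -- persistent store ---------------------------------------------------------

def save_store(path, subjects: dict, stats: NormStats | None = None) -> None:
    """HDF5 store: one group per subject (x, u, y, session, onset_s) plus a
    JSON sidecar with the normalization statistics and padded length."""
    path = str(path)
    with h5py.File(path, "w") as f:
        for name, ds in subjects.items():
            g = f.create_group(str(name))
            g.create_dataset("x", data=ds.x)
            g.create_dataset("u", data=ds.u)
            g.create_dataset("y", data=ds.y)
            g.create_dataset("session",
                             data=np.asarray(ds.session, dtype="S32"))
            g.create_dataset("onset_s", data=ds.onset_s)
            g.attrs["n_pad"] = ds.n_pad
            g.attrs["target_fs"] = ds.target_fs
    sidecar = {"n_pad": {str(k): int(v.n_pad) for k, v in subjects.items()}}
    if stats is not None:
        sidecar["norm_stats"] = stats.to_dict()
    with open(path + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=1)


def load_store(path):
    """Inverse of :func:`save_store`: ``(subjects dict, NormStats | None)``."""
    path = str(path)
    subjects = {}
    with h5py.File(path, "r") as f:
        for name in f:
            g = f[name]
            subjects[name] = BeatDataset(
                x=g["x"][()], u=g["u"][()], y=g["y"][()],
                session=np.array([s.decode() for s in g["session"][()]],
                                 dtype=object),
                onset_s=g["onset_s"][()],
                n_pad=int(g.attrs["n_pad"]),
                target_fs=float(g.attrs["target_fs"]),
            )
    stats = None
    try:
        with open(path + ".json") as fh:
            sidecar = json.load(fh)
        if "norm_stats" in sidecar:
            stats = NormStats.from_dict(sidecar["norm_stats"])
    except FileNotFoundError:
        pass
    return subjects, stats
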