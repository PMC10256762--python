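"""Synthetic bioimpedance / blood-pressure generator.

Emits quasi-periodic ΔZ traces whose per-beat morphology is driven by a
latent blood-pressure trajectory through three couplings a practitioner
would recognise:

* pulse amplitude falls as BP rises (CPT-like peripheral vasoconstriction:
  higher sympathetic tone, smaller arterial volume excursion);
* the reflected-wave delay shortens as BP rises (stiffer wall, higher pulse
  wave velocity, earlier reflection arrival);
* heart rate has a biphasic relation to BP: positive slope below a
  breakpoint, negative above (vagal dominance at high pressure).

Each beat of the *inverted* waveform (−ΔZ) is built from closed-form cosine
lobes so that every fiducial landmark has an exact analytic location:

    rise (half-width W1)  -> systolic peak at onset + W1, height A_k
    fall (half-width W2)  -> diastolic plateau at height beta * A_k
    reflection bump       -> symmetric, peak exactly at onset + W1 + d_k
    pre-onset dip         -> the time-reversed systolic rise truncated at
                             the plateau level, so the valley around every
                             onset is locally an even function and
                             zero-phase filtering does not move the
                             onset's derivative zero-crossing

The latent truths (per-beat SBP/DBP/PP, onset, amplitude, delay, HR and the
noise-free features u1, u2, u3) are recorded exactly, so the whole
downstream pipeline can be checked against a known ground truth.  This is a
phenomenological emulator, not an arterial-tree model: only the qualitative
couplings above are claimed.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import SignalTrace

__all__ = [
    "SimConfig",
    "LatentState",
    "generate_subject",
    "analytic_feature_gradients",
    "export_trace",
    "load_trace",
    "load_labels",
]

# beat morphology constants (seconds unless noted); see module docstring
SYS_RISE_W = 0.14       # systolic upstroke half-width
SYS_FALL_W = 0.06       # systolic decay half-width (to the plateau)
REFL_W = 0.09           # reflection bump half-width (symmetric)
REFL_REL_AMP = 0.45     # reflection amplitude relative to the systolic peak
PLATEAU_FRAC = 0.45     # diastolic plateau height relative to systolic peak
# the pre-onset dip is the time-reversed systolic rise truncated at the
# plateau level, so the valley around each onset is an even function over
# +-DIP_W and zero-phase filtering leaves the onset's derivative
# zero-crossing in place
DIP_W = (SYS_RISE_W / math.pi) * math.acos(1.0 - 2.0 * PLATEAU_FRAC)


@dataclasses.dataclass
class SimConfig:
    """Study-condition parameters for one synthetic subject.

    ``sessions`` is an ordered list of ``(kind, duration_s, target_sbp)``
    tuples, ``kind in {"cpt", "recovery"}``; SBP ramps smoothly (raised
    cosine) from the previous level to each session target.
    """

    sessions: tuple = (("cpt", 120.0, 150.0), ("recovery", 120.0, 120.0))
    fs: float = 250.0
    baseline_sbp: float = 120.0
    baseline_dbp: float = 80.0
    amp0: float = 1.0                 # ΔZ units at baseline SBP
    amp_coupling: float = -0.01       # a1: ΔZ units per mmHg (vasoconstriction => < 0)
    amp_coupling_kind: str = "linear"  # or "saturating" (compliance-like)
    amp_saturation_mmhg: float = 25.0  # scale of the saturating coupling
    reflection_delay0: float = 0.22   # s at baseline SBP
    reflection_coupling: float = -1.0e-3  # a2: s per mmHg (PWV rises with BP => < 0)
    hr0: float = 65.0                 # bpm at baseline SBP
    hr_slope_low: float = 0.25        # bpm per mmHg below the breakpoint
    hr_slope_high: float = -0.20      # bpm per mmHg above the breakpoint
    hr_breakpoint: float = 145.0      # mmHg where the HR-BP slope flips
    dbp_ratio: float = 0.5            # dDBP/dSBP along the trajectory
    ramp_s: float = 15.0              # max raised-cosine transition length
    noise_sd: float = 0.0             # additive white Gaussian, ΔZ units
    amp_jitter_rel: float = 0.0       # per-beat amplitude variability (rel.)
    hr_jitter_rel: float = 0.0        # per-beat HR variability (rel.)
    delay_jitter_rel: float = 0.0     # per-beat reflection-delay variability
    resp_rate_hz: float = 0.25        # respiratory modulation frequency
    amp_resp_rel: float = 0.0         # respiratory amplitude modulation (rel.)
    hr_resp_rel: float = 0.0          # respiratory sinus arrhythmia (rel.)
    seed: int = 0
    subject_id: int = 0

    @property
    def duration_s(self) -> float:
        return float(sum(d for _, d, _ in self.sessions))

    def validate(self) -> None:
        if not self.sessions:
            raise ValueError("at least one session is required")
        for kind, dur, target in self.sessions:
            if kind not in ("cpt", "recovery"):
                raise ValueError(f"unknown session kind {kind!r}")
            if not np.isfinite([dur, target]).all() or dur <= 0:
                raise ValueError("session duration/target must be finite and positive")
            if dur < 60.0 / min(self.hr0, 250.0):
                raise ValueError(
                    f"session of {dur} s is shorter than one beat period"
                )
        scalars = [
            self.fs, self.baseline_sbp, self.baseline_dbp, self.amp0,
            self.amp_coupling, self.reflection_delay0, self.reflection_coupling,
            self.hr0, self.hr_slope_low, self.hr_slope_high, self.hr_breakpoint,
            self.noise_sd,
        ]
        if not np.isfinite(scalars).all():
            raise ValueError("non-finite value in SimConfig")
        if self.fs <= 0 or self.noise_sd < 0:
            raise ValueError("fs must be > 0 and noise_sd >= 0")
        if min(self.amp_jitter_rel, self.hr_jitter_rel,
               self.delay_jitter_rel) < 0:
            raise ValueError("jitter magnitudes must be >= 0")
        if self.amp_coupling_kind not in ("linear", "saturating"):
            raise ValueError("amp_coupling_kind must be 'linear' or 'saturating'")


@dataclasses.dataclass
class LatentState:
    """Exact per-beat ground truth recorded by the generator."""

    onset_s: np.ndarray        # beat onset times (strictly increasing)
    period_s: np.ndarray       # beat period tau_k
    sbp: np.ndarray            # mmHg
    dbp: np.ndarray
    pp: np.ndarray
    amplitude: np.ndarray      # systolic peak height A_k, ΔZ units
    reflection_delay: np.ndarray  # d_k, s
    hr: np.ndarray             # instantaneous HR, bpm
    session: np.ndarray        # tag per beat, e.g. "cpt1"

    def __post_init__(self):
        if not np.all(np.diff(self.onset_s) > 0):
            raise ValueError("onset times must be strictly increasing")
        if not np.all(self.sbp > self.dbp) or not np.all(self.dbp > 0):
            raise ValueError("requires SBP > DBP > 0 per beat")
        if not np.all((self.reflection_delay > 0)
                      & (self.reflection_delay < self.period_s)):
            raise ValueError("reflection delay must lie in (0, beat period)")

    @property
    def n_beats(self) -> int:
        return len(self.onset_s)

    # noise-free features of the emitted waveform, in closed form
    @property
    def u1(self) -> np.ndarray:
        """(ΔZ)_A - (ΔZ)_C of the noise-free beat = systolic peak height."""
        return self.amplitude.copy()

    @property
    def u2(self) -> np.ndarray:
        """1/(t_F - t_B): reflection peak at W1 + d, max slope at W1/2."""
        return 1.0 / (self.reflection_delay + SYS_RISE_W / 2.0)

    @property
    def u3(self) -> np.ndarray:
        """60/(t_J - t_A) = instantaneous heart rate in bpm."""
        return 60.0 / self.period_s

    @property
    def u(self) -> np.ndarray:
        return np.column_stack([self.u1, self.u2, self.u3])

    # analytic landmark times (used by the fiducial oracle tests)
    @property
    def t_b(self) -> np.ndarray:
        return self.onset_s + SYS_RISE_W / 2.0

    @property
    def t_c(self) -> np.ndarray:
        return self.onset_s + SYS_RISE_W

    @property
    def t_f(self) -> np.ndarray:
        return self.onset_s + SYS_RISE_W + self.reflection_delay


# -- latent trajectory --------------------------------------------------------

def _sbp_trajectory(config: SimConfig):
    """Piecewise raised-cosine SBP(t) through the session targets."""
    starts, levels, targets, kinds = [], [], [], []
    t0, level = 0.0, config.baseline_sbp
    for kind, dur, target in config.sessions:
        starts.append(t0)
        levels.append(level)
        targets.append(target)
        kinds.append(kind)
        t0 += dur
        level = target
    starts = np.asarray(starts)
    durs = np.asarray([d for _, d, _ in config.sessions])

    def sbp(t: float) -> float:
        j = int(np.searchsorted(starts, t, side="right") - 1)
        j = min(max(j, 0), len(starts) - 1)
        ramp = min(config.ramp_s, durs[j] / 2.0)
        dt = t - starts[j]
        lo, hi = levels[j], targets[j]
        if dt >= ramp:
            return hi
        return lo + (hi - lo) * 0.5 * (1.0 - math.cos(math.pi * dt / ramp))

    def session_tag(t: float) -> str:
        j = int(np.searchsorted(starts, t, side="right") - 1)
        j = min(max(j, 0), len(starts) - 1)
        occurrence = 1 + sum(1 for k in kinds[:j] if k == kinds[j])
        return f"{kinds[j]}{occurrence}"

    return sbp, session_tag


def _amplitude(config: SimConfig, sbp: np.ndarray) -> np.ndarray:
    ds = np.asarray(sbp) - config.baseline_sbp
    if config.amp_coupling_kind == "linear":
        return config.amp0 + config.amp_coupling * ds
    s = config.amp_saturation_mmhg
    return config.amp0 + config.amp_coupling * s * np.tanh(ds / s)


def _amplitude_slope(config: SimConfig, sbp: np.ndarray) -> np.ndarray:
    """dA/dSBP along the configured coupling."""
    ds = np.asarray(sbp) - config.baseline_sbp
    if config.amp_coupling_kind == "linear":
        return np.full_like(ds, config.amp_coupling, dtype=float)
    return config.amp_coupling / np.cosh(ds / config.amp_saturation_mmhg) ** 2


def _heart_rate(config: SimConfig, sbp: float) -> float:
    b = config.hr_breakpoint
    base = config.hr0 + config.hr_slope_low * (min(sbp, b) - config.baseline_sbp)
    if sbp > b:
        base += config.hr_slope_high * (sbp - b)
    return base


# -- waveform synthesis -------------------------------------------------------

def _beat_waveform(t_rel: np.ndarray, amp: float, delay: float,
                   period: float) -> np.ndarray:
    """Inverted-waveform (−ΔZ) template for one beat on t_rel ∈ [0, period)."""
    w = np.zeros_like(t_rel)
    plateau = PLATEAU_FRAC * amp

    m = (t_rel >= 0) & (t_rel < SYS_RISE_W)
    w[m] = amp * 0.5 * (1.0 - np.cos(np.pi * t_rel[m] / SYS_RISE_W))
    m = (t_rel >= SYS_RISE_W) & (t_rel < SYS_RISE_W + SYS_FALL_W)
    w[m] = plateau + (amp - plateau) * 0.5 * (
        1.0 + np.cos(np.pi * (t_rel[m] - SYS_RISE_W) / SYS_FALL_W)
    )
    m = (t_rel >= SYS_RISE_W + SYS_FALL_W) & (t_rel < period - DIP_W)
    w[m] = plateau
    m = (t_rel >= period - DIP_W) & (t_rel < period)
    w[m] = amp * 0.5 * (1.0 - np.cos(np.pi * (period - t_rel[m]) / SYS_RISE_W))

    peak = SYS_RISE_W + delay
    m = np.abs(t_rel - peak) <= REFL_W
    w[m] += REFL_REL_AMP * amp * 0.5 * (
        1.0 + np.cos(np.pi * (t_rel[m] - peak) / REFL_W)
    )
    return w


def _check_geometry(delay: float, period: float) -> None:
    if delay - REFL_W < SYS_FALL_W:
        raise ValueError(
            "reflection bump would overlap the systolic decay; "
            "increase reflection_delay0 or reduce |reflection_coupling|"
        )
    if SYS_RISE_W + delay + REFL_W > period - DIP_W:
        raise ValueError(
            "beat period too short for the reflection bump; "
            "lower the heart rate or the reflection delay"
        )


def generate_subject(config: SimConfig):
    """Simulate one subject.

    Returns ``(SignalTrace, LatentState)``.  The trace holds ΔZ (negative
    systolic deflections); the latent state holds the exact per-beat truths.
    Identical config (including seed) gives bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(
        np.random.SeedSequence([int(config.seed), int(config.subject_id)])
    )
    sbp_of_t, tag_of_t = _sbp_trajectory(config)
    total = config.duration_s

    resp_phase = rng.uniform(0, 2 * np.pi, size=2)
    onsets, periods, sbps, hrs, tags = [], [], [], [], []
    t = 0.0
    while True:
        s = sbp_of_t(t)
        hr = _heart_rate(config, s)
        if config.hr_resp_rel > 0:
            hr *= 1.0 + config.hr_resp_rel * math.sin(
                2 * np.pi * config.resp_rate_hz * t + resp_phase[0])
        if config.hr_jitter_rel > 0:
            hr *= 1.0 + config.hr_jitter_rel * rng.standard_normal()
        if not 20.0 <= hr <= 250.0:
            raise ValueError(f"heart rate {hr:.1f} bpm outside plausible band")
        tau = 60.0 / hr
        if t + tau > total + 1e-9:
            break
        onsets.append(t)
        periods.append(tau)
        sbps.append(s)
        hrs.append(hr)
        tags.append(tag_of_t(t))
        t += tau
    if not onsets:
        raise ValueError("no complete beat fits in the configured duration")

    onsets = np.asarray(onsets)
    periods = np.asarray(periods)
    sbps = np.asarray(sbps)
    hrs = np.asarray(hrs)
    amps = _amplitude(config, sbps)
    if config.amp_resp_rel > 0:
        amps = amps * (1.0 + config.amp_resp_rel * np.sin(
            2 * np.pi * config.resp_rate_hz * onsets + resp_phase[1]))
    if config.amp_jitter_rel > 0:
        amps = amps * (1.0 + config.amp_jitter_rel
                       * rng.standard_normal(len(amps)))
    if np.any(amps <= 0):
        raise ValueError("amplitude coupling drives pulse amplitude <= 0")
    delays = config.reflection_delay0 + config.reflection_coupling * (
        sbps - config.baseline_sbp
    )
    if config.delay_jitter_rel > 0:
        delays = delays * (1.0 + config.delay_jitter_rel
                           * rng.standard_normal(len(delays)))
    for d, tau in zip(delays, periods):
        _check_geometry(float(d), float(tau))

    dbps = config.baseline_dbp + config.dbp_ratio * (sbps - config.baseline_sbp)
    state = LatentState(
        onset_s=onsets, period_s=periods, sbp=sbps, dbp=dbps, pp=sbps - dbps,
        amplitude=amps, reflection_delay=delays, hr=hrs,
        session=np.asarray(tags, dtype=object),
    )

    n = int(round(total * config.fs))
    tgrid = np.arange(n) / config.fs
    w = np.zeros(n)
    for T, tau, A, d in zip(onsets, periods, amps, delays):
        i0 = int(np.ceil(T * config.fs - 1e-9))
        i1 = min(int(np.floor((T + tau) * config.fs)), n - 1)
        sl = slice(i0, i1 + 1)
        w[sl] += _beat_waveform(tgrid[sl] - T, float(A), float(d), float(tau))
    delta_z = -w
    if config.noise_sd > 0:
        delta_z = delta_z + rng.normal(0.0, config.noise_sd, size=n)
    return SignalTrace(samples=delta_z, fs=config.fs, t0=0.0), state


# -- feature-gradient oracle --------------------------------------------------

def analytic_feature_gradients(config: SimConfig, state: LatentState) -> np.ndarray:
    """Exact (∂SBP/∂u1, ∂SBP/∂u2, ∂SBP/∂u3) per beat, from the couplings.

    Uses the inverse-function rule on the configured (monotone) feature-BP
    maps evaluated along the realised trajectory.  Rejects configurations
    whose couplings are not single-valued over the realised SBP range
    (e.g. the biphasic HR map straddling its breakpoint).
    """
    a_slope = _amplitude_slope(config, state.sbp)
    if np.any(a_slope == 0):
        raise ValueError("amplitude coupling has zero slope: gradient undefined")

    a2 = config.reflection_coupling
    if a2 == 0:
        raise ValueError("reflection coupling has zero slope: gradient undefined")
    # u2 = 1/(d(S) + W1/2)  =>  dSBP/du2 = -(d + W1/2)^2 / a2
    du2 = -((state.reflection_delay + SYS_RISE_W / 2.0) ** 2) / a2

    lo, hi = state.sbp.min(), state.sbp.max()
    if lo < config.hr_breakpoint < hi and np.sign(config.hr_slope_low) != np.sign(
        config.hr_slope_high
    ):
        raise ValueError(
            "HR-BP map is non-monotone on the realised range "
            "(breakpoint crossed): ∂SBP/∂u3 undefined as single-valued"
        )
    hr_slope = config.hr_slope_low if hi <= config.hr_breakpoint else config.hr_slope_high
    if hr_slope == 0:
        raise ValueError("HR coupling has zero slope: gradient undefined")

    return np.column_stack([
        1.0 / a_slope,
        du2,
        np.full(state.n_beats, 1.0 / hr_slope),
    ])


# -- file interchange ---------------------------------------------------------

def export_trace(trace: SignalTrace, labels: LatentState, trace_path,
                 labels_path) -> None:
    """Write the CSV layout consumed by :mod:`taylorbp.preprocess`.

    Trace: columns ``time_s,delta_z``.  Labels: one row per beat with
    ``beat_index,onset_s,SBP,DBP,PP,session``.  Round-trips losslessly.
    """
    if len(trace.samples) == 0:
        raise ValueError("refusing to export an empty trace")
    t = trace.t0 + np.arange(len(trace.samples)) / trace.fs
    pd.DataFrame({"time_s": t, "delta_z": trace.samples}).to_csv(
        trace_path, index=False, float_format="%.17g"
    )
    pd.DataFrame({
        "beat_index": np.arange(labels.n_beats),
        "onset_s": labels.onset_s,
        "SBP": labels.sbp,
        "DBP": labels.dbp,
        "PP": labels.pp,
        "session": labels.session,
    }).to_csv(labels_path, index=False, float_format="%.17g")


def load_trace(path) -> SignalTrace:
    df = pd.read_csv(path, float_precision="round_trip")
    t = df["time_s"].to_numpy()
    if len(t) < 2:
        raise ValueError("trace file must contain at least two samples")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ValueError("trace is not uniformly sampled")
    return SignalTrace(samples=df["delta_z"].to_numpy(),
                       fs=1.0 / float(np.mean(dt)), t0=float(t[0]))


def load_labels(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"beat_index", "onset_s", "SBP", "DBP", "PP", "session"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"label file missing columns: {sorted(missing)}")
    return df


def load_subject(trace_path, labels_path):
    """Convenience loader returning ``(SignalTrace, labels DataFrame)``."""
    return load_trace(Path(trace_path)), load_labels(Path(labels_path))
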