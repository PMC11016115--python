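"""Synthetic two-task gradual-rotation experiment generator.

Emulates the study design this package analyses: 8 subjects perform a
visually-guided and a memory-guided reaching task of 180 trials each
(baseline 30, adaptation 4 x 30, washout 30).  Targets appear 8 cm from the
start circle at a uniform random angle in [-10, +10] deg; during adaptation
the cursor is rotated counterclockwise by 0.2 deg/trial up to a 20 deg
ceiling.  Hand angles are produced by the single-rate state-space learner
(``reachadapt.adaptation``) driven by the cursor error it experiences, plus
Gaussian motor noise; each reach is a minimum-jerk trajectory sampled at
60 Hz.  Twenty-channel event-marked EEG is synthesized as 1/f background
noise carrying task-modulated band-limited oscillations (by default a
post-feedback parietal delta increase and a pre-movement C3/Fz beta decrease,
both stronger in the visually-guided task).

Oscillatory effects are injected as a Tukey-windowed multiplicative gain on
the band-passed component of each effect channel's own background.  The
scalar gain is calibrated through a forward model of the analysis chain
(wavelet temporal smearing into both the analysis window and the pre-event
baseline) so that the *measured* band-averaged dB difference between tasks
equals the configured value in expectation -- closing the loop between the
generator and the time-frequency/decoding modules.

Everything is seeded: one top-level seed fans out to fixed named substreams
(design, behaviour, EEG), so identical configurations yield byte-identical
on-disk datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, signal
from scipy import stats as sps

from .adaptation import RotationSchedule, build_rotation_schedule
from .timefreq import EEGRecording, wavelet_sigma_t

__all__ = [
    "TASKS",
    "QUICK20_CHANNELS",
    "EVENT_LABELS",
    "ExperimentDesign",
    "LearnerParams",
    "EEGEffect",
    "EEGParams",
    "DatasetFormatError",
    "make_design",
    "simulate_behavior",
    "simulate_eeg",
    "write_dataset",
    "read_dataset",
]

TASKS = ("visual", "memory")

# 10-20 montage of the 20-channel dry-electrode cap used in this paradigm.
QUICK20_CHANNELS = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T7", "C3", "Cz", "C4", "T8",
    "P7", "P3", "Pz", "P4", "P8",
    "O1", "Oz", "O2",
)

EVENT_LABELS = ("target_on", "go", "reach_onset", "feedback")

TARGET_DISTANCE_MM = 80.0  # feedback appears when the cursor crosses this radius
REACH_AMPLITUDE_MM = 100.0  # "shoot through the target": reaches overshoot the ring
FS_TRAJECTORY = 60.0

# Named substreams of the top-level seed.
_STREAM_DESIGN, _STREAM_BEHAVIOR, _STREAM_EEG = 0, 1, 2


class DatasetFormatError(ValueError):
    """Malformed or truncated on-disk dataset; message names file and line."""


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=[int(seed), *map(int, key)]))


# --------------------------------------------------------------------------
# Design
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ExperimentDesign:
    """Trial-level design table plus the parameters that generated it.

    ``trials`` has one row per subject x task x trial with columns
    ``subject, task, block_index (1..6), block_role, trial_in_block,
    trial_overall, target_angle_deg, rotation_deg``.
    """

    n_subjects: int
    tasks: tuple[str, ...]
    trials_per_block: int
    seed: int
    trials: pd.DataFrame
    schedule: RotationSchedule

    @property
    def n_trials_per_task(self) -> int:
        return 6 * self.trials_per_block


def make_design(
    n_subjects: int = 8,
    seed: int = 0,
    trials_per_block: int = 30,
    rotation_increment: float = 0.2,
    rotation_ceiling: float = 20.0,
) -> ExperimentDesign:
    """Full experimental design: both tasks, 6 blocks of ``trials_per_block``.

    Target angles are i.i.d. uniform on [-10, +10] deg.  Deterministic for a
    fixed seed.  With the defaults each subject x task has 180 trials, so 8
    subjects contribute 2880 trial records in total.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if trials_per_block < 1:
        raise ValueError("trials_per_block must be >= 1")
    schedule = build_rotation_schedule(
        n_baseline=trials_per_block,
        n_adapt=4 * trials_per_block,
        n_washout=trials_per_block,
        increment=rotation_increment,
        ceiling=rotation_ceiling,
    )
    roles = ["baseline"] + ["adaptation"] * 4 + ["washout"]
    rng = _rng(seed, _STREAM_DESIGN)
    rows = []
    n_total = 6 * trials_per_block
    for s in range(n_subjects):
        subject = f"S{s + 1:02d}"
        for task in TASKS:
            angles = rng.uniform(-10.0, 10.0, size=n_total)
            for i in range(n_total):
                block = i // trials_per_block
                rows.append(
                    dict(
                        subject=subject,
                        task=task,
                        block_index=block + 1,
                        block_role=roles[block],
                        trial_in_block=i % trials_per_block + 1,
                        trial_overall=i + 1,
                        target_angle_deg=angles[i],
                        rotation_deg=schedule.r[i],
                    )
                )
    return ExperimentDesign(
        n_subjects=n_subjects,
        tasks=TASKS,
        trials_per_block=trials_per_block,
        seed=seed,
        trials=pd.DataFrame(rows),
        schedule=schedule,
    )


# --------------------------------------------------------------------------
# Behaviour
# --------------------------------------------------------------------------

def _per_task(value, task: str) -> float:
    return float(value[task]) if isinstance(value, dict) else float(value)


@dataclass(frozen=True)
class LearnerParams:
    """Generative parameters of the state-space learner and trial timing.

    ``A_true``/``B_true`` are the retention and adaptation rates in [0, 1]
    (scalar, or a per-task mapping to emulate the task modulation of the
    learning rates); ``motor_noise_sd`` is trial-to-trial execution noise in
    degrees.  Reaction times are drawn per task from a normal truncated at 0;
    the memory-guided task is configured slower than the visually-guided one.
    Movement duration is ``mt_mean`` (s) with a small truncated-normal jitter.
    """

    A_true: float | dict = field(default_factory=lambda: {"visual": 0.98, "memory": 0.95})
    B_true: float | dict = field(default_factory=lambda: {"visual": 0.25, "memory": 0.15})
    motor_noise_sd: float = 3.0
    x1: float = 0.0
    rt_mean: dict = field(default_factory=lambda: {"visual": 0.30, "memory": 0.40})
    rt_sd: float = 0.05
    mt_mean: float = 0.35
    mt_sd: float = 0.02
    fixation_delay_range: tuple[float, float] = (1.5, 2.0)
    memory_target_duration: float = 0.2
    memory_go_delay: float = 2.0

    def __post_init__(self) -> None:
        if self.motor_noise_sd < 0:
            raise ValueError("motor_noise_sd must be >= 0")
        if _per_task(self.rt_mean, "memory") < _per_task(self.rt_mean, "visual"):
            raise ValueError(
                "memory-guided reaction times must not be faster than visually-guided ones"
            )


def _minjerk_position(tau: np.ndarray) -> np.ndarray:
    tau = np.clip(tau, 0.0, 1.0)
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


# Normalized time at which a minimum-jerk reach crosses 80% of its amplitude
# (the feedback ring at 80 mm for a 100 mm reach).
_TAU_FEEDBACK = float(
    optimize.brentq(lambda t: _minjerk_position(np.array([t]))[0] - TARGET_DISTANCE_MM / REACH_AMPLITUDE_MM, 0.0, 1.0)
)


def _unit_vector(angle_deg: float) -> tuple[float, float]:
    # Direction measured counterclockwise from the +y (reach) axis.
    a = np.radians(angle_deg)
    return (-np.sin(a), np.cos(a))


def simulate_behavior(
    design: ExperimentDesign,
    learner: LearnerParams | None = None,
    schedule: RotationSchedule | None = None,
    inject_outliers: int = 2,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the learner over the design and synthesize reach trajectories.

    For each subject x task series the internal state follows
    ``x[t+1] = A x[t] + B e[t]`` where ``e[t] = r[t] - h[t]`` is the cursor
    error actually experienced, and the executed hand angle is
    ``h[t] = x[t] + motor noise``.  Each trial's trajectory is a minimum-jerk
    reach of 100 mm (crossing the 80 mm feedback ring) in the direction
    ``target_angle - h[t]``, starting one reaction-time draw after the go
    signal and sampled at 60 Hz.

    ``inject_outliers`` replaces that many randomly chosen trials' hand
    angles with gross (+/-40 deg) deviations across the whole dataset, to
    exercise the outlier-exclusion rule at the observed scale of ~2 removals
    per 2880 trials.

    Returns ``(trials, trajectories)``: the design table augmented with event
    times and generative truth columns, and the long-format trajectory table.
    """
    learner = learner or LearnerParams()
    seed = design.seed if seed is None else seed
    sched = schedule or design.schedule
    n_trials = design.n_trials_per_task
    if len(sched.r) != n_trials:
        raise ValueError("schedule length does not match trials per task")

    trial_rows: list[dict] = []
    traj_frames: list[pd.DataFrame] = []
    for s in range(design.n_subjects):
        subject = f"S{s + 1:02d}"
        for ti, task in enumerate(design.tasks):
            rng = _rng(seed, _STREAM_BEHAVIOR, s, ti)
            sub = design.trials[
                (design.trials["subject"] == subject) & (design.trials["task"] == task)
            ].sort_values("trial_overall")
            A = _per_task(learner.A_true, task)
            B = _per_task(learner.B_true, task)
            r = sched.r
            noise = (
                rng.normal(0.0, learner.motor_noise_sd, size=n_trials)
                if learner.motor_noise_sd > 0
                else np.zeros(n_trials)
            )
            x = np.empty(n_trials)
            h = np.empty(n_trials)
            x[0] = learner.x1
            for t in range(n_trials):
                h[t] = x[t] + noise[t]
                if t + 1 < n_trials:
                    x[t + 1] = A * x[t] + B * (r[t] - h[t])

            mu_rt = _per_task(learner.rt_mean, task)
            rts = sps.truncnorm.rvs(
                -mu_rt / learner.rt_sd, np.inf, loc=mu_rt, scale=learner.rt_sd,
                size=n_trials, random_state=rng,
            )
            mts = sps.truncnorm.rvs(
                (0.1 - learner.mt_mean) / learner.mt_sd, np.inf,
                loc=learner.mt_mean, scale=learner.mt_sd,
                size=n_trials, random_state=rng,
            )
            delays = rng.uniform(*learner.fixation_delay_range, size=n_trials)

            for k, rec in enumerate(sub.itertuples(index=False)):
                t_target = delays[k]
                if task == "memory":
                    t_go = t_target + learner.memory_target_duration + learner.memory_go_delay
                else:
                    t_go = t_target
                t_onset = t_go + rts[k]
                t_feedback = t_onset + _TAU_FEEDBACK * mts[k]
                trial_rows.append(
                    dict(
                        subject=subject,
                        task=task,
                        block_index=rec.block_index,
                        block_role=rec.block_role,
                        trial_in_block=rec.trial_in_block,
                        trial_overall=rec.trial_overall,
                        target_angle_deg=rec.target_angle_deg,
                        rotation_deg=rec.rotation_deg,
                        t_target_on_s=t_target,
                        t_go_s=t_go,
                        t_reach_onset_s=t_onset,
                        t_feedback_s=t_feedback,
                        x_state_deg=x[k],
                        hand_angle_true_deg=h[k],
                        rt_true_s=rts[k],
                        mt_true_s=mts[k],
                    )
                )

    trials = pd.DataFrame(trial_rows)

    if inject_outliers:
        rng_out = _rng(seed, _STREAM_BEHAVIOR, 9999)
        picks = rng_out.choice(len(trials), size=int(inject_outliers), replace=False)
        signs = rng_out.choice([-1.0, 1.0], size=int(inject_outliers))
        for p, sgn in zip(picks, signs):
            trials.loc[trials.index[p], "hand_angle_true_deg"] += 40.0 * sgn

    for rec in trials.itertuples(index=False):
        traj_frames.append(
            _make_trajectory(
                rec.subject,
                rec.task,
                rec.trial_overall,
                rec.target_angle_deg,
                rec.hand_angle_true_deg,
                rec.t_reach_onset_s,
                rec.mt_true_s,
                rec.t_feedback_s,
            )
        )
    trajectories = pd.concat(traj_frames, ignore_index=True)
    return trials, trajectories


def _make_trajectory(
    subject: str,
    task: str,
    trial_overall: int,
    target_angle: float,
    hand_angle: float,
    t_onset: float,
    mt: float,
    t_feedback: float,
) -> pd.DataFrame:
    t_end = t_feedback + 0.5
    n = int(np.ceil(t_end * FS_TRAJECTORY)) + 1
    t = np.arange(n) / FS_TRAJECTORY
    amp = REACH_AMPLITUDE_MM * _minjerk_position((t - t_onset) / mt)
    ux, uy = _unit_vector(target_angle - hand_angle)
    return pd.DataFrame(
        dict(
            subject=subject,
            task=task,
            trial_overall=trial_overall,
            t_s=t,
            x_mm=amp * ux,
            y_mm=amp * uy,
        )
    )


# --------------------------------------------------------------------------
# EEG
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class EEGEffect:
    """One task-modulated band-limited oscillatory effect.

    ``db_difference`` is the band-averaged dB difference (visual - memory)
    that the canonical analysis should measure over ``window`` (seconds
    relative to ``align``).  Positive differences add power to the
    visually-guided task, negative ones to the memory-guided task.
    """

    band: tuple[float, float]
    channels: tuple[str, ...]
    align: str  # "reach_onset" | "feedback"
    window: tuple[float, float]
    db_difference: float
    tukey_alpha: float = 0.25


def _default_effects() -> tuple[EEGEffect, ...]:
    return (
        # Post-feedback parietal delta increase, stronger in the visual task.
        EEGEffect(band=(1.0, 4.0), channels=("P3", "Pz", "P4"), align="feedback",
                  window=(0.0, 1.0), db_difference=3.0),
        # Pre-movement beta desynchronization over C3/Fz, stronger (more
        # negative) in the visual task.
        EEGEffect(band=(13.0, 30.0), channels=("C3", "Fz"), align="reach_onset",
                  window=(-1.0, 0.0), db_difference=-2.0),
    )


@dataclass(frozen=True)
class EEGParams:
    """Synthetic EEG configuration: montage, background spectrum, effects.

    The background is 1/f noise with exponent ``background_exponent`` and an
    overall ``background_rms_uv`` scale.  ``wavelet_mode``/``n_cycles``/
    ``fixed_window_s`` describe the analysis the effect calibration assumes
    (they must match the settings later used by the time-frequency module for
    the configured dB differences to be recovered).
    """

    channels: tuple[str, ...] = QUICK20_CHANNELS
    fs: float = 500.0
    background_exponent: float = 1.0
    background_rms_uv: float = 10.0
    effects: tuple[EEGEffect, ...] = field(default_factory=_default_effects)
    wavelet_mode: str = "fixed_cycles"
    n_cycles: float = 3.0
    fixed_window_s: float = 0.2

    def __post_init__(self) -> None:
        if self.fs < 60.0:
            raise ValueError("sampling rate must be at least twice the 30 Hz analysis ceiling")
        montage = set(self.channels)
        for eff in self.effects:
            missing = set(eff.channels) - montage
            if missing:
                raise ValueError(f"effect channels {sorted(missing)} not in the montage")


def _pink_noise(rng: np.random.Generator, n: int, fs: float, exponent: float, rms: float) -> np.ndarray:
    white = rng.normal(size=n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = 1.0 / np.maximum(f, 0.1) ** (exponent / 2.0)
    shape[0] = 0.0
    y = np.fft.irfft(spec * shape, n=n)
    return y * (rms / y.std())


def _smoothed_profile(q: np.ndarray, dt: float, sigma_p: float) -> np.ndarray:
    half = int(np.ceil(4 * sigma_p / dt))
    tk = np.arange(-half, half + 1) * dt
    kern = np.exp(-(tk**2) / (2 * sigma_p**2))
    kern /= kern.sum()
    return np.convolve(q, kern, mode="same")


def _bandpass_moments(
    band: tuple[float, float],
    freq: float,
    sigma_f: float,
    fs: float,
    exponent: float,
) -> tuple[float, float]:
    """Weighted first/second moments of the burst filter's amplitude transfer
    under the wavelet's frequency window at ``freq``.

    The burst is the zero-phase 4th-order Butterworth band-passed background,
    so its amplitude transfer is ``A(nu) = |H(nu)|^2`` (two passes).  The
    wavelet at ``freq`` integrates the spectrum with a Gaussian window of SD
    ``sigma_f`` weighted by the 1/f background PSD; the measured power
    multiplier is ``1 + 2 g w Abar1 + g^2 w^2 Abar2`` with the weighted means
    ``Abar1 = <A>`` and ``Abar2 = <A^2>`` returned here.
    """
    nu = np.linspace(max(freq - 4 * sigma_f, 0.05), freq + 4 * sigma_f, 201)
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    _, h = signal.sosfreqz(sos, worN=nu, fs=fs)
    A = np.abs(h) ** 2
    weight = np.exp(-((nu - freq) ** 2) / (2 * sigma_f**2)) / np.maximum(nu, 0.1) ** exponent
    weight /= weight.sum()
    return float(weight @ A), float(weight @ A**2)


def _predicted_db(
    gain: float,
    band: tuple[float, float],
    window: tuple[float, float],
    baseline: tuple[float, float],
    epoch: tuple[float, float],
    mode: str,
    n_cycles: float,
    fixed_window_s: float,
    tukey_alpha: float,
    fs: float,
    exponent: float,
    step: float = 0.05,
) -> float:
    """Band-averaged dB the analysis chain measures for a burst gain ``g``.

    Models the burst as a relative band-power increase
    ``(1 + g w(t) A(nu))^2 - 1`` (``w`` the Tukey envelope over the effect
    window, ``A`` the two-pass Butterworth amplitude transfer integrated over
    the wavelet's bandwidth against the 1/f background), smoothed in time by
    the wavelet's power envelope (Gaussian, ``sigma_t / sqrt(2)``) at each
    integer frequency of the band, with the same inclusive-window baseline
    and edge-validity rules as the time-frequency module.
    """
    dt = 0.005
    lo = min(baseline[0], window[0]) - 3.0
    hi = max(baseline[1], window[1]) + 3.0
    t = np.arange(lo, hi + dt, dt)
    w = np.zeros_like(t)
    inw = (t >= window[0]) & (t <= window[1])
    nw = int(inw.sum())
    w[inw] = signal.windows.tukey(nw, alpha=tukey_alpha)

    freqs = np.arange(np.ceil(band[0]), np.floor(band[1]) + 1.0)
    bins = np.arange(np.ceil(window[0] / step), np.floor(window[1] / step) + 1) * step
    base_bins = np.arange(np.ceil(baseline[0] / step), np.floor(baseline[1] / step) + 1) * step
    vals = []
    for f in freqs:
        sig = wavelet_sigma_t(f, mode=mode, n_cycles=n_cycles, window_s=fixed_window_s)
        # Spectral window of |wavelet|^2: sqrt(2) narrower than the amplitude window.
        a1, a2 = _bandpass_moments(band, f, 1.0 / (2 * np.pi * sig * np.sqrt(2.0)), fs, exponent)
        q = 2.0 * gain * w * a1 + gain**2 * w**2 * a2
        smooth = _smoothed_profile(q, dt, sig / np.sqrt(2.0))
        valid_lo, valid_hi = epoch[0] + 2.0 * sig, epoch[1] - 2.0 * sig

        def _at(times: np.ndarray) -> np.ndarray:
            return np.interp(times, t, smooth)

        vb = base_bins[(base_bins >= valid_lo - 1e-9) & (base_bins <= valid_hi + 1e-9)]
        vw = bins[(bins >= valid_lo - 1e-9) & (bins <= valid_hi + 1e-9)]
        if len(vb) == 0 or len(vw) == 0:
            continue
        b = 1.0 + _at(vb).mean()
        vals.extend(10.0 * np.log10((1.0 + _at(vw)) / b))
    return float(np.mean(vals))


def effect_gain(
    db: float,
    band: tuple[float, float],
    window: tuple[float, float],
    align: str,
    params: EEGParams,
    tukey_alpha: float = 0.25,
    epoch: tuple[float, float] = (-2.0, 2.0),
) -> float:
    """Burst gain whose measured band-averaged dB equals ``db`` (db > 0)."""
    from .timefreq import DEFAULT_BASELINES

    baseline = DEFAULT_BASELINES[align]

    def fn(g: float) -> float:
        return _predicted_db(
            g, band, window, baseline, epoch,
            params.wavelet_mode, params.n_cycles, params.fixed_window_s, tukey_alpha,
            params.fs, params.background_exponent,
        ) - db

    return float(optimize.brentq(fn, 1e-6, 100.0, xtol=1e-6))


def simulate_eeg(
    design: ExperimentDesign,
    trials: pd.DataFrame,
    params: EEGParams | None = None,
    seed: int | None = None,
) -> dict[tuple[str, str], EEGRecording]:
    """Event-marked continuous EEG for every subject x task.

    Trials occupy fixed-length slots along a continuous recording padded so
    every event has at least 2.5 s of signal on both sides.  Each channel is
    an independent 1/f background; each configured effect multiplies the
    band-passed component of its channels by ``1 + g w(t)`` around the
    aligned event in the task that carries the extra power, with ``g``
    calibrated so the measured task dB difference matches the configuration.
    """
    params = params or EEGParams()
    seed = design.seed if seed is None else seed
    fs = params.fs
    pad = 2.5

    slot = float(np.ceil((trials["t_feedback_s"].max() + 0.5 + 2.0) * 10) / 10)
    gains = {
        eff: effect_gain(abs(eff.db_difference), eff.band, eff.window, eff.align, params,
                         tukey_alpha=eff.tukey_alpha)
        for eff in params.effects
        if eff.db_difference != 0.0
    }

    recordings: dict[tuple[str, str], EEGRecording] = {}
    for s in range(design.n_subjects):
        subject = f"S{s + 1:02d}"
        for ti, task in enumerate(design.tasks):
            rng = _rng(seed, _STREAM_EEG, s, ti)
            sub = trials[(trials["subject"] == subject) & (trials["task"] == task)]
            sub = sub.sort_values("trial_overall")
            n_tr = len(sub)
            n_samp = int(round((2 * pad + n_tr * slot) * fs))
            data = np.empty((len(params.channels), n_samp))
            for c in range(len(params.channels)):
                data[c] = _pink_noise(
                    rng, n_samp, fs, params.background_exponent, params.background_rms_uv
                )

            starts = pad + slot * np.arange(n_tr)
            marker_rows = []
            rel_times = {
                "target_on": sub["t_target_on_s"].to_numpy(),
                "go": sub["t_go_s"].to_numpy(),
                "reach_onset": sub["t_reach_onset_s"].to_numpy(),
                "feedback": sub["t_feedback_s"].to_numpy(),
            }
            for k, trial in enumerate(sub["trial_overall"]):
                for label in EVENT_LABELS:
                    marker_rows.append(
                        dict(
                            label=label,
                            sample=int(round((starts[k] + rel_times[label][k]) * fs)),
                            trial=int(trial),
                        )
                    )
            markers = pd.DataFrame(marker_rows)

            for eff in params.effects:
                if eff.db_difference == 0.0:
                    continue
                carrier_task = "visual" if eff.db_difference > 0 else "memory"
                if task != carrier_task:
                    continue
                g = gains[eff]
                env = np.zeros(n_samp)
                w0, w1 = eff.window
                n_win = int(round((w1 - w0) * fs))
                win = signal.windows.tukey(n_win, alpha=eff.tukey_alpha)
                ev_samples = markers[markers["label"] == eff.align]["sample"].to_numpy()
                for m in ev_samples:
                    i0 = m + int(round(w0 * fs))
                    i1 = i0 + n_win
                    if i0 >= 0 and i1 <= n_samp:
                        env[i0:i1] = np.maximum(env[i0:i1], win)
                sos = signal.butter(4, eff.band, btype="bandpass", fs=fs, output="sos")
                for ch in eff.channels:
                    c = params.channels.index(ch)
                    bp = signal.sosfiltfilt(sos, data[c])
                    data[c] = data[c] + g * env * bp

            recordings[(subject, task)] = EEGRecording(
                channels=params.channels, fs=fs, data=data, markers=markers
            )
    return recordings


# --------------------------------------------------------------------------
# On-disk dialect
# --------------------------------------------------------------------------

_FLOAT_FMT = "%.17g"  # lossless float64 round-trip


def write_dataset(
    out_dir: str | Path,
    trials: pd.DataFrame,
    trajectories: pd.DataFrame,
    recordings: dict[tuple[str, str], EEGRecording] | None = None,
) -> None:
    """Write trial table, trajectory table, event table and EEG files.

    EEG goes to ``eeg/<subject>_<task>.f32`` (32-bit floats, channel-major)
    with a plain-text sidecar carrying channel names, sampling rate and
    markers (``label,sample,trial``; sample indices are 0-based).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    trials.to_csv(out / "trials.csv", index=False, float_format=_FLOAT_FMT)
    trajectories.to_csv(out / "trajectories.csv", index=False, float_format=_FLOAT_FMT)
    if recordings is None:
        return
    events = []
    eeg_dir = out / "eeg"
    eeg_dir.mkdir(exist_ok=True)
    for (subject, task), rec in sorted(recordings.items()):
        stem = f"{subject}_{task}"
        rec.data.astype("<f4").tofile(eeg_dir / f"{stem}.f32")
        with open(eeg_dir / f"{stem}.sidecar.txt", "w") as fh:
            fh.write("format: reachadapt-eeg-v1\n")
            fh.write(f"subject: {subject}\n")
            fh.write(f"task: {task}\n")
            fh.write(f"fs_hz: {rec.fs:.17g}\n")
            fh.write(f"n_channels: {len(rec.channels)}\n")
            fh.write(f"n_samples: {rec.data.shape[1]}\n")
            fh.write(f"channels: {','.join(rec.channels)}\n")
            fh.write("markers:\n")
            for row in rec.markers.itertuples(index=False):
                fh.write(f"{row.label},{row.sample},{row.trial}\n")
        for row in rec.markers.itertuples(index=False):
            events.append(
                dict(subject=subject, task=task, trial=row.trial, label=row.label, sample=row.sample)
            )
    pd.DataFrame(events).to_csv(out / "events.csv", index=False)


def _parse_sidecar(path: Path) -> dict:
    header: dict = {}
    markers = []
    in_markers = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if in_markers:
                parts = line.split(",")
                if len(parts) != 3:
                    raise DatasetFormatError(
                        f"{path}:{lineno}: malformed marker row {line!r} (expected label,sample,trial)"
                    )
                try:
                    markers.append((parts[0], int(parts[1]), int(parts[2])))
                except ValueError:
                    raise DatasetFormatError(
                        f"{path}:{lineno}: non-integer marker fields in {line!r}"
                    )
            elif line == "markers:":
                in_markers = True
            else:
                if ":" not in line:
                    raise DatasetFormatError(f"{path}:{lineno}: expected 'key: value', got {line!r}")
                key, _, val = line.partition(":")
                header[key.strip()] = val.strip()
    for req in ("fs_hz", "n_channels", "n_samples", "channels"):
        if req not in header:
            raise DatasetFormatError(f"{path}: missing required header field {req!r}")
    header["markers"] = markers
    return header


def read_dataset(
    in_dir: str | Path, load_eeg: bool = True
) -> tuple[pd.DataFrame, pd.DataFrame, dict[tuple[str, str], EEGRecording]]:
    """Read back a dataset written by :func:`write_dataset`.

    Trial and trajectory tables round-trip exactly; signals round-trip to
    32-bit float precision.  Malformed files raise
    :class:`DatasetFormatError` naming the file and offending line.
    """
    src = Path(in_dir)
    # round_trip parsing: the default fast parser can be off by one ulp.
    trials = pd.read_csv(src / "trials.csv", float_precision="round_trip")
    trajectories = pd.read_csv(src / "trajectories.csv", float_precision="round_trip")
    recordings: dict[tuple[str, str], EEGRecording] = {}
    eeg_dir = src / "eeg"
    if load_eeg and eeg_dir.is_dir():
        for sidecar in sorted(eeg_dir.glob("*.sidecar.txt")):
            head = _parse_sidecar(sidecar)
            n_ch, n_samp = int(head["n_channels"]), int(head["n_samples"])
            raw_path = sidecar.with_name(sidecar.name.replace(".sidecar.txt", ".f32"))
            raw = np.fromfile(raw_path, dtype="<f4")
            if raw.size != n_ch * n_samp:
                raise DatasetFormatError(
                    f"{raw_path}: expected {n_ch * n_samp} samples, found {raw.size} "
                    f"(truncated or corrupt signal file)"
                )
            markers = pd.DataFrame(head["markers"], columns=["label", "sample", "trial"])
            recordings[(head["subject"], head["task"])] = EEGRecording(
                channels=tuple(head["channels"].split(",")),
                fs=float(head["fs_hz"]),
                data=raw.reshape(n_ch, n_samp).astype(float),
                markers=markers,
            )
    return trials, trajectories, recordings
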