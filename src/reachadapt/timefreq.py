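"""EEG preprocessing, epoching and Morlet time-frequency power.

Continuous multichannel EEG is band-pass filtered (0.05-100 Hz, zero phase)
with a 50 Hz notch, segmented into -2..+2 s epochs around reach onset or
feedback onset, decomposed with complex Morlet wavelets (1-30 Hz in 1 Hz
steps, power sampled every 50 ms) and expressed in decibels relative to an
event-specific pre-event baseline:

    dB(ch, f, t) = 10 log10( P(ch, f, t) / mean_baseline P(ch, f, .) )

Two wavelet modes are available.  The default ``fixed_cycles`` mode uses
3-cycle wavelets (sigma_t = n_cycles / (2 pi f)), giving frequency-
proportional time resolution; the alternative ``fixed_window`` mode uses a
constant 200 ms Gaussian envelope at all frequencies (sigma_t = window / 5),
which mimics a moving fixed-length analysis window but cannot truly resolve
1 Hz.  Bins closer than 2 sigma_t to an epoch edge are marked invalid (NaN)
and excluded from every average, never zero-filled.

Decibel conversion uses 10 log10 of the power ratio.  Per-trial maps are
normalized first and averaged afterwards; because dB values are averaged
arithmetically over trials, frequencies and electrodes, the order of band
and trial averaging is interchangeable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "EEGRecording",
    "Epochs",
    "TimeFrequencyMap",
    "BANDS",
    "ELECTRODE_GROUPS",
    "DEFAULT_BASELINES",
    "preprocess_raw",
    "ica_clean",
    "epoch_by_event",
    "wavelet_sigma_t",
    "morlet_tfr",
    "db_normalize",
    "average_trials",
    "band_average",
]

log = logging.getLogger(__name__)

BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
}

ELECTRODE_GROUPS: dict[str, tuple[str, ...]] = {
    "parietal": ("P3", "Pz", "P4"),
    "C3": ("C3",),
    "Fz": ("Fz",),
}

# Pre-event baseline windows in seconds, per alignment event.
DEFAULT_BASELINES: dict[str, tuple[float, float]] = {
    "reach_onset": (-1.5, -1.0),
    "feedback": (-0.1, 0.0),
}

EDGE_SIGMA = 2.0  # bins closer than this many sigma_t to an epoch edge are invalid


@dataclass(frozen=True)
class EEGRecording:
    """Continuous multichannel recording with event markers.

    ``data`` is channels x samples in microvolts; ``markers`` has columns
    ``label`` (event name), ``sample`` (0-based index) and ``trial``.
    """

    channels: tuple[str, ...]
    fs: float
    data: np.ndarray
    markers: pd.DataFrame

    def __post_init__(self) -> None:
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel names must be unique")
        if self.data.shape[0] != len(self.channels):
            raise ValueError("data rows must match channel count")
        if len(self.markers) and not (
            (self.markers["sample"] >= 0) & (self.markers["sample"] < self.data.shape[1])
        ).all():
            raise ValueError("marker sample indices outside the recording")


@dataclass(frozen=True)
class Epochs:
    """Fixed-length segments around one event type: trials x channels x samples."""

    alignment: str
    window: tuple[float, float]
    data: np.ndarray
    times: np.ndarray  # seconds relative to the event
    fs: float
    channels: tuple[str, ...]
    trial_keys: np.ndarray


@dataclass(frozen=True)
class TimeFrequencyMap:
    """Time-frequency power: trials x channels x frequencies x time bins.

    ``values`` holds power (uV^2) or dB after normalization; invalid edge
    bins are NaN.  ``times`` are bin centres in seconds relative to the
    alignment event, spaced exactly 50 ms.
    """

    values: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    channels: tuple[str, ...]
    alignment: str
    kind: str = "power"  # "power" | "db"
    baseline_window: tuple[float, float] | None = None
    trial_keys: np.ndarray | None = None


def preprocess_raw(
    rec: EEGRecording,
    band: tuple[float, float] = (0.05, 100.0),
    notch: float = 50.0,
    notch_q: float = 30.0,
) -> EEGRecording:
    """Zero-phase 0.05-100 Hz band-pass plus 50 Hz notch, per channel.

    The band-pass is applied as separate high-pass and low-pass sections: a
    single digital band-pass spanning nearly four decades (0.05-100 Hz at
    500 Hz sampling) is numerically ill-conditioned and distorts the passband.
    """
    if rec.fs <= 200.0:
        raise ValueError("sampling rate must exceed 200 Hz")
    if band[1] >= rec.fs / 2:
        raise ValueError("upper band edge must be below Nyquist")
    sos_hp = signal.butter(4, band[0], btype="highpass", fs=rec.fs, output="sos")
    sos_lp = signal.butter(4, band[1], btype="lowpass", fs=rec.fs, output="sos")
    out = signal.sosfiltfilt(sos_hp, rec.data, axis=-1)
    out = signal.sosfiltfilt(sos_lp, out, axis=-1)
    if notch:
        b, a = signal.iirnotch(notch, notch_q, fs=rec.fs)
        out = signal.filtfilt(b, a, out, axis=-1)
    return replace(rec, data=out)


def ica_clean(rec: EEGRecording) -> EEGRecording:
    """Artifact-removal hook.

    Synthetic recordings are artifact-free, so this is deliberately the
    identity; the interface point exists so an externally cleaned recording
    (e.g. after ICA in another toolbox) can be substituted.
    """
    return rec


def epoch_by_event(
    rec: EEGRecording,
    event_label: str,
    window: tuple[float, float] = (-2.0, 2.0),
) -> Epochs:
    """One epoch per marker of ``event_label``; markers too close to a
    recording edge are dropped with a logged warning.

    Every epoch has exactly ``(window[1] - window[0]) * fs`` samples (the
    right edge is exclusive), so a -2..+2 s window at ``fs`` Hz gives
    ``4 * fs`` samples.
    """
    sel = rec.markers[rec.markers["label"] == event_label]
    if sel.empty:
        raise ValueError(f"event label {event_label!r} not present in markers")
    o0 = int(round(window[0] * rec.fs))
    n_len = int(round((window[1] - window[0]) * rec.fs))
    segs, keys, dropped = [], [], 0
    for row in sel.itertuples(index=False):
        start = int(row.sample) + o0
        if start < 0 or start + n_len > rec.data.shape[1]:
            dropped += 1
            continue
        segs.append(rec.data[:, start : start + n_len])
        keys.append(row.trial if "trial" in sel.columns else len(keys))
    if dropped:
        log.warning(
            "epoch_by_event(%r): dropped %d marker(s) closer than the epoch "
            "half-width to a recording edge",
            event_label,
            dropped,
        )
    if not segs:
        raise ValueError(f"no marker of {event_label!r} has a full epoch inside the recording")
    times = (np.arange(n_len) + o0) / rec.fs
    return Epochs(
        alignment=event_label,
        window=window,
        data=np.stack(segs),
        times=times,
        fs=rec.fs,
        channels=rec.channels,
        trial_keys=np.asarray(keys),
    )


def wavelet_sigma_t(
    freq: float,
    mode: str = "fixed_cycles",
    n_cycles: float = 3.0,
    window_s: float = 0.2,
) -> float:
    """Gaussian envelope SD (s) of the analysis wavelet at ``freq``."""
    if mode == "fixed_cycles":
        return n_cycles / (2.0 * np.pi * freq)
    if mode == "fixed_window":
        return window_s / 5.0
    raise ValueError(f"unknown wavelet mode: {mode!r}")


def _morlet_kernel(freq: float, sigma_t: float, fs: float) -> np.ndarray:
    half = int(np.ceil(4.0 * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    env = np.exp(-(t**2) / (2.0 * sigma_t**2))
    kappa = np.exp(-0.5 * (2.0 * np.pi * freq * sigma_t) ** 2)  # zero-mean correction
    kern = (np.exp(2j * np.pi * freq * t) - kappa) * env
    # Scale so a pure sinusoid of amplitude A yields |conv| = A, power = A^2.
    return kern * (2.0 / env.sum())


def morlet_tfr(
    epochs: Epochs,
    freqs: np.ndarray | None = None,
    step_ms: float = 50.0,
    mode: str = "fixed_cycles",
    n_cycles: float = 3.0,
    window_s: float = 0.2,
) -> TimeFrequencyMap:
    """Per-trial Morlet wavelet power, sampled on the 50 ms analysis grid.

    Power is the squared magnitude of the complex convolution.  Bin centres
    fall on multiples of ``step_ms`` relative to the alignment event; bins
    within ``EDGE_SIGMA * sigma_t(f)`` of either epoch edge are NaN.
    """
    freqs = np.arange(1.0, 31.0) if freqs is None else np.asarray(freqs, float)
    if freqs.max() >= epochs.fs / 2:
        raise ValueError("requested frequency at or above Nyquist")
    step = step_ms / 1000.0
    decim = epochs.fs * step
    if abs(decim - round(decim)) > 1e-9:
        raise ValueError(
            f"sampling rate {epochs.fs} Hz does not divide the {step_ms} ms analysis step"
        )
    decim = int(round(decim))
    # Start the grid at the first sample whose time is a multiple of the step.
    first = int(np.ceil(round(epochs.times[0] / step, 9) - 1e-9))
    i0 = int(round(first * step * epochs.fs - epochs.times[0] * epochs.fs))
    bin_idx = np.arange(i0, epochs.data.shape[-1], decim)
    times = epochs.times[bin_idx]

    n_tr, n_ch, _ = epochs.data.shape
    power = np.empty((n_tr, n_ch, len(freqs), len(bin_idx)))
    t0, t1 = epochs.times[0], epochs.times[-1]
    for k, f in enumerate(freqs):
        sig = wavelet_sigma_t(f, mode=mode, n_cycles=n_cycles, window_s=window_s)
        kern = _morlet_kernel(f, sig, epochs.fs)
        conv = signal.fftconvolve(epochs.data, kern[None, None, :], mode="same", axes=-1)
        p = np.abs(conv[..., bin_idx]) ** 2
        invalid = (times - t0 < EDGE_SIGMA * sig) | (t1 - times < EDGE_SIGMA * sig)
        p[..., invalid] = np.nan
        power[:, :, k, :] = p
    return TimeFrequencyMap(
        values=power,
        freqs=freqs,
        times=times,
        channels=epochs.channels,
        alignment=epochs.alignment,
        kind="power",
        trial_keys=epochs.trial_keys,
    )


def db_normalize(
    tf: TimeFrequencyMap, baseline_window: tuple[float, float] | None = None
) -> TimeFrequencyMap:
    """Decibel conversion against the mean power in the pre-event baseline.

    The baseline is averaged per trial, channel and frequency over the valid
    bins inside ``baseline_window`` (defaults to the alignment's canonical
    window).  Raises if the window lies outside the epoch, has no valid bin
    at some frequency, or contains non-positive power.
    """
    if tf.kind != "power":
        raise ValueError("db_normalize expects a raw power map")
    if baseline_window is None:
        baseline_window = DEFAULT_BASELINES[tf.alignment]
    b0, b1 = baseline_window
    in_base = (tf.times >= b0 - 1e-9) & (tf.times <= b1 + 1e-9)
    if not in_base.any():
        raise ValueError("baseline window lies outside the epoch's time bins")
    base_vals = tf.values[..., in_base]
    if np.isnan(base_vals).all(axis=-1).any():
        raise ValueError("no valid baseline bin at some trial/channel/frequency")
    with np.errstate(invalid="ignore"):
        base = np.nanmean(base_vals, axis=-1, keepdims=True)
    if np.any(base <= 0):
        raise ValueError("baseline power must be strictly positive")
    with np.errstate(invalid="ignore", divide="ignore"):
        db = 10.0 * np.log10(tf.values / base)
    return replace(tf, values=db, kind="db", baseline_window=(b0, b1))


def average_trials(tf: TimeFrequencyMap) -> TimeFrequencyMap:
    """Mean map over trials (NaN-aware), keeping a singleton trial axis."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN edge bins
        mean = np.nanmean(tf.values, axis=0, keepdims=True)
    return replace(tf, values=mean, trial_keys=None)


def band_average(
    tf: TimeFrequencyMap,
    bands: dict[str, tuple[float, float]] | None = None,
    electrode_groups: dict[str, tuple[str, ...]] | None = None,
) -> pd.DataFrame:
    """Trial-averaged band power per electrode group, as a tidy long table.

    Band edges are inclusive on both sides, so with a 1 Hz frequency axis a
    shared edge bin (e.g. 4 Hz) contributes to both adjacent bands.  Values
    are arithmetic means of dB (or power) over the band's frequency bins, the
    group's electrodes and all trials; NaN edge bins are excluded.

    Returns columns ``band, group, time_ms, value``.
    """
    bands = BANDS if bands is None else bands
    groups = ELECTRODE_GROUPS if electrode_groups is None else electrode_groups
    ch_index = {c: i for i, c in enumerate(tf.channels)}
    rows = []
    time_ms = np.round(tf.times * 1000.0).astype(int)
    for gname, electrodes in groups.items():
        if not electrodes:
            raise ValueError(f"electrode group {gname!r} is empty")
        missing = [e for e in electrodes if e not in ch_index]
        if missing:
            raise ValueError(f"electrodes {missing} not in the montage")
        ch_sel = [ch_index[e] for e in electrodes]
        for bname, (f_lo, f_hi) in bands.items():
            f_sel = (tf.freqs >= f_lo - 1e-9) & (tf.freqs <= f_hi + 1e-9)
            if not f_sel.any():
                raise ValueError(f"band {bname!r} has no frequency bins on the axis")
            sub = tf.values[:, ch_sel][:, :, f_sel, :]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN edge bins
                series = np.nanmean(sub, axis=(0, 1, 2))
            for t, v in zip(time_ms, series):
                rows.append(dict(band=bname, group=gname, time_ms=int(t), value=float(v)))
    return pd.DataFrame(rows)
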