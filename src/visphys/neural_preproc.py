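"""Raw voltage -> multiunit activity (MUA) -> stimulus-locked epochs.

The preprocessing chain follows standard extracellular practice: common
median re-referencing per shank, zero-phase Butterworth band-pass for the
spike band, then an MUA envelope by full-wave rectification, 6th-order
Chebyshev-II low-pass (50 dB stopband) and downsampling to 1 kHz.  Epochs
span -100..+180 ms around each stimulus onset; artifact epochs (SD more than
10x the median epoch SD) are dropped per channel, and sites are kept only if
enough annulus and wedge conditions drive them above baseline.

All filters are applied forward-backward (zero phase) so response-onset
latencies in the 0-100 ms analysis window are not shifted by filter delay.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal, stats

__all__ = [
    "RawRecording",
    "MUATrace",
    "EpochSet",
    "median_rereference",
    "bandpass_spike",
    "compute_mua",
    "detect_stimulus_onsets",
    "epoch",
    "filter_epochs_by_fixation",
    "reject_artifacts",
    "select_responsive_sites",
]

log = logging.getLogger(__name__)


@dataclass
class RawRecording:
    """Multichannel voltage, channels x time, in microvolts."""

    samples: np.ndarray
    fs: float
    shank_map: np.ndarray  # shank token per channel

    def __post_init__(self):
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        self.shank_map = np.asarray(self.shank_map)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.shank_map.shape[0] != self.samples.shape[0]:
            raise ValueError("shank_map must assign every channel to a shank")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]


@dataclass
class MUATrace:
    """Non-negative MUA envelope, channels x time, at 1 kHz."""

    samples: np.ndarray
    fs: float = 1000.0

    def __post_init__(self):
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))


@dataclass
class EpochSet:
    """Stimulus-locked MUA segments.

    data has shape (n_epochs, n_channels, n_samples) with the onset sample
    at index ``pre_ms`` (1 kHz).  ``valid`` is per epoch and channel; the
    fixation filter clears whole epochs, artifact rejection per channel.
    """

    data: np.ndarray
    condition_ids: np.ndarray
    onset_ms: np.ndarray
    valid: np.ndarray = None
    fs: float = 1000.0
    pre_ms: float = 100.0
    post_ms: float = 180.0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_epochs, n_channels, n_samples)")
        self.condition_ids = np.asarray(self.condition_ids)
        self.onset_ms = np.asarray(self.onset_ms, dtype=float)
        if self.valid is None:
            self.valid = np.ones(self.data.shape[:2], dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
        n_samples = int(round((self.pre_ms + self.post_ms) * self.fs / 1000.0))
        if self.data.shape[2] != n_samples:
            raise ValueError(
                f"epoch window is {self.pre_ms}+{self.post_ms} ms at {self.fs} Hz "
                f"({n_samples} samples) but data has {self.data.shape[2]}"
            )

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def window_slice(self, start_ms: float, stop_ms: float) -> slice:
        """Half-open window [start_ms, stop_ms) relative to stimulus onset."""
        i0 = int(round((start_ms + self.pre_ms) * self.fs / 1000.0))
        i1 = int(round((stop_ms + self.pre_ms) * self.fs / 1000.0))
        return slice(i0, i1)

    def window_mean(self, start_ms: float, stop_ms: float) -> np.ndarray:
        """Mean over the window, per epoch and channel."""
        return self.data[:, :, self.window_slice(start_ms, stop_ms)].mean(axis=2)


def median_rereference(raw: RawRecording) -> RawRecording:
    """Subtract, per shank and per sample, the median across that shank's
    channels.  Removes common-mode signal such as movement artifacts."""
    if raw.samples.size == 0:
        raise ValueError("empty recording")
    out = raw.samples.copy()
    for shank in np.unique(raw.shank_map):
        idx = np.where(raw.shank_map == shank)[0]
        out[idx] -= np.median(raw.samples[idx], axis=0, keepdims=True)
    return replace(raw, samples=out)


def bandpass_spike(raw: RawRecording, low_hz: float = 300.0, high_hz: float = 6000.0, order: int = 4) -> RawRecording:
    """Zero-phase Butterworth band-pass for the spike band (0.3-6 kHz)."""
    if not 0 < low_hz < high_hz < raw.fs / 2:
        raise ValueError(f"band ({low_hz}, {high_hz}) invalid for fs={raw.fs}")
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=raw.fs, output="sos")
    return replace(raw, samples=signal.sosfiltfilt(sos, raw.samples, axis=1))


def compute_mua(
    filtered: RawRecording,
    target_fs: float = 1000.0,
    stopband_hz: float = 400.0,
    order: int = 6,
    stopband_db: float = 50.0,
) -> MUATrace:
    """MUA envelope: full-wave rectify, Chebyshev-II low-pass, downsample.

    The Chebyshev-II stopband edge (default 400 Hz) anti-aliases the 1 kHz
    output rate.  Non-integer rate ratios are handled by polyphase
    resampling of the rectified, low-passed signal; negative ringing is
    clipped at zero.
    """
    if filtered.fs < 2 * stopband_hz:
        raise ValueError("sampling rate too low for the anti-aliasing band")
    rectified = np.abs(filtered.samples)
    sos = signal.cheby2(order, stopband_db, stopband_hz, btype="lowpass", fs=filtered.fs, output="sos")
    envelope = signal.sosfiltfilt(sos, rectified, axis=1)
    ratio = filtered.fs / target_fs
    if abs(ratio - round(ratio)) < 1e-9:
        out = envelope[:, :: int(round(ratio))]
    else:
        # polyphase contract: resample_poly with up/down from the rational
        # approximation of target_fs/fs (limited denominator)
        from fractions import Fraction

        frac = Fraction(target_fs / filtered.fs).limit_denominator(10000)
        out = signal.resample_poly(envelope, frac.numerator, frac.denominator, axis=1)
    return MUATrace(samples=np.clip(out, 0.0, None), fs=target_fs)


def detect_stimulus_onsets(
    photodiode: np.ndarray,
    fs: float,
    threshold_fraction: float = 0.5,
    refractory_ms: float = 5.0,
) -> pd.DataFrame:
    """Rising-edge threshold crossings of the photodiode trace.

    The threshold sits at ``threshold_fraction`` of the signal range; a
    refractory period suppresses re-triggering on noise.  Returns a
    DataFrame with a single ``onset_ms`` column (empty if no crossings).
    """
    x = np.asarray(photodiode, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("photodiode trace must be finite")
    lo, hi = x.min(), x.max()
    if hi == lo:
        return pd.DataFrame({"onset_ms": np.array([], dtype=float)})
    thr = lo + threshold_fraction * (hi - lo)
    above = x >= thr
    crossings = np.where(~above[:-1] & above[1:])[0] + 1
    refractory = int(round(refractory_ms * fs / 1000.0))
    kept = []
    last = -np.inf
    for c in crossings:
        if c - last >= refractory:
            kept.append(c)
            last = c
    return pd.DataFrame({"onset_ms": np.array(kept, dtype=float) * 1000.0 / fs})


def epoch(
    mua: MUATrace,
    events: pd.DataFrame,
    pre_ms: float = 100.0,
    post_ms: float = 180.0,
) -> EpochSet:
    """Cut the MUA into per-presentation epochs around each onset.

    ``events`` needs an ``onset_ms`` column and, if available, a
    ``stimulus_id`` column used as the condition label.  Events whose window
    would run off the recording are dropped with a log entry.
    """
    n_pre = int(round(pre_ms * mua.fs / 1000.0))
    n_post = int(round(post_ms * mua.fs / 1000.0))
    n_time = mua.samples.shape[1]
    chunks, conds, onsets = [], [], []
    labels = events["stimulus_id"].to_numpy() if "stimulus_id" in events else np.full(len(events), "", dtype=object)
    for t_ms, label in zip(events["onset_ms"].to_numpy(), labels):
        i = int(round(t_ms * mua.fs / 1000.0))
        if i - n_pre < 0 or i + n_post > n_time:
            log.info("dropping event at %.1f ms: window outside recording", t_ms)
            continue
        chunks.append(mua.samples[:, i - n_pre : i + n_post])
        conds.append(label)
        onsets.append(t_ms)
    data = (
        np.stack(chunks).transpose(0, 1, 2)
        if chunks
        else np.empty((0, mua.samples.shape[0], n_pre + n_post))
    )
    return EpochSet(
        data=data,
        condition_ids=np.array(conds, dtype=object),
        onset_ms=np.array(onsets, dtype=float),
        fs=mua.fs,
        pre_ms=pre_ms,
        post_ms=post_ms,
    )


def filter_epochs_by_fixation(
    epochs: EpochSet,
    gaze_t_ms: np.ndarray,
    gaze_x_deg: np.ndarray,
    gaze_y_deg: np.ndarray,
    window_radius_deg: float,
    fixation=(0.0, 0.0),
) -> EpochSet:
    """Invalidate epochs during which gaze left the fixation window.

    An epoch is valid only if every gaze sample inside its -pre..+post
    window stays within ``window_radius_deg`` of the fixation point; epochs
    with no gaze coverage are conservatively invalid.
    """
    t = np.asarray(gaze_t_ms, dtype=float)
    d = np.hypot(np.asarray(gaze_x_deg) - fixation[0], np.asarray(gaze_y_deg) - fixation[1])
    valid = epochs.valid.copy()
    for k, onset in enumerate(epochs.onset_ms):
        in_win = (t >= onset - epochs.pre_ms) & (t < onset + epochs.post_ms)
        if not in_win.any() or np.any(d[in_win] > window_radius_deg):
            valid[k, :] = False
    return replace(epochs, data=epochs.data, valid=valid)


def reject_artifacts(epochs: EpochSet, factor: float = 10.0) -> EpochSet:
    """Drop epochs whose within-epoch SD exceeds ``factor`` times the median
    SD across epochs, independently per channel (strict inequality: an epoch
    exactly at the boundary is retained).  Only epochs valid at entry are
    considered; the median is computed over those same epochs."""
    if not epochs.valid.any():
        raise ValueError("no valid epochs to screen for artifacts")
    valid = epochs.valid.copy()
    sd = epochs.data.std(axis=2)  # (n_epochs, n_channels)
    for ch in range(epochs.n_channels):
        entering = valid[:, ch]
        if not entering.any():
            continue
        med = np.median(sd[entering, ch])
        valid[entering, ch] &= ~(sd[entering, ch] > factor * med)
    if not valid.any():
        warnings.warn("artifact rejection removed every epoch", stacklevel=2)
    return replace(epochs, data=epochs.data, valid=valid)


def select_responsive_sites(
    epochs: EpochSet,
    annulus_ids,
    wedge_ids,
    alpha: float = 0.01,
    min_conditions: int = 3,
    response_window=(0.0, 100.0),
    baseline_window=(-100.0, 0.0),
) -> np.ndarray:
    """Boolean mask of stimulus-driven channels.

    Per channel and condition, each epoch's mean MUA in the response window
    is paired with the same epoch's baseline-window mean and tested with a
    one-sided paired t-test (response > baseline).  A channel is selected iff
    at least ``min_conditions`` annulus conditions AND ``min_conditions``
    wedge conditions are significant at ``alpha``.  Conditions with fewer
    than two valid epochs are skipped.
    """
    resp = epochs.window_mean(*response_window)
    base = epochs.window_mean(*baseline_window)
    annulus_ids = set(annulus_ids)
    wedge_ids = set(wedge_ids)
    selected = np.zeros(epochs.n_channels, dtype=bool)
    for ch in range(epochs.n_channels):
        n_sig = {"annulus": 0, "wedge": 0}
        for cond in np.unique(epochs.condition_ids):
            group = "annulus" if cond in annulus_ids else "wedge" if cond in wedge_ids else None
            if group is None:
                continue
            idx = (epochs.condition_ids == cond) & epochs.valid[:, ch]
            if idx.sum() < 2:
                log.info("channel %d condition %s: <2 repetitions, skipped", ch, cond)
                continue
            r, b = resp[idx, ch], base[idx, ch]
            if np.allclose(r, b):
                continue  # degenerate pairing, no evidence of a response
            _, p = stats.ttest_rel(r, b, alternative="greater")
            if p < alpha:
                n_sig[group] += 1
        selected[ch] = n_sig["annulus"] >= min_conditions and n_sig["wedge"] >= min_conditions
    return selected
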