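"""High-gamma event-related band power (ERBP) from continuous recordings.

The chain is: anti-aliased downsampling to 1000 Hz, 70-150 Hz 100th-order
FIR bandpass (Hamming window design, applied forward-backward so the window
timing is unbiased by filter delay), Hilbert analytic amplitude, log power,
and per-trial normalization to a prestimulus baseline (50-200 ms before
stimulus onset).  ERBP is therefore in dB relative to baseline:

    ERBP(t) = 10 log10(env(t)^2 + eps) - mean over baseline of the same,

with ``eps`` a documented floor (1e-12 of the peak block power) guarding
log(0) on degenerate input.

Artifact screening follows the two-threshold rule: a trial is dropped when
any raw sample in its epoch deviates more than 5 SD, or any band-filtered
sample more than 10 SD, from the within-block mean of that site.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .dataio import ERBPMatrix, Recording, TrialEvent

log = logging.getLogger("hglock")

EPS_REL = 1e-12     # log floor, relative to max block power


def design_highgamma_fir(fs: float, band=(70.0, 150.0), order: int = 100
                         ) -> np.ndarray:
    """Hamming-window FIR bandpass of the stated order (order+1 taps)."""
    return sps.firwin(order + 1, band, pass_zero=False, window="hamming", fs=fs)


def fir_gain(taps: np.ndarray, freq_hz: float, fs: float,
             zero_phase: bool = True) -> float:
    """Amplitude gain of the (forward-backward) filter at one frequency."""
    _, h = sps.freqz(taps, worN=[freq_hz], fs=fs)
    g = float(np.abs(h[0]))
    return g * g if zero_phase else g


def downsample(rec: Recording, target_fs: float) -> Recording:
    """Anti-aliased resampling to exactly ``target_fs``."""
    if target_fs > rec.fs:
        raise ValueError(f"target_fs {target_fs} exceeds recording fs {rec.fs}")
    if target_fs == rec.fs:
        return rec
    frac = Fraction(target_fs / rec.fs).limit_denominator(100000)
    out = sps.resample_poly(rec.samples, frac.numerator, frac.denominator, axis=1)
    return Recording(out, target_fs, list(rec.channel_ids), rec.block_id)


def notch_denoise(x: np.ndarray, fs: float,
                  line_hz: tuple[float, ...] = (60.0, 120.0, 180.0),
                  q: float = 35.0) -> np.ndarray:
    """Optional substitute denoising: linear detrend + mains-harmonic notches."""
    y = sps.detrend(x)
    for f0 in line_hz:
        if f0 < fs / 2:
            b, a = sps.iirnotch(f0, q, fs=fs)
            y = sps.filtfilt(b, a, y)
    return y


def _hilbert_env(filtered: np.ndarray) -> np.ndarray:
    from scipy.fft import next_fast_len
    n = filtered.shape[-1]
    nfft = next_fast_len(n)
    analytic = sps.hilbert(filtered, N=nfft)
    return np.abs(analytic[..., :n])


def highgamma_envelope(x, fs, band=(70.0, 150.0), order=100, taps=None,
                       return_filtered=False):
    """Zero-phase FIR bandpass followed by Hilbert analytic amplitude.

    Output length equals input length; amplitude accuracy in the passband is
    limited by the squared ripple of the Hamming design (documented 5 %).
    """
    x = np.asarray(x, dtype=float)
    if taps is None:
        taps = design_highgamma_fir(fs, band, order)
    if x.shape[-1] <= 3 * (len(taps) - 1):
        raise ValueError("signal too short for zero-phase filtering padding")
    filtered = sps.filtfilt(taps, 1.0, x)
    env = _hilbert_env(filtered)
    if return_filtered:
        return env, filtered
    return env


@dataclass
class BlockStats:
    """Within-block mean/SD of the raw and band-filtered voltage of a site."""

    raw_mean: float
    raw_sd: float
    hg_mean: float
    hg_sd: float

    @classmethod
    def from_signals(cls, raw: np.ndarray, hg: np.ndarray) -> "BlockStats":
        return cls(float(np.mean(raw)), float(np.std(raw)),
                   float(np.mean(hg)), float(np.std(hg)))


@dataclass
class EpochSet:
    """Per-trial raw / band-filtered / envelope epochs at the analysis rate."""

    raw: np.ndarray              # trials x time
    hg_filtered: np.ndarray
    envelope: np.ndarray
    times_ms: np.ndarray
    alignment: str               # 'stimulus' or 'press'
    trial_index: np.ndarray      # event-list indices of the rows
    site_id: str = ""

    def __post_init__(self):
        if not (self.raw.shape == self.hg_filtered.shape == self.envelope.shape):
            raise ValueError("epoch arrays must share shape")

    @property
    def n_trials(self) -> int:
        return self.raw.shape[0]


def _alignment_times(events: list[TrialEvent], alignment: str,
                     indices) -> list[tuple[int, float]]:
    out = []
    for i in indices:
        e = events[i]
        if alignment == "stimulus":
            out.append((i, e.onset_s))
        elif alignment == "press":
            if e.press_s is not None:
                out.append((i, e.press_s))
        else:
            raise ValueError(f"unknown alignment {alignment!r}")
    return out


def epoch(raw: np.ndarray, hg: np.ndarray, env: np.ndarray, fs: float,
          events: list[TrialEvent], alignment: str,
          window_ms: tuple[float, float], trial_indices=None,
          site_id: str = "") -> EpochSet:
    """Cut aligned epochs out of continuous per-site signals.

    One row per event that carries the alignment timestamp, in event order.
    Epochs falling outside the recording are dropped with a logged warning.
    The window is half-open: sample k sits at ``window_ms[0] + k * 1000/fs``.
    """
    if trial_indices is None:
        trial_indices = range(len(events))
    n_samp = int(round((window_ms[1] - window_ms[0]) * fs / 1000.0))
    offset = window_ms[0] / 1000.0
    rows_raw, rows_hg, rows_env, kept = [], [], [], []
    for i, t_align in _alignment_times(events, alignment, trial_indices):
        start = int(round((t_align + offset) * fs))
        stop = start + n_samp
        if start < 0 or stop > raw.shape[-1]:
            log.warning("trial %d: %s-aligned epoch out of bounds, dropped",
                        i, alignment)
            continue
        rows_raw.append(raw[start:stop])
        rows_hg.append(hg[start:stop])
        rows_env.append(env[start:stop])
        kept.append(i)
    shape = (len(kept), n_samp)
    times = window_ms[0] + np.arange(n_samp) * 1000.0 / fs
    return EpochSet(
        raw=np.array(rows_raw, dtype=float).reshape(shape),
        hg_filtered=np.array(rows_hg, dtype=float).reshape(shape),
        envelope=np.array(rows_env, dtype=float).reshape(shape),
        times_ms=times, alignment=alignment,
        trial_index=np.asarray(kept, dtype=int), site_id=site_id)


def window_columns(times_ms: np.ndarray, window_ms) -> np.ndarray:
    """Boolean column mask for a half-open [start, end) window in ms."""
    mask = (times_ms >= window_ms[0] - 1e-9) & (times_ms < window_ms[1] - 1e-9)
    if not mask.any():
        raise ValueError(f"window {window_ms} outside epoch time axis")
    return mask


def compute_erbp(epochs: EpochSet, baseline_window_ms,
                 baseline_db: np.ndarray | None = None,
                 baseline_mode: str = "per_trial",
                 eps: float | None = None) -> ERBPMatrix:
    """Log power normalized to the prestimulus baseline.

    For stimulus-aligned epochs the per-trial baseline is taken from the
    epoch itself.  For press-aligned epochs the stimulus-anchored baseline of
    the same trials must be supplied via ``baseline_db`` (dB values, one per
    row).  ``baseline_mode='pooled'`` normalizes all trials by the grand mean
    baseline instead of each trial's own.
    """
    power = epochs.envelope ** 2
    if eps is None:
        peak = float(power.max()) if power.size else 1.0
        eps = EPS_REL * (peak if peak > 0 else 1.0)
    logp = 10.0 * np.log10(power + eps)
    if baseline_db is None:
        if epochs.alignment != "stimulus":
            raise ValueError("press-aligned ERBP needs stimulus-anchored "
                             "baseline_db values")
        cols = window_columns(epochs.times_ms, baseline_window_ms)
        baseline_db = logp[:, cols].mean(axis=1)
    baseline_db = np.asarray(baseline_db, dtype=float)
    if baseline_db.shape != (epochs.n_trials,):
        raise ValueError("baseline_db must hold one value per trial")
    if baseline_mode == "pooled":
        baseline_db = np.full(epochs.n_trials, baseline_db.mean())
    elif baseline_mode != "per_trial":
        raise ValueError(f"unknown baseline_mode {baseline_mode!r}")
    values = logp - baseline_db[:, None]
    return ERBPMatrix(values=values, times_ms=epochs.times_ms,
                      alignment=epochs.alignment,
                      trial_index=epochs.trial_index, site_id=epochs.site_id)


def stimulus_baseline_db(epochs: EpochSet, baseline_window_ms,
                         eps: float | None = None) -> np.ndarray:
    """Per-trial baseline mean log power (dB) from stimulus-aligned epochs."""
    power = epochs.envelope ** 2
    if eps is None:
        peak = float(power.max()) if power.size else 1.0
        eps = EPS_REL * (peak if peak > 0 else 1.0)
    cols = window_columns(epochs.times_ms, baseline_window_ms)
    return (10.0 * np.log10(power[:, cols] + eps)).mean(axis=1)


def reject_artifacts(epochs: EpochSet, stats: BlockStats,
                     raw_sd_thresh: float = 5.0,
                     hg_sd_thresh: float = 10.0) -> np.ndarray:
    """Keep-mask over trials under the 5 SD raw / 10 SD band-filtered rule."""
    if stats.raw_sd <= 0 or stats.hg_sd <= 0:
        raise ValueError("degenerate recording: zero within-block SD")
    raw_dev = np.abs(epochs.raw - stats.raw_mean).max(axis=1)
    hg_dev = np.abs(epochs.hg_filtered - stats.hg_mean).max(axis=1)
    keep = (raw_dev <= raw_sd_thresh * stats.raw_sd) & \
           (hg_dev <= hg_sd_thresh * stats.hg_sd)
    n_drop = int((~keep).sum())
    if n_drop:
        log.info("site %s: %d/%d trials rejected as artifacts",
                 epochs.site_id, n_drop, epochs.n_trials)
    return keep
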