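"""Ground-truthed synthetic datasets emulating the target-detection task.

Each participant contributes one task block: ~2 s Gaussian inter-stimulus
intervals (SD 10 ms), 300 ms stimuli in random order, hits with
lognormal-like reaction times (median 819 ms, truncated below 400 ms),
configurable miss/false-alarm rates.  Each site is 1/f background noise plus,
on hit trials, 70-150 Hz band-limited bursts with Gaussian amplitude
envelopes (SD 60 ms): a stimulus component centered 150 ms after onset
and/or a behavior component centered 125 ms before the button press,
depending on the site's intended pattern.  Occasional large square-pulse
artifacts (8-12 SD) exercise the artifact screen.

Burst amplitudes are calibrated analytically so that the *measured*
window-mean ERBP of the analysis chain equals the requested dB value: for a
constant-amplitude tone of envelope power ratio rho over the in-band noise,
the expected log-power excess over the noise baseline is

    E[ERBP] = (10/ln 10) * (ln rho + E1(rho) + gamma)   [dB],

(E1 the exponential integral, gamma Euler's constant), which accounts for
the Rayleigh-noise bias of the log transform at both ends.  The in-band
noise power after the analysis filter is computed in closed form from the
synthesis spectrum and the filter's frequency response.

An optional Gaussian copula couples per-trial stimulus-burst amplitude to
RT (target Spearman rho given per site), for power-vs-RT recovery tests.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
from scipy.fft import irfft, rfftfreq
from scipy.optimize import brentq
from scipy.special import exp1

from . import erbp as _erbp
from .behavior import score_trials
from .dataio import (Recording, SiteMeta, TrialEvent, write_electrodes_table,
                     write_events_table, write_recording)

log = logging.getLogger("hglock")

_LN10_10 = 10.0 / np.log(10.0)

TARGET_WORDS = ("cat", "dog")
NONTARGET_WORDS = ("five", "ten", "red", "white")


@dataclass
class SitePlanRow:
    participant: str
    hemisphere: str              # 'L' or 'R'
    roi: str
    intended_pattern: str        # stimulus | behavior | intermediate | none
    post_burst_db: float = 6.0
    pre_burst_db: float = 6.0
    rho_coupling: float = 0.0    # target Spearman(power, RT), in [-1, 1]

    def __post_init__(self):
        if not -1.0 <= self.rho_coupling <= 1.0:
            raise ValueError("rho_coupling must lie in [-1, 1]")
        if self.post_burst_db < 0 or self.pre_burst_db < 0:
            raise ValueError("burst dB must be nonnegative")


@dataclass
class SimulationConfig:
    """Stated world of the generator; defaults emulate the recorded task."""

    rng_seed: int = 0
    fs_raw: float = 2000.0
    n_participants: int = 3
    site_plan: list[SitePlanRow] | None = None
    n_trials_per_block: int = 140
    isi_mean_s: float = 2.0
    isi_sd_s: float = 0.010
    stimulus_dur_s: float = 0.300
    target_fraction: float = 0.5
    rt_median_ms: float = 819.0
    rt_sigma_log: float = 0.22
    rt_min_ms: float = 400.0
    miss_rate: float = 0.05
    fa_rate: float = 0.03
    noise_exponent: float = 1.0
    noise_rms_uv: float = 20.0
    artifact_rate: float = 0.02
    artifact_sd_range: tuple[float, float] = (8.0, 12.0)
    artifact_dur_ms: float = 20.0
    burst_freq_hz: float = 110.0
    burst_sd_ms: float = 60.0
    post_burst_center_ms: float = 150.0
    pre_burst_center_ms: float = -125.0   # relative to button press
    amp_jitter_log: float = 0.35          # ln-amplitude SD used when coupled
    pad_s: float = 3.0
    # analysis-chain parameters the calibration must mirror
    target_fs: float = 1000.0
    hg_band_hz: tuple[float, float] = (70.0, 150.0)
    fir_order: int = 100
    post_window_ms: tuple[float, float] = (50.0, 300.0)
    pre_window_ms: tuple[float, float] = (-250.0, 0.0)

    def __post_init__(self):
        for p in (self.target_fraction, self.miss_rate, self.fa_rate,
                  self.artifact_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.site_plan is None:
            self.site_plan = default_site_plan(self.n_participants)
        if not self.site_plan:
            raise ValueError("site_plan must not be empty")
        self.site_plan = [p if isinstance(p, SitePlanRow) else SitePlanRow(**p)
                          for p in self.site_plan]


def default_site_plan(n_participants: int = 3, n_per_pattern: int = 20
                      ) -> list[SitePlanRow]:
    """20 sites per intended pattern, spread round-robin over participants.

    Stimulus-pattern sites live in STGP with power->RT coupling -0.3 (the
    coupled ROI of the recovery test); intermediate sites in MTGP
    (uncoupled), behavior sites in MFG, silent sites in OG.
    """
    assignments = [
        ("stimulus", "STGP", -0.3),
        ("intermediate", "MTGP", 0.0),
        ("behavior", "MFG", 0.0),
        ("none", "OG", 0.0),
    ]
    plan = []
    for pattern, roi, coupling in assignments:
        for i in range(n_per_pattern):
            pid = f"sub-{i % n_participants + 1:02d}"
            plan.append(SitePlanRow(
                participant=pid, hemisphere="L" if i % 2 == 0 else "R",
                roi=roi, intended_pattern=pattern, rho_coupling=coupling,
                post_burst_db=6.0 if pattern in ("stimulus", "intermediate") else 0.0,
                pre_burst_db=6.0 if pattern in ("behavior", "intermediate") else 0.0))
    return plan


# ---------------------------------------------------------------------------
# trial structure

def _draw_rt_ms(cfg: SimulationConfig, rng) -> tuple[float, float]:
    """One truncated lognormal RT draw; returns (rt_ms, normal score)."""
    while True:
        z = rng.standard_normal()
        rt = cfg.rt_median_ms * np.exp(cfg.rt_sigma_log * z)
        if rt >= cfg.rt_min_ms:
            return float(rt), float(z)


def simulate_trials(cfg: SimulationConfig, rng) -> tuple[list[TrialEvent], dict]:
    """One block of scored trial events plus per-trial ground truth.

    Onsets accumulate Gaussian ISIs; a fixed fraction of trial slots are
    targets, shuffled.  Ground truth records each trial's outcome and the
    standard-normal score behind its RT draw (the copula anchor).
    """
    n = cfg.n_trials_per_block
    isi = rng.normal(cfg.isi_mean_s, cfg.isi_sd_s, size=n)
    onsets = cfg.pad_s + np.concatenate([[0.0], np.cumsum(isi[:-1])])
    n_targets = int(round(n * cfg.target_fraction))
    is_target = np.zeros(n, dtype=bool)
    is_target[rng.permutation(n)[:n_targets]] = True

    events, z_rt = [], []
    for i in range(n):
        target = bool(is_target[i])
        label = str(rng.choice(TARGET_WORDS if target else NONTARGET_WORDS))
        press, z = None, float("nan")
        if target and rng.random() >= cfg.miss_rate:
            rt, z = _draw_rt_ms(cfg, rng)
            press = onsets[i] + rt / 1000.0
        elif not target and rng.random() < cfg.fa_rate:
            rt, z = _draw_rt_ms(cfg, rng)
            press = onsets[i] + rt / 1000.0
        events.append(TrialEvent(onset_s=float(onsets[i]), label=label,
                                 is_target=target, press_s=press,
                                 duration_s=cfg.stimulus_dur_s))
        z_rt.append(z)
    score_trials(events)
    truth = {
        "outcome": [e.outcome for e in events],
        "rt_ms": [e.rt_ms for e in events],
        "z_rt": z_rt,
        "duration_s": float(onsets[-1] + cfg.pad_s),
    }
    return events, truth


# ---------------------------------------------------------------------------
# burst calibration

def expected_erbp_db(rho) -> np.ndarray:
    """Expected ERBP (dB over noise baseline) of a tone at envelope SNR rho."""
    rho = np.asarray(rho, dtype=float)
    out = np.zeros_like(rho)
    nz = rho > 0
    out[nz] = _LN10_10 * (np.log(rho[nz]) + exp1(rho[nz]) + np.euler_gamma)
    return out


@lru_cache(maxsize=8)
def _noise_synthesis(n: int, fs: float, beta: float, f_floor: float = 0.5):
    """Unit-RMS 1/f amplitude spectrum and its post-analysis in-band power.

    Returns (amplitudes A_k for rfft bins, in-band noise power sigma_b^2 of
    the unit-RMS noise after downsample + zero-phase FIR, passband amplitude
    gain of the zero-phase filter at the burst carrier placeholder 110 Hz is
    computed separately via :func:`hglock.erbp.fir_gain`).
    """
    freqs = rfftfreq(n, 1.0 / fs)
    amps = np.zeros_like(freqs)
    pos = freqs > 0
    amps[pos] = np.maximum(freqs[pos], f_floor) ** (-beta / 2.0)
    # variance of irfft with random-phase bins: sum of 2 A_k^2 / n^2
    var_unit = float(np.sum(2.0 * amps[1:] ** 2) / n ** 2)
    amps /= np.sqrt(var_unit)          # unit total RMS
    return freqs, amps


@lru_cache(maxsize=8)
def _band_noise_power(n: int, fs: float, beta: float, target_fs: float,
                      band: tuple[float, float], order: int) -> float:
    """In-band power of unit-RMS synthesis noise after the analysis filter."""
    freqs, amps = _noise_synthesis(n, fs, beta)
    taps = _erbp.design_highgamma_fir(target_fs, band, order)
    lo = max(band[0] - 60.0, 1.0)
    hi = min(band[1] + 150.0, target_fs / 2.0 - 1.0)
    sel = (freqs >= lo) & (freqs <= hi)
    from scipy.signal import freqz
    _, h = freqz(taps, worN=freqs[sel], fs=target_fs)
    gain4 = np.abs(h) ** 4            # filtfilt doubles the attenuation
    return float(np.sum(2.0 * (amps[sel] ** 2) * gain4) / n ** 2)


@lru_cache(maxsize=16)
def _analyzed_burst_shape(fs_raw: float, target_fs: float, burst_sd_ms: float,
                          freq_hz: float, band: tuple[float, float],
                          order: int) -> tuple[np.ndarray, np.ndarray]:
    """Envelope of a unit-peak Gaussian burst after the analysis chain.

    The anti-alias resampler and the zero-phase FIR smear the synthetic
    burst envelope; calibrating against the *analyzed* shape (rather than
    the synthesis Gaussian) keeps the window-mean ERBP on target.  Returns
    (offsets_ms relative to burst center, envelope at the analysis rate).
    """
    pad_s = 1.0
    half_s = 4.5 * burst_sd_ms / 1000.0 + pad_s
    t = np.arange(-half_s, half_s, 1.0 / fs_raw)
    g = np.exp(-(t ** 2) / (2.0 * (burst_sd_ms / 1000.0) ** 2))
    x = g * np.sin(2.0 * np.pi * freq_hz * t)
    rec = Recording(x[None, :], fs_raw, ["cal"])
    ds = _erbp.downsample(rec, target_fs)
    taps = _erbp.design_highgamma_fir(target_fs, band, order)
    env = _erbp.highgamma_envelope(ds.samples[0], target_fs, taps=taps)
    offsets_ms = (np.arange(env.size) / target_fs - half_s) * 1000.0
    return offsets_ms, env


def calibrate_burst_amplitude(target_db: float, window_ms, center_ms: float,
                              sigma_b2: float, shape) -> float:
    """Raw burst peak amplitude achieving a window-mean ERBP of target_db.

    ``sigma_b2`` is the in-band noise power after the analysis filter (so
    baseline envelope power is 2*sigma_b2); ``shape`` the analyzed burst
    envelope from :func:`_analyzed_burst_shape`.  Solves

        mean_t expected_erbp_db(a^2 env^2(t - center) / (2 sigma_b2)) = target_db

    over the half-open analysis window (1 ms grid) for the amplitude ``a``.
    """
    if target_db <= 0:
        return 0.0
    offsets_ms, env = shape
    t = np.arange(window_ms[0], window_ms[1])     # 1 ms grid, half-open
    env_win = np.interp(t - center_ms, offsets_ms, env, left=0.0, right=0.0)
    shape2 = env_win ** 2 / (2.0 * sigma_b2)

    def gap(log_a):
        return float(np.mean(
            expected_erbp_db(np.exp(2.0 * log_a) * shape2))) - target_db

    return float(np.exp(brentq(gap, -20.0, 25.0, xtol=1e-10)))


# ---------------------------------------------------------------------------
# per-site continuous signal

def _add_burst(x: np.ndarray, fs: float, center_s: float, amp: float,
               sd_ms: float, freq_hz: float, phase: float) -> None:
    if amp <= 0:
        return
    half = 4.5 * sd_ms / 1000.0
    i0 = max(int((center_s - half) * fs), 0)
    i1 = min(int((center_s + half) * fs) + 1, x.size)
    t = np.arange(i0, i1) / fs
    g = np.exp(-((t - center_s) ** 2) / (2.0 * (sd_ms / 1000.0) ** 2))
    x[i0:i1] += amp * g * np.sin(2.0 * np.pi * freq_hz * t + phase)


def simulate_site_signal(cfg: SimulationConfig, plan: SitePlanRow,
                         events: list[TrialEvent], truth: dict,
                         rng) -> tuple[np.ndarray, dict]:
    """Continuous channel (uV at cfg.fs_raw) for one site, plus ground truth."""
    n = int(round(truth["duration_s"] * cfg.fs_raw))
    freqs, amps = _noise_synthesis(n, cfg.fs_raw, cfg.noise_exponent)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=amps.size)
    spectrum = cfg.noise_rms_uv * amps * np.exp(1j * phases)
    spectrum[0] = 0.0
    x = irfft(spectrum, n)

    sigma_b2 = cfg.noise_rms_uv ** 2 * _band_noise_power(
        n, cfg.fs_raw, cfg.noise_exponent, cfg.target_fs,
        tuple(cfg.hg_band_hz), cfg.fir_order)
    shape = _analyzed_burst_shape(cfg.fs_raw, cfg.target_fs, cfg.burst_sd_ms,
                                  cfg.burst_freq_hz, tuple(cfg.hg_band_hz),
                                  cfg.fir_order)

    a_post = calibrate_burst_amplitude(
        plan.post_burst_db, cfg.post_window_ms, cfg.post_burst_center_ms,
        sigma_b2, shape)
    a_pre = calibrate_burst_amplitude(
        plan.pre_burst_db, cfg.pre_window_ms, cfg.pre_burst_center_ms,
        sigma_b2, shape)

    r_n = 2.0 * np.sin(np.pi * plan.rho_coupling / 6.0)   # Gaussian copula
    burst_amps, artifact_trials = [], []
    for i, ev in enumerate(events):
        if ev.outcome == "hit":
            if plan.rho_coupling != 0.0:
                z_amp = (r_n * truth["z_rt"][i]
                         + np.sqrt(1.0 - r_n ** 2) * rng.standard_normal())
                factor = float(np.exp(cfg.amp_jitter_log * z_amp))
            else:
                factor = 1.0
            _add_burst(x, cfg.fs_raw,
                       ev.onset_s + cfg.post_burst_center_ms / 1000.0,
                       a_post * factor, cfg.burst_sd_ms, cfg.burst_freq_hz,
                       rng.uniform(0, 2 * np.pi))
            _add_burst(x, cfg.fs_raw,
                       ev.press_s + cfg.pre_burst_center_ms / 1000.0,
                       a_pre, cfg.burst_sd_ms, cfg.burst_freq_hz,
                       rng.uniform(0, 2 * np.pi))
            burst_amps.append({"trial": i, "post_amp_uv": a_post * factor,
                               "pre_amp_uv": a_pre})
        if rng.random() < cfg.artifact_rate:
            mag = rng.uniform(*cfg.artifact_sd_range) * cfg.noise_rms_uv
            sign = 1.0 if rng.random() < 0.5 else -1.0
            t0 = ev.onset_s + rng.uniform(-0.3, 1.8)
            i0 = max(int(t0 * cfg.fs_raw), 0)
            i1 = min(i0 + int(cfg.artifact_dur_ms / 1000.0 * cfg.fs_raw), n)
            x[i0:i1] += sign * mag
            artifact_trials.append(i)

    site_truth = {
        "intended_pattern": plan.intended_pattern,
        "post_burst_db": plan.post_burst_db,
        "pre_burst_db": plan.pre_burst_db,
        "rho_coupling": plan.rho_coupling,
        "post_amp_uv": a_post, "pre_amp_uv": a_pre,
        "artifact_trials": artifact_trials,
        "burst_amps": burst_amps,
    }
    return x, site_truth


def simulate_calibration_channel(cfg: SimulationConfig,
                                 events: list[TrialEvent],
                                 amplitude_ratio: float,
                                 noise_floor_db: float = -20.0,
                                 carrier_rms_uv: float = 10.0,
                                 window_ms=(50.0, 300.0),
                                 edge_ms: float = 25.0,
                                 rng=None) -> np.ndarray:
    """Channel with an exactly known envelope ratio, for ERBP verification.

    A steady in-band carrier defines the baseline envelope; on every hit
    trial its amplitude is multiplied by ``amplitude_ratio`` across a
    plateau covering the analysis window (raised-cosine edges outside it),
    so the true window-mean ERBP is exactly ``20*log10(amplitude_ratio)``.
    1/f noise is added with in-band power ``noise_floor_db`` below the
    carrier's envelope power.
    """
    rng = rng or np.random.default_rng(0)
    n = int(round((events[-1].onset_s + cfg.pad_s) * cfg.fs_raw))
    t = np.arange(n) / cfg.fs_raw
    a0 = carrier_rms_uv * np.sqrt(2.0)           # envelope of the carrier
    gain = np.ones(n)
    lo, hi = window_ms[0] - edge_ms, window_ms[1] + edge_ms
    for ev in events:
        if ev.outcome != "hit":
            continue
        i0 = int((ev.onset_s + (lo - edge_ms) / 1000.0) * cfg.fs_raw)
        i1 = int((ev.onset_s + (hi + edge_ms) / 1000.0) * cfg.fs_raw)
        tt = (t[i0:i1] - ev.onset_s) * 1000.0
        ramp_up = np.clip((tt - (lo - edge_ms)) / edge_ms, 0.0, 1.0)
        ramp_dn = np.clip(((hi + edge_ms) - tt) / edge_ms, 0.0, 1.0)
        smooth = 0.5 - 0.5 * np.cos(np.pi * np.minimum(ramp_up, ramp_dn))
        gain[i0:i1] = 1.0 + (amplitude_ratio - 1.0) * smooth
    x = a0 * gain * np.sin(2.0 * np.pi * cfg.burst_freq_hz * t
                           + rng.uniform(0, 2 * np.pi))

    freqs, amps = _noise_synthesis(n, cfg.fs_raw, cfg.noise_exponent)
    band_unit = _band_noise_power(n, cfg.fs_raw, cfg.noise_exponent,
                                  cfg.target_fs, tuple(cfg.hg_band_hz),
                                  cfg.fir_order)
    # in-band envelope power of noise is 2*sigma_b^2; match it to the floor
    target_band_power = a0 ** 2 * 10.0 ** (noise_floor_db / 10.0) / 2.0
    noise_rms = np.sqrt(target_band_power / band_unit)
    spectrum = noise_rms * amps * np.exp(
        1j * rng.uniform(0, 2 * np.pi, size=amps.size))
    spectrum[0] = 0.0
    return x + irfft(spectrum, n)


# ---------------------------------------------------------------------------
# whole datasets

def _site_meta_for(plan: SitePlanRow, site_id: str, rng) -> SiteMeta:
    sign = -1.0 if plan.hemisphere == "L" else 1.0
    xyz = (sign * rng.normal(50.0, 5.0), rng.normal(-20.0, 15.0),
           rng.normal(15.0, 15.0))
    return SiteMeta(site_id=site_id, participant_id=plan.participant,
                    hemisphere=plan.hemisphere, roi=plan.roi,
                    mni_xyz=tuple(float(v) for v in xyz))


class SyntheticDataset:
    """In-memory dataset: events per participant plus lazily built channels.

    Implements the same access protocol as :class:`hglock.dataio.Dataset`
    (``sites``, ``events_for``, ``channel``, ``ground_truth``) so the
    pipeline can run without touching disk.  Every stream is derived from
    ``cfg.rng_seed`` through independent ``SeedSequence`` spawns, so a given
    seed yields byte-identical datasets.
    """

    def __init__(self, cfg: SimulationConfig):
        self.cfg = cfg
        self.fs_raw = cfg.fs_raw
        participants = sorted({p.participant for p in cfg.site_plan})
        self._events: dict[str, list[TrialEvent]] = {}
        self._truth: dict[str, dict] = {}
        for k, pid in enumerate(participants):
            rng = np.random.default_rng(
                np.random.SeedSequence([cfg.rng_seed, 1000 + k]))
            self._events[pid], self._truth[pid] = simulate_trials(cfg, rng)
        meta_rng = np.random.default_rng(
            np.random.SeedSequence([cfg.rng_seed, 500]))
        self.sites = []
        self._plan_by_site: dict[str, tuple[int, SitePlanRow]] = {}
        for idx, plan in enumerate(cfg.site_plan):
            site_id = f"{plan.participant}_s{idx:03d}_{plan.roi}"
            self.sites.append(_site_meta_for(plan, site_id, meta_rng))
            self._plan_by_site[site_id] = (idx, plan)
        self.ground_truth = {
            "sites": {}, "trials": {pid: self._truth[pid]
                                    for pid in participants}}
        for site_id, (idx, plan) in self._plan_by_site.items():
            self.ground_truth["sites"][site_id] = {
                "intended_pattern": plan.intended_pattern,
                "rho_coupling": plan.rho_coupling,
                "roi": plan.roi, "participant": plan.participant,
            }

    def events_for(self, participant_id: str) -> list[TrialEvent]:
        return self._events[participant_id]

    def channel(self, site: SiteMeta) -> tuple[np.ndarray, float]:
        idx, plan = self._plan_by_site[site.site_id]
        rng = np.random.default_rng(
            np.random.SeedSequence([self.cfg.rng_seed, 7000 + idx]))
        x, site_truth = simulate_site_signal(
            self.cfg, plan, self._events[plan.participant],
            self._truth[plan.participant], rng)
        self.ground_truth["sites"][site.site_id].update(site_truth)
        return x, self.cfg.fs_raw


def simulate_dataset(cfg: SimulationConfig, out_dir) -> Path:
    """Materialize a synthetic dataset directory readable by the pipeline."""
    ds = SyntheticDataset(cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    participants = sorted({s.participant_id for s in ds.sites})
    manifest = {"participants": [], "electrodes": "electrodes.tsv",
                "ground_truth": "ground_truth.json"}
    write_electrodes_table(out / "electrodes.tsv", ds.sites)
    for pid in participants:
        sites = [s for s in ds.sites if s.participant_id == pid]
        channels = [ds.channel(s)[0] for s in sites]
        rec = Recording(np.array(channels), cfg.fs_raw,
                        [s.site_id for s in sites], block_id=pid)
        write_recording(out / f"{pid}_ieeg.bin", rec)
        write_events_table(out / f"{pid}_events.tsv", ds.events_for(pid))
        manifest["participants"].append(
            {"id": pid, "events": f"{pid}_events.tsv",
             "recording": f"{pid}_ieeg.bin"})
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(_jsonable(ds.ground_truth), fh)
    with open(out / "dataset.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    log.info("synthetic dataset with %d sites / %d participants at %s",
             len(ds.sites), len(participants), out)
    return out


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj
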