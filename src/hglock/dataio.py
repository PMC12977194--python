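"""Domain types and file I/O for event-related intracranial recordings.

The on-disk contracts are deliberately plain text where possible:

* events: BIDS-style ``events.tsv`` with columns
  ``onset, duration, label, is_target, press_time`` (seconds; press_time may
  be empty);
* electrodes: TSV with ``site, participant, hemisphere, roi, x, y, z``
  (MNI mm, ROI from the 51-label parcellation in :mod:`hglock.rois`);
* recordings: EDF, or raw little-endian float32 (channels x time, row-major)
  with a JSON sidecar ``{"fs": ..., "channels": [...], "units": "uV"}``.

All voltages are converted to microvolts on ingest.  Event times are seconds
from block start; analysis windows are milliseconds relative to an alignment
event and are half-open ``[start, end)``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .rois import ROI_TABLE, roi_group

log = logging.getLogger("hglock")

HIT = "hit"
MISS = "miss"
FALSE_ALARM = "false_alarm"
CORRECT_REJECT = "correct_reject"

_UNIT_TO_UV = {"uV": 1.0, "µV": 1.0, "mV": 1e3, "V": 1e6}


class FormatError(ValueError):
    """Raised when an input file violates its declared contract."""


@dataclass
class Recording:
    """Continuous multichannel voltage block (microvolts)."""

    samples: np.ndarray          # channels x time, uV
    fs: float                    # Hz
    channel_ids: list[str]
    block_id: str = "block"

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(set(self.channel_ids)) != len(self.channel_ids):
            raise FormatError("duplicate channel labels")
        if self.samples.ndim != 2 or self.samples.shape[0] != len(self.channel_ids):
            raise FormatError("samples must be channels x time matching channel_ids")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    def channel(self, channel_id: str) -> np.ndarray:
        return self.samples[self.channel_ids.index(channel_id)]


@dataclass
class TrialEvent:
    """One stimulus presentation with optional button press."""

    onset_s: float
    label: str
    is_target: bool
    press_s: float | None = None
    outcome: str | None = None
    duration_s: float = 0.3

    @property
    def rt_ms(self) -> float | None:
        if self.press_s is None:
            return None
        return (self.press_s - self.onset_s) * 1000.0


@dataclass
class SiteMeta:
    """Anatomical metadata for one recording site."""

    site_id: str
    participant_id: str
    hemisphere: str              # 'L' or 'R'
    roi: str                     # one of the 51 parcellation labels
    mni_xyz: tuple[float, float, float]
    roi_group: str = ""

    def __post_init__(self):
        if self.hemisphere not in ("L", "R"):
            raise FormatError(f"hemisphere must be L or R, got {self.hemisphere!r}")
        grp = roi_group(self.roi)          # raises for unknown ROI
        if not self.roi_group:
            self.roi_group = grp
        elif self.roi_group != grp:
            raise FormatError(
                f"roi_group {self.roi_group!r} inconsistent with roi {self.roi!r}")


@dataclass
class ERBPMatrix:
    """Trials x time event-related band power (dB re. prestimulus baseline)."""

    values: np.ndarray           # trials x time, dB
    times_ms: np.ndarray         # relative to alignment event
    alignment: str               # 'stimulus' or 'press'
    trial_index: np.ndarray      # indices into the originating event list
    site_id: str = ""

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        steps = np.diff(self.times_ms)
        if self.times_ms.size > 1 and not (
                np.all(steps > 0) and np.allclose(steps, steps[0])):
            raise ValueError("times_ms must be strictly increasing with uniform step")
        if self.values.shape[1] != self.times_ms.size:
            raise ValueError("values/time axis mismatch")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]


@dataclass
class BehavioralSummary:
    n_hits: int
    n_misses: int
    n_fas: int
    n_crs: int
    hit_rate: float              # percent
    fa_rate: float               # percent
    d_prime: float
    median_rt_ms: float


@dataclass
class AnalysisConfig:
    """Tunable parameters of the analysis, with task defaults.

    Windows are ms relative to the alignment event, half-open [start, end).
    The post-stimulus and pre-behavior windows cannot overlap for retained
    trials because ``min_rt_ms`` (550) >= 300 + 250.
    """

    alpha_site: float = 0.05
    post_window_ms: tuple[float, float] = (50.0, 300.0)
    pre_window_ms: tuple[float, float] = (-250.0, 0.0)
    baseline_window_ms: tuple[float, float] = (-200.0, -50.0)
    min_rt_ms: float = 550.0
    hg_band_hz: tuple[float, float] = (70.0, 150.0)
    fir_order: int = 100
    target_fs: float = 1000.0
    voltage_sd_thresh: float = 5.0
    hg_sd_thresh: float = 10.0
    sb_min_sites: int = 5
    sb_min_participants: int = 2
    roi_min_sites_envelope: int = 10
    roi_min_sites_rho: int = 10
    rng_seed: int = 0
    # conventions not pinned down by the two-window procedure itself
    stim_epoch_ms: tuple[float, float] = (-500.0, 2000.0)
    press_epoch_ms: tuple[float, float] = (-750.0, 500.0)
    envelope_stim_window_ms: tuple[float, float] = (-100.0, 300.0)
    envelope_press_window_ms: tuple[float, float] = (-400.0, 200.0)
    baseline_mode: str = "per_trial"      # or 'pooled'
    fdr_family: str = "all_groups"        # or 'per_pattern'
    notch_denoise: bool = False           # optional detrend + 60/120/180 Hz notch

    def __post_init__(self):
        for name in ("post_window_ms", "pre_window_ms", "baseline_window_ms",
                     "stim_epoch_ms", "press_epoch_ms"):
            a, b = getattr(self, name)
            if not a < b:
                raise ValueError(f"{name} must be well-ordered")
        if self.min_rt_ms < self.post_window_ms[1] - self.pre_window_ms[0]:
            raise ValueError(
                "min_rt_ms too small: post-stimulus and pre-behavior windows "
                "could overlap on retained trials")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - fields
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        for key, val in raw.items():
            if isinstance(val, list):
                raw[key] = tuple(val)
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = {k: (list(v) if isinstance(v, tuple) else v)
                for k, v in dataclasses.asdict(self).items()}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# recordings

def read_recording(path, dialect: str | None = None, block_id: str | None = None
                   ) -> Recording:
    """Read a continuous recording (EDF or raw float32 + JSON sidecar).

    ``dialect`` is inferred from the extension when omitted ('.edf' vs
    anything else with a '.json' sidecar).  Values are returned in uV.
    """
    path = Path(path)
    if dialect is None:
        dialect = "edf" if path.suffix.lower() == ".edf" else "raw_binary+json"
    if dialect == "edf":
        from . import edf
        samples, fs, labels = edf.read_edf(path)
        if len(set(labels)) != len(labels):
            raise FormatError("duplicate channel labels in EDF header")
        return Recording(samples, fs, labels, block_id or path.stem)
    if dialect != "raw_binary+json":
        raise ValueError(f"unknown dialect {dialect!r}")
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise FormatError(f"missing JSON sidecar {sidecar}")
    with open(sidecar) as fh:
        header = json.load(fh)
    if "fs" not in header:
        raise FormatError("sidecar does not declare fs")
    if "channels" not in header:
        raise FormatError("sidecar does not declare channel labels")
    channels = list(header["channels"])
    if len(set(channels)) != len(channels):
        raise FormatError("duplicate channel labels")
    scale = _UNIT_TO_UV.get(header.get("units", "uV"))
    if scale is None:
        raise FormatError(f"unsupported units {header.get('units')!r}")
    raw = np.fromfile(path, dtype="<f4")
    if raw.size % len(channels):
        raise FormatError("binary payload does not divide into declared channels")
    samples = raw.reshape(len(channels), -1).astype(float) * scale
    return Recording(samples, float(header["fs"]), channels,
                     block_id or header.get("block_id", path.stem))


def write_recording(path, rec: Recording) -> None:
    """Write the raw float32 + JSON sidecar dialect."""
    path = Path(path)
    rec.samples.astype("<f4").tofile(path)
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump({"fs": rec.fs, "channels": rec.channel_ids, "units": "uV",
                   "block_id": rec.block_id}, fh)


# ---------------------------------------------------------------------------
# events

def read_events_table(path) -> list[TrialEvent]:
    """Read a BIDS-style events TSV into chronologically sorted trial events.

    Outcomes are left unassigned; :func:`hglock.behavior.score_trials`
    assigns them.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"onset", "duration", "label", "is_target", "press_time"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"events table missing columns: {sorted(missing)}")
    onsets = df["onset"].to_numpy(dtype=float)
    if np.any(np.diff(onsets) < 0):
        raise FormatError("event onsets are not monotone nondecreasing")
    events = []
    for row in df.itertuples(index=False):
        press = None if pd.isna(row.press_time) else float(row.press_time)
        if press is not None and press <= row.onset:
            raise FormatError(
                f"press_time {press} precedes onset {row.onset}")
        events.append(TrialEvent(
            onset_s=float(row.onset), label=str(row.label),
            is_target=bool(row.is_target), press_s=press,
            duration_s=float(row.duration)))
    events.sort(key=lambda e: e.onset_s)
    return events


def write_events_table(path, events: list[TrialEvent]) -> None:
    df = pd.DataFrame({
        "onset": [e.onset_s for e in events],
        "duration": [e.duration_s for e in events],
        "label": [e.label for e in events],
        "is_target": [int(e.is_target) for e in events],
        "press_time": [e.press_s if e.press_s is not None else np.nan
                       for e in events],
    })
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# electrodes

def read_electrodes_table(path) -> list[SiteMeta]:
    df = pd.read_csv(path, sep="\t")
    required = {"site", "participant", "hemisphere", "roi", "x", "y", "z"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"electrodes table missing columns: {sorted(missing)}")
    return [SiteMeta(site_id=str(r.site), participant_id=str(r.participant),
                     hemisphere=str(r.hemisphere), roi=str(r.roi),
                     mni_xyz=(float(r.x), float(r.y), float(r.z)))
            for r in df.itertuples(index=False)]


def write_electrodes_table(path, sites: list[SiteMeta]) -> None:
    df = pd.DataFrame({
        "site": [s.site_id for s in sites],
        "participant": [s.participant_id for s in sites],
        "hemisphere": [s.hemisphere for s in sites],
        "roi": [s.roi for s in sites],
        "x": [s.mni_xyz[0] for s in sites],
        "y": [s.mni_xyz[1] for s in sites],
        "z": [s.mni_xyz[2] for s in sites],
    })
    df.to_csv(path, sep="\t", index=False)


def sites_dataframe(sites: list[SiteMeta]) -> pd.DataFrame:
    return pd.DataFrame({
        "site_id": [s.site_id for s in sites],
        "participant_id": [s.participant_id for s in sites],
        "hemisphere": [s.hemisphere for s in sites],
        "roi": [s.roi for s in sites],
        "roi_group": [s.roi_group for s in sites],
        "z_mni": [s.mni_xyz[2] for s in sites],
    })


# ---------------------------------------------------------------------------
# dataset directory

class Dataset:
    """A dataset directory: electrodes + per-participant events/recordings.

    Layout (written by ``hglock simulate`` and accepted by the pipeline)::

        dataset.json        {"participants": [{"id", "events", "recording"}]}
        electrodes.tsv
        sub-XX_events.tsv
        sub-XX_ieeg.bin / .json

    Channels are loaded lazily, one site at a time.
    """

    def __init__(self, root):
        self.root = Path(root)
        manifest = self.root / "dataset.json"
        if not manifest.exists():
            raise FormatError(f"no dataset.json in {self.root}")
        with open(manifest) as fh:
            self.manifest = json.load(fh)
        electrodes = self.root / self.manifest.get("electrodes", "electrodes.tsv")
        if not electrodes.exists():
            raise FormatError(f"missing electrodes table {electrodes}")
        self.sites = read_electrodes_table(electrodes)
        self._events: dict[str, list[TrialEvent]] = {}
        self._participants = {p["id"]: p for p in self.manifest["participants"]}
        self._recordings: dict[str, Recording] = {}
        gt = self.root / self.manifest.get("ground_truth", "ground_truth.json")
        self.ground_truth = None
        if gt.exists():
            with open(gt) as fh:
                self.ground_truth = json.load(fh)

    @property
    def fs_raw(self) -> float:
        first = next(iter(self._participants.values()))
        return self._recording(first["id"]).fs

    def events_for(self, participant_id: str) -> list[TrialEvent]:
        if participant_id not in self._events:
            entry = self._participants[participant_id]
            self._events[participant_id] = read_events_table(
                self.root / entry["events"])
        return self._events[participant_id]

    def _recording(self, participant_id: str) -> Recording:
        if participant_id not in self._recordings:
            entry = self._participants[participant_id]
            self._recordings[participant_id] = read_recording(
                self.root / entry["recording"], block_id=participant_id)
        return self._recordings[participant_id]

    def channel(self, site: SiteMeta) -> tuple[np.ndarray, float]:
        rec = self._recording(site.participant_id)
        return rec.channel(site.site_id), rec.fs
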