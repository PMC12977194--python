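"""Minimal EDF (European Data Format) reader/writer.

Supports the subset of EDF needed for continuous multichannel voltage
recordings: a single common sampling rate, int16 samples, physical units of
uV/mV/V.  Values round-trip up to the 16-bit quantization of the
physical range.  Data records that do not divide the signal length evenly
are zero-padded on write; the writer picks the shortest record duration
(<= 10 s) for which samples-per-record is integral.
"""

from __future__ import annotations

import math

import numpy as np

_UNIT_TO_UV = {"uV": 1.0, "µV": 1.0, "mV": 1e3, "V": 1e6}


def _ascii(field: str, width: int) -> bytes:
    out = field.encode("ascii")[:width]
    return out + b" " * (width - len(out))


def write_edf(path, samples: np.ndarray, fs: float, channel_ids,
              units: str = "uV") -> None:
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2:
        raise ValueError("samples must be 2-D (channels x time)")
    n_sig, n_time = samples.shape
    if len(channel_ids) != n_sig:
        raise ValueError("channel_ids length mismatch")
    rec_dur = next((d for d in range(1, 11) if abs(fs * d - round(fs * d)) < 1e-9), None)
    if rec_dur is None:
        raise ValueError(f"cannot express fs={fs} as integer samples per <=10 s record")
    spr = int(round(fs * rec_dur))
    n_rec = math.ceil(n_time / spr)

    pmin = samples.min(axis=1)
    pmax = samples.max(axis=1)
    flat = pmax - pmin <= 0
    pmin[flat] -= 1.0
    pmax[flat] += 1.0
    dmin, dmax = -32768, 32767

    hdr = b"".join([
        _ascii("0", 8),
        _ascii("X X X X", 80),
        _ascii("Startdate X X X X", 80),
        _ascii("01.01.00", 8),
        _ascii("00.00.00", 8),
        _ascii(str(256 * (1 + n_sig)), 8),
        _ascii("", 44),
        _ascii(str(n_rec), 8),
        _ascii(str(rec_dur), 8),
        _ascii(str(n_sig), 4),
    ])
    sig_fields = [
        [_ascii(str(c), 16) for c in channel_ids],
        [_ascii("", 80)] * n_sig,
        [_ascii(units, 8)] * n_sig,
        [_ascii(f"{v:.8g}"[:8], 8) for v in pmin],
        [_ascii(f"{v:.8g}"[:8], 8) for v in pmax],
        [_ascii(str(dmin), 8)] * n_sig,
        [_ascii(str(dmax), 8)] * n_sig,
        [_ascii("", 80)] * n_sig,
        [_ascii(str(spr), 8)] * n_sig,
        [_ascii("", 32)] * n_sig,
    ]
    hdr += b"".join(b"".join(f) for f in sig_fields)

    scale = (pmax - pmin) / (dmax - dmin)
    dig = np.round((samples - pmin[:, None]) / scale[:, None] + dmin)
    dig = np.clip(dig, dmin, dmax).astype("<i2")
    pad = n_rec * spr - n_time
    if pad:
        baseline = np.round((0.0 - pmin) / scale + dmin)
        baseline = np.clip(baseline, dmin, dmax).astype("<i2")
        dig = np.concatenate(
            [dig, np.tile(baseline[:, None], (1, pad))], axis=1)

    with open(path, "wb") as fh:
        fh.write(hdr)
        # records are interleaved: rec0[sig0 .. sigN], rec1[...], ...
        recs = dig.reshape(n_sig, n_rec, spr).transpose(1, 0, 2)
        fh.write(np.ascontiguousarray(recs).tobytes())


def read_edf(path):
    """Read an EDF file; returns ``(samples_uv, fs, channel_ids)``."""
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise ValueError("truncated EDF header")
        n_rec = int(head[236:244].decode("ascii").strip())
        rec_dur = float(head[244:252].decode("ascii").strip())
        n_sig = int(head[252:256].decode("ascii").strip())
        sig = fh.read(256 * n_sig)

        def fields(offset, width):
            base = offset * n_sig
            return [sig[base + i * width: base + (i + 1) * width]
                    .decode("ascii").strip() for i in range(n_sig)]

        labels = fields(0, 16)
        dims = fields(16 + 80, 8)
        pmin = np.array([float(v) for v in fields(16 + 80 + 8, 8)])
        pmax = np.array([float(v) for v in fields(16 + 80 + 16, 8)])
        dmin = np.array([float(v) for v in fields(16 + 80 + 24, 8)])
        dmax = np.array([float(v) for v in fields(16 + 80 + 32, 8)])
        spr = np.array([int(v) for v in fields(16 + 80 + 40 + 80, 8)])

        if len(set(spr)) != 1:
            raise ValueError("mixed sampling rates are not supported")
        spr0 = int(spr[0])
        fs = spr0 / rec_dur
        raw = np.frombuffer(fh.read(2 * n_sig * spr0 * n_rec), dtype="<i2")

    if raw.size != n_sig * spr0 * n_rec:
        raise ValueError("truncated EDF data section")
    dig = raw.reshape(n_rec, n_sig, spr0).transpose(1, 0, 2).reshape(n_sig, -1)
    scale = (pmax - pmin) / (dmax - dmin)
    phys = (dig - dmin[:, None]) * scale[:, None] + pmin[:, None]
    to_uv = np.array([_UNIT_TO_UV.get(d, np.nan) for d in dims])
    if np.isnan(to_uv).any():
        bad = [d for d in dims if d not in _UNIT_TO_UV]
        raise ValueError(f"unsupported physical dimension(s): {bad}")
    return phys * to_uv[:, None], fs, labels
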