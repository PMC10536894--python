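"""Minimal EDF+ (continuous) writer.

Writes 16-bit EDF+C files with one annotation channel carrying the event
list as time-stamped annotation lists (TALs), readable by standard EDF
software. Signals are stored in physical units of microvolts over a
symmetric physical range chosen from the data (or given explicitly), so
the quantization step is ``2 * phys_max / (2^16 - 2)``.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np

from .preprocessing import AnnotatedRecording

_DIG_MIN, _DIG_MAX = -32767, 32767


def _field(value: str, width: int) -> bytes:
    raw = value.encode("ascii")
    if len(raw) > width:
        raise ValueError(f"EDF header field {value!r} exceeds {width} bytes")
    return raw.ljust(width)


def _fmt_seconds(x: float) -> str:
    s = f"{x:.7f}".rstrip("0").rstrip(".")
    return s if s else "0"


def _physical_limit(max_abs: float) -> float:
    """Smallest 5-significant-digit value >= max_abs * 1.02 (headroom)."""
    if max_abs == 0:
        return 1.0
    target = max_abs * 1.02
    exp = math.floor(math.log10(target))
    scale = 10 ** (exp - 4)
    return math.ceil(target / scale) * scale


def _record_duration(fs: float) -> tuple[float, int]:
    for dur in range(1, 61):
        n = fs * dur
        if abs(n - round(n)) < 1e-9:
            return float(dur), int(round(n))
    raise ValueError(
        f"sampling rate {fs} Hz has no integral samples-per-record for "
        "record durations of 1-60 s"
    )


def write_edf(
    recording: AnnotatedRecording,
    path: str | Path,
    physical_range_uv: float | None = None,
) -> Path:
    """Write the recording (µV) and its annotations to an EDF+C file.

    The last data record is zero-padded when the signal length is not a
    multiple of the samples-per-record. Annotations round-trip exactly
    when event onsets/durations are integral numbers of samples (they are,
    by construction of AnnotatedRecording).
    """
    path = Path(path)
    sig = np.asarray(recording.signal, dtype=np.float64)
    if not np.all(np.isfinite(sig)):
        raise ValueError("signal contains non-finite values")
    max_abs = float(np.abs(sig).max()) if sig.size else 0.0
    if physical_range_uv is None:
        phys = _physical_limit(max_abs)
    else:
        phys = float(physical_range_uv)
        if max_abs > phys:
            raise ValueError(
                f"signal amplitude {max_abs:.3f} µV overflows the physical "
                f"range ±{phys} µV"
            )
    fs = recording.sampling_rate_hz
    rec_dur, spr = _record_duration(fs)
    n_ch = recording.n_channels
    n_records = max(1, math.ceil(recording.n_samples / spr))

    # --- annotation TALs, assigned to the record containing their onset
    tals: list[list[bytes]] = [[] for _ in range(n_records)]
    for r in range(n_records):
        t0 = _fmt_seconds(r * rec_dur)
        tals[r].append(f"+{t0}\x14\x14\x00".encode("ascii"))
    for onset, dur, label in recording.events:
        r = min(int(onset // spr), n_records - 1)
        tal = (
            f"+{_fmt_seconds(onset / fs)}\x15{_fmt_seconds(dur / fs)}"
            f"\x14{label}\x14\x00"
        ).encode("utf-8")
        tals[r].append(tal)
    annot_bytes = max(sum(len(t) for t in rec) for rec in tals)
    annot_spr = (annot_bytes + 1) // 2 + 8  # headroom, in 2-byte samples

    ns = n_ch + 1
    header_bytes = 256 * (ns + 1)

    with open(path, "wb") as fh:
        fh.write(_field("0", 8))
        fh.write(_field("X X X X", 80))
        fh.write(_field("Startdate 01-JAN-2000 X X X", 80))
        fh.write(_field("01.01.00", 8))
        fh.write(_field("00.00.00", 8))
        fh.write(_field(str(header_bytes), 8))
        fh.write(_field("EDF+C", 44))
        fh.write(_field(str(n_records), 8))
        fh.write(_field(_fmt_seconds(rec_dur), 8))
        fh.write(_field(str(ns), 4))

        labels = [n[:16] for n in recording.channel_names] + ["EDF Annotations"]
        for lab in labels:
            fh.write(_field(lab, 16))
        for _ in range(ns):
            fh.write(_field("", 80))  # transducer
        for i in range(ns):
            fh.write(_field("uV" if i < n_ch else "", 8))
        for i in range(ns):
            fh.write(_field(f"{-phys:.8g}"[:8] if i < n_ch else "-1", 8))
        for i in range(ns):
            fh.write(_field(f"{phys:.8g}"[:8] if i < n_ch else "1", 8))
        for _ in range(ns):
            fh.write(_field(str(_DIG_MIN), 8))
        for _ in range(ns):
            fh.write(_field(str(_DIG_MAX), 8))
        for _ in range(ns):
            fh.write(_field("", 80))  # prefiltering
        for i in range(ns):
            fh.write(_field(str(spr if i < n_ch else annot_spr), 8))
        for _ in range(ns):
            fh.write(_field("", 32))

        gain = (_DIG_MAX - _DIG_MIN) / (2 * phys)
        for r in range(n_records):
            start = r * spr
            chunk = sig[:, start : start + spr]
            if chunk.shape[1] < spr:
                pad = np.zeros((n_ch, spr - chunk.shape[1]))
                chunk = np.concatenate([chunk, pad], axis=1)
            digital = np.rint((chunk + phys) * gain + _DIG_MIN)
            digital = np.clip(digital, _DIG_MIN, _DIG_MAX).astype("<i2")
            fh.write(digital.tobytes())
            tal_block = b"".join(tals[r])
            fh.write(tal_block.ljust(annot_spr * 2, b"\x00"))
    return path
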