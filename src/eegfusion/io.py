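"""Reading recordings and persisting windowed datasets.

EDF+ files are read through MNE; recordings from non-EDF sources can pair
a plain array with a sidecar event table (tab-separated text with columns
``onset_sample  duration_samples  label``). Windowed datasets are stored
as an ``.npz`` array container next to a JSON manifest recording class
names, sampling rate, recipe and seed.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from .preprocessing import AnnotatedRecording, WindowedDataset


def read_edf_recording(path: str | Path) -> AnnotatedRecording:
    """Load an EDF/EDF+ file (signals in µV plus its annotations)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    sig = raw.get_data() * 1e6  # MNE returns volts
    events = []
    for onset_s, dur_s, desc in zip(
        raw.annotations.onset, raw.annotations.duration, raw.annotations.description
    ):
        events.append(
            (int(round(onset_s * fs)), int(round(dur_s * fs)), str(desc))
        )
    events.sort(key=lambda e: e[0])
    return AnnotatedRecording(sig, fs, list(raw.ch_names), events)


def read_sidecar_events(path: str | Path) -> list[tuple[int, int, str]]:
    """Parse a tab-separated event sidecar (onset, duration, label)."""
    events = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if parts[0] == "onset_sample":  # header row
            continue
        if len(parts) != 3:
            raise ValueError(f"{path}:{ln}: expected 3 tab-separated fields")
        events.append((int(parts[0]), int(parts[1]), parts[2]))
    return sorted(events, key=lambda e: e[0])


def write_sidecar_events(
    events: list[tuple[int, int, str]], path: str | Path
) -> None:
    lines = ["onset_sample\tduration_samples\tlabel"]
    lines += [f"{o}\t{d}\t{lab}" for o, d, lab in events]
    Path(path).write_text("\n".join(lines) + "\n")


def dataset_fingerprint(data: WindowedDataset) -> str:
    """SHA-256 over the window array, labels and provenance."""
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(data.windows, dtype=np.float64).tobytes())
    h.update(np.ascontiguousarray(data.labels).tobytes())
    h.update(np.ascontiguousarray(data.provenance).tobytes())
    h.update(json.dumps(list(data.class_names)).encode())
    return h.hexdigest()


def save_windowed_dataset(
    data: WindowedDataset, path: str | Path, recipe: str = "custom",
    seed: int | None = None,
) -> Path:
    """Write ``<path>.npz`` and ``<path>.manifest.json``."""
    path = Path(path)
    base = path.with_suffix("") if path.suffix == ".npz" else path
    np.savez(
        base.with_suffix(".npz"),
        windows=data.windows,
        labels=data.labels,
        provenance=data.provenance,
    )
    manifest = {
        "class_names": list(data.class_names),
        "sampling_rate_hz": data.sampling_rate_hz,
        "recipe": recipe,
        "seed": seed,
        "n_windows": int(data.n_windows),
        "fingerprint": dataset_fingerprint(data),
    }
    base.with_suffix(".manifest.json").write_text(
        json.dumps(manifest, indent=2) + "\n"
    )
    return base.with_suffix(".npz")


def load_windowed_dataset(path: str | Path) -> WindowedDataset:
    path = Path(path)
    base = path.with_suffix("") if path.suffix == ".npz" else path
    with np.load(base.with_suffix(".npz")) as npz:
        windows = npz["windows"]
        labels = npz["labels"]
        provenance = npz["provenance"]
    manifest = json.loads(base.with_suffix(".manifest.json").read_text())
    data = WindowedDataset(
        windows,
        labels,
        list(manifest["class_names"]),
        float(manifest["sampling_rate_hz"]),
        provenance,
    )
    if manifest.get("fingerprint") and manifest["fingerprint"] != dataset_fingerprint(data):
        raise ValueError(f"dataset {base} does not match its manifest fingerprint")
    return data
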