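"""On-disk container for EEG recordings/evokeds and channel geometry.

Recordings are stored as a single compressed NumPy archive (``.rteeg.npz``:
a ZIP of ``.npy`` members) holding the sample array (``data``, micro-volt,
channels x time, float32) and a UTF-8 JSON header (``header``) with channel
names, sampling rate, units, condition labels and event annotations
(sample index + label).  The same container stores averaged evokeds
(``.rtevk.npz``) with the epoch count in the header.

Channel geometry (for spatial response weighting and bad-channel
interpolation) comes from the 129-channel geodesic sensor net montage
bundled with MNE.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np

__all__ = ["RawRecording", "Evoked", "save_recording", "load_recording",
           "save_evoked", "load_evoked", "channel_positions"]

RECORDING_SUFFIX = ".rteeg.npz"
EVOKED_SUFFIX = ".rtevk.npz"


@dataclass
class RawRecording:
    """A continuous Cz-referenced recording of one participant-condition."""

    data: np.ndarray            #: (n_channels, n_samples), micro-volt
    fs_hz: int
    ch_names: list[str]
    events: list[tuple[int, str]] = field(default_factory=list)
    participant: str = ""
    group: str = ""
    condition: str = ""
    reference: str = "Cz"

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]


@dataclass
class Evoked:
    """Per-condition average of accepted epochs (channels x time)."""

    data: np.ndarray
    fs_hz: int
    ch_names: list[str]
    n_epochs_averaged: int
    condition: str = ""
    participant: str = ""
    group: str = ""
    reference: str = "average"
    interpolated: list[str] = field(default_factory=list)


def _save(path, data: np.ndarray, header: dict) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(path, data=data.astype(np.float32),
                        header=np.frombuffer(
                            json.dumps(header).encode(), dtype=np.uint8))
    return path


def _load(path) -> tuple[np.ndarray, dict]:
    with np.load(path) as z:
        data = z["data"].astype(np.float64)
        header = json.loads(bytes(z["header"].tobytes()).decode())
    return data, header


def save_recording(path, rec: RawRecording) -> Path:
    header = dict(kind="recording", fs_hz=rec.fs_hz, ch_names=rec.ch_names,
                  units="uV", reference=rec.reference,
                  participant=rec.participant, group=rec.group,
                  condition=rec.condition,
                  events=[[int(s), l] for s, l in rec.events])
    return _save(path, rec.data, header)


def load_recording(path) -> RawRecording:
    data, h = _load(path)
    return RawRecording(data=data, fs_hz=int(h["fs_hz"]),
                        ch_names=list(h["ch_names"]),
                        events=[(int(s), l) for s, l in h["events"]],
                        participant=h.get("participant", ""),
                        group=h.get("group", ""),
                        condition=h.get("condition", ""),
                        reference=h.get("reference", "Cz"))


def save_evoked(path, ev: Evoked) -> Path:
    header = dict(kind="evoked", fs_hz=ev.fs_hz, ch_names=ev.ch_names,
                  units="uV", reference=ev.reference,
                  n_epochs_averaged=int(ev.n_epochs_averaged),
                  participant=ev.participant, group=ev.group,
                  condition=ev.condition, interpolated=list(ev.interpolated))
    return _save(path, ev.data, header)


def load_evoked(path) -> Evoked:
    data, h = _load(path)
    return Evoked(data=data, fs_hz=int(h["fs_hz"]),
                  ch_names=list(h["ch_names"]),
                  n_epochs_averaged=int(h["n_epochs_averaged"]),
                  condition=h.get("condition", ""),
                  participant=h.get("participant", ""),
                  group=h.get("group", ""),
                  reference=h.get("reference", "average"),
                  interpolated=list(h.get("interpolated", [])))


@lru_cache(maxsize=1)
def _montage_positions() -> dict[str, np.ndarray]:
    import mne
    mont = mne.channels.make_standard_montage("GSN-HydroCel-129")
    return {name: np.asarray(pos, dtype=float)
            for name, pos in mont.get_positions()["ch_pos"].items()}


def channel_positions(ch_names) -> np.ndarray:
    """(n, 3) electrode positions in meters for geodesic-net channel names."""
    pos = _montage_positions()
    missing = [c for c in ch_names if c not in pos]
    if missing:
        raise KeyError(f"channel(s) not in the 129-channel net: {missing}")
    return np.stack([pos[c] for c in ch_names])
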