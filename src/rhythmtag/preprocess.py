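"""Raw records to clean per-condition evoked averages.

Stage order is fixed and fingerprinted: band-pass filter (0.3-30 Hz
zero-phase windowed-sinc FIR) -> epoch [0, 30 s) at sequence onsets ->
bad-channel detection (robust variance vs. the channel population) ->
ocular-artifact handling (template regression on frontal proxies, or none)
-> interpolation of bad channels (inverse-distance weighting) -> rejection
of epochs exceeding +/-100 micro-volt -> average reference -> per-condition
averaging.  A participant-condition with fewer than 6 of 8 accepted epochs
is excluded; more than 12 bad channels flags the participant.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
from scipy import signal

from . import config as cfg
from .config import PreprocessConfig
from .containers import Evoked, RawRecording, channel_positions

__all__ = [
    "EpochedEEG", "ExclusionError", "bandpass", "epoch_record",
    "detect_bad_channels", "interpolate_channels",
    "detect_and_interpolate_bad_channels", "remove_ocular_artifacts",
    "reject_epochs", "rereference_and_average", "preprocess_recording",
    "PIPELINE_ORDER",
]

PIPELINE_ORDER = ("bandpass", "epoch", "detect_bad_channels",
                  "ocular", "interpolate", "reject", "rereference",
                  "average")


class ExclusionError(RuntimeError):
    """Participant-condition excluded (too few epochs / too many channels)."""

    def __init__(self, participant: str, condition: str, reason: str):
        super().__init__(f"{participant}/{condition}: {reason}")
        self.participant = participant
        self.condition = condition
        self.reason = reason


@dataclass
class EpochedEEG:
    """Epoch x channel x time array (micro-volt) with bookkeeping."""

    data: np.ndarray
    fs_hz: int
    ch_names: list[str]
    accept: np.ndarray = None          #: per-epoch accept flag
    bad_channels: list[str] = field(default_factory=list)
    interpolated: list[str] = field(default_factory=list)
    reference: str = "Cz"
    participant: str = ""
    group: str = ""
    condition: str = ""

    def __post_init__(self):
        if self.accept is None:
            self.accept = np.ones(self.data.shape[0], dtype=bool)

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    def copy_with(self, **kw) -> "EpochedEEG":
        out = replace(self, **kw)
        return out


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

@lru_cache(maxsize=8)
def _fir_taps(fs: int, low: float, high: float) -> np.ndarray:
    """Linear-phase windowed-sinc band-pass (Hamming).

    The filter length is set by the low-edge transition (pass 0.3 Hz,
    >=40 dB down at 0.05 Hz): the -6 dB cutoffs sit midway inside each
    transition band and the Hamming main-lobe width fixes the tap count.
    """
    trans = min(low - 0.05, 0.25)            # low-side transition width, Hz
    numtaps = int(np.ceil(3.3 * fs / trans)) | 1
    f1 = low - trans / 2.0
    f2 = high + min(10.0, (fs / 2 - high) / 2)
    return signal.firwin(numtaps, [f1, f2], pass_zero=False, fs=fs,
                         window="hamming")


def bandpass(record: RawRecording, low: float = cfg.BAND_LOW_HZ,
             high: float = cfg.BAND_HIGH_HZ) -> RawRecording:
    """Zero-phase FIR band-pass of a continuous record.

    Implemented as centered convolution with a symmetric (linear-phase)
    kernel, which is exactly zero-phase.
    """
    if high >= record.fs_hz / 2:
        raise ValueError("high cutoff must be below Nyquist")
    taps = _fir_taps(record.fs_hz, low, high)
    data = signal.fftconvolve(record.data.astype(np.float32),
                              taps[None, :].astype(np.float32),
                              mode="same", axes=1)
    return replace(record, data=data)


# ---------------------------------------------------------------------------
# Epoching
# ---------------------------------------------------------------------------

def epoch_record(record: RawRecording,
                 epoch_s: float = cfg.EPOCH_S) -> EpochedEEG:
    """Cut [onset, onset + 30 s) epochs at ``seq_onset`` annotations."""
    n = int(round(epoch_s * record.fs_hz))
    onsets = [s for s, label in record.events if label == "seq_onset"]
    if not onsets:
        raise ValueError("record has no seq_onset events")
    epochs = np.stack([record.data[:, s:s + n] for s in onsets])
    if epochs.shape[-1] != n:
        raise ValueError("epoch extends past end of record")
    return EpochedEEG(data=np.transpose(epochs, (0, 1, 2)), fs_hz=record.fs_hz,
                      ch_names=list(record.ch_names),
                      reference=record.reference,
                      participant=record.participant, group=record.group,
                      condition=record.condition)


# ---------------------------------------------------------------------------
# Bad channels
# ---------------------------------------------------------------------------

def detect_bad_channels(epochs: EpochedEEG, k: float = 5.0,
                        max_bad: int = cfg.MAX_BAD_CHANNELS) -> list[str]:
    """Channels whose robust amplitude SD is an outlier of the population.

    A channel is bad when its MAD-based SD exceeds the population median by
    more than ``k`` times the population MAD.  More than ``max_bad`` bad
    channels raises an exclusion (mirrors the plausible range of a clean
    recording).
    """
    # robust per-channel spread (MAD-based SD) on a time subsample --
    # a few thousand samples per epoch pin the scale down to ~1%
    step = max(1, epochs.data.shape[-1] // 2000)
    x = epochs.data[..., ::step].astype(np.float64)
    flat = np.abs(x - np.median(x, axis=-1, keepdims=True))
    ch_sd = 1.4826 * np.median(flat, axis=(0, 2))
    med = np.median(ch_sd)
    mad = 1.4826 * np.median(np.abs(ch_sd - med))
    mad = max(mad, 1e-12)
    bad = [epochs.ch_names[i] for i in np.nonzero(ch_sd > med + k * mad)[0]]
    if len(bad) > max_bad:
        raise ExclusionError(epochs.participant, epochs.condition,
                             f"{len(bad)} bad channels (> {max_bad})")
    return bad


def interpolate_channels(epochs: EpochedEEG, bad: list[str],
                         positions: np.ndarray | None = None,
                         n_neighbors: int = 4) -> EpochedEEG:
    """Replace bad channels by the inverse-distance-weighted (1/d^2) average
    of their ``n_neighbors`` nearest good channels."""
    if not bad:
        return epochs.copy_with(bad_channels=list(bad))
    if positions is None:
        positions = channel_positions(epochs.ch_names)
    names = list(epochs.ch_names)
    bad_idx = [names.index(c) for c in bad]
    good_idx = [i for i in range(len(names)) if i not in bad_idx]
    if len(good_idx) < n_neighbors:
        raise ValueError("not enough good channels to interpolate from")
    data = epochs.data.copy()
    for bi in bad_idx:
        d = np.linalg.norm(positions[good_idx] - positions[bi], axis=1)
        order = np.argsort(d)[:n_neighbors]
        wsum = np.sum(1.0 / d[order] ** 2)
        wts = (1.0 / d[order] ** 2) / wsum
        src = [good_idx[j] for j in order]
        data[:, bi, :] = np.tensordot(wts, data[:, src, :], axes=(0, 1))
    return epochs.copy_with(data=data, bad_channels=list(bad),
                            interpolated=list(bad))


def detect_and_interpolate_bad_channels(
        epochs: EpochedEEG, k: float = 5.0,
        positions: np.ndarray | None = None,
        n_neighbors: int = 4) -> EpochedEEG:
    bad = detect_bad_channels(epochs, k=k)
    return interpolate_channels(epochs, bad, positions=positions,
                                n_neighbors=n_neighbors)


# ---------------------------------------------------------------------------
# Ocular artifacts
# ---------------------------------------------------------------------------

def remove_ocular_artifacts(epochs: EpochedEEG, strategy: str = "regression",
                            frontal=cfg.FRONTAL_PROXIES,
                            threshold_uv: float = 60.0) -> EpochedEEG:
    """Reduce ocular artifacts by template regression on frontal proxies.

    The blink template per epoch is the mean of the frontal proxy channels.
    Samples where the template exceeds ``threshold_uv`` (dilated by 100 ms
    and cosine-tapered) define the artifact support; each channel is
    regressed on the template over that support and the fitted contribution
    subtracted there.  Epochs whose template never crosses the threshold are
    untouched.  ``strategy="none"`` is the identity.
    """
    if strategy == "none":
        return epochs
    if strategy != "regression":
        raise ValueError(f"unknown ocular strategy {strategy!r}")
    names = list(epochs.ch_names)
    f_idx = [names.index(c) for c in frontal
             if c in names and c not in epochs.bad_channels]
    if not f_idx:
        raise ValueError("no usable frontal proxy channels")
    data = epochs.data.copy()
    fs = epochs.fs_hz
    dilate = int(0.1 * fs)
    taper_n = int(0.05 * fs)
    for e in range(epochs.n_epochs):
        template = data[e, f_idx, :].mean(axis=0)
        mask = np.abs(template) > threshold_uv
        if not mask.any():
            continue
        # dilate the support and taper its edges
        idx = np.nonzero(mask)[0]
        support = np.zeros(template.size)
        for i0, i1 in _runs(idx):
            a = max(i0 - dilate, 0)
            b = min(i1 + dilate, template.size - 1)
            support[a:b + 1] = 1.0
            ta = min(taper_n, a)
            if ta > 0:
                support[a - ta:a] = np.maximum(
                    support[a - ta:a], 0.5 - 0.5 * np.cos(
                        np.pi * np.arange(ta) / ta))
            tb = min(taper_n, template.size - 1 - b)
            if tb > 0:
                support[b + 1:b + 1 + tb] = np.maximum(
                    support[b + 1:b + 1 + tb], 0.5 + 0.5 * np.cos(
                        np.pi * (np.arange(tb) + 1) / tb))
        t_sup = template * support
        denom = float(t_sup @ t_sup)
        if denom <= 0:
            continue
        beta = (data[e] @ t_sup) / denom
        data[e] -= np.outer(beta, t_sup)
    return epochs.copy_with(data=data)


def _runs(idx: np.ndarray):
    """Contiguous runs (start, stop inclusive) of sorted indices."""
    if idx.size == 0:
        return
    breaks = np.nonzero(np.diff(idx) > 1)[0]
    starts = np.r_[idx[0], idx[breaks + 1]]
    stops = np.r_[idx[breaks], idx[-1]]
    yield from zip(starts, stops)


# ---------------------------------------------------------------------------
# Rejection, referencing, averaging
# ---------------------------------------------------------------------------

def reject_epochs(epochs: EpochedEEG,
                  threshold_uv: float = cfg.REJECT_UV) -> EpochedEEG:
    """Flag epochs with any sample strictly exceeding the threshold on any
    non-interpolated channel."""
    names = list(epochs.ch_names)
    check = [i for i, c in enumerate(names) if c not in epochs.interpolated]
    peak = np.max(np.abs(epochs.data[:, check, :]), axis=(1, 2))
    return epochs.copy_with(accept=peak <= threshold_uv)


def rereference_and_average(epochs: EpochedEEG,
                            min_good: int = cfg.MIN_GOOD_EPOCHS) -> Evoked:
    """Average reference (channel mean removed per sample), then average the
    accepted epochs; too few accepted epochs excludes the dataset."""
    n_good = int(epochs.accept.sum())
    if n_good < min_good:
        raise ExclusionError(
            epochs.participant, epochs.condition,
            f"only {n_good} accepted epochs (< {min_good})")
    data = epochs.data[epochs.accept].astype(np.float64)
    data = data - data.mean(axis=1, keepdims=True)
    avg = data.mean(axis=0)
    return Evoked(data=avg, fs_hz=epochs.fs_hz,
                  ch_names=list(epochs.ch_names),
                  n_epochs_averaged=n_good, condition=epochs.condition,
                  participant=epochs.participant, group=epochs.group,
                  reference="average", interpolated=list(epochs.interpolated))


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def preprocess_recording(record: RawRecording,
                         pp: PreprocessConfig | None = None
                         ) -> tuple[Evoked, dict]:
    """Run the fixed stage order on one recording.

    Returns the evoked average and a log dict (stages, channels
    interpolated, epochs rejected).  Raises :class:`ExclusionError` when the
    dataset does not survive.
    """
    pp = pp or PreprocessConfig()
    log: dict = {"stages": list(PIPELINE_ORDER),
                 "participant": record.participant,
                 "condition": record.condition}
    filtered = bandpass(record, pp.band_low_hz, pp.band_high_hz)
    epochs = epoch_record(filtered)
    bad = detect_bad_channels(epochs, k=pp.bad_channel_mad_k,
                              max_bad=pp.max_bad_channels)
    epochs = epochs.copy_with(bad_channels=bad)
    log["bad_channels"] = bad
    epochs = remove_ocular_artifacts(
        epochs, strategy=pp.ocular_strategy,
        threshold_uv=pp.blink_threshold_uv)
    if pp.reject_before_interpolation:
        # alternative reading of the rejection/interpolation order: the
        # +/-100 uV rule applied before bad channels are replaced (bad
        # channels are still ignored by the rule either way)
        epochs = epochs.copy_with(interpolated=list(bad))
        epochs = reject_epochs(epochs, threshold_uv=pp.reject_uv)
        accept = epochs.accept
        epochs = interpolate_channels(epochs, bad).copy_with(accept=accept)
    else:
        epochs = interpolate_channels(epochs, bad)
        epochs = reject_epochs(epochs, threshold_uv=pp.reject_uv)
    log["epochs_rejected"] = int((~epochs.accept).sum())
    evoked = rereference_and_average(epochs, min_good=pp.min_good_epochs)
    log["epochs_averaged"] = evoked.n_epochs_averaged
    return evoked, log
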