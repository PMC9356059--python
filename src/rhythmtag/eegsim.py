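"""Forward simulation of frequency-tagged EEG with known ground truth.

Each simulated participant-condition is a continuous Cz-referenced record
containing 8 epochs of 30 s.  Within an epoch the tracking response is a sum
over the target rates (2.5, 5, 10 Hz) of non-sinusoidal periodic waveforms
(fundamental plus configured upper harmonics, zero phase), scaled by a
per-participant random amplitude and projected onto the scalp through a
fixed fronto-central weight vector normalized to unit mean over the default
ROI.  On top of that: 1/f background noise (spectrally shaped seeded white
noise), ocular artifacts (smooth frontal deflections of 150-250 micro-volt
lasting 0.5-2 s on a seeded Poisson schedule), and occasional bad channels
replaced by high-variance noise.  Everything the simulator embeds is
returned as ground truth so the analysis pipeline can be scored against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import config as cfg
from .config import SimConfig
from .containers import RawRecording, channel_positions, save_recording

__all__ = ["SimConfig", "GroundTruth", "spatial_weights", "blink_topography",
           "pink_noise", "response_waveform", "simulate_participant",
           "simulate_cohort"]


@dataclass
class GroundTruth:
    """What the simulator embedded for one participant."""

    participant: str
    group: str
    #: (condition, freq) -> embedded fundamental amplitude (micro-volt, ROI)
    amplitudes: dict[tuple[str, float], float] = field(default_factory=dict)
    #: (condition, freq) -> total amplitude at the target bin, including
    #: harmonics of lower target rates that land on it (coherent, zero phase)
    bin_amplitudes: dict[tuple[str, float], float] = field(
        default_factory=dict)
    #: condition -> per-epoch flag: epoch contains a >100 uV ocular artifact
    blink_epochs: dict[str, list[bool]] = field(default_factory=dict)
    #: condition -> channels replaced by high-variance noise
    bad_channels: dict[str, list[str]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Spatial model
# ---------------------------------------------------------------------------

def spatial_weights(ch_names, roi=cfg.DEFAULT_ROI) -> np.ndarray:
    """Fixed fronto-central projection of the response onto the scalp.

    Gaussian fall-off with distance from the ROI centroid, floored at 0.25,
    normalized so that after average-referencing the mean ROI weight equals
    1 — the pipeline's ROI amplitude estimates are then on the same scale
    as the embedded amplitudes.
    """
    pos = channel_positions(ch_names)
    roi_idx = [list(ch_names).index(c) for c in roi]
    center = pos[roi_idx].mean(axis=0)
    d = np.linalg.norm(pos - center, axis=1)
    w = 0.25 + 0.75 * np.exp(-((d / 0.06) ** 2))
    return w / (w[roi_idx].mean() - w.mean())


def blink_topography(ch_names,
                     frontal=cfg.FRONTAL_PROXIES) -> np.ndarray:
    """Rank-1 ocular topography peaking at the periocular channels."""
    pos = channel_positions(ch_names)
    f_idx = [list(ch_names).index(c) for c in frontal
             if c in list(ch_names)]
    front = pos[f_idx].mean(axis=0)
    d = np.linalg.norm(pos - front, axis=1)
    topo = np.exp(-((d / 0.09) ** 2))
    return topo / topo.max()


# ---------------------------------------------------------------------------
# Signal components
# ---------------------------------------------------------------------------

def pink_noise(rng: np.random.Generator, n_samples: int, fs: int,
               exponent: float = 1.0, rms: float = 1.0,
               n_channels: int = 1) -> np.ndarray:
    """1/f^exponent noise by spectral shaping of white noise.

    The power spectrum follows f^-exponent above 0.1 Hz and is flat below
    (avoids a divergent DC); each channel is scaled to the requested RMS.
    """
    from scipy import fft as sfft
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    shape = np.ones_like(freqs, dtype=np.float32)
    nz = freqs > 0.1
    shape[nz] = (freqs[nz] / 0.1) ** (-exponent / 2.0)
    spec = (rng.standard_normal((n_channels, freqs.size), dtype=np.float32)
            + 1j * rng.standard_normal((n_channels, freqs.size),
                                       dtype=np.float32)) * shape
    spec[:, 0] = 0.0
    x = sfft.irfft(spec.astype(np.complex64), n=n_samples, axis=1)
    cur = np.sqrt(np.mean(x ** 2, axis=1, keepdims=True))
    cur[cur == 0] = 1.0
    return x / cur * rms


def response_waveform(freq_hz: float, n_samples: int, fs: int,
                      harmonic_profile=None) -> np.ndarray:
    """Unit-fundamental periodic response: cos(2 pi f t) + harmonics."""
    t = np.arange(n_samples) / fs
    x = np.cos(2 * np.pi * freq_hz * t)
    for h, rel in (harmonic_profile or {}).items():
        x = x + rel * np.cos(2 * np.pi * h * freq_hz * t)
    return x


def _draw_amplitudes(sim: SimConfig, group: str, condition: str,
                     u_participant: float, rng: np.random.Generator
                     ) -> dict[float, float]:
    amps = {}
    for f in cfg.TARGET_FREQS_HZ:
        mean = sim.amplitude_mean(group, condition, f)
        if mean == 0.0:
            amps[f] = 0.0
            continue
        a = mean + u_participant + rng.normal(0.0, sim.amp_sd_within)
        amps[f] = max(a, 0.0)
    return amps


def _bin_amplitudes(amps: dict[float, float],
                    harmonic_profile) -> dict[float, float]:
    """Total embedded amplitude at each target bin, with harmonic overlap."""
    out = dict(amps)
    for f0, a in amps.items():
        for h, rel in (harmonic_profile or {}).items():
            fh = h * f0
            if fh in out:
                out[fh] += rel * a   # zero-phase cosines add coherently
    return out


# ---------------------------------------------------------------------------
# Participant / cohort simulation
# ---------------------------------------------------------------------------

def simulate_participant(sim: SimConfig, group: str, participant_seed: int,
                         participant: str = "p00", conditions=None
                         ) -> tuple[dict[str, RawRecording], GroundTruth]:
    """Simulate all conditions of one participant.

    Returns the per-condition continuous records (with ``seq_onset`` event
    markers) and the embedded ground truth.
    """
    conditions = list(conditions if conditions is not None
                      else sim.conditions)
    ch_names = cfg.channel_names(sim.n_channels)
    w = spatial_weights(ch_names)
    topo = blink_topography(ch_names)
    fs = sim.fs_hz
    n_ep = int(sim.n_epochs)
    n_epoch = int(round(cfg.EPOCH_S * fs))
    gap = int(round(sim.inter_epoch_gap_s * fs))
    pre = int(round(sim.pre_record_s * fs))
    n_total = pre + n_ep * (n_epoch + gap)

    ss = np.random.SeedSequence(participant_seed)
    rng_p = np.random.default_rng(ss.spawn(1)[0])
    u_p = rng_p.normal(0.0, sim.amp_sd_between)
    blink_rate = float(sim.blink_rate_overrides.get(
        participant, sim.blink_rate))

    truth = GroundTruth(participant=participant, group=group)
    records: dict[str, RawRecording] = {}
    for cond in conditions:
        rng = np.random.default_rng(ss.spawn(1)[0])
        amps = _draw_amplitudes(sim, group, cond, u_p, rng)
        truth.amplitudes.update({(cond, f): a for f, a in amps.items()})
        truth.bin_amplitudes.update(
            {(cond, f): a for f, a in
             _bin_amplitudes(amps, sim.harmonic_profile).items()})

        if sim.noise_rms_uv > 0:
            data = pink_noise(rng, n_total, fs, sim.noise_exponent,
                              sim.noise_rms_uv, sim.n_channels)
        else:
            data = np.zeros((sim.n_channels, n_total))

        # embedded periodic response inside each epoch
        resp = np.zeros(n_epoch)
        for f, a in amps.items():
            if a > 0:
                resp += a * response_waveform(f, n_epoch, fs,
                                              sim.harmonic_profile)
        events = []
        blink_flags = []
        for e in range(n_ep):
            start = pre + e * (n_epoch + gap)
            events.append((start, "seq_onset"))
            data[:, start:start + n_epoch] += np.outer(w, resp)
            # ocular artifacts on a per-epoch Poisson schedule
            n_blinks = rng.poisson(blink_rate)
            flagged = False
            for _ in range(n_blinks):
                dur = int(rng.uniform(0.5, 2.0) * fs)
                amp = rng.uniform(150.0, 250.0)
                t0 = start + int(rng.uniform(0, max(n_epoch - dur, 1)))
                data[:, t0:t0 + dur] += np.outer(
                    amp * topo, np.hanning(dur))
                flagged = True
            blink_flags.append(flagged)
        truth.blink_epochs[cond] = blink_flags

        # bad channels: replaced wholesale by high-variance white noise
        bad = [ch_names[i] for i in range(sim.n_channels)
               if rng.uniform() < sim.bad_channel_prob]
        for ch in bad:
            i = ch_names.index(ch)
            data[i] = rng.standard_normal(n_total) * 7 * max(
                sim.noise_rms_uv, 1.0)
        truth.bad_channels[cond] = bad

        records[cond] = RawRecording(
            data=data.astype(np.float32), fs_hz=fs, ch_names=list(ch_names),
            events=events, participant=participant, group=group,
            condition=cond)
    return records, truth


def simulate_response_table(sim: SimConfig, n_per_group: int, seed: int,
                            conditions=None) -> pd.DataFrame:
    """Draw ROI response amplitudes directly at the table level.

    Same amplitude model as the forward simulation (group/condition means,
    participant offset shared across rows, per-cell noise) without the EEG
    in between — the fast path for studying the group-level models.  Unlike
    embedded oscillation amplitudes, these emulate *measured* ROI means of
    noise-subtracted spectra and may therefore go (slightly) negative.
    """
    conditions = list(conditions if conditions is not None
                      else sim.conditions)
    rng = np.random.default_rng(seed)
    rows = []
    for group in sim.groups:
        for p in range(n_per_group):
            pid = participant_id(group, p)
            u = rng.normal(0.0, sim.amp_sd_between)
            for cond in conditions:
                for f in cfg.TARGET_FREQS_HZ:
                    mean = sim.amplitude_mean(group, cond, f)
                    if mean == 0.0:
                        amp = 0.0
                    else:
                        amp = mean + u + rng.normal(0.0, sim.amp_sd_within)
                    rows.append(dict(participant=pid, group=group,
                                     condition=cond, freq_hz=f,
                                     amplitude_uv=amp))
    return pd.DataFrame(rows)


def participant_id(group: str, index: int) -> str:
    return f"{group[:2]}{index:02d}"


def _participant_seed(base_seed: int, g_idx: int, p_idx: int) -> int:
    ss = np.random.SeedSequence([int(base_seed), g_idx, p_idx])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def simulate_cohort(sim: SimConfig, out_dir) -> pd.DataFrame:
    """Write one container file per participant-condition plus ground truth.

    Returns the ground-truth amplitude table (one row per participant x
    condition x target frequency).  Sidecar CSVs record the per-epoch
    artifact flags and bad channels.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    amp_rows, epoch_rows, bad_rows = [], [], []
    for g_idx, group in enumerate(sim.groups):
        for p_idx in range(sim.n_participants):
            pid = participant_id(group, p_idx)
            seed = _participant_seed(sim.seed, g_idx, p_idx)
            records, truth = simulate_participant(sim, group, seed, pid)
            for cond, rec in records.items():
                save_recording(out_dir / f"{pid}_{cond}.rteeg.npz", rec)
                for f in cfg.TARGET_FREQS_HZ:
                    amp_rows.append(dict(
                        participant=pid, group=group, condition=cond,
                        freq_hz=f,
                        amp_fundamental_uv=truth.amplitudes[(cond, f)],
                        amp_bin_uv=truth.bin_amplitudes[(cond, f)]))
                for e, flag in enumerate(truth.blink_epochs[cond]):
                    epoch_rows.append(dict(participant=pid, group=group,
                                           condition=cond, epoch=e,
                                           blink=bool(flag)))
                for ch in truth.bad_channels[cond]:
                    bad_rows.append(dict(participant=pid, group=group,
                                         condition=cond, channel=ch))
    gt = pd.DataFrame(amp_rows)
    gt.to_csv(out_dir / "ground_truth.csv", index=False)
    pd.DataFrame(epoch_rows).to_csv(out_dir / "ground_truth_epochs.csv",
                                    index=False)
    pd.DataFrame(bad_rows, columns=["participant", "group", "condition",
                                    "channel"]
                 ).to_csv(out_dir / "ground_truth_bad_channels.csv",
                          index=False)
    return gt
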