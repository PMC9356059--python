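"""Synthesis of CVn syllable sequences and their noise-vocoded equivalents.

Every stimulus is a 30 s concatenation of 150 CVn (consonant-vowel-nasal)
monosyllables of exactly 200 ms, so the acoustics carry a 5 Hz syllable
rhythm and a 10 Hz sub-syllabic (mora) component from the vowel/nasal
alternation, while nothing marks the 2.5 Hz foot.  Syllables are rendered
with a source-filter harmonic synthesizer: voiced segments are harmonic
stacks at the voice fundamental shaped by vowel/nasal formant resonances;
stop onsets are a silent closure plus a burst; fricative onsets are shaped
noise.  What matters downstream is the amplitude envelope (one dominant
energy peak per syllable), not segmental naturalness.

The 1-channel noise vocoder replaces the fine structure with white noise
modulated by the broadband (0-120 Hz) envelope, yielding an unintelligible
but envelope-matched non-speech control.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal
from scipy.io import wavfile

from . import config as cfg

__all__ = [
    "SyllableSpec", "SyllableInventory", "SequencePlan", "VoiceParams",
    "AudioSignal", "build_inventory", "plan_sequence", "synthesize_syllable",
    "render_sequence", "vocode", "estimate_f0", "write_wav", "read_wav",
    "generate_stimulus_set",
]


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyllableSpec:
    """One CVn token: onset consonant, vowel, nasal coda, and timing."""

    onset: str
    vowel: str
    coda: str

    def __post_init__(self):
        if self.onset not in cfg.ONSET_CLASS:
            raise ValueError(f"unknown consonant {self.onset!r}")
        if self.vowel not in cfg.VOWELS:
            raise ValueError(f"unknown vowel {self.vowel!r}")
        if self.coda not in cfg.NASALS:
            raise ValueError(f"unknown nasal {self.coda!r}")

    @property
    def onset_class(self) -> str:
        return cfg.ONSET_CLASS[self.onset]

    @property
    def durations_ms(self) -> tuple[float, float, float]:
        """(onset, vowel, coda) durations; always sums to 200 ms."""
        onset_ms, vowel_ms = cfg.ONSET_TIMING[self.onset_class]
        return (onset_ms, vowel_ms, cfg.CODA_MS)

    @property
    def label(self) -> str:
        return self.onset + self.vowel + self.coda


@dataclass(frozen=True)
class SyllableInventory:
    syllables: tuple[SyllableSpec, ...]
    voice_id: str = "english"

    def __len__(self) -> int:
        return len(self.syllables)


@dataclass(frozen=True)
class SequencePlan:
    """Order of syllable indices realizing the 150-token constrained design."""

    tokens: tuple[int, ...]
    seed: int

    @property
    def repeat_counts(self) -> dict[int, int]:
        counts: dict[int, int] = {}
        for t in self.tokens:
            counts[t] = counts.get(t, 0) + 1
        return counts


@dataclass(frozen=True)
class VoiceParams:
    """Synthesis shaping parameters of one synthetic voice.

    ``formant_scale`` shifts all formant targets (a crude vocal-tract-length
    cue distinguishing the four voices), ``spectral_tilt`` the per-harmonic
    roll-off exponent.  ``amp_vowel``/``amp_nasal``/``amp_onset`` set the
    segment-level amplitude envelope; ``noise_seed`` makes fricative/burst
    noise deterministic.
    """

    voice_id: str = "english"
    f0_hz: float = cfg.F0_HZ
    deviant_f0_hz: float = cfg.DEVIANT_F0_HZ
    sample_rate_hz: int = cfg.AUDIO_FS
    spectral_tilt: float = 1.0
    formant_scale: float = 1.0
    amp_vowel: float = 1.0
    amp_nasal: float = 0.45
    amp_onset: float = 0.35
    noise_seed: int = 1234

    def __post_init__(self):
        if self.f0_hz <= 0:
            raise ValueError("f0_hz must be positive")
        if self.sample_rate_hz < 2 * _MAX_PARTIAL_HZ:
            raise ValueError("sample rate below Nyquist of highest partial")


_MAX_PARTIAL_HZ = 5000.0  #: highest synthesized harmonic frequency

#: per-voice shaping defaults
_VOICE_PRESETS = {
    "english": dict(spectral_tilt=1.0, formant_scale=1.00),
    "french": dict(spectral_tilt=0.85, formant_scale=1.05),
    "japanese": dict(spectral_tilt=1.1, formant_scale=0.97),
    "polish": dict(spectral_tilt=0.95, formant_scale=1.02),
}

#: first two formant targets (Hz) per vowel, and the nasal murmur resonance
_FORMANTS = {"i": (310.0, 2200.0), "a": (700.0, 1300.0), "O": (500.0, 900.0)}
_NASAL_FORMANTS = (250.0, 1000.0)
_FORMANT_BW_HZ = 110.0


def voice_params(voice_id: str, **overrides) -> VoiceParams:
    """Voice preset by id (english|french|japanese|polish)."""
    if voice_id not in _VOICE_PRESETS:
        raise ValueError(f"unknown voice {voice_id!r}")
    kw = dict(_VOICE_PRESETS[voice_id])
    kw.update(overrides)
    return VoiceParams(voice_id=voice_id, **kw)


@dataclass(frozen=True)
class AudioSignal:
    samples: np.ndarray
    sample_rate_hz: int

    def __post_init__(self):
        object.__setattr__(self, "samples",
                           np.asarray(self.samples, dtype=np.float64))
        if self.samples.size and np.max(np.abs(self.samples)) > 1.0 + 1e-9:
            raise ValueError("samples exceed [-1, 1]")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate_hz


# ---------------------------------------------------------------------------
# Inventory and sequence planning
# ---------------------------------------------------------------------------

def build_inventory(syllables=None, voice_id: str = "english"
                    ) -> SyllableInventory:
    """Validate and build the syllable inventory.

    ``syllables`` is an iterable of (onset, vowel, coda) label triples;
    defaults to the packaged 14-token list.  Unknown phoneme labels and
    duplicate tokens are configuration errors.
    """
    if syllables is None:
        syllables = cfg.DEFAULT_SYLLABLES
    specs = tuple(SyllableSpec(*tok) for tok in syllables)
    labels = [s.label for s in specs]
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate syllable token(s): {dupes}")
    return SyllableInventory(syllables=specs, voice_id=voice_id)


def plan_sequence(inventory: SyllableInventory, seed: int,
                  max_retries: int = 10000) -> SequencePlan:
    """Plan a 150-token sequence: 10 randomly chosen syllables repeated 11
    times, the remaining 4 repeated 10 times, shuffled so that no token is
    adjacent to itself.

    Sampling: seeded shuffle followed by random swap-repair of any adjacent
    repeats (each violating position is swapped with a uniformly drawn
    position where neither side creates a new violation), with bounded
    retries.
    """
    n = len(inventory)
    if n != cfg.N_REPEAT_11 + cfg.N_REPEAT_10:
        raise ValueError(f"sequence design requires a 14-token inventory, "
                         f"got {n}")
    rng = np.random.default_rng(seed)
    eleven = rng.choice(n, size=cfg.N_REPEAT_11, replace=False)
    bag = np.concatenate([np.repeat(eleven, 11),
                          np.repeat(np.setdiff1d(np.arange(n), eleven), 10)])
    assert bag.size == cfg.SEQUENCE_N_SYLLABLES
    perm = rng.permutation(bag)
    m = perm.size
    for _ in range(max_retries):
        viol = np.nonzero(perm[1:] == perm[:-1])[0] + 1
        if viol.size == 0:
            return SequencePlan(tokens=tuple(int(t) for t in perm), seed=seed)
        i = int(viol[0])
        # candidate positions j where swapping perm[i] <-> perm[j] removes
        # the violation at i without creating one around j
        order = rng.permutation(m)
        for j in order:
            j = int(j)
            if perm[j] == perm[i]:
                continue
            a, b = perm[i], perm[j]
            ok_i = ((i == 0 or perm[i - 1] != b)
                    and (i == m - 1 or perm[i + 1] != b or i + 1 == j))
            ok_j = ((j == 0 or perm[j - 1] != a or j - 1 == i)
                    and (j == m - 1 or perm[j + 1] != a or j + 1 == i))
            if ok_i and ok_j:
                perm[i], perm[j] = b, a
                break
        else:
            perm = rng.permutation(bag)  # dead end: reshuffle
    raise RuntimeError("could not satisfy no-adjacent-repeat constraint")


# ---------------------------------------------------------------------------
# Syllable synthesis
# ---------------------------------------------------------------------------

def _segment_noise(kind: str, n: int, voice: VoiceParams) -> np.ndarray:
    """Deterministic noise for one segment kind (seeded per voice+kind)."""
    h = hashlib.sha256(f"{voice.noise_seed}:{kind}".encode()).digest()
    rng = np.random.default_rng(int.from_bytes(h[:4], "little"))
    return rng.standard_normal(n)


def _resonance_gain(freqs: np.ndarray, formants, scale: float) -> np.ndarray:
    """Sum of second-order resonance magnitudes at the given frequencies."""
    g = np.zeros_like(freqs)
    for f0 in formants:
        fc = f0 * scale
        g += 1.0 / (1.0 + ((freqs - fc) / _FORMANT_BW_HZ) ** 2)
    return g


def _fricative_band(onset: str) -> tuple[float, float]:
    return {"s": (4000.0, 7800.0), "z": (4000.0, 7800.0),
            "S": (2000.0, 5000.0)}[onset]


def synthesize_syllable(spec: SyllableSpec, voice: VoiceParams,
                        f0_hz: float | None = None) -> AudioSignal:
    """Render one 200 ms CVn syllable (3200 samples at 16 kHz).

    Voiced portions are a harmonic stack at the voice fundamental whose
    per-harmonic amplitudes crossfade from the vowel's formant shaping to
    the nasal murmur's; the segment amplitude envelope rises into the vowel
    and decays through the nasal, so each syllable carries a single dominant
    energy peak.
    """
    fs = voice.sample_rate_hz
    f0 = voice.f0_hz if f0_hz is None else f0_hz
    onset_ms, vowel_ms, coda_ms = spec.durations_ms
    n_total = int(round(cfg.SYLLABLE_MS * fs / 1000.0))
    n_on = int(round(onset_ms * fs / 1000.0))
    n_vow = int(round(vowel_ms * fs / 1000.0))
    n_cod = n_total - n_on - n_vow
    t = np.arange(n_total) / fs

    # --- harmonic source, shaped per segment --------------------------------
    kmax = int(_MAX_PARTIAL_HZ // f0)
    k = np.arange(1, kmax + 1)
    tilt = (1.0 / k) ** voice.spectral_tilt
    hf = k * f0
    g_vow = tilt * _resonance_gain(hf, _FORMANTS[spec.vowel],
                                   voice.formant_scale)
    g_nas = tilt * _resonance_gain(hf, _NASAL_FORMANTS, voice.formant_scale)
    # crossfade weight: 1 during vowel, ramping to 0 over 10 ms at the coda
    w = np.ones(n_total)
    ramp = min(int(0.010 * fs), n_cod)
    w[n_on + n_vow:n_on + n_vow + ramp] = np.linspace(1, 0, ramp)
    w[n_on + n_vow + ramp:] = 0.0
    phases = 0.37 * k ** 2  # fixed, spreads harmonic phases (crest control)
    args = 2 * np.pi * np.outer(k * f0, t) + phases[:, None]
    stack = (w * (g_vow @ np.cos(args))
             + (1 - w) * (g_nas @ np.cos(args)))
    peak = np.max(np.abs(stack))
    if peak > 0:
        stack /= peak

    # --- segment amplitude envelope ----------------------------------------
    env = np.zeros(n_total)
    atk = int(0.010 * fs)
    # vowel: quick attack to amp_vowel, slight decay toward the coda
    vow = slice(n_on, n_on + n_vow)
    env[vow] = voice.amp_vowel * np.minimum(
        1.0, np.arange(n_vow) / max(atk, 1))
    env[vow] *= np.linspace(1.0, 0.9, n_vow)
    # nasal: step down and decay away
    cod = slice(n_on + n_vow, n_total)
    env[cod] = voice.amp_nasal * np.linspace(1.0, 0.45, n_cod)

    voiced = stack * env

    # --- onset (the envelope above is zero there) ---------------------------
    out = voiced.copy()
    if spec.onset_class == "stop":
        # closure silence then a short noise burst before the vowel
        n_burst = min(int(0.005 * fs), n_on)
        burst = _segment_noise(f"burst:{spec.onset}", n_burst, voice)
        burst *= voice.amp_onset * np.hanning(n_burst)
        out[:n_on] = 0.0
        out[n_on - n_burst:n_on] = burst
    elif spec.onset_class == "fricative_or_affricate":
        lo, hi = _fricative_band(spec.onset)
        noise = _segment_noise(f"fric:{spec.onset}", n_on + 200, voice)
        sos = signal.butter(4, [lo / (fs / 2), hi / (fs / 2)],
                            btype="band", output="sos")
        fric = signal.sosfilt(sos, noise)[200:]
        fric /= max(np.max(np.abs(fric)), 1e-12)
        ramp_n = min(int(0.015 * fs), n_on)
        shape = np.ones(n_on)
        shape[:ramp_n] = np.linspace(0, 1, ramp_n)
        out[:n_on] = voice.amp_onset * fric * shape
        if spec.onset == "z":  # voiced fricative keeps a weak harmonic bed
            out[:n_on] += 0.3 * voice.amp_onset * stack[:n_on] * shape
    else:  # glide: voiced onset rising in amplitude into the vowel
        out[:n_on] = stack[:n_on] * np.linspace(0.15, 0.9, n_on) \
            * voice.amp_vowel

    m = np.max(np.abs(out))
    if m > 1.0:
        out = out / m
    return AudioSignal(samples=out, sample_rate_hz=fs)


# ---------------------------------------------------------------------------
# Sequence rendering and vocoding
# ---------------------------------------------------------------------------

def render_sequence(plan: SequencePlan, inventory: SyllableInventory,
                    voice: VoiceParams, deviants: frozenset[int] | set[int]
                    = frozenset()) -> AudioSignal:
    """Concatenate the planned syllables into one 30 s sequence.

    ``deviants`` are token positions re-synthesized at the deviant
    fundamental (the pitch-change targets of the behavioural task).  The
    result is peak-normalized to 0.9.
    """
    deviants = frozenset(deviants)
    bad = [p for p in deviants if not 0 <= p < len(plan.tokens)]
    if bad:
        raise ValueError(f"deviant position(s) out of range: {sorted(bad)}")
    cache: dict[tuple[int, bool], np.ndarray] = {}
    chunks = []
    for pos, idx in enumerate(plan.tokens):
        dev = pos in deviants
        key = (idx, dev)
        if key not in cache:
            f0 = voice.deviant_f0_hz if dev else None
            cache[key] = synthesize_syllable(
                inventory.syllables[idx], voice, f0_hz=f0).samples
        chunks.append(cache[key])
    seq = np.concatenate(chunks)
    peak = np.max(np.abs(seq))
    if peak > 0:
        seq = seq * (0.9 / peak)
    return AudioSignal(samples=seq, sample_rate_hz=voice.sample_rate_hz)


def broadband_envelope(x: np.ndarray, fs: int,
                       cutoff_hz: float = 120.0) -> np.ndarray:
    """Broadband amplitude envelope: rectify then zero-phase low-pass.

    4th-order Butterworth at ``cutoff_hz`` applied forward-backward.
    """
    sos = signal.butter(4, cutoff_hz / (fs / 2), btype="low", output="sos")
    env = signal.sosfiltfilt(sos, np.abs(x))
    return np.maximum(env, 0.0)


def vocode(audio: AudioSignal, seed: int = 0) -> AudioSignal:
    """1-channel noise vocoding: white noise modulated by the 0-120 Hz
    broadband envelope of the input, RMS-matched to the input.

    If RMS matching would push the peak beyond full scale the output is
    rescaled to peak 0.999 (the envelope shape is unaffected).
    """
    x = audio.samples
    if x.size == 0:
        raise ValueError("empty signal")
    env = broadband_envelope(x, audio.sample_rate_hz)
    rng = np.random.default_rng(seed)
    out = rng.standard_normal(x.size) * env
    rms_in = np.sqrt(np.mean(x ** 2))
    rms_out = np.sqrt(np.mean(out ** 2))
    if rms_out > 0:
        out *= rms_in / rms_out
    peak = np.max(np.abs(out)) if out.size else 0.0
    if peak > 0.999:
        out *= 0.999 / peak
    return AudioSignal(samples=out, sample_rate_hz=audio.sample_rate_hz)


# ---------------------------------------------------------------------------
# F0 estimation (shared verification utility)
# ---------------------------------------------------------------------------

def estimate_f0(x: np.ndarray, fs: int, fmin: float = 80.0,
                fmax: float = 400.0) -> float:
    """Autocorrelation pitch estimate with parabolic peak interpolation."""
    x = np.asarray(x, dtype=np.float64)
    x = x - np.mean(x)
    ac = signal.correlate(x, x, mode="full")[x.size - 1:]
    lag_lo = int(np.floor(fs / fmax))
    lag_hi = int(np.ceil(fs / fmin))
    if lag_hi + 1 >= ac.size:
        raise ValueError("signal too short for F0 search range")
    seg = ac[lag_lo:lag_hi + 1]
    i = int(np.argmax(seg)) + lag_lo
    # parabolic interpolation around the peak lag
    if 0 < i < ac.size - 1:
        y0, y1, y2 = ac[i - 1], ac[i], ac[i + 1]
        denom = y0 - 2 * y1 + y2
        delta = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
        delta = float(np.clip(delta, -0.5, 0.5))
    else:
        delta = 0.0
    return fs / (i + delta)


# ---------------------------------------------------------------------------
# I/O and batch generation
# ---------------------------------------------------------------------------

def write_wav(path, audio: AudioSignal) -> None:
    """16-bit PCM mono WAV."""
    pcm = np.clip(audio.samples, -1.0, 1.0)
    wavfile.write(path, audio.sample_rate_hz,
                  (pcm * 32767).astype(np.int16))


def read_wav(path) -> AudioSignal:
    fs, data = wavfile.read(path)
    if data.ndim > 1:
        data = data[:, 0]
    if data.dtype == np.int16:
        data = data.astype(np.float64) / 32767.0
    else:
        data = data.astype(np.float64)
    return AudioSignal(samples=np.clip(data, -1, 1), sample_rate_hz=int(fs))


def generate_stimulus_set(out_dir, voices=cfg.VOICE_IDS, n_sequences: int = 1,
                          seed: int = 0, vocoded: bool = True,
                          n_deviants: int = 0) -> list[Path]:
    """Render sequences per voice (plus the vocoded non-speech control of the
    last voice) to WAV files with sidecar JSON plans.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    paths = []
    for vi, voice_id in enumerate(voices):
        inv = build_inventory(voice_id=voice_id)
        voice = voice_params(voice_id)
        for si in range(n_sequences):
            sub_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2 ** 31))
            plan = plan_sequence(inv, sub_seed)
            rng = np.random.default_rng(sub_seed + 1)
            deviants = (set(int(p) for p in rng.choice(
                cfg.SEQUENCE_N_SYLLABLES, size=n_deviants, replace=False))
                if n_deviants else set())
            audio = render_sequence(plan, inv, voice, deviants)
            stem = f"{voice_id}_seq{si:02d}"
            write_wav(out_dir / f"{stem}.wav", audio)
            meta = {"voice": voice_id, "seed": sub_seed,
                    "tokens": list(plan.tokens),
                    "deviants": sorted(deviants)}
            (out_dir / f"{stem}.json").write_text(json.dumps(meta))
            paths.append(out_dir / f"{stem}.wav")
            if vocoded and voice_id == voices[-1]:
                voc = vocode(audio, seed=sub_seed + 2)
                write_wav(out_dir / f"vocoded_seq{si:02d}.wav", voc)
                paths.append(out_dir / f"vocoded_seq{si:02d}.wav")
    return paths
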