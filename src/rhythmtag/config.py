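"""Design constants and configuration objects shared across the pipeline.

The experimental design is fixed: 200 ms
consonant-vowel-nasal (CVn) syllables concatenated into 30 s sequences of
150 syllables, giving nominal rhythm rates of 5 Hz (syllable), 10 Hz
(sub-syllabic mora: CV vs. coda nasal alternation), and 2.5 Hz (the
supra-syllabic foot, deliberately carried by no acoustic cue).  EEG is
recorded from a 128-channel geodesic net (plus Cz reference) at 1000 Hz.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any, Mapping

import yaml

# ---------------------------------------------------------------------------
# Stimulus design constants
# ---------------------------------------------------------------------------

SYLLABLE_MS = 200.0            #: duration of every CVn syllable
CODA_MS = 100.0                #: the nasal coda is always 100 ms
SEQUENCE_N_SYLLABLES = 150     #: syllables per sequence (30 s at 5 Hz)
SEQUENCE_S = 30.0              #: sequence duration, seconds
AUDIO_FS = 16000               #: stimulus sample rate, Hz
F0_HZ = 180.0                  #: default voice fundamental, Hz
DEVIANT_F0_HZ = 280.0          #: pitch-deviant fundamental, Hz

FOOT_HZ = 2.5
SYLLABLE_HZ = 5.0
MORA_HZ = 10.0
TARGET_FREQS_HZ = (FOOT_HZ, SYLLABLE_HZ, MORA_HZ)

CONSONANTS = ("p", "t", "k", "b", "d", "g", "s", "z", "S", "j")
VOWELS = ("i", "a", "O")
NASALS = ("m", "n", "N")

#: onset class per consonant; timing depends only on this class
ONSET_CLASS = {
    "p": "stop", "t": "stop", "k": "stop",
    "b": "stop", "d": "stop", "g": "stop",
    "s": "fricative_or_affricate", "z": "fricative_or_affricate",
    "S": "fricative_or_affricate",
    "j": "glide",
}

#: (onset_ms, vowel_ms) per onset class; coda is always CODA_MS.
#: Stops: 20 ms consonant + 80 ms vowel.  Fricatives/affricates: 50 + 50.
#: Glides are voiced continuants and get the 50 + 50 split.
ONSET_TIMING = {
    "stop": (20.0, 80.0),
    "fricative_or_affricate": (50.0, 50.0),
    "glide": (50.0, 50.0),
}

#: The 14 phonotactically legal CVn tokens shipped as the default inventory.
#: The token identities are a fixture of this package (the design fixes only
#: the phoneme sets and the count); all 10 consonants, 3 vowels and 3 nasals
#: are used.  "S" is the postalveolar fricative, "O" the open-mid back vowel,
#: "N" the velar nasal.
DEFAULT_SYLLABLES = (
    ("p", "a", "n"),
    ("t", "a", "m"),
    ("k", "i", "n"),
    ("b", "i", "m"),
    ("d", "O", "n"),
    ("g", "a", "N"),
    ("s", "a", "n"),
    ("z", "O", "m"),
    ("S", "i", "n"),
    ("j", "a", "m"),
    ("p", "i", "N"),
    ("t", "O", "n"),
    ("k", "a", "m"),
    ("s", "i", "m"),
)

VOICE_IDS = ("english", "french", "japanese", "polish")
SPEECH_CONDITIONS = ("english", "french", "japanese")  #: pooled in Model 1
CONDITIONS = ("english", "french", "japanese", "polish", "vocoded")
GROUPS = ("english", "french", "japanese")

#: Sequence repeat design: 10 of the 14 syllables occur 11 times, the
#: remaining 4 occur 10 times -> 10*11 + 4*10 = 150.
N_REPEAT_11 = 10
N_REPEAT_10 = 4

# ---------------------------------------------------------------------------
# EEG design constants
# ---------------------------------------------------------------------------

EEG_FS = 1000                  #: EEG sample rate, Hz (never downsampled)
N_EEG_CHANNELS = 128           #: data channels of the HCGSN (ref at Cz)
N_EPOCHS = 8                   #: sequences (epochs) per condition
EPOCH_S = 30.0                 #: epoch length, seconds
BAND_LOW_HZ = 0.3
BAND_HIGH_HZ = 30.0
REJECT_UV = 100.0              #: epoch rejection threshold, micro-volt
MIN_GOOD_EPOCHS = 6            #: fewer accepted epochs excludes the dataset
MAX_BAD_CHANNELS = 12          #: more flags the participant

SPECTRUM_DF_HZ = 0.025         #: spectral resolution after zero-padding
BASELINE_OFFSETS = (2, 12)     #: neighbour bins subtracted (2nd..12th)
Z_OFFSETS = (2, 11)            #: z-score neighbourhood: 10 bins per side,
                               #: skipping the bin adjacent to the target
Z_THRESHOLD = 3.1              #: one-tailed p < 0.001 significance cut

#: 10 fronto-central electrodes of the 128-channel net used as the response
#: ROI.  The identities are a documented, overridable default (the net's
#: fronto-central cluster around FCz/Cz).
DEFAULT_ROI = ("E4", "E5", "E6", "E7", "E12", "E13",
               "E106", "E112", "E30", "E105")

#: Frontal channels used as ocular-artifact proxies (periocular ring of the
#: net).
FRONTAL_PROXIES = ("E1", "E8", "E14", "E17", "E21", "E25", "E32",
                   "E125", "E126", "E127", "E128")


def channel_names(n_channels: int = N_EEG_CHANNELS) -> list[str]:
    """Data-channel labels of the geodesic net ("E1".."E128")."""
    return [f"E{i + 1}" for i in range(n_channels)]


# ---------------------------------------------------------------------------
# Simulation configuration
# ---------------------------------------------------------------------------

#: Mean embedded response amplitude (micro-volt) at the ROI for each
#: (group, frequency).  The defaults encode the qualitative group ordering
#: the design is meant to resolve -- strongest syllable-rate (5 Hz) tracking
#: in the French group, weaker 10 Hz responses, no 2.5 Hz response -- as
#: configurable means, not hard-coded truths.
DEFAULT_AMP_5HZ = {"english": 0.55, "french": 0.80, "japanese": 0.50}
DEFAULT_AMP_10HZ = {"english": 0.28, "french": 0.36, "japanese": 0.22}
#: speech > non-speech at 10 Hz only: vocoded 10 Hz means are scaled by this
DEFAULT_VOCODED_10HZ_FACTOR = 0.65


@dataclass
class SimConfig:
    """Ground-truth configuration of the synthetic-EEG forward model.

    Amplitudes are micro-volt at the ROI; ``amp_sd_between`` is the
    between-participant SD of a participant-level offset shared across
    conditions (what the random intercept of the group models absorbs) and
    ``amp_sd_within`` the per-condition draw SD.
    """

    n_participants: int = 24
    groups: tuple[str, ...] = GROUPS
    conditions: tuple[str, ...] = CONDITIONS
    n_epochs: int = N_EPOCHS
    fs_hz: int = EEG_FS
    n_channels: int = N_EEG_CHANNELS
    amp_5hz: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AMP_5HZ))
    amp_10hz: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AMP_10HZ))
    amp_2p5hz: Mapping[str, float] = field(
        default_factory=lambda: {g: 0.0 for g in GROUPS})
    vocoded_10hz_factor: float = DEFAULT_VOCODED_10HZ_FACTOR
    amp_sd_between: float = 0.12
    amp_sd_within: float = 0.06
    harmonic_profile: Mapping[int, float] = field(
        default_factory=lambda: {2: 0.3})
    noise_exponent: float = 1.0
    noise_rms_uv: float = 15.0
    blink_rate: float = 0.8            #: expected blinks per 30 s epoch
    blink_rate_overrides: Mapping[str, float] = field(default_factory=dict)
    bad_channel_prob: float = 0.02
    inter_epoch_gap_s: float = 0.5
    pre_record_s: float = 1.0
    seed: int = 0

    def amplitude_mean(self, group: str, condition: str, freq: float) -> float:
        """Mean embedded amplitude for a (group, condition, frequency) cell."""
        if freq == SYLLABLE_HZ:
            return float(self.amp_5hz[group])
        if freq == MORA_HZ:
            base = float(self.amp_10hz[group])
            if condition == "vocoded":
                base *= self.vocoded_10hz_factor
            return base
        if freq == FOOT_HZ:
            return float(self.amp_2p5hz[group])
        raise ValueError(f"no amplitude configured at {freq} Hz")


@dataclass
class PreprocessConfig:
    band_low_hz: float = BAND_LOW_HZ
    band_high_hz: float = BAND_HIGH_HZ
    bad_channel_mad_k: float = 5.0
    max_bad_channels: int = MAX_BAD_CHANNELS
    ocular_strategy: str = "regression"      #: "none" or "regression"
    blink_threshold_uv: float = 60.0
    reject_uv: float = REJECT_UV
    min_good_epochs: int = MIN_GOOD_EPOCHS
    reject_before_interpolation: bool = False


@dataclass
class FreqtagConfig:
    resolution_hz: float = SPECTRUM_DF_HZ
    baseline_offsets: tuple[int, int] = BASELINE_OFFSETS
    z_span_mode: str = "adjacent_excluded"   #: or "quarter_hz"
    z_threshold: float = Z_THRESHOLD
    roi: tuple[str, ...] = DEFAULT_ROI


@dataclass
class StatsConfig:
    alpha: float = 0.05
    standardize: str = "per_model"           #: or "global"


@dataclass
class StimgenConfig:
    voices: tuple[str, ...] = VOICE_IDS
    n_sequences: int = 1
    vocode: bool = True
    n_deviants: int = 0
    seed: int = 0


@dataclass
class PipelineConfig:
    """Resolved configuration for a full pipeline run; YAML round-trips.

    The default cohort is reduced to 6 participants per group so the full
    orchestrated run stays desk-sized; the study-scale cohort (24/group,
    the simulator's own default) is one config field away.
    """

    stimgen: StimgenConfig = field(default_factory=StimgenConfig)
    sim: SimConfig = field(
        default_factory=lambda: SimConfig(n_participants=6))
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    freqtag: FreqtagConfig = field(default_factory=FreqtagConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    seed: int = 0

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        def conv(x: Any) -> Any:
            if dataclasses.is_dataclass(x) and not isinstance(x, type):
                return {f.name: conv(getattr(x, f.name))
                        for f in dataclasses.fields(x)}
            if isinstance(x, Mapping):
                return {k: conv(v) for k, v in x.items()}
            if isinstance(x, tuple):
                return [conv(v) for v in x]
            return x
        return conv(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "PipelineConfig":
        def build(klass, sub):
            kwargs = {}
            for f in dataclasses.fields(klass):
                if f.name not in sub:
                    continue
                v = sub[f.name]
                if isinstance(v, list):
                    v = tuple(tuple(x) if isinstance(x, list) else x
                              for x in v)
                if f.name == "harmonic_profile" and isinstance(v, Mapping):
                    v = {int(k): float(h) for k, h in v.items()}
                kwargs[f.name] = v
            return klass(**kwargs)

        return cls(
            stimgen=build(StimgenConfig, d.get("stimgen", {})),
            sim=build(SimConfig, d.get("sim", {})),
            preprocess=build(PreprocessConfig, d.get("preprocess", {})),
            freqtag=build(FreqtagConfig, d.get("freqtag", {})),
            stats=build(StatsConfig, d.get("stats", {})),
            seed=int(d.get("seed", 0)),
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})
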