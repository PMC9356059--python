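"""Acoustic model of response: Hilbert envelope and its amplitude spectrum.

The rhythmic structure a listener can track is carried by the stimulus
amplitude envelope.  The envelope of each 30 s sequence is the magnitude of
its analytic signal; its single-sided DFT amplitude spectrum (DC removed, no
window -- the sequence holds an integer number of 200 ms syllable cycles)
predicts where tracking responses can appear: a dominant 5 Hz syllable-rate
component, a weaker 10 Hz component, and nothing at the 2.5 Hz foot rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .stimgen import AudioSignal

__all__ = ["EnvelopeSpectrum", "hilbert_envelope", "envelope_spectrum",
           "amplitude_at"]


@dataclass(frozen=True)
class EnvelopeSpectrum:
    freqs_hz: np.ndarray
    amplitude: np.ndarray
    source_id: str = ""

    def __post_init__(self):
        f = np.asarray(self.freqs_hz, float)
        a = np.asarray(self.amplitude, float)
        if f[0] != 0 or np.any(np.diff(f) <= 0):
            raise ValueError("frequency axis must increase from 0")
        if np.any(a < 0):
            raise ValueError("amplitudes must be non-negative")


def hilbert_envelope(audio: AudioSignal | np.ndarray) -> np.ndarray:
    """Instantaneous amplitude |analytic signal|, same length as the input."""
    x = audio.samples if isinstance(audio, AudioSignal) else np.asarray(audio)
    return np.abs(hilbert(x))


def envelope_spectrum(envelope: np.ndarray, fs: int,
                      source_id: str = "") -> EnvelopeSpectrum:
    """Single-sided amplitude spectrum of an envelope, mean removed.

    Amplitudes are calibrated so a unit-amplitude sinusoid at a bin center
    reads 1.0.
    """
    x = np.asarray(envelope, dtype=np.float64)
    x = x - np.mean(x)
    n = x.size
    amp = np.abs(np.fft.rfft(x)) * 2.0 / n
    amp[0] /= 2.0
    if n % 2 == 0:
        amp[-1] /= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    return EnvelopeSpectrum(freqs_hz=freqs, amplitude=amp,
                            source_id=source_id)


def amplitude_at(spec: EnvelopeSpectrum, f_hz: float,
                 tol_hz: float = 1e-6) -> float:
    """Amplitude at the bin nearest ``f_hz`` (must lie on the grid)."""
    i = int(np.argmin(np.abs(spec.freqs_hz - f_hz)))
    if abs(spec.freqs_hz[i] - f_hz) > tol_hz:
        raise ValueError(f"{f_hz} Hz is not on the spectral grid")
    return float(spec.amplitude[i])
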