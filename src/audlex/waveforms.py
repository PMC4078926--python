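"""Stimulus waveform synthesis for the three auditory continua.

The battery's stimuli are: a 1 kHz carrier with 2 Hz sinusoidal frequency
modulation of varying depth (1000 ms, 50 ms cosine-gated onset/offset)
against a pure-tone reference; and speech-weighted noise bursts (800 ms,
linear amplitude ramps) for the rise-time and intensity tasks, where the
rise-time target varies its onset ramp against a 15 ms reference and the
intensity target its level against a 70 dB SPL reference.

Absolute SPL is not realizable digitally, so the 70 dB reference maps to a
configurable digital level; only relative level matters for the continua.
The speech-weighting filter is a parametric long-term-average-speech-
spectrum style tilt (flat to 500 Hz, -10 dB/decade in power above); the
original hardware's exact spectrum is unspecified, so this filter is a
documented synthetic stand-in.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.io import wavfile

from .errors import ConfigurationError

__all__ = [
    "WaveformSpec",
    "synth_fm_tone",
    "synth_speech_weighted_noise",
    "apply_envelope",
    "set_level",
    "write_wav",
    "read_wav",
    "render_continuum_level",
]

DEFAULT_SAMPLE_RATE = 44_100


@dataclass(frozen=True)
class WaveformSpec:
    sample_rate: int = DEFAULT_SAMPLE_RATE
    duration_ms: float = 1000.0
    onset_gate_ms: float = 50.0   # cosine gate at onset and offset (FM task)
    rise_ms: float = 0.0          # linear rise (noise stimuli)
    fall_ms: float = 0.0          # linear fall
    carrier_hz: float = 1000.0
    fm_rate_hz: float = 2.0
    fm_depth_hz: float = 0.0
    level_offset_db: float = 0.0  # relative to the task reference

    def __post_init__(self):
        if self.duration_ms <= 0 or self.sample_rate <= 0:
            raise ConfigurationError("duration and sample rate must be positive")
        if self.rise_ms + self.fall_ms > self.duration_ms:
            raise ConfigurationError("rise + fall must not exceed duration")
        if self.fm_depth_hz < 0:
            raise ConfigurationError("FM depth must be non-negative")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_ms * self.sample_rate / 1000.0))


def synth_fm_tone(spec: WaveformSpec) -> np.ndarray:
    """Sinusoidally frequency-modulated tone.

    Instantaneous frequency is carrier + depth*sin(2*pi*fm_rate*t); the
    phase is the closed-form integral, so depth 0 reduces exactly to the
    pure-tone reference.  Cosine on/off gates of ``onset_gate_ms`` are
    applied.
    """
    n = spec.n_samples
    t = np.arange(n) / spec.sample_rate
    if spec.fm_depth_hz == 0.0:
        phase = 2.0 * np.pi * spec.carrier_hz * t
    else:
        # integral of f(t) = fc + d*sin(2*pi*fm*t)
        phase = 2.0 * np.pi * (
            spec.carrier_hz * t
            + spec.fm_depth_hz / (2.0 * np.pi * spec.fm_rate_hz)
            * (1.0 - np.cos(2.0 * np.pi * spec.fm_rate_hz * t))
        )
    x = np.sin(phase)
    return _cosine_gate(x, spec.onset_gate_ms, spec.sample_rate)


def _cosine_gate(x: np.ndarray, gate_ms: float, fs: int) -> np.ndarray:
    n_gate = int(round(gate_ms * fs / 1000.0))
    if n_gate <= 0:
        return x
    out = x.copy()
    ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_gate) / n_gate))
    out[:n_gate] *= ramp
    out[-n_gate:] *= ramp[::-1]
    return out


def synth_speech_weighted_noise(
    duration_ms: float,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
    rng: np.random.Generator | None = None,
    corner_hz: float = 500.0,
    slope_db_per_decade: float = -10.0,
    shaped: bool = True,
) -> np.ndarray:
    """Gaussian noise with a speech-like long-term spectrum.

    The spectrum is flat up to ``corner_hz`` and tilts by
    ``slope_db_per_decade`` (in power) above it; ``shaped=False`` bypasses
    the filter and returns white noise.  Output is scaled to unit RMS.
    """
    if duration_ms <= 0:
        raise ConfigurationError("duration must be positive")
    rng = rng or np.random.default_rng()
    n = int(round(duration_ms * sample_rate / 1000.0))
    white = rng.standard_normal(n)
    if not shaped:
        return white / _rms(white)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / sample_rate)
    gain = np.ones_like(f)
    above = f > corner_hz
    # power slope s dB/decade -> amplitude gain (f/fc)^(s/20)
    gain[above] = (f[above] / corner_hz) ** (slope_db_per_decade / 20.0)
    shaped_sig = np.fft.irfft(spec * gain, n=n)
    return shaped_sig / _rms(shaped_sig)


def _rms(x: np.ndarray) -> float:
    return float(np.sqrt(np.mean(x**2)))


def filter_band_power_ratio_db(
    corner_hz: float = 500.0,
    slope_db_per_decade: float = -10.0,
    low: tuple[float, float] = (100.0, 1000.0),
    high: tuple[float, float] = (2000.0, 8000.0),
) -> float:
    """Designed power ratio (dB) between two bands of the speech filter,
    for validating synthesized noise against the filter's own transfer
    function."""

    def band_power(lo, hi):
        f = np.linspace(lo, hi, 20_000)
        g2 = np.ones_like(f)
        above = f > corner_hz
        g2[above] = (f[above] / corner_hz) ** (slope_db_per_decade / 10.0)
        return np.trapezoid(g2, f) / (hi - lo)

    return 10.0 * np.log10(band_power(*low) / band_power(*high))


def apply_envelope(waveform: np.ndarray, rise_ms: float, fall_ms: float,
                   sample_rate: int = DEFAULT_SAMPLE_RATE) -> np.ndarray:
    """Trapezoidal amplitude envelope: linear 0->1 over ``rise_ms``, hold,
    linear 1->0 over ``fall_ms``."""
    n = len(waveform)
    dur_ms = 1000.0 * n / sample_rate
    if rise_ms + fall_ms > dur_ms + 1e-9:
        raise ConfigurationError("rise + fall exceed waveform duration")
    n_rise = int(round(rise_ms * sample_rate / 1000.0))
    n_fall = int(round(fall_ms * sample_rate / 1000.0))
    env = np.ones(n)
    if n_rise > 0:
        env[:n_rise] = np.arange(n_rise) / n_rise
    if n_fall > 0:
        env[n - n_fall:] = np.arange(n_fall, 0, -1) / n_fall
    return waveform * env


def set_level(waveform: np.ndarray, offset_db: float) -> np.ndarray:
    """Scale RMS by 10^(offset_db/20)."""
    if not np.all(np.isfinite(waveform)):
        raise ConfigurationError("waveform must be finite")
    return waveform * 10.0 ** (offset_db / 20.0)


def write_wav(path, waveform: np.ndarray, sample_rate: int = DEFAULT_SAMPLE_RATE,
              peak: float = 0.5) -> None:
    """Write PCM 16-bit WAV, normalizing the absolute peak to ``peak``."""
    m = float(np.max(np.abs(waveform)))
    scaled = waveform if m == 0 else waveform * (peak / m)
    wavfile.write(path, sample_rate, np.round(scaled * 32767.0).astype(np.int16))


def read_wav(path) -> tuple[int, np.ndarray]:
    fs, data = wavfile.read(path)
    return fs, data.astype(np.float64) / 32767.0


def render_continuum_level(task: str, level: float, rng: np.random.Generator | None = None,
                           sample_rate: int = DEFAULT_SAMPLE_RATE) -> np.ndarray:
    """Synthesize the target stimulus for one continuum level of a task.

    FM: ``level`` is the modulation depth in Hz (1000 ms tone).
    RT: ``level`` is the rise-time difference in ms from the 15 ms
    reference (800 ms noise, 75 ms fall).
    ID: ``level`` is the increment in dB above the reference level
    (800 ms noise, 75 ms rise and fall).
    """
    task = task.upper()
    if task == "FM":
        spec = WaveformSpec(sample_rate=sample_rate, duration_ms=1000.0,
                            onset_gate_ms=50.0, fm_depth_hz=level)
        return synth_fm_tone(spec)
    if task == "RT":
        noise = synth_speech_weighted_noise(800.0, sample_rate, rng)
        return apply_envelope(noise, rise_ms=15.0 + level, fall_ms=75.0,
                              sample_rate=sample_rate)
    if task == "ID":
        noise = synth_speech_weighted_noise(800.0, sample_rate, rng)
        shaped = apply_envelope(noise, rise_ms=75.0, fall_ms=75.0,
                                sample_rate=sample_rate)
        return set_level(shaped, level)
    raise ConfigurationError(f"unknown task {task!r}")
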