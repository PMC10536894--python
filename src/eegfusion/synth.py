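"""Synthetic annotated EEG with class-dependent rhythm attenuation.

The generator emulates the physical signature that motor-imagery decoders
exploit: event-related desynchronization (ERD), i.e. attenuation of a
narrow-band rhythm (mu, 8-12 Hz by default) over the hemisphere
contralateral to the imagined limb. Channels are split into contiguous
blocks, one per class; during a trial of class k the rhythm amplitude on
block k is scaled by ``1 - erd_depth`` while the other blocks carry the
full-amplitude rhythm. The background is 1/f-shaped noise plus white
Gaussian noise, giving an EEG-like spectrum without modeling physiology.

Everything is driven by one seeded generator, so a config reproduces its
recording bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocessing import AnnotatedRecording


@dataclass(frozen=True)
class SynthConfig:
    """Geometry and signal parameters of one synthetic recording.

    Defaults mirror a single PhysioNet-style motor-imagery run: 64 channels
    at 160 Hz, 45 four-second trials, two classes, mu-band (8-12 Hz) rhythm.
    erd_depth is the fractional amplitude attenuation of the rhythm on the
    class-linked channel block (0 = no class signal, 1 = rhythm fully
    suppressed). noise_std is the white-noise standard deviation in µV on
    top of a unit-variance 1/f component.
    """

    n_channels: int = 64
    sampling_rate_hz: float = 160.0
    n_trials: int = 45
    trial_duration_s: float = 4.0
    n_classes: int = 2
    erd_band_hz: tuple[float, float] = (8.0, 12.0)
    erd_depth: float = 0.5
    noise_std: float = 1.0
    inter_trial_gap_s: float = 4.0
    seed: int = 0
    rhythm_amplitude_uv: float = 2.0

    def __post_init__(self) -> None:
        if self.n_channels < 2:
            raise ValueError(
                "n_channels must be >= 2 (class lateralization needs at "
                "least two channel blocks)"
            )
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.n_trials < 1:
            raise ValueError("n_trials must be positive")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        lo, hi = self.erd_band_hz
        if not 0 < lo < hi < self.sampling_rate_hz / 2:
            raise ValueError(
                "erd_band_hz must satisfy 0 < low < high < Nyquist"
            )
        if not 0 <= self.erd_depth <= 1:
            raise ValueError("erd_depth must be in [0, 1]")
        if self.noise_std < 0:
            raise ValueError("noise_std must be nonnegative")
        if self.inter_trial_gap_s < 0:
            raise ValueError("inter_trial_gap_s must be nonnegative")
        n = self.trial_duration_s * self.sampling_rate_hz
        if abs(n - round(n)) > 1e-9 or round(n) <= 0:
            raise ValueError(
                "trial_duration_s * sampling_rate_hz must be a positive "
                "integer number of samples"
            )

    @property
    def trial_len(self) -> int:
        return int(round(self.trial_duration_s * self.sampling_rate_hz))

    @property
    def gap_len(self) -> int:
        return int(round(self.inter_trial_gap_s * self.sampling_rate_hz))


def _pink_noise(rng: np.random.Generator, n_channels: int, n_samples: int) -> np.ndarray:
    """1/f-amplitude-shaped Gaussian noise, unit variance per channel."""
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples)
    scale = np.zeros_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    pink = np.fft.irfft(spec * scale[None, :], n=n_samples, axis=1)
    sd = pink.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return pink / sd


def _class_channel_blocks(n_channels: int, n_classes: int) -> list[np.ndarray]:
    """Contiguous channel block linked to each class (round-robin split)."""
    bounds = np.linspace(0, n_channels, n_classes + 1).round().astype(int)
    return [np.arange(bounds[k], bounds[k + 1]) for k in range(n_classes)]


def generate_recording(config: SynthConfig) -> AnnotatedRecording:
    """Simulate one continuous recording with annotated trials.

    Trial labels are drawn uniformly over ``T1 .. T<n_classes>``. Within
    each trial every channel carries a sinusoid at a random frequency in
    erd_band_hz with a random phase (per trial, shared across channels);
    the class-linked channel block has its amplitude attenuated by
    erd_depth. Annotation onsets/durations delimit the trials exactly.
    """
    rng = np.random.default_rng(config.seed)
    fs = config.sampling_rate_hz
    t_len, g_len = config.trial_len, config.gap_len
    period = t_len + g_len
    n_samples = config.n_trials * period

    signal = _pink_noise(rng, config.n_channels, n_samples)
    if config.noise_std > 0:
        signal += config.noise_std * rng.standard_normal(signal.shape)

    blocks = _class_channel_blocks(config.n_channels, config.n_classes)
    labels = rng.integers(0, config.n_classes, size=config.n_trials)
    t_trial = np.arange(t_len) / fs
    lo, hi = config.erd_band_hz
    events: list[tuple[int, int, str]] = []
    for i, k in enumerate(labels):
        onset = i * period
        freq = rng.uniform(lo, hi)
        phase = rng.uniform(0, 2 * np.pi)
        rhythm = np.sin(2 * np.pi * freq * t_trial + phase)
        amp = np.full(config.n_channels, config.rhythm_amplitude_uv)
        amp[blocks[k]] *= 1.0 - config.erd_depth
        signal[:, onset : onset + t_len] += amp[:, None] * rhythm[None, :]
        events.append((onset, t_len, f"T{k + 1}"))

    names = [f"SYN{c:03d}" for c in range(config.n_channels)]
    return AnnotatedRecording(signal, fs, names, events)
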