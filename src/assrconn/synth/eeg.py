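"""Synthetic multi-trial ASSR EEG.

Emulates the stimulation protocol the analysis assumes: 75 trials of 375 ms
click-train stimulation sampled at 1000 Hz, each trial carrying a 40 Hz
steady-state component with a phase that is fixed across trials (that phase
constancy is what "evoked" averaging and DSS exploit).  The entrained
component is a pure sinusoid — the analysis only reads the 40 Hz bin, so
harmonic structure of real click responses is irrelevant.  Background
activity is 1/f-shaped noise generated per source and spatially mixed by a
random well-conditioned matrix to give realistic channel covariance; it is
independent across trials.

The noise stream is drawn before any signal parameter is used, so two
configs that differ only in ``snr`` produce the identical noise realization
for the same seed — ground-truth decompositions (signal-only vs noise-only)
are exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..assr import EEGEpochs
from ..errors import ConfigurationError

__all__ = ["EEGSimConfig", "generate_eeg_epochs", "default_topography"]


def default_topography(n_channels: int) -> np.ndarray:
    """Smooth fronto-central weight profile, unit norm.

    A deterministic bell over the channel index emulating the scalp
    projection of a bilateral auditory source; channel ordering is
    arbitrary in the synthetic montage.
    """
    i = np.arange(n_channels)
    w = np.exp(-0.5 * ((i - 0.35 * n_channels) / (0.25 * n_channels)) ** 2)
    return w / np.linalg.norm(w)


@dataclass
class EEGSimConfig:
    """Parameters of the synthetic ASSR recording.

    ``snr`` is the amplitude of the 40 Hz component at the best channel
    (the channel with the largest topography weight) divided by the noise
    RMS at that channel; noise is normalized to unit RMS per channel.
    """

    n_trials: int = 75
    trial_ms: float = 375.0
    fs: float = 1000.0
    n_channels: int = 64
    f0: float = 40.0
    snr: float = 2.0
    topography: np.ndarray | None = None
    noise_exponent: float = 1.0
    seed: int | None = None
    mixing_seed: int | None = None  # fix to share one head geometry across subjects

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ConfigurationError("n_trials must be >= 1")
        if self.n_channels < 1:
            raise ConfigurationError("n_channels must be >= 1")
        if not self.fs > 2 * self.f0:
            raise ConfigurationError("fs must exceed twice the target frequency")
        if self.snr < 0:
            raise ConfigurationError("snr must be non-negative")
        if self.trial_ms <= 0:
            raise ConfigurationError("trial_ms must be positive")
        if self.topography is None:
            self.topography = default_topography(self.n_channels)
        else:
            self.topography = np.asarray(self.topography, dtype=float)
            if self.topography.shape != (self.n_channels,):
                raise ConfigurationError("topography must have one weight per channel")
            norm = np.linalg.norm(self.topography)
            if not np.isclose(norm, 1.0, atol=1e-6):
                raise ConfigurationError("topography must have unit norm")

    @property
    def n_samples(self) -> int:
        return int(round(self.trial_ms * self.fs / 1000.0))


def _one_over_f_noise(
    rng: np.random.Generator, shape: tuple[int, ...], exponent: float, fs: float
) -> np.ndarray:
    """White noise spectrally shaped to power ∝ 1/f**exponent along axis -1."""
    white = rng.standard_normal(shape)
    if exponent == 0:
        return white
    n = shape[-1]
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    gain = np.zeros_like(freqs)
    gain[1:] = freqs[1:] ** (-exponent / 2.0)
    spec *= gain
    return np.fft.irfft(spec, n, axis=-1)


def generate_eeg_epochs(config: EEGSimConfig) -> EEGEpochs:
    """Generate epochs of shape (n_trials, n_channels, n_samples).

    The returned container carries a ``ground_truth`` dict with the
    noiseless component waveform, per-channel amplitudes, phase, and the
    noise normalization, so tests can decompose any recording exactly.
    """
    rng = np.random.default_rng(config.seed)
    t_axis = np.arange(config.n_samples) / config.fs

    # noise first: identical across snr values for a fixed seed.  The
    # spatial mixing emulates volume conduction; with mixing_seed set it is
    # shared across recordings (one head geometry for a whole cohort).
    mix_rng = rng if config.mixing_seed is None else np.random.default_rng(
        config.mixing_seed
    )
    mixing = np.eye(config.n_channels) + 0.5 * mix_rng.standard_normal(
        (config.n_channels, config.n_channels)
    ) / np.sqrt(config.n_channels)
    sources = _one_over_f_noise(
        rng,
        (config.n_trials, config.n_channels, config.n_samples),
        config.noise_exponent,
        config.fs,
    )
    noise = np.einsum("cd,tds->tcs", mixing, sources)
    rms = np.sqrt(np.mean(noise**2, axis=(0, 2)))  # per channel
    rms[rms == 0] = 1.0
    noise /= rms[None, :, None]

    phase = rng.uniform(0, 2 * np.pi)
    w = config.topography
    best = float(np.max(np.abs(w)))
    amplitudes = (config.snr / best) * w  # best channel amplitude == snr
    waveform = np.sin(2 * np.pi * config.f0 * t_axis + phase)
    data = noise + amplitudes[None, :, None] * waveform[None, None, :]

    gt = {
        "waveform": waveform,
        "amplitudes": amplitudes,
        "topography": w,
        "phase": float(phase),
        "f0": config.f0,
        "snr": config.snr,
        "noise_rms_per_channel": 1.0,
        "noise_exponent": config.noise_exponent,
        "seed": config.seed,
    }
    names = [f"ch{i:02d}" for i in range(config.n_channels)]
    return EEGEpochs(data, config.fs, names, ground_truth=gt)
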