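"""Normalized 40 Hz auditory steady-state response (ASSR) power.

The ASSR is the EEG oscillation entrained by a periodically modulated
auditory stimulus; at 40 Hz its amplitude indexes the cortex's capacity for
gamma-band synchronization.  This module turns multi-trial EEG epochs into a
single scalar per recording:

1. light preprocessing (average reference, per-trial detrend, zero-phase
   high-pass),
2. denoising source separation (DSS) — a linear spatial filter that maximizes
   the ratio of trial-averaged (evoked, stimulus-locked) power to total
   power via a generalized eigenproblem, with components ordered by
   reliability,
3. a periodogram of the trial-averaged component waveform, zero-padded so
   the bin width can express sub-hertz band arithmetic,
4. the normalized power ratio: power at the stimulation frequency divided by
   the mean power of 1 Hz flanking bands, with 0.5 Hz guard bands excluded
   on either side of the target bin.

The ratio is dimensionless and invariant to global amplitude rescaling of
the input, which is what makes it comparable across subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .errors import (
    ConfigurationError,
    DegenerateDataError,
    ResolutionError,
)

__all__ = [
    "EEGEpochs",
    "SpatialFilterSet",
    "PowerSpectrum",
    "NormalizedASSRPower",
    "preprocess_epochs",
    "fit_dss",
    "apply_dss",
    "evoked_spectrum",
    "normalized_assr_power",
    "assr_pipeline",
]


@dataclass
class EEGEpochs:
    """Multi-trial evoked-response container.

    Parameters
    ----------
    data
        Array of shape ``(n_trials, n_channels, n_samples)`` in microvolts.
    fs
        Sampling rate in Hz.
    channel_names
        One label per channel.
    ground_truth
        Optional generator metadata (present on synthetic data only).
    """

    data: np.ndarray
    fs: float
    channel_names: list[str] = field(default_factory=list)
    ground_truth: dict | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ConfigurationError(
                f"epochs must be (trials, channels, samples); got {self.data.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ConfigurationError("epochs contain non-finite values")
        if not self.fs > 0:
            raise ConfigurationError("sampling rate must be positive")
        if not self.channel_names:
            self.channel_names = [f"ch{i:02d}" for i in range(self.data.shape[1])]
        if len(self.channel_names) != self.data.shape[1]:
            raise ConfigurationError("channel_names length mismatch")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]


@dataclass
class SpatialFilterSet:
    """DSS unmixing filters, forward patterns, and reliability scores.

    ``unmixing`` has shape (components, channels) with unit-norm rows;
    ``patterns`` is its pseudo-inverse (channels, components), so applying
    filters then patterns reconstructs the retained-rank content of the
    input.  ``reliability`` is the evoked/total power fraction of each
    component, sorted non-increasing, in [0, 1].
    """

    unmixing: np.ndarray
    patterns: np.ndarray
    reliability: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.reliability, dtype=float)
        if np.any(np.diff(r) > 1e-12):
            raise ConfigurationError("reliability must be non-increasing")
        if np.any((r < -1e-12) | (r > 1 + 1e-9)):
            raise ConfigurationError("reliability scores must lie in [0, 1]")
        self.reliability = np.clip(r, 0.0, 1.0)

    @property
    def n_components(self) -> int:
        return self.unmixing.shape[0]


@dataclass
class PowerSpectrum:
    """One-sided power spectrum on a uniform frequency grid."""

    freqs: np.ndarray
    power: np.ndarray
    bin_width: float

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        d = np.diff(self.freqs)
        if self.freqs.size < 2 or np.any(d <= 0):
            raise ConfigurationError("freqs must be strictly increasing")
        if not np.allclose(d, d[0], rtol=1e-8):
            raise ConfigurationError("freqs must be uniformly spaced")
        if np.any(self.power < -1e-30):
            raise ConfigurationError("power must be non-negative")


@dataclass
class NormalizedASSRPower:
    """Raw power at the target bin, flanking background power, and ratio."""

    raw_power: float
    background_power: float
    ratio: float

    def __post_init__(self) -> None:
        if not self.background_power > 0:
            raise DegenerateDataError("background power must be positive")


def preprocess_epochs(
    raw: EEGEpochs, highpass_hz: float = 0.8, filter_order: int = 4
) -> EEGEpochs:
    """Average-reference, detrend, and zero-phase high-pass filter epochs.

    The channel mean at every sample is subtracted (average reference),
    a zero-phase (forward-backward) Butterworth high-pass of the given
    order is applied, and a linear trend is removed per trial and channel.
    The high-pass runs on the trials concatenated in recording order — a
    0.8 Hz filter needs on the order of a second to settle, far longer
    than one 375 ms trial, so per-epoch filtering would be dominated by
    edge transients; filtering the concatenation emulates filtering the
    continuous recording before epoching.  All operations are linear and
    act identically on every channel, so the average-reference identity
    (zero channel mean at each sample) survives the later stages.
    """
    if raw.n_channels < 2:
        raise DegenerateDataError("average reference requires at least 2 channels")
    data = raw.data - raw.data.mean(axis=1, keepdims=True)
    if highpass_hz:
        if not 0 < highpass_hz < raw.fs / 2:
            raise ConfigurationError("highpass_hz must lie in (0, fs/2)")
        sos = signal.butter(
            filter_order, highpass_hz, btype="highpass", fs=raw.fs, output="sos"
        )
        n_tr, n_ch, n_s = data.shape
        record = data.transpose(1, 0, 2).reshape(n_ch, n_tr * n_s)
        record = signal.sosfiltfilt(sos, record, axis=-1)
        data = record.reshape(n_ch, n_tr, n_s).transpose(1, 0, 2)
    data = signal.detrend(data, axis=-1, type="linear")
    return EEGEpochs(data, raw.fs, list(raw.channel_names), raw.ground_truth)


def _covariances(epochs: EEGEpochs) -> tuple[np.ndarray, np.ndarray]:
    """Second-moment matrices of single-trial data and of the evoked mean."""
    x = epochs.data  # (T, C, S)
    n = x.shape[0] * x.shape[2]
    c_total = np.einsum("tcs,tds->cd", x, x) / n
    evoked = x.mean(axis=0)
    c_evoked = evoked @ evoked.T / evoked.shape[1]
    return c_total, c_evoked


def fit_dss(
    epochs: EEGEpochs, rank_tol: float = 1e-10, min_rank: int = 1
) -> SpatialFilterSet:
    """Fit denoising source separation filters to multi-trial epochs.

    The total covariance is taken over all single-trial data, the evoked
    covariance over the trial-averaged waveform.  The data are whitened by
    the total covariance (eigendecomposition, discarding eigenvalues below
    ``rank_tol`` times the largest), and the whitened evoked covariance is
    eigendecomposed.  Its eigenvalues are the fraction of total power that
    is reproducible across trials and serve as the component reliability
    scores; they coincide with the generalized eigenvalues of the
    (evoked, total) covariance pencil.

    Eigenvector signs are fixed so the largest-magnitude forward-pattern
    weight of each component is positive.  Ties in reliability keep a
    stable order by component index.
    """
    if epochs.n_trials < 2:
        raise DegenerateDataError("DSS needs at least 2 trials")
    c_total, c_evoked = _covariances(epochs)
    evals, evecs = np.linalg.eigh(c_total)
    keep = evals > rank_tol * evals.max()
    if keep.sum() < max(min_rank, 1):
        raise DegenerateDataError(
            f"total covariance rank {int(keep.sum())} below minimum {min_rank}"
        )
    whitener = evecs[:, keep] / np.sqrt(evals[keep])  # (C, r)
    c_white = whitener.T @ c_evoked @ whitener
    c_white = 0.5 * (c_white + c_white.T)
    mu, v = np.linalg.eigh(c_white)
    order = np.argsort(-mu, kind="stable")
    mu, v = mu[order], v[:, order]
    filters = (whitener @ v).T  # (r, C)
    filters /= np.linalg.norm(filters, axis=1, keepdims=True)
    patterns = np.linalg.pinv(filters)  # (C, r)
    # eigenvector sign is arbitrary; make the dominant pattern weight positive
    for k in range(filters.shape[0]):
        j = np.argmax(np.abs(patterns[:, k]))
        if patterns[j, k] < 0:
            filters[k] *= -1.0
            patterns[:, k] *= -1.0
    return SpatialFilterSet(filters, patterns, np.clip(mu, 0.0, 1.0))


def apply_dss(epochs: EEGEpochs, filters: SpatialFilterSet, k: int = 1) -> np.ndarray:
    """Project each trial onto the top-``k`` DSS components.

    Returns an array of shape ``(n_trials, k, n_samples)``.
    """
    if not 1 <= k <= filters.n_components:
        raise ConfigurationError(
            f"k={k} exceeds available components ({filters.n_components})"
        )
    if filters.unmixing.shape[1] != epochs.n_channels:
        raise ConfigurationError("channel dimension mismatch between data and filters")
    return np.einsum("kc,tcs->tks", filters.unmixing[:k], epochs.data)


def evoked_spectrum(
    component_epochs: np.ndarray, fs: float, pad_to_s: float = 4.0
) -> PowerSpectrum:
    """Steady-state periodogram of the component time course.

    The per-trial component waveforms are concatenated in trial order —
    reconstructing the steady-state record the trials were cut from — and
    Fourier transformed as one periodogram.  Because the entrained
    component has an integer number of cycles per trial (15 cycles of
    40 Hz in 375 ms), it is phase-continuous across the concatenation and
    its power confines to a single frequency bin, while trial-independent
    background activity spreads over all bins; this is what gives the
    normalization ratio its dynamic range.  A single trial cannot resolve
    the sub-hertz guard-band arithmetic (a 375 ms window has 2.67 Hz
    native resolution), which is why the estimator operates on the full
    record.

    The record is zero-padded to at least ``pad_to_s`` seconds (only
    relevant for very short recordings) and the bin width is
    ``1 / max(record_s, pad_to_s)``; with 75 default trials the record is
    28.125 s and the bins are 0.0356 Hz wide.  Power is normalized so the
    one-sided spectrum satisfies Parseval's identity: the sum over bins
    equals the time-domain energy of the record.
    """
    x = np.asarray(component_epochs, dtype=float)
    if x.ndim == 3:
        if x.shape[1] != 1:
            raise ConfigurationError(
                "evoked_spectrum expects a single component; apply_dss with k=1"
            )
        x = x[:, 0, :]
    if x.ndim != 2:
        raise ConfigurationError("component epochs must be 2-D or 3-D")
    record = x.reshape(-1)
    n_pad = max(record.size, int(round(pad_to_s * fs)))
    spec = np.fft.rfft(record, n_pad)
    power = np.abs(spec) ** 2 / n_pad
    power[1:] *= 2.0
    if n_pad % 2 == 0:
        power[-1] /= 2.0  # Nyquist bin is not duplicated
    freqs = np.fft.rfftfreq(n_pad, 1.0 / fs)
    return PowerSpectrum(freqs, power, fs / n_pad)


def normalized_assr_power(
    spectrum: PowerSpectrum,
    f0: float = 40.0,
    band_hz: float = 1.0,
    guard_hz: float = 0.5,
) -> NormalizedASSRPower:
    """Ratio of raw power at ``f0`` to mean flanking background power.

    Raw power is the bin nearest ``f0``.  Background power averages the
    bins in ``[f0-guard-band, f0-guard) ∪ (f0+guard, f0+guard+band]`` —
    1 Hz wide bands on either side, separated from the target bin by
    guard bands of 0.5 Hz (defaults).
    """
    lo, hi = f0 - guard_hz - band_hz, f0 + guard_hz + band_hz
    f = spectrum.freqs
    if f[0] > lo + 1e-9 or f[-1] < hi - 1e-9:
        raise ResolutionError(
            f"spectrum [{f[0]}, {f[-1]}] Hz does not cover [{lo}, {hi}] Hz"
        )
    eps = 1e-6 * spectrum.bin_width
    raw = float(spectrum.power[np.argmin(np.abs(f - f0))])
    lower = (f >= lo - eps) & (f < f0 - guard_hz - eps)
    upper = (f > f0 + guard_hz + eps) & (f <= hi + eps)
    n_bins = int(lower.sum() + upper.sum())
    if n_bins == 0:
        raise ResolutionError(
            "no spectral bins fall in the flanking bands; decrease bin width"
        )
    background = float(spectrum.power[lower | upper].mean())
    if background <= 0:
        raise DegenerateDataError("background power is zero; ratio undefined")
    return NormalizedASSRPower(raw, background, raw / background)


def assr_pipeline(
    raw: EEGEpochs,
    highpass_hz: float = 0.8,
    k: int = 1,
    pad_to_s: float = 4.0,
    f0: float = 40.0,
    band_hz: float = 1.0,
    guard_hz: float = 0.5,
) -> NormalizedASSRPower:
    """Preprocess, fit and apply DSS, and compute the normalized ratio.

    With ``k > 1`` the per-component evoked periodograms are averaged
    before normalization; the default uses only the most reliable
    component.
    """
    clean = preprocess_epochs(raw, highpass_hz=highpass_hz)
    filters = fit_dss(clean)
    comps = apply_dss(clean, filters, k=k)
    spectra = [
        evoked_spectrum(comps[:, j : j + 1, :], raw.fs, pad_to_s) for j in range(k)
    ]
    power = np.mean([s.power for s in spectra], axis=0)
    spectrum = PowerSpectrum(spectra[0].freqs, power, spectra[0].bin_width)
    return normalized_assr_power(spectrum, f0=f0, band_hz=band_hz, guard_hz=guard_hz)
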