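"""ASSR stage: preprocessing, DSS, spectrum, normalized-power ratio."""

import numpy as np
import pytest
from scipy import linalg, signal, stats

from assrconn.assr import (
    EEGEpochs,
    PowerSpectrum,
    apply_dss,
    assr_pipeline,
    evoked_spectrum,
    fit_dss,
    normalized_assr_power,
    preprocess_epochs,
)
from assrconn.errors import (
    ConfigurationError,
    DegenerateDataError,
    ResolutionError,
)
from assrconn.synth import EEGSimConfig, generate_eeg_epochs

FS = 1000.0


# ---------------------------------------------------------------- preprocess


def test_constant_offsets_become_zero():
    data = np.tile(np.array([1.0, -2.0, 5.0])[None, :, None], (3, 1, 100))
    out = preprocess_epochs(EEGEpochs(data, FS), highpass_hz=0.0)
    np.testing.assert_allclose(out.data, 0.0, atol=1e-12)


def test_average_reference_identity(small_epochs):
    out = preprocess_epochs(small_epochs)
    np.testing.assert_allclose(out.data.mean(axis=1), 0.0, atol=1e-9)


def test_highpass_barely_attenuates_40hz():
    """Zero-phase 0.8 Hz Butterworth leaves a 40 Hz tone essentially
    untouched; checked against the filter's own frequency response."""
    sos = signal.butter(4, 0.8, btype="highpass", fs=FS, output="sos")
    _, h = signal.sosfreqz(sos, worN=[40.0], fs=FS)
    assert abs(h[0]) ** 2 > 0.999  # |H|^2 because filtfilt applies twice

    t = np.arange(2000) / FS
    tone = np.sin(2 * np.pi * 40 * t)
    amps = np.array([1.0, 0.5, -0.3, 0.8])
    data = np.tile(amps[None, :, None] * tone[None, None, :], (2, 1, 1))
    out = preprocess_epochs(EEGEpochs(data, FS))
    # average reference shifts every channel by the same multiple of the
    # tone; compare the referenced input to the filtered output instead
    ref = data - data.mean(axis=1, keepdims=True)
    atten = np.linalg.norm(out.data) / np.linalg.norm(ref)
    assert atten > 0.99


def test_single_channel_reference_error():
    with pytest.raises(DegenerateDataError):
        preprocess_epochs(EEGEpochs(np.zeros((2, 1, 50)), FS))


# ----------------------------------------------------------------------- DSS


def test_identical_trials_fully_reliable(rng):
    trial = rng.standard_normal((4, 200))
    data = np.tile(trial[None], (6, 1, 1))
    filters = fit_dss(EEGEpochs(data, FS))
    np.testing.assert_allclose(filters.reliability, 1.0, atol=1e-8)


def test_reliability_bounded_sorted(small_epochs):
    filters = fit_dss(preprocess_epochs(small_epochs))
    r = filters.reliability
    assert np.all((r >= 0) & (r <= 1))
    assert np.all(np.diff(r) <= 1e-12)
    np.testing.assert_allclose(
        np.linalg.norm(filters.unmixing, axis=1), 1.0, atol=1e-12
    )


def test_component_one_recovers_planted_source():
    epochs = generate_eeg_epochs(EEGSimConfig(n_channels=8, snr=4.0, seed=77))
    clean = preprocess_epochs(epochs)
    comp = apply_dss(clean, fit_dss(clean), k=1)[:, 0, :]
    evoked = comp.mean(axis=0)
    r = np.corrcoef(evoked, epochs.ground_truth["waveform"])[0, 1]
    assert abs(r) > 0.95


def test_component_one_beats_best_channel():
    """DSS optimality: the evoked/total power fraction of component 1 is at
    least that of every single channel (per-channel oracle)."""
    epochs = generate_eeg_epochs(EEGSimConfig(n_channels=6, snr=1.5, seed=8))
    clean = preprocess_epochs(epochs)
    filters = fit_dss(clean)
    x = clean.data
    evoked = x.mean(axis=0)
    per_channel = (evoked**2).mean(axis=1) / (x**2).mean(axis=(0, 2))
    assert filters.reliability[0] >= per_channel.max() - 1e-10


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_dss_matches_generalized_eigenproblem(seed):
    """Brute-force oracle: reliabilities equal the generalized eigenvalues
    of the (evoked, total) covariance pencil on tiny full-rank instances."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((8, 4, 64))
    x += 0.5 * np.sin(2 * np.pi * 8 * np.arange(64) / 64)[None, None, :]
    epochs = EEGEpochs(x, FS)
    filters = fit_dss(epochs)

    c_total = sum(xi @ xi.T for xi in x) / (8 * 64)
    ev = x.mean(axis=0)
    c_evoked = ev @ ev.T / 64
    gev = np.sort(linalg.eigh(c_evoked, c_total, eigvals_only=True))[::-1]
    np.testing.assert_allclose(filters.reliability, np.clip(gev, 0, 1),
                               atol=1e-8)
    # filters agree up to sign with the generalized eigenvectors
    _, vecs = linalg.eigh(c_evoked, c_total)
    top = vecs[:, -1] / np.linalg.norm(vecs[:, -1])
    cos = abs(top @ filters.unmixing[0])
    assert cos > 1 - 1e-8


def test_noise_reliability_scales_with_trial_count(rng):
    """For pure noise the mean evoked/total power fraction is ~1/n_trials."""
    vals = []
    for seed in range(6):
        r = np.random.default_rng(seed)
        x = r.standard_normal((25, 3, 300))
        vals.append(fit_dss(EEGEpochs(x, FS)).reliability.mean())
    assert abs(np.mean(vals) - 1 / 25) < 0.3 / 25
    assert 1 / 25 < np.mean([fit_dss(EEGEpochs(
        np.random.default_rng(s).standard_normal((25, 3, 300)), FS
    )).reliability[0] for s in range(3)]) < 5 / 25


def test_apply_round_trip_full_rank(rng):
    x = rng.standard_normal((5, 4, 80))
    epochs = EEGEpochs(x, FS)
    filters = fit_dss(epochs)
    comps = apply_dss(epochs, filters, k=filters.n_components)
    back = np.einsum("ck,tks->tcs", filters.patterns, comps)
    np.testing.assert_allclose(back, x, atol=1e-8)


def test_apply_k_out_of_range(small_epochs):
    filters = fit_dss(small_epochs)
    with pytest.raises(ConfigurationError):
        apply_dss(small_epochs, filters, k=filters.n_components + 1)


def test_too_few_trials(rng):
    with pytest.raises(DegenerateDataError):
        fit_dss(EEGEpochs(rng.standard_normal((1, 3, 40)), FS))


# ------------------------------------------------------------------ spectrum


def test_spectrum_peak_at_40hz_single_trial():
    t = np.arange(375) / FS
    x = np.sin(2 * np.pi * 40 * t)[None, None, :]
    spec = evoked_spectrum(x, FS, pad_to_s=4.0)
    assert np.isclose(spec.bin_width, 0.25)
    assert np.isclose(spec.freqs[np.argmax(spec.power)], 40.0)


def test_parseval_identity(rng):
    x = rng.standard_normal((5, 1, 100))
    spec = evoked_spectrum(x, FS, pad_to_s=0.0)
    energy = np.sum(x.reshape(-1) ** 2)
    assert np.isclose(spec.power.sum(), energy, rtol=1e-10)


def test_concatenated_record_bin_width():
    x = np.zeros((75, 1, 375))
    spec = evoked_spectrum(x + 1e-9, FS)
    assert np.isclose(spec.bin_width, 1.0 / 28.125)


def test_multi_component_rejected(rng):
    with pytest.raises(ConfigurationError):
        evoked_spectrum(rng.standard_normal((3, 2, 64)), FS)


# ---------------------------------------------------------- normalized power


def _uniform_spectrum(power):
    freqs = np.arange(power.size) * 0.25
    return PowerSpectrum(freqs, power, 0.25)


def test_flat_spectrum_ratio_one():
    spec = _uniform_spectrum(np.full(400, 3.7))
    res = normalized_assr_power(spec)
    assert res.ratio == 1.0


def test_isolated_line_degenerate():
    power = np.zeros(400)
    power[160] = 5.0  # exactly 40 Hz
    with pytest.raises(DegenerateDataError):
        normalized_assr_power(_uniform_spectrum(power))


def test_insufficient_coverage():
    spec = PowerSpectrum(np.arange(100) * 0.25, np.ones(100), 0.25)  # to 24.75 Hz
    with pytest.raises(ResolutionError):
        normalized_assr_power(spec)


def test_ratio_matches_bruteforce_bin_accounting(rng):
    """Independent oracle: sum bins by explicit frequency arithmetic."""
    power = rng.uniform(0.5, 2.0, 2000)
    freqs = np.arange(2000) * 0.05
    spec = PowerSpectrum(freqs, power, 0.05)
    res = normalized_assr_power(spec, f0=40.0, band_hz=1.0, guard_hz=0.5)

    raw = power[np.argmin(np.abs(freqs - 40.0))]
    picked = [
        p
        for f, p in zip(freqs, power)
        if (38.5 - 1e-9 <= f < 39.5 - 1e-9) or (40.5 + 1e-9 < f <= 41.5 + 1e-9)
    ]
    oracle = raw / np.mean(picked)
    assert np.isclose(res.ratio, oracle, rtol=1e-12)


# ------------------------------------------------------------------ pipeline


def test_pipeline_amplitude_invariance():
    epochs = generate_eeg_epochs(EEGSimConfig(n_channels=6, snr=2.0, seed=3))
    r1 = assr_pipeline(epochs).ratio
    scaled = EEGEpochs(37.5 * epochs.data, epochs.fs, epochs.channel_names)
    r2 = assr_pipeline(scaled).ratio
    assert np.isclose(r1, r2, rtol=1e-9)


def test_pipeline_no_entrainment_ratio_near_one():
    ratios = [
        assr_pipeline(
            generate_eeg_epochs(EEGSimConfig(n_channels=4, snr=0.0, seed=s))
        ).ratio
        for s in range(25)
    ]
    assert abs(np.mean(ratios) - 1.0) < 0.6


def test_pipeline_oracle_decomposition_snr10():
    """Ratio within 5% of the oracle built from the noiseless ground-truth
    component and the noise-only background (snr = 0 regeneration)."""
    cfg = dict(n_channels=8, seed=55)
    full = generate_eeg_epochs(EEGSimConfig(snr=10.0, **cfg))
    noise = generate_eeg_epochs(EEGSimConfig(snr=0.0, **cfg))

    clean = preprocess_epochs(full)
    filters = fit_dss(clean)
    comp = apply_dss(clean, filters, k=1)

    # oracle: route the exact signal/noise decomposition through the same
    # measurement chain and form the ratio from its parts
    sig_only = preprocess_epochs(
        EEGEpochs(full.data - noise.data, full.fs), highpass_hz=0.8
    )
    sig_comp = apply_dss(sig_only, filters, k=1)
    noi_comp = apply_dss(preprocess_epochs(noise), filters, k=1)
    sig_spec = evoked_spectrum(sig_comp, full.fs)
    noi_spec = evoked_spectrum(noi_comp, full.fs)
    raw_oracle = sig_spec.power[np.argmin(np.abs(sig_spec.freqs - 40.0))]
    bg_oracle = normalized_assr_power(noi_spec).background_power
    oracle = raw_oracle / bg_oracle

    measured = normalized_assr_power(evoked_spectrum(comp, full.fs)).ratio
    assert abs(measured / oracle - 1) < 0.05


def test_pipeline_monotone_in_snr():
    ladder = [0.0, 0.5, 1.0, 2.0, 4.0, 8.0]
    means = []
    for snr in ladder:
        vals = [
            assr_pipeline(
                generate_eeg_epochs(EEGSimConfig(n_channels=6, snr=snr, seed=s))
            ).ratio
            for s in range(5)
        ]
        means.append(np.mean(vals))
    rho = stats.spearmanr(ladder, means).statistic
    assert rho > 0.95
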