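"""Phase-locking unit and property tests."""

import numpy as np
import pytest
from scipy import stats

from ammod import coupling, synth
from ammod.coupling import PhaseSeries
from ammod.eeg import EEGRecording
from ammod.errors import (
    InsufficientDataError,
    InvalidInputError,
    InvalidParameterError,
)
from conftest import LIGHT

EEG_FS = 250.0


def _phase_series(phase, freq=10.0, fs=EEG_FS):
    return PhaseSeries(
        phase=phase, freq=freq, sample_rate=fs, valid=np.ones(len(phase), bool)
    )


def _noise_eeg(env, seed, duration=60.0):
    spec = synth.CouplingSpec(
        components=(synth.CouplingComponent(freq=16.0, strength=0.0),)
    )
    return synth.synth_eeg(env, spec, seed=seed, duration_s=duration)


# ---------------------------------------------------------- narrowband phase


def test_pure_cosine_phase_advances_linearly():
    t = np.arange(int(20 * EEG_FS)) / EEG_FS
    x = np.cos(2 * np.pi * 10.0 * t)
    ps = coupling.narrowband_phase(x, 10.0, EEG_FS)
    unwrapped = np.unwrap(ps.phase[ps.valid])
    slope = np.polyfit(np.arange(unwrapped.size) / EEG_FS, unwrapped, 1)[0]
    assert slope == pytest.approx(2 * np.pi * 10.0, rel=0.01)


def test_white_noise_phase_is_uniform(rng):
    """Phase of narrowband-filtered white noise is uniform on (-pi, pi];
    samples are subsampled past the filter's correlation length so the KS
    test's independence assumption holds."""
    x = rng.standard_normal(10_000)
    ps = coupling.narrowband_phase(x, 10.0, EEG_FS)
    v = ps.phase[ps.valid][::40]
    p = stats.kstest((v + np.pi) / (2 * np.pi), "uniform").pvalue
    assert p > 0.01
    assert np.all(ps.phase > -np.pi) and np.all(ps.phase <= np.pi)


def test_phase_frequency_validation():
    with pytest.raises(InvalidParameterError):
        coupling.narrowband_phase(np.zeros(100), 0.0, EEG_FS)
    with pytest.raises(InvalidParameterError):
        coupling.narrowband_phase(np.zeros(100), 200.0, EEG_FS)


# ---------------------------------------------------------------------- plv


def test_plv_identities(rng):
    n = 10_000
    phase = rng.uniform(-np.pi, np.pi, n)
    assert coupling.plv(_phase_series(phase), _phase_series(phase)) == pytest.approx(1.0)
    # constant offsets do not matter
    shifted = np.angle(np.exp(1j * (phase + np.pi / 3)))
    assert coupling.plv(_phase_series(phase), _phase_series(shifted)) == pytest.approx(
        1.0, abs=1e-12
    )
    # independent phases: Rayleigh expectation sqrt(pi/4)/sqrt(n) ~ 0.009
    other = rng.uniform(-np.pi, np.pi, n)
    assert coupling.plv(_phase_series(phase), _phase_series(other)) < 0.03


def test_plv_input_validation(rng):
    a = _phase_series(rng.uniform(-np.pi, np.pi, 100))
    b = _phase_series(rng.uniform(-np.pi, np.pi, 99))
    with pytest.raises(InvalidInputError):
        coupling.plv(a, b)
    c = _phase_series(rng.uniform(-np.pi, np.pi, 100), freq=12.0)
    with pytest.raises(InvalidInputError):
        coupling.plv(a, c)


# ------------------------------------------------------------- plv spectrum


def test_plv_spectrum_recovers_coupling_frequency(env60):
    spec = synth.CouplingSpec(
        components=(synth.CouplingComponent(freq=16.0, strength=1.0),), snr_db=0.0
    )
    eeg = synth.synth_eeg(env60, spec, seed=42)
    ps = coupling.plv_spectrum(eeg, env60[: eeg.n_samples])
    avg = ps.channel_average()
    window = (ps.freqs >= 10) & (ps.freqs <= 20)
    assert ps.freqs[window][np.argmax(avg[window])] == 16.0
    assert np.all(ps.plv >= 0) and np.all(ps.plv <= 1)


def test_noise_only_plv_respects_rayleigh_bound(env60):
    """Null PLV scales like sqrt(pi/4)/sqrt(N_eff) with N_eff = T*f/n_cycles
    effective phase samples; the absolute < 0.1 bound is only meaningful
    where that mean falls well below it (f >= 30 Hz at 60 s)."""
    eeg = _noise_eeg(env60, seed=7)
    ps = coupling.plv_spectrum(eeg, env60[: eeg.n_samples])
    n_eff = 60.0 * ps.freqs / coupling.DEFAULT_N_CYCLES
    bound = 3.5 * np.sqrt(np.pi / 4) / np.sqrt(n_eff)
    assert np.all(ps.plv.max(axis=0) < np.maximum(bound, 1e-3))
    assert ps.plv[:, ps.freqs >= 30].max() < 0.1


def test_six_component_local_maxima_recovered(env60):
    """Components at the note-rate harmonics and modulation rates (8, 12,
    14, 16, 24, 32 Hz) come back as local maxima of the channel-averaged
    spectrum. 1-Hz-spaced structure needs sub-hertz analysis bandwidth, so
    28-cycle wavelets are used."""
    targets = (8, 12, 14, 16, 24, 32)
    spec = synth.CouplingSpec(
        components=tuple(synth.CouplingComponent(freq=f) for f in targets),
        snr_db=0.0,
    )
    for seed in (100, 101):
        eeg = synth.synth_eeg(env60, spec, seed=seed)
        ps = coupling.plv_spectrum(eeg, env60[: eeg.n_samples], n_cycles=28.0)
        avg = ps.channel_average()
        f = ps.freqs
        for t in targets:
            assert avg[f == t][0] > avg[f == t - 1][0]
            assert avg[f == t][0] > avg[f == t + 1][0]


def test_plv_spectrum_length_mismatch(env60):
    eeg = _noise_eeg(env60, seed=1)
    with pytest.raises(InvalidInputError):
        coupling.plv_spectrum(eeg, env60[: eeg.n_samples - 10])


# --------------------------------------------------------- binned effect size


def _spectrum_from(vec, labels=("Fz", "Cz", "Pz")):
    return coupling.PLVSpectrum(
        plv=np.tile(vec, (len(labels), 1)),
        freqs=np.arange(1.0, 51.0),
        channel_labels=labels,
    )


def test_effect_size_zero_for_identical_spectra(rng):
    a = _spectrum_from(rng.uniform(0.1, 0.5, 50))
    rep = coupling.binned_effect_size(a, a)
    assert rep.cohens_d_4hz == 0.0 and rep.cohens_d_1hz == 0.0


def test_effect_size_degenerate_constant_offset():
    a = _spectrum_from(np.full(50, 0.3))
    b = _spectrum_from(np.full(50, 0.2))
    rep = coupling.binned_effect_size(a, b)
    assert rep.degenerate and np.isinf(rep.cohens_d_4hz)
    assert rep.cohens_d_4hz > 0


def test_effect_size_larger_for_matching_binning(rng):
    """Coupling elevated only at multiples of 4 Hz: sampling at 4-Hz bin
    centers concentrates the effect, so d(4 Hz bins) > d(1 Hz bins) — the
    direction behind the 4-Hz-bin vs 1-Hz-bin contrast."""
    freqs = np.arange(1.0, 51.0)
    base = 0.1 + 0.01 * rng.standard_normal(50)
    boost = np.where(np.mod(freqs, 4.0) == 0, 0.3, 0.0)
    a = _spectrum_from(base + boost)
    b = _spectrum_from(0.1 + 0.01 * rng.standard_normal(50))
    rep = coupling.binned_effect_size(a, b)
    assert rep.cohens_d_4hz > rep.cohens_d_1hz > 0


def test_effect_size_needs_enough_bins(rng):
    a = _spectrum_from(rng.uniform(0.1, 0.5, 50))
    with pytest.raises(InsufficientDataError):
        coupling.binned_effect_size(a, a, bin_width=20.0)


# ------------------------------------------------------------- early vs late


def test_ramping_coupling_detected_with_power(env60):
    """16 Hz coupling emerging from the noise over the recording (gain
    ramping 0.1x -> 1.9x at -10 dB broadband SNR): positive mean
    delta-PLV with at least one FDR-significant channel in >= 80% of
    simulated recordings."""
    spec = synth.CouplingSpec(
        components=(synth.CouplingComponent(freq=16.0, strength=0.8, drift=1.8),),
        snr_db=-10.0,
    )
    detected = 0
    n_runs = 20
    for seed in range(n_runs):
        eeg = synth.synth_eeg(env60, spec, seed=seed)
        res = coupling.early_late_change(eeg, env60[: eeg.n_samples], 16.0,
                                         epoch_s=5.0)
        if res.delta_plv.mean() > 0 and res.significant.any():
            detected += 1
    assert detected >= 0.8 * n_runs


def test_ramp_down_gives_negative_delta(env60):
    spec = synth.CouplingSpec(
        components=(synth.CouplingComponent(freq=8.0, strength=0.8, drift=-1.8),),
        snr_db=-10.0,
    )
    eeg = synth.synth_eeg(env60, spec, seed=5)
    res = coupling.early_late_change(eeg, env60[: eeg.n_samples], 8.0, epoch_s=5.0)
    assert res.delta_plv.mean() < 0


def test_stationary_coupling_fdr_calibration(env60):
    """Under stationary coupling the FDR procedure rejects on average at
    most q of the channels (Monte Carlo over simulated recordings)."""
    spec = synth.CouplingSpec(
        components=(synth.CouplingComponent(freq=16.0, strength=0.8, drift=0.0),),
        snr_db=0.0,
    )
    fracs = []
    for seed in range(60):
        eeg = synth.synth_eeg(env60, spec, seed=seed)
        res = coupling.early_late_change(eeg, env60[: eeg.n_samples], 16.0)
        fracs.append(res.significant.mean())
    assert np.mean(fracs) <= 0.05 + 0.03  # q plus Monte-Carlo margin


def test_too_short_recording_raises(env60):
    spec = synth.CouplingSpec(components=())
    eeg = synth.synth_eeg(env60, spec, seed=0, duration_s=40.0)
    with pytest.raises(InsufficientDataError):
        coupling.early_late_change(eeg, env60[: eeg.n_samples], 16.0)


# ------------------------------------------------------------- stimulus prep


def test_stimulus_envelope_validation(music12):
    from ammod.audio import AudioTrack

    env = coupling.stimulus_envelope_for_plv(music12, 250.0, **LIGHT)
    assert env.shape[0] == pytest.approx(12.0 * 250.0, abs=2)
    silent = AudioTrack(np.zeros(music12.n_samples), music12.sample_rate)
    with pytest.raises(InvalidInputError):
        coupling.stimulus_envelope_for_plv(silent, 250.0, **LIGHT)
    with pytest.raises(InvalidParameterError):
        coupling.stimulus_envelope_for_plv(music12, 1000.0, **LIGHT)
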