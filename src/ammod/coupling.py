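"""Stimulus-brain phase locking.

Both the EEG and a stimulus envelope are narrowband-filtered with Morlet
(Gaussian-windowed) wavelets at every integer frequency from 1 to 50 Hz; the
instantaneous phase of each is the angle of the analytic signal, and the
phase-locking value (PLV) between stimulus and brain at a frequency is

    PLV = | (1/N) sum_n exp(i (phi_EEG[n] - phi_stim[n])) |

i.e. the magnitude of the mean complex phase difference, which lies in [0, 1]
(1 = perfect locking, ~0 = independence). The raw sum is normalized by the
sample count so values are bounded and comparable across recording lengths.

The module also provides binned effect sizes between two PLV spectra
(channel-averaged, Cohen's d paired across bin centers — wide bins centered
on multiples of 4 Hz capture note-rate harmonics and modulation rates) and an
early-vs-late comparison of epoch-wise PLV with channel-wise t-tests under
Benjamini-Hochberg FDR correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import gcd

import numpy as np
from scipy import signal as _sig
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .audio import AudioTrack
from .eeg import EEGRecording, channels_in_groups
from .errors import InsufficientDataError, InvalidInputError, InvalidParameterError
from . import modspec as _ms

__all__ = [
    "PhaseSeries",
    "PLVSpectrum",
    "EffectSizeReport",
    "EarlyLateResult",
    "stimulus_envelope_for_plv",
    "morlet_analytic",
    "narrowband_phase",
    "plv",
    "plv_spectrum",
    "binned_effect_size",
    "early_late_change",
]

DEFAULT_N_CYCLES = 7.0
EDGE_CYCLES = 3.0
DEFAULT_FREQS = np.arange(1.0, 51.0)


@dataclass(frozen=True)
class PhaseSeries:
    """Instantaneous phase of one signal at one analysis frequency.

    ``valid`` flags samples further than three wavelet cycles from either
    edge; filter transients there make the phase unreliable.
    """

    phase: np.ndarray
    freq: float
    sample_rate: float
    valid: np.ndarray

    def __len__(self) -> int:
        return self.phase.shape[0]


@dataclass(frozen=True)
class PLVSpectrum:
    """Channels x frequencies matrix of stimulus-brain PLV in [0, 1]."""

    plv: np.ndarray
    freqs: np.ndarray
    channel_labels: tuple[str, ...]
    segment_tag: str = "whole"

    def channel_average(self, groups: tuple[str, ...] | str | None = None) -> np.ndarray:
        """PLV averaged over a named montage group set (None = all channels)."""
        if groups is None:
            return self.plv.mean(axis=0)
        idx = channels_in_groups(self.channel_labels, groups)
        if not idx:
            raise InvalidInputError(f"no channels match groups {groups}")
        return self.plv[idx].mean(axis=0)


def stimulus_envelope_for_plv(
    track: AudioTrack,
    target_rate: float,
    n_channels: int = _ms.DEFAULT_N_CHANNELS,
    f_range: tuple[float, float] = _ms.DEFAULT_F_RANGE,
) -> np.ndarray:
    """Broadband envelope (cochleagram channel sum) resampled to the EEG rate.

    Filtering raw audio at 1-50 Hz would pick up near-DC pressure, not the
    perceptual modulation content, so the stimulus signal entering the PLV
    analysis is the summed cochlear envelope.
    """
    coch = _ms.cochlear_filterbank(track, n_channels=n_channels, f_range=f_range)
    if target_rate > coch.frame_rate:
        raise InvalidParameterError(
            f"target_rate {target_rate} exceeds envelope frame rate {coch.frame_rate}"
        )
    env = coch.envelopes.sum(axis=0)
    if not np.any(env > 0):
        raise InvalidInputError("silent stimulus: envelope is identically zero")
    fr_i, tr_i = int(round(coch.frame_rate)), int(round(target_rate))
    g = gcd(fr_i, tr_i)
    return _sig.resample_poly(env, tr_i // g, fr_i // g)


def morlet_analytic(
    x: np.ndarray, freq: float, sample_rate: float, n_cycles: float = DEFAULT_N_CYCLES
) -> np.ndarray:
    """Complex Morlet-filtered signal (Gaussian-windowed analytic narrowband).

    Works on the last axis; accepts 1-D or 2-D input.
    """
    if freq <= 0:
        raise InvalidParameterError("freq must be > 0")
    if freq >= sample_rate / 2:
        raise InvalidParameterError(f"freq {freq} at or above Nyquist")
    sigma_t = n_cycles / (2.0 * np.pi * freq)
    half = int(np.ceil(5.0 * sigma_t * sample_rate))
    t = np.arange(-half, half + 1) / sample_rate
    wavelet = np.exp(2j * np.pi * freq * t) * np.exp(-(t**2) / (2.0 * sigma_t**2))
    wavelet /= np.abs(wavelet).sum()
    x2 = np.atleast_2d(x)
    out = _sig.fftconvolve(x2, wavelet[None, :], mode="same", axes=1)
    return out[0] if np.ndim(x) == 1 else out


def narrowband_phase(
    x: np.ndarray,
    freq: float,
    sample_rate: float,
    n_cycles: float = DEFAULT_N_CYCLES,
) -> PhaseSeries:
    """Instantaneous phase at ``freq`` with edge samples flagged invalid."""
    analytic = morlet_analytic(x, freq, sample_rate, n_cycles)
    phase = np.angle(analytic)
    n = phase.shape[-1]
    edge = int(np.ceil(EDGE_CYCLES / freq * sample_rate))
    valid = np.zeros(n, dtype=bool)
    if 2 * edge < n:
        valid[edge : n - edge] = True
    return PhaseSeries(phase=phase, freq=freq, sample_rate=sample_rate, valid=valid)


def plv(eeg_phase: PhaseSeries, stim_phase: PhaseSeries) -> float:
    """Phase-locking value between two phase series (valid samples only)."""
    if len(eeg_phase) != len(stim_phase):
        raise InvalidInputError("phase series differ in length")
    if eeg_phase.freq != stim_phase.freq:
        raise InvalidInputError("phase series are at different frequencies")
    m = eeg_phase.valid & stim_phase.valid
    if not m.any():
        raise InsufficientDataError("no valid samples after edge exclusion")
    return float(np.abs(np.mean(np.exp(1j * (eeg_phase.phase[m] - stim_phase.phase[m])))))


def _plv_matrix(
    data: np.ndarray,
    stim: np.ndarray,
    sample_rate: float,
    freqs: np.ndarray,
    n_cycles: float,
    sample_mask: np.ndarray | None = None,
) -> np.ndarray:
    """PLV per channel per frequency, optionally restricted to a sample mask
    (applied on top of edge exclusion)."""
    n = data.shape[1]
    out = np.empty((data.shape[0], freqs.shape[0]))
    for j, f in enumerate(freqs):
        eeg_an = morlet_analytic(data, f, sample_rate, n_cycles)
        stim_an = morlet_analytic(stim, f, sample_rate, n_cycles)
        edge = int(np.ceil(EDGE_CYCLES / f * sample_rate))
        valid = np.zeros(n, dtype=bool)
        if 2 * edge < n:
            valid[edge : n - edge] = True
        if sample_mask is not None:
            valid &= sample_mask
        if not valid.any():
            raise InsufficientDataError(f"no valid samples at {f} Hz")
        dphi = np.angle(eeg_an[:, valid]) - np.angle(stim_an[valid])[None, :]
        out[:, j] = np.abs(np.mean(np.exp(1j * dphi), axis=1))
    return out


def plv_spectrum(
    eeg: EEGRecording,
    stim: np.ndarray,
    freqs: np.ndarray = DEFAULT_FREQS,
    n_cycles: float = DEFAULT_N_CYCLES,
    segment_tag: str = "whole",
) -> PLVSpectrum:
    """Stimulus-brain PLV for every channel at every frequency (1-Hz bins)."""
    stim = np.asarray(stim, dtype=np.float64)
    if stim.shape[0] != eeg.n_samples:
        raise InvalidInputError(
            f"stimulus length {stim.shape[0]} != EEG length {eeg.n_samples}"
        )
    mat = _plv_matrix(eeg.data, stim, eeg.sample_rate, np.asarray(freqs, float), n_cycles)
    return PLVSpectrum(
        plv=mat, freqs=np.asarray(freqs, float),
        channel_labels=eeg.channel_labels, segment_tag=segment_tag,
    )


@dataclass(frozen=True)
class EffectSizeReport:
    """Cohen's d between two PLV spectra, paired across frequency-bin centers.

    ``cohens_d_4hz`` samples the channel-averaged spectra at multiples of the
    bin width (default 4 Hz: 4, 8, ..., 48, capturing the note-rate harmonics
    and added-modulation rates); ``cohens_d_1hz`` uses every 1-Hz bin.
    ``degenerate`` flags a zero-variance difference (d reported as +/-inf).
    """

    cohens_d_4hz: float
    cohens_d_1hz: float
    bin_centers: np.ndarray
    channel_set: tuple[str, ...] | None
    degenerate: bool = False


def _paired_d(diff: np.ndarray) -> tuple[float, bool]:
    sd = float(np.std(diff, ddof=1))
    mean = float(np.mean(diff))
    # zero-variance differences (up to float rounding) make d undefined
    if sd <= 1e-12 * max(abs(mean), 1e-30):
        if mean == 0.0:
            return 0.0, False
        return float(np.sign(mean) * np.inf), True
    return mean / sd, False


def binned_effect_size(
    plv_a: PLVSpectrum,
    plv_b: PLVSpectrum,
    bin_width: float = 4.0,
    channel_set: tuple[str, ...] | None = ("frontal", "central", "parietal"),
) -> EffectSizeReport:
    """Effect size (Cohen's d) of A vs B over binned PLV spectra.

    Both spectra are averaged over ``channel_set`` (montage group names;
    None = all channels), then compared bin-center-by-bin-center:
    d = mean(A - B) / sd(A - B) across centers.
    """
    if plv_a.freqs.shape != plv_b.freqs.shape or not np.allclose(plv_a.freqs, plv_b.freqs):
        raise InvalidInputError("PLV spectra are on different frequency grids")
    a = plv_a.channel_average(channel_set)
    b = plv_b.channel_average(channel_set)
    freqs = plv_a.freqs
    centers_mask = np.isclose(np.mod(freqs, bin_width), 0.0) & (freqs > 0)
    centers = freqs[centers_mask]
    if centers.shape[0] < 3:
        raise InsufficientDataError(f"fewer than 3 bins at width {bin_width} Hz")
    d_binned, degen_b = _paired_d(a[centers_mask] - b[centers_mask])
    d_1hz, degen_1 = _paired_d(a - b)
    return EffectSizeReport(
        cohens_d_4hz=d_binned,
        cohens_d_1hz=d_1hz,
        bin_centers=centers,
        channel_set=channel_set,
        degenerate=degen_b or degen_1,
    )


@dataclass(frozen=True)
class EarlyLateResult:
    """Per-channel change in PLV from the early to the late half of a
    recording, with channel-wise Welch t-tests under BH-FDR correction."""

    delta_plv: np.ndarray  # late - early, per channel
    t: np.ndarray
    p: np.ndarray
    significant: np.ndarray  # BH-FDR mask at q
    q: float
    freq: float
    n_epochs_early: int
    n_epochs_late: int
    channel_labels: tuple[str, ...]


def early_late_change(
    eeg: EEGRecording,
    stim: np.ndarray,
    freq: float,
    split: float = 0.5,
    epoch_s: float = 10.0,
    q: float = 0.05,
    n_cycles: float = DEFAULT_N_CYCLES,
) -> EarlyLateResult:
    """Compare late-half vs early-half epoch-wise PLV at one frequency.

    The recording is cut into contiguous ``epoch_s``-second epochs; PLV is
    computed per epoch per channel (phases from the continuous filtering, so
    only recording-edge samples are lost); epochs are split into early/late
    halves at ``split``; each channel gets a two-sample t-test and the
    p-values are Benjamini-Hochberg corrected across channels at level ``q``.
    """
    stim = np.asarray(stim, dtype=np.float64)
    if stim.shape[0] != eeg.n_samples:
        raise InvalidInputError("stimulus and EEG lengths differ")
    epoch_len = int(round(epoch_s * eeg.sample_rate))
    n_epochs = eeg.n_samples // epoch_len
    n_early = int(round(n_epochs * split))
    n_late = n_epochs - n_early
    # each half must retain at least 30 s of analyzable data
    if min(n_early, n_late) * epoch_s < 30.0:
        raise InsufficientDataError(
            f"each half needs >= 30 s of epochs; got {n_early}/{n_late} "
            f"epochs of {epoch_s} s"
        )
    eeg_an = morlet_analytic(eeg.data, freq, eeg.sample_rate, n_cycles)
    stim_an = morlet_analytic(stim, freq, eeg.sample_rate, n_cycles)
    dphase = np.angle(eeg_an) - np.angle(stim_an)[None, :]
    edge = int(np.ceil(EDGE_CYCLES / freq * eeg.sample_rate))
    valid = np.zeros(eeg.n_samples, dtype=bool)
    valid[edge : eeg.n_samples - edge] = True

    plv_epochs = np.empty((eeg.n_channels, n_epochs))
    for e in range(n_epochs):
        sl = slice(e * epoch_len, (e + 1) * epoch_len)
        m = valid[sl]
        if not m.any():
            raise InsufficientDataError(f"epoch {e} fully inside the edge-exclusion zone")
        plv_epochs[:, e] = np.abs(np.mean(np.exp(1j * dphase[:, sl][:, m]), axis=1))

    early = plv_epochs[:, :n_early]
    late = plv_epochs[:, n_early:]
    t, p = stats.ttest_ind(late, early, axis=1)
    sig = multipletests(p, alpha=q, method="fdr_bh")[0]
    return EarlyLateResult(
        delta_plv=late.mean(axis=1) - early.mean(axis=1),
        t=t, p=p, significant=sig, q=q, freq=freq,
        n_epochs_early=n_early, n_epochs_late=n_late,
        channel_labels=eeg.channel_labels,
    )
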