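"""Synthetic inputs for the full pipeline.

Everything the analysis modules consume can be generated here: music-like
audio on a 120-bpm metrical grid, pink noise, EEG whose components are
phase-locked to a stimulus envelope at chosen frequencies over 1/f
background noise, and SART response logs emitted by a signal-detection
agent whose sensitivity varies by condition, block, and ASRS score. Every
generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .audio import AudioTrack
from .behavior import TrialSchedule
from .coupling import morlet_analytic, stimulus_envelope_for_plv
from .eeg import EEGRecording
from .errors import InvalidParameterError

__all__ = [
    "derive_seed",
    "synth_music",
    "synth_pink_noise",
    "CouplingComponent",
    "CouplingSpec",
    "synth_eeg",
    "EffectMap",
    "synth_cohort",
    "synth_cohort_counts",
    "DEFAULT_CHANNEL_LABELS",
]

# 8-channel default montage spanning frontal/central/parietal/occipital sites
DEFAULT_CHANNEL_LABELS = ("Fp1", "Fz", "F3", "Cz", "C3", "Pz", "P3", "Oz")

NOTE_RATES = {"quarter": 1, "8th": 2, "16th": 4, "32nd": 8, "64th": 16}

# A-minor pentatonic pitches over two octaves, semitones above 220 Hz
_PENTATONIC_SEMITONES = (0, 3, 5, 7, 10, 12, 15, 17, 19, 22, 24)


def derive_seed(root_seed: int, stage: str) -> int:
    """Stable per-stage seed from a root seed (counter-based fan-out: adding
    a stage never perturbs another stage's stream)."""
    key = zlib.crc32(stage.encode()) & 0x7FFFFFFF
    ss = np.random.SeedSequence(entropy=root_seed, spawn_key=(key,))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def synth_music(
    bpm: float = 120.0,
    duration_s: float = 30.0,
    note_pattern: tuple[str, ...] = ("quarter", "8th", "16th"),
    sample_rate: float = 22050.0,
    seed: int | None = 0,
) -> AudioTrack:
    """Music-like audio: enveloped tone events on the metrical grid.

    Each entry in ``note_pattern`` adds a layer of decaying tone bursts at
    the corresponding subdivision rate (at 120 bpm: quarter = 2 Hz,
    8th = 4 Hz, 16th = 8 Hz, ...), with pitches drawn from a pentatonic set
    and a low-level pink-noise bed underneath. Deterministic per seed; the
    returned track carries the bpm metadata.
    """
    if duration_s < 10.0:
        raise InvalidParameterError("duration must be >= 10 s")
    if not note_pattern:
        raise InvalidParameterError("note_pattern must name at least one layer")
    for name in note_pattern:
        if name not in NOTE_RATES:
            raise InvalidParameterError(f"unknown note value {name!r}")
    rng = np.random.default_rng(seed)
    fs = sample_rate
    n = int(round(duration_s * fs))
    quarter = bpm / 60.0
    out = np.zeros(n)
    pitches = 220.0 * 2.0 ** (np.array(_PENTATONIC_SEMITONES) / 12.0)

    for li, name in enumerate(note_pattern):
        rate = NOTE_RATES[name] * quarter
        period = 1.0 / rate
        layer_gain = 0.9 ** li / len(note_pattern)
        n_events = int(np.floor(duration_s * rate))
        ev_len = int(round(min(0.9 * period, 0.25) * fs))
        t_ev = np.arange(ev_len) / fs
        attack = np.minimum(t_ev / 0.005, 1.0)
        decay = np.exp(-t_ev / (0.25 * period))
        env = attack * decay
        freqs = rng.choice(pitches, size=n_events)
        for k in range(n_events):
            start = int(round(k * period * fs))
            stop = min(start + ev_len, n)
            if stop <= start:
                continue
            f0 = freqs[k]
            seg = t_ev[: stop - start]
            tone = (
                np.sin(2 * np.pi * f0 * seg)
                + 0.5 * np.sin(2 * np.pi * 2 * f0 * seg)
                + 0.25 * np.sin(2 * np.pi * 3 * f0 * seg)
            )
            out[start:stop] += layer_gain * env[: stop - start] * tone

    bed = synth_pink_noise(duration_s, sample_rate, seed=derive_seed(seed or 0, "music-bed"))
    out += 0.02 * bed.samples / max(bed.rms(), 1e-12) * np.abs(out).max()
    out *= 0.9 / np.abs(out).max()
    return AudioTrack(samples=out, sample_rate=fs, bpm=bpm)


def synth_pink_noise(
    duration_s: float,
    sample_rate: float = 22050.0,
    seed: int | None = 0,
    alpha: float = 1.0,
    rms: float = 0.1,
) -> AudioTrack:
    """1/f^alpha noise by spectral shaping of white noise.

    The default alpha = 1 gives pink noise: power spectral density falling
    at -3 dB/octave. alpha = 0 reproduces white noise.
    """
    if duration_s <= 0:
        raise InvalidParameterError("duration must be > 0")
    if not 0.0 <= alpha <= 2.0:
        raise InvalidParameterError("alpha must be in [0, 2]")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * sample_rate))
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / sample_rate)
    shape = np.zeros_like(f)
    shape[1:] = f[1:] ** (-alpha / 2.0)
    x = np.fft.irfft(spec * shape, n=n)
    x *= rms / np.sqrt(np.mean(x**2))
    return AudioTrack(samples=x, sample_rate=sample_rate)


@dataclass(frozen=True)
class CouplingComponent:
    """One stimulus-locked EEG component.

    ``strength`` scales the component amplitude; ``channel_weights`` (one
    gain per channel, None = all ones) shapes its topography; ``drift`` is
    the linear fractional change of strength across the recording
    (drift = 1 ramps the gain from 0.5x to 1.5x, mean 1)."""

    freq: float
    strength: float = 1.0
    channel_weights: tuple[float, ...] | None = None
    drift: float = 0.0

    def __post_init__(self) -> None:
        if self.strength < 0:
            raise InvalidParameterError("strength must be >= 0")


@dataclass(frozen=True)
class CouplingSpec:
    """Coupling components plus the 1/f^alpha background-noise model."""

    components: tuple[CouplingComponent, ...]
    noise_alpha: float = 1.0
    snr_db: float = 0.0


def synth_eeg(
    stim: AudioTrack | np.ndarray,
    spec: CouplingSpec,
    n_channels: int = 8,
    sample_rate: float = 250.0,
    duration_s: float = 60.0,
    seed: int | None = 0,
    channel_labels: tuple[str, ...] | None = None,
    phase_n_cycles: float = 28.0,
) -> EEGRecording:
    """EEG with components phase-locked to the stimulus envelope.

    Each channel is ``sum_f w_ch * strength * g(t) * cos(phi_f(t) + offset_ch)``
    plus 1/f^alpha noise, where ``phi_f`` is the phase of the stimulus
    envelope narrowband-filtered at the component frequency and ``g(t)`` the
    linear drift ramp. The noise is scaled so the broadband
    signal-to-noise ratio equals ``snr_db`` (when any component is active).

    ``stim`` may be an :class:`AudioTrack` or an already-computed broadband
    envelope sampled at ``sample_rate`` (the cheap path when simulating many
    recordings of the same stimulus).

    ``phase_n_cycles`` sets the width of the Morlet filter that extracts the
    envelope phase driving each component. It is deliberately narrow (28
    cycles, ~0.04 f bandwidth): with a wide filter, a component placed at a
    frequency where the envelope is weak would inherit the phase — and hence
    the frequency — of a strong spectral neighbor instead of oscillating at
    its nominal frequency.
    """
    for comp in spec.components:
        if comp.freq >= sample_rate / 2:
            raise InvalidParameterError(f"coupling freq {comp.freq} at or above Nyquist")
    if channel_labels is None:
        channel_labels = tuple(
            DEFAULT_CHANNEL_LABELS[i] if i < len(DEFAULT_CHANNEL_LABELS) else f"Ch{i}"
            for i in range(n_channels)
        )
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * sample_rate))
    if isinstance(stim, AudioTrack):
        if duration_s > stim.duration + 1e-9:
            raise InvalidParameterError("requested duration exceeds stimulus duration")
        env = stimulus_envelope_for_plv(stim, sample_rate)[:n]
    else:
        env = np.asarray(stim, dtype=np.float64)
        if env.shape[0] < n:
            raise InvalidParameterError("envelope shorter than requested duration")
        env = env[:n]
    t_frac = np.arange(n) / max(n - 1, 1)

    sig = np.zeros((n_channels, n))
    for comp in spec.components:
        if comp.strength == 0:
            continue
        phi = np.angle(morlet_analytic(env, comp.freq, sample_rate, phase_n_cycles))
        gain = comp.strength * (1.0 + comp.drift * (t_frac - 0.5))
        w = (
            np.ones(n_channels)
            if comp.channel_weights is None
            else np.asarray(comp.channel_weights, dtype=float)
        )
        offsets = 2.0 * np.pi * np.arange(n_channels) / n_channels
        sig += w[:, None] * gain[None, :] * np.cos(phi[None, :] + offsets[:, None])

    noise = np.empty((n_channels, n))
    for c in range(n_channels):
        noise[c] = synth_pink_noise(
            n / sample_rate, sample_rate, seed=int(rng.integers(2**31)),
            alpha=spec.noise_alpha, rms=1.0,
        ).samples[:n]
    p_sig = np.mean(sig**2)
    if p_sig > 0:
        p_noise_target = p_sig / 10.0 ** (spec.snr_db / 10.0)
        noise *= np.sqrt(p_noise_target / np.mean(noise**2))
    return EEGRecording(
        data=sig + noise, sample_rate=sample_rate, channel_labels=channel_labels
    )


@dataclass(frozen=True)
class EffectMap:
    """Ground-truth effect structure for the SART signal-detection agent.

    Per subject x condition x block, the agent's sensitivity is

        d' = baseline + offset[condition] + block_slope * l(block)
             + asrs_interaction * z(ASRS) * w[condition] * l(block)

    with l the linear block weights (-1 ... +1) and w the per-condition
    interaction weights (default: quadratic -1/+2/-1 over 8/16/32 Hz, 0 for
    the no-modulation baseline). The agent presses when the trial's evidence
    exceeds ``criterion`` (evidence ~ N(d', 1) on go trials, N(0, 1) on
    no-go trials) and emits lognormal RTs when it presses.
    """

    baseline_dprime: float = 2.5
    condition_offsets: dict = field(default_factory=dict)
    block_slope: float = 0.0
    asrs_interaction: float = 0.0
    interaction_weights: dict = field(
        default_factory=lambda: {8: -1.0, 16: 2.0, 32: -1.0}
    )
    criterion: float = 0.2
    rt_median_s: float = 0.35
    rt_sigma: float = 0.25

    def __post_init__(self) -> None:
        if self.rt_sigma <= 0:
            raise InvalidParameterError("rt_sigma must be > 0")

    def cell_dprime(self, condition, l_block: float, z_asrs: float) -> float:
        return (
            self.baseline_dprime
            + self.condition_offsets.get(condition, 0.0)
            + self.block_slope * l_block
            + self.asrs_interaction * z_asrs
            * self.interaction_weights.get(condition, 0.0) * l_block
        )


# ASRS v1.1 total score range and default population parameters for the
# discretized truncated-normal draw
ASRS_RANGE = (0, 72)
DEFAULT_ASRS_DIST = (31.0, 12.0)


def _draw_profiles(n_subjects: int, asrs_dist, rng) -> pd.DataFrame:
    mu, sd = asrs_dist
    scores = np.clip(np.round(rng.normal(mu, sd, size=n_subjects)), *ASRS_RANGE).astype(int)
    median = np.median(scores)
    return pd.DataFrame(
        {
            "subject": np.arange(n_subjects),
            "asrs_score": scores,
            "asrs_group": np.where(scores > median, "high", "low"),
        }
    )


def _block_weights(n_blocks: int) -> np.ndarray:
    return np.linspace(-1.0, 1.0, n_blocks)


def synth_cohort(
    n_subjects: int,
    schedule: TrialSchedule,
    effects: EffectMap,
    conditions: tuple = ("none", 8, 16, 32),
    asrs_dist: tuple[float, float] = DEFAULT_ASRS_DIST,
    seed: int | None = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Trial-level response logs for a simulated cohort.

    Each subject completes ``schedule`` once per condition; the schedule's
    own blocks serve as the trial-block factor (use a 2-block schedule for
    an early/late design). Returns ``(logs, profiles)``: ``logs`` is one row
    per trial (subject, condition, block, trial, digit, is_target, pressed,
    rt_s); ``profiles`` carries each subject's ASRS score and median-split
    group label.
    """
    if n_subjects < 2:
        raise InvalidParameterError("n_subjects must be >= 2")
    rng = np.random.default_rng(seed)
    profiles = _draw_profiles(n_subjects, asrs_dist, rng)
    mu, sd = asrs_dist
    lweights = _block_weights(schedule.n_blocks)
    trials = schedule.trials

    frames = []
    for s in range(n_subjects):
        z = (profiles.loc[s, "asrs_score"] - mu) / sd
        for cond in conditions:
            d_cell = np.array(
                [effects.cell_dprime(cond, lweights[b], z) for b in trials["block"]]
            )
            p_press = np.where(
                trials["is_target"],
                norm.cdf(-effects.criterion),
                norm.cdf(d_cell - effects.criterion),
            )
            pressed = rng.random(len(trials)) < p_press
            rt = np.where(
                pressed,
                rng.lognormal(np.log(effects.rt_median_s), effects.rt_sigma, len(trials)),
                np.nan,
            )
            frames.append(
                pd.DataFrame(
                    {
                        "subject": s,
                        "condition": cond,
                        "block": trials["block"].to_numpy(),
                        "trial": trials["trial"].to_numpy(),
                        "digit": trials["digit"].to_numpy(),
                        "is_target": trials["is_target"].to_numpy(),
                        "pressed": pressed,
                        "rt_s": rt,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True), profiles


def synth_cohort_counts(
    n_subjects: int,
    n_go: int,
    n_nogo: int,
    effects: EffectMap,
    conditions: tuple = ("none", 8, 16, 32),
    n_blocks: int = 2,
    asrs_dist: tuple[float, float] = DEFAULT_ASRS_DIST,
    seed: int | None = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Counts-level fast path for large simulation studies.

    Distributionally identical to scoring :func:`synth_cohort` output (the
    agent's trials are independent, so per-cell hit and false-alarm counts
    are binomial); skips the per-trial bookkeeping. Returns a tidy d' table
    (subject, condition, block, hits, misses, fas, crs, dprime) and the
    profiles frame.
    """
    rng = np.random.default_rng(seed)
    profiles = _draw_profiles(n_subjects, asrs_dist, rng)
    mu, sd = asrs_dist
    z = (profiles["asrs_score"].to_numpy() - mu) / sd
    lw = _block_weights(n_blocks)

    rows = []
    p_fa = norm.cdf(-effects.criterion)
    for cond in conditions:
        for b in range(n_blocks):
            d = np.array([effects.cell_dprime(cond, lw[b], zi) for zi in z])
            hits = rng.binomial(n_go, norm.cdf(d - effects.criterion))
            fas = rng.binomial(n_nogo, p_fa, size=n_subjects)
            hr = (hits + 0.5) / (n_go + 1.0)
            fr = (fas + 0.5) / (n_nogo + 1.0)
            rows.append(
                pd.DataFrame(
                    {
                        "subject": np.arange(n_subjects),
                        "condition": cond,
                        "block": b,
                        "hits": hits,
                        "misses": n_go - hits,
                        "fas": fas,
                        "crs": n_nogo - fas,
                        "dprime": norm.ppf(hr) - norm.ppf(fr),
                    }
                )
            )
    return pd.concat(rows, ignore_index=True), profiles
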