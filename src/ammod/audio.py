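"""Audio container and WAV I/O.

:class:`AudioTrack` is the substrate of every acoustic operation in the
package: a float waveform (one column per channel), its sampling rate, and
optional tempo metadata used by the metrical-alignment machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.io import wavfile

from .errors import InvalidInputError, InvalidParameterError

__all__ = ["AudioTrack", "read_wav", "write_wav"]


@dataclass(frozen=True)
class AudioTrack:
    """A sampled pressure waveform.

    Parameters
    ----------
    samples
        Array of shape ``(n_samples,)`` for mono or ``(n_samples, 2)`` for
        stereo; dimensionless pressure amplitude, conventionally in [-1, 1].
    sample_rate
        Sampling rate in Hz.
    bpm
        Optional tempo metadata (beats per minute) carried along so that
        modulators can be aligned to the metrical grid.
    """

    samples: np.ndarray
    sample_rate: float
    bpm: float | None = field(default=None)

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim == 1:
            pass
        elif samples.ndim == 2 and samples.shape[1] in (1, 2):
            if samples.shape[1] == 1:
                samples = samples[:, 0]
        else:
            raise InvalidInputError(
                f"samples must be mono or stereo, got shape {samples.shape}"
            )
        if samples.shape[0] == 0:
            raise InvalidInputError("empty audio")
        if not self.sample_rate > 0:
            raise InvalidParameterError(f"sample_rate must be > 0, got {self.sample_rate}")
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "sample_rate", float(self.sample_rate))

    @property
    def n_channels(self) -> int:
        return 1 if self.samples.ndim == 1 else self.samples.shape[1]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        """Duration in seconds."""
        return self.n_samples / self.sample_rate

    def mono(self) -> np.ndarray:
        """Mono waveform: the channel average for stereo input."""
        if self.samples.ndim == 1:
            return self.samples
        return self.samples.mean(axis=1)

    def rms(self) -> float:
        """Root-mean-square level, averaged over channels for stereo."""
        if self.samples.ndim == 1:
            return float(np.sqrt(np.mean(self.samples**2)))
        per_channel = np.sqrt(np.mean(self.samples**2, axis=0))
        return float(per_channel.mean())

    def with_samples(self, samples: np.ndarray) -> "AudioTrack":
        return replace(self, samples=samples)


def read_wav(path: str | Path, bpm: float | None = None) -> AudioTrack:
    """Read a PCM (16/24/32-bit) or float32 WAV file into an AudioTrack.

    Integer PCM is rescaled to [-1, 1) by the type's full scale.
    """
    rate, data = wavfile.read(str(path))
    if np.issubdtype(data.dtype, np.integer):
        scale = float(np.iinfo(data.dtype).max) + 1.0
        data = data.astype(np.float64) / scale
    else:
        data = data.astype(np.float64)
    return AudioTrack(samples=data, sample_rate=float(rate), bpm=bpm)


def write_wav(path: str | Path, track: AudioTrack) -> None:
    """Write an AudioTrack as float32 WAV."""
    wavfile.write(str(path), int(round(track.sample_rate)), track.samples.astype(np.float32))
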