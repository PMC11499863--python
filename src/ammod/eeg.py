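"""EEG container and I/O.

The native on-disk format is a plain-text sample matrix (TSV, one column per
channel) with a JSON sidecar holding sampling rate, channel labels and event
onsets. EDF files are read through MNE when available.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import InvalidInputError

__all__ = ["EEGRecording", "read_eeg", "write_eeg", "MONTAGE_GROUPS", "channels_in_groups"]

# 10-20 label prefixes defining named montage groups. AF/FC/CP/TP sites are
# assigned to the frontal/central/parietal groups by their leading letter(s).
MONTAGE_GROUPS = {
    "frontal": ("Fp", "AF", "F"),
    "central": ("FC", "C"),
    "parietal": ("CP", "P"),
    "temporal": ("FT", "T", "TP"),
    "occipital": ("PO", "O"),
}


@dataclass(frozen=True)
class EEGRecording:
    """Multichannel EEG: (n_channels, n_samples) in microvolts."""

    data: np.ndarray
    sample_rate: float
    channel_labels: tuple[str, ...]
    events: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=np.float64)
        if data.ndim != 2 or data.shape[0] < 1:
            raise InvalidInputError("data must be (n_channels, n_samples) with >= 1 channel")
        labels = tuple(self.channel_labels)
        if len(labels) != data.shape[0]:
            raise InvalidInputError("one label per channel required")
        if len(set(labels)) != len(labels):
            raise InvalidInputError("channel labels must be unique")
        if np.isnan(data).any():
            raise InvalidInputError("EEG data contain NaNs")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "channel_labels", labels)
        object.__setattr__(self, "events", np.asarray(self.events, dtype=int))

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate


def channels_in_groups(labels: tuple[str, ...], groups: tuple[str, ...] | str) -> list[int]:
    """Indices of channels whose 10-20 label belongs to the named montage
    group(s) (e.g. ``("frontal", "central", "parietal")``).

    Prefix matching is longest-first so e.g. FC3 lands in "central", not
    "frontal".
    """
    if isinstance(groups, str):
        groups = (groups,)
    for g in groups:
        if g not in MONTAGE_GROUPS:
            raise InvalidInputError(f"unknown montage group {g!r}")
    # map every label to its group via longest matching prefix
    all_prefixes = sorted(
        ((p, g) for g, ps in MONTAGE_GROUPS.items() for p in ps),
        key=lambda t: -len(t[0]),
    )
    out = []
    for i, lab in enumerate(labels):
        for prefix, g in all_prefixes:
            if lab.startswith(prefix):
                if g in groups:
                    out.append(i)
                break
    return out


def write_eeg(path: str | Path, rec: EEGRecording) -> None:
    """Write TSV (samples x channels) plus JSON sidecar."""
    path = Path(path)
    np.savetxt(path, rec.data.T, delimiter="\t", fmt="%.6g")
    sidecar = {
        "sample_rate": rec.sample_rate,
        "channel_labels": list(rec.channel_labels),
        "events": [int(e) for e in rec.events],
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_eeg(path: str | Path) -> EEGRecording:
    """Read EEG from TSV+JSON sidecar, or from EDF (requires MNE)."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        import mne  # deferred: only needed for EDF

        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
        return EEGRecording(
            data=raw.get_data() * 1e6,  # MNE uses volts
            sample_rate=float(raw.info["sfreq"]),
            channel_labels=tuple(raw.ch_names),
        )
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    data = np.loadtxt(path, delimiter="\t", ndmin=2).T
    return EEGRecording(
        data=data,
        sample_rate=float(meta["sample_rate"]),
        channel_labels=tuple(meta["channel_labels"]),
        events=np.asarray(meta.get("events", []), dtype=int),
    )
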