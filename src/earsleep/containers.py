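"""Core in-memory containers: recordings, epochs and hypnograms.

Amplitudes are carried in microvolts (µV) throughout the package; sampling
rates in Hz.  Sleep-stage labels follow AASM nomenclature: ``W`` (wake),
``N1``/``N2``/``N3`` (non-REM depths), plus ``REM`` and ``UNSCORED`` which
are representable in a hypnogram but excluded from classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError

#: Stages that enter automatic classification.
STAGES: tuple[str, ...] = ("W", "N1", "N2", "N3")

#: Every label a hypnogram may carry.
ALL_LABELS: tuple[str, ...] = STAGES + ("REM", "UNSCORED")


@dataclass
class Recording:
    """A multichannel signal matrix in µV.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_samples)
        Signal amplitudes in µV.  A 1-D array is promoted to one channel.
    fs : float
        Sampling rate in Hz, > 0.
    channel_labels : list of str
        One label per channel.
    """

    samples: np.ndarray
    fs: float
    channel_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=np.float64))
        if self.fs <= 0:
            raise InputError(f"sampling rate must be positive, got {self.fs}")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i}" for i in range(self.samples.shape[0])]
        if len(self.channel_labels) != self.samples.shape[0]:
            raise InputError(
                f"{len(self.channel_labels)} channel labels for "
                f"{self.samples.shape[0]} channels"
            )

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        """Return one channel's sample vector by label."""
        try:
            idx = self.channel_labels.index(label)
        except ValueError:
            raise InputError(
                f"channel {label!r} not in {self.channel_labels}"
            ) from None
        return self.samples[idx]


@dataclass
class Epoch:
    """One channel's samples for a single scoring epoch (µV)."""

    samples: np.ndarray
    fs: float
    label: str | None = None
    index: int | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64).ravel()
        if self.fs <= 0:
            raise InputError(f"sampling rate must be positive, got {self.fs}")
        if self.label is not None and self.label not in ALL_LABELS:
            raise InputError(f"unknown stage label {self.label!r}")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs


@dataclass
class Hypnogram:
    """Ordered sleep-stage labels at a fixed epoch duration.

    Labels are validated against :data:`ALL_LABELS`; parsing from text is
    case-insensitive (handled by the reader in :mod:`earsleep.signal_io`).
    """

    labels: list[str]
    epoch_duration: float = 30.0

    def __post_init__(self) -> None:
        self.labels = [str(lab) for lab in self.labels]
        if self.epoch_duration <= 0:
            raise InputError(
                f"epoch duration must be positive, got {self.epoch_duration}"
            )
        for i, lab in enumerate(self.labels):
            if lab not in ALL_LABELS:
                raise InputError(
                    f"unknown stage label {lab!r} at epoch {i}; "
                    f"expected one of {ALL_LABELS}"
                )

    def __len__(self) -> int:
        return len(self.labels)

    def __getitem__(self, i):
        return self.labels[i]

    def __eq__(self, other) -> bool:
        if not isinstance(other, Hypnogram):
            return NotImplemented
        return (
            self.labels == other.labels
            and self.epoch_duration == other.epoch_duration
        )

    def select(self, mask) -> "Hypnogram":
        """New hypnogram keeping epochs where ``mask`` is true."""
        mask = np.asarray(mask, dtype=bool)
        if mask.size != len(self.labels):
            raise InputError(
                f"mask length {mask.size} != hypnogram length {len(self.labels)}"
            )
        kept = [lab for lab, m in zip(self.labels, mask) if m]
        return Hypnogram(kept, self.epoch_duration)
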