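"""Shared in-memory containers for multichannel time-series segments."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass
class MultiTrialSegment:
    """A stack of equal-length multichannel trials.

    Parameters
    ----------
    data
        Real array indexed ``[trial, channel, sample]`` (µV for EEG, arbitrary
        units for simulations).
    fs
        Sampling rate in Hz.
    labels
        Channel names, one per row of the channel axis.
    epoch_tag
        Free-form condition label (e.g. ``"preictal"``).
    t0
        Time of the first sample relative to the recording's reference point,
        in seconds (negative = before the reference).
    """

    data: np.ndarray
    fs: float
    labels: tuple[str, ...]
    epoch_tag: str = ""
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim == 2:  # single trial convenience
            self.data = self.data[None, :, :]
        if self.data.ndim != 3:
            raise ValueError("data must be [trial, channel, sample]")
        self.labels = tuple(self.labels)
        if self.data.shape[1] != len(self.labels):
            raise ValueError(
                f"{self.data.shape[1]} channel rows but {len(self.labels)} labels"
            )
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.data.shape[2] < 2:
            raise ValueError("each trial needs at least 2 samples")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def channel_index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(
                f"channel {label!r} not found; available: {list(self.labels)}"
            ) from None

    def select(self, labels: list[str] | tuple[str, ...]) -> "MultiTrialSegment":
        """Return a view-like copy restricted to ``labels``, in that order."""
        idx = [self.channel_index(l) for l in labels]
        return replace(self, data=self.data[:, idx, :].copy(), labels=tuple(labels))

    def times(self) -> np.ndarray:
        """Sample times in seconds relative to the reference point."""
        return self.t0 + np.arange(self.n_samples) / self.fs
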