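"""Shared in-memory containers."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class MultichannelEpoch:
    """One epoch of multichannel signal.

    Attributes
    ----------
    data:
        Array of shape ``(n_samples, n_channels)``.  Units are microvolts
        for real recordings and arbitrary for synthetic signals.
    rate:
        Sampling rate in Hz.
    channels:
        Channel labels, one per column, in canonical montage order.
    label:
        Optional condition label (e.g. ``"easy"`` / ``"hard"``).
    epoch_id:
        Optional identifier within a recording or dataset.
    """

    data: np.ndarray
    rate: float
    channels: tuple[str, ...]
    label: str | None = None
    epoch_id: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (samples x channels)")
        if self.data.shape[1] != len(self.channels):
            raise ValueError(
                f"{self.data.shape[1]} columns but {len(self.channels)} labels"
            )
        self.channels = tuple(self.channels)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Epoch length in seconds."""
        return self.n_samples / self.rate

    def channel(self, label: str) -> np.ndarray:
        """Return the sample series of one channel by label."""
        return self.data[:, self.channels.index(label)]
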