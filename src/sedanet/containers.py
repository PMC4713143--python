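"""Core data containers shared across the pipeline.

A :class:`Recording` is a continuous multichannel EEG signal in microvolts;
:class:`EpochedData` is its segmented counterpart with rejection bookkeeping.
Both are thin, validated wrappers around numpy arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Sedation levels, in experimental order.
LEVELS = ("baseline", "mild", "moderate", "recovery")


@dataclass
class Recording:
    """Continuous multichannel signal.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    fs : float
        Sampling rate in Hz.
    labels : list of str
        Unique channel names.
    positions : ndarray, shape (n_channels, 3), optional
        Unit-sphere electrode coordinates (needed for spline interpolation).
    """

    data: np.ndarray
    fs: float
    labels: list[str]
    positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if not np.isfinite(self.data).all():
            raise ValueError("data contains NaN or infinite values")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        self.labels = list(self.labels)
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("one label per channel required")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        if self.positions is not None:
            self.positions = np.asarray(self.positions, dtype=float)
            if self.positions.shape != (self.n_channels, 3):
                raise ValueError("positions must be (n_channels, 3)")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def copy(self) -> "Recording":
        return replace(
            self,
            data=self.data.copy(),
            labels=list(self.labels),
            positions=None if self.positions is None else self.positions.copy(),
        )


@dataclass
class EpochedData:
    """Fixed-length epochs with channel/epoch rejection bookkeeping.

    ``retained_epochs`` / ``retained_channels`` index into the *original*
    segmentation so a rejection log entry can always be traced back.
    """

    data: np.ndarray  # (n_epochs, n_channels, n_samples)
    fs: float
    labels: list[str]
    retained_epochs: list[int] = field(default_factory=list)
    retained_channels: list[int] = field(default_factory=list)
    rejection_log: list[dict] = field(default_factory=list)
    positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be 3-D (epochs x channels x samples)")
        if not self.retained_epochs:
            self.retained_epochs = list(range(self.data.shape[0]))
        if not self.retained_channels:
            self.retained_channels = list(range(self.data.shape[1]))
        for name, idx, dim in (
            ("retained_epochs", self.retained_epochs, 0),
            ("retained_channels", self.retained_channels, 1),
        ):
            if len(idx) != self.data.shape[dim]:
                raise ValueError(f"{name} length must match data shape")
            if sorted(set(idx)) != list(idx):
                raise ValueError(f"{name} must be sorted and unique")
        if len(self.labels) != self.data.shape[1]:
            raise ValueError("one label per retained channel required")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def copy(self) -> "EpochedData":
        return replace(
            self,
            data=self.data.copy(),
            labels=list(self.labels),
            retained_epochs=list(self.retained_epochs),
            retained_channels=list(self.retained_channels),
            rejection_log=[dict(e) for e in self.rejection_log],
            positions=None if self.positions is None else self.positions.copy(),
        )
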