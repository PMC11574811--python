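"""Core in-memory containers for multichannel EEG recordings.

An :class:`EEGRecording` is a plain ``(n_channels, n_samples)`` float array in
microvolts plus a sampling rate and unique channel labels.  Sample ``k`` of a
channel is the instant ``k / fs`` seconds (0-based indexing).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InvalidArgumentError

__all__ = ["EEGRecording", "ChannelMask", "PreprocConfig"]


@dataclass
class EEGRecording:
    """Multichannel time series in microvolts.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Channel-major signal matrix, microvolts.
    fs : float
        Sampling rate, Hz.
    channel_labels : list of str
        One unique, non-empty label per channel (e.g. ``"Fz"``).
    id : str
        Recording identifier used as key in exported tables.
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise InvalidArgumentError("data must be a 2-D (channels x samples) array")
        if not self.fs > 0:
            raise InvalidArgumentError(f"fs must be positive, got {self.fs}")
        self.channel_labels = list(self.channel_labels)
        if len(self.channel_labels) != self.data.shape[0]:
            raise InvalidArgumentError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} channels"
            )
        if any(not lab for lab in self.channel_labels):
            raise InvalidArgumentError("channel labels must be non-empty")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise InvalidArgumentError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        """Return one channel by (case-insensitive) label."""
        from .errors import MissingChannelError

        lowered = [lab.lower() for lab in self.channel_labels]
        try:
            idx = lowered.index(label.lower())
        except ValueError:
            raise MissingChannelError(label) from None
        return self.data[idx]

    def with_data(self, data: np.ndarray, fs: float | None = None) -> "EEGRecording":
        """Copy of this recording with new samples (labels and id preserved)."""
        return replace(self, data=data, fs=self.fs if fs is None else fs)


@dataclass
class ChannelMask:
    """Per-channel good/bad flags with reason codes.

    ``reasons[i]`` is a (possibly empty) set drawn from
    ``{"flatline", "correlated", "burst", "drift"}``; a channel is bad iff its
    reason set is non-empty.
    """

    bad: np.ndarray  # bool, one per channel
    reasons: list[set[str]] = field(default_factory=list)

    VALID_REASONS = frozenset({"flatline", "correlated", "burst", "drift"})

    def __post_init__(self) -> None:
        self.bad = np.asarray(self.bad, dtype=bool)
        if not self.reasons:
            self.reasons = [set() for _ in range(self.bad.size)]
        if len(self.reasons) != self.bad.size:
            raise InvalidArgumentError("reasons length must equal channel count")
        for r in self.reasons:
            unknown = set(r) - self.VALID_REASONS
            if unknown:
                raise InvalidArgumentError(f"unknown reason codes: {unknown}")

    @property
    def n_bad(self) -> int:
        return int(self.bad.sum())

    @classmethod
    def all_good(cls, n_channels: int) -> "ChannelMask":
        return cls(bad=np.zeros(n_channels, dtype=bool))


@dataclass
class PreprocConfig:
    """Parameters of the pre-processing chain.

    Defaults follow the standard resting-state protocol: downsample to
    250 Hz, zero-phase FIR band-pass 0.5-40 Hz (Hamming), flatline threshold
    5 s, channel-correlation threshold 0.8, burst threshold 5 robust SDs,
    clip to exactly 300 s, frontal ROI {Fz, F1, F2} and occipital ROI
    {Oz, O1, O2}.
    """

    target_fs: float = 250.0
    band: tuple[float, float] = (0.5, 40.0)
    flatline_s: float = 5.0
    corr_thresh: float = 0.8
    burst_sd: float = 5.0
    clip_s: float = 300.0
    frontal_labels: tuple[str, str, str] = ("Fz", "F1", "F2")
    occipital_labels: tuple[str, str, str] = ("Oz", "O1", "O2")

    def __post_init__(self) -> None:
        low, high = self.band
        if not (0 < low < high < self.target_fs / 2):
            raise InvalidArgumentError(
                f"band {self.band} must satisfy 0 < low < high < target_fs/2"
            )

    @property
    def roi_labels(self) -> tuple[str, ...]:
        return tuple(self.frontal_labels) + tuple(self.occipital_labels)
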