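"""Welch power spectral density estimation and ROI averaging.

The estimator follows the standard resting-state recipe: 3-s Hamming-tapered
segments with 50 % overlap, per-segment linear detrend, density (per-Hz)
normalization, averaged across segments.  Electrode PSDs are averaged in
LINEAR power and log10 is taken afterwards; all downstream peak analysis
operates on the log10 values restricted to the 0.5-40 Hz analysis band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .errors import InsufficientDataError, InvalidArgumentError
from .recording import EEGRecording

__all__ = ["PSDEstimate", "welch_psd", "roi_average_psd", "restrict_band", "roi_psd"]


@dataclass
class PSDEstimate:
    """Frequency grid plus linear and log10 power density.

    ``log_power`` is ``log10(power)`` pointwise; zero-power bins map to
    ``-inf`` (excluded from peak analysis downstream).
    """

    freqs: np.ndarray  # Hz, strictly increasing, uniform
    power: np.ndarray  # linear density, uV^2/Hz
    log_power: np.ndarray

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        self.log_power = np.asarray(self.log_power, dtype=float)
        if not (self.freqs.shape == self.power.shape == self.log_power.shape):
            raise InvalidArgumentError("freqs/power/log_power must share one shape")
        if self.freqs.size >= 2 and not np.all(np.diff(self.freqs) > 0):
            raise InvalidArgumentError("frequency grid must be strictly increasing")
        if np.any(self.power < 0):
            raise InvalidArgumentError("power must be non-negative")

    @property
    def df(self) -> float:
        """Grid spacing in Hz (1/window_s for a Welch estimate)."""
        return float(self.freqs[1] - self.freqs[0])

    @classmethod
    def from_linear(cls, freqs: np.ndarray, power: np.ndarray) -> "PSDEstimate":
        power = np.asarray(power, dtype=float)
        with np.errstate(divide="ignore"):
            log_power = np.where(power > 0, np.log10(np.maximum(power, 1e-300)), -np.inf)
        return cls(freqs=freqs, power=power, log_power=log_power)


def welch_psd(
    series: np.ndarray, fs: float, window_s: float = 3.0, overlap: float = 0.5
) -> PSDEstimate:
    """Welch PSD of one channel (density normalization, Hamming taper).

    Integrating ``power`` over the full [0, fs/2] grid approximates the
    series variance (Parseval), which is what makes the density convention
    testable.
    """
    series = np.asarray(series, dtype=float)
    nperseg = int(round(window_s * fs))
    if series.size < nperseg:
        raise InsufficientDataError(
            f"series ({series.size} samples) shorter than one {window_s}-s window"
        )
    if not 0 <= overlap < 1:
        raise InvalidArgumentError("overlap must lie in [0, 1)")
    freqs, power = signal.welch(
        series,
        fs=fs,
        window="hamming",
        nperseg=nperseg,
        noverlap=int(round(nperseg * overlap)),
        detrend="linear",
        scaling="density",
        average="mean",
    )
    return PSDEstimate.from_linear(freqs, power)


def roi_average_psd(psds: list[PSDEstimate]) -> PSDEstimate:
    """Pointwise mean of linear power across electrodes; log10 recomputed."""
    if not psds:
        raise InvalidArgumentError("need at least one PSD to average")
    grid = psds[0].freqs
    for p in psds[1:]:
        if p.freqs.shape != grid.shape or not np.allclose(p.freqs, grid):
            raise InvalidArgumentError("PSDs must share one frequency grid")
    mean_power = np.mean([p.power for p in psds], axis=0)
    return PSDEstimate.from_linear(grid.copy(), mean_power)


def restrict_band(psd: PSDEstimate, low: float = 0.5, high: float = 40.0) -> PSDEstimate:
    """Restrict to the inclusive [low, high] Hz sub-grid."""
    if low >= high:
        raise InvalidArgumentError("low must be below high")
    keep = (psd.freqs >= low) & (psd.freqs <= high)
    if not keep.any():
        raise InvalidArgumentError(
            f"band [{low}, {high}] Hz does not intersect the grid "
            f"[{psd.freqs[0]}, {psd.freqs[-1]}]"
        )
    return PSDEstimate(
        freqs=psd.freqs[keep].copy(),
        power=psd.power[keep].copy(),
        log_power=psd.log_power[keep].copy(),
    )


def roi_psd(
    roi: EEGRecording,
    window_s: float = 3.0,
    overlap: float = 0.5,
    band: tuple[float, float] = (0.5, 40.0),
) -> PSDEstimate:
    """Convenience: per-channel Welch -> ROI average -> band restriction."""
    psds = [welch_psd(roi.data[i], roi.fs, window_s, overlap) for i in range(roi.n_channels)]
    return restrict_band(roi_average_psd(psds), *band)
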