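"""Autocorrelation function and autocorrelation-window (ACW) statistics.

The intrinsic neural timescale of a channel is indexed by how quickly its
autocorrelation function (ACF) decays.  Three windows are computed from one
ACF evaluation:

* **ACW-50**   -- first lag where the ACF reaches 0.5,
* **ACW-e-1**  -- first lag where it reaches 1/e (the e-folding time of an
  exponential ACF),
* **ACW-0**    -- first lag where it reaches 0 (the first zero crossing).

"Reaches" means the first positive lag whose ACF value is <= the threshold
(thresholds are approached from above for decaying ACFs).  The ACF is the
biased (1/n) estimator of the mean-removed, variance-normalized series,
computed via FFT, which guarantees values in [-1, 1] and positive
semidefiniteness.  If a threshold is never reached within the lag range the
window is *censored* (value clamped to the maximum lag, flag set).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateSignalError, InvalidArgumentError
from .recording import EEGRecording

__all__ = [
    "ACFResult",
    "ACWTriplet",
    "autocorrelation",
    "acw",
    "acw_triplet",
    "roi_average_acw",
    "roi_acw",
    "ACW_THRESHOLDS",
]

#: The three thresholds, in the order (acw50, acw_e, acw0).
ACW_THRESHOLDS = (0.5, float(np.exp(-1.0)), 0.0)

DEFAULT_MAX_LAG_S = 20.0


@dataclass
class ACFResult:
    """Autocorrelation values at lags 0 ... max_lag with spacing 1/fs."""

    lags: np.ndarray  # seconds, lags[0] == 0
    values: np.ndarray  # correlation coefficients, values[0] == 1
    fs: float

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.lags.shape != self.values.shape:
            raise InvalidArgumentError("lags and values must have equal length")


@dataclass
class ACWTriplet:
    """ACW-50, ACW-e-1 and ACW-0 in seconds for one channel or ROI."""

    acw50: float
    acw_e: float
    acw0: float
    censored: tuple[bool, bool, bool] = (False, False, False)

    def values(self) -> tuple[float, float, float]:
        return (self.acw50, self.acw_e, self.acw0)

    @property
    def any_censored(self) -> bool:
        return any(self.censored)


def autocorrelation(
    series: np.ndarray, fs: float, max_lag_s: float = DEFAULT_MAX_LAG_S
) -> ACFResult:
    """Biased FFT-based ACF of the mean-removed series up to ``max_lag_s``."""
    x = np.asarray(series, dtype=float)
    if fs <= 0:
        raise InvalidArgumentError("fs must be positive")
    n = x.size
    if max_lag_s >= n / fs:
        raise InvalidArgumentError(
            f"max_lag_s {max_lag_s} must be below the series duration {n / fs:g} s"
        )
    x = x - x.mean()
    var = float(np.dot(x, x)) / n
    if var == 0:
        raise DegenerateSignalError("series has zero variance")
    max_lag = int(round(max_lag_s * fs))
    # circular FFT autocorrelation with zero padding => linear lag sums
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(spec * np.conj(spec), nfft)[: max_lag + 1] / n
    values = acov / acov[0]
    lags = np.arange(max_lag + 1) / fs
    return ACFResult(lags=lags, values=values, fs=fs)


def acw(acf: ACFResult, threshold: float) -> tuple[float, bool]:
    """First lag (seconds) where the ACF value drops to <= ``threshold``.

    Returns ``(max_lag, True)`` if the ACF stays above the threshold over the
    whole lag range (censored).
    """
    if threshold >= 1:
        raise InvalidArgumentError("threshold must be below 1")
    below = np.flatnonzero(acf.values[1:] <= threshold)
    if below.size == 0:
        return float(acf.lags[-1]), True
    return float(acf.lags[below[0] + 1]), False


def acw_triplet(
    series: np.ndarray, fs: float, max_lag_s: float = DEFAULT_MAX_LAG_S
) -> ACWTriplet:
    """Compute (ACW-50, ACW-e-1, ACW-0) from one ACF evaluation.

    The threshold ordering 0.5 > 1/e > 0 makes acw50 <= acw_e <= acw0 for any
    ACF, censoring aside.
    """
    acf = autocorrelation(series, fs, max_lag_s)
    out, flags = [], []
    for thr in ACW_THRESHOLDS:
        value, cens = acw(acf, thr)
        out.append(value)
        flags.append(cens)
    return ACWTriplet(acw50=out[0], acw_e=out[1], acw0=out[2],
                      censored=(flags[0], flags[1], flags[2]))


def roi_average_acw(triplets: list[ACWTriplet]) -> ACWTriplet:
    """Arithmetic mean per measure across electrodes.

    Censored members propagate their flag; the mean is taken over the
    uncensored values of that measure (all-censored measures keep the
    censored value).
    """
    if not triplets:
        raise InvalidArgumentError("need at least one triplet to average")
    means: list[float] = []
    flags: list[bool] = []
    for k in range(3):
        vals = np.array([t.values()[k] for t in triplets])
        cens = np.array([t.censored[k] for t in triplets])
        flags.append(bool(cens.any()))
        means.append(float(vals[~cens].mean() if (~cens).any() else vals.mean()))
    return ACWTriplet(acw50=means[0], acw_e=means[1], acw0=means[2],
                      censored=(flags[0], flags[1], flags[2]))


def roi_acw(roi: EEGRecording, max_lag_s: float = DEFAULT_MAX_LAG_S) -> ACWTriplet:
    """Per-channel ACW triplets averaged across the ROI's electrodes."""
    trips = [acw_triplet(roi.data[i], roi.fs, max_lag_s) for i in range(roi.n_channels)]
    return roi_average_acw(trips)
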