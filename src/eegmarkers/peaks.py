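"""Spectral peak detection and the seven spectral measures.

All quantities are computed from first principles on the log10 ROI power
spectrum.  A *peak* is a strict interior local maximum (plateaus count once,
at their first index).  Its measures follow the classic peak-finding
conventions:

``power``
    the log10-power height of the local maximum (Y-coordinate);
``frequency``
    its frequency (X-coordinate, Hz);
``prominence``
    height above the *highest minimum*: trace horizontally from the apex to
    the left and right until the signal end or a strictly higher sample is
    reached, take the minimum of each traced segment, and subtract the larger
    of the two minima from the height;
``width``
    the frequency-axis distance between the points where the descending
    slopes cross the half-prominence reference line (linear interpolation
    between grid points);
``max_power`` / ``min_power``
    the extrema of the log10 spectrum over the whole analysis band,
    independent of any peak;
``power_ratio``
    the ratio of the chosen peak's power to the spectrum's maximum power.
    By default this is a ratio of *linear* powers, ``10**(power -
    max_power)``, guaranteed to lie in (0, 1]; dividing the two (negative)
    log values instead is available behind ``ratio_scale="log"``.

Detection applies a minimum prominence (default 0.1 log10 units) and a
minimum inter-peak distance (default 0.4 Hz; the less prominent of two close
peaks is discarded, ties broken toward lower frequency).  The dominant peak
among those with frequency in 3-13 Hz is classified as ``theta`` ([3, 7.5)
Hz) or ``alpha`` ([7.5, 13] Hz); a spectrum with no candidate is ``none``
("flat").
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .errors import InvalidArgumentError
from .spectral import PSDEstimate

__all__ = [
    "SpectralPeak",
    "PeakMeasures",
    "WidthResult",
    "find_local_maxima",
    "compute_prominence",
    "compute_width",
    "detect_peaks",
    "classify_band",
    "spectral_measures",
    "measures_from_psd",
    "THETA_BAND",
    "ALPHA_BAND",
]

THETA_BAND = (3.0, 7.5)  # [3, 7.5) Hz
ALPHA_BAND = (7.5, 13.0)  # [7.5, 13] Hz


@dataclass(frozen=True)
class SpectralPeak:
    """One detected peak on the log10 spectrum."""

    index: int
    frequency: float  # Hz
    height: float  # log10 power ("power" measure)
    prominence: float  # log10-power units
    width: float  # Hz
    left_cross: float  # Hz, x1
    right_cross: float  # Hz, x2
    boundary: bool = False  # a width crossing was clamped to the grid edge

    def __post_init__(self) -> None:
        if self.prominence <= 0:
            raise InvalidArgumentError("prominence must be positive")
        if self.width <= 0:
            raise InvalidArgumentError("width must be positive")
        if not (self.left_cross < self.frequency < self.right_cross):
            raise InvalidArgumentError("crossings must bracket the peak frequency")


@dataclass(frozen=True)
class PeakMeasures:
    """The seven spectral measures (plus band label) for one ROI spectrum.

    Peak-derived fields are ``None`` exactly when ``band == "none"``; the
    band extrema ``max_power``/``min_power`` are always reported.
    """

    band: str  # alpha | theta | none
    power: float | None
    frequency: float | None
    prominence: float | None
    width: float | None
    max_power: float
    min_power: float
    power_ratio: float | None
    boundary: bool = False

    def __post_init__(self) -> None:
        peak_fields = (self.power, self.frequency, self.prominence, self.width,
                       self.power_ratio)
        if (self.band == "none") != all(v is None for v in peak_fields):
            raise InvalidArgumentError(
                "peak fields must be absent exactly when band is 'none'"
            )
        if self.max_power < self.min_power:
            raise InvalidArgumentError("max_power must be >= min_power")


class WidthResult(NamedTuple):
    width: float
    left_cross: float
    right_cross: float
    boundary: bool


def find_local_maxima(values: Sequence[float]) -> list[int]:
    """Indices of strict interior local maxima; plateaus count once, at their
    first index; endpoints are never peaks."""
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise InvalidArgumentError("need at least 3 samples to find local maxima")
    out: list[int] = []
    i = 1
    n = v.size
    while i < n - 1:
        if v[i] > v[i - 1]:
            j = i
            while j < n - 1 and v[j + 1] == v[i]:
                j += 1  # walk the plateau
            if j < n - 1 and v[j + 1] < v[i]:
                out.append(i)
            i = j + 1
        else:
            i += 1
    return out


def _is_local_max(v: np.ndarray, idx: int) -> bool:
    return idx in find_local_maxima(v)


def compute_prominence(values: Sequence[float], peak_index: int) -> float:
    """Prominence of the local maximum at ``peak_index``.

    Trace horizontally from the apex to each side until the signal end or a
    strictly higher sample; the prominence is the height minus the larger of
    the two segment minima.
    """
    v = np.asarray(values, dtype=float)
    if not _is_local_max(v, peak_index):
        raise InvalidArgumentError(f"index {peak_index} is not a local maximum")
    h = v[peak_index]

    def side_min(step: int) -> float:
        lowest = h
        j = peak_index + step
        while 0 <= j < v.size and v[j] <= h:
            lowest = min(lowest, v[j])
            j += step
        return lowest

    return float(h - max(side_min(-1), side_min(+1)))


def compute_width(
    values: Sequence[float],
    grid: Sequence[float],
    peak_index: int,
    prominence: float,
) -> WidthResult:
    """Half-prominence width of the peak at ``peak_index``.

    The reference line sits at ``height - prominence/2``; each crossing is
    located on the descending slope with linear interpolation between grid
    points.  If a slope leaves the grid before reaching the reference line,
    the crossing is clamped to the grid edge and the boundary flag is set.
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(grid, dtype=float)
    if v.shape != g.shape:
        raise InvalidArgumentError("values and grid must have equal length")
    if prominence <= 0:
        raise InvalidArgumentError("prominence must be positive")
    ref = v[peak_index] - prominence / 2.0

    def crossing(step: int) -> tuple[float, bool]:
        j = peak_index + step
        prev = peak_index
        while 0 <= j < v.size:
            if v[j] <= ref:
                # interpolate between (g[prev], v[prev]) and (g[j], v[j])
                if v[j] == v[prev]:
                    return float(g[j]), False
                frac = (v[prev] - ref) / (v[prev] - v[j])
                return float(g[prev] + frac * (g[j] - g[prev])), False
            prev = j
            j += step
        edge = g[0] if step < 0 else g[-1]
        return float(edge), True

    left, left_clamped = crossing(-1)
    right, right_clamped = crossing(+1)
    return WidthResult(right - left, left, right, left_clamped or right_clamped)


def detect_peaks(
    psd: PSDEstimate, min_prominence: float = 0.1, min_distance: float = 0.4
) -> list[SpectralPeak]:
    """All peaks of the band-restricted log10 spectrum passing both thresholds.

    Local maxima with prominence >= ``min_prominence`` (log10 units) are kept;
    among maxima closer than ``min_distance`` Hz only the more prominent
    survives (ties toward lower frequency).  An empty list is a valid outcome
    ("flat" spectrum).
    """
    v = psd.log_power
    if not np.all(np.isfinite(v)):
        raise InvalidArgumentError(
            "log_power must be finite on the analysis band (zero-power bins?)"
        )
    if v.size < 3:
        return []
    candidates = []
    for idx in find_local_maxima(v):
        prom = compute_prominence(v, idx)
        if prom >= min_prominence:
            candidates.append((idx, prom))

    # min-distance pruning: most prominent first, ties toward lower frequency
    candidates.sort(key=lambda c: (-c[1], psd.freqs[c[0]]))
    kept: list[tuple[int, float]] = []
    for idx, prom in candidates:
        if all(abs(psd.freqs[idx] - psd.freqs[k]) >= min_distance for k, _ in kept):
            kept.append((idx, prom))

    peaks = []
    for idx, prom in sorted(kept):
        width = compute_width(v, psd.freqs, idx, prom)
        peaks.append(
            SpectralPeak(
                index=idx, frequency=float(psd.freqs[idx]), height=float(v[idx]),
                prominence=prom, width=width.width, left_cross=width.left_cross,
                right_cross=width.right_cross, boundary=width.boundary,
            )
        )
    return peaks


def classify_band(
    peaks: Sequence[SpectralPeak],
) -> tuple[str, SpectralPeak | None]:
    """Pick the dominant 3-13 Hz peak and label its band.

    Candidates are peaks with frequency in [3, 13] Hz (the union of theta and
    alpha); the one with greatest prominence wins, ties toward lower
    frequency.  Returns ``("none", None)`` when there is no candidate.
    """
    candidates = [p for p in peaks if THETA_BAND[0] <= p.frequency <= ALPHA_BAND[1]]
    if not candidates:
        return "none", None
    chosen = min(candidates, key=lambda p: (-p.prominence, p.frequency))
    band = "alpha" if chosen.frequency >= ALPHA_BAND[0] else "theta"
    return band, chosen


def spectral_measures(
    psd: PSDEstimate,
    band: str,
    chosen: SpectralPeak | None,
    ratio_scale: str = "linear",
) -> PeakMeasures:
    """Assemble the seven spectral measures for one band-restricted spectrum."""
    finite = psd.log_power[np.isfinite(psd.log_power)]
    if finite.size == 0:
        raise InvalidArgumentError("spectrum has no finite log-power values")
    max_power = float(finite.max())
    min_power = float(finite.min())
    if chosen is None or band == "none":
        return PeakMeasures(
            band="none", power=None, frequency=None, prominence=None, width=None,
            max_power=max_power, min_power=min_power, power_ratio=None,
        )
    if ratio_scale == "linear":
        ratio = float(10.0 ** (chosen.height - max_power))
    elif ratio_scale == "log":
        ratio = float(chosen.height / max_power) if max_power != 0 else float("nan")
    else:
        raise InvalidArgumentError(f"unknown ratio_scale {ratio_scale!r}")
    return PeakMeasures(
        band=band, power=chosen.height, frequency=chosen.frequency,
        prominence=chosen.prominence, width=chosen.width,
        max_power=max_power, min_power=min_power, power_ratio=ratio,
        boundary=chosen.boundary,
    )


def measures_from_psd(
    psd: PSDEstimate,
    min_prominence: float = 0.1,
    min_distance: float = 0.4,
    ratio_scale: str = "linear",
) -> PeakMeasures:
    """Detect -> classify -> measure, in one call."""
    peaks = detect_peaks(psd, min_prominence, min_distance)
    band, chosen = classify_band(peaks)
    return spectral_measures(psd, band, chosen, ratio_scale)
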