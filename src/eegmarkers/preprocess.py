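"""The pre-processing chain for resting-state recordings.

Fixed stage order: downsample -> band-pass FIR -> bad-channel detection and
repair -> common average reference -> clip to exact duration -> ROI selection.
Filtering is zero-phase (symmetric linear-phase FIR applied centred), so the
group delay cannot distort downstream autocorrelation-window estimates.

Bad-channel criteria (numeric renderings of the usual verbal rules):

* ``flatline``  -- absolute successive difference below 1e-8 uV for a run
  longer than ``flatline_s`` seconds;
* ``correlated`` -- Pearson correlation with another channel above
  ``corr_thresh`` (the later-indexed channel of the pair is flagged);
* ``burst``     -- any 1-s window whose log RMS exceeds the channel's median
  log window-RMS by more than ``burst_sd`` robust standard deviations
  (1.4826 * MAD of the log values);
* ``drift``     -- reserved reason code, not populated (no threshold is
  defined for low-frequency drifts).

Spherical-spline interpolation of bad channels requires 3-D electrode
geometry, which this package does not model; bad channels are instead
replaced by the mean of the good channels.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .errors import (
    InsufficientDataError,
    InvalidArgumentError,
    MissingChannelError,
    UnrecoverableRecordingError,
)
from .recording import ChannelMask, EEGRecording, PreprocConfig

__all__ = [
    "downsample",
    "bandpass_fir",
    "detect_bad_channels",
    "interpolate_bad",
    "rereference_average",
    "clip_duration",
    "select_rois",
    "preprocess",
]

FLATLINE_EPS_UV = 1e-8


def downsample(rec: EEGRecording, target_fs: float) -> EEGRecording:
    """Anti-alias filter and decimate to ``target_fs`` (a divisor of ``fs``)."""
    if target_fs > rec.fs:
        raise InvalidArgumentError(
            f"target_fs {target_fs} exceeds recording rate {rec.fs}"
        )
    if target_fs <= 0:
        raise InvalidArgumentError("target_fs must be positive")
    factor = rec.fs / target_fs
    if abs(factor - round(factor)) > 1e-9:
        raise InvalidArgumentError(
            f"fs {rec.fs} is not an integer multiple of target_fs {target_fs}"
        )
    factor = int(round(factor))
    if factor == 1:
        return rec.with_data(rec.data.copy())
    out = signal.decimate(rec.data, factor, ftype="fir", zero_phase=True, axis=1)
    return rec.with_data(out, fs=target_fs)


def _fir_taps(low: float, high: float, fs: float) -> np.ndarray:
    # transition-width heuristic: length ~ 3 periods of the lowest band edge
    n_taps = int(round(3.0 * fs / low))
    if n_taps % 2 == 0:
        n_taps += 1  # odd length => symmetric, integer group delay
    return signal.firwin(n_taps, [low, high], pass_zero=False, window="hamming", fs=fs)


def bandpass_fir(rec: EEGRecording, low: float, high: float) -> EEGRecording:
    """Zero-phase Hamming-window FIR band-pass between ``low`` and ``high`` Hz.

    The symmetric kernel is applied centred (linear phase, delay compensated)
    on reflection-padded data, giving zero phase distortion and clean edges.
    """
    if not (0 < low < high < rec.fs / 2):
        raise InvalidArgumentError(
            f"band ({low}, {high}) must satisfy 0 < low < high < Nyquist={rec.fs / 2}"
        )
    taps = _fir_taps(low, high, rec.fs)
    half = len(taps) // 2
    if rec.n_samples <= half:
        raise InsufficientDataError("recording shorter than the filter kernel")
    padded = np.pad(rec.data, [(0, 0), (half, half)], mode="reflect")
    out = signal.fftconvolve(padded, taps[None, :], mode="same", axes=1)
    return rec.with_data(out[:, half:-half])


def _flatline_run(x: np.ndarray, fs: float, flatline_s: float) -> bool:
    quiet = np.abs(np.diff(x)) < FLATLINE_EPS_UV
    if not quiet.any():
        return False
    # longest run of consecutive True values
    edges = np.diff(np.concatenate([[0], quiet.view(np.int8), [0]]))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    longest = (ends - starts).max() if starts.size else 0
    return longest / fs > flatline_s


def _burst_windows(x: np.ndarray, fs: float, burst_sd: float) -> bool:
    # RMS per 1-s portion, compared on a log scale to the channel's own
    # baseline (median +/- robust SD); the log keeps the statistic
    # near-symmetric for narrowband signals whose envelope fluctuates
    win = int(round(fs))
    n_win = x.size // win
    if n_win < 3:
        return False
    rms = np.sqrt((x[: n_win * win].reshape(n_win, win) ** 2).mean(axis=1))
    rms = rms[rms > 0]  # silent windows are flatline territory, not bursts
    if rms.size < 3:
        return False
    log_rms = np.log(rms)
    med = np.median(log_rms)
    mad = np.median(np.abs(log_rms - med))
    robust_sd = 1.4826 * mad
    if robust_sd == 0:
        return bool((log_rms > med).any())
    return bool((log_rms > med + burst_sd * robust_sd).any())


def detect_bad_channels(rec: EEGRecording, config: PreprocConfig | None = None) -> ChannelMask:
    """Flag flatline, mutually correlated and burst-contaminated channels."""
    config = config or PreprocConfig()
    if rec.duration_s <= config.flatline_s:
        raise InsufficientDataError(
            f"recording ({rec.duration_s:g} s) not longer than flatline_s "
            f"({config.flatline_s:g} s)"
        )
    n = rec.n_channels
    reasons: list[set[str]] = [set() for _ in range(n)]

    for i in range(n):
        if _flatline_run(rec.data[i], rec.fs, config.flatline_s):
            reasons[i].add("flatline")
        if _burst_windows(rec.data[i], rec.fs, config.burst_sd):
            reasons[i].add("burst")

    sd = rec.data.std(axis=1)
    valid = sd > 0
    if valid.sum() >= 2:
        z = rec.data[valid] - rec.data[valid].mean(axis=1, keepdims=True)
        z /= z.std(axis=1, keepdims=True)
        corr = z @ z.T / rec.n_samples
        idx = np.flatnonzero(valid)
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                if corr[a, b] > config.corr_thresh:
                    reasons[idx[b]].add("correlated")  # later-indexed one

    bad = np.array([len(r) > 0 for r in reasons])
    return ChannelMask(bad=bad, reasons=reasons)


def interpolate_bad(rec: EEGRecording, mask: ChannelMask) -> EEGRecording:
    """Replace bad channels by the mean of the good ones (labels preserved)."""
    if mask.bad.size != rec.n_channels:
        raise InvalidArgumentError("mask length does not match channel count")
    if not mask.bad.any():
        return rec.with_data(rec.data.copy())
    good = ~mask.bad
    if not good.any():
        raise UnrecoverableRecordingError("all channels are bad")
    out = rec.data.copy()
    out[mask.bad] = rec.data[good].mean(axis=0)
    return rec.with_data(out)


def rereference_average(rec: EEGRecording) -> EEGRecording:
    """Common average reference: subtract the across-channel mean per sample."""
    if rec.n_channels < 2:
        raise InvalidArgumentError("average reference needs at least 2 channels")
    return rec.with_data(rec.data - rec.data.mean(axis=0, keepdims=True))


def clip_duration(rec: EEGRecording, clip_s: float = 300.0) -> EEGRecording:
    """Keep exactly the first ``clip_s`` seconds."""
    n_keep = int(round(clip_s * rec.fs))
    if rec.n_samples < n_keep:
        raise InsufficientDataError(
            f"recording has {rec.n_samples} samples, needs {n_keep}"
        )
    return rec.with_data(rec.data[:, :n_keep].copy())


def select_rois(
    rec: EEGRecording, config: PreprocConfig | None = None
) -> tuple[EEGRecording, EEGRecording]:
    """Extract the frontal and occipital 3-channel sub-recordings.

    Label matching is case-insensitive; output channel order follows the
    config.  A missing electrode raises :class:`MissingChannelError` naming it.
    """
    config = config or PreprocConfig()
    lowered = {lab.lower(): i for i, lab in enumerate(rec.channel_labels)}

    def pick(wanted: tuple[str, ...]) -> EEGRecording:
        rows = []
        for lab in wanted:
            if lab.lower() not in lowered:
                raise MissingChannelError(lab)
            rows.append(lowered[lab.lower()])
        return EEGRecording(
            data=rec.data[rows].copy(), fs=rec.fs,
            channel_labels=list(wanted), id=rec.id,
        )

    return pick(tuple(config.frontal_labels)), pick(tuple(config.occipital_labels))


def preprocess(
    rec: EEGRecording, config: PreprocConfig | None = None
) -> tuple[EEGRecording, ChannelMask]:
    """Run the full fixed-order chain; returns the cleaned recording and mask."""
    config = config or PreprocConfig()
    rec = downsample(rec, config.target_fs)
    rec = bandpass_fir(rec, *config.band)
    mask = detect_bad_channels(rec, config)
    rec = interpolate_bad(rec, mask)
    rec = rereference_average(rec)
    rec = clip_duration(rec, config.clip_s)
    return rec, mask
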