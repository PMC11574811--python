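"""Synthetic resting-state EEG with known ground truth.

The generator produces 5-minute multichannel recordings whose region-of-interest
channels carry three controllable ingredients:

* a 1/f^e aperiodic background (spectrally shaped white noise),
* an optional band-limited stochastic oscillation (Gaussian spectral bump,
  alpha or theta), which is what the downstream peak analysis detects, and
* a first-order autoregressive (AR(1), i.e. discretized Ornstein-Uhlenbeck)
  component with a prescribed correlation-decay timescale tau, which is what
  the autocorrelation-window (ACW) statistics estimate.

Cohorts add a latent mediation structure: a per-subject "peak power" latent
``x`` drives the oscillation amplitude, an "ACW" latent ``m = a*x + noise``
drives the AR timescale, and a behavioural latent ``y = b*m + noise`` is
discretized to a CRS-R-like 0-23 ordinal score.  The product ``a*b`` is
therefore a recoverable indirect effect with known ground truth.  Latents are
kept unit-variance so that ``(a, b)`` are standardized path coefficients.

Every function is a pure function of ``(parameters, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .errors import InvalidArgumentError
from .recording import EEGRecording

__all__ = [
    "PhenotypeParams",
    "GroundTruth",
    "PHENOTYPES",
    "simulate_aperiodic",
    "add_band_oscillation",
    "simulate_ar1",
    "simulate_subject",
    "simulate_cohort",
]

#: Default channel set: the two regions of interest used throughout.
DEFAULT_LABELS = ("Fz", "F1", "F2", "Oz", "O1", "O2")

#: Required labels for a simulated subject (frontal + occipital ROI).
REQUIRED_LABELS = frozenset(lab.lower() for lab in DEFAULT_LABELS)

#: Standard deviation of the aperiodic background relative to the unit-SD
#: AR component.  Kept small so the AR component dominates the short-lag
#: autocorrelation while the 1/f trend still shapes the spectrum.
APERIODIC_SD = 0.3

#: Overall output scale (microvolt RMS of a simulated channel).
OUTPUT_RMS_UV = 20.0

#: Log-scale sensitivity of the per-subject oscillation amplitude to the
#: peak-power latent, and of the AR timescale to the ACW latent.  The
#: amplitude factor is kept small because a stronger oscillation also
#: *shortens* the measured ACW (its autocorrelation crosses zero at a quarter
#: period), which would confound the latent power -> timescale path; the
#: timescale factor is larger so the ACW latent dominates the measured ACW.
#: Both keep the lognormal latent -> measured mapping near-linear over
#: +/- 2 SD.
AMP_LOGSCALE = 0.25
TAU_LOGSCALE = 0.45


@dataclass(frozen=True)
class PhenotypeParams:
    """Spectral/temporal ground truth of one simulated subject class.

    Parameters
    ----------
    label : str
        One of ``control``, ``doc_alpha``, ``doc_theta``, ``doc_flat``.
    aperiodic_exponent : float
        Slope magnitude of log-power vs log-frequency (power ~ 1/f^e), >= 0.
    oscillation_center_hz : float or None
        Center of the band-limited oscillation; ``None`` for no oscillation.
        When present it must lie in [3, 13] Hz (theta/alpha range).
    oscillation_bandwidth_hz : float
        Full bandwidth (2 sigma) of the Gaussian spectral bump, Hz.
    oscillation_amplitude : float
        SD of the oscillation relative to the unit-SD AR background.
    ar_timescale_s : float
        Target autocorrelation e-folding time tau of the AR component, s.
    delta_amplitude : float
        SD (relative units) of a low-frequency (~0.5-2 Hz) band component.
        Real resting EEG carries most of its spectral density in the delta
        range; without it the detected theta/alpha peak would be the global
        spectrum maximum and the power-ratio measure degenerate at 1.
    """

    label: str
    aperiodic_exponent: float
    oscillation_center_hz: float | None
    oscillation_bandwidth_hz: float
    oscillation_amplitude: float
    ar_timescale_s: float
    delta_amplitude: float = 0.0

    def __post_init__(self) -> None:
        if self.ar_timescale_s <= 0:
            raise InvalidArgumentError("ar_timescale_s must be positive")
        if self.aperiodic_exponent < 0:
            raise InvalidArgumentError("aperiodic_exponent must be >= 0")
        if self.oscillation_center_hz is not None and not (
            3.0 <= self.oscillation_center_hz <= 13.0
        ):
            raise InvalidArgumentError(
                "oscillation_center_hz must lie in [3, 13] Hz when present"
            )


#: Default phenotypes.  Healthy controls carry a clear alpha bump and a short
#: timescale; DOC phenotypes shift the peak to theta (doc_theta), keep a
#: weakened alpha peak (doc_alpha, the minority seen clinically), or lose the
#: peak entirely while the timescale lengthens further (doc_flat).
PHENOTYPES: dict[str, PhenotypeParams] = {
    "control": PhenotypeParams("control", 1.0, 10.0, 2.0, 0.8, 0.03, 0.7),
    "doc_alpha": PhenotypeParams("doc_alpha", 1.3, 9.0, 2.0, 0.45, 0.055, 0.75),
    "doc_theta": PhenotypeParams("doc_theta", 1.3, 5.0, 2.0, 0.6, 0.038, 0.8),
    "doc_flat": PhenotypeParams("doc_flat", 1.5, None, 2.0, 0.0, 0.11, 0.85),
}

#: Center and full bandwidth (Hz) of the delta-range background component.
DELTA_BAND = (1.0, 1.5)


@dataclass
class GroundTruth:
    """What the generator actually put into one recording."""

    phenotype: PhenotypeParams
    crs_r_score: int | None  # present iff not a control
    mediation_paths: tuple[float, float]
    seed: int
    group: str = "control"  # control | MCS | UWS
    latent_power: float = 0.0  # x: drives oscillation amplitude
    latent_acw: float = 0.0  # m = a*x + noise: drives AR timescale
    latent_score: float = 0.0  # y = b*m + noise: behind the CRS-R score
    recording_id: str = ""

    def __post_init__(self) -> None:
        is_control = self.phenotype.label == "control"
        if is_control != (self.crs_r_score is None):
            raise InvalidArgumentError(
                "crs_r_score must be present iff the phenotype is not control"
            )


def _rng(seed: int | np.random.SeedSequence) -> np.random.Generator:
    return np.random.default_rng(seed)


def simulate_aperiodic(
    duration_s: float, fs: float, exponent: float, seed: int | np.random.SeedSequence
) -> np.ndarray:
    """Zero-mean, unit-SD noise whose expected PSD follows 1/f^exponent.

    Synthesis is by frequency-domain shaping: white Gaussian noise is
    transformed, its amplitudes multiplied by f^(-exponent/2) (DC removed),
    and transformed back.  This gives the exact expected spectrum in
    O(n log n).
    """
    if duration_s <= 0 or fs <= 0:
        raise InvalidArgumentError("duration_s and fs must be positive")
    if exponent < 0:
        raise InvalidArgumentError("exponent must be >= 0")
    n = int(round(duration_s * fs))
    rng = _rng(seed)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.zeros_like(freqs)
    nonzero = freqs > 0
    shape[nonzero] = freqs[nonzero] ** (-exponent / 2.0)
    series = np.fft.irfft(spec * shape, n=n)
    series -= series.mean()
    sd = series.std()
    if sd > 0:
        series /= sd
    return series


def add_band_oscillation(
    series: np.ndarray,
    fs: float,
    center_hz: float,
    bandwidth_hz: float,
    amplitude: float,
    seed: int | np.random.SeedSequence,
) -> np.ndarray:
    """Add a narrowband stochastic oscillation to ``series``.

    The oscillation is white noise shaped by a Gaussian spectral window
    centred at ``center_hz`` with sigma ``bandwidth_hz / 2`` -- band-pass
    filtered noise rather than a pure sinusoid, so the resulting spectral
    peak has a realistic, measurable width.  Its SD is ``amplitude`` times
    the SD of the input series; ``amplitude = 0`` returns the input
    unchanged.
    """
    series = np.asarray(series, dtype=float)
    if not (0 < center_hz < fs / 2):
        raise InvalidArgumentError(
            f"center_hz must lie in (0, Nyquist={fs / 2} Hz), got {center_hz}"
        )
    if bandwidth_hz <= 0:
        raise InvalidArgumentError("bandwidth_hz must be positive")
    if amplitude < 0:
        raise InvalidArgumentError("amplitude must be >= 0")
    if amplitude == 0:
        return series
    n = series.size
    rng = _rng(seed)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    sigma_f = bandwidth_hz / 2.0
    window = np.exp(-0.5 * ((freqs - center_hz) / sigma_f) ** 2)
    osc = np.fft.irfft(spec * window, n=n)
    osc -= osc.mean()
    sd = osc.std()
    if sd > 0:
        osc /= sd
    return series + amplitude * float(series.std()) * osc


def simulate_ar1(
    phi: float, n: int, fs: float, seed: int | np.random.SeedSequence
) -> np.ndarray:
    """Stationary AR(1) series with lag-k autocorrelation phi^k.

    Innovation variance is ``1 - phi**2`` so the series has unit variance,
    keeping signal-to-noise ratios interpretable when components are mixed.
    The first sample is drawn from the stationary distribution (no burn-in
    needed).
    """
    if not abs(phi) < 1:
        raise InvalidArgumentError(f"|phi| must be < 1 for stationarity, got {phi}")
    if n <= 1:
        raise InvalidArgumentError("n must be > 1")
    if fs <= 0:
        raise InvalidArgumentError("fs must be positive")
    rng = _rng(seed)
    innovations = rng.standard_normal(n) * np.sqrt(1.0 - phi**2)
    innovations[0] = rng.standard_normal()  # stationary start, unit variance
    series, _ = signal.lfilter([1.0], [1.0, -phi], innovations, zi=[0.0])
    return series


def phi_for_timescale(tau_s: float, fs: float) -> float:
    """Lag-one coefficient giving an ACF e-folding time of ``tau_s`` seconds."""
    if tau_s <= 0:
        raise InvalidArgumentError("tau_s must be positive")
    return float(np.exp(-1.0 / (fs * tau_s)))


def _simulate_channel(
    phenotype: PhenotypeParams,
    fs: float,
    duration_s: float,
    seed: np.random.SeedSequence,
) -> np.ndarray:
    """One channel: AR(1) core + aperiodic background + optional oscillation."""
    n = int(round(duration_s * fs))
    ar_seed, ap_seed, delta_seed, osc_seed = seed.spawn(4)
    x = simulate_ar1(phi_for_timescale(phenotype.ar_timescale_s, fs), n, fs, ar_seed)
    x = x + APERIODIC_SD * simulate_aperiodic(
        duration_s, fs, phenotype.aperiodic_exponent, ap_seed
    )
    if phenotype.delta_amplitude > 0:
        rel = phenotype.delta_amplitude / float(x.std())
        x = add_band_oscillation(x, fs, DELTA_BAND[0], DELTA_BAND[1], rel, delta_seed)
    if phenotype.oscillation_center_hz is not None and phenotype.oscillation_amplitude > 0:
        # amplitude is specified relative to the unit-SD AR background, while
        # add_band_oscillation scales by the SD of its input; compensate.
        rel = phenotype.oscillation_amplitude / float(x.std())
        x = add_band_oscillation(
            x, fs, phenotype.oscillation_center_hz,
            phenotype.oscillation_bandwidth_hz, rel, osc_seed,
        )
    return x * (OUTPUT_RMS_UV / float(x.std()))


def simulate_subject(
    phenotype: PhenotypeParams,
    n_channels: int = 6,
    channel_labels: tuple[str, ...] | list[str] | None = None,
    fs: float = 250.0,
    duration_s: float = 300.0,
    seed: int | np.random.SeedSequence = 0,
    recording_id: str = "",
    ground_truth: GroundTruth | None = None,
) -> tuple[EEGRecording, GroundTruth]:
    """Simulate one recording whose ROI channels carry ``phenotype``.

    Channels are independent realizations of the same phenotype (each with a
    child seed), so ROI averaging behaves as it does for real electrodes with
    mostly uncorrelated noise.
    """
    if channel_labels is None:
        channel_labels = list(DEFAULT_LABELS)[:n_channels] if n_channels <= 6 else (
            list(DEFAULT_LABELS) + [f"E{i}" for i in range(n_channels - 6)]
        )
    channel_labels = list(channel_labels)
    if len(channel_labels) != n_channels:
        raise InvalidArgumentError("channel_labels length must equal n_channels")
    present = {lab.lower() for lab in channel_labels}
    missing = REQUIRED_LABELS - present
    if missing:
        raise InvalidArgumentError(f"missing required ROI labels: {sorted(missing)}")

    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    child_seeds = root.spawn(n_channels)
    data = np.vstack(
        [_simulate_channel(phenotype, fs, duration_s, s) for s in child_seeds]
    )
    seed_int = int(root.entropy) if isinstance(root.entropy, int) else 0
    rec = EEGRecording(
        data=data, fs=fs, channel_labels=channel_labels,
        id=recording_id or f"{phenotype.label}-{seed_int}",
    )
    if ground_truth is None:
        crs = None if phenotype.label == "control" else 0
        ground_truth = GroundTruth(
            phenotype=phenotype, crs_r_score=crs, mediation_paths=(0.0, 0.0),
            seed=seed_int, recording_id=rec.id,
        )
    return rec, ground_truth


def _modulated(base: PhenotypeParams, amp_latent: float, acw_latent: float) -> PhenotypeParams:
    """Per-subject phenotype: latents modulate amplitude and timescale."""
    amp = base.oscillation_amplitude * float(np.exp(AMP_LOGSCALE * amp_latent))
    tau = base.ar_timescale_s * float(np.exp(TAU_LOGSCALE * acw_latent))
    return PhenotypeParams(
        base.label, base.aperiodic_exponent, base.oscillation_center_hz,
        base.oscillation_bandwidth_hz, amp, tau, base.delta_amplitude,
    )


#: Phenotype mixture among patients, close to the observed occurrence of
#: alpha / theta / no peak among DOC recordings.
DOC_PHENOTYPE_PROBS = {"doc_alpha": 0.10, "doc_theta": 0.30, "doc_flat": 0.60}


def simulate_cohort(
    n_control: int = 25,
    n_mcs: int = 47,
    n_uws: int = 48,
    paths: tuple[float, float] = (0.6, 0.5),
    noise_sd: float = 1.0,
    seed: int = 0,
    fs: float = 250.0,
    duration_s: float = 300.0,
) -> tuple[list[EEGRecording], list[GroundTruth]]:
    """Simulate a whole cohort with a known mediation structure.

    Per patient, unit-variance latents are drawn as::

        x ~ N(0, 1)                                (peak-power latent)
        m = a*x + noise_sd * sqrt(1 - a^2) * e1    (ACW latent)
        y = b*m + noise_sd * sqrt(1 - b^2) * e2    (behavioural latent)

    so with ``noise_sd = 1`` all three latents have unit variance and the
    standardized indirect effect is exactly ``a*b``.  The CRS-R-like score is
    a clipped, rounded affine transform of ``y``; the ``n_mcs`` highest
    scores are labelled MCS and the rest UWS, which gives MCS the higher
    score range without adding variance orthogonal to the mediation paths.

    Controls draw the same latents (for realistic within-group spread) but
    receive no score.
    """
    if n_control < 0 or n_mcs < 0 or n_uws < 0:
        raise InvalidArgumentError("cohort counts must be >= 0")
    if n_control + n_mcs + n_uws == 0:
        raise InvalidArgumentError("at least one cohort count must be positive")
    if noise_sd <= 0:
        raise InvalidArgumentError("noise_sd must be positive")
    a, b = paths
    root = np.random.SeedSequence(seed)
    latent_seed, pheno_seed, *_ = root.spawn(2)
    rng = _rng(latent_seed)

    n_patients = n_mcs + n_uws
    n_total = n_control + n_patients
    x = rng.standard_normal(n_total)
    m = a * x + noise_sd * np.sqrt(max(0.0, 1.0 - a * a)) * rng.standard_normal(n_total)
    y = b * m + noise_sd * np.sqrt(max(0.0, 1.0 - b * b)) * rng.standard_normal(n_total)

    # CRS-R-like ordinal score: centre 11.5, spread covering 0-23 at ~2.5 SD.
    score = np.clip(np.round(11.5 + 4.5 * y), 0, 23).astype(int)

    pheno_rng = _rng(pheno_seed)
    labels = list(DOC_PHENOTYPE_PROBS)
    probs = np.array([DOC_PHENOTYPE_PROBS[k] for k in labels])
    patient_phenos = pheno_rng.choice(labels, size=n_patients, p=probs)

    # MCS = the n_mcs highest-scoring patients (stable order on ties).
    patient_idx = np.arange(n_control, n_total)
    order = np.argsort(-score[patient_idx], kind="stable")
    groups = np.empty(n_patients, dtype=object)
    groups[order[:n_mcs]] = "MCS"
    groups[order[n_mcs:]] = "UWS"

    rec_seeds = root.spawn(n_total)
    recordings: list[EEGRecording] = []
    truths: list[GroundTruth] = []
    for i in range(n_total):
        if i < n_control:
            base, group, crs = PHENOTYPES["control"], "control", None
        else:
            j = i - n_control
            base, group, crs = PHENOTYPES[str(patient_phenos[j])], str(groups[j]), int(score[i])
        pheno = _modulated(base, x[i], m[i])
        rec_id = f"{group.lower()}-{i:03d}"
        gt = GroundTruth(
            phenotype=pheno, crs_r_score=crs, mediation_paths=(a, b), seed=seed,
            group=group, latent_power=float(x[i]), latent_acw=float(m[i]),
            latent_score=float(y[i]), recording_id=rec_id,
        )
        rec, gt = simulate_subject(
            pheno, fs=fs, duration_s=duration_s, seed=rec_seeds[i],
            recording_id=rec_id, ground_truth=gt,
        )
        recordings.append(rec)
        truths.append(gt)
    return recordings, truths
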