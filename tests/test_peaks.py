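"""Peak analysis: maxima, prominence, width, detection, band classification.

The prominence/width implementations are checked exactly against (a) an
independent brute-force oracle that literally walks the textual definition
and (b) scipy's peak routines on strictly-valued sequences.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import signal as sps

from eegmarkers.errors import InvalidArgumentError
from eegmarkers.peaks import (
    SpectralPeak,
    classify_band,
    compute_prominence,
    compute_width,
    detect_peaks,
    find_local_maxima,
    measures_from_psd,
    spectral_measures,
)
from eegmarkers.spectral import PSDEstimate


def oracle_prominence(values, peak_index):
    """Brute-force trace: walk from the apex until the signal end or a
    strictly higher sample; the prominence is the height minus the larger of
    the two traversed minima."""
    h = values[peak_index]
    mins = []
    for step in (-1, +1):
        seen = []
        j = peak_index + step
        while 0 <= j < len(values) and values[j] <= h:
            seen.append(values[j])
            j += step
        mins.append(min(seen) if seen else h)
    return h - max(mins)


def oracle_width(values, peak_index, prominence):
    """Brute-force half-prominence width with per-segment interpolation."""
    ref = values[peak_index] - prominence / 2.0
    crossings = []
    for step in (-1, +1):
        prev, j, found = peak_index, peak_index + step, None
        while 0 <= j < len(values):
            if values[j] <= ref:
                if values[j] == values[prev]:
                    found = float(j)
                else:
                    frac = (values[prev] - ref) / (values[prev] - values[j])
                    found = prev + frac * (j - prev)
                break
            prev, j = j, j + step
        if found is None:
            found = 0.0 if step < 0 else float(len(values) - 1)
        crossings.append(found)
    return crossings[1] - crossings[0]


def _psd(freqs, log_power):
    freqs = np.asarray(freqs, dtype=float)
    log_power = np.asarray(log_power, dtype=float)
    return PSDEstimate(freqs=freqs, power=10.0**log_power, log_power=log_power)


class TestLocalMaxima:
    def test_textbook_sequence(self):
        assert find_local_maxima([0, 2, 1, 3, 0]) == [1, 3]

    def test_monotone_sequence_has_none(self):
        assert find_local_maxima([5, 4, 3, 2, 1]) == []

    def test_plateau_counted_once_at_start(self):
        assert find_local_maxima([0, 1, 1, 0]) == [1]
        assert find_local_maxima([0, 2, 2, 2, 1, 3, 0]) == [1, 5]

    def test_endpoints_never_peaks(self):
        assert find_local_maxima([3, 1, 2]) == []

    def test_too_short_rejected(self):
        with pytest.raises(InvalidArgumentError):
            find_local_maxima([1, 2])


class TestProminence:
    def test_worked_example_half_log_unit(self):
        """A peak of height -3.2 whose highest flanking minimum is -3.7 has
        prominence 0.5 exactly."""
        values = [-3.7, -3.45, -3.2, -3.5, -3.7, -3.9]
        assert compute_prominence(values, 2) == pytest.approx(0.5, abs=1e-12)

    def test_interleaved_peaks(self):
        values = [0, 2, 1, 3, 0]
        assert compute_prominence(values, 3) == 3
        assert compute_prominence(values, 1) == 1

    def test_peak_on_flat_zero_baseline(self):
        values = [0, 0, 0, 4.5, 0, 0]
        assert compute_prominence(values, 3) == 4.5

    def test_non_maximum_rejected(self):
        with pytest.raises(InvalidArgumentError):
            compute_prominence([0, 2, 1, 3, 0], 2)

    def test_matches_bruteforce_oracle_on_random_sequences(self):
        rng = np.random.default_rng(7)
        checked = 0
        while checked < 1000:
            n = int(rng.integers(20, 201))
            values = rng.standard_normal(n)
            for idx in find_local_maxima(values):
                assert compute_prominence(values, idx) == pytest.approx(
                    oracle_prominence(values, idx), abs=0.0), (values, idx)
                checked += 1

    def test_matches_scipy_on_strict_sequences(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            values = rng.standard_normal(100)
            peaks, _ = sps.find_peaks(values)
            proms = sps.peak_prominences(values, peaks)[0]
            assert find_local_maxima(values) == list(peaks)
            for idx, prom in zip(peaks, proms):
                assert compute_prominence(values, idx) == pytest.approx(prom)


class TestWidth:
    def test_triangular_peak_crossings_9_and_11(self):
        """Symmetric triangle over [8, 12] Hz with apex at 10: the
        half-prominence line crosses at 9 and 11, width 2."""
        grid = np.arange(0, 20.5, 0.5)
        values = np.maximum(-1.0, -0.5 * np.abs(grid - 10.0))
        idx = int(np.flatnonzero(grid == 10.0)[0])
        prom = compute_prominence(values, idx)
        assert prom == pytest.approx(1.0)
        res = compute_width(values, grid, idx, prom)
        assert res.left_cross == pytest.approx(9.0, abs=1e-12)
        assert res.right_cross == pytest.approx(11.0, abs=1e-12)
        assert res.width == pytest.approx(2.0, abs=1e-12)
        assert not res.boundary

    def test_slope_leaving_grid_clamped_with_flag(self):
        grid = np.array([8.0, 9.0, 10.0, 11.0])
        values = np.array([3.9, 3.95, 4.0, 0.0])
        res = compute_width(values, grid, 2, 4.0)
        assert res.boundary
        assert res.left_cross == 8.0

    def test_matches_bruteforce_oracle_on_random_sequences(self):
        rng = np.random.default_rng(9)
        checked = 0
        while checked < 1000:
            values = rng.standard_normal(int(rng.integers(20, 201)))
            grid = np.arange(values.size, dtype=float)
            for idx in find_local_maxima(values):
                prom = compute_prominence(values, idx)
                got = compute_width(values, grid, idx, prom)
                assert got.width == pytest.approx(
                    oracle_width(list(values), idx, prom), abs=1e-12)
                checked += 1

    def test_matches_scipy_peak_widths(self):
        rng = np.random.default_rng(10)
        for _ in range(50):
            values = rng.standard_normal(150)
            peaks, _ = sps.find_peaks(values)
            widths = sps.peak_widths(values, peaks, rel_height=0.5)[0]
            grid = np.arange(values.size, dtype=float)
            for idx, w in zip(peaks, widths):
                prom = compute_prominence(values, idx)
                assert compute_width(values, grid, idx, prom).width == \
                    pytest.approx(w, abs=1e-9)


class TestDetect:
    def test_flat_spectrum_yields_empty_list(self):
        grid = np.arange(0.5, 40, 1 / 3)
        psd = _psd(grid, -np.log10(grid))  # monotone decay
        assert detect_peaks(psd) == []

    def test_prominence_threshold_semantics(self):
        grid = np.arange(0.0, 30.0, 0.5)
        base = np.zeros_like(grid)
        bump = np.exp(-0.5 * ((grid - 10) / 0.8) ** 2)
        for height, expected in [(0.05, 0), (0.15, 1)]:
            psd = _psd(grid, base + height * bump)
            assert len(detect_peaks(psd)) == expected

    def test_min_distance_keeps_more_prominent(self):
        # two maxima 0.3 Hz apart (below the 0.4 Hz minimum distance) with
        # prominences 0.5 and 0.1: only the more prominent survives
        grid = np.array([9.0, 9.15, 9.3, 9.45, 9.6])
        values = np.array([0.0, 0.5, 0.2, 0.35, 0.0])
        psd = _psd(grid, values)
        peaks = detect_peaks(psd, min_prominence=0.1, min_distance=0.4)
        assert len(peaks) == 1
        assert peaks[0].frequency == pytest.approx(9.15)
        # with a permissive distance both survive
        both = detect_peaks(psd, min_prominence=0.1, min_distance=0.1)
        assert len(both) == 2

    def test_raising_threshold_never_adds_peaks(self, rng):
        grid = np.arange(0.5, 40, 1 / 3)
        values = rng.standard_normal(grid.size) * 0.3
        psd = _psd(grid, values)
        previous = None
        for thr in (0.05, 0.1, 0.2, 0.4):
            got = {p.index for p in detect_peaks(psd, min_prominence=thr)}
            if previous is not None:
                assert got <= previous
            previous = got

    def test_nonfinite_log_power_rejected(self):
        psd = PSDEstimate(freqs=np.array([1.0, 2.0, 3.0]),
                          power=np.array([1.0, 0.0, 1.0]),
                          log_power=np.array([0.0, -np.inf, 0.0]))
        with pytest.raises(InvalidArgumentError):
            detect_peaks(psd)


def _peak(freq, prom, height=0.0):
    return SpectralPeak(index=0, frequency=freq, height=height, prominence=prom,
                        width=1.0, left_cross=freq - 0.5, right_cross=freq + 0.5)


class TestClassify:
    def test_single_alpha_peak(self):
        band, chosen = classify_band([_peak(10.0, 0.3)])
        assert band == "alpha" and chosen.frequency == 10.0

    def test_single_theta_peak(self):
        band, chosen = classify_band([_peak(5.0, 0.3)])
        assert band == "theta"

    def test_most_prominent_wins_across_bands(self):
        band, chosen = classify_band([_peak(5.0, 0.3), _peak(10.0, 0.2)])
        assert band == "theta" and chosen.frequency == 5.0

    def test_boundary_7_5_is_alpha(self):
        band, _ = classify_band([_peak(7.5, 0.3)])
        assert band == "alpha"

    def test_peaks_outside_3_13_ignored(self):
        band, chosen = classify_band([_peak(1.0, 2.0), _peak(20.0, 2.0)])
        assert band == "none" and chosen is None


class TestMeasures:
    def test_chosen_global_maximum_has_ratio_one(self):
        grid = np.arange(3.0, 14.0, 1 / 3)
        values = -0.5 * np.abs(grid - 10.0)
        psd = _psd(grid, values)
        pm = measures_from_psd(psd)
        assert pm.band == "alpha"
        assert pm.power_ratio == pytest.approx(1.0)

    def test_linear_ratio_formula(self):
        """power -3.48 against max power -3.30 gives 10**(-0.18) ~ 0.661."""
        peak = _peak(10.0, 0.4, height=-3.48)
        psd = _psd(np.array([1.0, 10.0, 20.0]), np.array([-3.30, -3.48, -4.0]))
        pm = spectral_measures(psd, "alpha", peak)
        assert pm.power_ratio == pytest.approx(10 ** (-0.18), rel=1e-12)
        assert pm.power_ratio == pytest.approx(0.661, abs=5e-4)

    def test_log_ratio_switch(self):
        peak = _peak(10.0, 0.4, height=-3.48)
        psd = _psd(np.array([1.0, 10.0, 20.0]), np.array([-3.30, -3.48, -4.0]))
        pm = spectral_measures(psd, "alpha", peak, ratio_scale="log")
        assert pm.power_ratio == pytest.approx(-3.48 / -3.30)

    def test_flat_spectrum_reports_extrema_only(self):
        grid = np.arange(0.5, 40, 1 / 3)
        psd = _psd(grid, -np.log10(grid))
        pm = measures_from_psd(psd)
        assert pm.band == "none"
        assert pm.power is None and pm.power_ratio is None
        assert np.isfinite(pm.max_power) and np.isfinite(pm.min_power)
        assert pm.max_power >= pm.min_power


@settings(max_examples=100, derandomize=True)
@given(shift=st.floats(-5, 5, allow_nan=False))
def test_shift_invariance_of_peak_geometry(shift):
    """Adding a constant to the log spectrum leaves prominence, width,
    frequency and power_ratio unchanged; power and the extrema shift."""
    grid = np.arange(3.0, 14.0, 1 / 3)
    values = -0.4 * np.abs(grid - 9.0) - 2.0
    base = measures_from_psd(_psd(grid, values))
    moved = measures_from_psd(_psd(grid, values + shift))
    assert moved.band == base.band == "alpha"
    assert moved.prominence == pytest.approx(base.prominence)
    assert moved.width == pytest.approx(base.width)
    assert moved.frequency == base.frequency
    assert moved.power_ratio == pytest.approx(base.power_ratio, rel=1e-9)
    assert moved.power == pytest.approx(base.power + shift)
    assert moved.max_power == pytest.approx(base.max_power + shift)
    assert moved.min_power == pytest.approx(base.min_power + shift)


def test_annotated_plot_smoke(tmp_path):
    import matplotlib

    matplotlib.use("Agg")
    from eegmarkers.peaks import detect_peaks
    from eegmarkers.plotting import plot_annotated_psd

    grid = np.arange(3.0, 14.0, 1 / 3)
    values = -0.4 * np.abs(grid - 10.0)
    psd = _psd(grid, values)
    peaks = detect_peaks(psd)
    ax = plot_annotated_psd(psd, peaks, measures_from_psd(psd))
    assert ax is not None
    ax.figure.savefig(tmp_path / "psd.png")
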