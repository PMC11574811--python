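"""Statistical layer: gated contrasts, correlations, FDR, splits, mediation.

Conventions pinned here and used by the whole pipeline:

* Normality gating uses a Shapiro-Wilk test per sample at alpha = 0.05; both
  samples normal -> independent t-test, otherwise Mann-Whitney U.  All tests
  are two-sided.
* Correlations involving an ordinal variable (CRS-R) force Spearman;
  otherwise the same Shapiro gate chooses Pearson vs Spearman.
* Multiple comparisons are adjusted with the Benjamini-Hochberg step-up
  procedure, one family per analysis block.
* Mediation is OLS product-of-coefficients with a case-resampling percentile
  bootstrap after standard scaling, not structural-equation estimation; all
  reported paths are standardized coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import (
    CollinearityError,
    DegenerateSignalError,
    InsufficientDataError,
    InvalidArgumentError,
)

__all__ = [
    "StatResult",
    "ContingencyTable",
    "MediationResult",
    "normality_gated_compare",
    "correlate",
    "bh_adjust",
    "chi_square",
    "quantile_split",
    "peak_presence_by_split",
    "mediation_bootstrap",
    "SHAPIRO_ALPHA",
]

SHAPIRO_ALPHA = 0.05


@dataclass
class StatResult:
    """Outcome of one hypothesis test."""

    test_name: str
    statistic: float
    p_value: float
    p_adjusted: float | None = None
    n: tuple[int, ...] = ()
    normal: tuple[bool, ...] = ()
    direction: int = 0  # sign of (first sample's center - second's), 0 if n/a
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 <= self.p_value <= 1):
            raise InvalidArgumentError(f"p_value {self.p_value} outside [0, 1]")


@dataclass
class ContingencyTable:
    """Labeled non-negative integer counts (groups x peak categories)."""

    counts: np.ndarray
    row_labels: list[str]
    col_labels: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or min(self.counts.shape) < 2:
            raise InvalidArgumentError("contingency table must be at least 2x2")
        if np.any(self.counts < 0):
            raise InvalidArgumentError("counts must be non-negative")
        if len(self.row_labels) != self.counts.shape[0] or len(self.col_labels) != self.counts.shape[1]:
            raise InvalidArgumentError("label lengths must match the count matrix")


@dataclass
class MediationResult:
    """Standardized mediation paths with a percentile bootstrap CI for ab."""

    a: float
    b: float
    c_total: float
    c_direct: float
    ab: float
    ci_low: float
    ci_high: float
    p_ab: float
    n_boot: int
    seed: int
    n: int
    ci_contains_point: bool = True


def _clean_pair(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return x, y


def _shapiro_normal(sample: np.ndarray) -> bool:
    """Shapiro-Wilk gate; a zero-range sample counts as non-normal."""
    if np.ptp(sample) == 0:
        return False
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = stats.shapiro(sample).pvalue
    return bool(np.isfinite(p) and p > SHAPIRO_ALPHA)


def normality_gated_compare(x, y) -> StatResult:
    """Two-group contrast: t-test if both samples pass Shapiro-Wilk, else
    Mann-Whitney U (both two-sided)."""
    x, y = _clean_pair(x, y)
    if x.size < 3 or y.size < 3:
        raise InsufficientDataError("each sample needs n >= 3")
    normal = tuple(_shapiro_normal(s) for s in (x, y))
    if all(normal):
        res = stats.ttest_ind(x, y)
        name = "t-test"
        direction = int(np.sign(x.mean() - y.mean()))
    else:
        res = stats.mannwhitneyu(x, y, alternative="two-sided")
        name = "mann-whitney"
        direction = int(np.sign(np.median(x) - np.median(y)))
    return StatResult(
        test_name=name, statistic=float(res.statistic), p_value=float(res.pvalue),
        n=(x.size, y.size), normal=normal, direction=direction,
    )


def correlate(x, y, force_ordinal: bool = False) -> StatResult:
    """Pearson or Spearman correlation under the normality gate.

    ``force_ordinal`` always uses Spearman (required whenever one variable is
    an ordinal scale such as CRS-R).
    """
    x, y = _clean_pair(x, y)
    if x.size != y.size:
        raise InvalidArgumentError("samples must have equal length")
    if x.size < 4:
        raise InsufficientDataError("correlation needs n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateSignalError("constant sample in correlation")
    if force_ordinal:
        name, normal = "spearman", ()
    else:
        normal = tuple(_shapiro_normal(s) for s in (x, y))
        name = "pearson" if all(normal) else "spearman"
    if name == "pearson":
        res = stats.pearsonr(x, y)
    else:
        res = stats.spearmanr(x, y)
    coef = float(res.statistic)
    return StatResult(
        test_name=name, statistic=coef, p_value=float(res.pvalue),
        n=(x.size,), normal=normal, direction=int(np.sign(coef)),
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise InvalidArgumentError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(p, method="fdr_bh")
    return adjusted


def chi_square(table: ContingencyTable) -> StatResult:
    """Pearson chi-square of independence, no continuity correction."""
    counts = table.counts
    if counts.sum(axis=0).min() == 0 or counts.sum(axis=1).min() == 0:
        raise InvalidArgumentError("zero row or column total in contingency table")
    chi2, p, dof, expected = stats.chi2_contingency(counts, correction=False)
    if expected.min() <= 0:
        raise InvalidArgumentError("all expected counts must be positive")
    return StatResult(
        test_name="chi-square", statistic=float(chi2), p_value=float(p),
        n=(int(counts.sum()),), extra={"dof": int(dof)},
    )


def quantile_split(values, n_groups: int) -> np.ndarray:
    """Rank-based split into ``n_groups`` contiguous near-equal groups.

    Group 0 holds the smallest values.  The remainder of ``n // n_groups``
    is distributed to the lowest groups; ties are resolved by stable sort on
    (value, position), so the assignment is deterministic.
    """
    v = np.asarray(values, dtype=float)
    if n_groups not in (2, 3):
        raise InvalidArgumentError("n_groups must be 2 or 3")
    n = v.size
    if n < n_groups:
        raise InsufficientDataError(f"need at least {n_groups} values")
    if np.ptp(v) == 0:
        import warnings

        warnings.warn("all values identical: split is arbitrary but deterministic")
    order = np.argsort(v, kind="stable")
    base, rem = divmod(n, n_groups)
    sizes = [base + (1 if g < rem else 0) for g in range(n_groups)]
    assignment = np.empty(n, dtype=int)
    start = 0
    for g, size in enumerate(sizes):
        assignment[order[start : start + size]] = g
        start += size
    return assignment


def peak_presence_by_split(
    table: pd.DataFrame, acw_measure: str = "acw0", n_groups: int = 3
) -> ContingencyTable:
    """Counts of (peak present, absent) per ACW quantile group.

    ``table`` is a subject table with one row per (recording, ROI); rows with
    a censored value of the chosen ACW measure are dropped first.
    """
    if acw_measure not in table.columns:
        raise InvalidArgumentError(f"no column {acw_measure!r} in subject table")
    rows = table
    cens_col = f"{acw_measure}_censored"
    if cens_col in rows.columns:
        rows = rows[~rows[cens_col].astype(bool)]
    if rows.empty:
        raise InsufficientDataError("no uncensored rows for the requested measure")
    groups = quantile_split(rows[acw_measure].to_numpy(), n_groups)
    present = (rows["band"] != "none").to_numpy()
    counts = np.zeros((n_groups, 2), dtype=int)
    for g in range(n_groups):
        sel = groups == g
        counts[g, 0] = int(present[sel].sum())
        counts[g, 1] = int((~present[sel]).sum())
    labels = [f"q{g + 1}" for g in range(n_groups)]
    return ContingencyTable(counts=counts, row_labels=labels,
                            col_labels=["peak", "no_peak"])


def _standardized_paths(x: np.ndarray, m: np.ndarray, y: np.ndarray):
    """Standardized OLS paths from the correlation structure.

    a      : slope of m ~ x
    b, c'  : slopes of y ~ m + x
    c      : slope of y ~ x
    """
    r_xm = np.mean(x * m, axis=-1)
    r_xy = np.mean(x * y, axis=-1)
    r_my = np.mean(m * y, axis=-1)
    denom = 1.0 - r_xm**2
    b = (r_my - r_xy * r_xm) / denom
    c_direct = (r_xy - r_my * r_xm) / denom
    return r_xm, b, r_xy, c_direct


def mediation_bootstrap(
    x, m, y, n_boot: int = 5000, seed: int = 0
) -> MediationResult:
    """Indirect effect a*b with a case-resampling percentile bootstrap.

    Variables are standardized; each bootstrap resample is re-standardized so
    every replicate estimates the same standardized quantity.  The two-sided
    bootstrap p-value is ``2 * min(P(ab* <= 0), P(ab* >= 0))``.
    """
    x = np.asarray(x, dtype=float)
    m = np.asarray(m, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if not (m.size == n and y.size == n):
        raise InvalidArgumentError("x, m, y must have equal length")
    if n < 10:
        raise InsufficientDataError("mediation needs n >= 10")
    for name, v in (("x", x), ("m", m), ("y", y)):
        if np.ptp(v) == 0:
            raise DegenerateSignalError(f"variable {name} is constant")

    def zscore(v):
        return (v - v.mean(axis=-1, keepdims=True)) / v.std(axis=-1, keepdims=True)

    xs, ms, ys = zscore(x), zscore(m), zscore(y)
    r_xm = float(np.mean(xs * ms))
    if abs(r_xm) > 0.999:
        raise CollinearityError(f"x and m are collinear (r = {r_xm:.4f})")

    a_hat, b_hat, c_hat, c_dir_hat = _standardized_paths(xs, ms, ys)
    ab_hat = float(a_hat * b_hat)

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    xb, mb, yb = zscore(x[idx]), zscore(m[idx]), zscore(y[idx])
    a_b, b_b, _, _ = _standardized_paths(xb, mb, yb)
    ab_b = a_b * b_b
    ab_b = ab_b[np.isfinite(ab_b)]  # degenerate resamples (collinear) dropped
    ci_low, ci_high = np.percentile(ab_b, [2.5, 97.5])
    p_ab = float(min(1.0, 2.0 * min(np.mean(ab_b <= 0), np.mean(ab_b >= 0))))
    return MediationResult(
        a=float(a_hat), b=float(b_hat), c_total=float(c_hat),
        c_direct=float(c_dir_hat), ab=ab_hat,
        ci_low=float(ci_low), ci_high=float(ci_high), p_ab=p_ab,
        n_boot=n_boot, seed=seed, n=n,
        ci_contains_point=bool(ci_low <= ab_hat <= ci_high),
    )
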