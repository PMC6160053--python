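"""Statistical battery for comparing trabecular descriptor distributions.

Group comparisons use a subsampled Wilcoxon rank-sum protocol: both groups
are repeatedly subsampled to a common size (default N = 300) so that
unequal and large sample sizes do not bias the test, the two-sided
rank-sum test is run on each subsample pair (normal approximation with tie
and continuity correction, as in R's ``wilcox.test``), and the mean
p-value over the iterations (default 10000) is reported.  The full
p-value distribution is kept, since a mean p is an unconventional summary
and quantiles may be wanted.

Distribution shape is assessed with Shapiro-Wilk, moment skewness
(m3 / m2^1.5) and non-excess moment kurtosis (m4 / m2^2, Gaussian = 3),
and azimuth uniformity with a chi-square test on equal-width sectors
(df = bins - 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps


@dataclass
class ComparisonResult:
    """Outcome of a subsampled two-group rank-sum comparison."""

    label_x: str
    label_y: str
    subsample_size: int
    iterations: int
    pvalues: np.ndarray
    seed: int | None
    replace: bool = False

    @property
    def mean_p(self) -> float:
        return float(np.mean(self.pvalues))

    @property
    def frac_below_alpha(self) -> float:
        return float(np.mean(self.pvalues < 0.05))

    def to_dict(self) -> dict:
        return {
            "groups": [self.label_x, self.label_y],
            "subsample_size": self.subsample_size,
            "iterations": self.iterations,
            "mean_p": self.mean_p,
            "p_quantiles": {q: float(np.quantile(self.pvalues, float(q)))
                            for q in ("0.05", "0.25", "0.5", "0.75", "0.95")},
            "frac_p_below_0.05": self.frac_below_alpha,
            "seed": self.seed,
            "replace": self.replace,
        }


@dataclass
class DistributionTest:
    name: str
    statistic: float
    pvalue: float
    n: int
    df: int | None = None
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {"test": self.name, "statistic": self.statistic,
             "pvalue": self.pvalue, "n": self.n}
        if self.df is not None:
            d["df"] = self.df
        d.update(self.extra)
        return d


# ---------------------------------------------------------------------------
# rank-sum core (vectorized over iterations)
# ---------------------------------------------------------------------------

def _tie_terms(sorted_rows: np.ndarray) -> np.ndarray:
    """sum(t^3 - t) over tied groups, per row of a row-sorted array."""
    it, N = sorted_rows.shape
    out = np.zeros(it)
    eq = sorted_rows[:, 1:] == sorted_rows[:, :-1]
    rows = np.nonzero(eq.any(axis=1))[0]
    for i in rows:
        # run lengths of equal values in row i
        boundaries = np.nonzero(~eq[i])[0]
        starts = np.concatenate(([0], boundaries + 1))
        ends = np.concatenate((boundaries + 1, [N]))
        t = (ends - starts).astype(float)
        out[i] = np.sum(t ** 3 - t)
    return out


def rank_sum_p(X: np.ndarray, Y: np.ndarray, continuity: bool = True) -> np.ndarray:
    """Two-sided rank-sum p-values, rows of ``X`` vs rows of ``Y``.

    Normal approximation with tie correction and (optionally) continuity
    correction; matches ``scipy.stats.mannwhitneyu(method="asymptotic")``.
    Accepts 1-D inputs for a single test.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must have the same number of rows")
    n1, n2 = X.shape[1], Y.shape[1]
    if n1 == 0 or n2 == 0:
        raise ValueError("empty group")
    comb = np.concatenate([X, Y], axis=1)
    ranks = sps.rankdata(comb, axis=1, method="average")
    R1 = ranks[:, :n1].sum(axis=1)
    U1 = R1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    N = n1 + n2
    tie = _tie_terms(np.sort(comb, axis=1))
    var = n1 * n2 / 12.0 * ((N + 1) - tie / (N * (N - 1.0)))
    dev = U1 - mu
    if continuity:
        dev = np.sign(dev) * np.maximum(np.abs(dev) - 0.5, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = dev / np.sqrt(var)
    p = np.where(var > 0, 2.0 * sps.norm.sf(np.abs(z)), 1.0)
    return np.minimum(p, 1.0)


def subsampled_wilcoxon(x, y, n: int = 300, iterations: int = 10000,
                        seed: int | None = None, replace: bool = False,
                        label_x: str = "x", label_y: str = "y") -> ComparisonResult:
    """Subsampled two-sided Wilcoxon rank-sum comparison of two samples.

    Each iteration draws ``n`` values from each group (without replacement
    by default, independently across iterations), runs the rank-sum test,
    and the mean of all iteration p-values is the headline summary.  If a
    group is smaller than ``n``, ``n`` is lowered to the smaller size with
    a warning.  Fully reproducible for a fixed ``seed``.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    m = min(x.size, y.size)
    if n > m and not replace:
        warnings.warn(f"subsample size lowered from {n} to {m} "
                      f"(smallest group size)", stacklevel=2)
        n = m
    rng = np.random.default_rng(seed)
    if replace:
        xi = rng.integers(0, x.size, size=(iterations, n))
        yi = rng.integers(0, y.size, size=(iterations, n))
    else:
        if n == x.size:
            xi = np.tile(np.arange(x.size), (iterations, 1))
        else:
            xi = np.argsort(rng.random((iterations, x.size)), axis=1)[:, :n]
        if n == y.size:
            yi = np.tile(np.arange(y.size), (iterations, 1))
        else:
            yi = np.argsort(rng.random((iterations, y.size)), axis=1)[:, :n]
    p = rank_sum_p(x[xi], y[yi])
    return ComparisonResult(label_x, label_y, n, iterations, p, seed, replace)


# ---------------------------------------------------------------------------
# distribution tests
# ---------------------------------------------------------------------------

#: largest sample passed to the Shapiro-Wilk algorithm before subsampling
SHAPIRO_MAX_N = 5000


def shapiro_wilk(x, max_n: int = SHAPIRO_MAX_N, seed: int | None = None) -> DistributionTest:
    """Shapiro-Wilk normality test (W statistic and p-value).

    Samples larger than ``max_n`` are subsampled (seeded) because the
    algorithm's published coefficients degrade for very large N; the
    subsampling is recorded in the result.
    """
    x = np.asarray(x, dtype=float).ravel()
    x = x[~np.isnan(x)]
    if x.size < 3:
        raise ValueError("Shapiro-Wilk requires at least 3 values")
    extra = {}
    if np.ptp(x) == 0:
        return DistributionTest("shapiro-wilk", float("nan"), float("nan"),
                                int(x.size), extra={"degenerate": True})
    if x.size > max_n:
        rng = np.random.default_rng(seed)
        x = rng.choice(x, size=max_n, replace=False)
        extra = {"subsampled_to": max_n, "seed": seed}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        w, p = sps.shapiro(x)
    return DistributionTest("shapiro-wilk", float(w), float(p), int(x.size),
                            extra=extra)


def moment_skewness(x) -> float:
    """Moment skewness m3 / m2^1.5 (biased moments, as in R's moments pkg)."""
    x = np.asarray(x, dtype=float).ravel()
    x = x[~np.isnan(x)]
    return float(sps.skew(x, bias=True))


def moment_kurtosis(x) -> float:
    """Non-excess moment kurtosis m4 / m2^2; 3 for a Gaussian."""
    x = np.asarray(x, dtype=float).ravel()
    x = x[~np.isnan(x)]
    return float(sps.kurtosis(x, fisher=False, bias=True))


def chi_square_uniformity(angles, bins: int = 36) -> DistributionTest:
    """Chi-square test of azimuth uniformity over equal-width sectors.

    ``angles`` in degrees, all within [0, 360).  Counts in ``bins``
    half-open sectors are tested against equal expected counts with
    df = bins - 1.
    """
    a = np.asarray(angles, dtype=float).ravel()
    a = a[~np.isnan(a)]
    if bins < 2:
        raise ValueError("need at least 2 bins")
    if a.size and (a.min() < 0 or a.max() >= 360):
        raise ValueError("angles must lie in [0, 360)")
    expected = a.size / bins
    if expected < 1:
        raise ValueError(
            f"expected count per bin is {expected:.2f} < 1; use fewer bins")
    counts = rose_bins(a, bins)
    stat, p = sps.chisquare(counts)
    return DistributionTest("chi-square-uniformity", float(stat), float(p),
                            int(a.size), df=bins - 1,
                            extra={"bins": bins})


def rose_bins(angles, bins: int) -> np.ndarray:
    """Sector counts over [0, 360) with half-open equal-width bins."""
    a = np.asarray(angles, dtype=float).ravel()
    a = a[~np.isnan(a)]
    if a.size and (a.min() < 0 or a.max() >= 360):
        raise ValueError("angles must lie in [0, 360)")
    idx = np.floor(a * bins / 360.0).astype(int)
    return np.bincount(idx, minlength=bins)[:bins]
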