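"""Finite-sample diagnostics for interaction-energy time series.

Block averaging, running averages, power-law extrapolation in the
sample size, autocorrelation / statistical inefficiency, and
Gaussianity diagnostics. Together these answer the practical question
the entropy estimators raise: is the value I computed converged, and if
not, in which direction is it drifting?

The key diagnostic is the block-averaged entropy as a function of block
size N: for well-behaved data the C2 estimate is flat in N while a
steadily increasing IE estimate signals an unconverged exponential
average.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .estimators import CumulantEntropy, InteractionEntropy
from .series import EnergySeries

__all__ = [
    "ConvergenceCurve",
    "ExtrapolationFit",
    "block_estimates",
    "convergence_curve",
    "running_average",
    "extrapolate",
    "autocorrelation",
    "statistical_inefficiency",
    "gaussianity_report",
    "GaussianityReport",
]

_ESTIMATORS = {"IE": InteractionEntropy, "C2": CumulantEntropy}


def _estimator_for(name: str):
    try:
        return _ESTIMATORS[name.upper()]
    except KeyError:
        raise ValueError(f"estimator must be one of {sorted(_ESTIMATORS)}, got {name!r}")


@dataclass(frozen=True)
class ConvergenceCurve:
    """Entropy estimates as a function of sample size N.

    points : list of (N, estimate kJ/mol, std_error kJ/mol or None,
    n_batches); N strictly increasing.
    """

    points: List[Tuple[int, float, Optional[float], int]]
    estimator: str

    def __post_init__(self) -> None:
        ns = [p[0] for p in self.points]
        if any(b <= a for a, b in zip(ns, ns[1:])):
            raise ValueError("N values must be strictly increasing")

    @property
    def n(self) -> np.ndarray:
        return np.array([p[0] for p in self.points], dtype=float)

    @property
    def estimates(self) -> np.ndarray:
        return np.array([p[1] for p in self.points], dtype=float)


@dataclass(frozen=True)
class ExtrapolationFit:
    """Least-squares fit of S(N) = s∞ − a·N^(−c) with c fixed.

    The exponent c is an input, not an estimand: the fit is sensitive to
    it, so callers sweep a small grid (conventionally 0.20–0.30) and
    compare residuals.
    """

    s_infinity: float
    amplitude: float
    exponent_c: float
    residual: float

    def __post_init__(self) -> None:
        if self.exponent_c <= 0:
            raise ValueError("exponent_c must be > 0")
        if self.residual < 0:
            raise ValueError("residual must be >= 0")


def block_estimates(
    series: EnergySeries,
    block_size: int,
    estimator: str = "IE",
) -> Tuple[float, Optional[float], np.ndarray]:
    """Entropy from non-overlapping contiguous blocks of the series.

    The series is cut into ⌊N_total/block_size⌋ contiguous blocks
    (trailing remainder discarded); the estimator runs on each block.
    Returns (mean over blocks, standard error = SD(blocks)/√n_blocks or
    None for a single block, per-block values).
    """
    if block_size < 2:
        raise ValueError(f"block_size must be >= 2, got {block_size}")
    n_total = len(series)
    n_blocks = n_total // block_size
    if n_blocks < 1:
        raise ValueError(
            f"block_size {block_size} exceeds series length {n_total}"
        )
    cls = _estimator_for(estimator)
    values = series.values[: n_blocks * block_size].reshape(n_blocks, block_size)
    est = cls(temperature=series.temperature)
    per_block = np.array(
        [est.fit(row).minus_T_delta_S_ for row in values]
    )
    mean = float(per_block.mean())
    std_error = (
        float(per_block.std(ddof=1) / np.sqrt(n_blocks)) if n_blocks >= 2 else None
    )
    return mean, std_error, per_block


def convergence_curve(
    series: EnergySeries,
    block_sizes: Sequence[int],
    estimator: str = "IE",
) -> ConvergenceCurve:
    """Block-averaged entropy at each block size, as a curve in N."""
    points = []
    for n in sorted(set(int(b) for b in block_sizes)):
        mean, se, per_block = block_estimates(series, n, estimator)
        points.append((n, mean, se, per_block.size))
    return ConvergenceCurve(points, estimator.upper())


def running_average(
    series: EnergySeries,
    estimator: str = "IE",
    stride: int = 1,
) -> ConvergenceCurve:
    """Estimate over the first k·stride frames for k = 1, 2, ...

    The final point uses the whole series (prefixes of length < 2 are
    skipped since the estimators need at least two energies).
    """
    if stride < 1:
        raise ValueError(f"stride must be >= 1, got {stride}")
    cls = _estimator_for(estimator)
    est = cls(temperature=series.temperature)
    n_total = len(series)
    sizes = list(range(stride, n_total + 1, stride))
    if not sizes or sizes[-1] != n_total:
        sizes.append(n_total)
    points = []
    for n in sizes:
        if n < 2:
            continue
        val = est.fit(series.values[:n]).minus_T_delta_S_
        points.append((n, float(val), None, 1))
    return ConvergenceCurve(points, estimator.upper())


def extrapolate(curve: ConvergenceCurve, c: float) -> ExtrapolationFit:
    """Fit S(N) = s∞ − a·N^(−c) to a convergence curve by least squares.

    Linear in (s∞, a) once c is fixed, so an ordinary lstsq on the
    design [1, −N^(−c)] suffices. Returns the fit and the RMS residual.
    """
    if c <= 0:
        raise ValueError(f"c must be > 0, got {c}")
    if len(curve.points) < 3:
        raise ValueError("need at least 3 curve points to extrapolate")
    n = curve.n
    y = curve.estimates
    if np.ptp(n) == 0:
        raise ValueError("all N equal: rank-deficient design")
    design = np.column_stack([np.ones_like(n), -(n ** (-c))])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    rms = float(np.sqrt(np.mean(resid**2)))
    return ExtrapolationFit(
        s_infinity=float(coef[0]), amplitude=float(coef[1]), exponent_c=c, residual=rms
    )


def autocorrelation(series: EnergySeries, max_lag: int) -> np.ndarray:
    """Normalized autocorrelation at lags 0..max_lag (lag 0 exactly 1).

    Biased (1/N) autocovariance normalized by the sample variance — the
    standard estimator whose truncated sum feeds the statistical
    inefficiency.
    """
    x = series.values
    n = x.size
    if max_lag >= n:
        raise ValueError(f"max_lag {max_lag} must be < series length {n}")
    xc = x - x.mean()
    var = float(np.dot(xc, xc)) / n
    if var == 0:
        raise ValueError("zero-variance series has no autocorrelation")
    # FFT autocovariance: O(N log N), exact to rounding
    m = 1 << int(np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(xc, m)
    acov = np.fft.irfft(f * np.conj(f), m)[: max_lag + 1] / n
    rho = acov / var
    rho[0] = 1.0
    return rho


def statistical_inefficiency(series: EnergySeries, max_lag: Optional[int] = None) -> float:
    """Statistical inefficiency g = 1 + 2·Σ ρ_k (truncated sum), g ≥ 1.

    The sum runs over positive lags and stops at the first non-positive
    autocorrelation. The effective number of independent energies is
    N/g; for an AR(1) process with lag-1 coefficient φ the population
    value is (1+φ)/(1−φ).
    """
    n = len(series)
    if n < 100:
        raise ValueError(f"need at least 100 frames, got {n}")
    if max_lag is None:
        max_lag = n - 1
    rho = autocorrelation(series, min(max_lag, n - 1))
    tail = rho[1:]
    nonpos = np.nonzero(tail <= 0)[0]
    stop = nonpos[0] if nonpos.size else tail.size
    g = 1.0 + 2.0 * float(tail[:stop].sum())
    return max(g, 1.0)


@dataclass(frozen=True)
class GaussianityReport:
    """Histogram vs matched-moments normal, with shape statistics."""

    bin_centers: np.ndarray
    counts: np.ndarray
    normal_density: np.ndarray  # matched mean/σ normal at bin centers
    mean: float
    sigma: float
    skewness: float
    excess_kurtosis: float


def gaussianity_report(series: EnergySeries, n_bins: int = 50) -> GaussianityReport:
    """How Gaussian is the energy distribution?

    Returns the histogram, the normal density with the same mean and
    (population) standard deviation evaluated at the bin centers, and
    the sample skewness and excess kurtosis (moment estimators, no bias
    correction — immaterial at the sample sizes this is meant for).
    Heavy non-Gaussianity is exactly the regime where IE and even C2
    drift with N on real data.
    """
    x = series.values
    if x.size < 100:
        raise ValueError(f"need at least 100 frames, got {x.size}")
    counts, edges = np.histogram(x, bins=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    mean = float(x.mean())
    sigma = float(x.std())
    density = stats.norm.pdf(centers, loc=mean, scale=sigma) if sigma > 0 else np.zeros_like(centers)
    return GaussianityReport(
        bin_centers=centers,
        counts=counts,
        normal_density=density,
        mean=mean,
        sigma=sigma,
        skewness=float(stats.skew(x, bias=True)),
        excess_kurtosis=float(stats.kurtosis(x, fisher=True, bias=True)),
    )
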