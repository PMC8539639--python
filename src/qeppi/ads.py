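"""Asymmetric-double-sigmoid (ADS) desirability functions.

Each of the seven property distributions of the modeling set is summarized by
a histogram and fitted with the ADS curve

    Q(x) = a + b * s((x - c + d/2) / e) * [1 - s((x - c - d/2) / f)]

where s is the logistic function, c locates the peak region, d separates the
two flanks, and e, f (> 0) set the rising and falling slopes independently —
so the curve can be steep on one side and heavy-tailed on the other, which is
what right-skewed property histograms look like. The fitted curve divided by
its maximum is the desirability function d(x) in (0, 1].

Fitting is nonlinear least squares (Levenberg–Marquardt) of raw bin counts
against bin centers, with a deterministic multi-start to avoid bad local
minima. Slopes are optimized in log space so e, f stay positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares, minimize_scalar
from scipy.special import expit

from .descriptors import INTEGER_PROPERTIES, PROPERTY_NAMES

logger = logging.getLogger(__name__)

#: Default histogram bin widths for the continuous properties.
DEFAULT_BIN_WIDTHS: dict[str, float] = {"MW": 25.0, "ALogP": 0.5, "TPSA": 10.0}

#: Desirability floor: keeps the geometric mean's logarithm finite.
DEFAULT_EPS = 1e-6

#: Minimum number of finite values for a meaningful histogram fit.
MIN_HISTOGRAM_VALUES = 30


@dataclass(frozen=True)
class ADSParams:
    """The six ADS parameters; ``e`` and ``f`` are slope scales and must be
    positive."""

    a: float
    b: float
    c: float
    d: float
    e: float
    f: float

    def __post_init__(self) -> None:
        vals = (self.a, self.b, self.c, self.d, self.e, self.f)
        if not all(np.isfinite(vals)):
            raise ValueError(f"non-finite ADS parameters: {vals}")
        if self.e <= 0 or self.f <= 0:
            raise ValueError(f"slope scales must be positive: e={self.e}, f={self.f}")

    def as_tuple(self) -> tuple[float, ...]:
        return (self.a, self.b, self.c, self.d, self.e, self.f)


def ads_value(params: ADSParams, x):
    """Evaluate Q(x). Vectorized over ``x``; overflow-safe for extreme
    arguments (both tails converge to the baseline ``a``)."""
    x = np.asarray(x, dtype=float)
    rise = expit((x - params.c + params.d / 2.0) / params.e)
    fall = expit((x - params.c - params.d / 2.0) / params.f)
    out = params.a + params.b * rise * (1.0 - fall)
    return float(out) if out.ndim == 0 else out


@dataclass
class PropertyHistogram:
    """Histogram of one property over the modeling set.

    Integer-valued properties use unit-width bins centered on 0..max;
    continuous properties use fixed-width bins spanning the data range.
    """

    property: str
    bin_centers: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.bin_centers.shape != self.counts.shape:
            raise ValueError("bin_centers and counts must have equal length")
        if len(self.bin_centers) > 1 and not np.all(np.diff(self.bin_centers) > 0):
            raise ValueError("bin centers must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")


def build_histogram(
    values: Sequence[float],
    property: str,
    bin_widths: Mapping[str, float] | None = None,
) -> PropertyHistogram:
    """Bin property values for ADS fitting.

    Raises
    ------
    ValueError
        If fewer than 30 finite values are supplied (a fit to fewer would be
        meaningless) or the property name is unknown.
    """
    if property not in PROPERTY_NAMES:
        raise ValueError(f"unknown property {property!r}")
    vals = np.asarray(values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if len(vals) < MIN_HISTOGRAM_VALUES:
        raise ValueError(
            f"need at least {MIN_HISTOGRAM_VALUES} finite values for {property}, got {len(vals)}"
        )

    if property in INTEGER_PROPERTIES:
        ints = np.rint(vals).astype(int)
        top = int(ints.max())
        counts = np.bincount(ints, minlength=top + 1).astype(float)
        centers = np.arange(top + 1, dtype=float)
        return PropertyHistogram(property=property, bin_centers=centers, counts=counts)

    widths = dict(DEFAULT_BIN_WIDTHS)
    if bin_widths:
        widths.update(bin_widths)
    width = widths[property]
    lo, hi = float(vals.min()), float(vals.max())
    n_bins = max(1, int(np.ceil((hi - lo) / width - 1e-9)))
    edges = lo + width * np.arange(n_bins + 1)
    counts, _ = np.histogram(vals, bins=edges)
    centers = edges[:-1] + width / 2.0
    return PropertyHistogram(property=property, bin_centers=centers, counts=counts.astype(float))


def _weighted_quantile(x: np.ndarray, w: np.ndarray, q: float) -> float:
    order = np.argsort(x)
    cw = np.cumsum(w[order])
    if cw[-1] <= 0:
        return float(x[order[len(x) // 2]])
    idx = int(np.searchsorted(cw, q * cw[-1]))
    return float(x[order[min(idx, len(x) - 1)]])


def _residuals(theta: np.ndarray, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    a, b, c, d, log_e, log_f = theta
    rise = expit((x - c + d / 2.0) / np.exp(log_e))
    fall = expit((x - c - d / 2.0) / np.exp(log_f))
    return a + b * rise * (1.0 - fall) - y


def fit_ads(
    hist: PropertyHistogram,
    n_starts: int = 5,
    seed: int = 0,
    full_output: bool = False,
):
    """Fit the ADS curve to a histogram by Levenberg–Marquardt least squares.

    Initialization: a = 0, b = max count, c = modal bin center, d =
    interquartile range of the binned data, e = f = range/10; then
    ``n_starts - 1`` additional starts with deterministic multiplicative
    jitter, best residual norm wins. Slopes are parameterized as log(e),
    log(f) so the fitted scales are strictly positive.

    Parameters
    ----------
    full_output
        If True return ``(params, report)`` where ``report`` carries the
        residual norm and the number of converged starts.

    Raises
    ------
    ValueError
        If fewer than 6 bins have nonzero counts.
    RuntimeError
        If no start converges.
    """
    x, y = hist.bin_centers, hist.counts
    if int(np.count_nonzero(y)) < 6:
        raise ValueError(
            f"need >= 6 nonzero bins to fit {hist.property}, got {int(np.count_nonzero(y))}"
        )

    span = float(x.max() - x.min()) or 1.0
    c0 = float(x[np.argmax(y)])
    d0 = _weighted_quantile(x, y, 0.75) - _weighted_quantile(x, y, 0.25)
    d0 = d0 if d0 > 0 else span / 4.0
    s0 = span / 10.0
    base = np.array([0.0, float(y.max()), c0, d0, np.log(s0), np.log(s0)])

    rng = np.random.default_rng(seed)
    starts = [base]
    for _ in range(max(0, n_starts - 1)):
        jitter = base.copy()
        jitter[1] *= rng.uniform(0.5, 1.5)
        jitter[2] += rng.uniform(-0.5, 0.5) * d0
        jitter[3] *= rng.uniform(0.5, 1.5)
        jitter[4] += rng.uniform(-0.7, 0.7)
        jitter[5] += rng.uniform(-0.7, 0.7)
        starts.append(jitter)

    best_theta, best_cost, n_ok = None, np.inf, 0
    for theta0 in starts:
        try:
            res = least_squares(_residuals, theta0, args=(x, y), method="lm", max_nfev=20000)
        except Exception:
            continue
        if not np.all(np.isfinite(res.x)):
            continue
        n_ok += 1
        if res.cost < best_cost:
            best_cost, best_theta = res.cost, res.x

    if best_theta is None:
        raise RuntimeError(f"ADS fit failed to converge for {hist.property} after {n_starts} starts")

    a, b, c, d, log_e, log_f = best_theta
    params = ADSParams(a=a, b=b, c=c, d=d, e=float(np.exp(log_e)), f=float(np.exp(log_f)))
    if full_output:
        report = {
            "residual_norm": float(np.sqrt(2.0 * best_cost)),
            "converged_starts": n_ok,
            "n_bins": int(len(x)),
        }
        return params, report
    return params


@dataclass
class DesirabilityFunction:
    """A normalized ADS curve: d(x) = clamp(Q(x)/q_max, eps, 1).

    ``peak`` is the argmax of Q on ``domain`` (where d = 1); ``eps`` is the
    positivity floor that keeps log d finite in the geometric mean.
    """

    property: str
    params: ADSParams
    q_max: float
    peak: float
    domain: tuple[float, float]
    eps: float = DEFAULT_EPS

    def __post_init__(self) -> None:
        if self.q_max <= 0:
            raise ValueError(f"degenerate fit for {self.property}: q_max={self.q_max}")

    def __call__(self, x):
        val = np.asarray(ads_value(self.params, x), dtype=float) / self.q_max
        out = np.clip(val, self.eps, 1.0)
        return float(out) if out.ndim == 0 else out


def normalize(
    params: ADSParams,
    domain: tuple[float, float],
    property: str = "",
    eps: float = DEFAULT_EPS,
    grid_size: int = 2001,
) -> DesirabilityFunction:
    """Normalize a fitted ADS curve to a maximum of 1 on ``domain``.

    The maximum has no closed form, so it is located on a dense grid and
    refined by bounded scalar minimization around the best grid point.
    """
    lo, hi = float(domain[0]), float(domain[1])
    if not hi > lo:
        raise ValueError(f"degenerate domain [{lo}, {hi}]")
    grid = np.linspace(lo, hi, grid_size)
    qvals = ads_value(params, grid)
    k = int(np.argmax(qvals))
    left = grid[max(k - 1, 0)]
    right = grid[min(k + 1, grid_size - 1)]
    res = minimize_scalar(
        lambda x: -ads_value(params, x), bounds=(left, right), method="bounded",
        options={"xatol": (hi - lo) * 1e-10},
    )
    peak, q_peak = float(res.x), float(-res.fun)
    if qvals[k] >= q_peak:  # grid point can beat the local refinement at the boundary
        peak, q_peak = float(grid[k]), float(qvals[k])
    if q_peak <= 0:
        raise ValueError(f"degenerate fit: maximum of Q is {q_peak} <= 0 on [{lo}, {hi}]")
    return DesirabilityFunction(
        property=property, params=params, q_max=q_peak, peak=peak, domain=(lo, hi), eps=eps
    )


def fit_desirability(
    values: Sequence[float],
    property: str,
    bin_widths: Mapping[str, float] | None = None,
    eps: float = DEFAULT_EPS,
    seed: int = 0,
) -> DesirabilityFunction:
    """Histogram -> ADS fit -> normalized desirability, in one call.

    The normalization domain is the data range extended by 10% on each side,
    so the located maximum reflects the fitted region rather than the tails.
    """
    hist = build_histogram(values, property, bin_widths=bin_widths)
    params, report = fit_ads(hist, seed=seed, full_output=True)
    lo = float(hist.bin_centers[0])
    hi = float(hist.bin_centers[-1])
    pad = 0.1 * (hi - lo)
    fn = normalize(params, (lo - pad, hi + pad), property=property, eps=eps)
    logger.debug("fit %s: peak=%.4g residual=%.4g", property, fn.peak, report["residual_norm"])
    return fn
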