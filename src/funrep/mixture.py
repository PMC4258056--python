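"""Two-component mixture models for unsupervised threshold calibration.

With liberal homology-search cutoffs almost every function in the
reference database accumulates some evidence, so the observed evidence
values form a bimodal blend of weak spurious homology (the "low"
component) and strong genuine homology (the "high" component).  A
two-component mixture model separates the blend without any labels:

* a Gaussian mixture, fitted by expectation-maximisation (EM), for
  measures on the whole real line (the mean-score measure);
* a Gamma mixture, fitted by stochastic EM (SEM), for strictly positive,
  right-skewed measures (the scaled mean-score measure).

The presence/absence decision threshold is the equal-cost Bayes boundary:
the point between the component means where the weighted component
densities cross.  Values above it are more probably genuine than spurious.

EM here is deterministic (median-split initialisation); SEM draws hard
component labels from the posterior responsibilities each iteration and
is reproducible only through its mandatory seed.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
from scipy import stats
from scipy.special import digamma, logsumexp, polygamma

__all__ = [
    "GaussianMixtureFit",
    "GammaMixtureFit",
    "MixtureFitError",
    "ThresholdResult",
    "fit_gaussian_em",
    "fit_gamma_sem",
    "gamma_shape_mle",
    "posterior_responsibilities",
    "derive_threshold",
    "plot_fit",
]

MIN_VALUES = 10  # fewer points cannot support a 2-component fit


class MixtureFitError(RuntimeError):
    """Raised when a mixture model cannot be fitted to the data."""


@dataclass(frozen=True)
class GaussianMixtureFit:
    """Two-component Gaussian mixture, components sorted by mean.

    The "high" component models genuine homology; ``log_likelihood_trace``
    records the total log-likelihood after every EM iteration (it is
    non-decreasing, a standard EM guarantee).
    """

    weight_low: float
    weight_high: float
    mean_low: float
    mean_high: float
    sd_low: float
    sd_high: float
    log_likelihood: float = math.nan
    n_iterations: int = 0
    converged: bool = True
    log_likelihood_trace: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if not math.isclose(self.weight_low + self.weight_high, 1.0, abs_tol=1e-6):
            raise ValueError("mixture weights must sum to 1")
        if self.mean_low > self.mean_high:
            raise ValueError("components must be sorted by mean")
        if self.sd_low <= 0 or self.sd_high <= 0:
            raise ValueError("standard deviations must be positive")

    @property
    def component_means(self) -> tuple[float, float]:
        return (self.mean_low, self.mean_high)

    def weighted_log_densities(self, values) -> np.ndarray:
        """(2, n) array of log(weight_k * density_k(x)), low row first."""
        x = np.asarray(values, dtype=float)
        return np.stack(
            [
                np.log(self.weight_low) + stats.norm.logpdf(x, self.mean_low, self.sd_low),
                np.log(self.weight_high) + stats.norm.logpdf(x, self.mean_high, self.sd_high),
            ]
        )

    def in_support(self, values) -> np.ndarray:
        return np.isfinite(np.asarray(values, dtype=float))


@dataclass(frozen=True)
class GammaMixtureFit:
    """Two-component Gamma mixture fitted by SEM.

    Parameters are the averages over the post-burn-in SEM iterations; the
    component with the smaller mean (shape x scale) is labelled "low".
    """

    weight_low: float
    weight_high: float
    shape_low: float
    scale_low: float
    shape_high: float
    scale_high: float
    log_likelihood: float = math.nan
    seed: int = 0
    n_iterations: int = 0
    burn_in: int = 0

    def __post_init__(self) -> None:
        if not math.isclose(self.weight_low + self.weight_high, 1.0, abs_tol=1e-6):
            raise ValueError("mixture weights must sum to 1")
        if min(self.shape_low, self.scale_low, self.shape_high, self.scale_high) <= 0:
            raise ValueError("shape and scale parameters must be positive")
        if self.shape_low * self.scale_low > self.shape_high * self.scale_high:
            raise ValueError("components must be sorted by mean (shape x scale)")

    @property
    def mean_low(self) -> float:
        return self.shape_low * self.scale_low

    @property
    def mean_high(self) -> float:
        return self.shape_high * self.scale_high

    @property
    def component_means(self) -> tuple[float, float]:
        return (self.mean_low, self.mean_high)

    def weighted_log_densities(self, values) -> np.ndarray:
        x = np.asarray(values, dtype=float)
        return np.stack(
            [
                np.log(self.weight_low)
                + stats.gamma.logpdf(x, a=self.shape_low, scale=self.scale_low),
                np.log(self.weight_high)
                + stats.gamma.logpdf(x, a=self.shape_high, scale=self.scale_high),
            ]
        )

    def in_support(self, values) -> np.ndarray:
        x = np.asarray(values, dtype=float)
        return np.isfinite(x) & (x > 0)


MixtureFit = Union[GaussianMixtureFit, GammaMixtureFit]


@dataclass(frozen=True)
class ThresholdResult:
    """Decision threshold derived from a fitted mixture.

    ``method`` is ``density_crossing`` when the weighted component
    densities cross between the component means, else
    ``fallback_midpoint`` (degenerate or non-crossing fits).
    """

    threshold: float
    method: str
    fallback_used: bool


def _check_values(values, positive: bool = False) -> np.ndarray:
    x = np.asarray(values, dtype=float).ravel()
    if x.size < MIN_VALUES:
        raise MixtureFitError(
            f"insufficient data for mixture: need >= {MIN_VALUES} values, got {x.size}"
        )
    if not np.all(np.isfinite(x)):
        raise MixtureFitError("non-finite evidence values")
    if positive and np.any(x <= 0):
        raise ValueError("Gamma mixture requires strictly positive values")
    if np.ptp(x) == 0:
        raise MixtureFitError("insufficient data for mixture: all values identical")
    return x


def fit_gaussian_em(
    values: Sequence[float], tol: float = 1e-8, max_iter: int = 500
) -> GaussianMixtureFit:
    """Maximum-likelihood two-component Gaussian fit by EM.

    Initialisation splits the values at their median and seeds each
    component with its half's mean and standard deviation at weight 0.5 —
    deterministic, so no seed is involved.  Convergence is declared when
    the relative log-likelihood change drops below *tol*; component
    variances are floored at 1e-6 times the overall data variance to
    prevent collapse onto single points.
    """
    x = _check_values(values)
    n = x.size
    var_floor = 1e-6 * float(np.var(x))

    median = float(np.median(x))
    lower = x[x <= median]
    upper = x[x > median]
    if upper.size == 0:  # heavy ties at the median
        order = np.sort(x)
        lower, upper = order[: n // 2], order[n // 2 :]
    means = np.array([lower.mean(), upper.mean()])
    variances = np.maximum(np.array([lower.var(), upper.var()]), var_floor)
    weights = np.array([0.5, 0.5])

    trace: list[float] = []
    log_likelihood = -np.inf
    converged = False
    iteration = 0
    for iteration in range(1, max_iter + 1):
        # E-step
        log_weighted = np.stack(
            [
                np.log(weights[k]) + stats.norm.logpdf(x, means[k], np.sqrt(variances[k]))
                for k in range(2)
            ]
        )
        log_total = logsumexp(log_weighted, axis=0)
        new_ll = float(log_total.sum())
        resp = np.exp(log_weighted - log_total)

        # M-step
        resp_sums = resp.sum(axis=1)
        weights = resp_sums / n
        means = (resp @ x) / resp_sums
        variances = np.array(
            [
                max(float(resp[k] @ (x - means[k]) ** 2 / resp_sums[k]), var_floor)
                for k in range(2)
            ]
        )

        trace.append(new_ll)
        if np.isfinite(log_likelihood):
            rel_change = abs(new_ll - log_likelihood) / max(abs(log_likelihood), 1.0)
            if rel_change < tol:
                log_likelihood = new_ll
                converged = True
                break
        log_likelihood = new_ll

    order = np.argsort(means)
    return GaussianMixtureFit(
        weight_low=float(weights[order[0]]),
        weight_high=float(weights[order[1]]),
        mean_low=float(means[order[0]]),
        mean_high=float(means[order[1]]),
        sd_low=float(np.sqrt(variances[order[0]])),
        sd_high=float(np.sqrt(variances[order[1]])),
        log_likelihood=log_likelihood,
        n_iterations=iteration,
        converged=converged,
        log_likelihood_trace=tuple(trace),
    )


def gamma_shape_mle(
    mean_x: float, mean_log_x: float, max_iter: int = 50, tol: float = 1e-10
) -> float:
    """Maximum-likelihood Gamma shape from sufficient statistics.

    Solves ln(k) - digamma(k) = ln(mean(x)) - mean(ln x) by Newton
    iteration, started from the standard closed-form approximation.  The
    right-hand side is >= 0 by Jensen's inequality; values near 0 (nearly
    constant data) give a very large shape, capped at 1e6.
    """
    s = math.log(mean_x) - mean_log_x
    if s <= 1e-12:
        return 1e6
    k = (3.0 - s + math.sqrt((s - 3.0) ** 2 + 24.0 * s)) / (12.0 * s)
    for _ in range(max_iter):
        f = math.log(k) - digamma(k) - s
        fprime = 1.0 / k - polygamma(1, k)
        step = f / fprime
        new_k = k - step
        while new_k <= 0:  # keep the iterate in the positive domain
            step /= 2.0
            new_k = k - step
        if abs(new_k - k) < tol * max(k, 1.0):
            return min(float(new_k), 1e6)
        k = new_k
    return min(float(k), 1e6)


def _gamma_mle(x: np.ndarray) -> tuple[float, float]:
    """(shape, scale) ML estimates for one component's assigned values."""
    mean_x = float(x.mean())
    shape = gamma_shape_mle(mean_x, float(np.log(x).mean()))
    return shape, mean_x / shape


def fit_gamma_sem(
    values: Sequence[float],
    n_iterations: int = 300,
    burn_in: int = 100,
    seed: int = 1,
    max_redraws: int = 10,
) -> GammaMixtureFit:
    """Two-component Gamma mixture fitted by stochastic EM.

    Each iteration draws a hard component label for every value from its
    posterior responsibilities, then re-estimates each component's Gamma
    parameters by maximum likelihood from its assigned values (closed-form
    scale given the shape; shape by Newton iteration on the ML equation).
    The reported parameters are the averages over the post-burn-in
    iterations, which smooths out the label-sampling noise of the chain.
    A component left with fewer than two values by the sampling step is
    redrawn up to *max_redraws* times before the fit fails.

    Fully reproducible given *seed*.
    """
    x = _check_values(values, positive=True)
    n = x.size
    if burn_in >= n_iterations:
        raise ValueError("burn_in must be smaller than n_iterations")
    rng = np.random.default_rng(seed)

    # Median-split method-of-moments initialisation.
    median = float(np.median(x))
    lower = x[x <= median]
    upper = x[x > median]
    if upper.size < 2 or lower.size < 2:
        order = np.sort(x)
        lower, upper = order[: n // 2], order[n // 2 :]
    params = []  # rows: weight, shape, scale for each component
    for part in (lower, upper):
        var = max(float(part.var()), 1e-12)
        mean = float(part.mean())
        shape = max(mean * mean / var, 1e-6)
        params.append([0.5, shape, mean / shape])
    weights = np.array([params[0][0], params[1][0]])
    shapes = np.array([params[0][1], params[1][1]])
    scales = np.array([params[0][2], params[1][2]])

    kept: list[np.ndarray] = []
    log_x = np.log(x)
    for iteration in range(n_iterations):
        log_weighted = np.stack(
            [
                np.log(weights[k]) + stats.gamma.logpdf(x, a=shapes[k], scale=scales[k])
                for k in range(2)
            ]
        )
        p_high = np.exp(
            log_weighted[1] - logsumexp(log_weighted, axis=0)
        )

        for attempt in range(max_redraws + 1):
            labels = rng.random(n) < p_high  # True = component 1
            n_high = int(labels.sum())
            if 2 <= n_high <= n - 2:
                break
        else:
            raise MixtureFitError(
                "SEM component emptied by label sampling and could not be redrawn"
            )

        for k, mask in enumerate((~labels, labels)):
            xk = x[mask]
            shapes[k] = gamma_shape_mle(float(xk.mean()), float(log_x[mask].mean()))
            scales[k] = float(xk.mean()) / shapes[k]
            weights[k] = mask.sum() / n

        if iteration >= burn_in:
            kept.append(np.concatenate([weights, shapes, scales]))

    avg = np.mean(kept, axis=0)
    weights, shapes, scales = avg[:2], avg[2:4], avg[4:6]
    weights = weights / weights.sum()
    order = np.argsort(shapes * scales)

    fit = GammaMixtureFit(
        weight_low=float(weights[order[0]]),
        weight_high=float(weights[order[1]]),
        shape_low=float(shapes[order[0]]),
        scale_low=float(scales[order[0]]),
        shape_high=float(shapes[order[1]]),
        scale_high=float(scales[order[1]]),
        seed=seed,
        n_iterations=n_iterations,
        burn_in=burn_in,
    )
    ll = float(logsumexp(fit.weighted_log_densities(x), axis=0).sum())
    return dataclasses.replace(fit, log_likelihood=ll)


def posterior_responsibilities(fit: MixtureFit, values: Sequence[float]) -> np.ndarray:
    """(n, 2) array of (p_low, p_high) membership probabilities.

    Each row sums to 1 and is proportional to weight x component density
    at the value.  Values outside the model support (non-positive values
    for a Gamma fit) are an error.
    """
    x = np.asarray(values, dtype=float).ravel()
    if not np.all(fit.in_support(x)):
        bad = x[~fit.in_support(x)]
        raise ValueError(f"values outside model support: {bad[:5]}")
    log_weighted = fit.weighted_log_densities(x)
    resp = np.exp(log_weighted - logsumexp(log_weighted, axis=0))
    return resp.T


def derive_threshold(
    fit: MixtureFit, cost_ratio: float = 1.0, n_grid: int = 10_000
) -> ThresholdResult:
    """Decision threshold minimising the misclassification risk.

    Locates the point t between the component means where
    ``cost_ratio * weight_low * density_low(t) = weight_high * density_high(t)``
    — the Bayes boundary under 0/1 loss when *cost_ratio* is 1; a ratio
    above 1 penalises false positives more and pushes the threshold up.
    The sign change of the weighted log-density difference is bracketed on
    an *n_grid*-point grid over [mean_low, mean_high] and refined by
    bisection to a width below 1e-9 of the inter-mean distance.

    When the component means coincide (to tolerance) or the densities do
    not cross between them, the midpoint of the means is returned with
    ``fallback_used`` set.
    """
    if cost_ratio <= 0:
        raise ValueError("cost_ratio must be positive")
    mean_low, mean_high = fit.component_means
    span = mean_high - mean_low
    midpoint = 0.5 * (mean_low + mean_high)
    if span <= 1e-12 * max(1.0, abs(mean_high)):
        return ThresholdResult(midpoint, "fallback_midpoint", True)

    log_cost = math.log(cost_ratio)

    def diff(t: np.ndarray | float) -> np.ndarray:
        low, high = fit.weighted_log_densities(t)
        return (low + log_cost) - high

    grid = np.linspace(mean_low, mean_high, n_grid)
    d = diff(grid)
    sign_change = np.nonzero(np.diff(np.sign(d)) != 0)[0]
    if sign_change.size == 0:
        return ThresholdResult(midpoint, "fallback_midpoint", True)

    lo, hi = grid[sign_change[0]], grid[sign_change[0] + 1]
    d_lo = float(diff(lo))
    while hi - lo > 1e-9 * span:
        mid = 0.5 * (lo + hi)
        d_mid = float(diff(mid))
        if d_mid == 0.0:
            lo = hi = mid
            break
        if (d_lo > 0) == (d_mid > 0):
            lo, d_lo = mid, d_mid
        else:
            hi = mid
    return ThresholdResult(0.5 * (lo + hi), "density_crossing", False)


def plot_fit(
    fit: MixtureFit,
    values: Sequence[float],
    threshold: float | None = None,
    path: str | None = None,
    bins: int = 60,
):
    """Diagnostic histogram of evidence values with the fitted weighted
    component densities overlaid (and the threshold, when given).

    Returns the matplotlib figure; writes it to *path* when given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.asarray(values, dtype=float)
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.hist(x, bins=bins, density=True, color="0.8", edgecolor="0.6", label="evidence")
    grid = np.linspace(x.min(), x.max(), 500)
    grid = grid[fit.in_support(grid)]
    low, high = np.exp(fit.weighted_log_densities(grid))
    ax.plot(grid, low, color="firebrick", label="low (spurious) component")
    ax.plot(grid, high, color="seagreen", label="high (genuine) component")
    if threshold is not None:
        ax.axvline(threshold, color="navy", linestyle="--", label=f"threshold {threshold:.3g}")
    ax.set_xlabel("evidence value")
    ax.set_ylabel("density")
    ax.legend(frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
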