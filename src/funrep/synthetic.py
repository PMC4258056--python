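"""Seeded synthetic data emulating the study design.

Two generators make every pipeline stage testable without real RNA-seq
data:

* :func:`simulate_evidence` draws evidence values from a specified
  two-component mixture with per-draw ground-truth component labels, for
  testing the mixture fitters and threshold derivation directly.

* :func:`simulate_hit_tables` builds full read-level hit tables for a set
  of technical replicates with a planted truth: a chosen fraction of
  functions is "present" and receives many high-scoring hits whose count
  follows a negative-binomial read-count distribution (mimicking the
  expression-level bias of real counts), while every function — present
  or absent — additionally picks up Poisson-distributed spurious hits
  with low scores, the residue of weak homology under liberal search
  cutoffs.  Aggregating such tables yields the characteristic bimodal
  evidence histogram the mixture calibration relies on.

Scores are truncated-at-zero normal draws so all evidence measures stay
positive (valid Gamma support).  Each hit also carries a pseudo E-value
derived monotonically from its score (``10 ** (-score / 10)``), which is
enough to exercise E-value-cutoff sweeps; no sequence-level realism is
attempted.  All generators are bit-reproducible under a fixed seed.

:func:`bayes_threshold_oracle` locates the weighted-density crossing of a
mixture spec by dense grid scan plus Brent root refinement — an
implementation independent of the calibration module, used to cross-check
its thresholds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .assignments_io import HIT_COLUMNS, HitTable

__all__ = [
    "MixtureSpec",
    "ExperimentSpec",
    "ThresholdOracleResult",
    "simulate_evidence",
    "simulate_hit_tables",
    "bayes_threshold_oracle",
]


@dataclass(frozen=True)
class MixtureSpec:
    """A two-component mixture to draw evidence values from.

    ``params_low``/``params_high`` are (mean, sd) for the Gaussian family
    and (shape, scale) for the Gamma family.
    """

    family: str  # "gaussian" or "gamma"
    weight_low: float
    weight_high: float
    params_low: tuple[float, float]
    params_high: tuple[float, float]
    n: int = 1000
    seed: int = 1

    def __post_init__(self) -> None:
        if self.family not in ("gaussian", "gamma"):
            raise ValueError(f"unknown family {self.family!r}")
        if not math.isclose(self.weight_low + self.weight_high, 1.0, abs_tol=1e-9):
            raise ValueError("weights must sum to 1")
        if min(self.weight_low, self.weight_high) < 0:
            raise ValueError("weights must be nonnegative")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        for params in (self.params_low, self.params_high):
            if len(params) != 2:
                raise ValueError("component parameters must be (mean, sd) or (shape, scale)")
            if self.family == "gamma" and min(params) <= 0:
                raise ValueError("Gamma parameters must be positive")
            if self.family == "gaussian" and params[1] <= 0:
                raise ValueError("Gaussian sd must be positive")

    def component_mean(self, which: str) -> float:
        a, b = self.params_low if which == "low" else self.params_high
        return a if self.family == "gaussian" else a * b

    def component_density(self, which: str):
        a, b = self.params_low if which == "low" else self.params_high
        if self.family == "gaussian":
            return stats.norm(loc=a, scale=b)
        return stats.gamma(a=a, scale=b)


@dataclass(frozen=True)
class ExperimentSpec:
    """Study design for read-level simulation across technical replicates.

    Defaults model a well-separated setting: 1,000 functions of which 30%
    are planted present; present functions draw their per-replicate hit
    count from a negative binomial (mean 50, dispersion 5) with scores
    from a truncated Normal(60, 8); every function also receives
    Poisson(2) spurious hits with scores from a truncated Normal(20, 6);
    five technical replicates are drawn independently from the same spec.
    """

    n_functions: int = 1000
    fraction_present: float = 0.3
    reads_per_present_mean: float = 50.0
    reads_per_present_dispersion: float = 5.0
    spurious_hit_rate: float = 2.0
    score_high: tuple[float, float] = (60.0, 8.0)
    score_low: tuple[float, float] = (20.0, 6.0)
    n_replicates: int = 5
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_functions < 1 or self.n_replicates < 1:
            raise ValueError("n_functions and n_replicates must be >= 1")
        if not 0.0 < self.fraction_present < 1.0:
            raise ValueError("fraction_present must be in (0, 1)")
        if self.reads_per_present_mean <= 0 or self.reads_per_present_dispersion <= 0:
            raise ValueError("read-count mean and dispersion must be positive")
        if self.spurious_hit_rate < 0:
            raise ValueError("spurious_hit_rate must be >= 0")
        if self.score_high[0] <= self.score_low[0]:
            raise ValueError("high score mean must exceed low score mean")
        if min(self.score_high[1], self.score_low[1]) <= 0:
            raise ValueError("score standard deviations must be positive")


class ThresholdOracleResult(NamedTuple):
    """Independent weighted-density-crossing location for a mixture spec."""

    threshold: float
    crossing_found: bool


def simulate_evidence(spec: MixtureSpec) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``spec.n`` evidence values with ground-truth labels.

    Returns ``(values, labels)`` where ``labels`` is an integer array with
    0 for the low and 1 for the high component.  Reproducible given
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    labels = (rng.random(spec.n) < spec.weight_high).astype(int)
    values = np.empty(spec.n, dtype=float)
    for which, label in (("low", 0), ("high", 1)):
        mask = labels == label
        n_draw = int(mask.sum())
        if n_draw == 0:
            continue
        a, b = spec.params_low if which == "low" else spec.params_high
        if spec.family == "gaussian":
            values[mask] = rng.normal(a, b, size=n_draw)
        else:
            values[mask] = rng.gamma(shape=a, scale=b, size=n_draw)
    return values, labels


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    """Normal draws truncated at zero (rejection-free via the CDF trick)."""
    lo = stats.norm.cdf(0.0, loc=mean, scale=sd)
    u = rng.uniform(lo, 1.0, size=size)
    return stats.norm.ppf(u, loc=mean, scale=sd)


def simulate_hit_tables(
    spec: ExperimentSpec,
) -> tuple[list[HitTable], frozenset[str], frozenset[str]]:
    """Simulate per-replicate hit tables with a planted truth.

    Returns ``(tables, present, universe)``: one best-hit-resolved
    :class:`HitTable` per replicate (each simulated read carries exactly
    one function assignment), the planted set of present functions
    (exactly ``round(fraction_present * n_functions)`` of them, chosen at
    random), and the function universe.
    """
    rng = np.random.default_rng(spec.seed)
    width = len(str(spec.n_functions))
    function_ids = np.array(
        [f"F{i + 1:0{width}d}" for i in range(spec.n_functions)], dtype=object
    )
    n_present = round(spec.fraction_present * spec.n_functions)
    present_idx = rng.choice(spec.n_functions, size=n_present, replace=False)
    present_mask = np.zeros(spec.n_functions, dtype=bool)
    present_mask[present_idx] = True

    mean = spec.reads_per_present_mean
    disp = spec.reads_per_present_dispersion
    nb_p = disp / (disp + mean)

    tables: list[HitTable] = []
    for rep in range(spec.n_replicates):
        true_counts = np.zeros(spec.n_functions, dtype=int)
        true_counts[present_mask] = rng.negative_binomial(disp, nb_p, size=n_present)
        spurious_counts = rng.poisson(spec.spurious_hit_rate, size=spec.n_functions)

        fid_col = np.concatenate(
            [
                np.repeat(function_ids, true_counts),
                np.repeat(function_ids, spurious_counts),
            ]
        )
        scores = np.concatenate(
            [
                _truncated_normal(rng, *spec.score_high, size=int(true_counts.sum())),
                _truncated_normal(rng, *spec.score_low, size=int(spurious_counts.sum())),
            ]
        )
        n_reads = fid_col.size
        read_ids = np.array(
            [f"r{rep + 1}_{i + 1:07d}" for i in range(n_reads)], dtype=object
        )
        frame = pd.DataFrame(
            {
                "read_id": read_ids,
                "function_id": fid_col,
                "score": scores,
                "e_value": 10.0 ** (-scores / 10.0),
            }
        )
        tables.append(
            HitTable(
                sample_id=f"rep{rep + 1}",
                frame=frame,
                best_hit_resolved=True,
            )
        )
    present = frozenset(function_ids[present_mask])
    universe = frozenset(function_ids)
    return tables, present, universe


def bayes_threshold_oracle(
    spec: MixtureSpec, n_grid: int = 100_001
) -> ThresholdOracleResult:
    """Locate the weighted component-density crossing of a mixture spec.

    Scans a dense grid over the inter-mean interval for a sign change of
    ``weight_low * pdf_low - weight_high * pdf_high`` and refines the
    bracket with Brent's method.  Independent of the calibration module's
    threshold search, so the two can validate each other.  When the
    densities do not cross between the means, ``crossing_found`` is False
    and the threshold is NaN.
    """
    mean_low = spec.component_mean("low")
    mean_high = spec.component_mean("high")
    if mean_low >= mean_high:
        raise ValueError("low component mean must be below high component mean")
    pdf_low = spec.component_density("low").pdf
    pdf_high = spec.component_density("high").pdf

    def diff(t):
        return spec.weight_low * pdf_low(t) - spec.weight_high * pdf_high(t)

    grid = np.linspace(mean_low, mean_high, n_grid)
    d = diff(grid)
    idx = np.nonzero(np.diff(np.sign(d)) != 0)[0]
    if idx.size == 0:
        return ThresholdOracleResult(float("nan"), False)
    root = optimize.brentq(diff, grid[idx[0]], grid[idx[0] + 1], xtol=1e-12)
    return ThresholdOracleResult(float(root), True)
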