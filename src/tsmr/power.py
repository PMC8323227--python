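"""Statistical power for MR with a binary outcome, and its inversion to a
minimum detectable odds ratio.

Implements the mRnd binary-outcome calculation. For a case fraction
K = n_cases / N, instrument variance explained R² and true odds ratio
OR, the attenuated risk-difference effect is

    b = K * (OR / (1 + K*(OR - 1)) - 1)

its sampling variance v = (K*(1-K) - b²) / (N * R²), and the power is
the upper-tail probability of a noncentral chi-square with 1 degree of
freedom and noncentrality b²/v beyond the central chi-square (1-alpha)
quantile. At OR = 1 the noncentrality vanishes and power equals alpha.

The minimum detectable OR inverts this on a grid: the smallest OR above
1 (and, mirrored, the largest OR below 1) whose power reaches the
target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import chi2, ncx2


class PowerError(ValueError):
    pass


@dataclass(frozen=True)
class PowerDesign:
    """A binary-outcome MR design for power calculation."""

    n_cases: int
    n_controls: int
    r2: float = 0.0187
    alpha: float = 0.05
    power_target: float = 0.80

    def __post_init__(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise PowerError("case and control counts must be positive")
        if not 0.0 < self.r2 < 1.0:
            raise PowerError(f"r2 {self.r2} outside (0, 1)")
        if not 0.0 < self.alpha < 1.0:
            raise PowerError(f"alpha {self.alpha} outside (0, 1)")
        if not 0.0 < self.power_target < 1.0:
            raise PowerError(f"power_target {self.power_target} outside (0, 1)")

    @property
    def n(self) -> int:
        return self.n_cases + self.n_controls

    @property
    def k(self) -> float:
        """Case fraction."""
        return self.n_cases / self.n


@dataclass(frozen=True)
class MinDetectableOR:
    """Paired lower/upper detectable odds-ratio bounds at the target power."""

    or_lower: float
    or_upper: float
    grid_step: float

    def __post_init__(self) -> None:
        if not (self.or_lower < 1.0 < self.or_upper):
            raise PowerError("bounds must bracket OR = 1")


def mr_power_binary(design: PowerDesign, or_true: float) -> float:
    """Power to detect ``or_true`` under ``design`` (two-sided test)."""
    if or_true <= 0:
        raise PowerError(f"odds ratio {or_true} must be positive")
    k, n, r2 = design.k, design.n, design.r2
    b = k * (or_true / (1.0 + k * (or_true - 1.0)) - 1.0)
    var_num = k * (1.0 - k) - b * b
    if var_num <= 0:
        raise PowerError(f"degenerate variance at OR={or_true} (b² >= K(1-K))")
    v = var_num / (n * r2)
    ncp = b * b / v
    crit = chi2.ppf(1.0 - design.alpha, 1)
    return float(ncx2.sf(crit, 1, ncp))


def min_detectable_or(design: PowerDesign, grid_step: float = 0.01) -> MinDetectableOR:
    """Smallest OR > 1 and largest OR < 1 on the grid reaching the target
    power. Grid convention: {1 ± grid_step, 1 ± 2 grid_step, ...}."""
    if grid_step <= 0:
        raise PowerError(f"grid_step {grid_step} must be positive")
    target = design.power_target

    or_upper = None
    step = 1
    while True:
        or_ = 1.0 + step * grid_step
        if or_ > 10.0:
            raise PowerError("target power unreachable below OR = 10")
        if mr_power_binary(design, or_) >= target:
            or_upper = or_
            break
        step += 1

    or_lower = None
    step = 1
    while True:
        or_ = 1.0 - step * grid_step
        if or_ < 0.1:
            raise PowerError("target power unreachable above OR = 0.1")
        if mr_power_binary(design, or_) >= target:
            or_lower = or_
            break
        step += 1

    return MinDetectableOR(round(or_lower, 10), round(or_upper, 10), grid_step)


def mr_power_continuous(
    n: int, r2: float, beta_sd: float, alpha: float = 0.05
) -> float:
    """Power for a continuous outcome (SD scale): noncentrality N R² b².

    Provided for the reverse direction of a bi-directional design; the
    analogous mRnd continuous-outcome approximation with unit outcome
    variance.
    """
    if n <= 0 or not 0.0 < r2 < 1.0 or not 0.0 < alpha < 1.0:
        raise PowerError("invalid design")
    ncp = n * r2 * beta_sd * beta_sd
    crit = chi2.ppf(1.0 - alpha, 1)
    return float(ncx2.sf(crit, 1, ncp))
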