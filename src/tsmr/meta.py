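"""Random-effects meta-analysis (DerSimonian-Laird) and Egger's
publication-bias test.

Used two ways in a bi-directional MR study: pooling causal odds ratios
for the same outcome across datasets, and pooling published
highest-versus-lowest relative risks across prospective studies. All
pooling is on the log scale; printed OR/RR confidence intervals are
converted to standard errors with se = (ln hi - ln lo) / (2 * 1.959964).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2
from scipy.stats import t as t_dist

Z95 = 1.959964


class MetaError(ValueError):
    pass


@dataclass(frozen=True)
class MetaInput:
    """One study's effect on the log scale (log OR or log RR)."""

    label: str
    effect: float
    se: float

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise MetaError(f"{self.label}: se must be positive")

    @classmethod
    def from_ratio_ci(
        cls, label: str, point: float, ci_low: float, ci_high: float
    ) -> "MetaInput":
        """Build from a published ratio (OR/RR) with its 95% CI."""
        if not 0 < ci_low < point < ci_high:
            raise MetaError(
                f"{label}: need 0 < ci_low < point < ci_high, got "
                f"{ci_low}, {point}, {ci_high}"
            )
        se = (math.log(ci_high) - math.log(ci_low)) / (2.0 * Z95)
        return cls(label, math.log(point), se)

    def ratio_ci(self) -> tuple[float, float, float]:
        """(point, ci_low, ci_high) back on the ratio scale."""
        return (
            math.exp(self.effect),
            math.exp(self.effect - Z95 * self.se),
            math.exp(self.effect + Z95 * self.se),
        )


@dataclass(frozen=True)
class MetaResult:
    """Pooled random-effects estimate on the log scale."""

    pooled: float
    se: float
    ci_low: float
    ci_high: float
    tau2: float
    q: float
    q_df: int
    q_p: float
    i2: float
    n_studies: int

    def ratio(self) -> tuple[float, float, float]:
        return math.exp(self.pooled), math.exp(self.ci_low), math.exp(self.ci_high)


def dl_random_effects(inputs: list[MetaInput]) -> MetaResult:
    """DerSimonian-Laird pooling.

    Fixed-effect weights 1/se² give Cochran's Q about the fixed-effect
    mean; the moment estimator tau² = max(0, (Q - df) / (S1 - S2/S1))
    with S1 = sum(w), S2 = sum(w²); random-effects weights 1/(se²+tau²)
    give the pooled mean with a normal 95% CI.
    """
    if len(inputs) < 2:
        raise MetaError("meta-analysis needs at least 2 studies")
    e = np.array([s.effect for s in inputs])
    se = np.array([s.se for s in inputs])
    w = 1.0 / (se * se)
    fe = float(np.sum(w * e) / np.sum(w))
    q = float(np.sum(w * (e - fe) ** 2))
    df = len(inputs) - 1
    s1 = float(np.sum(w))
    s2 = float(np.sum(w * w))
    tau2 = max(0.0, (q - df) / (s1 - s2 / s1))
    wr = 1.0 / (se * se + tau2)
    pooled = float(np.sum(wr * e) / np.sum(wr))
    se_p = float(1.0 / math.sqrt(np.sum(wr)))
    i2 = max(0.0, (q - df) / q) if q > 0 else 0.0
    return MetaResult(
        pooled=pooled,
        se=se_p,
        ci_low=pooled - Z95 * se_p,
        ci_high=pooled + Z95 * se_p,
        tau2=tau2,
        q=q,
        q_df=df,
        q_p=float(chi2.sf(q, df)),
        i2=i2,
        n_studies=len(inputs),
    )


def egger_asymmetry(inputs: list[MetaInput]) -> tuple[float, float, float]:
    """Egger's funnel-asymmetry test.

    Regresses the standardized effect (effect/se) on precision (1/se);
    returns the intercept, its SE and a two-sided p-value (t
    distribution, n-2 df). A nonzero intercept indicates small-study
    asymmetry such as publication bias.
    """
    n = len(inputs)
    if n < 3:
        raise MetaError("Egger's test needs at least 3 studies")
    z = np.array([s.effect / s.se for s in inputs])
    prec = np.array([1.0 / s.se for s in inputs])
    X = np.column_stack([np.ones(n), prec])
    coef, res, *_ = np.linalg.lstsq(X, z, rcond=None)
    resid = z - X @ coef
    s2 = float(np.sum(resid**2)) / (n - 2)
    cov = np.linalg.inv(X.T @ X) * s2
    intercept = float(coef[0])
    se_int = float(math.sqrt(cov[0, 0]))
    if se_int == 0:
        p = 1.0 if intercept == 0 else 0.0
    else:
        p = float(2.0 * t_dist.sf(abs(intercept / se_int), n - 2))
    return intercept, se_int, p


def read_meta_inputs(path: str) -> list[MetaInput]:
    """Read studies from TSV: either (label, point, ci_low, ci_high) on
    the ratio scale or (label, log_effect, se) on the log scale."""
    df = pd.read_csv(path, sep="\t")
    cols = set(df.columns)
    if {"label", "point", "ci_low", "ci_high"} <= cols:
        return [
            MetaInput.from_ratio_ci(r.label, r.point, r.ci_low, r.ci_high)
            for r in df.itertuples(index=False)
        ]
    if {"label", "log_effect", "se"} <= cols:
        return [
            MetaInput(r.label, r.log_effect, r.se) for r in df.itertuples(index=False)
        ]
    raise MetaError(
        "need columns (label, point, ci_low, ci_high) or (label, log_effect, se)"
    )
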