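"""Subgroup meta-analysis and a priori power for binary-outcome MR.

``subgroup_meta`` pools causal estimates across related outcomes (cancer
subtypes, subsites, sexes) with a fixed-effect model and quantifies their
heterogeneity with Q and I^2.

``mr_power`` / ``min_detectable_or`` implement the standard
normal-approximation power calculation for two-sample MR with a binary
outcome: with N subjects, case fraction K, and instruments explaining a
fraction R^2 of exposure variance, the non-centrality of the causal test
is |ln OR| * sqrt(N * R^2 * K * (1-K)), so

    power = Phi(|ln OR| * sqrt(N R^2 K (1-K)) - z_{1-alpha/2}).

Two-sided alpha throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .estimators import MREstimate, QResult
from .exceptions import MRError, ValidationError


@dataclass
class MetaResult:
    """Fixed-effect pooled estimate with between-group heterogeneity."""

    beta: float
    se: float
    pval: float
    m: int
    heterogeneity: QResult

    @property
    def I2(self) -> float:
        return self.heterogeneity.I2

    def summary(self) -> str:
        return (
            f"fixed-effect pool of {self.m} groups: beta={self.beta:.4f} "
            f"(se {self.se:.4f}), p={self.pval:.3g}; "
            f"between-group {self.heterogeneity_str()}"
        )

    def heterogeneity_str(self) -> str:
        h = self.heterogeneity
        return f"Q={h.Q:.2f} (df={h.df}), p_het={h.pval:.2g}, I2={h.I2:.0f}%"


def subgroup_meta(estimates: list[MREstimate]) -> MetaResult:
    """Pool subgroup estimates (log-OR scale) with inverse-variance weights.

    Raises
    ------
    MRError
        Fewer than two groups, or any estimate lacking an SE.
    """
    if len(estimates) < 2:
        raise MRError("subgroup meta-analysis needs at least 2 estimates")
    if any(e.se is None for e in estimates):
        raise MRError("every estimate must carry a standard error")
    b = np.array([e.beta for e in estimates])
    se = np.array([e.se for e in estimates])
    w = 1.0 / se**2
    pooled = float(np.sum(w * b) / np.sum(w))
    pooled_se = float(np.sum(w) ** -0.5)
    Q = float(np.sum(w * (b - pooled) ** 2))
    df = len(b) - 1
    return MetaResult(
        beta=pooled,
        se=pooled_se,
        pval=float(2 * stats.norm.sf(abs(pooled / pooled_se))),
        m=len(b),
        heterogeneity=QResult(Q=Q, df=df, pval=float(stats.chi2.sf(Q, df))),
    )


@dataclass
class PowerSpec:
    """Design parameters for a binary-outcome MR power calculation."""

    n_total: int
    n_cases: int
    r2: float
    alpha: float = 0.05
    target_power: float = 0.80
    or_grid_step: float = 0.01

    def __post_init__(self) -> None:
        if not 0 < self.n_cases < self.n_total:
            raise ValidationError("need 0 < n_cases < n_total")
        if not 0 < self.r2 < 1:
            raise ValidationError("instrument r2 must lie in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must lie in (0, 1)")
        if not 0 < self.target_power < 1:
            raise ValidationError("target power must lie in (0, 1)")

    @property
    def case_fraction(self) -> float:
        return self.n_cases / self.n_total


def mr_power(spec: PowerSpec, or_alt: float) -> float:
    """Power to detect ``or_alt`` (OR per 1-SD exposure) at ``spec.alpha``."""
    if or_alt <= 0:
        raise ValidationError("odds ratio must be positive")
    K = spec.case_fraction
    ncp = abs(np.log(or_alt)) * np.sqrt(spec.n_total * spec.r2 * K * (1 - K))
    z = stats.norm.ppf(1 - spec.alpha / 2)
    return float(stats.norm.cdf(ncp - z))


@dataclass
class MinDetectableOR:
    """Grid-search and closed-form minimum detectable odds ratios."""

    grid: float
    closed_form: float
    power_at_grid: float

    def summary(self) -> str:
        return (
            f"minimum detectable OR per SD: {self.grid:.2f} "
            f"(power {self.power_at_grid:.1%}; closed form {self.closed_form:.4f})"
        )


def min_detectable_or(spec: PowerSpec, max_or: float = 10.0) -> MinDetectableOR:
    """Smallest OR on the grid with power above ``spec.target_power``.

    Searches upward from 1.00 in ``or_grid_step`` increments and also
    returns the closed-form threshold
    exp((z_{1-alpha/2} + z_{power}) / sqrt(N R^2 K (1-K))).
    """
    K = spec.case_fraction
    denom = np.sqrt(spec.n_total * spec.r2 * K * (1 - K))
    closed = float(
        np.exp(
            (stats.norm.ppf(1 - spec.alpha / 2) + stats.norm.ppf(spec.target_power))
            / denom
        )
    )
    steps = int(np.ceil((max_or - 1.0) / spec.or_grid_step)) + 1
    for i in range(steps):
        or_alt = round(1.0 + i * spec.or_grid_step, 10)
        p = mr_power(spec, or_alt)
        if p > spec.target_power:
            return MinDetectableOR(grid=or_alt, closed_form=closed, power_at_grid=p)
    raise MRError(f"no OR below {max_or} reaches the target power")
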