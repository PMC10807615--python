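"""Synthetic two-sample GWAS summary statistics with known causal truth.

Emulates the data-generating structure a two-sample MR design assumes:
independent (post-clumping) instruments, SNP-exposure effects explaining
a chosen fraction of exposure variance in one cohort, and SNP-outcome
effects measured in a disjoint cohort, optionally contaminated with
horizontal pleiotropy.

Per SNP j with effect-allele frequency f_j:

* gamma_j — true SNP-exposure effect, drawn N(0,1) then rescaled so that
  sum 2 f_j (1-f_j) gamma_j^2 equals ``h2x`` exactly;
* alpha_j — true direct SNP-outcome effect:
  Bernoulli(pi) * (mu_alpha + sigma_alpha * Z_j) + psi * gamma_j, where a
  non-zero psi couples alpha to instrument strength (an InSIDE violation);
* Gamma_j = theta * gamma_j + alpha_j — true SNP-outcome effect;
* observed betas are drawn independently around the truth with standard
  GWAS standard errors, se = 1/sqrt(2 f (1-f) n) for continuous traits and
  se = 1/sqrt(2 f (1-f) n K (1-K)) on the log-odds scale for binary ones.

Binary outcomes are generated directly on the log-odds scale with the
K(1-K) variance factor (consistent with the power module) rather than via
a liability model — a documented approximation. Defaults mirror a large
sedentary-behaviour exposure GWAS (J=200 instruments, h2x=2%, n=408,815)
paired with a colorectal-cancer-scale case-control outcome.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ValidationError
from .sumstats import SumStatsTable

def _pval(beta, se):
    """Two-sided normal p, floored at the smallest positive float so that
    extreme z scores never underflow outside the (0, 1] invariant."""
    return np.maximum(2 * stats.norm.sf(np.abs(beta / se)), np.finfo(float).tiny)


# ordered, non-palindromic allele pairs assigned cyclically to simulated SNPs
_ALLELE_PAIRS = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C"), ("A", "C"), ("G", "T")]


@dataclass
class PleiotropyConfig:
    """Direct-effect contamination of the instruments."""

    pi: float = 0.0  # fraction of SNPs with direct outcome effects
    mu_alpha: float = 0.0  # mean direct effect (directional when != 0)
    sigma_alpha: float = 0.0  # spread of direct effects
    inside_violation_psi: float = 0.0  # couples alpha to gamma


@dataclass
class SimConfig:
    """Study conditions for one simulated exposure/outcome pair."""

    J: int = 200
    maf_range: tuple[float, float] = (0.05, 0.5)
    h2x: float = 0.02
    theta: float = 0.0
    pleiotropy: PleiotropyConfig = field(default_factory=PleiotropyConfig)
    n_exp: int = 408_815
    n_out: int = 98_715
    case_fraction: float = 52_775 / 98_715
    outcome_type: str = "binary"
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.h2x < 1:
            raise ValidationError("h2x must lie in (0, 1)")
        if not 0 <= self.pleiotropy.pi <= 1:
            raise ValidationError("pleiotropy.pi must lie in [0, 1]")
        if self.outcome_type not in ("continuous", "binary"):
            raise ValidationError("outcome_type must be continuous or binary")
        if self.outcome_type == "binary" and not 0 < self.case_fraction < 1:
            raise ValidationError("case_fraction must lie in (0, 1)")


@dataclass
class SimTruth:
    """Ground-truth parameters behind a simulated dataset."""

    gamma: np.ndarray
    alpha: np.ndarray
    theta: float
    h2x_realized: float
    maf: np.ndarray
    seed: int | None


def simulate_pair(
    config: SimConfig,
) -> tuple[SumStatsTable, SumStatsTable, SimTruth]:
    """Simulate an exposure table, an outcome table and their ground truth.

    The two observed tables are drawn with independent noise, matching the
    non-overlapping samples of a two-sample design. Identical seeds give
    bitwise-identical tables.
    """
    rng = np.random.default_rng(config.seed)
    J = config.J
    f = rng.uniform(*config.maf_range, size=J)
    gamma = rng.normal(0.0, 1.0, size=J)
    gamma *= np.sqrt(config.h2x / np.sum(2 * f * (1 - f) * gamma**2))

    pl = config.pleiotropy
    has_direct = rng.random(J) < pl.pi
    alpha = has_direct * (pl.mu_alpha + pl.sigma_alpha * rng.normal(size=J))
    alpha = alpha + pl.inside_violation_psi * gamma
    Gamma = config.theta * gamma + alpha

    se_x = 1.0 / np.sqrt(2 * f * (1 - f) * config.n_exp)
    if config.outcome_type == "binary":
        K = config.case_fraction
        se_y = 1.0 / np.sqrt(2 * f * (1 - f) * config.n_out * K * (1 - K))
        n_cases = int(round(K * config.n_out))
    else:
        se_y = 1.0 / np.sqrt(2 * f * (1 - f) * config.n_out)
        n_cases = None

    beta_x = rng.normal(gamma, se_x)
    beta_y = rng.normal(Gamma, se_y)

    rsid = np.array([f"rs{j + 1:07d}" for j in range(J)])
    ea = np.array([_ALLELE_PAIRS[j % len(_ALLELE_PAIRS)][0] for j in range(J)])
    oa = np.array([_ALLELE_PAIRS[j % len(_ALLELE_PAIRS)][1] for j in range(J)])

    def table(beta, se, trait, trait_type, n, n_cases=None):
        return SumStatsTable(
            trait_label=trait,
            trait_type=trait_type,
            records=pd.DataFrame(
                {
                    "rsid": rsid,
                    "effect_allele": ea,
                    "other_allele": oa,
                    "eaf": f,
                    "beta": beta,
                    "se": se,
                    "pval": _pval(beta, se),
                    "n_total": n,
                    "n_cases": n_cases,
                }
            ),
        )

    exposure = table(beta_x, se_x, "sim_exposure", "continuous", config.n_exp)
    outcome = table(
        beta_y, se_y, "sim_outcome", config.outcome_type, config.n_out, n_cases
    )
    truth = SimTruth(
        gamma=gamma,
        alpha=alpha,
        theta=config.theta,
        h2x_realized=float(np.sum(2 * f * (1 - f) * gamma**2)),
        maf=f,
        seed=config.seed,
    )
    return exposure, outcome, truth


def inject_outliers(
    outcome: SumStatsTable, indices, offset_in_se_units: float
) -> SumStatsTable:
    """Shift selected outcome betas by ``offset * se`` (pleiotropic spikes).

    Returns a new table; the injected rows are recorded on its
    ``injected`` attribute (rsid and offset applied) for spike-recovery
    harnesses.
    """
    indices = np.asarray(indices, dtype=int)
    if len(indices) and (indices.min() < 0 or indices.max() >= len(outcome.records)):
        raise IndexError("outlier index out of range")
    records = outcome.records.copy()
    records.loc[indices, "beta"] = (
        records.loc[indices, "beta"] + offset_in_se_units * records.loc[indices, "se"]
    )
    out = SumStatsTable(
        trait_label=outcome.trait_label,
        trait_type=outcome.trait_type,
        sd_units=outcome.sd_units,
        records=records,
    )
    out.injected = pd.DataFrame(
        {
            "rsid": records.loc[indices, "rsid"].to_numpy(),
            "offset_in_se_units": offset_in_se_units,
        }
    )
    return out


def two_exposure_pair(
    config: SimConfig,
    theta2: float,
    rg: float = 0.0,
    h2x2: float | None = None,
    n_exp2: int | None = None,
    label1: str = "sim_exposure_1",
    label2: str = "sim_exposure_2",
):
    """Simulate two exposures with genetic correlation ``rg`` and one outcome.

    The second exposure's per-SNP effects are
    gamma2 = rg * gamma1 + sqrt(1 - rg^2) * e (rescaled to ``h2x2``), and
    the outcome's true effects are theta*gamma1 + theta2*gamma2. Used for
    multivariable recovery and conditional-F behaviour under correlated
    exposures (e.g. television watching vs years of education).
    """
    rng = np.random.default_rng(config.seed)
    base_seed = rng.integers(2**31)
    exposure, outcome, truth = simulate_pair(replace(config, seed=int(base_seed)))
    f = truth.maf
    h2x2 = config.h2x if h2x2 is None else h2x2
    n_exp2 = config.n_exp if n_exp2 is None else n_exp2

    e = rng.normal(size=config.J)
    g2 = rg * truth.gamma / np.sqrt(np.sum(2 * f * (1 - f) * truth.gamma**2)) * np.sqrt(
        h2x2
    ) + np.sqrt(max(0.0, 1 - rg**2)) * e * np.sqrt(
        h2x2 / max(np.sum(2 * f * (1 - f) * e**2), np.finfo(float).tiny)
    )
    se_x2 = 1.0 / np.sqrt(2 * f * (1 - f) * n_exp2)
    beta_x2 = rng.normal(g2, se_x2)

    records = exposure.records.copy()
    records["beta"] = beta_x2
    records["se"] = se_x2
    records["pval"] = _pval(beta_x2, se_x2)
    records["n_total"] = n_exp2
    exposure2 = SumStatsTable(
        trait_label=label2, trait_type="continuous", records=records
    )
    exposure.trait_label = label1

    # rebuild the outcome around the joint truth
    Gamma = config.theta * truth.gamma + theta2 * g2 + truth.alpha
    out_records = outcome.records.copy()
    se_y = out_records["se"].to_numpy()
    beta_y = rng.normal(Gamma, se_y)
    out_records["beta"] = beta_y
    out_records["pval"] = _pval(beta_y, se_y)
    outcome2 = SumStatsTable(
        trait_label=outcome.trait_label,
        trait_type=outcome.trait_type,
        records=out_records,
    )
    return exposure, exposure2, outcome2, truth, g2
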