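"""Univariable two-sample MR estimators.

Implements, as explicit closed-form algebra on a
:class:`~mrkit.sumstats.HarmonisedSet`:

* per-SNP Wald ratios (first-order delta-method SEs),
* the inverse-variance-weighted (IVW) estimate — algebraically the
  weighted regression of SNP-outcome on SNP-exposure effects through the
  origin with weights 1/se_out^2 — in fixed-effect, multiplicative
  random-effects, and automatic (random when Cochran's Q p <= 0.05) forms,
* MR-Egger regression (unconstrained intercept; the intercept tests
  directional pleiotropy, the slope estimates the causal effect under the
  InSIDE assumption),
* the weighted-median estimator with a seeded parametric bootstrap SE,
* Cochran's Q and I^2 heterogeneity statistics.

The statsmodels-style entry point is :class:`TwoSampleMR`: build the model
from harmonised data (or a pair of summary tables) and ``fit`` it with the
method of choice; every fit returns a results object with ``summary()``.

Causal effects are per 1 SD of the exposure; for binary outcomes
``or_view`` re-expresses them as odds ratios per SD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    DegenerateInstrumentError,
    EmptySetError,
    InsufficientInstrumentsError,
    MRError,
)
from .sumstats import HarmonisedSet, SumStatsTable, harmonise

Z975 = float(stats.norm.ppf(0.975))


# ----------------------------------------------------------------------
# Results containers
# ----------------------------------------------------------------------

@dataclass
class MREstimate:
    """A causal-effect estimate per 1-SD exposure increment."""

    method: str
    beta: float
    se: float | None
    pval: float | None
    k: int
    exposure: str = ""
    outcome: str = ""

    @property
    def ci95(self) -> tuple[float, float]:
        if self.se is None:
            return (float("nan"), float("nan"))
        return (self.beta - Z975 * self.se, self.beta + Z975 * self.se)

    @property
    def or_view(self) -> tuple[float, float, float]:
        """(OR, lower, upper) per 1 SD for binary outcomes (log-odds betas)."""
        lo, hi = self.ci95
        return (float(np.exp(self.beta)), float(np.exp(lo)), float(np.exp(hi)))

    def summary(self) -> str:
        o, lo, hi = self.or_view
        clo, chi = self.ci95
        p = "NA" if self.pval is None else f"{self.pval:.3g}"
        return (
            f"{self.method} ({self.exposure} -> {self.outcome}, k={self.k}): "
            f"beta={self.beta:.4f} (95% CI {clo:.4f} to {chi:.4f}), "
            f"OR per SD={o:.2f} ({lo:.2f}-{hi:.2f}), p={p}"
        )


@dataclass
class QResult:
    """Cochran's Q heterogeneity across per-SNP (or per-group) estimates."""

    Q: float
    df: int
    pval: float

    @property
    def I2(self) -> float:
        """Percent of variation attributable to heterogeneity, floored at 0."""
        if self.Q <= 0:
            return 0.0
        return max(0.0, (self.Q - self.df) / self.Q) * 100.0

    def summary(self) -> str:
        return f"Q={self.Q:.3f} (df={self.df}), p={self.pval:.3g}, I2={self.I2:.1f}%"


@dataclass
class EggerResult:
    """MR-Egger slope (causal effect) and intercept (pleiotropy test)."""

    slope: MREstimate
    intercept_estimate: float
    intercept_se: float
    intercept_pval: float
    dispersion: float = 1.0

    def summary(self) -> str:
        return (
            self.slope.summary()
            + f"\n  intercept={self.intercept_estimate:.4f} "
            f"(se {self.intercept_se:.4f}), p={self.intercept_pval:.3g}"
        )


# ----------------------------------------------------------------------
# Estimators
# ----------------------------------------------------------------------

def wald_ratios(h: HarmonisedSet) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP causal ratios beta_out/beta_exp and first-order SEs.

    Raises
    ------
    DegenerateInstrumentError
        If any SNP-exposure effect is exactly zero.
    """
    zero = h.beta_exp == 0
    if np.any(zero):
        raise DegenerateInstrumentError(
            f"zero exposure effect for SNP(s): {', '.join(h.rsid[zero][:5])}"
        )
    ratio = h.beta_out / h.beta_exp
    se = h.se_out / np.abs(h.beta_exp)
    return ratio, se


def cochran_q(ratios: np.ndarray, ses: np.ndarray) -> QResult:
    """Cochran's Q across per-SNP causal estimates; p <= 0.05 flags pleiotropy."""
    ratios = np.asarray(ratios, float)
    ses = np.asarray(ses, float)
    k = len(ratios)
    if k < 2:
        raise InsufficientInstrumentsError("Cochran's Q needs at least 2 SNPs")
    w = 1.0 / ses**2
    pooled = np.sum(w * ratios) / np.sum(w)
    Q = float(np.sum(w * (ratios - pooled) ** 2))
    df = k - 1
    pval = float(stats.chi2.sf(Q, df))
    return QResult(Q=Q, df=df, pval=pval)


def ivw(h: HarmonisedSet, model: str = "auto") -> tuple[MREstimate, QResult | None]:
    """Inverse-variance-weighted causal estimate with heterogeneity.

    ``model`` is ``"fixed"``, ``"random"`` (multiplicative overdispersion,
    floored at 1, df = k-1) or ``"auto"`` (fixed unless Q's p <= 0.05).
    With a single SNP the Wald ratio is returned and Q is None.
    """
    if model not in ("fixed", "random", "auto"):
        raise ValueError(f"unknown IVW model {model!r}")
    if h.k == 0:
        raise EmptySetError("no SNPs available for IVW")
    ratio, se = wald_ratios(h)
    w = 1.0 / se**2
    beta = float(np.sum(w * ratio) / np.sum(w))
    se_fixed = float(np.sum(w) ** -0.5)
    if h.k == 1:
        est = MREstimate(
            method="wald",
            beta=beta,
            se=se_fixed,
            pval=float(2 * stats.norm.sf(abs(beta / se_fixed))),
            k=1,
            exposure=h.exposure_label,
            outcome=h.outcome_label,
        )
        return est, None
    q = cochran_q(ratio, se)
    use_random = model == "random" or (model == "auto" and q.pval <= 0.05)
    scale = max(1.0, np.sqrt(q.Q / q.df)) if use_random else 1.0
    se_final = se_fixed * scale
    est = MREstimate(
        method="ivw_random" if use_random else "ivw_fixed",
        beta=beta,
        se=se_final,
        pval=float(2 * stats.norm.sf(abs(beta / se_final))),
        k=h.k,
        exposure=h.exposure_label,
        outcome=h.outcome_label,
    )
    return est, q


def egger(h: HarmonisedSet) -> EggerResult:
    """MR-Egger regression with multiplicative overdispersion.

    Each SNP is oriented so the exposure effect is non-negative (both
    betas flipped together), then SNP-outcome effects are regressed on
    SNP-exposure effects with an unconstrained intercept and weights
    1/se_out^2. Both SEs are scaled by max(1, sqrt(RSS_w/(k-2)));
    intercept p-values use t(k-2), slope p-values the normal.
    """
    if h.k < 3:
        raise InsufficientInstrumentsError(
            f"MR-Egger needs at least 3 SNPs, got {h.k}"
        )
    flip = np.sign(h.beta_exp)
    flip[flip == 0] = 1.0
    x = h.beta_exp * flip
    y = h.beta_out * flip
    w = 1.0 / h.se_out**2

    # closed-form weighted least squares with intercept
    sw = np.sum(w)
    xbar = np.sum(w * x) / sw
    ybar = np.sum(w * y) / sw
    sxx = np.sum(w * (x - xbar) ** 2)
    if sxx <= np.finfo(float).tiny:
        raise MRError(
            "exposure effects show no variation after orientation; "
            "the Egger intercept and slope are not separable"
        )
    slope = float(np.sum(w * (x - xbar) * (y - ybar)) / sxx)
    intercept = float(ybar - slope * xbar)
    resid = y - intercept - slope * x
    rss_w = float(np.sum(w * resid**2))
    dispersion = max(1.0, np.sqrt(rss_w / (h.k - 2)))
    se_slope = float(np.sqrt(1.0 / sxx)) * dispersion
    se_int = float(np.sqrt(1.0 / sw + xbar**2 / sxx)) * dispersion

    slope_est = MREstimate(
        method="egger_slope",
        beta=slope,
        se=se_slope,
        pval=float(2 * stats.norm.sf(abs(slope / se_slope))),
        k=h.k,
        exposure=h.exposure_label,
        outcome=h.outcome_label,
    )
    return EggerResult(
        slope=slope_est,
        intercept_estimate=intercept,
        intercept_se=se_int,
        intercept_pval=float(2 * stats.t.sf(abs(intercept / se_int), h.k - 2)),
        dispersion=dispersion,
    )


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Weight-ordered median by linear interpolation at cumulative weight 1/2.

    Uses the midpoint convention: the j-th sorted ratio sits at normalized
    cumulative weight (S_{j-1} + S_j) / (2 S_k).
    """
    order = np.argsort(ratios, kind="stable")
    r = ratios[order]
    w = weights[order]
    s = np.cumsum(w)
    p = (s - w / 2) / s[-1]
    return float(np.interp(0.5, p, r))


def weighted_median(
    h: HarmonisedSet, n_boot: int = 1000, seed: int | None = None
) -> MREstimate:
    """Weighted-median causal estimate, valid with <50% invalid weight.

    The SE is the standard deviation of the estimate over ``n_boot``
    parametric-bootstrap resamples (per-SNP betas redrawn from
    N(beta, se)); pass ``n_boot=0`` to skip the bootstrap and return the
    point estimate alone (se, p and CI then unavailable).
    """
    if h.k < 3:
        raise InsufficientInstrumentsError(
            f"weighted median needs at least 3 SNPs, got {h.k}"
        )
    ratio, se_ratio = wald_ratios(h)
    w = 1.0 / se_ratio**2
    beta = _weighted_median(ratio, w)

    se = pval = None
    if n_boot:
        rng = np.random.default_rng(seed)
        bx = rng.normal(h.beta_exp, h.se_exp, size=(n_boot, h.k))
        by = rng.normal(h.beta_out, h.se_out, size=(n_boot, h.k))
        bx[bx == 0] = np.finfo(float).tiny  # guard degenerate resamples
        rat = by / bx
        wgt = (np.abs(bx) / h.se_out) ** 2
        boots = np.empty(n_boot)
        for b in range(n_boot):
            boots[b] = _weighted_median(rat[b], wgt[b])
        se = float(np.std(boots, ddof=1))
        pval = float(2 * stats.norm.sf(abs(beta / se))) if se > 0 else 0.0
    return MREstimate(
        method="weighted_median",
        beta=beta,
        se=se,
        pval=pval,
        k=h.k,
        exposure=h.exposure_label,
        outcome=h.outcome_label,
    )


# ----------------------------------------------------------------------
# Model object
# ----------------------------------------------------------------------

class TwoSampleMR:
    """Univariable two-sample MR model over harmonised summary statistics.

    Examples
    --------
    >>> model = TwoSampleMR.from_tables(exposure_table, outcome_table)
    >>> res = model.fit()                     # IVW, auto fixed/random
    >>> res.summary()
    >>> model.fit(method="egger").summary()
    """

    def __init__(self, data: HarmonisedSet):
        self.data = data

    @classmethod
    def from_tables(
        cls,
        exposure: SumStatsTable,
        outcome: SumStatsTable,
        palindrome_eaf_window: float = 0.08,
    ) -> "TwoSampleMR":
        return cls(harmonise(exposure, outcome, palindrome_eaf_window))

    @property
    def k(self) -> int:
        return self.data.k

    def wald_ratios(self):
        return wald_ratios(self.data)

    def heterogeneity(self) -> QResult:
        return cochran_q(*wald_ratios(self.data))

    def fit(self, method: str = "ivw", **kwargs):
        """Fit one estimator; returns its results object.

        ``method`` is one of ``ivw`` (kwargs: ``model``), ``egger``,
        ``weighted_median`` (kwargs: ``n_boot``, ``seed``) or ``presso``
        (kwargs: ``n_sim``, ``sig``, ``seed``).
        """
        if method == "ivw":
            est, q = ivw(self.data, **kwargs)
            est.heterogeneity = q
            return est
        if method == "egger":
            return egger(self.data, **kwargs)
        if method == "weighted_median":
            return weighted_median(self.data, **kwargs)
        if method == "presso":
            from .presso import mr_presso

            return mr_presso(self.data, **kwargs)
        raise ValueError(f"unknown method {method!r}")

    def fit_all(
        self,
        ivw_model: str = "auto",
        n_boot: int = 1000,
        presso_n_sim: int = 1000,
        presso_sig: float = 0.05,
        seed: int | None = None,
    ) -> pd.DataFrame:
        """Run the full estimator suite, gated on instrument count.

        Returns a tidy frame with one row per method; methods whose
        minimum SNP count is not met appear as ``not_run`` rows with the
        reason, mirroring empty sensitivity cells in reported tables.
        """
        from .presso import mr_presso

        rows = []

        def row(est: MREstimate, extra=None):
            lo, hi = est.ci95
            o, olo, ohi = est.or_view
            d = {
                "exposure": self.data.exposure_label,
                "outcome": self.data.outcome_label,
                "method": est.method,
                "k": est.k,
                "beta": est.beta,
                "se": est.se,
                "ci_low": lo,
                "ci_high": hi,
                "pval": est.pval,
                "or": o,
                "or_low": olo,
                "or_high": ohi,
                "note": "",
            }
            if extra:
                d.update(extra)
            return d

        est, q = ivw(self.data, model=ivw_model)
        rows.append(
            row(est, {"het_Q": q.Q, "het_p": q.pval, "het_I2": q.I2} if q else None)
        )
        for method, min_k, run in [
            ("egger_slope", 3, lambda: egger(self.data)),
            ("weighted_median", 3, lambda: weighted_median(self.data, n_boot, seed)),
            (
                "presso_corrected",
                4,
                lambda: mr_presso(self.data, presso_n_sim, presso_sig, seed),
            ),
        ]:
            if self.data.k < min_k:
                rows.append(
                    {
                        "exposure": self.data.exposure_label,
                        "outcome": self.data.outcome_label,
                        "method": method,
                        "k": self.data.k,
                        "note": f"not run: needs >= {min_k} SNPs",
                    }
                )
                continue
            try:
                res = run()
            except MRError as exc:
                rows.append(
                    {
                        "exposure": self.data.exposure_label,
                        "outcome": self.data.outcome_label,
                        "method": method,
                        "k": self.data.k,
                        "note": f"not run: {exc}",
                    }
                )
                continue
            if isinstance(res, EggerResult):
                rows.append(
                    row(
                        res.slope,
                        {
                            "egger_intercept": res.intercept_estimate,
                            "egger_intercept_p": res.intercept_pval,
                        },
                    )
                )
            elif isinstance(res, MREstimate):
                rows.append(row(res))
            else:  # PressoResult
                est_p = res.corrected if res.corrected is not None else res.raw
                r = row(
                    est_p,
                    {
                        "presso_global_p": res.global_p,
                        "presso_outliers": ",".join(res.outlier_rsids),
                        "presso_distortion_p": res.distortion_p,
                    },
                )
                r["method"] = "presso_corrected"
                if res.corrected is None:
                    r["note"] = "no outliers flagged; raw IVW retained"
                rows.append(r)
        return pd.DataFrame(rows)
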