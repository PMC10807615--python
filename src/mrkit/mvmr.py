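"""Multivariable MR and conditional instrument-strength diagnostics.

Multivariable MR regresses SNP-outcome effects jointly on several
SNP-exposure effect columns (no intercept, weights 1/se_out^2), so each
coefficient is one exposure's direct effect holding the others fixed —
the tool used here to ask whether a sedentary-behaviour association
survives adjustment for BMI, education, smoking or alcohol.

The instrument set is the union of each exposure's instruments,
cross-exposure clumped (default r^2 < 0.001, greedy by best p across
exposures) and harmonised to a single orientation. Conditional
F-statistics measure how strongly the SNPs predict each exposure given
the others; values above ~10 indicate adequate conditional strength, and
strongly genetically correlated exposure pairs (e.g. television watching
and years of education) push them far below that.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import Z975, MREstimate
from .exceptions import CollinearityError, UnderIdentifiedError, ValidationError
from .instruments import LDMatrix
from .sumstats import SumStatsTable, align_orientation, is_palindromic


@dataclass
class MVHarmonisedSet:
    """Joint instrument set: k SNPs x L exposures plus one outcome."""

    outcome_label: str
    exposure_labels: list[str]
    rsid: np.ndarray
    beta_exp: np.ndarray  # (k, L)
    se_exp: np.ndarray  # (k, L)
    beta_out: np.ndarray
    se_out: np.ndarray
    provenance: list[set] = field(default_factory=list)  # which exposure(s) contributed each SNP
    dropped: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["rsid", "reason"])
    )

    def __post_init__(self) -> None:
        self.beta_exp = np.atleast_2d(np.asarray(self.beta_exp, float))
        self.se_exp = np.atleast_2d(np.asarray(self.se_exp, float))
        k, L = self.beta_exp.shape
        if len(self.exposure_labels) != L:
            raise ValidationError("exposure_labels length does not match beta columns")
        if len(set(self.rsid)) != len(self.rsid):
            raise ValidationError("rsids must be unique")
        if np.any(self.se_exp <= 0) or np.any(self.se_out <= 0):
            raise ValidationError("standard errors must be positive")
        if k <= L:
            raise UnderIdentifiedError(
                f"{k} SNPs cannot identify {L} exposure effects"
            )

    @property
    def k(self) -> int:
        return self.beta_exp.shape[0]

    @property
    def L(self) -> int:
        return self.beta_exp.shape[1]


@dataclass
class MVMRResult:
    """Per-exposure direct effects with conditional instrument strength."""

    estimates: dict[str, MREstimate]
    conditional_F: dict[str, float]
    k: int
    Q_a: float
    Q_a_df: int
    Q_a_pval: float
    dispersion: float
    conditional_f_df_convention: str = "Q_x / (k - L + 1)"

    def summary(self) -> str:
        lines = [
            f"Multivariable MR, k={self.k} SNPs; residual heterogeneity "
            f"Q_a={self.Q_a:.2f} (df={self.Q_a_df}, p={self.Q_a_pval:.3g}); "
            f"conditional F df convention: {self.conditional_f_df_convention}"
        ]
        for label, est in self.estimates.items():
            lines.append(
                f"  {est.summary()}  [conditional F={self.conditional_F[label]:.1f}]"
            )
        return "\n".join(lines)


def build_mv_set(
    exposure_tables: list[SumStatsTable],
    outcome: SumStatsTable,
    ld: LDMatrix | None = None,
    r2_threshold: float = 0.001,
    p_threshold: float = 5e-8,
    palindrome_eaf_window: float = 0.08,
) -> MVHarmonisedSet:
    """Union-then-clump construction of a multivariable instrument set.

    Every SNP reaching ``p_threshold`` in any exposure enters the union;
    the union is clumped across exposures at ``r2_threshold`` (greedy by
    each SNP's best p over the exposures); survivors must carry effects in
    all exposure tables and the outcome, aligned to the orientation of the
    table that first contributed them. Drops are logged per reason.
    """
    if len(exposure_tables) < 2:
        raise ValidationError("multivariable MR needs at least 2 exposure tables")
    for t in exposure_tables:
        t.validate()
    outcome.validate()

    labels = [t.trait_label for t in exposure_tables]
    lookup = [
        {r.rsid: r for r in t.records.itertuples(index=False)} for t in exposure_tables
    ]
    out_lookup = {r.rsid: r for r in outcome.records.itertuples(index=False)}

    # union of instruments with best p and contributing exposures
    best_p: dict[str, float] = {}
    contributed: dict[str, set] = {}
    for li, t in enumerate(exposure_tables):
        df = t.records
        sig = df[df["pval"].notna() & (df["pval"] < p_threshold)]
        for r in sig.itertuples(index=False):
            if r.rsid not in best_p or r.pval < best_p[r.rsid]:
                best_p[r.rsid] = r.pval
            contributed.setdefault(r.rsid, set()).add(labels[li])

    dropped: list[tuple[str, str]] = []
    ranked = sorted(best_p, key=lambda r: (best_p[r], r))
    if ld is not None:
        accepted: list[str] = []
        candidates = ranked
        while candidates:
            best = candidates[0]
            accepted.append(best)
            nxt = []
            for rsid in candidates[1:]:
                if ld.covers([best, rsid]) and ld.lookup(best, rsid) >= r2_threshold:
                    dropped.append((rsid, f"r2>={r2_threshold:g} with {best}"))
                else:
                    nxt.append(rsid)
            candidates = nxt
    else:
        accepted = ranked

    rows = []
    provenance = []
    lo, hi = 0.5 - palindrome_eaf_window, 0.5 + palindrome_eaf_window
    for rsid in accepted:
        # reference orientation: the first exposure table carrying the SNP
        ref = next((lk[rsid] for lk in lookup if rsid in lk), None)
        missing = [labels[i] for i, lk in enumerate(lookup) if rsid not in lk]
        if missing:
            dropped.append((rsid, f"missing_in_{missing[0]}"))
            continue
        if rsid not in out_lookup:
            dropped.append((rsid, "missing_in_outcome"))
            continue
        e1, o1 = ref.effect_allele, ref.other_allele
        betas, ses = [], []
        ok = True
        for lk in lookup + [out_lookup]:
            r = lk[rsid]
            sign = align_orientation(e1, o1, r.effect_allele, r.other_allele)
            if sign is None:
                dropped.append((rsid, "allele_mismatch"))
                ok = False
                break
            if is_palindromic(e1, o1):
                eaf_ref = ref.eaf
                eaf_r = r.eaf if sign == 1 else (1 - r.eaf if not pd.isna(r.eaf) else np.nan)
                if (
                    pd.isna(eaf_ref)
                    or pd.isna(eaf_r)
                    or lo <= eaf_ref <= hi
                    or lo <= eaf_r <= hi
                    or (eaf_ref - 0.5) * (eaf_r - 0.5) <= 0
                ):
                    dropped.append((rsid, "palindromic_ambiguous"))
                    ok = False
                    break
            betas.append(sign * r.beta)
            ses.append(r.se)
        if not ok:
            continue
        rows.append((rsid, betas, ses))
        provenance.append(contributed.get(rsid, set()))

    if not rows:
        raise UnderIdentifiedError("no SNPs survive multivariable harmonisation")
    rsids = np.array([r[0] for r in rows])
    beta_all = np.array([r[1] for r in rows])
    se_all = np.array([r[2] for r in rows])
    return MVHarmonisedSet(
        outcome_label=outcome.trait_label,
        exposure_labels=labels,
        rsid=rsids,
        beta_exp=beta_all[:, :-1],
        se_exp=se_all[:, :-1],
        beta_out=beta_all[:, -1],
        se_out=se_all[:, -1],
        provenance=provenance,
        dropped=pd.DataFrame(dropped, columns=["rsid", "reason"]),
    )


def _wls_no_intercept(X: np.ndarray, y: np.ndarray, w: np.ndarray, labels):
    """Weighted normal-equations solve; raises on rank deficiency."""
    Xw = X * np.sqrt(w)[:, None]
    yw = y * np.sqrt(w)
    xtx = Xw.T @ Xw
    rank = np.linalg.matrix_rank(xtx)
    if rank < X.shape[1]:
        # name columns involved in the dependency via tiny R diagonal
        _, R = np.linalg.qr(Xw)
        diag = np.abs(np.diag(R))
        bad = [labels[i] for i in np.where(diag < 1e-10 * max(diag.max(), 1))[0]]
        raise CollinearityError(
            f"rank-deficient exposure design; offending exposure(s): "
            f"{', '.join(bad) if bad else ', '.join(labels)}"
        )
    coef = np.linalg.solve(xtx, Xw.T @ yw)
    cov = np.linalg.inv(xtx)
    rss = float(np.sum((yw - Xw @ coef) ** 2))
    return coef, cov, rss


def conditional_f(m: MVHarmonisedSet) -> dict[str, float]:
    """Conditional instrument-strength F per exposure.

    For exposure x, its beta column is regressed (weights 1/se_x^2, no
    intercept) on the other columns; the weighted residual sum of squares
    Q_x is reported as F_x = Q_x / (k - L + 1). The df convention is
    stated in all outputs because the literature varies. All-zero columns
    are excluded from the predictor side (they carry no signal).
    """
    out: dict[str, float] = {}
    k, L = m.beta_exp.shape
    nonzero = [i for i in range(L) if np.any(m.beta_exp[:, i])]
    for j, label in enumerate(m.exposure_labels):
        y = m.beta_exp[:, j]
        w = 1.0 / m.se_exp[:, j] ** 2
        others = [i for i in nonzero if i != j]
        if others:
            X = m.beta_exp[:, others]
            try:
                _, _, q_x = _wls_no_intercept(
                    X, y, w, [m.exposure_labels[i] for i in others]
                )
            except CollinearityError:
                q_x = 0.0  # perfectly collinear predictors absorb everything
        else:
            q_x = float(np.sum(w * y**2))
        out[label] = q_x / (k - L + 1)
    return out


def mvmr_ivw(m: MVHarmonisedSet) -> MVMRResult:
    """Multivariable IVW: WLS of outcome effects on all exposure columns.

    No intercept; weights 1/se_out^2; per-coefficient normal CIs.
    Residual heterogeneity Q_a has df k-L; when its p <= 0.05 the SEs are
    scaled by the multiplicative overdispersion sqrt(Q_a/df) (floored
    at 1), as in the univariable random-effects IVW.
    """
    k, L = m.beta_exp.shape
    w = 1.0 / m.se_out**2
    # an exactly-zero column identifies a null covariable: its coefficient
    # is zero by definition and must not make the solve singular
    nonzero = [j for j in range(L) if np.any(m.beta_exp[:, j])]
    labels_nz = [m.exposure_labels[j] for j in nonzero]
    coef_nz, cov, q_a = _wls_no_intercept(
        m.beta_exp[:, nonzero], m.beta_out, w, labels_nz
    )
    df = k - len(nonzero)
    q_p = float(stats.chi2.sf(q_a, df))
    dispersion = max(1.0, np.sqrt(q_a / df)) if q_p <= 0.05 else 1.0
    ses_nz = np.sqrt(np.diag(cov)) * dispersion
    coef = np.zeros(L)
    ses = np.full(L, np.inf)
    coef[nonzero], ses[nonzero] = coef_nz, ses_nz

    estimates = {}
    for j, label in enumerate(m.exposure_labels):
        beta, se = float(coef[j]), float(ses[j])
        estimates[label] = MREstimate(
            method="mvmr_ivw",
            beta=beta,
            se=se,
            pval=float(2 * stats.norm.sf(abs(beta / se))) if np.isfinite(se) else 1.0,
            k=k,
            exposure=label,
            outcome=m.outcome_label,
        )
    return MVMRResult(
        estimates=estimates,
        conditional_F=conditional_f(m),
        k=k,
        Q_a=q_a,
        Q_a_df=df,
        Q_a_pval=q_p,
        dispersion=dispersion,
    )


class MultivariableMR:
    """Model object over an :class:`MVHarmonisedSet`; ``fit()`` runs MV-IVW.

    >>> model = MultivariableMR.from_tables([tv, education], crc, ld=ldm)
    >>> res = model.fit()
    >>> res.estimates["television watching"].or_view
    """

    def __init__(self, data: MVHarmonisedSet):
        self.data = data

    @classmethod
    def from_tables(
        cls,
        exposure_tables: list[SumStatsTable],
        outcome: SumStatsTable,
        **kwargs,
    ) -> "MultivariableMR":
        return cls(build_mv_set(exposure_tables, outcome, **kwargs))

    def fit(self) -> MVMRResult:
        return mvmr_ivw(self.data)

    def conditional_f(self) -> dict[str, float]:
        return conditional_f(self.data)
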