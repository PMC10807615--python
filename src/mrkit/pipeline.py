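"""Orchestration of a full two-sample MR study from one config.

Runs the analysis graph a summary-data MR study needs: the univariable
estimator suite per exposure x outcome cell, multivariable adjustment per
covariable with conditional instrument strength, subgroup heterogeneity
meta-analysis, bidirectional MR between trait pairs, and an a priori
power table — writing tidy TSV/JSON reports that carry enough metadata
(method, k, seeds, thresholds) to re-derive any row in isolation.

Per-cell failures are logged as explicit ``not run: reason`` rows and the
run continues; only configuration errors abort. No multiple-testing
adjustment is applied across outcomes (p-values are reported as-is).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .estimators import TwoSampleMR, ivw, wald_ratios
from .exceptions import ConfigError, MRError
from .instruments import LDMatrix, select_instruments
from .meta_power import MetaResult, subgroup_meta
from .mvmr import MultivariableMR
from .sumstats import SumStatsTable, harmonise, read_sumstats

logger = logging.getLogger("mrkit")


@dataclass
class TraitSpec:
    """One trait's summary-statistics source."""

    label: str
    path: str
    trait_type: str = "continuous"
    sd_units: str | None = None
    n: int | None = None
    n_cases: int | None = None
    subgroup_of: str | None = None
    column_map: dict = field(default_factory=dict)
    sep: str = "\t"

    def load(self) -> SumStatsTable:
        return read_sumstats(
            self.path,
            column_map=self.column_map or None,
            trait_label=self.label,
            trait_type=self.trait_type,
            sd_units=self.sd_units,
            sep=self.sep,
        )


@dataclass
class AnalysisConfig:
    """Declarative description of a whole MR study."""

    exposures: list[TraitSpec]
    outcomes: list[TraitSpec]
    covariables: list[TraitSpec] = field(default_factory=list)
    ivw_model: str = "auto"
    n_boot: int = 1000
    presso_n_sim: int = 1000
    presso_sig: float = 0.05
    seed: int = 0
    p_threshold: float = 5e-8
    mv_r2_threshold: float = 0.001
    palindrome_eaf_window: float = 0.08
    ld_path: str | None = None
    out_dir: str = "mr_results"

    def __post_init__(self) -> None:
        labels = [t.label for t in self.exposures + self.outcomes + self.covariables]
        if len(set(labels)) != len(labels):
            raise ConfigError("trait labels must be unique across the config")
        if not self.exposures or not self.outcomes:
            raise ConfigError("config needs at least one exposure and one outcome")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        try:
            return cls(
                exposures=[TraitSpec(**t) for t in raw["exposures"]],
                outcomes=[TraitSpec(**t) for t in raw["outcomes"]],
                covariables=[TraitSpec(**t) for t in raw.get("covariables", [])],
                **{
                    k: v
                    for k, v in raw.items()
                    if k not in ("exposures", "outcomes", "covariables")
                },
            )
        except (KeyError, TypeError) as exc:
            raise ConfigError(f"malformed analysis config: {exc}") from exc

    def ld_matrix(self) -> LDMatrix | None:
        return LDMatrix.read(self.ld_path) if self.ld_path else None


def _not_run(exposure, outcome, reason, method="all"):
    return {
        "exposure": exposure,
        "outcome": outcome,
        "method": method,
        "note": f"not run: {reason}",
    }


def run_univariable(
    config: AnalysisConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full univariable suite per exposure x outcome cell.

    Returns the tidy results table and a per-SNP diagnostics table
    (Wald ratios — the data behind scatter and funnel plots).
    """
    results, diags = [], []
    for exp_spec in config.exposures:
        try:
            exposure = exp_spec.load()
        except MRError as exc:
            results.append(_not_run(exp_spec.label, "*", exc))
            continue
        for out_spec in config.outcomes:
            try:
                outcome = out_spec.load()
                h = harmonise(exposure, outcome, config.palindrome_eaf_window)
                model = TwoSampleMR(h)
                df = model.fit_all(
                    ivw_model=config.ivw_model,
                    n_boot=config.n_boot,
                    presso_n_sim=config.presso_n_sim,
                    presso_sig=config.presso_sig,
                    seed=config.seed,
                )
                df["seed"] = config.seed
                df["sd_units"] = exp_spec.sd_units
                df["subgroup_of"] = out_spec.subgroup_of
                results.append(df)
                ratio, se_r = wald_ratios(h)
                diags.append(
                    pd.DataFrame(
                        {
                            "exposure": exp_spec.label,
                            "outcome": out_spec.label,
                            "rsid": h.rsid,
                            "beta_exp": h.beta_exp,
                            "se_exp": h.se_exp,
                            "beta_out": h.beta_out,
                            "se_out": h.se_out,
                            "wald_ratio": ratio,
                            "wald_se": se_r,
                        }
                    )
                )
            except MRError as exc:
                logger.warning("%s x %s skipped: %s", exp_spec.label, out_spec.label, exc)
                results.append(_not_run(exp_spec.label, out_spec.label, exc))
    res = pd.concat(
        [r if isinstance(r, pd.DataFrame) else pd.DataFrame([r]) for r in results],
        ignore_index=True,
    )
    diag = (
        pd.concat(diags, ignore_index=True)
        if diags
        else pd.DataFrame(columns=["exposure", "outcome", "rsid"])
    )
    return res, diag


def subgroup_heterogeneity(results: pd.DataFrame) -> pd.DataFrame:
    """Fixed-effect meta-analysis of IVW estimates across subgroup outcomes.

    Groups rows whose outcome declared a ``subgroup_of`` parent; reports
    pooled effect, Q, p_het and I^2 per (exposure, parent) pair.
    """
    from .estimators import MREstimate

    if "subgroup_of" not in results.columns or "method" not in results.columns:
        return pd.DataFrame()
    ivw_rows = results[
        results["method"].isin(["ivw_fixed", "ivw_random", "wald"])
        & results["subgroup_of"].notna()
    ]
    out = []
    for (exp_label, parent), grp in ivw_rows.groupby(["exposure", "subgroup_of"]):
        if len(grp) < 2:
            continue
        ests = [
            MREstimate(method="ivw", beta=r.beta, se=r.se, pval=r.pval, k=int(r.k))
            for r in grp.itertuples()
        ]
        meta: MetaResult = subgroup_meta(ests)
        out.append(
            {
                "exposure": exp_label,
                "outcome_group": parent,
                "m": meta.m,
                "pooled_beta": meta.beta,
                "pooled_se": meta.se,
                "pooled_p": meta.pval,
                "Q_between": meta.heterogeneity.Q,
                "df": meta.heterogeneity.df,
                "p_het": meta.heterogeneity.pval,
                "I2": meta.I2,
            }
        )
    return pd.DataFrame(out)


def run_mvmr(config: AnalysisConfig) -> pd.DataFrame:
    """Univariable-vs-adjusted attenuation report per covariable.

    For each exposure x outcome x covariable triple: univariable IVW,
    the multivariable estimate adjusting for that covariable, and the
    conditional F of both variables.
    """
    if not config.covariables:
        raise ConfigError("no covariables configured for multivariable MR")
    ld = config.ld_matrix()
    rows = []
    for exp_spec in config.exposures:
        exposure = exp_spec.load()
        for out_spec in config.outcomes:
            outcome = out_spec.load()
            try:
                h = harmonise(exposure, outcome, config.palindrome_eaf_window)
                uni, _ = ivw(h, model=config.ivw_model)
            except MRError as exc:
                rows.append(_not_run(exp_spec.label, out_spec.label, exc, "mvmr_ivw"))
                continue
            for cov_spec in config.covariables:
                try:
                    cov = cov_spec.load()
                    model = MultivariableMR.from_tables(
                        [exposure, cov],
                        outcome,
                        ld=ld,
                        r2_threshold=config.mv_r2_threshold,
                        p_threshold=config.p_threshold,
                        palindrome_eaf_window=config.palindrome_eaf_window,
                    )
                    fit = model.fit()
                    adj = fit.estimates[exp_spec.label]
                    rows.append(
                        {
                            "exposure": exp_spec.label,
                            "outcome": out_spec.label,
                            "adjusted_for": cov_spec.label,
                            "k": fit.k,
                            "univariable_beta": uni.beta,
                            "univariable_se": uni.se,
                            "univariable_or": uni.or_view[0],
                            "adjusted_beta": adj.beta,
                            "adjusted_se": adj.se,
                            "adjusted_or": adj.or_view[0],
                            "adjusted_ci_low": adj.or_view[1],
                            "adjusted_ci_high": adj.or_view[2],
                            "conditional_F_exposure": fit.conditional_F[exp_spec.label],
                            "conditional_F_covariable": fit.conditional_F[cov_spec.label],
                            "Q_a": fit.Q_a,
                            "Q_a_p": fit.Q_a_pval,
                            "note": "",
                        }
                    )
                except MRError as exc:
                    rows.append(
                        {
                            "exposure": exp_spec.label,
                            "outcome": out_spec.label,
                            "adjusted_for": cov_spec.label,
                            "note": f"not run: {exc}",
                        }
                    )
    return pd.DataFrame(rows)


def run_bidirectional(
    trait_a: SumStatsTable,
    trait_b: SumStatsTable,
    ld: LDMatrix | None = None,
    r2_threshold: float = 0.001,
    p_threshold: float = 5e-8,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """MR in both directions between two instrument-grade traits.

    A->B uses A's instruments against B, B->A uses B's against A, each
    with the full univariable suite; each direction's instruments are
    re-clumped (default r^2 < 0.001) when an LD matrix is supplied, and
    assumed pre-clumped otherwise.
    """
    frames = []
    for exposure, outcome in ((trait_a, trait_b), (trait_b, trait_a)):
        try:
            inst = select_instruments(
                exposure, p_threshold=p_threshold, ld=ld, r2_threshold=r2_threshold
            )
            sub = SumStatsTable(
                trait_label=exposure.trait_label,
                trait_type=exposure.trait_type,
                sd_units=exposure.sd_units,
                records=exposure.records[
                    exposure.records["rsid"].isin(inst.rsids)
                ],
            )
            model = TwoSampleMR.from_tables(sub, outcome)
            df = model.fit_all(n_boot=n_boot, seed=seed)
            df["direction"] = f"{exposure.trait_label} -> {outcome.trait_label}"
            df["n_instruments"] = len(inst)
            df["preclumped_assumed"] = inst.preclumped_assumed
            frames.append(df)
        except MRError as exc:
            frames.append(
                pd.DataFrame(
                    [
                        {
                            "direction": f"{exposure.trait_label} -> {outcome.trait_label}",
                            "method": "all",
                            "note": f"not run: {exc}",
                        }
                    ]
                )
            )
    return pd.concat(frames, ignore_index=True)


def write_reports(
    out_dir,
    results: pd.DataFrame,
    diagnostics: pd.DataFrame | None = None,
    meta: pd.DataFrame | None = None,
    mvmr: pd.DataFrame | None = None,
    config: AnalysisConfig | None = None,
) -> Path:
    """Write results.tsv / results.json (+ sidecars) deterministically."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results.to_csv(out / "results.tsv", sep="\t", index=False)
    with open(out / "results.json", "w") as fh:
        json.dump(
            json.loads(results.to_json(orient="records")), fh, indent=1, sort_keys=True
        )
    if diagnostics is not None and not diagnostics.empty:
        diagnostics.to_csv(out / "snp_diagnostics.tsv", sep="\t", index=False)
    if meta is not None and not meta.empty:
        meta.to_csv(out / "subgroup_meta.tsv", sep="\t", index=False)
    if mvmr is not None and not mvmr.empty:
        mvmr.to_csv(out / "mvmr_attenuation.tsv", sep="\t", index=False)
    if config is not None:
        with open(out / "run_log.json", "w") as fh:
            json.dump(
                {
                    "mrkit_version": __version__,
                    "seed": config.seed,
                    "ivw_model": config.ivw_model,
                    "n_boot": config.n_boot,
                    "presso_n_sim": config.presso_n_sim,
                    "presso_sig": config.presso_sig,
                    "p_threshold": config.p_threshold,
                    "mv_r2_threshold": config.mv_r2_threshold,
                    "palindrome_eaf_window": config.palindrome_eaf_window,
                    "note": (
                        "sex-specific outcomes analysed with sex-combined "
                        "instruments where applicable"
                    ),
                },
                fh,
                indent=1,
                sort_keys=True,
            )
    return out


def run(config: AnalysisConfig) -> Path:
    """Execute the configured study end to end and write all reports."""
    results, diagnostics = run_univariable(config)
    meta = subgroup_heterogeneity(results)
    mv = run_mvmr(config) if config.covariables else None
    return write_reports(config.out_dir, results, diagnostics, meta, mv, config)
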