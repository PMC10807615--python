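"""GWAS summary-statistic tables and exposure/outcome harmonisation.

A :class:`SumStatsTable` holds one trait's per-SNP association summaries
(effect/other allele, effect-allele frequency, beta, SE, p, sample sizes)
as a validated :class:`pandas.DataFrame`. :func:`harmonise` aligns an
exposure (instrument) table against an outcome table onto a common
effect-allele orientation, producing the :class:`HarmonisedSet` of aligned
effect arrays that every estimator in this package consumes.

Conventions
-----------
* Betas are per effect allele: per-SD units for continuous traits,
  log-odds for binary traits.
* Strand complementing (A<->T, C<->G) is attempted before declaring an
  allele mismatch, because consortium files mix strands.
* Palindromic SNPs (A/T or C/G) are kept only when the effect-allele
  frequencies on both sides are informative: both outside
  0.5 +/- ``palindrome_eaf_window`` and on the same side of 0.5 once
  nominally aligned. Anything else is dropped as ambiguous.
* A duplicated rsid in the outcome table is resolved by keeping the
  record with the smallest SE (deterministic tie-break); the discarded
  records are logged on the result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigError, EmptySetError, ValidationError

#: canonical column order used on disk and in memory
COLUMNS = [
    "rsid",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n_total",
    "n_cases",
]

MANDATORY_ROLES = ["rsid", "effect_allele", "other_allele", "beta", "se"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

_ALLELE_CHARS = set("ACGT")


def _complement(allele: str) -> str | None:
    """Strand complement of an allele string; None if not complementable."""
    try:
        return "".join(_COMPLEMENT[b] for b in reversed(allele)) if len(allele) > 1 else _COMPLEMENT[allele]
    except KeyError:
        return None


def is_palindromic(a1: str, a2: str) -> bool:
    """True for A/T and C/G pairs, whose strand cannot be read off the labels."""
    return len(a1) == 1 and len(a2) == 1 and _COMPLEMENT.get(a1) == a2


@dataclass
class SumStatsTable:
    """Per-SNP association summaries for one trait.

    Parameters
    ----------
    trait_label : str
        Human-readable trait name, e.g. ``"television watching"``.
    trait_type : {"continuous", "binary"}
        Scale of ``beta``: per-SD units or log-odds.
    records : pandas.DataFrame
        One row per SNP with columns :data:`COLUMNS`.
    sd_units : str, optional
        What one SD of a continuous trait means, e.g. ``"1.5 h/day"``.
    rejected : pandas.DataFrame
        Rows refused at read time, with a ``reason`` column.
    """

    trait_label: str
    trait_type: str
    records: pd.DataFrame
    sd_units: str | None = None
    rejected: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["rsid", "reason"])
    )

    def __post_init__(self) -> None:
        if self.trait_type not in ("continuous", "binary"):
            raise ValidationError(
                f"trait_type must be 'continuous' or 'binary', got {self.trait_type!r}"
            )
        self.records = _canonicalise(self.records)
        self.validate()

    # ------------------------------------------------------------------
    def validate(self, allow_duplicates: bool = False) -> None:
        """Enforce table invariants; raise :class:`ValidationError` on failure.

        ``allow_duplicates`` relaxes rsid uniqueness — used by
        :func:`harmonise`, which resolves outcome-side duplicates itself.
        """
        df = self.records
        if not allow_duplicates:
            dups = df["rsid"][df["rsid"].duplicated()].unique().tolist()
            if dups:
                raise ValidationError(f"duplicate rsid(s): {', '.join(map(str, dups))}")
        bad = _row_violations(df)
        if bad:
            raise ValidationError(
                "invalid records: " + "; ".join(f"{r}: {why}" for r, why in bad[:10])
            )

    def __len__(self) -> int:
        return len(self.records)

    def equals(self, other: "SumStatsTable") -> bool:
        """Field-for-field equality (NaN-aware on the records)."""
        if (self.trait_label, self.trait_type, self.sd_units) != (
            other.trait_label,
            other.trait_type,
            other.sd_units,
        ):
            return False
        a = self.records.reset_index(drop=True)
        b = other.records.reset_index(drop=True)
        if len(a) != len(b):
            return False
        for col in COLUMNS:
            x, y = a[col], b[col]
            if x.dtype.kind in "fc" or str(x.dtype) == "Float64":
                if not np.allclose(
                    x.astype(float), y.astype(float), rtol=0, atol=0, equal_nan=True
                ):
                    return False
            else:
                if not (x.isna() == y.isna()).all():
                    return False
                if not (x[x.notna()] == y[y.notna()]).all():
                    return False
        return True


def _canonicalise(df: pd.DataFrame) -> pd.DataFrame:
    """Coerce a records frame to canonical columns and dtypes."""
    df = df.copy()
    for col in COLUMNS:
        if col not in df.columns:
            df[col] = pd.NA
    df = df[COLUMNS]
    df["rsid"] = df["rsid"].astype(str)
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.upper()
    for col in ("eaf", "beta", "se", "pval"):
        df[col] = pd.to_numeric(df[col], errors="coerce").astype(float)
    for col in ("n_total", "n_cases"):
        df[col] = pd.to_numeric(df[col], errors="coerce").astype("Int64")
    return df.reset_index(drop=True)


def _row_violations(df: pd.DataFrame) -> list[tuple[str, str]]:
    """Per-row invariant violations as (rsid, reason)."""
    out: list[tuple[str, str]] = []
    for row in df.itertuples(index=False):
        reason = _record_violation(row)
        if reason:
            out.append((row.rsid, reason))
    return out


def _record_violation(row) -> str | None:
    for col in ("effect_allele", "other_allele"):
        allele = getattr(row, col)
        if not allele or allele in ("NAN", "NA") or not set(allele) <= _ALLELE_CHARS:
            return f"invalid {col}"
    if pd.isna(row.beta):
        return "missing beta"
    if pd.isna(row.se):
        return "missing se"
    if row.se <= 0:
        return "nonpositive se"
    if not pd.isna(row.eaf) and not 0 < row.eaf < 1:
        return "eaf outside (0,1)"
    if not pd.isna(row.pval) and not 0 < row.pval <= 1:
        return "pval outside (0,1]"
    if not pd.isna(row.n_total) and row.n_total <= 0:
        return "nonpositive n_total"
    if not pd.isna(row.n_cases):
        if row.n_cases <= 0:
            return "nonpositive n_cases"
        if not pd.isna(row.n_total) and row.n_cases > row.n_total:
            return "n_cases exceeds n_total"
    return None


# ----------------------------------------------------------------------
# I/O
# ----------------------------------------------------------------------

def read_sumstats(
    path,
    column_map: dict[str, str] | None = None,
    trait_label: str = "trait",
    trait_type: str = "continuous",
    sd_units: str | None = None,
    sep: str = "\t",
    fail_fast: bool = False,
) -> SumStatsTable:
    """Read a delimited summary-statistics file into a validated table.

    Parameters
    ----------
    column_map : dict, optional
        Maps file column names to roles (``{"SNP": "rsid", ...}``). When
        omitted the file must already use the default column names.
    fail_fast : bool
        If True, any invalid row raises instead of being rejected with a
        logged reason.

    Raises
    ------
    ConfigError
        A mandatory role (rsid, alleles, beta, se) has no source column.
    ValidationError
        Duplicate rsids, or any invalid row under ``fail_fast``.
    """
    raw = pd.read_csv(path, sep=sep, dtype=str)
    if column_map:
        raw = raw.rename(columns=column_map)
    missing = [role for role in MANDATORY_ROLES if role not in raw.columns]
    if missing:
        raise ConfigError(
            f"no column mapped to mandatory role(s): {', '.join(missing)}"
        )
    df = _canonicalise(raw)

    dups = df["rsid"][df["rsid"].duplicated()].unique().tolist()
    if dups:
        raise ValidationError(f"duplicate rsid(s): {', '.join(map(str, dups))}")

    bad = dict(_row_violations(df))
    if bad and fail_fast:
        rsid, why = next(iter(bad.items()))
        raise ValidationError(f"row {rsid}: {why}")
    keep = ~df["rsid"].isin(bad)
    rejected = pd.DataFrame(
        {"rsid": list(bad), "reason": list(bad.values())}
    )
    return SumStatsTable(
        trait_label=trait_label,
        trait_type=trait_type,
        sd_units=sd_units,
        records=df[keep],
        rejected=rejected,
    )


def write_sumstats(table: SumStatsTable, path, sep: str = "\t"):
    """Write a table as delimited text re-readable by :func:`read_sumstats`.

    Output is bit-stable for identical inputs; optional fields absent in
    memory round-trip to absent (empty cells).
    """
    table.validate()
    df = table.records.copy()
    # repr-based float formatting round-trips exactly
    for col in ("eaf", "beta", "se", "pval"):
        df[col] = df[col].map(lambda v: "" if pd.isna(v) else repr(float(v)))
    for col in ("n_total", "n_cases"):
        df[col] = df[col].map(lambda v: "" if pd.isna(v) else str(int(v)))
    df.to_csv(path, sep=sep, index=False)
    return path


# ----------------------------------------------------------------------
# Harmonisation
# ----------------------------------------------------------------------

@dataclass
class HarmonisedSet:
    """Allele-aligned exposure/outcome effects — the unit of all estimation.

    All per-SNP arrays share length ``k``; ``dropped`` accounts for every
    exposure SNP not retained, so retained + dropped rsids equal the
    exposure instrument list submitted to :func:`harmonise`.
    """

    exposure_label: str
    outcome_label: str
    rsid: np.ndarray
    beta_exp: np.ndarray
    se_exp: np.ndarray
    beta_out: np.ndarray
    se_out: np.ndarray
    eaf_exp: np.ndarray
    dropped: pd.DataFrame
    outcome_type: str = "continuous"
    duplicates_resolved: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["rsid", "se_kept", "n_discarded"])
    )

    def __post_init__(self) -> None:
        arrays = (self.rsid, self.beta_exp, self.se_exp, self.beta_out, self.se_out, self.eaf_exp)
        lengths = {len(a) for a in arrays}
        if lengths != {len(self.rsid)}:
            raise ValidationError("harmonised arrays have mismatched lengths")
        if self.k < 1:
            raise EmptySetError("no SNPs retained; no analysis is possible")
        if np.any(self.se_exp <= 0) or np.any(self.se_out <= 0):
            raise ValidationError("standard errors must be positive")

    @property
    def k(self) -> int:
        return len(self.rsid)

    def subset(self, mask) -> "HarmonisedSet":
        """A new set restricted to ``mask`` (bool array or index array)."""
        mask = np.asarray(mask)
        return HarmonisedSet(
            exposure_label=self.exposure_label,
            outcome_label=self.outcome_label,
            rsid=self.rsid[mask],
            beta_exp=self.beta_exp[mask],
            se_exp=self.se_exp[mask],
            beta_out=self.beta_out[mask],
            se_out=self.se_out[mask],
            eaf_exp=self.eaf_exp[mask],
            dropped=self.dropped,
            outcome_type=self.outcome_type,
        )


def align_orientation(e1, o1, e2, o2):
    """Orientation of outcome alleles (e2, o2) relative to exposure (e1, o1).

    Returns ``+1`` (same orientation), ``-1`` (alleles swapped, flip the
    outcome beta and complement its EAF) or ``None`` (different allele
    pair even after strand complementing).
    """
    if (e2, o2) == (e1, o1):
        return 1
    if (e2, o2) == (o1, e1):
        return -1
    ce, co = _complement(e2), _complement(o2)
    if ce is None or co is None:
        return None
    if (ce, co) == (e1, o1):
        return 1
    if (ce, co) == (o1, e1):
        return -1
    return None


def harmonise(
    exposure: SumStatsTable,
    outcome: SumStatsTable,
    palindrome_eaf_window: float = 0.08,
) -> HarmonisedSet:
    """Align an outcome table to the exposure's effect-allele orientation.

    The exposure table is the instrument list: every one of its SNPs ends
    up either retained (aligned arrays) or in ``dropped`` with a reason in
    {missing_in_outcome, allele_mismatch, palindromic_ambiguous, duplicate}.

    Raises
    ------
    EmptySetError
        If zero SNPs are retained.
    """
    exposure.validate()
    outcome.validate(allow_duplicates=True)

    out_df = outcome.records
    dup_mask = out_df["rsid"].duplicated(keep=False)
    dup_log = []
    if dup_mask.any():
        # keep the smallest-se record per duplicated rsid (ties: first row)
        best = out_df.sort_values(["rsid", "se"], kind="stable").drop_duplicates("rsid")
        for rsid, grp in out_df[dup_mask].groupby("rsid"):
            dup_log.append(
                {"rsid": rsid, "se_kept": grp["se"].min(), "n_discarded": len(grp) - 1}
            )
        out_df = best
    out_by_rsid = {r.rsid: r for r in out_df.itertuples(index=False)}

    retained: list[dict] = []
    dropped: list[tuple[str, str]] = []
    seen: set[str] = set()
    lo, hi = 0.5 - palindrome_eaf_window, 0.5 + palindrome_eaf_window

    for row in exposure.records.itertuples(index=False):
        if row.rsid in seen:  # defensive; validated tables cannot hit this
            dropped.append((row.rsid, "duplicate"))
            continue
        seen.add(row.rsid)
        orow = out_by_rsid.get(row.rsid)
        if orow is None:
            dropped.append((row.rsid, "missing_in_outcome"))
            continue
        sign = align_orientation(
            row.effect_allele, row.other_allele, orow.effect_allele, orow.other_allele
        )
        if sign is None:
            dropped.append((row.rsid, "allele_mismatch"))
            continue
        if is_palindromic(row.effect_allele, row.other_allele):
            eaf_x = row.eaf
            eaf_y = orow.eaf if sign == 1 else (1 - orow.eaf if not pd.isna(orow.eaf) else np.nan)
            informative = (
                not pd.isna(eaf_x)
                and not pd.isna(eaf_y)
                and not lo <= eaf_x <= hi
                and not lo <= eaf_y <= hi
                and (eaf_x - 0.5) * (eaf_y - 0.5) > 0
            )
            if not informative:
                dropped.append((row.rsid, "palindromic_ambiguous"))
                continue
        retained.append(
            {
                "rsid": row.rsid,
                "beta_exp": row.beta,
                "se_exp": row.se,
                "beta_out": sign * orow.beta,
                "se_out": orow.se,
                "eaf_exp": row.eaf,
            }
        )

    if not retained:
        raise EmptySetError(
            f"no SNPs retained harmonising {exposure.trait_label!r} against "
            f"{outcome.trait_label!r}; no analysis is possible"
        )
    kept = pd.DataFrame(retained)
    return HarmonisedSet(
        exposure_label=exposure.trait_label,
        outcome_label=outcome.trait_label,
        rsid=kept["rsid"].to_numpy(),
        beta_exp=kept["beta_exp"].to_numpy(float),
        se_exp=kept["se_exp"].to_numpy(float),
        beta_out=kept["beta_out"].to_numpy(float),
        se_out=kept["se_out"].to_numpy(float),
        eaf_exp=kept["eaf_exp"].to_numpy(float),
        dropped=pd.DataFrame(dropped, columns=["rsid", "reason"]),
        outcome_type=outcome.trait_type,
        duplicates_resolved=pd.DataFrame(
            dup_log, columns=["rsid", "se_kept", "n_discarded"]
        ),
    )
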