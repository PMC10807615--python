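"""Instrument selection and strength diagnostics.

Selects genome-wide-significant, LD-independent SNPs by greedy clumping
against an explicit LD (r-squared) matrix, and computes the per-SNP
F-statistic and the total exposure variance explained.

The LD matrix is supplied by the caller (or the data are declared
pre-clumped); this package never computes LD from genotype panels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import EmptySetError, UnavailableResultError, ValidationError
from .sumstats import HarmonisedSet, SumStatsTable


@dataclass
class LDMatrix:
    """Symmetric matrix of squared allelic correlations between SNPs."""

    rsids: list[str]
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        n = len(self.rsids)
        if self.r2.shape != (n, n):
            raise ValidationError(
                f"LD matrix shape {self.r2.shape} does not match {n} rsids"
            )
        if not np.allclose(self.r2, self.r2.T):
            raise ValidationError("LD matrix must be symmetric")
        if not np.allclose(np.diag(self.r2), 1.0):
            raise ValidationError("LD matrix diagonal must be 1")
        if self.r2.min() < 0 or self.r2.max() > 1 + 1e-12:
            raise ValidationError("LD r2 values must lie in [0, 1]")
        self._index = {rsid: i for i, rsid in enumerate(self.rsids)}

    def lookup(self, a: str, b: str) -> float:
        return float(self.r2[self._index[a], self._index[b]])

    def covers(self, rsids) -> bool:
        return all(r in self._index for r in rsids)

    @classmethod
    def read(cls, path, sep: str = "\t") -> "LDMatrix":
        """Read a square delimited table whose header and first column are rsids."""
        df = pd.read_csv(path, sep=sep, index_col=0)
        return cls(rsids=[str(c) for c in df.columns], r2=df.to_numpy(float))

    def write(self, path, sep: str = "\t"):
        pd.DataFrame(self.r2, index=self.rsids, columns=self.rsids).to_csv(path, sep=sep)
        return path


@dataclass
class InstrumentSet:
    """Result of instrument selection: retained SNPs plus strength summaries."""

    rsids: list[str]
    f_stats: pd.Series
    total_r2: float | None
    p_threshold: float
    r2_threshold: float
    window_bp: float
    preclumped_assumed: bool = False
    discarded: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["rsid", "reason"])
    )

    def __post_init__(self) -> None:
        if len(set(self.rsids)) != len(self.rsids):
            raise ValidationError("instrument rsids must be unique")
        if (self.f_stats < 0).any():
            raise ValidationError("F statistics must be non-negative")
        if self.total_r2 is not None and not 0 <= self.total_r2 <= 1:
            raise ValidationError("total_r2 must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.rsids)


def select_instruments(
    table: SumStatsTable,
    p_threshold: float = 5e-8,
    ld: LDMatrix | None = None,
    r2_threshold: float = 0.005,
    window_bp: float = 5e6,
    positions: dict[str, tuple] | None = None,
) -> InstrumentSet:
    """Greedy LD clumping of genome-wide-significant SNPs.

    SNPs passing ``p_threshold`` are ranked by ascending p (rsid breaks
    ties, making the result invariant to input row order); the best is
    accepted and any unaccepted SNP with r2 >= ``r2_threshold`` to an
    accepted SNP within ``window_bp`` is discarded, until none remain.

    When ``ld`` is absent all passing SNPs are accepted and the result is
    flagged ``preclumped_assumed``. When ``positions`` (rsid -> (chrom, bp))
    is absent, every SNP pair is treated as within-window.

    Raises
    ------
    EmptySetError
        If no SNP passes ``p_threshold``.
    """
    table.validate()
    df = table.records
    passing = df[df["pval"].notna() & (df["pval"] < p_threshold)]
    if passing.empty:
        raise EmptySetError(
            f"no SNP in {table.trait_label!r} passes p < {p_threshold:g}"
        )
    ranked = passing.sort_values(["pval", "rsid"], kind="stable")

    discarded: list[tuple[str, str]] = []
    if ld is None:
        accepted = list(ranked["rsid"])
        preclumped = True
    else:
        if not ld.covers(ranked["rsid"]):
            missing = [r for r in ranked["rsid"] if r not in ld._index]
            raise ValidationError(
                f"LD matrix does not cover SNP(s): {', '.join(missing[:5])}"
            )
        preclumped = False
        accepted = []
        candidates = list(ranked["rsid"])
        while candidates:
            best = candidates.pop(0)
            accepted.append(best)
            survivors = []
            for rsid in candidates:
                in_window = True
                if positions is not None:
                    ca, pa = positions[best]
                    cb, pb = positions[rsid]
                    in_window = ca == cb and abs(float(pa) - float(pb)) <= window_bp
                if in_window and ld.lookup(best, rsid) >= r2_threshold:
                    discarded.append((rsid, f"r2>={r2_threshold:g} with {best}"))
                else:
                    survivors.append(rsid)
            candidates = survivors

    sel = df.set_index("rsid").loc[accepted]
    f = (sel["beta"] / sel["se"]) ** 2
    if sel["eaf"].notna().all():
        total_r2 = float(
            min(1.0, (2 * sel["eaf"] * (1 - sel["eaf"]) * sel["beta"] ** 2).sum())
        )
    else:
        total_r2 = None
    return InstrumentSet(
        rsids=accepted,
        f_stats=f,
        total_r2=total_r2,
        p_threshold=p_threshold,
        r2_threshold=r2_threshold,
        window_bp=window_bp,
        preclumped_assumed=preclumped,
        discarded=pd.DataFrame(discarded, columns=["rsid", "reason"]),
    )


def f_statistics(h: HarmonisedSet) -> tuple[np.ndarray, float]:
    """Per-SNP instrument strength F_j = (beta_exp_j / se_exp_j)^2 and its mean.

    Values above ~10 are conventionally read as little evidence of weak
    instrument bias.
    """
    f = (h.beta_exp / h.se_exp) ** 2
    return f, float(f.mean())


def variance_explained(h: HarmonisedSet) -> float:
    """Total exposure variance explained, R2 = sum 2 f (1-f) beta^2.

    Assumes a standardized continuous exposure; capped at 1.

    Raises
    ------
    UnavailableResultError
        If any SNP lacks an effect-allele frequency — supply R2 directly
        (e.g. to :class:`mrkit.meta_power.PowerSpec`) in that case.
    """
    if np.any(~np.isfinite(h.eaf_exp)):
        raise UnavailableResultError(
            "effect-allele frequencies missing; cannot compute variance "
            "explained — supply R2 directly"
        )
    r2 = float(np.sum(2 * h.eaf_exp * (1 - h.eaf_exp) * h.beta_exp**2))
    return min(1.0, r2)
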