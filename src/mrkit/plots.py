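"""Scatter and funnel diagnostics for a harmonised SNP set.

Each plotting helper first builds the plain data table behind the figure
(and returns it), so pipelines can emit the numbers even when no figure
is wanted; pass ``ax=None, draw=False`` for data-only use. Figure
styling is deliberately minimal.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .estimators import MREstimate, egger, ivw, wald_ratios, weighted_median
from .sumstats import HarmonisedSet


def scatter_data(h: HarmonisedSet) -> pd.DataFrame:
    """Per-SNP exposure vs outcome effects, oriented to positive exposure."""
    flip = np.sign(h.beta_exp)
    flip[flip == 0] = 1.0
    return pd.DataFrame(
        {
            "rsid": h.rsid,
            "beta_exp": h.beta_exp * flip,
            "se_exp": h.se_exp,
            "beta_out": h.beta_out * flip,
            "se_out": h.se_out,
        }
    )


def funnel_data(h: HarmonisedSet) -> pd.DataFrame:
    """Per-SNP Wald ratio against its precision (asymmetry = pleiotropy)."""
    ratio, se = wald_ratios(h)
    return pd.DataFrame({"rsid": h.rsid, "wald_ratio": ratio, "precision": 1.0 / se})


def plot_scatter(
    h: HarmonisedSet, fits: list[MREstimate] | None = None, ax=None, draw: bool = True
):
    """SNP-effect scatter with estimator slope lines; returns (data, ax)."""
    data = scatter_data(h)
    if not draw:
        return data, None
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.errorbar(
        data["beta_exp"],
        data["beta_out"],
        xerr=data["se_exp"],
        yerr=data["se_out"],
        fmt="o",
        ms=3,
        lw=0.5,
        alpha=0.6,
        color="grey",
    )
    if fits is None:
        est, _ = ivw(h)
        fits = [est]
        if h.k >= 3:
            fits.append(egger(h).slope)
            fits.append(weighted_median(h, n_boot=0))
    xs = np.array([0, data["beta_exp"].max()])
    for est in fits:
        intercept = getattr(est, "intercept", 0.0)
        ax.plot(xs, intercept + est.beta * xs, label=est.method)
    ax.set_xlabel(f"SNP effect on {h.exposure_label}")
    ax.set_ylabel(f"SNP effect on {h.outcome_label}")
    ax.legend(fontsize=8)
    return data, ax


def plot_funnel(h: HarmonisedSet, ax=None, draw: bool = True):
    """Funnel of per-SNP ratios vs precision; returns (data, ax)."""
    data = funnel_data(h)
    if not draw:
        return data, None
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(data["wald_ratio"], data["precision"], "o", ms=3, alpha=0.6)
    est, _ = ivw(h)
    ax.axvline(est.beta, color="k", lw=1, label="IVW")
    ax.set_xlabel("Wald ratio")
    ax.set_ylabel("1 / SE")
    ax.legend(fontsize=8)
    return data, ax
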