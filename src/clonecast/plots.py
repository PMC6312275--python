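"""Figure analogs for the end-to-end analysis.

All functions return a matplotlib Figure; callers save with ``fig.savefig``.
"""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .benefit import triage_fraction  # noqa: E402
from .cohort import DCB_COLUMN  # noqa: E402


def loocv_scatter(result) -> plt.Figure:
    """Held-out predicted vs observed log expansion; y = x marks perfection."""
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(result.y, result.held_out_predictions, color="tab:blue", zorder=3)
    lo = min(result.y.min(), result.held_out_predictions.min())
    hi = max(result.y.max(), result.held_out_predictions.max())
    ax.plot([lo, hi], [lo, hi], color="red", lw=1)
    ax.set_xlabel("observed log clonal expansion")
    ax.set_ylabel("held-out predicted log clonal expansion")
    ax.set_title(
        f"LOOCV MSE {result.mse:.3f}, "
        f"VE {100 * result.variance_explained_nominal:.0f}%"
    )
    fig.tight_layout()
    return fig


def permutation_histogram(result) -> plt.Figure:
    """Null LOOCV-error distribution with the observed error overlaid."""
    fig, ax = plt.subplots(figsize=(5.5, 4))
    ax.hist(result.null_draws, bins=30, color="tab:gray", edgecolor="white")
    ax.axvline(result.observed_stat, color="black", ls=":", lw=2,
               label=f"observed (p = {result.p_value:.3g})")
    ax.set_xlabel("LOOCV MSE under permutation of " + result.permuted_target)
    ax.set_ylabel("count")
    ax.legend()
    fig.tight_layout()
    return fig


def coefficient_chart(fit) -> plt.Figure:
    """Retained elastic-net coefficients, colored by feature category."""
    palette = {"clinical": "tab:blue", "tumor": "tab:red",
               "circulating": "tab:green"}
    idx = np.flatnonzero(fit.coef)
    order = idx[np.argsort(fit.coef[idx])]
    names = [fit.columns[j].name if fit.columns is not None else str(j)
             for j in order]
    colors = [palette.get(fit.columns[j].category, "tab:gray")
              if fit.columns is not None else "tab:gray" for j in order]
    fig, ax = plt.subplots(figsize=(6, max(2.5, 0.28 * len(order) + 1)))
    ax.barh(range(len(order)), fit.coef[order], color=colors)
    ax.set_yticks(range(len(order)), names, fontsize=8)
    ax.axvline(0, color="black", lw=0.8)
    ax.set_xlabel("elastic-net coefficient (standardized features)")
    handles = [plt.Rectangle((0, 0), 1, 1, color=c) for c in palette.values()]
    ax.legend(handles, palette.keys(), fontsize=8)
    fig.tight_layout()
    return fig


def triage_stripplot(cohort, biomarker_scores: dict) -> plt.Figure:
    """DCB-stratified biomarker distributions; must-treat patients in red.

    ``biomarker_scores`` maps biomarker name -> per-patient scores aligned
    with the cohort (patients without a DCB label are dropped).
    """
    dcb = cohort.data[DCB_COLUMN]
    keep = dcb.notna().to_numpy()
    labels = dcb.to_numpy(dtype=float)[keep]
    names = list(biomarker_scores)
    fig, axes = plt.subplots(1, len(names), figsize=(2.6 * len(names), 4),
                             squeeze=False)
    rng = np.random.default_rng(0)  # jitter only; cosmetic
    for ax, name in zip(axes[0], names):
        scores = np.asarray(biomarker_scores[name], dtype=float)[keep]
        have = ~np.isnan(scores)
        scores, grp_labels = scores[have], labels[have]
        res = triage_fraction(scores, grp_labels, biomarker=name)
        treated = scores >= res.threshold
        for grp, x0 in ((0.0, 0), (1.0, 1)):
            sel = grp_labels == grp
            x = x0 + rng.uniform(-0.12, 0.12, sel.sum())
            colors = np.where(treated[sel], "red", "tab:gray")
            ax.scatter(x, scores[sel], c=colors, s=24, zorder=3)
        ax.axhline(res.threshold, color="red", lw=0.8, ls="--")
        ax.set_xticks([0, 1], ["no DCB", "DCB"])
        ax.set_title(f"{name}\ntreat {100 * res.fraction_non_dcb_treated:.0f}% "
                     "of non-DCB", fontsize=8)
    fig.tight_layout()
    return fig
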