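"""Binned coefficient-of-variation screen for high intercellular variance.

Within each treatment group, genes with mean E-value above ``min_mean`` are
ranked into equal-frequency bins by mean E.  A gene is flagged when its
log10(CV) exceeds its bin's mean log10(CV) by more than ``fold`` bin standard
deviations — an upper-tail rule relative to genes expressed at similar
levels, which absorbs the mean-dependence of the CV (including dropout).

An alternative literal reading of the criterion (flag when
log10(CV) > fold * bin std, regardless of the bin mean) is available via
``criterion="absolute"`` for sensitivity analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError


@dataclass
class ConditionVariability:
    stats: pd.DataFrame      # per analyzed gene: mean_e, cv, log10_cv, bin, flagged
    bin_stats: pd.DataFrame  # per bin: n, mean_log10_cv, std_log10_cv
    flagged: list[str]


@dataclass
class HighVarianceReport:
    per_condition: dict[str, ConditionVariability] = field(default_factory=dict)

    def flagged(self, condition: str) -> list[str]:
        return self.per_condition[condition].flagged


def _merge_small_bins(bins: np.ndarray, min_size: int = 3) -> np.ndarray:
    """Merge bins holding fewer than ``min_size`` genes into their lower
    neighbour (the first bin merges upward).  Bin labels stay sorted by
    mean-E order, so merging neighbours keeps bins contiguous."""
    bins = bins.copy()
    changed = True
    while changed:
        changed = False
        labels = np.unique(bins)
        for i, lab in enumerate(labels):
            n = int((bins == lab).sum())
            if n < min_size and len(labels) > 1:
                target = labels[i - 1] if i > 0 else labels[i + 1]
                warnings.warn(
                    f"bin {lab} has {n} genes; merging into bin {target}",
                    stacklevel=2,
                )
                bins[bins == lab] = target
                changed = True
                break
    return bins


def _condition_report(
    E_cond: pd.DataFrame, n_bins: int, fold: float, min_mean: float, criterion: str
) -> ConditionVariability:
    mean_e = E_cond.mean(axis=1)
    analyzed = mean_e.index[mean_e > min_mean]
    if len(analyzed) == 0:
        raise DataError("no gene passes the mean-E gate in this condition")
    sub = E_cond.loc[analyzed]
    sd = sub.std(axis=1, ddof=1)
    cv = sd / mean_e.loc[analyzed]
    positive = cv.index[cv > 0]
    if len(positive) < len(cv):
        warnings.warn(
            f"{len(cv) - len(positive)} genes with zero CV excluded", stacklevel=2
        )
    cv = cv.loc[positive]
    log_cv = np.log10(cv)
    me = mean_e.loc[positive]

    q = min(n_bins, max(1, len(me)))
    bins = pd.qcut(me.rank(method="first"), q=q, labels=False).to_numpy()
    bins = _merge_small_bins(bins)

    stats = pd.DataFrame({"mean_e": me, "cv": cv, "log10_cv": log_cv, "bin": bins})
    grp = stats.groupby("bin")["log10_cv"]
    bin_stats = grp.agg(n="size", mean_log10_cv="mean", std_log10_cv=lambda s: s.std(ddof=1))
    center = stats["bin"].map(bin_stats["mean_log10_cv"])
    spread = stats["bin"].map(bin_stats["std_log10_cv"]).fillna(0.0)
    if criterion == "upper_tail":
        flagged = (stats["log10_cv"] - center) > fold * spread
    elif criterion == "absolute":
        flagged = stats["log10_cv"] > fold * spread
    else:
        raise DataError(f"unknown criterion {criterion!r}")
    stats["flagged"] = flagged
    return ConditionVariability(
        stats=stats, bin_stats=bin_stats, flagged=stats.index[flagged].tolist()
    )


def high_variance_genes(
    E: pd.DataFrame,
    annotation: pd.DataFrame,
    n_bins: int = 100,
    fold: float = 2.0,
    min_mean: float = 1.0,
    criterion: str = "upper_tail",
) -> HighVarianceReport:
    """Flag high-intercellular-variance genes within each condition.

    CV is the ratio of the across-cell standard deviation of E-values to
    their mean; genes with mean E <= ``min_mean`` are excluded entirely.
    Requires >= 2 cells per condition.
    """
    report = HighVarianceReport()
    for cond, cells in annotation.groupby("condition").groups.items():
        cells = [c for c in cells if c in E.columns]
        if len(cells) < 2:
            raise DataError(f"condition {cond!r} has fewer than 2 cells")
        report.per_condition[str(cond)] = _condition_report(
            E[cells], n_bins, fold, min_mean, criterion
        )
    return report
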