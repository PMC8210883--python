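"""Condition-level differential expression, regulatory clusters, geneset
scores and rank-sum group comparisons."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .errors import DataError


@dataclass
class GeneSet:
    name: str
    genes: list[str]

    def __post_init__(self):
        if len(self.genes) < 1:
            raise DataError(f"geneset {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise DataError(f"geneset {self.name!r} has duplicate ids")


@dataclass
class GenesetScoreVector:
    """Control-normalized per-gene values M_jk and the per-cell mean score.

    By construction the mean score over control cells is exactly 1."""

    geneset: str
    M: pd.DataFrame            # used genes x cells
    scores: pd.Series          # per cell
    dropped_genes: list[str]


@dataclass
class ClusterAssignment:
    labels: pd.Series          # per gene: I / II / III / none
    fold_changes: pd.DataFrame # gene x condition, log2 vs control


def condition_fold_changes(
    E: pd.DataFrame,
    annotation: pd.DataFrame,
    control_condition: str = "control",
) -> pd.DataFrame:
    """Per-gene log2 fold change of condition mean E vs control mean E."""
    cond = annotation["condition"]
    cells = [c for c in E.columns if c in cond.index]
    cond = cond.loc[cells]
    ctrl = [c for c in cells if cond[c] == control_condition]
    if not ctrl:
        raise DataError(f"no cells in control condition {control_condition!r}")
    ctrl_mean = E[ctrl].mean(axis=1)
    out = {}
    for c, group in cond.groupby(cond).groups.items():
        if c == control_condition:
            continue
        if len(group) == 0:
            raise DataError(f"condition {c!r} has no cells")
        out[str(c)] = E[list(group)].mean(axis=1) - ctrl_mean
    return pd.DataFrame(out)


def assign_regulatory_clusters(
    fold_changes: pd.DataFrame,
    fold_threshold: float = 1.5,
    cele_condition: str = "CELE16",
    combo_condition: str = "COMBO16",
) -> ClusterAssignment:
    """Three coherent clusters from the celecoxib-16h / combination-16h FCs.

    With t = log2(fold_threshold):
      I:   down at celecoxib (FC <= -t) and up after combination (FC >= t)
      II:  down at celecoxib, no dynamic change after combination (|FC| < t)
      III: up after combination, no dynamic change at celecoxib
    """
    for c in (cele_condition, combo_condition):
        if c not in fold_changes.columns:
            raise DataError(f"fold changes missing required condition {c!r}")
    t = np.log2(fold_threshold)
    cele = fold_changes[cele_condition]
    combo = fold_changes[combo_condition]
    labels = pd.Series("none", index=fold_changes.index, name="cluster")
    labels[(cele <= -t) & (combo >= t)] = "I"
    labels[(cele <= -t) & (combo.abs() < t)] = "II"
    labels[(combo >= t) & (cele.abs() < t)] = "III"
    return ClusterAssignment(labels=labels, fold_changes=fold_changes)


def geneset_relative_expression(
    E: pd.DataFrame,
    geneset: GeneSet,
    annotation: pd.DataFrame,
    control_condition: str = "control",
) -> GenesetScoreVector:
    """M_jk = E_jk / control-mean(E_j); score_k = mean over the geneset.

    Genes absent from the matrix or with zero control mean are dropped with a
    warning; an empty effective geneset is an error.
    """
    cond = annotation["condition"]
    cells = [c for c in E.columns if c in cond.index]
    ctrl = [c for c in cells if cond[c] == control_condition]
    if not ctrl:
        raise DataError(f"no cells in control condition {control_condition!r}")
    present = [g for g in geneset.genes if g in E.index]
    dropped = [g for g in geneset.genes if g not in E.index]
    ctrl_mean = E.loc[present, ctrl].mean(axis=1)
    zero = ctrl_mean.index[ctrl_mean <= 0].tolist()
    if zero or dropped:
        warnings.warn(
            f"geneset {geneset.name!r}: dropped {len(dropped)} absent and "
            f"{len(zero)} zero-control-mean genes", stacklevel=2,
        )
    used = [g for g in present if g not in set(zero)]
    if not used:
        raise DataError(f"geneset {geneset.name!r} empty after filtering")
    M = E.loc[used, cells].div(ctrl_mean.loc[used], axis=0)
    scores = M.mean(axis=0).rename(f"score_{geneset.name}")
    return GenesetScoreVector(geneset=geneset.name, M=M, scores=scores,
                              dropped_genes=dropped + zero)


def compare_groups_wilcoxon(
    values: pd.Series,
    annotation: pd.DataFrame,
    comparisons: list[tuple[str, str]] | None = None,
    control_condition: str = "control",
) -> pd.Series:
    """Two-sided Wilcoxon rank-sum p-value per (group, reference) comparison.

    Defaults to every non-control condition vs control.  Exact distribution
    for group sizes <= 20 each, normal approximation with tie correction
    otherwise.  Groups need >= 2 values.
    """
    cond = annotation["condition"]
    common = values.index.intersection(cond.index)
    cond = cond.loc[common]
    vals = values.loc[common]
    if comparisons is None:
        comparisons = [(str(c), control_condition)
                       for c in cond.unique() if c != control_condition]
    out = {}
    for grp, ref in comparisons:
        a = vals[cond == grp].to_numpy(dtype=float)
        b = vals[cond == ref].to_numpy(dtype=float)
        if len(a) < 2 or len(b) < 2:
            raise DataError(f"comparison {grp!r} vs {ref!r}: group with < 2 values")
        method = "exact" if max(len(a), len(b)) <= 20 else "asymptotic"
        p = mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue
        out[f"{grp}_vs_{ref}"] = float(p)
    return pd.Series(out, name="wilcoxon_p")
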