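"""Coherent-module extraction over a sample panel and the response index.

Starting from a seed geneset, genes are filtered for expression breadth and
dynamic range, then pruned iteratively: each round recomputes the per-sample
summary S_k (median over current genes of the per-gene median-centered log2
expression) and drops genes whose Spearman correlation with S falls below
``rho_min``.  The fixed point defines the module; its S_k is the response
index.  Higher index values associate with worse drug response.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_auc_score

from .dynamics import compare_groups_wilcoxon  # noqa: F401  (CLI convenience)
from .errors import DataError, ModuleCollapseError


@dataclass
class PanelMatrix:
    """log2 expression (genes x samples) with an expressed-call mask and
    optional per-sample IC50 / responder annotations."""

    values: pd.DataFrame
    mask: pd.DataFrame | None = None
    ic50: pd.Series | None = None
    responder: pd.Series | None = None

    def __post_init__(self):
        if self.mask is not None:
            if self.mask.shape != self.values.shape:
                raise DataError("mask shape differs from expression shape")
            if not self.mask.index.equals(self.values.index) or \
               not self.mask.columns.equals(self.values.columns):
                self.mask = self.mask.reindex(index=self.values.index,
                                              columns=self.values.columns)
                if self.mask.isna().any().any():
                    raise DataError("mask does not cover the expression matrix")
        if self.ic50 is not None and (self.ic50 <= 0).any():
            raise DataError("IC50 values must be > 0")


@dataclass
class ModuleResult:
    seed_genes: list[str]
    retained_genes: list[str]
    trace: list[list[str]] = field(default_factory=list)  # gene set per iteration
    index: pd.Series | None = None                        # final S_k
    rho_min: float = 0.1
    final_rho: pd.Series | None = None


def filter_expressed_variable_genes(
    panel: PanelMatrix,
    seed: list[str],
    expr_fraction: float = 0.5,
    range_fold: float = 3.0,
) -> list[str]:
    """Seed genes expressed in > ``expr_fraction`` of samples whose
    p90 - p10 log2 range exceeds log2(``range_fold``).  Strict inequalities.
    """
    if panel.mask is None:
        raise DataError("panel has no expressed-call mask")
    present = [g for g in seed if g in panel.values.index]
    if not present:
        raise DataError("no seed gene present in the panel")
    vals = panel.values.loc[present]
    expr_frac = panel.mask.loc[present].mean(axis=1)
    p90 = vals.quantile(0.9, axis=1)
    p10 = vals.quantile(0.1, axis=1)
    keep = (expr_frac > expr_fraction) & ((p90 - p10) > np.log2(range_fold))
    return keep.index[keep].tolist()


def _spearman_vs_index(values: pd.DataFrame, s: np.ndarray) -> pd.Series:
    """Spearman correlation of every gene row against the index vector,
    average ranks for ties.  Constant rows yield NaN."""
    ranks = np.apply_along_axis(rankdata, 1, values.to_numpy(dtype=float))
    s_rank = rankdata(s)
    ranks_c = ranks - ranks.mean(axis=1, keepdims=True)
    s_c = s_rank - s_rank.mean()
    denom = np.sqrt((ranks_c ** 2).sum(axis=1) * (s_c ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (ranks_c @ s_c) / denom
    return pd.Series(rho, index=values.index)


def compute_response_index(panel: PanelMatrix, module_genes: list[str]) -> pd.Series:
    """index_k = median over module genes of (log2 value - per-gene median)."""
    if not module_genes:
        raise DataError("empty gene module")
    missing = [g for g in module_genes if g not in panel.values.index]
    if missing:
        raise DataError(f"module genes absent from panel: {missing}")
    vals = panel.values.loc[module_genes]
    centered = vals.sub(vals.median(axis=1), axis=0)
    return centered.median(axis=0).rename("response_index")


def module_gene_correlations(
    centered: pd.DataFrame, leave_one_out: bool = True
) -> pd.Series:
    """Spearman of each gene against the module summary S_k.

    With ``leave_one_out`` (the default) each gene is correlated against the
    median of the *other* genes.  The self-inclusive alternative
    (``leave_one_out=False``) correlates against the median over all genes,
    including the gene itself; with G independent genes that self-term alone
    is ~ sqrt(pi / 2G), so the pruning rule then never removes anything from
    small random gene sets — it hallucinates coherence.  Leave-one-out keeps
    the null clean and is indistinguishable on genuinely coherent modules.
    """
    arr = centered.to_numpy(dtype=float)
    if not leave_one_out:
        s = np.median(arr, axis=0)
        return _spearman_vs_index(centered, s)
    g = arr.shape[0]
    rhos = np.empty(g)
    keep = np.ones(g, dtype=bool)
    for j in range(g):
        keep[j] = False
        s_j = np.median(arr[keep], axis=0)
        keep[j] = True
        rhos[j] = _spearman_vs_index(centered.iloc[[j]], s_j).iloc[0]
    return pd.Series(rhos, index=centered.index)


def iterative_module_refinement(
    panel: PanelMatrix,
    genes: list[str],
    rho_min: float = 0.1,
    max_iter: int = 100,
    leave_one_out: bool = True,
) -> ModuleResult:
    """Prune genes until every survivor's Spearman with the module index is
    >= ``rho_min``.

    Per iteration the per-sample summary is the median of the per-gene
    median-centered log2 values over the current genes; each gene's Spearman
    against the summary (leave-one-out by default, see
    :func:`module_gene_correlations`) is computed and genes below ``rho_min``
    are dropped.  The gene set strictly shrinks on every non-final iteration,
    so the loop terminates within ``len(genes)`` rounds; ``max_iter`` is a
    safety cap.  Collapse below 2 genes raises :class:`ModuleCollapseError`
    carrying the trace.
    """
    current = [g for g in genes if g in panel.values.index]
    if len(current) < 2:
        raise DataError("module refinement needs >= 2 genes present in the panel")
    seed = list(current)
    centered = panel.values.loc[current].sub(
        panel.values.loc[current].median(axis=1), axis=0
    )
    trace: list[list[str]] = []
    rho = None
    for _ in range(max_iter):
        trace.append(list(current))
        rho = module_gene_correlations(centered.loc[current], leave_one_out)
        drop = rho.index[~(rho >= rho_min)].tolist()  # NaN counts as drop
        if not drop:
            break
        current = [g for g in current if g not in set(drop)]
        if len(current) < 2:
            trace.append(list(current))
            raise ModuleCollapseError(trace)
    index = centered.loc[current].median(axis=0).rename("response_index")
    return ModuleResult(
        seed_genes=seed, retained_genes=current, trace=trace,
        index=index, rho_min=rho_min, final_rho=rho.loc[current],
    )


def evaluate_index_outcome(
    index: pd.Series,
    outcome: pd.Series,
    n_groups: int = 3,
) -> dict[str, float]:
    """Rank-sum p and ROC AUC linking the index to an outcome.

    Binary outcome (responder labels): the index is compared between classes
    and scored as a predictor of the *adverse* class (non-responder), so a
    higher index predicting worse response yields AUC > 0.5.  Continuous
    outcome (IC50): samples are grouped into ``n_groups`` index quantile
    groups and the top group's IC50 values are compared against the bottom
    group's; the AUC dichotomizes IC50 at its median.
    """
    common = index.index.intersection(outcome.index)
    if len(common) < 10:
        raise DataError("outcome evaluation needs >= 10 samples")
    idx = index.loc[common].astype(float)
    out = outcome.loc[common]

    if out.dtype == bool or set(pd.unique(out)) <= {0, 1, True, False}:
        responder = out.astype(bool)
        if responder.all() or (~responder).all():
            raise DataError("one outcome class is empty")
        groups = pd.DataFrame({"condition": np.where(responder, "responder",
                                                     "non_responder")}, index=common)
        p = compare_groups_wilcoxon(
            idx, groups, comparisons=[("responder", "non_responder")]
        ).iloc[0]
        auc = float(roc_auc_score((~responder).to_numpy(), idx.to_numpy()))
    else:
        ic50 = out.astype(float)
        q = pd.qcut(idx.rank(method="first"), q=n_groups, labels=False)
        top = ic50[q == n_groups - 1]
        bottom = ic50[q == 0]
        if len(top) < 2 or len(bottom) < 2:
            raise DataError("index quantile group too small")
        groups = pd.DataFrame(
            {"condition": np.where(q == n_groups - 1, "top",
                                   np.where(q == 0, "bottom", "mid"))}, index=common)
        p = compare_groups_wilcoxon(
            ic50, groups, comparisons=[("top", "bottom")]
        ).iloc[0]
        high = (ic50 > ic50.median()).to_numpy()
        if high.all() or not high.any():
            raise DataError("IC50 median split produced an empty class")
        auc = float(roc_auc_score(high, idx.to_numpy()))
    return {"wilcoxon_p": float(p), "auc": auc}


def restrict_geneset_to_context(
    module_genes: list[str],
    mask: pd.DataFrame,
    context_samples: list[str],
    expr_fraction: float = 0.5,
) -> list[str]:
    """Module genes expressed in > ``expr_fraction`` of the context samples."""
    missing = [g for g in module_genes if g not in mask.index]
    if missing:
        raise DataError(f"mask lacks module genes: {missing}")
    ctx = [s for s in context_samples if s in mask.columns]
    if not ctx:
        raise DataError("no context samples present in the mask")
    frac = mask.loc[module_genes, ctx].mean(axis=1)
    kept = frac.index[frac > expr_fraction].tolist()
    if not kept:
        raise DataError("no module gene passes the context expression filter")
    return kept
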