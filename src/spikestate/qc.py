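"""Cell- and gene-level quality control.

Order matters: cells are filtered first (housekeeping detection), then gene
detection fractions are computed on the retained cells only.  Both filters
use strict inequalities: a cell is removed iff its mean housekeeping E-value
is strictly below the threshold, and a gene is kept iff its detection
fraction is strictly above the cutoff in at least one condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import DataError
from .normalization import SpikeInSet, spikein_normalize_evalues, EvalueMatrix


@dataclass
class QCReport:
    removed_cell_ids: list[str] = field(default_factory=list)
    retained_cell_ids: list[str] = field(default_factory=list)
    removed_gene_ids: list[str] = field(default_factory=list)
    retained_gene_ids: list[str] = field(default_factory=list)
    housekeeping_mean_e: pd.Series | None = None          # per cell
    detection_fractions: pd.DataFrame | None = None       # gene x condition


def read_gene_list(path) -> list[str]:
    """One id per line; '#' starts a comment; blank lines ignored."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                out.append(line)
    return out


def filter_cells_by_housekeeping(
    E: pd.DataFrame, housekeeping: list[str], threshold: float = 1.0
) -> QCReport:
    """Remove cells whose mean housekeeping E-value is < ``threshold``.

    Housekeeping genes absent from the matrix are ignored, not treated as
    zero.  Raises if none overlap the matrix.
    """
    present = [g for g in housekeeping if g in E.index]
    if not present:
        raise DataError("no housekeeping gene overlaps the expression matrix")
    mean_e = E.loc[present].mean(axis=0)
    removed = mean_e.index[mean_e < threshold].tolist()
    retained = mean_e.index[mean_e >= threshold].tolist()
    return QCReport(
        removed_cell_ids=removed,
        retained_cell_ids=retained,
        housekeeping_mean_e=mean_e.rename("housekeeping_mean_e"),
    )


def filter_genes_by_detection(
    tpm: pd.DataFrame,
    annotation: pd.DataFrame,
    fraction: float = 0.3,
    spikein_ids: list[str] | None = None,
) -> QCReport:
    """Keep genes detected (TPM > 0) in > ``fraction`` of cells of >= 1 condition.

    ``tpm`` must already be restricted to QC-retained cells.  Spike-in rows
    (``spikein_ids``) are always kept.
    """
    cells = tpm.columns
    missing = cells.difference(annotation.index)
    if len(missing):
        raise DataError(f"cells without condition labels: {missing.tolist()}")
    conditions = annotation.loc[cells, "condition"]
    counts = conditions.value_counts()
    if (counts == 0).any():
        raise DataError("condition with zero cells")

    detected = tpm > 0
    frac = detected.T.groupby(conditions).mean().T  # gene x condition
    keep = (frac > fraction).any(axis=1)
    spike = set(spikein_ids or [])
    if spike:
        keep |= tpm.index.to_series().isin(spike)
    return QCReport(
        retained_cell_ids=list(cells),
        removed_gene_ids=keep.index[~keep].tolist(),
        retained_gene_ids=keep.index[keep].tolist(),
        detection_fractions=frac,
    )


def run_qc_pipeline(
    tpm: pd.DataFrame,
    spikeins: SpikeInSet,
    housekeeping: list[str],
    annotation: pd.DataFrame,
    cell_threshold: float = 1.0,
    gene_fraction: float = 0.3,
    capture_scale: float = 10.0,
) -> tuple[EvalueMatrix, QCReport]:
    """Full QC: normalize, drop poor cells, renormalize on retained cells,
    drop poorly detected genes, and return the final E-value matrix.

    The anchor-ratio mean is recomputed on the retained cells so removed
    cells do not influence the normalization of survivors.
    """
    ev0 = spikein_normalize_evalues(tpm, spikeins, capture_scale)
    cell_rep = filter_cells_by_housekeeping(ev0.E, housekeeping, cell_threshold)
    kept_cells = cell_rep.retained_cell_ids
    if not kept_cells:
        raise DataError("all cells removed by housekeeping filter")
    tpm2 = tpm[kept_cells]
    gene_rep = filter_genes_by_detection(
        tpm2, annotation, gene_fraction, spikein_ids=spikeins.spikein_ids
    )
    tpm3 = tpm2.loc[gene_rep.retained_gene_ids]
    ev = spikein_normalize_evalues(tpm3, spikeins, capture_scale)
    report = QCReport(
        removed_cell_ids=cell_rep.removed_cell_ids,
        retained_cell_ids=kept_cells,
        removed_gene_ids=gene_rep.removed_gene_ids,
        retained_gene_ids=gene_rep.retained_gene_ids,
        housekeeping_mean_e=cell_rep.housekeeping_mean_e,
        detection_fractions=gene_rep.detection_fractions,
    )
    return ev, report
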