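"""Spike-in normalization and global transcriptome-abundance estimation.

The central quantity is the spike-in-normalized expression value

    N_jk = TPM_jk / (TPM_sk / mean_i(TPM_si))

where ``s`` is the anchor (highest-expressed) spike-in, followed by the
log-scale expression value

    E_jk = log2(N_jk / capture_scale + 1)

with ``capture_scale`` defaulting to 10 (single-cell capture complexity
relative to bulk).  Because the spike-in amount is constant per cell, the
per-cell anchor ratio tracks inverse mRNA content and N recovers relative
absolute expression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError

DEFAULT_CAPTURE_SCALE = 10.0


@dataclass
class SpikeInSet:
    """The spike-in rows of an expression matrix.

    ``anchor_id`` may be given explicitly; otherwise it is inferred as the
    spike-in with the largest mean TPM across cells (see :meth:`resolve_anchor`).
    """

    spikein_ids: list[str]
    designed_concentrations: list[float] | None = None
    anchor_id: str | None = None

    def __post_init__(self):
        if not self.spikein_ids:
            raise DataError("spike-in set is empty")
        if len(set(self.spikein_ids)) != len(self.spikein_ids):
            raise DataError("spike-in ids are not unique")
        if self.designed_concentrations is not None:
            if len(self.designed_concentrations) != len(self.spikein_ids):
                raise DataError("designed_concentrations length mismatch")
            if any(c <= 0 for c in self.designed_concentrations):
                raise DataError("designed concentrations must be > 0")
        if self.anchor_id is not None and self.anchor_id not in self.spikein_ids:
            raise DataError(f"anchor {self.anchor_id!r} not among spike-in ids")

    def resolve_anchor(self, tpm: pd.DataFrame) -> str:
        if self.anchor_id is not None:
            return self.anchor_id
        present = [s for s in self.spikein_ids if s in tpm.index]
        if not present:
            raise DataError("no spike-in row present in the matrix")
        return tpm.loc[present].mean(axis=1).idxmax()


@dataclass
class EvalueMatrix:
    """Normalized (N) and log-scale (E) expression; E filled lazily."""

    N: pd.DataFrame
    E: pd.DataFrame | None = None
    capture_scale: float = DEFAULT_CAPTURE_SCALE


@dataclass
class AbundanceVector:
    """Per-cell log2 relative transcriptome abundance, control-median-centered."""

    values: pd.Series
    method: str
    control_median_log2: float = field(default=np.nan)


def _check_matrix(tpm: pd.DataFrame) -> None:
    if tpm.index.has_duplicates:
        raise DataError("gene ids are not unique")
    if tpm.columns.has_duplicates:
        raise DataError("cell ids are not unique")
    if (tpm.values < 0).any():
        raise DataError("TPM values must be non-negative")


def normalize_to_spikein(tpm: pd.DataFrame, spikeins: SpikeInSet) -> EvalueMatrix:
    """Divide each cell's TPM by its anchor-spike-in ratio to the cross-cell mean.

    Spike-in rows are kept in the output.  Raises :class:`DataError` listing
    the offending cells if the anchor spike-in has zero TPM anywhere (such
    cells should have been removed by QC first).
    """
    _check_matrix(tpm)
    anchor = spikeins.resolve_anchor(tpm)
    anchor_tpm = tpm.loc[anchor]
    zero_cells = anchor_tpm.index[anchor_tpm <= 0].tolist()
    if zero_cells:
        raise DataError(
            f"anchor spike-in {anchor!r} has zero TPM in cells: {zero_cells}"
        )
    factor = anchor_tpm / anchor_tpm.mean()
    N = tpm.div(factor, axis=1)
    return EvalueMatrix(N=N)


def compute_evalues(
    ev: EvalueMatrix, capture_scale: float = DEFAULT_CAPTURE_SCALE
) -> EvalueMatrix:
    """Fill E = log2(N / capture_scale + 1) elementwise."""
    if capture_scale <= 0:
        raise ConfigError("capture_scale", "must be > 0")
    ev.E = np.log2(ev.N / capture_scale + 1.0)
    ev.capture_scale = capture_scale
    return ev


def spikein_normalize_evalues(
    tpm: pd.DataFrame,
    spikeins: SpikeInSet,
    capture_scale: float = DEFAULT_CAPTURE_SCALE,
) -> EvalueMatrix:
    """Convenience: :func:`normalize_to_spikein` then :func:`compute_evalues`."""
    return compute_evalues(normalize_to_spikein(tpm, spikeins), capture_scale)


def relative_transcriptome_abundance(
    annotation: pd.DataFrame,
    method: str = "read_ratio",
    reads: pd.DataFrame | None = None,
    tpm: pd.DataFrame | None = None,
    spikeins: SpikeInSet | None = None,
    top_n: int = 5000,
    control_condition: str = "control",
) -> AbundanceVector:
    """Per-cell log2 relative transcriptome abundance.

    ``method="read_ratio"`` uses the ratio of endogenous to spike-in mapped
    reads (``reads`` must have columns ``endogenous_reads``/``spikein_reads``);
    ``method="top_tpm"`` uses the sum of the ``top_n`` highest endogenous TPM
    values divided by the anchor spike-in TPM.  The log2 ratios are centered
    so the median over control cells is exactly 0.
    """
    conditions = annotation["condition"]
    control_cells = conditions.index[conditions == control_condition]
    if len(control_cells) == 0:
        raise DataError(f"no cells in control condition {control_condition!r}")

    if method == "read_ratio":
        if reads is None:
            raise DataError("read_ratio method requires per-cell read counts")
        cells = annotation.index
        missing = cells.difference(reads.index)
        if len(missing):
            raise DataError(f"read counts missing for cells: {missing.tolist()}")
        r = reads.loc[cells]
        if (r["spikein_reads"] <= 0).any():
            bad = r.index[r["spikein_reads"] <= 0].tolist()
            raise DataError(f"zero spike-in reads in cells: {bad}")
        ratio = r["endogenous_reads"] / r["spikein_reads"]
    elif method == "top_tpm":
        if tpm is None or spikeins is None:
            raise DataError("top_tpm method requires a TPM matrix and spike-in set")
        _check_matrix(tpm)
        anchor = spikeins.resolve_anchor(tpm)
        endo = tpm.drop(index=[s for s in spikeins.spikein_ids if s in tpm.index])
        cells = annotation.index
        missing = cells.difference(tpm.columns)
        if len(missing):
            raise DataError(f"TPM missing for cells: {missing.tolist()}")
        anchor_tpm = tpm.loc[anchor, cells]
        if (anchor_tpm <= 0).any():
            bad = anchor_tpm.index[anchor_tpm <= 0].tolist()
            raise DataError(f"zero anchor spike-in TPM in cells: {bad}")
        # deterministic top-n: stable descending sort over a lexicographically
        # ordered index breaks TPM ties by gene id
        endo = endo.sort_index()
        order = endo.apply(
            lambda col: col.sort_values(ascending=False, kind="mergesort")
            .iloc[:top_n].sum()
        )
        ratio = order.loc[cells] / anchor_tpm
    else:
        raise DataError(f"unknown abundance method {method!r}")

    if (ratio <= 0).any():
        raise DataError("non-positive endogenous/spike-in ratio encountered")
    log_ratio = np.log2(ratio.astype(float))
    center = float(log_ratio.loc[control_cells].median())
    return AbundanceVector(values=log_ratio - center, method=method,
                           control_median_log2=center)
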