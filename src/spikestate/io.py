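"""TSV readers/writers for the CLI.

Dialect: tab-separated, UTF-8, no quoting; matrices carry the gene id in the
first column and cell/sample ids in the header row.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd


def read_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def write_matrix(df: pd.DataFrame, path, index_label: str = "gene_id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_annotation(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if "condition" not in df.columns:
        raise ValueError(f"{path}: annotation needs a 'condition' column")
    return df


def read_reads(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    for col in ("endogenous_reads", "spikein_reads"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return df


def read_mask(path) -> pd.DataFrame:
    return read_matrix(path).astype(bool)


def write_mtx(tpm: pd.DataFrame, outdir) -> None:
    """Optional MatrixMarket triplet next to the TSV outputs."""
    from scipy.io import mmwrite
    from scipy.sparse import csr_matrix

    outdir = Path(outdir)
    mmwrite(outdir / "matrix.mtx", csr_matrix(tpm.to_numpy()))
    (outdir / "genes.tsv").write_text("\n".join(tpm.index) + "\n")
    (outdir / "barcodes.tsv").write_text("\n".join(tpm.columns) + "\n")
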