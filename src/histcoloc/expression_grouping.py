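"""Partition genes into the eleven expression groups used throughout.

Genes with FPKM = 0 form the "zero" group; the remaining genes are ranked
ascending by FPKM and cut at rank deciles into ten equal-count groups
q0-10 (lowest nonzero expression) through q90-100 (highest). The same
rank-decile cut is reused to group genes by promoter ChIP signal.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .signal_track import SignalTrack

logger = logging.getLogger(__name__)

__all__ = [
    "GROUP_LABELS",
    "DECILE_LABELS",
    "read_expression_table",
    "assign_expression_groups",
    "assign_signal_decile_groups",
    "promoter_mean_si",
]

DECILE_LABELS = tuple(f"q{10 * i}-{10 * (i + 1)}" for i in range(10))
GROUP_LABELS = ("zero",) + DECILE_LABELS


def read_expression_table(path, gene_col: str | None = None,
                          fpkm_col: str | None = None) -> pd.Series:
    """Read gene_id -> FPKM from a Cufflinks gene_exp.diff-style TSV.

    With a header line, columns are picked by name (defaults: 'gene_id'/'gene'
    and a column containing 'fpkm' or named 'value_1'); a headerless 2-column
    file is taken as (gene_id, fpkm).
    """
    df = pd.read_csv(path, sep="\t")
    cols = [c.lower() for c in df.columns]
    if gene_col is None:
        for cand in ("gene_id", "gene", "test_id"):
            if cand in cols:
                gene_col = df.columns[cols.index(cand)]
                break
    if fpkm_col is None:
        for i, c in enumerate(cols):
            if "fpkm" in c or c == "value_1":
                fpkm_col = df.columns[i]
                break
    if gene_col is None or fpkm_col is None:
        # headerless two-column fallback
        df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "fpkm"])
        gene_col, fpkm_col = "gene_id", "fpkm"
    out = df.set_index(gene_col)[fpkm_col].astype(float)
    if (out < 0).any():
        raise ValueError("FPKM values must be non-negative")
    if out.index.duplicated().any():
        raise ValueError("duplicate gene_id in expression table")
    out.name = "fpkm"
    return out


def _rank_deciles(values: pd.Series) -> pd.Series:
    """Ten equal-count groups by ascending value, ties broken by gene_id.

    Group sizes differ by at most one; the i-th of n ranked genes gets
    decile floor(10*i/n).
    """
    order = values.reset_index()
    order.columns = ["gene_id", "value"]
    order = order.sort_values(["value", "gene_id"], kind="stable").reset_index(drop=True)
    n = len(order)
    decile = (10 * np.arange(n)) // n
    labels = pd.Series(
        pd.Categorical.from_codes(decile, categories=list(DECILE_LABELS)),
        index=order["gene_id"],
    )
    return labels.reindex(values.index)


def assign_expression_groups(fpkm: pd.Series) -> pd.Series:
    """gene_id -> one of 'zero', 'q0-10', ..., 'q90-100'.

    FPKM = 0 genes are labelled 'zero'; the rest are cut at rank deciles of
    FPKM. Raises on an empty table; warns if every gene has FPKM 0.
    """
    if len(fpkm) == 0:
        raise ValueError("expression table is empty")
    if (fpkm < 0).any():
        raise ValueError("FPKM values must be non-negative")
    labels = pd.Series(
        pd.Categorical([None] * len(fpkm), categories=list(GROUP_LABELS)),
        index=fpkm.index, name="group",
    )
    zero = fpkm == 0
    labels[zero] = "zero"
    nonzero = fpkm[~zero]
    if len(nonzero) == 0:
        logger.warning("all genes have FPKM = 0; only the 'zero' group is populated")
        return labels
    labels[nonzero.index] = _rank_deciles(nonzero).astype(str)
    return labels


def promoter_mean_si(si: SignalTrack, genes: pd.DataFrame, flank: int = 2000) -> pd.Series:
    """Per-gene mean SI over [tss - flank, tss + flank), strand-agnostic.

    Windows extending past a chromosome edge are truncated, not an error.
    The mean is over the SI bins the (truncated) window touches, so it is
    invariant to the bin count of the underlying grid.
    """
    L = si.grid.bin_size
    out = np.empty(len(genes))
    for i, (_, g) in enumerate(genes.iterrows()):
        length = si.grid.layout.length_of(g["chrom"])
        lo = max(0, int(g["tss"]) - flank)
        hi = min(length, int(g["tss"]) + flank)
        b0 = lo // L
        b1 = (hi - 1) // L + 1
        off = si.grid.offsets[g["chrom"]]
        out[i] = si.values[off + b0:off + b1].mean()
    return pd.Series(out, index=genes["gene_id"].to_numpy(), name="promoter_si")


def assign_signal_decile_groups(si: SignalTrack, genes: pd.DataFrame,
                                flank: int = 2000) -> pd.Series:
    """gene_id -> q0-10 ... q90-100 by rank decile of promoter mean SI."""
    return _rank_deciles(promoter_mean_si(si, genes, flank)).rename("group")
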