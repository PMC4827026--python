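"""Anchor-relative aggregation profiles stratified by expression group.

"Peaks per gene" profiles average, over all genes of an expression group, an
indicator of peak coverage at each base-pair offset from the TSS (or TES),
with minus-strand genes flipped so that positive offsets always point
downstream of transcription. Metagene profiles additionally rescale the gene
body linearly to [0, 1] between TSS and TES while flanks keep absolute
distances. Raw-signal profiles aggregate binned SI instead of peak
indicators.

Profiles are returned in long form: one row per (group, axis position).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from ._intervals import ChromIntervalIndex
from .expression_grouping import GROUP_LABELS
from .genomic_io import IntervalSet
from .signal_track import SignalTrack

logger = logging.getLogger(__name__)

__all__ = [
    "peaks_per_gene_profile",
    "metagene_profile",
    "raw_signal_tss_profile",
    "select_enriched_genes",
    "write_profile",
]


def _group_iter(genes: pd.DataFrame, groups: pd.Series):
    labels = groups.reindex(genes["gene_id"])
    if isinstance(labels.dtype, pd.CategoricalDtype):
        present = [str(g) for g in labels.cat.categories]
    else:
        present = [g for g in GROUP_LABELS if g in set(labels.dropna().astype(str))]
        if not present:
            present = list(pd.unique(labels.dropna().astype(str)))
    for lab in present:
        sub = genes[(labels == lab).to_numpy()]
        if len(sub) == 0:
            logger.warning("expression group %s is empty; profile will be zeros", lab)
        yield lab, sub


def _anchor_points(sub: pd.DataFrame, anchor: str, offsets: np.ndarray):
    """Genome coordinates anchor + offset, strand-flipped, per chromosome."""
    col = "tss" if anchor.upper() == "TSS" else "tes"
    for chrom, grp in sub.groupby("chrom", sort=False):
        a = grp[col].to_numpy(np.int64)[:, None]
        sign = np.where(grp["strand"].to_numpy() == "+", 1, -1)[:, None]
        yield chrom, a + sign * offsets[None, :]


def _evaluate(source, chrom: str, points: np.ndarray) -> np.ndarray:
    """Coverage indicator (IntervalSet index) or track value at each point."""
    if isinstance(source, ChromIntervalIndex):
        return source.points_covered(chrom, points).astype(float)
    return source.value_at(chrom, points)


def _profile_over_offsets(source, genes, groups, anchor, offsets) -> pd.DataFrame:
    rows = []
    for lab, sub in _group_iter(genes, groups):
        acc = np.zeros(len(offsets))
        n = 0
        for chrom, points in _anchor_points(sub, anchor, offsets):
            acc += _evaluate(source, chrom, points).sum(axis=0)
            n += len(points)
        vals = acc / n if n else acc
        rows.append(pd.DataFrame({"group": lab, "axis": offsets, "value": vals}))
    return pd.concat(rows, ignore_index=True)


def peaks_per_gene_profile(peaks: IntervalSet, genes: pd.DataFrame, groups: pd.Series,
                           anchor: str = "TSS", flank: int = 5000,
                           step: int = 50) -> pd.DataFrame:
    """Group-average peak-coverage indicator by bp offset from the anchor.

    Values lie in [0, 1]: the fraction of the group's genes whose anchor
    offset falls inside a peak ("peaks per gene").
    """
    offsets = np.arange(-flank, flank + 1, step, dtype=np.int64)
    index = ChromIntervalIndex(peaks)
    return _profile_over_offsets(index, genes, groups, anchor, offsets)


def raw_signal_tss_profile(si: SignalTrack, genes: pd.DataFrame, groups: pd.Series,
                           flank: int = 5000) -> pd.DataFrame:
    """Group-mean SI by window offset from the TSS, strand-flipped.

    Sampling steps at the track's own bin size (200 bp in the nucleosome-scale
    configuration); each offset reads the SI of the window containing it.
    """
    step = si.grid.bin_size
    offsets = np.arange(-flank, flank + 1, step, dtype=np.int64)
    return _profile_over_offsets(si, genes, groups, "TSS", offsets)


def metagene_profile(source, genes: pd.DataFrame, groups: pd.Series,
                     flank: int = 5000, n_body_bins: int = 100,
                     step: int = 50) -> pd.DataFrame:
    """Composite profile: -flank..TSS, gene body rescaled to [0,1], TES..+flank.

    ``source`` is an IntervalSet (peak-coverage indicator averaged per group)
    or a SignalTrack (mean SI). Body positions sample the point at fraction
    (j + 0.5)/n_body_bins between TSS and TES, so genes shorter than
    n_body_bins bases still contribute to every body bin. The numeric ``axis``
    is upstream bp scaled to [-1,0), body fraction in [0,1], downstream
    mapped to (1,2]; ``segment`` and ``position`` keep the native units.
    """
    if isinstance(source, IntervalSet):
        source = ChromIntervalIndex(source)
    up = np.arange(-flank, 0, step, dtype=np.int64)  # bp upstream of TSS
    body_f = (np.arange(n_body_bins) + 0.5) / n_body_bins
    down = np.arange(step, flank + 1, step, dtype=np.int64)  # bp past TES

    rows = []
    for lab, sub in _group_iter(genes, groups):
        acc = np.zeros(len(up) + n_body_bins + len(down))
        n = 0
        for chrom, grp in sub.groupby("chrom", sort=False):
            tss = grp["tss"].to_numpy(np.int64)[:, None]
            tes = grp["tes"].to_numpy(np.int64)[:, None]
            sign = np.where(grp["strand"].to_numpy() == "+", 1, -1)[:, None]
            pts = np.concatenate(
                [
                    tss + sign * up[None, :],
                    np.rint(tss + body_f[None, :] * (tes - tss)).astype(np.int64),
                    tes + sign * down[None, :],
                ],
                axis=1,
            )
            acc += _evaluate(source, chrom, pts).sum(axis=0)
            n += len(grp)
        vals = acc / n if n else acc
        axis = np.concatenate([up / flank, body_f, 1 + down / flank])
        segment = (["upstream"] * len(up) + ["body"] * n_body_bins
                   + ["downstream"] * len(down))
        position = np.concatenate([up, body_f, down])
        rows.append(pd.DataFrame({"group": lab, "segment": segment,
                                  "position": position, "axis": axis, "value": vals}))
    return pd.concat(rows, ignore_index=True)


def select_enriched_genes(peaks: IntervalSet, genes: pd.DataFrame,
                          window: int = 1000) -> pd.DataFrame:
    """Genes with >= 1 bp of peak overlap within [tss - window, tss + window)."""
    index = ChromIntervalIndex(peaks)
    keep = np.zeros(len(genes), dtype=bool)
    pos = {c: np.flatnonzero((genes["chrom"] == c).to_numpy())
           for c in pd.unique(genes["chrom"])}
    for chrom, idx in pos.items():
        tss = genes["tss"].to_numpy(np.int64)[idx]
        keep[idx] = index.ranges_overlap(str(chrom), tss - window, tss + window)
    return genes[keep].reset_index(drop=True)


def write_profile(profile: pd.DataFrame, path) -> None:
    profile.to_csv(path, sep="\t", index=False)
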