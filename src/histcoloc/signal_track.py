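"""Binned RPKM, input-subtracted signal intensity and region fold-change.

Read counts in fixed genomic bins are normalised as RPKM
(count / (bin_kb * million_mapped_reads)); the per-bin difference
RPKM_ChIP - RPKM_input is the normalised signal intensity (SI) used by every
downstream analysis. Region fold-change is RPKM_ChIP / RPKM_input over a
strand-aware promoter (TSS +/- 1 kb) or gene-body region.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genomic_io import GenomeLayout, IntervalSet, ReadSet

logger = logging.getLogger(__name__)

__all__ = [
    "BinGrid",
    "SignalTrack",
    "count_reads_in_bins",
    "rpkm",
    "signal_intensity",
    "region_rpkm",
    "fold_change",
    "fold_change_table",
    "naive_peak_call",
    "write_bedgraph",
    "read_bedgraph",
]


@dataclass(frozen=True)
class BinGrid:
    """Fixed-width tiling of a genome; the last bin per chromosome may be short."""

    layout: GenomeLayout
    bin_size: int

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")

    @property
    def n_bins_per_chrom(self) -> tuple[int, ...]:
        return tuple(-(-l // self.bin_size) for l in self.layout.chrom_lengths)

    @property
    def n_bins(self) -> int:
        return sum(self.n_bins_per_chrom)

    @property
    def offsets(self) -> dict[str, int]:
        """First flat index of each chromosome's bins."""
        out, acc = {}, 0
        for name, n in zip(self.layout.chrom_names, self.n_bins_per_chrom):
            out[name] = acc
            acc += n
        return out

    def bin_index(self, chrom: str, pos) -> np.ndarray:
        """Flat bin index of genomic position(s); positions clipped to chrom."""
        length = self.layout.length_of(chrom)
        pos = np.clip(np.asarray(pos, dtype=np.int64), 0, length - 1)
        return self.offsets[chrom] + pos // self.bin_size

    def bins_frame(self) -> pd.DataFrame:
        """All bins as a (chrom, start, end) table in flat order."""
        rows = []
        for name, length in zip(self.layout.chrom_names, self.layout.chrom_lengths):
            starts = np.arange(0, length, self.bin_size, dtype=np.int64)
            ends = np.minimum(starts + self.bin_size, length)
            rows.append(pd.DataFrame({"chrom": name, "start": starts, "end": ends}))
        return pd.concat(rows, ignore_index=True)


@dataclass
class SignalTrack:
    """One value per grid bin; kind 'rpkm' or 'si'."""

    grid: BinGrid
    values: np.ndarray
    kind: str = "si"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (self.grid.n_bins,):
            raise ValueError("values length must equal number of bins")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("track values must be finite")

    def chrom_values(self, chrom: str) -> np.ndarray:
        off = self.grid.offsets[chrom]
        n = self.grid.n_bins_per_chrom[self.grid.layout.chrom_names.index(chrom)]
        return self.values[off:off + n]

    def value_at(self, chrom: str, pos) -> np.ndarray:
        """Track value of the bin containing each genomic position."""
        return self.values[self.grid.bin_index(chrom, pos)]


def count_reads_in_bins(reads: ReadSet, grid: BinGrid) -> np.ndarray:
    """Per-bin 5'-end counts; sums to total_mapped for in-layout reads."""
    counts = np.zeros(grid.n_bins, dtype=np.int64)
    npc = dict(zip(grid.layout.chrom_names, grid.n_bins_per_chrom))
    for chrom, pos in reads.positions.items():
        if chrom not in npc:
            raise ValueError(f"reads on chromosome {chrom!r} outside the grid layout")
        off = grid.offsets[chrom]
        counts[off:off + npc[chrom]] = np.bincount(
            pos // grid.bin_size, minlength=npc[chrom]
        )
    return counts


def rpkm(counts: np.ndarray, bin_size: int, total_mapped: int, grid: BinGrid | None = None):
    """Reads per kilobase per million mapped: count / (L_kb * M_reads).

    Returns a SignalTrack(kind='rpkm') when a grid is given, else the array.
    """
    if total_mapped <= 0:
        raise ValueError("total_mapped must be positive")
    values = np.asarray(counts, dtype=np.float64) / (
        (bin_size / 1000.0) * (total_mapped / 1e6)
    )
    if grid is None:
        return values
    return SignalTrack(grid, values, kind="rpkm")


def reads_to_rpkm_track(reads: ReadSet, grid: BinGrid) -> SignalTrack:
    return rpkm(count_reads_in_bins(reads, grid), grid.bin_size, reads.total_mapped, grid)


def signal_intensity(chip: SignalTrack, input_: SignalTrack) -> SignalTrack:
    """SI = RPKM_ChIP - RPKM_input per bin (may be negative)."""
    if chip.grid != input_.grid:
        raise ValueError("signal_intensity requires tracks on the same grid")
    return SignalTrack(chip.grid, chip.values - input_.values, kind="si")


def si_track(chip: ReadSet, input_: ReadSet, grid: BinGrid) -> SignalTrack:
    """Convenience: reads -> binned RPKM -> input-subtracted SI."""
    return signal_intensity(reads_to_rpkm_track(chip, grid), reads_to_rpkm_track(input_, grid))


def region_rpkm(reads: ReadSet, chrom: str, start: int, end: int,
                total_mapped: int | None = None) -> float:
    """RPKM over one region, with the region's own length as the kb denominator."""
    if end <= start:
        raise ValueError("region must have positive length")
    total = reads.total_mapped if total_mapped is None else total_mapped
    if total <= 0:
        raise ValueError("total_mapped must be positive")
    count = reads.count_in(chrom, start, end)
    return count / (((end - start) / 1000.0) * (total / 1e6))


def _gene_region(gene: pd.Series, region_kind: str, layout: GenomeLayout) -> tuple[int, int] | None:
    """Strand-aware region bounds, clipped to the chromosome; None => skip."""
    length = layout.length_of(gene["chrom"])
    if region_kind == "tss1kb":
        start, end = gene["tss"] - 1000, gene["tss"] + 1000
    elif region_kind == "genebody":
        if gene["end"] - gene["start"] <= 1000:
            return None
        # 1 kb downstream of TSS to TES, following the strand
        if gene["strand"] == "+":
            start, end = gene["start"] + 1000, gene["end"]
        else:
            start, end = gene["start"], gene["end"] - 1000
    else:
        raise ValueError(f"unknown region kind {region_kind!r}")
    return max(0, int(start)), min(length, int(end))


def fold_change(chip_reads: ReadSet, input_reads: ReadSet, gene: pd.Series,
                region_kind: str, layout: GenomeLayout) -> float | None:
    """FC = RPKM_ChIP / RPKM_input over the gene's region.

    A pseudocount of one read is added to both numerator and denominator
    counts when the input count is zero, keeping FC finite while applied
    symmetrically. Genes too short for a gene-body region return None.
    """
    region = _gene_region(gene, region_kind, layout)
    if region is None:
        logger.warning("gene %s shorter than 1 kb: gene-body FC skipped", gene["gene_id"])
        return None
    start, end = region
    c = chip_reads.count_in(gene["chrom"], start, end)
    i = input_reads.count_in(gene["chrom"], start, end)
    if i == 0:
        c, i = c + 1, i + 1
    kb = (end - start) / 1000.0
    num = c / (kb * chip_reads.total_mapped / 1e6)
    den = i / (kb * input_reads.total_mapped / 1e6)
    return num / den


def fold_change_table(chip_reads: ReadSet, input_reads: ReadSet, genes: pd.DataFrame,
                      region_kind: str, layout: GenomeLayout) -> pd.DataFrame:
    """Per-gene FC over tss1kb or genebody regions (skipped genes omitted)."""
    rows = []
    for _, gene in genes.iterrows():
        fc = fold_change(chip_reads, input_reads, gene, region_kind, layout)
        if fc is not None:
            rows.append((gene["gene_id"], region_kind, fc))
    return pd.DataFrame(rows, columns=["gene_id", "region", "fc"])


def naive_peak_call(chip_si: SignalTrack, min_si: float, min_run: int = 1) -> IntervalSet:
    """Maximal runs of >= min_run consecutive bins with SI >= min_si.

    Convenience caller so the pipeline runs without an external peak caller;
    it implements no background model.
    """
    grid = chip_si.grid
    chroms, starts, ends = [], [], []
    for chrom in grid.layout.chrom_names:
        v = chip_si.chrom_values(chrom) >= min_si
        if not v.any():
            continue
        edges = np.diff(np.concatenate(([0], v.view(np.int8), [0])))
        run_s = np.flatnonzero(edges == 1)
        run_e = np.flatnonzero(edges == -1)
        keep = (run_e - run_s) >= min_run
        length = grid.layout.length_of(chrom)
        for s, e in zip(run_s[keep], run_e[keep]):
            chroms.append(chrom)
            starts.append(s * grid.bin_size)
            ends.append(min(e * grid.bin_size, length))
    return IntervalSet.from_arrays(chroms, starts, ends, role="peak")


def write_bedgraph(track: SignalTrack, path) -> None:
    df = track.grid.bins_frame()
    df["value"] = track.values
    df.to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph(path, grid: BinGrid, kind: str = "si") -> SignalTrack:
    """Read a bedGraph written on exactly this grid (bin-aligned)."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "value"])
    values = np.zeros(grid.n_bins)
    for chrom, grp in df.groupby("chrom", sort=False):
        values[grid.bin_index(str(chrom), grp["start"].to_numpy())] = grp["value"].to_numpy()
    return SignalTrack(grid, values, kind=kind)
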