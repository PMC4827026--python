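"""Readers/writers for the genomic formats the pipeline touches.

All internal coordinates are 0-based half-open (BED convention). GTF input
(1-based, closed) is converted on read. Aligned reads are reduced to their
5'-end base: ``start`` for + strand records, ``end - 1`` for - strand records,
applied identically to ChIP and input libraries so that downstream
input-subtraction is unaffected by read length.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GenomeLayout",
    "IntervalSet",
    "ReadSet",
    "read_gene_annotation",
    "read_intervals",
    "write_intervals",
    "read_alignments",
]


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names and lengths (bp)."""

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.chrom_names) != len(set(self.chrom_names)):
            raise ValueError("chromosome names must be unique")
        if any(l <= 0 for l in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ValueError("names and lengths differ in count")

    def length_of(self, chrom: str) -> int:
        return self.chrom_lengths[self.chrom_names.index(chrom)]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_names

    @classmethod
    def from_dict(cls, lengths: dict[str, int]) -> "GenomeLayout":
        return cls(tuple(lengths), tuple(lengths.values()))

    def to_dict(self) -> dict[str, int]:
        return dict(zip(self.chrom_names, self.chrom_lengths))


# gene table column order used throughout the package
GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand", "tss", "tes"]


def _gene_frame(records: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(records, columns=GENE_COLUMNS)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    df["tss"] = df["tss"].astype(np.int64)
    df["tes"] = df["tes"].astype(np.int64)
    return df


def make_gene_table(
    gene_id, chrom, start, end, strand, *, validate: bool = True
) -> pd.DataFrame:
    """Build a gene table from column arrays, deriving TSS/TES from strand.

    TSS is ``start`` on the + strand and ``end - 1`` on the - strand; TES is
    the opposite end. One row per gene_id.
    """
    df = pd.DataFrame(
        {
            "gene_id": gene_id,
            "chrom": chrom,
            "start": np.asarray(start, dtype=np.int64),
            "end": np.asarray(end, dtype=np.int64),
            "strand": strand,
        }
    )
    if validate:
        if (df["start"] >= df["end"]).any():
            raise ValueError("gene start must be < end")
        if df["gene_id"].duplicated().any():
            raise ValueError("duplicate gene_id")
        if not df["strand"].isin(["+", "-"]).all():
            raise ValueError("strand must be + or -")
    plus = df["strand"].to_numpy() == "+"
    df["tss"] = np.where(plus, df["start"], df["end"] - 1)
    df["tes"] = np.where(plus, df["end"] - 1, df["start"])
    return df[GENE_COLUMNS]


@dataclass
class IntervalSet:
    """Half-open genomic intervals with a role tag (peak, motif_site, ...)."""

    df: pd.DataFrame  # columns: chrom, start, end [, name, score, strand]
    role: str = "interval"

    def __post_init__(self) -> None:
        for col in ("chrom", "start", "end"):
            if col not in self.df.columns:
                raise ValueError(f"IntervalSet missing column {col!r}")
        if len(self.df) and (self.df["start"] >= self.df["end"]).any():
            raise ValueError("interval start must be < end")

    def __len__(self) -> int:
        return len(self.df)

    def sorted(self) -> "IntervalSet":
        out = self.df.sort_values(["chrom", "start", "end"], kind="stable")
        return IntervalSet(out.reset_index(drop=True), self.role)

    def by_chrom(self) -> dict[str, pd.DataFrame]:
        return {c: g for c, g in self.df.groupby("chrom", sort=False)}

    @classmethod
    def from_arrays(cls, chrom, start, end, role="interval", **extra) -> "IntervalSet":
        df = pd.DataFrame(
            {
                "chrom": chrom,
                "start": np.asarray(start, dtype=np.int64),
                "end": np.asarray(end, dtype=np.int64),
                **extra,
            }
        )
        return cls(df, role)


@dataclass
class ReadSet:
    """5'-end positions of uniquely mapped reads, grouped per chromosome.

    Positions are stored sorted per chromosome so that region counting is a
    pair of binary searches.
    """

    positions: dict[str, np.ndarray]  # chrom -> sorted int64 5'-end positions
    total_mapped: int = field(default=0)

    def __post_init__(self) -> None:
        n = sum(len(p) for p in self.positions.values())
        if self.total_mapped == 0:
            self.total_mapped = n
        elif self.total_mapped != n:
            raise ValueError("total_mapped inconsistent with stored records")

    def count_in(self, chrom: str, start: int, end: int) -> int:
        """Number of read 5' ends in [start, end) on chrom."""
        pos = self.positions.get(chrom)
        if pos is None:
            return 0
        return int(np.searchsorted(pos, end, "left") - np.searchsorted(pos, start, "left"))

    @classmethod
    def from_records(cls, chrom, pos) -> "ReadSet":
        chrom = np.asarray(chrom)
        pos = np.asarray(pos, dtype=np.int64)
        out: dict[str, np.ndarray] = {}
        for c in pd.unique(chrom):
            out[str(c)] = np.sort(pos[chrom == c])
        return cls(out)

    def concat(self, other: "ReadSet") -> "ReadSet":
        """Pool two libraries (replicate handling is pooling before counting)."""
        merged = {}
        for c in set(self.positions) | set(other.positions):
            parts = [d.positions[c] for d in (self, other) if c in d.positions]
            merged[c] = np.sort(np.concatenate(parts))
        return ReadSet(merged)


_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def _five_prime(start: np.ndarray, end: np.ndarray, strand: np.ndarray) -> np.ndarray:
    return np.where(strand == "-", end - 1, start)


def read_gene_annotation(path, layout: GenomeLayout | None = None) -> pd.DataFrame:
    """Read a GTF or BED12 gene annotation into the gene table.

    GTF ``transcript`` features (fallback: ``gene``, or exon spans grouped by
    transcript) are reduced to one model per gene_id, keeping the longest
    transcript. GTF 1-based closed coordinates become 0-based half-open.
    Records on chromosomes absent from ``layout`` are skipped with a warning;
    malformed lines raise with their line number.
    """
    path = str(path)
    if path.endswith((".bed", ".bed12")):
        return _read_bed12_genes(path, layout)
    return _read_gtf_genes(path, layout)


def _read_gtf_genes(path: str, layout: GenomeLayout | None) -> pd.DataFrame:
    # transcript_id -> (gene_id, chrom, start, end, strand)
    transcripts: dict[str, list] = {}
    gene_only: dict[str, list] = {}
    n_skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GTF columns, got {len(fields)}")
            chrom, _, feature, start_s, end_s, _, strand, _, attrs = fields[:9]
            if feature not in ("transcript", "mRNA", "gene", "exon"):
                continue
            try:
                start = int(start_s) - 1  # to 0-based half-open
                end = int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start < 0 or start >= end:
                raise ValueError(f"{path}:{lineno}: invalid coordinates {start_s}-{end_s}")
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: strand must be + or -")
            if layout is not None and chrom not in layout:
                n_skipped += 1
                continue
            attr = dict(_GTF_ATTR.findall(attrs))
            gene_id = attr.get("gene_id")
            if gene_id is None:
                raise ValueError(f"{path}:{lineno}: missing gene_id attribute")
            tid = attr.get("transcript_id")
            if feature == "gene" or tid is None:
                rec = gene_only.setdefault(gene_id, [gene_id, chrom, start, end, strand])
                rec[2] = min(rec[2], start)
                rec[3] = max(rec[3], end)
                continue
            rec = transcripts.setdefault(tid, [gene_id, chrom, start, end, strand])
            rec[2] = min(rec[2], start)
            rec[3] = max(rec[3], end)
    if n_skipped:
        logger.warning("%s: skipped %d records on chromosomes outside the layout", path, n_skipped)
    # longest transcript defines the gene; fall back to gene features
    best: dict[str, list] = {}
    for rec in transcripts.values():
        gid = rec[0]
        cur = best.get(gid)
        if cur is None or (rec[3] - rec[2]) > (cur[3] - cur[2]):
            best[gid] = rec
    for gid, rec in gene_only.items():
        best.setdefault(gid, rec)
    if not best:
        return _gene_frame([])
    rows = sorted(best.values(), key=lambda r: (r[1], r[2], r[0]))
    gid, chrom, start, end, strand = map(list, zip(*rows))
    return make_gene_table(gid, chrom, start, end, strand)


def _read_bed12_genes(path: str, layout: GenomeLayout | None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 6:
        raise ValueError(f"{path}: BED gene annotation needs >= 6 columns")
    df = df.iloc[:, [0, 1, 2, 3, 5]]
    df.columns = ["chrom", "start", "end", "gene_id", "strand"]
    if layout is not None:
        bad = ~df["chrom"].isin(layout.chrom_names)
        if bad.any():
            logger.warning("%s: skipped %d records on chromosomes outside the layout", path, int(bad.sum()))
            df = df[~bad]
    # keep the longest record per gene_id
    df = df.assign(_len=df["end"] - df["start"])
    df = df.sort_values("_len", kind="stable").drop_duplicates("gene_id", keep="last")
    df = df.sort_values(["chrom", "start"], kind="stable")
    return make_gene_table(
        df["gene_id"].tolist(), df["chrom"].tolist(), df["start"], df["end"], df["strand"].tolist()
    )


_NARROWPEAK_COLS = ["chrom", "start", "end", "name", "score", "strand",
                    "signalValue", "pValue", "qValue", "peak"]


def read_intervals(path, role: str = "interval") -> IntervalSet:
    """Read a BED3+/narrowPeak file into an IntervalSet (verbatim, half-open)."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return IntervalSet(pd.DataFrame(columns=["chrom", "start", "end"]), role)
    if df.shape[1] < 3:
        raise ValueError(f"{path}: BED requires >= 3 columns")
    ncol = min(df.shape[1], len(_NARROWPEAK_COLS))
    df = df.iloc[:, :ncol]
    df.columns = _NARROWPEAK_COLS[:ncol]
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    if (df["start"] >= df["end"]).any():
        bad = df.index[df["start"] >= df["end"]][0]
        raise ValueError(f"{path}: start >= end at record {bad}")
    return IntervalSet(df, role)


def write_intervals(ivs: IntervalSet, path) -> None:
    """Write an IntervalSet as BED (TSV, no header; round-trips read_intervals)."""
    ivs.df.to_csv(path, sep="\t", header=False, index=False)


def read_alignments(path, layout: GenomeLayout | None = None) -> ReadSet:
    """Read aligned reads (BED or SAM) reduced to 5'-end positions.

    Unmapped SAM records are skipped and counted in the log; total_mapped is
    the number of retained records.
    """
    path = str(path)
    if path.endswith(".sam") or path.endswith(".bam"):
        return _read_sam(path)
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2, 5] if _bed_has_strand(path) else [0, 1, 2])
    if df.shape[1] == 4:
        df.columns = ["chrom", "start", "end", "strand"]
        strand = df["strand"].to_numpy(dtype=str)
    else:
        df.columns = ["chrom", "start", "end"]
        strand = np.full(len(df), "+")
    pos = _five_prime(df["start"].to_numpy(np.int64), df["end"].to_numpy(np.int64), strand)
    if layout is not None:
        keep = df["chrom"].isin(layout.chrom_names).to_numpy()
        if not keep.all():
            logger.warning("%s: skipped %d reads on chromosomes outside the layout",
                           path, int((~keep).sum()))
        df, pos = df[keep], pos[keep]
    return ReadSet.from_records(df["chrom"].to_numpy(), pos)


def _bed_has_strand(path: str) -> bool:
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                return len(line.rstrip("\n").split("\t")) >= 6
    return False


def _read_sam(path: str) -> ReadSet:
    import pysam

    chroms: list[str] = []
    pos: list[int] = []
    n_unmapped = 0
    mode = "rb" if path.endswith(".bam") else "r"
    with pysam.AlignmentFile(path, mode) as fh:
        for rec in fh.fetch(until_eof=True):
            if rec.is_unmapped:
                n_unmapped += 1
                continue
            chroms.append(rec.reference_name)
            if rec.is_reverse:
                pos.append(rec.reference_end - 1)
            else:
                pos.append(rec.reference_start)
    if n_unmapped:
        logger.info("%s: skipped %d unmapped records", path, n_unmapped)
    if not chroms:
        return ReadSet({})
    return ReadSet.from_records(np.asarray(chroms), np.asarray(pos, dtype=np.int64))
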