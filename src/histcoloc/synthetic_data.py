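"""Seeded synthetic ChIP-seq inputs with planted, recoverable structure.

The generator emulates the statistical structure the downstream analysis
assumes: a small genome of stranded, non-overlapping genes; a zero-inflated
log-normal expression distribution; ChIP read coverage that is uniform
Poisson background plus planted enrichment — TSS-proximal windows in the
low-but-nonzero expression deciles and mild gene-body enrichment in the top
decile — with a matched uniform input library; and motif-site catalogs
placed inside or independent of the planted windows. Ground truth (per-gene
group, planted windows, site/peak overlap flags) is kept alongside the
emitted files so every pipeline stage can be checked against it.

Reads are piecewise-uniform draws: a read falls in the background with
probability G/(G+E) where G is the genome size and E the total excess weight
sum((fold-1) * width) over planted windows; excess reads pick a window
proportionally to its excess weight. This realises an exact fold-change
``fold`` in expectation inside each window relative to background.

All draws descend from a single seed; the same seed yields byte-identical
output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .genomic_io import GenomeLayout, IntervalSet, ReadSet, make_gene_table

__all__ = ["SimulationConfig", "SimResult", "simulate", "generate",
           "generate_site_catalog"]

# expression groups whose genes get planted TSS enrichment / body enrichment
_DEFAULT_TSS_FOLDS = {"q0-10": 5.0, "q10-20": 5.0, "q20-30": 5.0}
_DEFAULT_BODY_FOLDS = {"q90-100": 2.0}


@dataclass
class SimulationConfig:
    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 5_000_000
    n_genes: int = 1000
    gene_length_range: tuple[int, int] = (2000, 10_000)
    # zero-inflated log-normal expression
    zero_fraction: float = 0.3
    fpkm_meanlog: float = 1.0
    fpkm_sdlog: float = 1.5
    # ChIP model
    tss_enrichment_fold: dict = field(default_factory=lambda: dict(_DEFAULT_TSS_FOLDS))
    body_enrichment_fold: dict = field(default_factory=lambda: dict(_DEFAULT_BODY_FOLDS))
    enrichment_width: int = 2000  # TSS +/- width/2
    n_reads_chip: int = 1_000_000
    n_reads_input: int = 1_000_000
    read_length: int = 36
    # motif model
    n_sites: int = 500
    site_width: int = 12
    fraction_in_enriched: float = 0.6
    tf_peak_width: int = 300
    tf_site_overlap_fraction: float = 0.5

    def __post_init__(self) -> None:
        for name in ("n_chroms", "chrom_length", "n_genes", "n_reads_chip",
                     "n_reads_input", "enrichment_width", "n_sites"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.zero_fraction < 1:
            raise ValueError("zero_fraction must be in [0, 1)")
        for folds in (self.tss_enrichment_fold, self.body_enrichment_fold):
            if any(f < 1 for f in folds.values()):
                raise ValueError("enrichment folds must be >= 1")
        if not 0 <= self.fraction_in_enriched <= 1:
            raise ValueError("fraction_in_enriched must be in [0, 1]")
        if not 0 <= self.tf_site_overlap_fraction <= 1:
            raise ValueError("tf_site_overlap_fraction must be in [0, 1]")


@dataclass
class SimResult:
    config: SimulationConfig
    layout: GenomeLayout
    genes: pd.DataFrame
    fpkm: pd.Series
    groups: pd.Series  # ground-truth expression group per gene
    enrichment_windows: pd.DataFrame  # chrom, start, end, kind, fold, gene_id
    chip_reads: ReadSet
    input_reads: ReadSet
    chip_records: pd.DataFrame  # chrom, pos5, strand (emission order)
    input_records: pd.DataFrame

    def truth(self) -> dict:
        return {
            "groups": {g: str(l) for g, l in self.groups.items()},
            "enrichment_windows": self.enrichment_windows.to_dict("records"),
        }


def _rank_decile_labels(fpkm: pd.Series) -> pd.Series:
    """Ground-truth grouping: 'zero' plus rank deciles of nonzero FPKM."""
    labels = pd.Series("zero", index=fpkm.index, dtype=object)
    nz = fpkm[fpkm > 0]
    order = sorted(nz.index, key=lambda g: (nz[g], g))
    n = len(order)
    for i, gid in enumerate(order):
        d = (10 * i) // n
        labels[gid] = f"q{10 * d}-{10 * (d + 1)}"
    return labels


def _place_genes(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Non-overlapping stranded genes; random gaps fill the leftover space."""
    per_chrom = np.full(cfg.n_chroms, cfg.n_genes // cfg.n_chroms)
    per_chrom[: cfg.n_genes % cfg.n_chroms] += 1
    gid, chroms, starts, ends, strands = [], [], [], [], []
    k = 0
    for ci in range(cfg.n_chroms):
        n = per_chrom[ci]
        lo, hi = cfg.gene_length_range
        lengths = rng.integers(lo, hi + 1, size=n)
        slack = cfg.chrom_length - int(lengths.sum())
        if slack < 0:
            raise ValueError(
                "genes cannot be placed without overlap; increase chrom_length "
                "or reduce n_genes/gene lengths"
            )
        gaps = rng.multinomial(slack, np.full(n + 1, 1.0 / (n + 1)))
        pos = 0
        for j in range(n):
            pos += int(gaps[j])
            gid.append(f"g{k:05d}")
            chroms.append(f"chr{ci + 1}")
            starts.append(pos)
            pos += int(lengths[j])
            ends.append(pos)
            strands.append("+" if rng.random() < 0.5 else "-")
            k += 1
    return make_gene_table(gid, chroms, starts, ends, strands)


def _enrichment_windows(cfg: SimulationConfig, genes: pd.DataFrame,
                        groups: pd.Series, layout: GenomeLayout) -> pd.DataFrame:
    half = cfg.enrichment_width // 2
    rows = []
    for _, g in genes.iterrows():
        lab = groups[g["gene_id"]]
        tss_fold = cfg.tss_enrichment_fold.get(lab, 1.0)
        if tss_fold > 1:
            length = layout.length_of(g["chrom"])
            s = max(0, int(g["tss"]) - half)
            e = min(length, int(g["tss"]) + half)
            rows.append((g["chrom"], s, e, "tss", tss_fold, g["gene_id"]))
        body_fold = cfg.body_enrichment_fold.get(lab, 1.0)
        if body_fold > 1:
            rows.append((g["chrom"], int(g["start"]), int(g["end"]), "body",
                         body_fold, g["gene_id"]))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "kind", "fold",
                                       "gene_id"])


def _draw_reads(cfg: SimulationConfig, layout: GenomeLayout,
                windows: pd.DataFrame, n_reads: int,
                rng: np.random.Generator) -> pd.DataFrame:
    """5'-end positions from uniform background + excess window weight."""
    chrom_len = np.asarray(layout.chrom_lengths, dtype=np.int64)
    genome = int(chrom_len.sum())
    if len(windows):
        w_len = (windows["end"] - windows["start"]).to_numpy(np.int64)
        w_excess = (windows["fold"].to_numpy() - 1.0) * w_len
        excess = float(w_excess.sum())
    else:
        excess = 0.0
    n_extra = rng.binomial(n_reads, excess / (genome + excess)) if excess else 0
    n_bg = n_reads - n_extra

    # background: uniform over the concatenated genome
    flat = rng.integers(0, genome, size=n_bg)
    bounds = np.concatenate(([0], np.cumsum(chrom_len)))
    ci = np.searchsorted(bounds, flat, "right") - 1
    pos = flat - bounds[ci]
    chroms = np.asarray(layout.chrom_names, dtype=object)[ci]

    if n_extra:
        wi = rng.choice(len(windows), size=n_extra, p=w_excess / excess)
        ws = windows["start"].to_numpy(np.int64)[wi]
        we = windows["end"].to_numpy(np.int64)[wi]
        wpos = ws + (rng.random(n_extra) * (we - ws)).astype(np.int64)
        pos = np.concatenate([pos, wpos])
        chroms = np.concatenate([chroms, windows["chrom"].to_numpy(object)[wi]])

    strand = np.where(rng.random(len(pos)) < 0.5, "+", "-")
    # keep the emitted read interval inside the chromosome without moving
    # the 5' end: force strand near the edges
    clen = np.array([layout.length_of(c) for c in chroms])
    strand = np.where(pos < cfg.read_length - 1, "+", strand)
    strand = np.where(pos > clen - cfg.read_length, "-", strand)
    return pd.DataFrame({"chrom": chroms, "pos5": pos, "strand": strand})


def simulate(config: SimulationConfig) -> SimResult:
    """Run the generator in memory; `generate` writes the same result to files."""
    ss = np.random.SeedSequence(config.seed)
    rng_genes, rng_expr, rng_chip, rng_input = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    layout = GenomeLayout(
        tuple(f"chr{i + 1}" for i in range(config.n_chroms)),
        tuple([config.chrom_length] * config.n_chroms),
    )
    genes = _place_genes(config, rng_genes)

    zero = rng_expr.random(config.n_genes) < config.zero_fraction
    fpkm = np.where(
        zero, 0.0,
        rng_expr.lognormal(config.fpkm_meanlog, config.fpkm_sdlog, config.n_genes),
    )
    fpkm = pd.Series(fpkm, index=genes["gene_id"].to_numpy(), name="fpkm")
    groups = _rank_decile_labels(fpkm)

    windows = _enrichment_windows(config, genes, groups, layout)
    chip_rec = _draw_reads(config, layout, windows, config.n_reads_chip, rng_chip)
    input_rec = _draw_reads(config, layout, windows.iloc[0:0],
                            config.n_reads_input, rng_input)
    chip = ReadSet.from_records(chip_rec["chrom"].to_numpy(), chip_rec["pos5"].to_numpy())
    inp = ReadSet.from_records(input_rec["chrom"].to_numpy(), input_rec["pos5"].to_numpy())
    return SimResult(config, layout, genes, fpkm, groups, windows, chip, inp,
                     chip_rec, input_rec)


def generate_site_catalog(config: SimulationConfig, sim: SimResult,
                          tf: str = "SYNTF") -> tuple[IntervalSet, IntervalSet]:
    """Motif-site BED intervals plus synthetic TF ChIP peaks.

    A configured fraction of sites lands inside planted enrichment windows
    (chosen proportionally to window length), the remainder uniformly over
    the genome; each site is independently covered by a TF peak with
    probability ``tf_site_overlap_fraction``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(5)[4])
    layout, windows = sim.layout, sim.enrichment_windows
    n_in = int(round(config.fraction_in_enriched * config.n_sites))
    if n_in and len(windows) == 0:
        raise ValueError("fraction_in_enriched > 0 but no enrichment windows planted")
    usable = windows[(windows["end"] - windows["start"]) > config.site_width]
    if n_in and len(usable) == 0:
        raise ValueError("enrichment windows too small to hold motif sites")

    chroms, starts, planted = [], [], []
    if n_in:
        w_len = (usable["end"] - usable["start"]).to_numpy(np.int64)
        wi = rng.choice(len(usable), size=n_in, p=w_len / w_len.sum())
        ws = usable["start"].to_numpy(np.int64)[wi]
        we = usable["end"].to_numpy(np.int64)[wi]
        s = ws + (rng.random(n_in) * (we - ws - config.site_width)).astype(np.int64)
        chroms.extend(usable["chrom"].to_numpy(object)[wi])
        starts.extend(s.tolist())
        planted.extend([True] * n_in)
    n_out = config.n_sites - n_in
    if n_out:
        chrom_len = np.asarray(layout.chrom_lengths, dtype=np.int64)
        flat = rng.integers(0, int(chrom_len.sum()) - config.site_width, size=n_out)
        bounds = np.concatenate(([0], np.cumsum(chrom_len)))
        ci = np.clip(np.searchsorted(bounds, flat, "right") - 1, 0, len(chrom_len) - 1)
        chroms.extend(np.asarray(layout.chrom_names, dtype=object)[ci])
        starts.extend((flat - bounds[ci]).tolist())
        planted.extend([False] * n_out)

    starts = np.asarray(starts, dtype=np.int64)
    sites = IntervalSet.from_arrays(
        chroms, starts, starts + config.site_width, role="motif_site",
        name=tf, score=0, strand="+", planted=planted,
    )

    covered = rng.random(config.n_sites) < config.tf_site_overlap_fraction
    mid = starts + config.site_width // 2
    half = config.tf_peak_width // 2
    ps = np.maximum(0, mid[covered] - half)
    pe = ps + config.tf_peak_width
    tf_peaks = IntervalSet.from_arrays(
        np.asarray(chroms, dtype=object)[covered], ps, pe, role="tf_peak"
    )
    return sites, tf_peaks


def _write_reads_bed(rec: pd.DataFrame, read_length: int, path: Path) -> None:
    minus = rec["strand"].to_numpy() == "-"
    start = np.where(minus, rec["pos5"] - (read_length - 1), rec["pos5"])
    end = start + read_length
    out = pd.DataFrame({
        "chrom": rec["chrom"], "start": start, "end": end,
        "name": [f"read{i}" for i in range(len(rec))],
        "score": 0, "strand": rec["strand"],
    })
    out.to_csv(path, sep="\t", header=False, index=False)


def generate(config: SimulationConfig, outdir) -> SimResult:
    """Emit annotation.gtf, expression.tsv, chip.bed, input.bed, chrom.sizes
    and truth.json under outdir; identical seeds give byte-identical files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = simulate(config)

    with open(outdir / "annotation.gtf", "w") as fh:
        for _, g in sim.genes.iterrows():
            attrs = f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1";'
            fh.write(f"{g.chrom}\thistcoloc_sim\ttranscript\t{g.start + 1}\t{g.end}"
                     f"\t.\t{g.strand}\t.\t{attrs}\n")

    sim.fpkm.rename_axis("gene_id").reset_index().to_csv(
        outdir / "expression.tsv", sep="\t", index=False)
    _write_reads_bed(sim.chip_records, config.read_length, outdir / "chip.bed")
    _write_reads_bed(sim.input_records, config.read_length, outdir / "input.bed")
    pd.DataFrame({"chrom": sim.layout.chrom_names,
                  "length": sim.layout.chrom_lengths}).to_csv(
        outdir / "chrom.sizes", sep="\t", header=False, index=False)
    truth = {"config": asdict(config), **sim.truth()}
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
    return sim
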