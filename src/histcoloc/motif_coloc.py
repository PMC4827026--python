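"""TF binding-site co-localization with enriched regions.

Profiles SI around binding-site midpoints, ranks TF site catalogs by how many
sites fall in peaks relative to a shuffled-peak background, and scores
predicted motif sites against TF ChIP peaks (positive rate).

The shuffle background re-places the peak set uniformly within each
chromosome, preserving per-chromosome peak counts and lengths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._intervals import ChromIntervalIndex
from .genomic_io import GenomeLayout, IntervalSet
from .signal_track import SignalTrack

__all__ = [
    "SiteCatalog",
    "read_site_catalogs",
    "profile_over_sites",
    "motif_enrichment_table",
    "positive_rate",
]


@dataclass
class SiteCatalog:
    """Binding-site intervals for one TF (optionally stranded)."""

    tf: str
    sites: IntervalSet

    def __post_init__(self) -> None:
        if len(self.sites) == 0:
            raise ValueError(f"site catalog for {self.tf!r} is empty")


def read_site_catalogs(path) -> dict[str, SiteCatalog]:
    """Split a tfbsConsSites-style BED (name column = TF) into per-TF catalogs."""
    from .genomic_io import read_intervals

    ivs = read_intervals(path, role="motif_site")
    if "name" not in ivs.df.columns:
        raise ValueError("site BED needs a name column identifying the TF")
    return {
        str(tf): SiteCatalog(str(tf), IntervalSet(grp.reset_index(drop=True), "motif_site"))
        for tf, grp in ivs.df.groupby("name", sort=False)
    }


def profile_over_sites(si: SignalTrack, catalog: SiteCatalog, flank: int = 2000) -> pd.DataFrame:
    """Mean SI by offset from site midpoint over all sites of the catalog.

    Offsets step at the track bin size; sites carrying a '-' strand are
    flipped so positive offsets point along the site orientation.
    """
    step = si.grid.bin_size
    offsets = np.arange(-flank, flank + 1, step, dtype=np.int64)
    df = catalog.sites.df
    acc = np.zeros(len(offsets))
    n = 0
    for chrom, grp in df.groupby("chrom", sort=False):
        mid = ((grp["start"].to_numpy(np.int64) + grp["end"].to_numpy(np.int64)) // 2)[:, None]
        if "strand" in grp.columns:
            sign = np.where(grp["strand"].to_numpy() == "-", -1, 1)[:, None]
        else:
            sign = 1
        pts = mid + sign * offsets[None, :]
        acc += si.value_at(str(chrom), pts).sum(axis=0)
        n += len(grp)
    return pd.DataFrame({"tf": catalog.tf, "axis": offsets, "value": acc / n})


def _count_sites_in_peaks(index: ChromIntervalIndex, sites: IntervalSet) -> int:
    total = 0
    for chrom, grp in sites.df.groupby("chrom", sort=False):
        total += int(index.ranges_overlap(
            str(chrom), grp["start"].to_numpy(np.int64), grp["end"].to_numpy(np.int64)
        ).sum())
    return total


def _shuffled_peaks(peaks: IntervalSet, layout: GenomeLayout,
                    rng: np.random.Generator) -> IntervalSet:
    """Uniform re-placement per chromosome, preserving counts and lengths."""
    chroms, starts, ends = [], [], []
    for chrom, grp in peaks.df.groupby("chrom", sort=False):
        lengths = (grp["end"] - grp["start"]).to_numpy(np.int64)
        span = layout.length_of(str(chrom))
        new_start = rng.integers(0, np.maximum(span - lengths, 1))
        chroms.extend([chrom] * len(grp))
        starts.append(new_start)
        ends.append(new_start + lengths)
    return IntervalSet.from_arrays(
        chroms, np.concatenate(starts), np.concatenate(ends), role="peak"
    )


def motif_enrichment_table(peaks: IntervalSet, catalogs: dict[str, SiteCatalog],
                           layout: GenomeLayout, n_shuffles: int = 10,
                           seed: int = 0, top_k: int | None = 20) -> pd.DataFrame:
    """Rank TFs by observed-vs-shuffled counts of sites overlapping peaks.

    fold = (#sites in peaks) / mean(#sites in shuffled peaks); TFs whose
    background count is zero get fold = inf, are flagged, and rank first.
    Seeded: a repeated run gives an identical table.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    rng = np.random.default_rng(seed)
    obs_index = ChromIntervalIndex(peaks)
    rows = []
    bg_counts = {tf: [] for tf in catalogs}
    for _ in range(n_shuffles):
        index = ChromIntervalIndex(_shuffled_peaks(peaks, layout, rng))
        for tf, cat in catalogs.items():
            bg_counts[tf].append(_count_sites_in_peaks(index, cat.sites))
    for tf, cat in catalogs.items():
        obs = _count_sites_in_peaks(obs_index, cat.sites)
        bg = float(np.mean(bg_counts[tf]))
        fold = np.inf if bg == 0 else obs / bg
        rows.append((tf, obs, len(cat.sites), bg, fold, bg == 0))
    out = pd.DataFrame(rows, columns=["tf", "n_sites_in_peaks", "n_sites_total",
                                      "background_mean", "fold", "zero_background"])
    out = out.sort_values(["fold", "n_sites_in_peaks"], ascending=False,
                          kind="stable").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out.head(top_k) if top_k is not None else out


def positive_rate(predicted_sites: SiteCatalog, tf_peaks: IntervalSet) -> float:
    """Fraction of predicted sites overlapping >= 1 TF ChIP peak by >= 1 bp."""
    if len(predicted_sites.sites) == 0 or len(tf_peaks) == 0:
        raise ValueError("positive_rate requires non-empty sites and peaks")
    index = ChromIntervalIndex(tf_peaks)
    hits = _count_sites_in_peaks(index, predicted_sites.sites)
    return hits / len(predicted_sites.sites)
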