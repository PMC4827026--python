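"""Genome-wide and promoter-scoped correlation between two SI tracks."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .expression_grouping import promoter_mean_si
from .signal_track import SignalTrack

__all__ = ["CorrelationResult", "windowed_correlation"]


@dataclass
class CorrelationResult:
    track_a: str
    track_b: str
    n_windows: int
    pearson_r: float
    scatter: pd.DataFrame  # paired values (possibly downsampled) for plotting


def windowed_correlation(a: SignalTrack, b: SignalTrack, scope: str = "genome",
                         genes: pd.DataFrame | None = None, flank: int = 2000,
                         names: tuple[str, str] = ("a", "b"),
                         max_scatter: int = 50_000, seed: int = 0) -> CorrelationResult:
    """Pearson correlation of two SI tracks over windows or promoter means.

    scope='genome' pairs every window of the shared grid; scope='tss_flank'
    pairs per-gene mean SI over TSS +/- flank (a gene table is then required).
    The scatter sample is downsampled (seeded) for plotting only; the
    statistic always uses all paired values. Zero variance in either vector
    raises, as r is undefined there.
    """
    if a.grid != b.grid:
        raise ValueError("tracks must share the grid")
    if scope == "genome":
        x, y = a.values, b.values
    elif scope == "tss_flank":
        if genes is None:
            raise ValueError("tss_flank scope requires a gene table")
        x = promoter_mean_si(a, genes, flank).to_numpy()
        y = promoter_mean_si(b, genes, flank).to_numpy()
    else:
        raise ValueError(f"unknown scope {scope!r}")
    if len(x) < 2:
        raise ValueError("need at least two paired windows")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: zero variance in one track")
    r = float(stats.pearsonr(x, y).statistic)
    if len(x) > max_scatter:
        idx = np.random.default_rng(seed).choice(len(x), max_scatter, replace=False)
        scatter = pd.DataFrame({names[0]: x[idx], names[1]: y[idx]})
    else:
        scatter = pd.DataFrame({names[0]: x, names[1]: y})
    return CorrelationResult(names[0], names[1], len(x), r, scatter)
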