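"""Track similarity by Jaccard index of percentile-thresholded 10-kb windows.

A "matching control" labels every 10-kb window true when its SI reaches the
track's 90th or 95th SI percentile (broad vs spiky marks respectively). A
query track is swept through cutoffs in SI ∈ [-1, 2]; at each cutoff the
positive windows (SI >= cutoff) are scored against the control by
J = |true ∩ positive| / |true ∪ positive| = #TP / (#true + #FP).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .signal_track import SignalTrack

__all__ = [
    "WindowLabels",
    "PERCENTILE_BY_MARK",
    "percentile_for_mark",
    "label_windows",
    "jaccard",
    "jaccard_curve",
]

# spiky marks use the 95th SI percentile, broad/dispersed marks the 90th
PERCENTILE_BY_MARK = {
    "H3K4me3": 95.0,
    "H3K27ac": 95.0,
    "H3K9me3": 90.0,
    "H3K27me3": 90.0,
    "H4K20ac": 90.0,
}


def percentile_for_mark(mark: str, default: float = 90.0) -> float:
    return PERCENTILE_BY_MARK.get(mark, default)


@dataclass
class WindowLabels:
    """Boolean labels on a window grid, with the threshold that produced them."""

    grid: object  # BinGrid
    labels: np.ndarray
    source: str = ""
    threshold_used: float = float("nan")

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=bool)
        if self.labels.shape != (self.grid.n_bins,):
            raise ValueError("label count must equal window count")


def label_windows(si: SignalTrack, percentile: float, source: str = "") -> WindowLabels:
    """True label iff window SI >= the given percentile of all window SIs.

    The percentile uses linear interpolation between order statistics; when
    every window has the same SI the threshold equals that value and every
    label is true (SI >= threshold holds everywhere).
    """
    if si.grid.n_bins == 0:
        raise ValueError("track has no windows")
    thr = float(np.percentile(si.values, percentile))
    return WindowLabels(si.grid, si.values >= thr, source=source, threshold_used=thr)


def jaccard(true_labels: WindowLabels, positive_labels: WindowLabels) -> float:
    """J = |A ∩ B| / |A ∪ B| over window label sets; NaN when both are empty."""
    if true_labels.grid != positive_labels.grid:
        raise ValueError("label sets must share the window grid")
    a, b = true_labels.labels, positive_labels.labels
    union = int(np.sum(a | b))
    if union == 0:
        return float("nan")
    return float(np.sum(a & b) / union)


def jaccard_curve(control: WindowLabels, query_si: SignalTrack,
                  cutoff_lo: float = -1.0, cutoff_hi: float = 2.0,
                  cutoff_step: float = 0.05) -> pd.DataFrame:
    """Jaccard against the control at each cutoff over the query SI.

    Returns a (cutoff, J) table in cutoff order; cutoffs where both label
    sets are empty carry J = NaN (missing point).
    """
    if control.grid != query_si.grid:
        raise ValueError("control labels and query track must share the grid")
    n_steps = int(round((cutoff_hi - cutoff_lo) / cutoff_step))
    cutoffs = cutoff_lo + cutoff_step * np.arange(n_steps + 1)
    js = [
        jaccard(control, WindowLabels(query_si.grid, query_si.values >= c))
        for c in cutoffs
    ]
    return pd.DataFrame({"cutoff": cutoffs, "J": js})


def jaccard_curve_table(controls: dict[str, WindowLabels],
                        queries: dict[str, SignalTrack],
                        **kwargs) -> pd.DataFrame:
    """All control x query curves stacked as (control, query, cutoff, J)."""
    rows = []
    for cname, control in controls.items():
        for qname, q in queries.items():
            cur = jaccard_curve(control, q, **kwargs)
            cur.insert(0, "query", qname)
            cur.insert(0, "control", cname)
            rows.append(cur)
    return pd.concat(rows, ignore_index=True)
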