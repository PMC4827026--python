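"""Vectorised overlap primitives over merged, sorted half-open intervals."""

from __future__ import annotations

import numpy as np

from .genomic_io import IntervalSet


def merge_intervals(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Union of half-open intervals as disjoint sorted (starts, ends).

    Abutting intervals ([0,10) and [10,20)) are merged; the union predicate
    is unchanged by that.
    """
    if len(starts) == 0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    order = np.argsort(starts, kind="stable")
    s, e = np.asarray(starts)[order], np.asarray(ends)[order]
    out_s, out_e = [s[0]], [e[0]]
    for a, b in zip(s[1:], e[1:]):
        if a <= out_e[-1]:
            out_e[-1] = max(out_e[-1], b)
        else:
            out_s.append(a)
            out_e.append(b)
    return np.asarray(out_s, np.int64), np.asarray(out_e, np.int64)


class ChromIntervalIndex:
    """Per-chromosome merged-interval index supporting point and range queries."""

    def __init__(self, ivs: IntervalSet):
        self._idx: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, grp in ivs.df.groupby("chrom", sort=False):
            self._idx[str(chrom)] = merge_intervals(
                grp["start"].to_numpy(np.int64), grp["end"].to_numpy(np.int64)
            )

    def points_covered(self, chrom: str, points: np.ndarray) -> np.ndarray:
        """Boolean mask: is each point inside some interval on chrom."""
        entry = self._idx.get(chrom)
        points = np.asarray(points)
        if entry is None:
            return np.zeros(points.shape, dtype=bool)
        starts, ends = entry
        i = np.searchsorted(starts, points, "right") - 1
        ok = i >= 0
        cov = np.zeros(points.shape, dtype=bool)
        cov[ok] = points[ok] < ends[i[ok]]
        return cov

    def ranges_overlap(self, chrom: str, qstart: np.ndarray, qend: np.ndarray) -> np.ndarray:
        """Boolean mask: does each half-open query range share >=1 bp with an interval."""
        entry = self._idx.get(chrom)
        qstart = np.asarray(qstart)
        if entry is None:
            return np.zeros(qstart.shape, dtype=bool)
        starts, ends = entry
        # last interval starting before the query end; merged+sorted => it has
        # the maximal end among candidates
        i = np.searchsorted(starts, np.asarray(qend), "left") - 1
        ok = i >= 0
        hit = np.zeros(qstart.shape, dtype=bool)
        hit[ok] = ends[i[ok]] > qstart[ok]
        return hit
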