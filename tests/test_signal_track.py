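import numpy as np
import pandas as pd
import pytest

from histcoloc import (
    BinGrid,
    GenomeLayout,
    ReadSet,
    SignalTrack,
    count_reads_in_bins,
    fold_change,
    fold_change_table,
    naive_peak_call,
    read_bedgraph,
    region_rpkm,
    rpkm,
    signal_intensity,
    write_bedgraph,
)
from histcoloc.genomic_io import make_gene_table

from conftest import uniform_reads


def track(grid, values, kind="si"):
    return SignalTrack(grid, np.asarray(values, float), kind)


class TestCounting:
    def test_reads_fall_in_containing_bin(self):
        layout = GenomeLayout(("chr1",), (200,))
        rs = ReadSet.from_records(["chr1"] * 3, [0, 50, 150])
        counts = count_reads_in_bins(rs, BinGrid(layout, 100))
        assert counts.tolist() == [2, 1]

    def test_empty_readset_gives_zero_counts(self, tiny_grid):
        counts = count_reads_in_bins(ReadSet({}), tiny_grid)
        assert counts.sum() == 0

    def test_conservation_sum_equals_total_mapped(self, tiny_layout):
        rs = uniform_reads(tiny_layout, 5000, seed=3)
        for L in (100, 1000, 7000):
            counts = count_reads_in_bins(rs, BinGrid(tiny_layout, L))
            assert counts.sum() == rs.total_mapped == 5000

    def test_uniform_reads_match_binomial_oracle(self):
        # 10,000 uniform reads on a 10-kb chromosome, 1-kb bins: each count
        # within 4 sigma of n*p under Binomial(n, p=1/10)
        layout = GenomeLayout(("chr1",), (10_000,))
        rs = uniform_reads(layout, 10_000, seed=7)
        counts = count_reads_in_bins(rs, BinGrid(layout, 1000))
        n, p = 10_000, 0.1
        sigma = np.sqrt(n * p * (1 - p))
        assert np.all(np.abs(counts - n * p) < 4 * sigma)


class TestRpkm:
    @pytest.mark.parametrize("count,L,total,expected", [
        (10, 1000, 10**6, 10.0),
        (0, 1000, 10**6, 0.0),
        (25, 200, 2 * 10**7, 6.25),
    ])
    def test_definition(self, count, L, total, expected):
        assert rpkm(np.array([count]), L, total)[0] == pytest.approx(expected)

    def test_zero_total_is_hard_error(self):
        with pytest.raises(ValueError):
            rpkm(np.array([1]), 1000, 0)


class TestSignalIntensity:
    def test_difference_and_null_case(self, tiny_grid):
        chip = track(tiny_grid, np.full(tiny_grid.n_bins, 5.0), "rpkm")
        inp = track(tiny_grid, np.full(tiny_grid.n_bins, 3.0), "rpkm")
        si = signal_intensity(chip, inp)
        assert np.allclose(si.values, 2.0)
        assert np.allclose(signal_intensity(chip, chip).values, 0.0)

    def test_antisymmetry(self, tiny_grid):
        rng = np.random.default_rng(5)
        a = track(tiny_grid, rng.random(tiny_grid.n_bins), "rpkm")
        b = track(tiny_grid, rng.random(tiny_grid.n_bins), "rpkm")
        assert np.allclose(signal_intensity(a, b).values,
                           -signal_intensity(b, a).values)

    def test_grid_mismatch_is_hard_error(self, tiny_layout):
        a = track(BinGrid(tiny_layout, 1000), np.zeros(18), "rpkm")
        b = track(BinGrid(tiny_layout, 2000), np.zeros(9), "rpkm")
        with pytest.raises(ValueError):
            signal_intensity(a, b)


class TestRegionRpkm:
    def test_hand_arithmetic(self):
        rs = ReadSet.from_records(["chr1"] * 100, np.arange(1000, 3000, 20))
        rs = ReadSet(rs.positions, 0)
        assert region_rpkm(rs, "chr1", 1000, 3000, total_mapped=10**6) == pytest.approx(50.0)

    def test_zero_reads_and_scale_equivariance(self):
        rs = ReadSet.from_records(["chr1"] * 10, np.arange(10))
        assert region_rpkm(rs, "chr1", 5000, 6000, total_mapped=10**6) == 0.0
        v1 = region_rpkm(rs, "chr1", 0, 1000, total_mapped=10**6)
        v2 = region_rpkm(rs, "chr1", 0, 1000, total_mapped=2 * 10**6)
        assert v2 == pytest.approx(v1 / 2)

    def test_zero_length_region_is_hard_error(self):
        rs = ReadSet.from_records(["chr1"], [5])
        with pytest.raises(ValueError):
            region_rpkm(rs, "chr1", 100, 100)


class TestFoldChange:
    def setup_method(self):
        self.layout = GenomeLayout(("chr1",), (100_000,))
        self.gene_plus = make_gene_table(["g"], ["chr1"], [50_000], [60_000], ["+"]).iloc[0]
        self.gene_minus = make_gene_table(["g"], ["chr1"], [50_000], [60_000], ["-"]).iloc[0]

    def reads(self, n, lo, hi, total_pad=0):
        pos = np.linspace(lo, hi - 1, n).astype(int)
        rs = ReadSet.from_records(["chr1"] * n, pos)
        if total_pad:
            pad = ReadSet.from_records(["chr1"] * total_pad,
                                       np.full(total_pad, 90_000))
            rs = rs.concat(pad)
        return rs

    def test_equal_coverage_gives_unity(self):
        chip = self.reads(40, 49_000, 51_000)
        fc = fold_change(chip, chip, self.gene_plus, "tss1kb", self.layout)
        assert fc == pytest.approx(1.0)

    def test_ratio_arithmetic(self):
        # 40 chip vs 10 input reads in TSS+/-1kb, equal totals of 50
        chip = self.reads(40, 49_000, 51_000, total_pad=10)
        inp = self.reads(10, 49_000, 51_000, total_pad=40)
        fc = fold_change(chip, inp, self.gene_plus, "tss1kb", self.layout)
        assert fc == pytest.approx(4.0)

    def test_minus_strand_tss_region_is_right_end(self):
        # reads only near the gene's right end (TSS of a - strand gene)
        chip = self.reads(20, 59_000, 61_000, total_pad=20)
        inp = self.reads(20, 49_000, 51_000, total_pad=20)  # near left end
        fc_minus = fold_change(chip, inp, self.gene_minus, "tss1kb", self.layout)
        fc_plus = fold_change(chip, inp, self.gene_plus, "tss1kb", self.layout)
        assert fc_minus > 1 > fc_plus

    def test_genebody_region_follows_strand(self):
        # body of + gene is [51k, 60k); body of - gene is [50k, 59k)
        chip = self.reads(30, 50_000, 51_000, total_pad=10)  # first kb only
        inp = uniform_reads(self.layout, 40, seed=1)
        fc_plus = fold_change(chip, inp, self.gene_plus, "genebody", self.layout)
        fc_minus = fold_change(chip, inp, self.gene_minus, "genebody", self.layout)
        assert fc_minus > fc_plus

    def test_zero_input_uses_symmetric_pseudocount(self):
        chip = self.reads(10, 49_500, 50_500, total_pad=10)
        inp = self.reads(20, 90_000, 95_000)  # nothing at the TSS
        fc = fold_change(chip, inp, self.gene_plus, "tss1kb", self.layout)
        # counts become (11, 1) with equal region/total scaling
        assert fc == pytest.approx(11.0)

    def test_short_gene_skipped_for_genebody(self):
        short = make_gene_table(["s"], ["chr1"], [100], [900], ["+"])
        table = fold_change_table(self.reads(5, 0, 1000), self.reads(5, 0, 1000),
                                  short, "genebody", self.layout)
        assert len(table) == 0


class TestNaivePeakCall:
    def test_flat_zero_track_has_no_peaks(self, tiny_grid):
        si = track(tiny_grid, np.zeros(tiny_grid.n_bins))
        assert len(naive_peak_call(si, min_si=1.0)) == 0

    def test_single_block_recovered_exactly(self, tiny_grid):
        v = np.zeros(tiny_grid.n_bins)
        v[2:7] = 10.0  # 5 bins on chr1
        peaks = naive_peak_call(track(tiny_grid, v), min_si=5.0, min_run=3)
        assert len(peaks) == 1
        row = peaks.df.iloc[0]
        assert (row.chrom, row.start, row.end) == ("chr1", 2000, 7000)

    def test_subthreshold_gap_splits_peaks(self, tiny_grid):
        v = np.zeros(tiny_grid.n_bins)
        v[1:3] = 10.0
        v[4:6] = 10.0  # bin 3 below threshold
        peaks = naive_peak_call(track(tiny_grid, v), min_si=5.0, min_run=1)
        assert len(peaks) == 2

    def test_output_disjoint_and_sorted(self, tiny_grid):
        rng = np.random.default_rng(0)
        peaks = naive_peak_call(track(tiny_grid, rng.normal(size=tiny_grid.n_bins)),
                                min_si=0.5, min_run=1)
        for _, grp in peaks.df.groupby("chrom"):
            starts, ends = grp["start"].to_numpy(), grp["end"].to_numpy()
            assert np.all(np.diff(starts) > 0)
            assert np.all(starts[1:] >= ends[:-1])


def test_bedgraph_round_trip(tiny_grid, tmp_path):
    rng = np.random.default_rng(2)
    si = track(tiny_grid, rng.normal(size=tiny_grid.n_bins))
    p = tmp_path / "si.bedgraph"
    write_bedgraph(si, p)
    back = read_bedgraph(p, tiny_grid)
    assert np.allclose(back.values, si.values)
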