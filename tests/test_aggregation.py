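import numpy as np
import pandas as pd
import pytest

from histcoloc import (
    BinGrid,
    GenomeLayout,
    IntervalSet,
    SignalTrack,
    metagene_profile,
    peaks_per_gene_profile,
    raw_signal_tss_profile,
    select_enriched_genes,
)
from histcoloc.genomic_io import make_gene_table


def groups_for(genes, label="q0-10"):
    return pd.Series(label, index=genes["gene_id"].to_numpy())


@pytest.fixture
def layout():
    return GenomeLayout(("chr1",), (100_000,))


class TestPeaksPerGene:
    def test_single_gene_peak_at_tss(self, layout):
        genes = make_gene_table(["g"], ["chr1"], [50_000], [60_000], ["+"])
        peaks = IntervalSet.from_arrays(["chr1"], [50_000], [50_100], role="peak")
        prof = peaks_per_gene_profile(peaks, genes, groups_for(genes),
                                      flank=500, step=50)
        covered = prof[(prof.axis >= 0) & (prof.axis < 100)]
        outside = prof[(prof.axis < 0) | (prof.axis >= 100)]
        assert (covered.value == 1.0).all()
        assert (outside.value == 0.0).all()

    def test_minus_strand_upstream_peak_maps_to_negative_axis(self, layout):
        genes = make_gene_table(["g"], ["chr1"], [50_000], [60_000], ["-"])
        tss = 59_999
        # genomically right of the TSS = upstream for a - strand gene
        peaks = IntervalSet.from_arrays(["chr1"], [tss + 100], [tss + 300], role="peak")
        prof = peaks_per_gene_profile(peaks, genes, groups_for(genes),
                                      flank=500, step=50)
        assert prof[prof.axis < 0].value.sum() > 0
        assert prof[prof.axis > 0].value.sum() == 0

    def test_group_average_of_indicators(self, layout):
        genes = make_gene_table(
            [f"g{i}" for i in range(4)], ["chr1"] * 4,
            [10_000, 30_000, 50_000, 70_000],
            [15_000, 35_000, 55_000, 75_000], ["+"] * 4,
        )
        # identical anchored peak for 2 of the 4 genes
        peaks = IntervalSet.from_arrays(
            ["chr1", "chr1"], [10_000, 30_000], [10_100, 30_100], role="peak")
        prof = peaks_per_gene_profile(peaks, genes, groups_for(genes),
                                      flank=200, step=50)
        assert prof[prof.axis == 0].value.iloc[0] == pytest.approx(0.5)

    def test_values_are_indicator_averages_in_unit_interval(self, layout, small_sim):
        sim = small_sim
        peaks = IntervalSet.from_arrays(
            sim.enrichment_windows["chrom"], sim.enrichment_windows["start"],
            sim.enrichment_windows["end"], role="peak")
        prof = peaks_per_gene_profile(peaks, sim.genes, sim.groups, flank=2000)
        assert ((prof.value >= 0) & (prof.value <= 1)).all()


class TestMetagene:
    def test_uniform_coverage_gives_flat_unit_body(self, layout):
        genes = make_gene_table(["a", "b"], ["chr1", "chr1"], [10_000, 50_000],
                                [20_000, 58_000], ["+", "-"])
        peaks = IntervalSet.from_arrays(["chr1"], [0], [100_000], role="peak")
        prof = metagene_profile(peaks, genes, groups_for(genes))
        assert np.allclose(prof[prof.segment == "body"].value, 1.0)

    def test_body_fraction_maps_tss_to_0_and_tes_to_1(self, layout):
        # peak over the first half of the gene only
        genes = make_gene_table(["g"], ["chr1"], [10_000], [20_000], ["+"])
        peaks = IntervalSet.from_arrays(["chr1"], [10_000], [15_000], role="peak")
        prof = metagene_profile(peaks, genes, groups_for(genes), n_body_bins=10)
        body = prof[prof.segment == "body"]
        assert (body[body.position < 0.5].value == 1.0).all()
        assert (body[body.position > 0.5].value == 0.0).all()

    def test_minus_strand_body_runs_tss_to_tes(self, layout):
        # - strand gene: TSS at the right end; peak at the genomic right half
        # covers body fractions < 0.5
        genes = make_gene_table(["g"], ["chr1"], [10_000], [20_000], ["-"])
        peaks = IntervalSet.from_arrays(["chr1"], [15_000], [20_000], role="peak")
        prof = metagene_profile(peaks, genes, groups_for(genes), n_body_bins=10)
        body = prof[prof.segment == "body"]
        assert (body[body.position < 0.5].value == 1.0).all()
        assert (body[body.position > 0.5].value == 0.0).all()

    def test_short_gene_still_contributes_to_every_body_bin(self, layout):
        genes = make_gene_table(["tiny"], ["chr1"], [10_000], [10_050], ["+"])
        peaks = IntervalSet.from_arrays(["chr1"], [10_000], [10_050], role="peak")
        prof = metagene_profile(peaks, genes, groups_for(genes), n_body_bins=100)
        assert np.allclose(prof[prof.segment == "body"].value, 1.0)

    def test_axis_strictly_increasing(self, layout):
        genes = make_gene_table(["g"], ["chr1"], [10_000], [20_000], ["+"])
        peaks = IntervalSet.from_arrays(["chr1"], [0], [1], role="peak")
        prof = metagene_profile(peaks, genes, groups_for(genes))
        assert np.all(np.diff(prof["axis"].to_numpy()) > 0)


class TestRawSignalProfile:
    def test_constant_track_gives_constant_profile(self, layout, toy_genes):
        grid = BinGrid(GenomeLayout(("chr1", "chr2"), (10_000, 8_000)), 200)
        si = SignalTrack(grid, np.full(grid.n_bins, 3.25))
        prof = raw_signal_tss_profile(si, toy_genes, groups_for(toy_genes), flank=1000)
        assert np.allclose(prof.value, 3.25)

    def test_group_mean_of_two_spikes(self):
        layout = GenomeLayout(("chr1",), (100_000,))
        grid = BinGrid(layout, 200)
        genes = make_gene_table(["a", "b"], ["chr1", "chr1"], [10_000, 50_000],
                                [20_000, 60_000], ["+", "+"])
        values = np.zeros(grid.n_bins)
        values[10_000 // 200] = 2.0
        values[50_000 // 200] = 4.0
        prof = raw_signal_tss_profile(SignalTrack(grid, values), genes,
                                      groups_for(genes), flank=1000)
        assert prof[prof.axis == 0].value.iloc[0] == pytest.approx(3.0)


class TestEnrichedGeneSelection:
    def test_peak_within_window_selects_gene(self, layout):
        genes = make_gene_table(["g"], ["chr1"], [50_000], [60_000], ["+"])
        peaks = IntervalSet.from_arrays(["chr1"], [50_500], [50_600], role="peak")
        assert select_enriched_genes(peaks, genes)["gene_id"].tolist() == ["g"]

    def test_halfopen_boundary_peak_not_selected(self, layout):
        genes = make_gene_table(["g"], ["chr1"], [50_000], [60_000], ["+"])
        # peak ends exactly at tss-1000: shares no base with [tss-1000, tss+1000)
        peaks = IntervalSet.from_arrays(["chr1"], [48_800], [49_000], role="peak")
        assert len(select_enriched_genes(peaks, genes)) == 0
        # one base further right does overlap
        peaks2 = IntervalSet.from_arrays(["chr1"], [48_800], [49_001], role="peak")
        assert len(select_enriched_genes(peaks2, genes)) == 1

    def test_chromosome_wide_peak_selects_every_gene(self, toy_genes, tiny_layout):
        peaks = IntervalSet.from_arrays(["chr1", "chr2"], [0, 0],
                                        [10_000, 8_000], role="peak")
        assert len(select_enriched_genes(peaks, toy_genes)) == len(toy_genes)
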