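# Methods

## Coordinate and counting conventions

All internal coordinates are 0-based half-open (BED convention); GTF input
(1-based closed) is converted on read. A gene is one model per `gene_id`:
when an annotation carries several transcripts the longest defines the span.
TSS is the 5′ end of the model (`start` on +, `end − 1` on −) and TES the
opposite end.

Each aligned read contributes only its 5′-end base (`start` for +,
`end − 1` for − records). This makes binning independent of read length and,
because it is applied identically to ChIP and input libraries, leaves the
input-subtracted signal unaffected. Reads are not extended to fragment
length. Replicates are pooled by concatenating read sets before counting.

## Signal model

Counts in *L*-bp bins are normalised as RPKM = count / ((L/1000) ·
(total/10⁶)), which makes tracks of different depth and bin size comparable.
The signal intensity SI = RPKM_ChIP − RPKM_input is a per-bin difference and
may be negative; no smoothing is applied. Bin size is a free parameter:
1000 bp is the general default, 200 bp (≈ one nucleosome plus linker) for
TSS-proximal raw-signal aggregation, 10 000 bp for track-similarity windows.

Region fold-change FC = RPKM_ChIP / RPKM_input is computed over TSS ± 1 kb
or the gene body (1 kb downstream of the TSS to the TES, following the
strand; genes ≤ 1 kb are skipped with a warning). When the input count in
the region is zero, one read is added to both counts — a symmetric
pseudocount that keeps FC finite without biasing either library.

The naive peak caller (maximal runs of ≥ `min_run` bins with
SI ≥ `min_si`) is plumbing so the pipeline runs end-to-end without external
software; it has no background model, FDR or fragment-size estimation and is
not a MACS replacement. Its thresholds are data-scale dependent: on the
default synthetic genome, background SI in 200-bp bins has a standard
deviation near 30 while planted promoter SI is ≈ 400, so `min_si = 100`,
`min_run = 2` separates them by a wide margin.

## Expression groups

FPKM = 0 genes form the "zero" group; FPKM > 0 genes are sorted by
(FPKM, gene_id) — the stable ID tie-break makes grouping deterministic under
ties — and the i-th of n genes goes to decile ⌊10·i/n⌋. Group sizes differ
by at most one, and within-group median FPKM is non-decreasing from q0-10 to
q90-100. The decile cut is by rank, not by equal FPKM intervals: with a
zero-inflated, long-tailed expression distribution, value-interval deciles
would leave most groups nearly empty. The same cut applied to per-gene mean
SI over TSS ± 2 kb (mean, not sum, so the statistic is bin-count invariant;
windows truncated at chromosome edges) gives signal-decile groups.

## Aggregation profiles

Peaks-per-gene profiles evaluate, for each gene, a peak-coverage indicator
at offsets −flank … +flank from the anchor (TSS or TES), flipped for −
strand genes so positive offsets always point downstream; group profiles are
the mean over the group's genes and therefore lie in [0, 1]. The default
plotting step is 50 bp. Coverage is indicator-based (is this base inside any
peak), not summit counting; overlapping peaks are merged before evaluation,
so stacked peak calls do not double-count.

Metagene profiles use a composite axis: absolute offsets over ± 5 kb flanks
and the gene body mapped linearly to [0, 1] between TSS and TES, discretised
into `n_body_bins` (default 100) sampling points at fractions
(j + ½)/n_body_bins. Point sampling means genes shorter than the bin count
still contribute to every body bin. Raw-signal TSS profiles read the SI of
the window containing each offset, stepping at the track's own bin size.

A gene is "enriched" when its TSS ± 1 kb window shares at least one base
with a peak (half-open overlap; a peak ending exactly at `tss − 1000`
does not count). Each gene contributes only to its own group's profile.

## Jaccard consistency

Matching-control labels mark 10-kb windows with SI at or above the track's
percentile threshold — 95th for spiky marks (H3K4me3, H3K27ac), 90th for
broad ones (H3K9me3, H3K27me3, H4K20ac); the assignment is a per-mark
configuration. Percentiles use linear interpolation between order
statistics. Query labels are swept through cutoffs in SI ∈ [−1, 2] at step
0.05 (61 points), and each cutoff is scored by J = |A∩B|/|A∪B|. J is
symmetric, positives at a higher cutoff nest inside those at a lower one,
and a track scored against its own labels reaches J = 1 at its threshold.
When both label sets are empty J is undefined and reported as a missing
point (NaN). All windows enter the percentile computation, including
zero-coverage ones.

## Motif co-localization

Site profiles anchor at the site midpoint (flipped for − strand sites) and
average SI over all sites of a catalog. The enrichment ranking counts sites
overlapping peaks and divides by the mean count over seeded uniform
re-placements of the peak set within each chromosome (counts and lengths
preserved; default 10 shuffles). This background model is a deliberate
simple stand-in for public-catalog enrichment servers: it conditions on the
peak length distribution but not on sequence composition or mappability.
Zero-background TFs are reported with infinite fold and flagged rather than
dropped. The positive rate is the fraction of predicted sites overlapping a
TF ChIP peak by ≥ 1 bp.

## Peptide masses

MH⁺ = Σ residue monoisotopic masses + water (18.010565) + modification
deltas + one proton (1.007276), reported to 4 decimals. Residue masses are
the IUPAC monoisotopic values to 6 decimals — 5-decimal tables can
accumulate enough rounding error to shift the fourth printed decimal of a
peptide MH⁺. Modification deltas: acetyl +42.010565, methyl +14.015650,
dimethyl +28.031300, trimethyl +42.046950 Da.

Assignment picks the candidate with the smallest |measured − theoretical|.
The call is **assigned** only when that candidate is within the tolerance
and no other candidate could also explain the measurement: a runner-up
within the tolerance, or within the resolution margin (default 5 mDa) of
the best error, yields **ambiguous**; no candidate within tolerance yields
**no_match**. Consequently K20ac vs K20me3 (Δ = 36.4 mDa on H4 17-23) is
resolvable at a 10 mDa tolerance and ambiguous at 50 mDa, and an exactly
midway measurement is always ambiguous.

## Synthetic data

The generator emulates the structure the analysis is designed to detect, at
desk scale. Defaults: 2 chromosomes × 5 Mb, 1000 non-overlapping stranded
genes of 2–10 kb, zero fraction 0.3 with log-normal(meanlog 1, sdlog 1.5)
FPKM for expressed genes, 10⁶ ChIP and 10⁶ input reads. Enrichment is
planted as TSS ± 1 kb windows at fold 5 for genes in q0-10…q20-30 and
whole-gene-body windows at fold 2 for q90-100; the genome sizes keep roughly
60% of each chromosome genic, so planted windows stay mostly disjoint.
Reads are drawn from a piecewise-uniform mixture: background with
probability G/(G+E) (G genome size, E = Σ(fold−1)·width excess weight),
excess reads choosing a window proportionally to its excess — the realised
in-window rate is exactly `fold` times the background rate in expectation.
Input reads are uniform. Because the excess mass inflates the ChIP total,
background SI is slightly negative and region FC in enriched promoters is
5·G/(G+E) ≈ 4.1 rather than 5; tests and the acceptance script measure
against this, not against the nominal fold.

Motif sites (500 × 12 bp) land inside planted windows with probability 0.6
(length-weighted window choice) and uniformly otherwise; each site is
independently covered by a 300-bp synthetic TF peak with probability 0.5, so
the positive rate estimates that probability with binomial error.

A single seed drives everything through spawned per-stage generators;
identical seeds give byte-identical output files. What the generator does
*not* emulate: sequence content and mappability, fragment-length effects,
duplicate reads, copy-number and GC biases, overdispersion beyond Poisson,
and correlated placement of multiple marks. Passing recovery tests therefore
show the pipeline arithmetic is correct under the assumed model, not that
the biological conclusions transfer to any real library.

## Problem sizes and determinism

Module tests run on an 80-gene / 0.4 Mb / 1.2×10⁵-read configuration;
recovery tests and `scripts/acceptance.py` use the full default
configuration above, which completes in a few seconds. All stochastic tests
fix seeds; the acceptance script derives every random stream from its
`--seed` argument.

## Known limitations

- The peak caller is intentionally naive (see above); peak-based analyses on
  real data should import MACS output instead (`read_intervals`).
- Percentile thresholds, the 0.05 cutoff step, the 50-bp profile step and
  100 body bins are conventions, configurable per call.
- `windowed_correlation` is Pearson only, on raw window SI; heavy-tailed
  tracks may warrant rank correlation, which is out of scope.
- The enrichment ranking's shuffle background ignores chromatin
  accessibility and sequence bias; its folds are comparative, not
  significance statements.
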