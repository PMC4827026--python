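# histcoloc

Downstream analysis of histone-modification ChIP-seq, built around the
observation that some marks — H4K20ac is the motivating case — concentrate at
transcription start sites (TSSs) of *minimally expressed* genes rather than
active ones. The package is for computational biologists who have aligned
ChIP/input reads, peak calls and a gene-expression table, and want the
standard battery of stratified co-localization analyses plus the
accurate-mass arithmetic used to validate the modification itself.

## What it computes

**Signal intensity.** Reads are counted in fixed *L*-bp bins and normalised
as RPKM = count / (L/1000 · total/10⁶). The normalised signal intensity is
the per-bin difference

    SI = RPKM_ChIP − RPKM_input

which may be negative. Region fold-change is FC = RPKM_ChIP / RPKM_input over
TSS ± 1 kb or the gene body (1 kb downstream of the TSS to the TES,
strand-aware).

**Expression stratification.** Genes with FPKM = 0 form a "zero" group; the
rest are ranked and cut into ten equal-count deciles q0-10 … q90-100. The
same rank-decile cut can stratify by promoter SI instead of FPKM.

**Aggregation profiles.** "Peaks per gene" averages, over each group's genes,
an indicator of peak coverage at every bp offset from the TSS (strand-flipped
so positive offsets point downstream); metagene profiles rescale the gene
body linearly to [0, 1] between TSS and TES with absolute ± 5 kb flanks; raw
SI can be aggregated the same way in 200-bp windows.

**Jaccard track similarity.** Each track labels 10-kb windows true at its
90th (broad marks) or 95th (spiky marks) SI percentile; a query track swept
through cutoffs in SI ∈ [−1, 2] is scored against a control by
J = |A∩B| / |A∪B| = #TP / (#true + #FP).

**Motif co-localization.** SI profiles around binding-site midpoints, a
fold-vs-shuffled-background enrichment ranking of site catalogs in peaks, and
the positive rate of predicted motif sites against TF ChIP peaks.

**Peptide masses.** Monoisotopic MH⁺ of modified peptides and accurate-mass
assignment of the modification state: acetyl (+42.0106 Da) and trimethyl
(+42.0470 Da) differ by 36 mDa, resolvable at a 10 mDa tolerance but
reported as ambiguous at 50 mDa.

A seeded synthetic-data generator (`histcoloc.synthetic_data`) emits a small
genome, zero-inflated expression, ChIP/input reads with planted TSS and
gene-body enrichment, and motif/TF-peak catalogs with known overlap — so the
whole pipeline is testable against ground truth without any downloads.

## Worked example

```python
from histcoloc import (BinGrid, assign_expression_groups, fold_change_table,
                       monoisotopic_mh, naive_peak_call, peaks_per_gene_profile,
                       si_track)
from histcoloc.synthetic_data import SimulationConfig, simulate

sim = simulate(SimulationConfig(seed=1))          # 2 x 5 Mb, 1000 genes, 1e6+1e6 reads
groups = assign_expression_groups(sim.fpkm)
si = si_track(sim.chip_reads, sim.input_reads, BinGrid(sim.layout, 200))
peaks = naive_peak_call(si, min_si=100.0, min_run=2)

profile = peaks_per_gene_profile(peaks, sim.genes, groups, flank=5000, step=50)
print(profile[profile.axis == 0].to_string(index=False))
```

prints the peaks-per-gene value at the TSS for each expression group:

```
  group  axis  value
   zero     0    0.0
  q0-10     0    1.0
 q10-20     0    1.0
 q20-30     0    1.0
 q30-40     0    0.0
 ...
q90-100     0    0.0
```

Every gene of the three lowest nonzero deciles carries a TSS peak (value 1.0,
the planted enrichment) while silent and highly expressed genes carry none —
the signature of a mark at minimally expressed promoters. The matching
promoter fold-changes:

```python
fc = fold_change_table(sim.chip_reads, sim.input_reads, sim.genes, "tss1kb", sim.layout)
print(fc.set_index("gene_id")["fc"].groupby(groups, observed=True).median().round(2))
```

```
zero       0.82
q0-10      4.14
q10-20     4.16
q20-30     4.14
q40-50     0.81
...
q90-100    1.22
```

median FC ≈ 4.1 in the enriched deciles against ≈ 0.8 background (input-
normalised; the planted fold of 5 is diluted by the genome-wide excess read
mass). And the mass arithmetic behind the modification call:

```python
>>> monoisotopic_mh("RHRKVLR", [(4, "dimethyl")])   # H4 17-23, K20me2
992.6588
```

There is also a small CLI: `histcoloc simulate`, `histcoloc signal`
(reads → SI bedGraph, optional naive peaks) and `histcoloc pepmass`.

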