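# senmeth

Analysis of senescence-associated DNA methylation in cultured primary cells:
targeted bisulfite amplicon methylation calling, a multi-CpG linear
"senescence clock", read-level co-methylation of neighboring CpGs in bulk
versus clonally derived populations, and array-style differential
methylation with gene-region/CpG-island enrichment — all driven, when no
real data are at hand, by a stochastic methylation-drift simulator.

It is written for people who work with replicative senescence of primary
cell preparations (mesenchymal stromal cells, endothelial cells,
fibroblasts) and want to (i) quantify the state of cellular aging of a
culture from CpG methylation, (ii) ask whether that state is homogeneous
across the cells of a preparation, and (iii) characterise where in the
genome senescence-associated methylation drift accumulates.

## The models

**Drift.** At a senescence-associated CpG the methylation level (beta value,
the fraction of methylated alleles) drifts approximately linearly with
passage number t:

    E[beta_c(t)] = clip(p0_c + s_c * t, 0, 1)

with per-CpG baseline `p0_c` and slope `s_c` (negative for hypomethylating
sites). Cells are diploid: each cell carries two independent epialleles per
CpG.

**Clock.** For each signature CpG c an ordinary-least-squares model

    t = alpha_c + gamma_c * beta_c

is fitted on training cultures; a sample's predicted passage (or cumulative
population doublings, cPD) is the unweighted mean of the per-CpG estimates.
Predictions are deliberately not clipped — strongly negative or
out-of-range predictions are the signature of clonal populations, which
inherit a single founder cell's epialleles (per-CpG beta of 0, 0.5 or 1)
rather than the population-average drift.

**Co-methylation.** From reads of one amplicon, the conditional profile

    P_j(S) = P(CpG_j methylated | anchor CpG in state S),  S in {M, U}

is the multiplicity-weighted fraction of anchor-state reads methylated at
each neighbor j. It obeys the exact decomposition
`beta_j = P_j(M) * beta_a + P_j(U) * (1 - beta_a)` for X-free reads.

**Differential methylation.** On beta matrices a CpG is called hyper- or
hypomethylated when the late-minus-early mean difference is at least 0.20
*and* the Benjamini–Hochberg adjusted p-value of a moderated t-test
(empirical-Bayes variance shrinkage, method-of-moments fit of the variance
prior) is below 0.05. Annotation categories are tested for
enrichment/depletion of these CpGs with exact hypergeometric tails.

## Worked example

`examples/02_senescence_clock.py` trains the clock on simulated bulk
cultures and applies it to bulk and subclone samples:

```
per-CpG linear models (passage = intercept + slope * beta):
  GRM7_cpg0          intercept   -0.63  slope   21.13  R2 0.999
  CASR_cpg0          intercept   -0.88  slope   21.82  R2 1.000
  SELP_cpg1          intercept   -1.21  slope   22.35  R2 0.999
  CASP14_cpg2        intercept   20.89  slope  -21.74  R2 0.999
  KRTAP13-3_cpg0     intercept   20.90  slope  -21.75  R2 0.999
  PRAMEF2_cpg1       intercept   -0.60  slope   21.22  R2 1.000

bulk validation: R2 1.000, RMSE 0.07 passages
subclones of the passage-8 culture predict passages 1.0 to 15.4 (SD 4.0)
```

Each line is one signature CpG's linear map from methylation level to
passage; the fitted slopes (~±22 passages per unit beta) invert the
simulated drift of ~0.046 beta per passage. Bulk cultures are predicted
essentially perfectly, while single-cell-derived subclones of one and the
same passage-8 culture scatter from passage 1 to 15: a clone reports its
founder cell's epialleles, not the culture's average drift.

The other examples cover simulation + demultiplexing + calling (`01`),
read-level co-methylation and subclone-vs-bulk convergence (`03`), and
array-style differential methylation with CGI/region enrichment (`04`).

## Command line

A thin CLI wraps the library for shell pipelines:

```bash
senmeth simulate --out sim/ --seed 1
senmeth demux --fastq sim/reads.fastq --sample-sheet sim/samples.tsv --out demux/
senmeth call --fastq demux/bulk_p08.fastq --panel-fasta sim/panel.fasta \
             --panel-bed sim/panel_cpgs.bed --out calls.tsv
senmeth run --out run/ --seed 1          # composite amplicon + array pipelines
```

`senmeth run` is deterministic: the same config and seed reproduce every
output byte-for-byte.

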