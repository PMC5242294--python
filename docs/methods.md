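# Methods

This note documents the models implemented in `senmeth`, the assumptions
behind them, the defaults and why they were chosen, and what the simulator
does and does not emulate.

## The stochastic drift model

Replicative senescence leaves continuous methylation changes at specific
CpGs. We model each CpG's methylation probability at passage `t` as

    p_c(t) = clip(p0_c + s_c * t, 0, 1)

and draw every allele of every cell independently as Bernoulli(p_c(t)).
Cells are diploid: a cell carries two epialleles per CpG, so a single
cell's beta at a CpG is 0, 0.5 or 1. Modeling drift as a passage-indexed
probability (rather than an explicit per-division Markov chain) keeps the
parameter count minimal; an explicit per-allele switch rate exists only
after a clonal bottleneck (`post_switch_rate`, default 0), where it stands
in for continued drift during colony outgrowth.

Drift is linear in passage rather than in cumulative population doublings;
cPD is derived as `cpd_per_passage * passage` (default 2.5 doublings per
passage, a typical harvest-at-80%-confluency regime). Whether drift is more
nearly linear in passage or in cPD at single-CpG resolution is not
decidable from the data the package targets; passage was chosen as the
axis on which such clocks are usually reported and validated.

CpGs within an amplicon are independent by default — the central phenomenon
the package exists to analyse is precisely *non*-co-regulated, stochastic
acquisition. An optional `anchor_correlation` (rho) lets each neighbor
allele copy the anchor (clock) CpG's allele state with probability rho,
which generates the bulk co-methylation decay seen in anchored conditional
profiles; it is off in every default.

### Clonal bottlenecks

`sample_clone` picks one founder uniformly from a population and copies its
two epialleles into every output cell. With `post_switch_rate = 0` the
clone's per-CpG beta is exactly the founder beta (0/0.5/1, the tri-modal
signature of clonality); across many clones the mean per-CpG beta is an
unbiased estimate of the parent population's beta with variance
`p(1-p)/(2 * n_clones)` — the theoretical SE used in the convergence
checks.

### Default signature panel and drift parameters

The packaged six-amplicon panel (GRM7, CASR, SELP, CASP14, KRTAP13-3,
PRAMEF2) is synthetic/illustrative: sequences are generated with CG
dinucleotides only at the tracked CpG offsets (so every remaining cytosine
is a genuine non-CpG conversion-QC site); real assay coordinates and primer
sequences are not distributed and user panels are loaded from FASTA + BED.
The CASR amplicon carries seven CpGs with the clock CpG first, the layout
used by the anchored co-methylation analyses.

Signature CpGs drift with |slope| 0.045–0.048 beta per passage from
baselines near the ends of the scale, i.e. they traverse most of [0, 1]
over passages 2–20 without clipping. This is the defining property of CpGs
selected for senescence clocks — sites whose dynamic range spans the
culture lifetime — and it is also what makes the inverse regression
well-conditioned: with pyrosequencing-scale measurement noise (SD 0.03 per
beta), regressing passage on beta attenuates the slope by
`var(x)/(var(x)+sigma^2)`; at full-range drift this attenuation is ~3% and
the true coefficients sit inside their fitted 95% CIs at close to nominal
rates. Neighbor CpGs drift in the same direction but more mildly
(|slope| 0.008–0.022 from intermediate baselines), so neighboring-CpG
profiles are informative but not redundant with the clock CpG.

## Read generation and calling

Reads are top-strand bisulfite reads anchored at the amplicon's 5' end
(primer-defined, ungapped). Conversion chemistry is simulated per base:
unmethylated CpG cytosines and all non-CpG cytosines read T except with
`conversion_failure_rate` (default 0.005); methylated CpG cytosines read C
except with `inappropriate_conversion_rate` (default 0.002); uniform
substitution error is applied last at `seq_error_rate` (default 0.001).
Defaults are typical of EZ-methylation-kit conversion with MiSeq amplicon
sequencing. Two coverage modes exist: `multinomial` (each read samples a
random cell and allele — the realistic mode) and `stratified` (each
cell×allele pair covered an equal integer number of times), the latter
making read-derived betas equal population allele fractions exactly, which
is what end-to-end exactness tests need.

Sample multiplexing uses 12-bp barcodes, carried either as a `BC:` token in
the FASTQ header (default) or as an inline 12-bp prefix that demultiplexing
trims. Barcodes are assigned by unique nearest Hamming distance within
`max_barcode_mismatch` (default 1); a sheet whose barcodes are within twice
that distance of each other is rejected outright as ambiguous.

Amplicon assignment compares the read, ungapped at offset 0, against each
reference with every reference C treated as a C/T wildcard; the read goes
to the amplicon with the fewest mismatches if the mismatch fraction is at
most `max_mismatch_frac` (default 0.10), ties unassigned, reverse
complement attempted as a flagged fallback. Indels are deliberately not
handled — amplicon reads are primer-anchored and indel reads drop out via
the mismatch threshold.

Calling scores each CpG offset as M (read C), U (read T) or X (anything
else, including positions beyond the read end). X at a CpG is sequencing
error, not conversion evidence, so it is excluded from both numerator and
denominator of beta. Identical read sequences are collapsed and sequences
seen fewer than `min_multiplicity` times (default 10) are discarded — a
PCR-family denoising filter applied per identical sequence, not per total
coverage; retained sequences keep full multiplicity so betas remain read
frequencies. A `min_multiplicity` of 1 disables the filter.

## The senescence clock

Per signature CpG, ordinary least squares of target (passage or cPD) on
beta; missing betas dropped pairwise; CpGs with fewer than 3 complete pairs
or zero beta variance are excluded with a warning. Prediction is the
unweighted mean of per-CpG estimates over available CpGs (no R² weighting,
no clipping); `n_cpgs_used` is reported so degraded samples are visible.
Accuracy is reported as the squared Pearson correlation of predicted versus
true (scatterplot convention, insensitive to constant offsets) plus RMSE on
the target scale. Deviation profiles (per-CpG estimate minus truth) carry
the bulk-versus-clone contrast: bulk deviations hug zero at every CpG,
clone deviations scatter widely and discordantly across CpGs.

## Co-methylation statistics

Conditional profiles weight reads by multiplicity; reads with X at the
anchor are excluded entirely, reads with X at a non-anchor CpG only from
that CpG's denominator. The anchor defaults to the amplicon's clock CpG.
With no X calls the profiles satisfy the exact law-of-total-probability
decomposition, which doubles as an internal-consistency test on any input.
Between-clone spread uses the sample SD (n-1): clone counts per preparation
are small (5–15).

## Differential methylation

Per CpG, a two-group (early/late, unpaired) moderated t-test: pooled
residual variances are shrunk toward a prior fitted to the observed
variance distribution by method of moments on log variances (matching of
digamma/trigamma moments of the scaled inverse-chi-square model, after
Smyth 2004), with the total degrees of freedom capped at the summed
residual df. `prior_df = 0` disables moderation and reproduces the
ordinary pooled t-test — the limiting-case oracle bounding the
implementation; the full fit is cross-checked against an independent
reference implementation in the test suite. Exact-zero variances are
floored at 1e-12 to keep the log-moment fit finite.

Adjustment is Benjamini–Hochberg step-up with monotonicity enforcement. A
CpG is called hyper-/hypomethylated when |delta| >= 0.20 (inclusive —
"at least 20%") and adjusted p < 0.05; both thresholds are parameters.

Enrichment uses exact hypergeometric tails (scipy's log-space pmf
accumulation) and reports both `P(X >= k)` and `P(X <= k)` — depletion is
the scientifically interesting tail for promoter/CGI categories. The
universe is the set of CpGs actually tested (post-missingness), not a full
array manifest. Multi-mapping gene-region annotations resolve by precedence
TSS200 > TSS1500 > 5'UTR > 1stExon > Body > 3'UTR, Intergenic when empty.

### The array simulator

`generate_beta_matrix` plants a chosen fraction of drifting CpGs shifted by
±`effect_size` between early and late groups, with Gaussian measurement
noise (default SD 0.02, a 450k-scale technical noise) and truncation to
[0, 1]. Annotations mimic array composition (≈31% Island, ≈41% promoter
classes), and drifting CpGs are under-drawn from promoter and island/shore
classes by `depletion_factor` 0.15 — the planted analogue of the observed
concentration of senescence drift away from promoters and CGIs. It emulates
group mean shifts and annotation structure only: no probe-type chemistry,
no spatial correlation along the genome, no batch effects, no
donor pairing. Passing tests on these matrices therefore demonstrates the
statistics and the calling rule, not robustness to array artefacts.

## Pipelines and determinism

The composite runs validate their configuration against a strict schema
(unknown keys rejected, declared input paths checked for existence) before
any computation. All randomness flows through `numpy.random.Generator`
seeded from the config; outputs are plain TSV/JSON and reruns of the same
config are byte-identical (the run log records parameters and versions, no
wall-clock timestamps). On a stage failure, partial outputs are kept and
`MANIFEST.json` records the failed stage.

The array pipeline simulates two series ("A"/"B") with independently seeded
drifting sets so the cross-series overlap table exercises the overlap
operation; with independent planting the expected overlap is the
hypergeometric mean, not the high overlap real replicate cell types show.

## Problem sizes

Default analysis sizes were chosen so every property is measured with
comfortable statistical margin at desk scale: clock calibration uses 200
replicates of 30 samples; population simulations use 2000–3000 cells
(binomial SE on beta <= 0.01); convergence checks use 15 clones (the
figure-scale clone count); differential-methylation error control uses 50
null matrices of 400 CpGs and power uses 1000 CpGs with 100 planted sites
at n = 4 per group.

## Known limitations

* Only the converted top strand is modeled; paired-end merging and read-2
  handling are out of scope (amplicons are shorter than one read).
* No SNP-aware calling, no CpH methylation, no indel realignment, no
  general-purpose bisulfite alignment.
* The packaged panel and the demo clock trained on simulated data are
  synthetic; real assays require user-supplied panels and training tables.
* Telomere attrition, differentiation potential, gene expression and
  IDAT-level array processing are outside the package's scope.
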