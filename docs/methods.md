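# Methods

## Problem and setting

The early *C. elegans* embryo develops through an invariant cell lineage:
every embryo produces the same named blastomeres (P0 → AB/P1 → … through
the founder lineages AB, MS, E, C, D and the germline P cells) with
stereotyped division timing, and cleavage is reductive — the eggshell
volume is constant, so each division roughly halves cell volume.  Because
total mRNA content scales with cell size, relative expression (TPM) per
named cell can be calibrated to absolute molecule counts, and differences
between a parent cell and its daughters become absolute transcript
accumulation rates.  This package implements that calibration and rate
inference, the decay adjustment that converts accumulation into synthesis,
an independent smFISH-based rate estimator, genomic-feature and
promoter-motif enrichment across rate categories, a Mendelian dosage model
for complementation crosses, and a forward simulator that makes every
stage testable by parameter recovery without any external dataset.

## Lineage model

Cells are nodes of a binary tree annotated with stage label, founder
lineage, volume fraction, birth time (minutes after first cleavage) and
cell-cycle duration.  Invariants enforced on load: daughter volume
fractions sum to the parent's (|Δ| < 1e-9), a daughter's birth time equals
the parent's division time, the root (P0) has volume 1, and volume
fractions over any complete stage sum to 1.

The bundled default table covers the lineage through the "16-cell" cohort.
Stage labels follow the sampled-cohort convention: the 16-cell stage is
the cohort born when the eight AB granddaughters divide, i.e. a ~24-cell
embryo.  Published values fix only part of the table, so defaults are:

* AB/P1 volume split 0.55/0.45, symmetric halving afterwards.  Exact
  early-embryo volume fractions are not published alongside the expression
  data; the AB cell is visibly larger than P1 and 0.55/0.45 is the
  conventional figure.  All values are overridable via the lineage TSV.
* Sulston-scale division timings, with two anchors pinned: the MS cell
  cycle is 16 min, and the 15-cell stage begins 4 min after the 14-cell
  stage.  The E2 (Ea/Ep) cycle is long (35 min), which matters for genes
  that reach high levels at low rates.
* The root P0 carries cycle duration 0: the time origin is first cleavage,
  so P0's "division" is the origin itself.  The positivity requirement on
  cycle durations applies to every non-root cell.

Nuclei-count staging uses a bundled table of intervals [start, end) during
which the embryo holds exactly n nuclei, derived from the division times
above.  `nuclei_to_time` returns the interval midpoint (1 nucleus maps to
0 by convention); counts skipped by simultaneous divisions resolve to the
transition time between the flanking tabulated counts.

## Calibration and rate metrics

With TPM_c the pseudobulk (median over non-tossed replicates) expression
of a gene in cell c, v_c the cell's volume fraction and N = 8,000,000 the
whole-embryo mRNA total:

* absolute count: A_c = TPM_c / 10^6 × v_c × N
* absolute change on edge parent → daughter:
  AC = (TPM_d − TPM_p) / 10^6 × v_d × N — the number of new transcripts
  made during the daughter's cycle, assuming the daughter inherits the
  parental *concentration* (hence the parent term is evaluated at the
  daughter's volume)
* fold change: FC = (A_d + 10) / (A_p→d + 10) with the parent count also
  re-scaled to daughter volume, pseudocount 10 molecules
* accumulation rate: AC / T_d transcripts per minute, T_d the daughter's
  cycle duration.

Genes above 12.5 TPM at P0 (strictly; = 100 molecules in the whole-volume
zygote) are maternal and excluded.  Edges whose parent lacks expression
data are skipped, not zero-filled — a dropout parent would otherwise
inflate FC.

The pseudocount is applied on the absolute-count scale.  10 molecules
corresponds to 1.25 TPM at P0, which matches the scale of the AC
thresholds; applying it on the TPM scale instead would make the FC depend
on cell volume in an unintended way.  Both the pseudocount and the
parent-volume convention are configurable.

### Rate categories

Each metric is ranked — AC: high > 200, medium > 50, low > 1; FC: high >
10, medium > 5, low > 1 — and the category of a gene/edge is the lower of
the two ranks, with "none" when AC ≤ 1 or FC ≤ 1.  This single rule
reproduces all the binning conventions (both high → high; one high with
the other medium → medium; FC in (1, 5] caps at low regardless of AC) and
is monotone: raising AC or FC never lowers the category.  Negative AC is
retained (category none) for decay diagnostics rather than clamped.

Gene-level "strict" sets used for architecture and motif comparisons
require a gene to be high (or medium) on at least one edge and never low
on any edge; genes violating that fall to low.  Note a direct consequence
of the FC metric: a gene that keeps transcribing in the next generation
accumulates on top of a large inherited pool, its FC drops below 5, and
the strict filter demotes it — only transiently activated genes survive
as clean high-rate examples.

Rate profiles (genes × cells AC) are clustered with average linkage on
1 − Pearson distance; zero-variance rows receive distance 1 to everything
(logged) so degenerate profiles neither crash nor attract.

## Decay kinetics

The kinetic model within a cell cycle is constant synthesis with
first-order decay, dA/dt = k − λA, whose solution is

    A(t) = A0·e^(−λt) + (k/λ)(1 − e^(−λt)),  λ = ln 2 / t½.

Half-lives are fitted from whole-embryo time courses on the window from
peak abundance to the first zero (later zeros are excluded; the
log-linear initialiser is undefined there), by nonlinear least squares on
the linear scale seeded with a log-linear regression.  Fits with fewer
than `min_points` (default 3 — the minimum that overdetermines the
two-parameter model) window points, or with non-positive fitted λ, return
"insufficient data" rather than a negative half-life.

Synthesis rates invert the solution: k = λ(A_T − A0·e^(−λt)) / (1 −
e^(−λt)), with A0 the inherited count and A_T the count at division.  The
implementation uses the standard ODE solution throughout; a superficially
similar closed form that multiplies (k/λ − A0) by (1 − e^(−λt)) agrees at
A0 = 0 but is not the solution of the model for A0 > 0, and is therefore
not used.  The denominator is computed with expm1, and below λt = 1e-8
the no-decay limit (A_T − A0)/t is returned (the branches differ by less
than λ(A_T + A0)/2 there).  A round-trip property — forward-integrate the
ODE, then invert — recovers k to 1e-8 relative error.

Adjusted synthesis over an edge uses the daughter's cycle as t, the
volume-rescaled parent count as A0 and the daughter count as A_T; genes
without a fit keep their raw rate, flagged unadjusted.  Records without
net accumulation (A_T ≤ A0) are also left unadjusted: the constant-k model
has no meaningful synthesis estimate for a shrinking pool on this scale.

## smFISH rates

smFISH observations are (embryo, gene, cell label, nuclei count, spot
count) rows.  Embryos are staged by nuclei count → interval midpoint, and
the rate is the OLS slope of per-cell spot count versus time over the
user-chosen staging window (the interval between the two divisions
bracketing maximal expression; windows are gene-specific inputs).  The
slope uses all embryos rather than an endpoint difference.  Labels
covering equivalent sisters ("MSx" = both MS daughters) divide total
counts by the number of expressing cells, so rates are per cell.
Concordance with sequencing-derived rates is the Pearson r over rate
pairs plus the fraction within two-fold (fold difference = max/min ≥ 1).

## Promoter motifs and genomic features

Coordinates: GFF3 input is 1-based inclusive, BED 0-based half-open;
internally everything is 0-based half-open, and offsets relative to the
TSS are negative upstream.  Gene "length" is the primary (unspliced)
transcript span of the longest isoform; introns are the gaps between its
sorted exons; intron density is introns per kb of that span.

TSS consolidation takes up to three candidate sources per gene: if two or
more agree within a 10-bp window (configurable), the consolidated TSS is
the median of the largest agreeing group; otherwise the highest-priority
source wins; candidates on different chromosomes drop the gene with a log
entry.  Promoters are the 500 bp upstream of the TSS on the coding strand
(reverse-complemented for minus-strand genes), clipped at chromosome ends
with a flag.

PWM scanning scores log2 odds against a 0-order background at every
offset of both strands.  Significance per match is the exact p-value of
the score under the background model, obtained by dynamic-programming
convolution of per-position score distributions; for motifs up to 10
positions the convolution is exact over float score sums (verified
against full 4^w enumeration to 1e-12), wider motifs merge states at 1e-4
score granularity.  Hits are matches with p ≤ 1e-4 (default; a width-6
motif cannot clear this cutoff — its consensus alone carries null
probability ≈ 0.25^6 ≈ 2.4e-4 — so supplied PWMs should be ≥ 7
informative positions).  N-containing windows are skipped.

Enrichment statistics: per-motif occurrence proportions (fraction of
genes with ≥ 1 hit) compared across disjoint rate categories with an
uncorrected chi-square test of homogeneity, Wilson 95% CIs, and BH
adjustment across motifs; positional profiles are per-category normalised
histograms of TSS-relative offsets with the peak bin reported; chromosome
enrichment is a chi-square goodness-of-fit of each category's
per-chromosome counts against all-gene proportions (BH across categories,
expected counts < 5 flagged); generic 2×2 category associations use
Fisher's exact p with the odds ratio and Woolf CI, Haldane-corrected
(+0.5) when a cell is zero.  1-D positional clusters are single-linkage
chains with a maximum inter-gene gap.

## Dosage model

Alleles carry an activity in [0, 1] relative to one wild-type copy;
genotype expression is the additive mean of the two activities with no
dominance term (the 50% reduction of a null heterozygote and the ~63% of
a 0.74-activity promoter mutant over a null are exactly this arithmetic).
Selfing a heterozygote yields ¼/½/¼ genotype fractions; the expected
arrest fraction is the total probability of genotypes mapped to "arrest"
by the viability rule.

## Synthetic data generator

The simulator propagates each gene down the lineage with the same model
the pipeline inverts: per cycle A_end = A_birth·e^(−λT) + (k/λ)(1 −
e^(−λT)), with k switched on in the onset cell and its descendants and
always off in P-lineage cells (germline transcriptional quiescence);
maternal genes are a P0 pool that dilutes and decays.  Division
partitioning is either deterministic by volume share or binomial per
molecule (daughters then sum exactly to the parent).  The optional
stochastic mode draws survivors binomially at e^(−λT) and arrivals
Poisson with the exact integrated mean — an exact sample of the linear
birth–death process, not a time-stepped approximation.

Renderers:

* scRNA-seq: multinomial reads per cell over genes proportional to true
  counts (default depth 1e6), TPM = reads/depth × 1e6; noiseless mode
  uses exact proportions, in which case calibration inverts the render
  exactly when cell totals are proportional to volume and sum to the
  embryo total.
* smFISH: binomial thinning of true counts at detection efficiency 0.95
  (imaging misses a few percent of molecules), embryos staged by the
  nuclei count of their sampling time; 5 sampling times per onset-cell
  cycle, 3 embryos each.
* time course: whole-embryo abundance rising from onset under the same
  ODE, synthesis shut off at 60 min so the half-life fitter has a clean
  peak-to-zero window; optional lognormal noise.

Default study conditions: embryo total 8,000,000 molecules; a 2,000-gene
maternal background holding 95% of them (lognormal abundances, floored
above the maternal threshold) so TPM denominators behave like real cells;
a 100-gene zygotic cohort — 20 high (k ∈ [15, 25]/min), 30 medium (k ∈
[3.7, 9]/min) and 50 low (k ∈ [0.15, 0.5]/min), λ = 0, spread over the
seven somatic 8-cell blastomeres.  The medium band is set so the designed
category is well defined for every onset cell: cycle lengths span 14–21
min and the band keeps k·T inside (50, 200] at both extremes.  A separate
decay cohort uses t½ = 20 min, for which the closed form predicts an
adjusted-synthesis/raw-rate fold of λT/(1 − e^(−λT)) ≈ 1.3 over a 16-min
cycle.

What the generator does *not* emulate: transcriptional bursting and
active-transcription-site counts, allele-specific expression, UMI
measurement models, batch or amplification noise beyond multinomial
sampling, stage-mixing within a pseudobulk cell, and decay rates that
differ between the rise and fall phases.  Passing recovery tests
therefore demonstrate that the inference inverts its own generative
assumptions at realistic counts and noise — not that those assumptions
hold in any particular real dataset.

## Problem sizes and reproducibility

The test suite and the acceptance script run the 2,100-gene × 31-cell
simulation (about a thousandfold smaller than a genome-scale analysis,
chosen to keep every check well under a minute), depth 1e6, with all RNG
flowing through seeded `numpy.random.default_rng` streams; renders are
bitwise reproducible for a given (specs, seed).  `scripts/acceptance.py
--seed N --out f.json` derives every internal seed from N.

## Known limitations

* Volume fractions and most cycle durations are conventional defaults,
  not measurements; calibrated counts inherit their error linearly.
* The calibration assumes cell totals of v_c × N molecules; with the 95%
  maternal background the remaining unmodelled 5% makes calibrated counts
  overestimate by ~5%, well inside category widths.
* Pseudobulk medians hide cell-to-cell variability; the FC pseudocount
  makes small counts conservative.
* Half-lives come from whole-embryo data: a single λ per gene across all
  cells, and the fall-phase λ is assumed to apply during the rise.
* The PWM scanner's null is 0-order; higher-order background models (as
  used for de novo discovery) are out of scope, as is discovery itself.
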