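# Methods

This note documents the models, parameter choices and known limitations
behind `trmscore`. Everything quantitative stated here is computed by the
test-suite or by `scripts/acceptance.py`; nothing is quoted from external
data.

## The scoring model

Counts are scaled to a fixed per-cell total (default 10,000) and
transformed as `log2(1 + scaled)`. For UMI counts, gene length carries no
information, so counts-per-fixed-total replaces a length-normalized unit;
the total is configurable. Genes are then standardized across all cells.
The default standardization is center-and-scale (true z-scores, with
zero-variance genes mapped to zero rows); a center-only mode is available
because the two conventions coexist in the literature this statistic comes
from, and both satisfy the invariant that the raw score's grand mean over
cells is exactly zero.

The raw signature score of a cell is the mean standardized expression of
the signature's up genes minus that of its down genes. The control score
repeats this on randomly drawn gene sets of identical sizes — uniform
draws from all genes, without replacement, averaged over `n_iter`
iterations (default 100, seeded and recorded in the result object).
Expression-bin-matched controls are a known refinement and are deliberately
not the default: the baseline definition draws uniformly, and the bias a
uniform control leaves (high-expression signatures score against an
average-expression null) is part of the statistic being implemented.
Signature genes absent from the matrix are dropped with a logged count
rather than zero-filled, because zero-filling would bias centered means.

Group summaries report the mean net score with a 95% CI; t-based by
default, bootstrap (2,000 resamples) as an option — on null data at
n ≥ 100 the two agree within 15% half-width. Many-to-one cluster
comparisons use Dunnett's procedure via the multivariate-t distribution
(scipy), seeded so the quasi-Monte-Carlo integration is deterministic;
with a single comparison group the exact pooled t-test is used instead,
which is the same test without adjustment and avoids integration error.
Family-wise error measured over 2,000 null simulations sits at the nominal
5% level.

Paired site comparisons sum raw counts over each (sample, site) unit,
renormalize and log-transform the unit profiles, standardize across units,
score each unit like a cell, and compare the two sites with a paired
t-test over samples present at both sites (at least two pairs required).

## Droplet processing

**Cell calling.** Totals are sorted descending; distinct totals are
collapsed to their average rank; log10(total) versus log10(rank) is
smoothed with an 11-point running median; the threshold is placed at the
geometric midpoint of the steepest descending segment, excluding three
points at each end of the curve. If the steepest slope is shallower than 2
decades per decade the curve is declared inflection-free and an error is
raised rather than an arbitrary cut made. The midpoint placement matters:
the bottom of the cliff lies inside the ambient mode's upper tail.

**Demultiplexing.** A per-tag positivity threshold is the 0.99 quantile of
the tag's counts over droplets where it is not the maximal tag (its
ambient background). Droplets with two or more positive tags are doublets.
Otherwise a droplet is assigned to its top tag iff that tag has ≥ 10
counts and more than double the second tag; ties and failures are
unassigned. A tag with zero counts overall (or no background droplets)
raises an error naming the tag, since its background cannot be estimated.

**QC filters.** A droplet is removed if RNA counts < 500, mitochondrial
fraction > 10%, combined antibody-tag counts < 500, or two isotype
controls are positive (isotype positivity uses the same background-quantile
construction). The thresholds are exclusive on the removal side: exactly
500 counts and exactly 10% mitochondrial are retained. The attrition
report attributes each removal to its first failing rule in that order,
making the counts additive; the retained set itself is order-independent,
and on every synthetic dataset tested it equals an independent per-droplet
re-check of the four rules.

**Non-T exclusion.** Per-cell rank-based module scores (within-cell
expression ranks of the signature genes, rescaled so a signature of all
genes scores 0.5): a cell is removed iff any non-T lineage score exceeds
the cutoff (default 0.6) while the T-cell score is below it. On planted
lineage programs at LFC 3 this separates myeloid from T cells with ≥ 95%
accuracy in both directions.

## Differential expression

Two-sided Wilcoxon rank-sum per gene with tie-corrected normal
approximation and no continuity correction, implemented vectorized and
cross-checked in the tests against scipy's exact and asymptotic
Mann-Whitney routines; Benjamini-Hochberg adjustment across all tested
genes; log2 fold changes from scaled group means with pseudocount 1. At
extreme separations and small n the normal approximation is anti-
conservative relative to the exact test on the raw p scale (about an order
of magnitude at 10-vs-10 perfect separation) while agreeing on the
-log10 scale; both reject decisively, and the tests check both routes.
Top-k gene sets are ranked by adjusted p with ties broken by |LFC| then
gene name, so repeated calls return identical ordered sets.

## The synthetic-data generator

The generator emulates the statistical structure of a pooled two-flank
experiment: negative-binomial counts (variance `μ + φμ²`, global
dispersion φ = 0.3) around gamma-distributed baseline gene means scaled by
log-normal library sizes (median 5,000 counts, σ_log = 0.35); five
clusters of 500 cells by default, cluster 0 the naive analogue and cluster
3 carrying a 50-up/50-down-gene residency program at log2 fold change
±1; two sites whose cluster mixtures enrich cluster 3 at the
antigen-bearing site; eight hashtags = four mice × two flanks, own-tag
counts NB(800, φ=0.02) over a Poisson(2) ambient background (the panel
simulated here carries no surface-capture antibodies, so hashtags and
isotypes must carry the tag-count total the 500-count filter sees); 5%
doublets (sums of two independent cells with two strong tags), 5% dying
cells (mitochondrial counts rescaled to a 15–40% fraction; expression
otherwise unchanged, since only the QC fraction matters downstream),
2,000 empty droplets at 1.5% of the cell library size, and 0.5% sticky
droplets with both isotype controls elevated. Configurations whose empty
and cell library-size distributions overlap (less than six log-sd of
separation) are rejected at validation, because the barcode-rank
inflection would be undetectable. All randomness derives from one seed
through fixed-key substreams, so enabling one artifact never perturbs the
draws of another, and identical configs reproduce datasets bitwise.

Cell numbers and gene counts are desk-scale choices (2,000 genes by
default; smaller in some tests) made so the full suite runs in minutes;
every size is config-overridable.

The differentiation time-course simulates one population per timepoint
(days 5, 10, …): program genes switch on at gene-specific onsets spread
uniformly across the course (some before it starts) and reach a gene-
specific saturation LFC ~ U(0.5, 2.0) within one timepoint. Activation is
deliberately instantaneous: with gradual ramps, a population frozen
mid-course differs from the final state on half-ramped genes, which
contaminates early-timepoint signatures and moves the apparent divergence
earlier than the planted truncation. Down-program genes mirror up-program
genes (same onsets and magnitudes, opposite sign) so the up- and
down-program library shares cancel to first order and normalization does
not manufacture spurious group differences. The reference gene sets are
the top-k up and down DE genes of each timepoint's population versus a
matched naive population, computed with the package's own DE stage —
the same mathematical object as a published time-course reference, built
without external data.

## Trajectory analysis choices

Scores are relative: genes are standardized across the query cells, so a
group's curve measures enrichment against the query mixture, and the sum
of scores over all cells is zero at every timepoint. Two consequences are
operationalized explicitly:

- **Plateau.** "No continued differentiation" is measured as the
  least-squares slope of group mean versus day over the last ⌈T/2⌉
  timepoints (window configurable). Under relative scoring a frozen
  population's curve peaks at its truncation point and then declines
  mildly (its share of later signatures shrinks); the package therefore
  calls a group plateaued when its late-window slope falls below a quarter
  of the fully differentiating group's slope, which must itself be
  positive. An absolute zero-slope criterion is not attainable under
  all-cell centering and is not used.
- **Divergence.** The divergence timepoint of two groups is the earliest
  timepoint from which their 95% CIs remain disjoint through the end of
  the course. Requiring persistence distinguishes true late divergence
  from single-timepoint fluctuations, which occur because up- and
  down-program genes have asymmetric per-gene variances after
  normalization. Measured over seeded replicates, the reported divergence
  falls within one timepoint of the planted truncation in ≥ 90% of runs.

The self-consistency of the reference is tested: the population a
timepoint's gene set was derived from scores maximally at or after that
timepoint, and a fully differentiating group's curve is monotone
(Spearman ρ > 0.9).

## Pipeline and reproducibility

`run_pipeline` executes simulate → QC → DE → score → trajectory from one
YAML-serializable config whose single seed drives every draw; each run
writes its resolved config, flat-file outputs (MTX/TSV/GMT/JSON) and a
manifest of SHA-256 output hashes plus library versions. Rerunning with
the same config and seed reproduces every output bitwise. Cluster labels
are taken from the simulator's ground truth: graph clustering of real
data is out of scope here, and the analysis treats cluster assignments as
pipeline inputs.

## Known limitations

- The simulator has no batch effects, no ambient-RNA contamination, no
  expression-based doublet structure beyond summed profiles, and no
  surface-protein biology beyond tag and isotype counts; passing tests
  show the statistics behave correctly under the generative model, not
  that the model captures every failure mode of real droplet data.
- The demultiplexing positivity rule is a quantile-background
  construction, a declared substitute for model-based background fits
  used by some toolkits; the headline ≥10-count/>2× assignment rule is
  implemented exactly.
- The uniform randomized control does not match expression bins; for
  signatures concentrated in very high- or low-expression genes the
  control under- or over-corrects accordingly.
- Dunnett p-values for three or more comparisons carry quasi-Monte-Carlo
  integration error around 1e-4; they are seeded for reproducibility.
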