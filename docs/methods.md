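# Methods

## Scope

This package analyses the genomic neighborhood of six *S. cerevisiae* genes
implicated in freeze–thaw tolerance (AQY1, ATH1, CAR1, POG1, PUT1, YCP4) and
provides a synthetic-data generator with planted ground truth for every
analysis it implements. The generator is the package's primary evidence
source: each statistical routine is validated by recovering known parameters
from simulated data at stated tolerances.

## Annotation model

Gene annotations are held as ordered tables (gene id, chromosome, start, end,
strand, essential flag) using 0-based half-open coordinates; GFF3 input
(1-based, inclusive) is converted on load via `gffutils`. Neighborhoods of a
focal gene are the ±k genes by midpoint order on the same chromosome. Signed
distances are midpoint differences; when the chromosome carries a centromere
annotation, direction labels are assigned relative to it: a neighbor is
"telomeric" when it lies farther from the centromere than the focal gene,
"centromeric" otherwise. Without a centromere the labels fall back to
left/right. Essential flags propagate to neighbors so downstream assays can
mark positions that cannot be deleted.

The packaged annotation reproduces the real gene names, order, strands and
essential flags around the six loci, but with synthetic coordinates (~1–2 kb
genes and gaps). It fixes neighborhood topology for tests and demos; any
analysis needing true base-pair distances must load a real annotation.

## Expression simulation

`simulate_expression` draws gene expression as a zero-mean multivariate
normal per chromosome with correlation

```
corr(g_i, g_j) = c0 + a0 · exp(−d_ij / λ0)
```

where `d_ij` is the midpoint distance in bp. Defaults: `a0 = 0.6`,
`λ0 = 10 kb`, `c0 = 0.05`. Genes on different chromosomes are independent.
The kernel matrix is projected to the nearest positive-semidefinite
correlation matrix by eigenvalue clipping before Cholesky factorization.
`noise_sd` scales the overall expression SD rather than adding independent
noise, so the sampled gene–gene correlations equal the kernel exactly in
expectation — the planted parameters are recoverable without attenuation.
Condition blocks add a per-gene mean shift that is constant within a block
(N(0, 0.5)), which changes between-block structure but preserves within-block
correlations.

Gene lengths are gamma-distributed and intergenic gaps exponential, with
configurable means; a centromere is placed in the middle gap of each
chromosome.

## Correlation profiles

Pearson correlation uses pairwise-complete observations with a minimum of
3 pairs; undefined correlations (constant series, too few pairs) propagate as
NaN and are excluded from locus averages rather than treated as zero.
Identical series return exactly 1.0. Locus averages are arithmetic means of
defined neighbor correlations; Fisher-z averaging is available as an option.
Condition heatmaps cluster condition columns by average-linkage hierarchical
clustering on Euclidean distances, computed on an alphabetically sorted
column order so results are independent of input order; NaNs are imputed by
column means for the distance computation only.

## Distance-decay fit

`fit_decay` fits `r(d) = c + a·exp(−|d|/λ)` by least squares with multistart
over λ₀ ∈ {1, 5, 25} kb and bounds λ ∈ [100 bp, 10 Mb]; a power-law
alternative is available. A fit is flagged flat when a constant model has
lower residual error or when the amplitude's t-interval (from the covariance
matrix, df = n − 3) covers zero. At least 4 finite points with 3 distinct
distances are required.

Identifiability note: with the default ±3-gene windows (6 points over
~10–20 kb) and the default λ₀ = 10 kb, amplitude and range are weakly
identified and the flat flag fires routinely; this is intended conservatism.
The decay fit is designed for wide windows — with 59 points over a ~90 kb
simulated locus and 8000 samples, λ is recovered within ±20% and amplitude
within ±0.1 in ≥90% of runs across a grid of planted parameters
(a₀ ∈ {0.4, 0.8}, λ₀ ∈ {2, 5, 25} kb, c₀ ∈ {0, 0.1}; verified in
`tests/test_acceptance.py`).

## Growth assays

A spotting grid is a vector of per-dilution scores in [0, 1]; the growth
index is their sum, so a strain that grows through G dilution steps has
expected index G. The simulator draws each spot as
`clip(G − d + ε, 0, 1)` with ε ~ N(0, 0.05), making expected scores
monotonically non-increasing along the dilution series. Relative growth is
the ratio of mean stress index to mean control index (NaN when the control
index is zero, exact 0 for zero stress growth). Strain-vs-WT comparisons use
Student's pooled t-test by default (Welch optional) at α = 0.05. Locus
heatmaps mark essential flanking positions as "essential" rather than
imputing a value.

## qPCR quantification

Relative expression follows the 2^−ΔΔCt method with ACT1 as reference and a
wild-type calibrator: ΔCt = mean Ct(target) − mean Ct(reference) per strain,
ΔΔCt subtracts the calibrator's ΔCt, fold = E^−ΔΔCt with efficiency E = 2 by
default. Reactions failing the melt-curve check are excluded first; strains
with fewer than 2 usable target replicates are dropped with a warning. The
fold's SEM comes from the delta method on the replicate Ct variance of both
genes. Replicate-level log2 folds pair target and reference Cts
replicate-wise, so reference-gene noise contributes to within-strain
variance; pairing against the strain's mean reference Ct instead would hide
that noise from between-strain t-tests and inflate their type-I error (the
paired version is calibrated: empirical null rejection ≈ 0.05, checked at
1000 trials in the acceptance suite). Statistics are computed on log2 folds,
where Gaussian Ct noise is additive.

## Synteny

Cross-species gene orders (position rank, gene id, family id) are aligned to
a reference window anchored on a focal gene. Matching maximizes the length of
an order-preserving chain of shared family ids (O(n²) dynamic program), run
on both the forward and reversed species order and keeping the better, so
inverted regions align. Reference genes without a matched pillar are called
lost; genes of the species falling between two matched pillars that do not
belong to an intervening lost column are counted as insertions in that gap.
The conservation summary partitions every species as present or lost per
column (`n_present + n_lost = n_species`). The packaged seven-lineage YCP4
panel encodes anchor loss in two post-WGD-distant lineages with an intact
telomeric flank (CIT2 present in all seven).

## Pipeline and reproducibility

`locus-echo run` executes annotation → simulation (or user-supplied inputs)
→ profiles/heatmaps/decay fits → growth → qPCR → synteny, wrapping each
stage so failures name the stage. All randomness derives from one seed with
fixed per-stage offsets (expression +1, growth +11/+12, qPCR +21), and the
manifest records package versions, the seed and SHA-256 hashes of outputs;
reruns with the same seed are byte-identical. `scripts/acceptance.py`
re-computes the headline quantities from a single `--seed` and writes them
with sample sizes to JSON.

## Limitations

- The planted correlation kernel is stationary and isotropic in genomic
  distance; real co-expression has operon-like, divergent-promoter and
  chromatin-domain structure it does not model.
- Synthetic coordinates in the packaged annotation mean absolute distances
  (and hence fitted λ on that fixture) are not biologically meaningful.
- The decay fit assumes independent residuals across neighbor pairs; profile
  points sharing the focal gene are actually correlated, so reported
  parameter SEs are optimistic and only the flat flag, not the SEs, is used
  for decisions.
- The growth model treats dilution steps as exchangeable unit decrements of
  a latent capacity; it ignores colony-size saturation and plate effects.
- Real-compendium analyses require a locally exported expression matrix; no
  network access is attempted.
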