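# Methods

## The problem and the model

Protein complexes only function when their subunits are present together, so
the pairwise co-expression of the genes encoding a complex is a useful proxy
for the integrity of its interaction network.  `codyn` compares that
co-expression structure between two sample groups — a *case* condition (e.g.
the AD11 anti-NGF transgenic mouse, a model of progressive Alzheimer-like
neurodegeneration) and a matched *control* — at each timepoint of an
expression time course.

For a complex of size *n* measured in one (group, timepoint) cell, the
co-expression matrix is the upper triangle of pairwise Pearson correlations
of the members' expression profiles, computed over that cell's samples only:
N = n(n−1)/2 values A_ij (case) and B_ij (control).  Genes inside a complex
are kept in a canonical lexicographic order so that matrices, difference
matrices and reports are deterministic; no ordering is implied by the data
itself.

Two statistics compare A and B at each timepoint:

**Average-shift (paired t).**  With D_ij = A_ij − B_ij,

    t = Σ D_ij / sqrt[ (N · Σ D_ij² − (Σ D_ij)²) / (N − 1) ]

which is algebraically the textbook paired t, mean(D)/(sd(D)/√N), referred to
a t distribution with N − 1 degrees of freedom, two-sided.  A complex gets a
code per timepoint: +1 for a significant (p < α, default 0.05) positive
shift of the case average, −1 for a significant negative shift, 0 otherwise.
Over the four default timepoints these codes form the *quadruplet*, a compact
signature of when in the time course the average co-expression diverges.

**Rewiring distance.**  The root mean squared entrywise difference

    d = sqrt[ Σ_{i<j} (A_ij − B_ij)² / N ]

is sensitive to internal re-organization even when the averages agree
(positive and negative entry changes do not cancel).  d has no theoretical
maximum, so it is calibrated empirically: for each complex size n and
timepoint, the distances of `n_random` (default 1000) random gene sets of
size n, drawn uniformly without replacement from all measured genes, give a
null mean ⟨x⟩ and standard deviation S, and the observed distance is reduced
to

    z = (d − ⟨x⟩) / S .

Significance is one-sided at z > 1.9 (default): only an excess over random
rewiring is called; negative z (more similar than random gene sets) is
reported but never significant.

**Single-gene decorrelation.**  The difference matrix D = A − B localizes a
shift to individual genes: each gene is scored by the mean of the N − 1
difference entries involving it, and genes are ranked ascending, so a member
that is strongly anti-correlated with the rest of the complex in the case
group only — a candidate for dissociation from the complex — ranks first.

## Pipeline stages and their parameters

1. **Probe selection** (probe-level input only).  Each probe is scored by a
   two-class one-way ANOVA (case vs. control), pooling samples across
   timepoints; per gene the probe with the smallest p is kept (largest F,
   then lexicographically smallest probe id, on ties).  No absolute p cutoff
   is applied: the filter exists to pick the most discriminative probe per
   gene, not to threshold genes.  Zero-variance probes get p = 1 with a
   warning rather than an error so that flat probes on real arrays pass
   through.
2. **Catalog mapping.**  Complex gene sets (CORUM-style or two-column TSV)
   are intersected with the measured genes; complexes with fewer than
   `min_size` (default 3) measured genes are dropped.  Report tables apply a
   stricter `report_min_size` (default 4, i.e. size > 3), keeping the
   analysis and reporting filters distinct.
3. **Comparison.**  Per complex and timepoint: averages, paired t, code,
   distance, and z against the (size, timepoint) null.  Null draws use
   deterministic sub-seeds derived from the master seed via
   `SeedSequence([master, size, timepoint_index])`, so adding or removing
   complexes does not perturb other nulls.
4. **Reports.**  The quadruplet table lists complexes with size > 3 and a
   non-trivial quadruplet, sorted by size then name; the distance table
   lists complexes with size > 3 and at least one z above threshold, ordered
   by earliest significant timepoint, then size, then name (the ordering is
   stated so external tables can be compared cell-wise).

Defaults in one place: α = 0.05 (two-sided paired t), z threshold 1.9
(one-sided), 1000 random complexes per null, min size 3, report size > 3,
timepoints "1", "3", "6", "15" (months).

## Synthetic data

The generator emulates the structure of the targeted study design — 4
timepoints, 15 case and 15 control samples per timepoint, a configurable
background of independent genes — with complexes realized as equicorrelation
blocks: within each (group, timepoint) cell the members are drawn from a
multivariate normal with unit variances and a single intra-block correlation
ρ, configurable per cell.  An optional *anti-member* replaces one gene's
correlations with −ρ_anti to every other member in chosen cells, reproducing
the single-gene dissociation pattern the ranking stage targets.  Requested
correlation matrices are checked numerically for positive semi-definiteness
and rejected otherwise (equicorrelation alone requires ρ > −1/(n−1)).
Marginals are Gaussian with mean zero: every statistic in the pipeline is
location- and scale-free, so marginal realism adds nothing.  Probe-level
data is derived by expanding each gene into one clean probe plus decoy
probes carrying heavy independent noise, giving probe selection a planted
right answer.

What the generator does *not* emulate: dye and batch effects, probe sequence
behavior, heavy-tailed or discrete expression marginals, mean shifts between
groups (except where a test plants them explicitly), and non-uniform
correlation structure within a complex.  Passing tests therefore demonstrate
the statistics' behavior under clean, exchangeable-sample conditions, not
robustness to array artifacts.

## Calibration caveat and simulation design

The paired t treats the N gene pairs as independent observations; they are
not, because pairs share genes.  Empirically the miscalibration vanishes at
ρ = 0 (correlation estimates of pairs sharing a gene are uncorrelated at the
null), where the nonzero-code rate matches α, but at ρ > 0 the pair
dependence inflates the false-positive rate substantially (measured ≈0.2 per
timepoint at ρ = 0.1, size 8, 15 samples per cell).  This is a property of
the published procedure, implemented as published.  Consequently the
power/recovery simulations plant the case/control contrast (ρ_case = 0.6 vs
ρ_control = 0.1) at the first timepoint and leave the remaining timepoints
at the calibrated null ρ = 0; type-I behavior is asserted only on ρ = 0
complexes.  Problem sizes used by the validation suite — 500 null complexes
of size 6, 100 recovery replicates of a size-8 complex, 1000-draw nulls with
1000 held-out random complexes on a 300-gene background — were chosen to
bound Monte-Carlo noise well below the asserted tolerances while keeping the
suite fast.

## Numerical choices and degenerate inputs

* Pearson values are computed from row-standardized profiles (centered,
  unit norm) so a complex's matrix is a single inner product; entries are
  clipped to [−1, 1] against floating-point overshoot.
* Zero-variance profiles make correlations undefined; such genes abort the
  affected complex with a logged skip (no imputation) and are excluded from
  the null's gene universe with a warning.
* Paired-t degeneracies: all-zero differences → t = 0, p = 1 (no change);
  constant nonzero differences → p = 0 with a warning (a real shift with
  zero spread).  Both are logged.
* A degenerate null (S = 0, e.g. identical case and control data) is a hard
  error in `z_score`; the pipeline leaves z unset for affected complexes and
  warns instead of aborting the run.
* Null standard deviation uses the sample estimator (ddof = 1).
* Missing expression values are rejected at read time: Pearson over
  incomplete pairs would silently change N.
* Expression values are treated as already-normalized log ratios; no
  normalization stage is implemented.

## Using real data

The pipeline runs unchanged on real inputs: an expression TSV (probe or gene
level), a sample-metadata TSV (`sample_id`, `group` ∈ {case, control},
`timepoint`), an optional probe map, and a complex catalog (e.g. a CORUM
release, whose name/subunit column names are configurable).  For the AD11
study the expression data is GEO series GSE63617; neither it nor any CORUM
release is bundled, since catalog release and identifier namespace
materially affect which complexes map — the catalog is an explicit input.
Published per-complex distances and z-scores can be compared cell-wise with
`codyn analyze` output, subject to catalog-version caveats.

## Known limitations

* The paired t's pair-dependence (above) makes codes anticonservative for
  complexes whose baseline intra-complex correlation is high; the distance
  z-score, whose null is built from size-matched gene sets of the same data,
  does not share this issue.
* No multiple-testing correction is applied across complexes, matching the
  published procedure.
* Mutual-information or partial-correlation co-expression measures are out
  of scope; Pearson only.
* The z-score threshold is applied to an empirical null summarized by mean
  and sd; for very small `n_random` the normal reduction is noisy (the
  pipeline warns below 100 draws).
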