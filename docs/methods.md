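# Methods

## The line-cross model

A dataset is a set of cohorts from crosses between two diverged lines,
each summarized by a phenotype mean and the standard error of that mean.
Cohort means are modelled as `y = Cβ + e` with independent Gaussian errors
whose variances are the squared reported SEs (the diagonal of V).  The
C-matrix rows are deterministic functions of each cohort's pedigree:

- **source index** θ_S — the expected fraction of a cohort's autosomal
  alleles originating from line 1.  For a sire × dam cross,
  θ_S = (θ_S^sire + θ_S^dam)/2.
- **hybridity index** θ_H — the expected fraction of loci heterozygous for
  line-1/line-2 alleles.  Each parent is assumed to transmit a line-1
  allele with probability equal to its own θ_S, independently across loci,
  giving θ_H = θ_S^sire(1 − θ_S^dam) + (1 − θ_S^sire)θ_S^dam.  This
  independence approximation is exact for the designs in common use: the
  F1 × F1 intercross yields the Mendelian θ_H = 1/2 with no special case,
  and selfing a pure line returns that line.

Column conventions: `Aa = 2θ_S − 1` (P1 = +1, P2 = −1), `Ad = θ_H`
(F1 = 1, inbred parents = 0), digenic epistatic columns are products of
the single-locus columns, maternal columns (`Ma`, `Md`) use the dam's own
indices, and `Ca = ±1` marks the cytoplasm's line of origin.  These are
the source/hybridity-index conventions of the composite-effects
literature; because downstream summaries use absolute values, the final
architecture proportions are invariant to which line is called P1 (tested
as a property).

When the sexes of the crossed parents are unreported, maternal and
cytotype effects are unidentifiable and the **reduced** vocabulary
{Aa, Ad, AaAa, AaAd, AdAd} is used; otherwise the **full** eight-effect
vocabulary applies.  Sex-linked composite effects and G×E extensions are
out of scope.

## Multimodel inference

Candidate architectures are all non-empty effect subsets with at most
`min(n_cohorts − 1, 7)` composite effects; the intercept (grand mean) is
in every candidate and does not count against the cap.  Candidates whose
weighted design submatrix V^(−1/2)·X is rank-deficient or has condition
number above 1e8 are dropped (logged with the most correlated column
pair); duplicated rows from reciprocal crosses under the reduced
vocabulary make this screen essential rather than cosmetic.

Each surviving candidate is fitted by solving the weighted normal
equations.  With reported SEs, V is known: the log-likelihood is the
Gaussian likelihood at fixed V and AICc counts k = p coefficients.
Without SEs the fit is ordinary least squares, the residual variance is
profiled out by maximum likelihood, and k = p + 1.  Candidates with
n − k − 1 ≤ 0 have no defined AICc; they are solved (useful for
diagnostics) but excluded from the ranking with a logged reason.  A
consequence worth knowing: a weighted 3-cohort dataset has no scorable
candidate and is reported uninformative rather than erroring.

Akaike weights are computed after subtracting the minimum AICc.  The
confidence set is the smallest prefix of weight-ranked models reaching
cumulative weight 0.95 (ties break toward fewer parameters, then
lexicographic effect order); its weights are renormalized before
averaging — the renormalization and the 1.96 CI multiplier are
conventional choices, both exposed in `PipelineConfig`.  Model-averaged
estimates use the zero-substitution convention (absent effect ⇒ estimate
0), and the unconditional variance
`Σ wᵢ(varᵢ + (θ̂ᵢ − θ̂)²)` adds model-selection spread to within-model
variance.  Significance = variable importance ≥ 0.5 **and** 95% CI
excluding zero; both thresholds configurable.

All orderings and tie-breaks are deterministic, so repeated runs are
byte-identical.

## Architecture proportions and group comparisons

Significant effects are pooled by mode of gene action — Aa, Ma, Ca →
additive; Ad, Md → dominance; digenic terms → epistatic — using absolute
values, normalized by the grand sum.  Datasets with no significant effect
are flagged uninformative and excluded from comparisons (the skip ledger
records them; transparency of exclusions is part of the result).

Before comparisons, datasets sharing a (species, trait) pair are
consolidated by averaging their proportions, so prolific study systems
cannot dominate; metadata conflicts within a pair are hard errors.  Group
comparisons use a Monte-Carlo permutation test of the difference in group
means: 10,000 label shuffles by default, two-sided on |difference| with
the add-one correction (1 + #extreme)/(n_perm + 1).  Two-sided is the
conservative reading; sidedness is a config option.  Counts of datasets
pinned at proportion 0 and 1 are reported per group.

## Synthetic data generator

The generator emulates an empirical line-cross study: true cohort means
are `C·β_true`; `n_per_cohort` individual phenotypes are drawn Gaussian
around each true mean with within-cohort SD σ; the *sample* mean and
SE are reported, so reported uncertainties carry realistic sampling
error.  A means-only fast mode skips the individual draws for property
tests.  When the sample SD is zero the SE is floored at 1e−6 to keep V
invertible.

Defaults, chosen to represent a typical published cross: grand mean 10,
σ = 1 (effect sizes are then in within-cohort SD units), 30 individuals
per cohort, cohort designs from 4 to 16 cohorts weighted toward the small
designs that dominate the literature.  Database-level defaults: plants :
animals = 3 : 1, within- : between-species = 4 : 1, trait classes 1 : 1
(roughly the composition of published line-cross compilations); effect
presence priors additive 0.9 / dominance 0.5 / epistatic 0.5 with
half-normal(sd = 2) effect sizes and random signs; 20% of datasets carry
parent-sex information.  Group-level architecture differences can be
injected through per-group presence overrides.  Per-dataset RNG streams
are spawned from the master seed, so a database is reproducible as a
whole and each dataset independently.

What the generator does *not* emulate: linkage and finite genome size,
segregation variance differences between cohort types, non-Gaussian
phenotypes, digitization error from published figures, and correlated
traits within a study.  Passing tests therefore demonstrate correctness
of the inference machinery under the stated sampling model, not
robustness to every feature of real literature data.

## Verification

The suite checks, among others: C-matrix rows against hand-computed
pedigree expectations and sign-flip/product invariants (with random
pedigrees via hypothesis); WLS against an exact rational solve of a
4-cohort toy and against an independent WLS route; Akaike weights against
closed forms; the entire enumeration → weighting → confidence set →
averaging chain against a naively coded brute-force oracle (exact to
1e−10 on model spaces of 7 and 15); permutation p-values against exact
enumeration on a 2-vs-2 toy and for null uniformity.

Simulation-scale guarantees (also recomputed by `scripts/acceptance.py`):
with a purely additive truth of 2 within-SD the significance rule
declares non-additive effects in well under 5% of dataset-effect pairs
(200 datasets, 6 cohorts, n = 30); with truth (mean 10, Aa 3, AdAd 2,
n = 50) both effects are detected in ≥ 90% of 100 replicates with < 10%
bias; thinning 16-cohort epistatic datasets to {P1, P2, F1, BC1, BC2}
lowers the mean estimated epistatic proportion (the method is
conservative, not anti-conservative, when data are sparse); and removing
maternal/cytotype columns on maternal-free truths leaves the epistatic
proportion essentially unchanged for the majority of datasets.  Problem
sizes (200/100/100 replicates, 30–50 individuals per cohort) keep the
whole verification under a minute while leaving the Monte-Carlo error
far below the asserted margins.

## Known limitations

- Cohort means are assumed independent; shared parents across cohorts
  induce covariances that the diagonal-V model ignores (as does standard
  practice in this literature).
- The AICc likelihood treats reported SEs as exact variances;
  heavy-tailed or misreported uncertainties will distort weights.
- The unconditional CI uses a normal quantile; for very small cohort
  counts a t-quantile would be wider.
- Model spaces are enumerated exhaustively; with the 7-effect cap the
  largest space here is a few hundred candidates, so no stochastic search
  is implemented.
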