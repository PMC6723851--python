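# Methods

## Problem setting

`dietnet` models a cross-sectional dietary survey of adolescents in which
each participant answers a 97-item semi-quantitative food frequency
questionnaire (FFQ) and is measured for weight and height.  The analysis
asks not whether heavier adolescents eat *more* of any food group — in the
modelled study they do not — but whether the *joint structure* of
consumption differs across anthropometric strata: whether eating more of
one group predicts eating more (or less) of others, and how tightly
connected that correlation structure is.

## Pipeline

The stages run in the order the data flow:

1. **FFQ ingestion** (`ffq_ingest`).  Each item response carries a
   frequency category, a times-per-occasion count, and a portion in grams
   (mL treated as grams 1:1).  Categories are deconvoluted to occurrences
   per day by fixed midpoints — never/rare → 0, 1–3/month → 2/30,
   1/week → 1/7, 2–4/week → 3/7, ≥4/week → 5/7 — with months standardized
   to 30 days and weeks to 7.  The open-ended top category has no stated
   upper bound; 5/week is the package's convention and is overridable, as
   are all midpoints.  `times` multiplies the occurrence rate (an
   occasions multiplier), not the portion.  Daily grams per item are
   `occurrences/day × portion`, summed within each of 14 food groups
   defined by nutritional similarity.  Missing responses count as
   never/rare.  The shipped 97-item map makes editorial splits of prose
   item lists; users may supply their own map CSV.

2. **Anthropometry** (`anthropometry`).  BMI = (weight − 0.1 kg school
   uniform correction) / height².  Classification against sex- and
   age-specific BMI percentile cut-offs: `<p3` underweight, `[p3, p85)`
   eutrophy, `[p85, p97)` overweight, `≥p97` obesity (lower bounds closed
   upward).  Cut-offs are *data*, supplied as a CSV keyed by sex and age
   in months with linear interpolation between grid rows — the simplest
   convention consistent with tabulated growth references.  The packaged
   table (`make_synthetic_reference_table`) is synthetic, for tests only.

3. **Cohort statistics** (`cohort_stats`).  Dietary grams are right-skewed
   and non-Gaussian, so summaries are median/IQR (quartiles by linear
   interpolation between order statistics) and tests are rank-based:
   Mann-Whitney U (normal approximation, tie-corrected, no continuity
   correction — cohort sizes are far beyond the exact-test range),
   Kruskal-Wallis with a hand-implemented Dunn post-test (pooled mean-rank
   z with the tie-corrected variance), Pearson chi-square without
   continuity correction, and Holm-Bonferroni step-down adjustment.  The
   multiplicity family for the by-status consumption table is the 14
   food-group tests; demographic rows can be added to the family by flag.

4. **Two-way Ward clustering** (`consumption_clustering`).  The matrix is
   z-scored per food group (sample sd, divisor n−1; a zero-variance group
   is an error naming the group).  Both axes are clustered with Ward
   linkage on Euclidean distances (Ward.D2 increments under the
   Lance-Williams recurrence, delegated to scipy's deterministic NN-chain
   implementation).  Defaults cut k=4 food-group clusters and k=3
   participant clusters; the participant clusters are labelled
   high/medium/low by mean row z-score, with exact ties broken by cluster
   size (larger → lower label).  Internal-node stability is a plain
   bipartition bootstrap — resample the complementary axis with
   replacement, rebuild, count containment — not an approximately-unbiased
   correction.  Degenerate resamples are skipped with a warning but stay
   in the denominator.  Trees export as Newick with branch lengths from
   merge-height differences.

5. **Correlation networks** (`correlation_networks`) — the analytical
   core.  Per stratum: the 14×14 Spearman matrix (rank-then-Pearson, ties
   averaged; p from the t approximation with n−2 df), Holm-adjusted across
   the 91 unordered pairs, then a B=100 participant bootstrap at the
   original stratum size.  An edge is included iff

   * full-sample adjusted p < α (default 0.05),
   * |ρ| > 0.5 strictly (the "strong" threshold), and
   * the pair stays adjusted-significant in ≥ 50% of replicates.

   Each replicate also yields a density sample L/(N(N−1)/2) where L counts
   the adjusted-significant pairs of *that replicate* — the density L
   carries no rho or support filter; the three-part rule defines included
   edges only.  Density vectors are compared across strata by
   Kruskal-Wallis + Dunn; node degree counts included incident edges.
   Whether within-replicate significance should use adjusted or raw p is
   genuinely open; adjusted is the default and raw is a flag
   (`adjust_within_bootstrap=False`).  The edge ρ reported is always the
   full-sample value, not a bootstrap median.

## Synthetic cohort generator

No cohort data are distributed with the modelled study, so
`synthetic_cohort` defines the test conditions.  A Gaussian copula couples
log-normal marginals: targets are specified as Spearman matrices,
converted by the exact identity r = 2 sin(πρ_s/6); because Spearman
correlation is invariant under the monotone exp transform, empirical rank
correlations converge to the target.  Non-PSD hand-specified targets are
repaired by eigenvalue clipping with diagonal rescaling; the maximum
elementwise change is returned and warns above 0.05 (escalatable to an
error).

Defaults are the modelled study's published structure:

* stratum sizes 120 / 1155 / 132 / 89 (total 1496);
* per-group log-medians ln(published median grams) and log-sd
  ln(q3/q1)/(2·z₀.₇₅) from the published whole-cohort IQRs — the study
  reports no variance-generating mechanism, so the log-normal quartile
  ratio is the package's choice;
* demographic categories allocated per stratum by largest remainder from
  the published per-stratum frequencies (then seed-shuffled), so default
  cohorts reproduce the published cross-tabulations exactly; demographics
  are independent of consumption given the stratum, matching the reported
  absence of mean-consumption differences by sex or status;
* correlation regimes: equicorrelation 0.55 for eutrophy; a one-factor
  all-positive matrix with coffee largely decoupled for underweight; and
  for overweight/obesity three-block structures in which a western subset
  is anticorrelated (−0.55) with the prudent block
  (cereals/roots/legumes/vegetables/fruits) over a weak background —
  chosen, with PSD verified, so that default cohorts show all-positive
  eutrophic networks, mixed-sign non-eutrophic networks, and bootstrap
  densities lowest in the obesity-like stratum.  These defaults are
  configuration, not estimates of the real cohort's matrices.

Ages are truncated-normal around 14.3 y within 11–17.9; heights normal
around 1.62 m; BMI is drawn uniformly inside the planted class's band at
the participant's sex/age cut-offs, and weight back-computed (plus the
uniform correction), so anthropometric classification recovers the
planted classes exactly.

What the generator does **not** emulate: item-level answer patterns (the
disaggregation helper is only an aggregation round-trip inverse),
correlation between demographics and diet, measurement error, missing
data, or within-stratum heterogeneity of correlation structure.  Passing
tests therefore demonstrate that the machinery recovers known planted
structure under realistic marginals and sizes — not that the real
cohort's specific matrices would be recovered.

## Numerical choices

* Quartiles, z-scores and tie handling follow the conventions stated
  above; all are fixed in config rather than silently library-dependent.
* Spearman pairs with zero rank variance are not-computable (NaN) and are
  excluded from the Holm family rather than imputed.
* |ρ| = 1 pairs get p = 0 directly (the t statistic diverges).
* Ward ties at equal merge cost follow scipy's deterministic internal
  order; merge heights are unaffected.
* The copula Cholesky adds a 1e-10 diagonal jitter after PSD repair.
* Bootstrap seed streams derive from one root seed via
  `numpy.random.SeedSequence` spawning, per stratum and per stage, so
  parallel or partial re-runs reproduce.

## Problem sizes

Simulation-based checks use scaled designs chosen to make planted effects
decisively detectable while keeping runs short: edge recovery and density
separation use n = 150 participants per stratum, B = 100 bootstraps,
20 seeded repetitions; copula fidelity uses n = 10 000 (±0.05 tolerance);
Ward oracle equivalence uses ≤15 leaves over 50 seeds (the naive oracle
is cubic); the null rejection-rate study uses 1 000 replicates of 25 vs
25.

## Known limitations

* The density statistic counts adjusted-significant pairs, so it depends
  on stratum size: equal correlation structure at different n yields
  different densities.  Cross-stratum comparisons inherit this property
  of the method being modelled.
* Bipartition bootstrap supports are frequencies, known to be biased
  downward for true splits; no AU correction is applied.
* The Dunn implementation assumes large-sample normality of mean-rank
  differences; very small groups should be compared pairwise instead.
* The shipped item→group map resolves prose ambiguity editorially; any
  serious reuse should supply the instrument's own item list.
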