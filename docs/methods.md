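# Methods

## Problem and data model

The package compares two explanations for variation in an insect
herbivore's feeding intensity across candidate host-plant species: that
feeding tracks the *phenotypic* (metabolite-profile) similarity of the
plants, or that it tracks their *genetic* relatedness. Both hypotheses
are expressed as trees over the same species — a chemotaxonomic
dendrogram built from glucosinolate (GS) concentration profiles, and a
genetic phylogram supplied externally (newick) or built from a genetic
distance matrix — and the question becomes: on which tree does the
feeding trait carry more phylogenetic signal?

Inputs are long-format tables: per-plant compound concentrations
(µmol/g dry mass) keyed by species, population, leaf stratum
(young/old), replicate and compound; per-plant feeding observations
(counts of feeding punctures for a specialist, mm² leaf area removed
for a generalist); and the genetic tree or matrix.

## Compound reduction

Raw HPLC–MS screens overcount compounds. Three rules reduce the list:
peaks not confirmed as GS are discarded; identified peaks eluting after
a configurable cutoff (default 30 min) are discarded as likely dimers;
groups of near co-eluters with indistinguishable spectra are collapsed
to a single compound whose concentration is the sum of its members
(mass conserving). A merge-group member that also carries a discard
flag is rejected as contradictory rather than silently resolved. The
reduction is idempotent and order-preserving.

## Aggregation conventions

Species profiles are means of means: replicate plants are averaged
within each (population, leaf stratum) cell; populations are averaged
with equal weight (not pooled by plant), because species with two
sampled populations would otherwise dominate by sample size; the
"all leaves" profile is the equal-weight mean of the young-leaf and
old-leaf species values, not the pooled mean over plants. Compounds
never detected in a species are explicit zeros — required for the
Euclidean distances that follow.

## Trees

Profile distances are plain Euclidean distances between species rows.
Neighbor joining uses the standard Q-criterion with Studier–Keppler
branch lengths; among numerically tied joins the pair whose clusters
carry the lexicographically smallest tip labels wins, making the output
independent of input row order. The tree is returned unrooted with its
basal trifurcation, and raw NJ branch lengths — which can be negative —
are retained. Bootstrap supports resample compound columns with
replacement, rebuild the tree, and count replicates containing each tip
bipartition (reported as counts by default, percent optionally).

For covariance computation negative branch lengths are clamped: a
negative internal edge is set to zero and its (negative) length is
pushed onto the edges of its child node, which preserves every
root-to-tip path length exactly; negative pendant edges are simply set
to zero. The raw tree is never modified. By default the basal
trifurcation serves as the root for signal analysis (midpoint rooting
is available by flag); this choice affects K and is therefore surfaced
as an explicit parameter rather than hidden.

## Blomberg's K and the permutation test

K is the ratio of the observed mean-square ratio to its expectation
under Brownian motion on the given tree (formula in the README). The
implementation factorizes the tip covariance V once per tree (Cholesky)
and evaluates K for arbitrarily many trait vectors by triangular
solves, which makes the permutation test and the bootstrap comparison
cheap. Singular V (for example duplicate tips at zero distance, or an
all-zero tree) raises an error; it is never regularized. K is invariant
to affine transforms of the trait and to global rescaling of branch
lengths; both invariances are tested to 1e-9.

The permutation test shuffles trait values across tips uniformly
(default 999 permutations) and reports
p = (1 + #{K_perm ≥ K_obs}) / (n_perm + 1), so p can never be smaller
than 1/(n_perm+1). Under the null of no association the test rejects at
the nominal rate (checked over 500 simulated null runs).

## Comparing K between trees

The two candidate trees are compared by a within-species nonparametric
bootstrap of the replicate feeding observations: each of b iterations
(default 1000) resamples observations with replacement within every
species, recomputes species means, and recomputes K on both trees;
ΔK = K_chemical − K_genetic. The resampled means carry extra
within-species noise, which attenuates K, so the bootstrap ΔK
distribution is not centred on the observed ΔK and is right-skewed (K
is a nonnegative ratio statistic). The reported 95% interval is
therefore Efron's bias-corrected (BC) percentile interval; the
acceleration constant is omitted because the natural jackknife —
deleting a species — would change the tree's tip set and with it the
statistic's definition. The raw percentile interval is also reported.
The two-sided p-value is 2·min(frac ΔK ≤ 0, frac ΔK ≥ 0), floored at
1/b.

**Caveat.** The bootstrap answers: *is the observed K difference robust
to which individual plants were measured?* Its estimand is the ΔK of
the realized species-mean configuration. It is **not** a test of
process-level coupling: when feeding is generated with no relation to
either tree, the realized configuration still has some nonzero ΔK and
the interval excludes zero in far more than 5% of datasets. The
calibrated null test for "is there signal at all" is the permutation
test; the ΔK interval quantifies the stability of the *contrast*
between trees.

## Classical statistics

The regression layer predicts per-species feeding means from three
predictors: patristic distance to the reference species on the genetic
tree, patristic distance to the reference on the chemical dendrogram,
and total GS concentration. Effect tests use partial (marginal) sums of
squares — SSE of the model refit without the effect minus SSE of the
full model — with F = SS/MSE_full; sequential SS are available behind a
flag. Spearman rank correlation (tie-averaged ranks, t-approximation
p-value) is used for per-compound associations because concentration
vectors are zero-inflated. Kruskal–Wallis (tie-corrected, chi-square
approximation) serves the count response, one-way ANOVA the continuous
responses, and population differences within a species are tested by a
single-df contrast in a cell-means model with pooled error. Tests are
two-sided throughout and no multiple-testing correction is applied. An
optional temporal-block covariate is accepted but excluded by default.
Ranking, tail probabilities and least squares come from scipy; the
effect-table assembly, the contrast, and all tree-based statistics are
implemented here and verified against brute-force oracles in the test
suite.

## Synthetic-data generator

`simulate_study` emulates the *shape* of a host-specificity screening
study: 13 species × 26 compounds × 5 replicate plants × {young, old}
leaf strata; a second population for 6 species; young totals ≈ 33.4 and
old ≈ 17.8 µmol/g; zero-inflated profiles (default occupancy 0.35);
overdispersed specialist counts and lognormal generalist areas for two
insects. Key design choices:

- **Chemical profiles** mix a Brownian component simulated on a
  "chemical" tree with iid noise on the log scale
  (`profile_tree_weight`, default 0.8). Sparsity is *clade-structured*:
  a compound is present in the species where its tree-structured latent
  abundance is highest. An iid presence mask would make all
  between-clade Euclidean distances nearly equal (concentration of
  measure in 26 dimensions), which no real GS table shows — real
  profiles contain clade-restricted compounds.
- **Specialist feeding** declines *linearly* from `count_max_mean`
  (default 125, at the reference host) to `count_min_mean` (default
  0.3, near-complete rejection) along a blend of the normalized
  chemical and genetic distances weighted by `chem_signal_weight` and
  `phylo_signal_weight`; counts are negative-binomial with shape
  `count_dispersion` (default 3, matching puncture-count standard
  errors of roughly a third of the mean at n = 5). The linear form
  mirrors the linear feeding-versus-distance analyses the pipeline
  itself runs and yields a realistic spread of species means rather
  than a single-host spike.
- **Generalist feeding** depends only weakly on the same blend
  (`generalist_coupling`, default 0.2), around 14 mm² with CV 0.45.
- **Genetic distances** are the patristic matrix of an independently
  simulated pure-birth tree, so they are additive and neighbor joining
  reconstructs the generating tree exactly.
- One master seed feeds named substreams (trees, chemistry, feeding),
  so identical seeds give byte-identical output files and components
  can be regenerated independently.

What the generator does **not** emulate: chromatographic raw signal,
retention-time structure, compound identities, correlated measurement
error between strata, or realistic Brassicaceae phylogenies. Passing
tests on synthetic data therefore establish the statistical behaviour
of the pipeline (calibration, consistency, recovery of known coupling),
not chemical realism.

## Numerical choices and degenerate inputs

- Linear solves use a symmetric (Cholesky) factorization of V, cached
  per tree; explicit inverses appear only in test oracles.
- NJ join ties break lexicographically; distance-matrix symmetry is
  enforced at 1e-8 relative tolerance; asymmetric or non-square inputs
  are errors with the offending labels named.
- Constant traits, constant regressors, single-population contrasts,
  all-zero trees and sub-minimal sample sizes raise errors rather than
  returning NaN; all-identical Kruskal–Wallis input returns H = 0,
  p = 1 by documented convention.
- Default problem sizes in the acceptance script (200 Brownian
  replicates, 500 calibration runs, 100 NJ matrices, 50 recovery
  studies at 1000 bootstrap iterations) were chosen to estimate each
  rate to a few percent while keeping the whole script in seconds.

## Known limitations

- The ΔK bootstrap's estimand caveat above: it is a stability measure,
  not a process-level null test.
- With 13 species, K itself is noisy; the chemistry-over-phylogeny
  recovery rate under pure chemical coupling is about 0.9 at the
  default noise levels, so single studies of this size can fail to
  resolve the contrast even when the coupling is real.
- Rooting of the (intrinsically unrooted) NJ dendrogram affects K; the
  basal-trifurcation default is a convention, and midpoint rooting can
  change results for strongly unbalanced trees.
- The genetic side is taken as given (tree or distance matrix);
  sequence alignment and likelihood tree inference are out of scope, so
  K on a genetic tree inherits whatever branch-length conventions that
  input used.
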