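# Methods

`phyloassembly` analyses how tree communities assemble along environmental
gradients by combining three strands of evidence: phylogenetic dispersion
within communities, functional-trait dispersion within communities, and the
coupling of both to measured soil gradients. This note records the models,
conventions and design choices behind each stage, and what the synthetic
benchmark can and cannot demonstrate.

## Data model

The unit of observation is the individual stem: every tree with dbh >= 10 cm
in a 0.25-ha plot, tagged with a subplot (a 5x5 grid of 10x10-m cells,
labelled 1..25 row-major), a species, and its diameter. Basal area is always
recomputed from dbh as pi(dbh/2)^2 (cm^2), never stored separately, so the
two community weight layers (stem counts and summed basal area) can never
drift apart. Analyses run at two scales — plots (0.25 ha) and subplots
(0.01 ha) — and under both weightings. At the subplot scale every cell of
every enumerated plot is a sampling unit, including empty ones (they carry
zero weights and their dispersion values are flagged undefined).

Species names are reconciled across tree, trait table and community by exact
string match after trimming and underscore/space normalization; no fuzzy
matching, because a silent mis-join is worse than a visible drop. The
reconciliation report lists what was dropped from each source and the
fraction of individuals excluded.

## Null model

All dispersion and similarity tests share one randomization engine:
individual stems keep their species identity and basal area, and the
sampling-unit labels are permuted over the multiset of stems. Each replicate
therefore preserves every unit's stem count and every species'
community-wide abundance exactly; this is the individual-reallocation null
("model 1s" in the abundance-weighted community phylogenetics literature).
Basal area travels with the stem — the only treatment consistent with
individual-level randomization. One ensemble object (community, n_reps,
seed) regenerates identical replicate streams on every pass, so NRI, ZFDis
and the similarity tests are all judged against the same null communities.
The default is 999 replicates.

## Dispersion metrics

**MPD / NRI.** MPD is the weighted mean pairwise distance,
`sum_{i!=j} w_i w_j d_ij / sum_{i!=j} w_i w_j`, with the intraspecific
diagonal excluded. NRI is the sign-flipped standardized effect size,
`-(MPD_obs - mean(MPD_null)) / sd(MPD_null)`, so clustering (small MPD) is
positive. A variant that divides the centered MPD by the observed MPD
instead of the null SD appears in some descriptions of the index; it is
available behind `printed_formula=True` but is not the default, because only
SD standardization is consistent with the +-1.96 significance rule used
throughout.

**FDis / ZFDis.** FDis is the weighted mean distance of species to the
community's weighted centroid in trait space. For an arbitrary (possibly
non-Euclidean) distance matrix the centroid is defined through principal
coordinates: the Gower-centered matrix is eigendecomposed, positive- and
negative-eigenvalue axes are kept separately, and the squared distance to
the centroid is the positive part minus the negative part (absolute value
before the square root). On Euclidean-embeddable input this equals the plain
geometric computation exactly (tested to 1e-9), and the geometric form is
exposed as a fast path (`coords=`). Per-community FDis uses only the species
present in that community. ZFDis reports the raw SES and a sign-flipped
clustering index so that positive values mean trait dispersion below the
null expectation; significance is |SES| > 1.96. Multivariate FDis defaults
to the complete-linkage trait dendrogram's cophenetic distances
(`fdis_space="dendrogram"`), with raw log-trait Euclidean distances as an
option; per-trait FDis uses the one-dimensional trait distance directly.

A structural caveat discovered while validating the generator: against the
individual-reallocation null, the *mean* FDis clustering index across units
cannot be negative in expectation when units partition the stems. The null
communities inherit the realized community-wide trait mix, and a mixture is
always at least as dispersed around its own centroid as its components
(E[FDis_null] ~ FDis(pooled) >= weighted mean of unit FDis). Limiting-
similarity assembly, which spaces species within units without widening any
unit's trait spread relative to the pool, is therefore invisible to ZFDis
under this null — the measured index is a small *positive* number (~ +0.08)
where trait over-dispersion is ecologically expected. A pairwise trait
dispersion index (MPD computed on trait distances) does recover the
signature strongly (SES ~ -2), because removing close trait pairs raises a
pairwise mean but not a centroid deviation. Both behaviors are pinned by
tests; users hunting for limiting similarity should look at pairwise trait
dispersion, not centroid dispersion, whenever the null conditions on
abundances.

**Trait screening and derived traits.** Height and crown width are strongly
size-dependent, so their per-species OLS slopes on dbh (raw scale) replace
the raw values as traits. Trait screening is a greedy scan in a configurable
priority order keeping a trait iff its pairwise Pearson |r| with every kept
trait is below 0.50. Trait values are log10-transformed before Euclidean
distances (positive physical traits); no z-standardization by default, with
a `standardize` flag for mixed-unit tables. Synthetic traits are raw
Brownian states and may be negative; analyses of synthetic data set
`log10_traits=False`.

**PhyloSor.** Similarity of two communities is shared branch length over the
mean total branch length of their spanning subtrees, each subtree including
the paths from its tips to the root of the community tree. The same code
runs on the trait dendrogram converted to a tree (edge length = half the
merge-height difference, so tip-to-tip path length equals the cophenetic
distance; PhyloSor is invariant to that global factor).

## Phylogenetic signal

Blomberg's K is the ratio of the observed MSE ratio (cross-species variance
over phylogenetically weighted variance, both around the GLS mean) to its
Brownian expectation on the given tree. Branch lengths are taken as
expected-variance units with no rescaling. Significance comes from shuffling
trait values across tips: p is the add-one fraction of permutations whose
phylogenetically weighted MSE is at most the observed one (low MSE = good
fit to the tree). Implementation checks: K matches a closed-form dense
linear-algebra oracle to 1e-12, matches an independent reference
implementation on a frozen fixture to 1e-5, is invariant to affine trait
maps and global branch scaling, and averages 1.02 over 500 Brownian traits
on a fixed 128-tip Yule tree (the acceptance script recomputes this).

## Gradient statistics

Soil PCA is correlation-matrix PCA of z-scored parameters (component signs
fixed by making the largest loading positive). CCA follows the chi-square
standardization: `Qbar = D_r^{-1/2}(P - r c^T) D_c^{-1/2}` projected onto
the row-weighted standardized environmental space; singular values of the
projection are the constrained axes, and total inertia equals the Pearson
chi-square of the table over its grand total (asserted as an identity).
Eigenvalues match an independent reference implementation to 1e-6 and a
column-by-column regression oracle to 1e-9. Axis significance uses
unrestricted permutations of whole environment rows, testing axis k with the
previously fitted axes projected out of both sides; with more environmental
columns than units-1 the constraint set is truncated to keep residual
degrees of freedom. Compositional texture columns (sand+silt+clay = 100)
cannot enter CCA together; the default CCA column set is (pH, OM, N, P,
K2O), configurable.

The Mantel statistic is the Pearson correlation of upper-triangle distance
entries, with simultaneous row/column permutation of one matrix (one-tailed
"greater", add-one rule; exhaustive enumeration available for <= 8 units).
Dispersion-gradient inference is ordinary least squares of the per-unit
clustering index on a PCA axis score, with the two-sided t-test on the
slope. The ZFDis clustering index enters regressions untransformed: a log10
of the index is undefined for its negative half, so no transform is applied.

Multiple testing: raw significance flags are reported as-is;
Benjamini-Hochberg q-values are added to the regression table as clearly
supplementary columns.

## Synthetic benchmark

The generator emulates an 11-plot survey: a 123-species pool on a Yule tree
(unit birth rate), 25 subplots per plot, 111 stems per plot (1221 total),
dbh lognormal(ln 20, 0.5) truncated at 10 cm, and a latent soil gradient
expressed through eight correlated soil parameters whose leading PCA axis
recovers the gradient with |r| > 0.95. The assembly trait (column T1) is
Brownian (conserved) or Brownian plus 10x tip noise (convergent); decoy
traits are iid, plus one constructed pair with |r| > 0.8 so screening has
something to drop. The analysis pipeline is never told which trait drives
assembly.

Three processes assemble stems per plot. Filtering draws each stem's species
with probability proportional to exp(-(t_s - theta_u)^2 / 2 sigma_f^2),
theta_u mapped linearly from the soil gradient onto the trait scale
(`gradient_range`, default +-1.5 pool SD) and sigma_f = 0.4 pool SD by
default; `filtering_width_range` instead varies sigma_f linearly across
plots (used to reproduce the dispersion-gradient regression pattern, with
strong filtering at a common off-center optimum: sigma_f from 1.2 to 0.2 SD
at optimum +1.5 SD). Competitive exclusion admits species sequentially in
random arrival order, rejecting candidates within delta = 0.5 pool SD of any
resident, to a target richness of 10, then spreads stems uniformly over
residents. Neutral draws species uniformly from the pool. Subplots are
assigned with mild conspecific aggregation (each species has a "home"
subplot attracting half its stems), so the two scales can diverge. As
sigma_f -> infinity, filtering provably reduces to neutral (chi-square
tested).

Effect-size defaults were chosen once to make each process strong and
unambiguous at the survey's size: sigma_f = 0.4 SD keeps ~10-20 species per
plot under filtering; delta = 0.5 SD with richness 10 forces resident sets
spanning several SD. Scenario recovery is checked over 100 datasets per cell
with a 99-replicate null per dataset (sizes chosen to keep the whole check
under a minute per cell); "random/null" expectations are operationalized as
|mean standardized index| < 0.5 — half a null SD, an order of magnitude
below the recovered strong signals.

What the benchmark does not emulate: spatially explicit dispersal,
intraspecific trait variation, measurement error in traits or soil, multiple
interacting assembly processes, and real phylogenetic branch-length error.
Passing the recovery tests shows the estimators point the right way under
clean, single-process assembly; it does not bound their power on field data.

## Numerical conventions

Null summaries use streaming moments (population variance corrected to the
n-1 denominator). SES values with zero or undefined null SD are NaN and
flagged insignificant. Dendrogram ties follow scipy's deterministic
nearest-pair order. PCoA eigenvalues within 1e-10 of zero (relative) are
treated as null axes. All randomness flows from explicit integer seeds;
generator sub-seeds are spawned from one root seed, and analysis stages
derive distinct fixed offsets so reports are byte-reproducible from
(config, seed).
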