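# Methods

`ecoassembly` implements the quantitative core of a microbial
community-assembly analysis as applied to surface-biofilm amplicon surveys:
null-model partitioning of assembly processes, dissimilarity-overlap curve
(DOC) analysis, habitat-niche metrics, and thresholded co-occurrence
networks, together with a synthetic metacommunity generator used to
validate every stage end to end. This note describes the models, the
parameters that matter, the numerical choices, and what the synthetic
validation does and does not establish.

## Data model and preprocessing

The substrate is a taxon x sample count table (ASV table), a rooted
phylogeny with branch lengths whose tips cover the taxa used in
phylogenetic analyses, and a sample -> group map. Preprocessing follows the
conventions of amplicon workflows:

* **Rarefaction** subsamples each sample without replacement to a common
  depth (default: the minimum observed sample total), via the multivariate
  hypergeometric distribution; samples below the depth are dropped and
  logged. Counts must be integers — rarefaction draws individual reads.
* **Low-occurrence filtering** (applied before the null models only)
  retains taxa with prevalence >= 50% of samples AND total count >= the
  number of samples. The 50% boundary is inclusive: only strictly lower
  prevalence is excluded. This filter sharpens taxon-specific assembly
  signals and reduces false positives from rare taxa.
* **Top-k abundance restriction** (k = 400 by default) precedes network
  construction. Ties in total abundance are broken lexicographically on
  the taxon identifier so results are platform-independent.
* The same rarefied table feeds every downstream stage; only the
  null-model stage additionally applies the occurrence filter.

## Assembly-process partitioning

Every unordered sample pair is classified into one of five processes.

**Phylogenetic turnover.** The beta mean nearest taxon distance,
betaMNTD(j,k) = 0.5 [ sum_i f_ij min_{i' in k} d(i,i')
                    + sum_i f_ik min_{i' in j} d(i,i') ],
uses patristic distances d and within-sample relative abundances f over the
taxa present (an unweighted presence/absence mode is available). The null
model shuffles taxon identities across the phylogeny's tips — equivalently,
permutes the rows of the abundance matrix against the distance matrix —
jointly for all samples, over the full filtered taxon set; this matches the
convention of the standard phylogenetic-null tooling. betaNTI is the
z-score of the observed betaMNTD against 999 null draws. |betaNTI| > 2
indicates selection: > 2 heterogeneous (divergent environments), < -2
homogeneous (a shared filter). Pairs whose null standard deviation falls
below 1e-12 are degenerate: they are reported as NaN, excluded from the
fraction denominator and counted, rather than coerced to zero — coercion
would silently inflate apparent stochasticity. An `exhaustive` mode
enumerates all tip permutations for small tables and is tested against an
independent enumeration oracle at 1e-12.

**Taxonomic turnover.** For pairs with |betaNTI| <= 2, the Bray-Curtis
Raup-Crick metric rebuilds both communities 999 times, preserving each
observed richness and total read count: taxa enter by weighted draws
without replacement (probability proportional to occurrence frequency
across all samples), each entrant receives one read, and the remaining
reads follow a multinomial on regional relative abundances restricted to
the entrants. RCbray = 2 [ #(null < obs) + 0.5 #(null ~ obs) ] / n - 1,
with ties counted within 1e-10 (Bray-Curtis on integer tables can tie
exactly). One seeded stream per unordered pair makes the matrix exactly
symmetric. RCbray > 0.95 indicates dispersal limitation, < -0.95
homogenizing dispersal, |RCbray| <= 0.95 drift. Dispersal and drift are
reported as stochastic processes; the two selection regimes as
deterministic.

## Dissimilarity-overlap curves

For each sample pair, overlap O is the mean shared-taxon abundance
fraction and dissimilarity is the root Jensen-Shannon divergence (natural
logarithm; maximum sqrt(ln 2)) of the two profiles renormalised over the
shared taxa. Pairs sharing fewer than two taxa are dropped and counted. A
LOWESS smoother (span 0.7 by default; the sparse high-overlap tail
overfits with much smaller spans) is fitted on a 50-point overlap grid.

Uncertainty comes from a bootstrap with 1,000 replicates. The default
resampling unit is the **sample**: pairs sharing a sample are dependent,
and resampling samples (keeping the pairs of the resampled samples, with
multiplicity) propagates that dependence into the slope distribution. The
change point xc is the smallest grid overlap above which the median
bootstrap slope is negative everywhere; Fns is the fraction of observed
pairs with overlap beyond xc; the one-sided p-value is the fraction of
replicates whose slope at the high-overlap end is non-negative. Because
the change-point statistic is sometimes reported as a slope elsewhere,
both the terminal slope of the fitted curve and Fns are emitted, labelled
distinctly.

A calibration subtlety: on data whose pair values are exchangeable —
no shared-sample dependence at all — the sample-level bootstrap is
conservative (its spread encodes a dependence the data lack), and the
conservativeness grows with the number of samples. `doc_fit` therefore
accepts `resample="pairs"`, the calibrated unit for exchangeable pair
data; on simulated exchangeable nulls the pair bootstrap rejects at ~5-6%
at the nominal 5% level, while the sample bootstrap rejects at ~2% (n=15
samples) falling towards 0 (n=25). For community tables the default
sample-level unit remains the statistically appropriate choice.

## Niche metrics

Resource states are the individual samples — the standard habitat-niche
reading for ASV tables, and the only one under which per-group community
breadth shows within-group variation. Taxon i's usage p_ij is its
abundance in sample j normalised across samples, making the indices
invariant to per-sample sequencing depth. Levins breadth B = 1 / sum p^2,
Shannon breadth H = -sum p ln p (reported as H, with exp(H) available);
both are Schur-concave, so they rank taxa concordantly. Schoener overlap
1 - 0.5 sum |p - q| and Pianka overlap (cosine similarity) are computed
between taxa; the community overlap Ocom for a scope is the mean over
taxon pairs co-occurring within the scope's samples. Bcom for a sample is
the mean Levins B over the taxa present, weighted by within-sample
relative abundance (an unweighted mean is available). Classification uses
strict thresholds: B < 1.5 specialist, B > 5 generalist, the closed
interval [1.5, 5] middle. Group comparisons of Bcom delegate to a stock
Wilcoxon rank-sum routine.

## Co-occurrence networks

Pairwise Spearman correlations are computed on mid-ranked abundances over
samples; two-sided p-values use the t-approximation
t = r sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom, adequate at the
survey's n ~ 27. Edges require |r| > 0.75 AND p < 0.001, both strict, with
no multiple-testing correction by default (an optional Benjamini-Hochberg
mode exists). Constant taxa have no defined rank correlation and are
skipped, not assigned r = 0. The global network keeps isolated nodes;
group subnetworks keep nodes with nonzero group abundance and the global
edges between them, then prune newly isolated nodes. Topology metrics:
density 2E/(n(n-1)), mean degree 2E/n, transitivity
3 triangles / connected triples, Freeman degree centralization
sum(d_max - d_i)/((n-1)(n-2)), and the proportion of negative edges
(computed from the subnetwork's own edges only). For n < 3, transitivity
and centralization are undefined and reported as such.

## Group-separation tests

Bray-Curtis BC(x,y) = sum|x-y| / sum(x+y) feeds one-way ANOSIM and
PERMANOVA. ANOSIM uses mid-ranks over all n(n-1)/2 distances,
R = (mean between-group rank - mean within-group rank)/(M/2). PERMANOVA
uses SS_total = (1/n) sum_{i<j} d^2 and group-wise within sums; when
SS_within = 0 the pseudo-F is reported as +inf with the permutation
p-value still defined. Both p-values use the (1 + #extreme)/(1 + n_perm)
estimator, which is never zero. Calibration is verified by simulation:
type-I error at alpha = 0.05 over 500 unstructured 20-sample datasets
falls within [0.03, 0.07] for both tests.

## Synthetic metacommunities

The generator emulates the survey design the package targets — 27 samples
in 4 groups (the control group keeps the smaller share: 6 + 7 + 7 + 7), a
few hundred taxa, and read depths around 13,600 — while planting one of
the five assembly processes. Defaults: 500 taxa, 13,622 reads/sample,
lognormal (sigma = 1) regional abundances.

* **Phylogeny**: pure-birth (Yule) trees, unit birth rate. The simulator's
  clock is run past the final birth by the Exp(n) waiting time to the next
  (uncounted) event so every terminal branch is positive, and pre-crown
  time is excluded.
* **Traits**: Brownian motion, root value 0, variance sigma^2 per unit
  branch length; oracle-tested against the closed-form BM covariance
  (sigma^2 x shared root-to-MRCA path). For the *filtering* trait the
  scenarios use an early-burst variant (instantaneous rate
  sigma^2 exp(-2t)): on trees of this size, plain tip-level BM leaves most
  trait variance on terminal branches, so trait similarity barely tracks
  clade membership and no trait-based filter can produce detectable
  phylogenetic selection; concentrating variance at deep splits restores
  the niche conservatism that selection scenarios require.
* **Selection scenarios**: each sample is colonised by a fixed number of
  occupants (default 10% of the pool) drawn without replacement with
  probability proportional to a Gaussian filter
  exp(-(trait - env)^2 / (2 width^2)) (width 0.15 trait-sd), then given
  Dirichlet-distributed abundances (evenness mass 2 per occupant) and
  multinomial reads. The occupancy + drift construction is essential:
  deterministic filter weights alone make same-optimum samples
  compositionally identical, and identical communities have a degenerate
  betaMNTD null (tip shuffling moves both members of every shared taxon
  together). Heterogeneous selection anchors four strongly contrasting
  optima at tip trait values near the 5th/35th/65th/95th trait quantiles;
  homogeneous selection anchors one optimum on a tip whose trait
  neighbourhood is both well populated and phylogenetically tight — a
  filter selecting a sparse or convergent trait band exerts no meaningful
  phylogenetic selection.
* **Dispersal scenarios**: trait-blind patch pools (one per group,
  lognormal patch effects) mixed with the regional mean pool at migration
  rate m (0.02 for dispersal limitation, 0.98 for homogenizing dispersal),
  then multinomial reads.
* **Drift**: every sample's composition is an independent Dirichlet draw
  around one shared pool (concentration 100), then multinomial reads.

**What validation shows.** With 200 taxa, 16 samples, 1,000 reads and 999
randomizations — sizes chosen so a full five-scenario, 20-replicate
recovery run completes on one CPU in minutes — the modal inferred process
matches the planted process in well over 60% of replicates for the
selection and dispersal scenarios, and under drift over 70% of pairs keep
|betaNTI| <= 2. Two caveats. First, the drift scenario's pair-level RCbray
tends toward dispersal limitation rather than drift: Dirichlet pool drift
creates more between-sample turnover than the Raup-Crick null's
common-pool reassembly, so "drift" in the RC sense (|RC| <= 0.95) is a
narrow target; the drift scenario is therefore validated on its betaNTI
behaviour, which is the defining signature the partition uses first.
Second, recovery percentages are deliberately modest: the betaNTI signal
depends on tree shape and clade structure, and individual replicates near
the +-2 threshold can fall either way. Passing these tests shows the
machinery is correct and the planted signals are detectable at realistic
effect sizes; it does not show that real stone-surface communities meet
the scenarios' assumptions (no compositional biases, perfect phylogeny,
single-habitat groups).

## Numerical choices and degenerate inputs

* All randomness flows through `numpy.random.Generator` seeded explicitly;
  per-pair Raup-Crick streams are spawned from a single `SeedSequence` so
  results are independent of pair evaluation order.
* betaNTI matrices are symmetrised (0.5(Z + Z')) to remove floating-point
  asymmetry from the shared null stream.
* Distance matrices validate symmetry to 1e-12 and a zero diagonal;
  proportions columns must sum to 1 within 1e-9.
* Empty samples, all-zero taxa vectors, singleton groups, sub-depth
  samples, and taxa missing from the tree all raise or are dropped with a
  logged warning naming the offender, as documented per function.
* Pipeline runs write a manifest echoing the effective configuration;
  identical config + seed reproduces the report byte-for-byte.

## Known limitations

* The null models assume integer counts (Raup-Crick) and a one-to-one
  taxon-tip mapping; externally normalised tables must be rarefied or
  rounded upstream.
* PERMANOVA is one-way only; no nested or multi-factor designs, no
  restricted permutations.
* The DOC implementation fits one point cloud per table; within/between
  group DOC variants are out of scope.
* The co-occurrence network intentionally reproduces the raw-threshold
  convention (|r| > 0.75, p < 0.001, uncorrected); the BH-FDR option is
  provided but off by default, and compositionality-aware estimators
  (e.g. SparCC-type) are out of scope.
* NMDS ordination is not implemented; the Bray-Curtis matrix is exported
  for external ordination and plotting.
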