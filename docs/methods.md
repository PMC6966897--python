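# Methods

## The model

A genomic locus binned at 5 kb is modeled as a connected, self-avoiding
bead chain: each bead represents 5 kb of 11-nm chromatin fiber, consecutive
beads sit at a fixed 30-nm center-to-center bond, no two beads approach
closer than the 11-nm fiber diameter, and the chain is confined to a sphere
whose radius preserves a constant base-pair density,

    r = (3 L / (4 pi rho))^(1/3),

with L the locus length in bp and rho = genome size / nuclear volume
(defaults: 6.2 Gb diploid genome, 7-um nuclear diameter, giving
rho ~ 0.035 bp/nm^3; both constants are configuration, the formula is
fixed). Two beads are *in contact* when their Euclidean distance is at most
80 nm, a cross-linking-range threshold. The bond length is a declared
constant: the source measurements fix only the bead size, fiber width and
contact threshold, so the 30-nm step (between the fiber diameter and the
contact range) is the single free geometric choice, kept explicit in
`PolymerParams`.

## Chain-growth sampling

Ensembles are generated by sequential Monte Carlo chain growth. At each
step, 50 candidate directions are drawn uniformly on the sphere of radius
`bond_length`; candidates violating confinement, self-avoidance, or any
active proximity constraint are discarded; one survivor is chosen uniformly
and the chain accumulates a Rosenbluth-style log-weight
`log(n_valid / n_candidates)`, so that weighted averages target the uniform
distribution over feasible chains. Every 10 beads, systematic resampling is
applied whenever the effective sample size falls below half the population
(weight-enrichment "deep sampling"); resampling also recycles dead-ended
chains. Chains still dead after the final checkpoint are regrown in
additional rounds (up to `max_restarts`); weights are normalized within a
growth round before rounds are pooled, a small approximation that matters
only when late dead-ends occur.

Constrained ensembles condition the same process on a set of required
contacts. A constraint (i, j) becomes active when bead max(i, j) is placed
and is enforced exactly; while growing an intermediate bead b (i < b < j),
a look-ahead prunes candidates that leave the tip farther than
`threshold + (j - b) * bond` from bead i, the distance the remaining
contour could still close. Constraint satisfaction is a hard invariant of
every returned conformation, not a statistical one.

The uniform-sampling property is validated against an independent oracle:
free growth with rejection (accept only feasible chains), which draws
exactly uniformly at small bead counts.

## Specific pairwise contacts

Measured Hi-C counts are quantile-normalized onto the contact-frequency
scale of the random ensemble (rank mapping onto the sorted null frequency
distribution; ties share averaged targets). The null over random contact
frequencies is a Bag of Little Bootstraps: each outer replicate draws
ceil(n^0.7) conformations without replacement and multinomially resamples
to full ensemble size; the resulting per-pair frequencies are pooled per
genomic distance. A pair's p-value is the add-one proportion of pooled null
frequencies at its distance reaching its normalized frequency;
Benjamini-Hochberg FDR at 0.05 defines the specific set. Pairs within 10 kb
(|i - j| <= 2 bins) are never tested: at 5-kb bins they are dominated by
chain connectivity.

The pooled-per-distance null is conservative by construction (measured
values are full-ensemble means; replicate values carry bootstrap noise),
and the pipeline default of 10,000 outer replicates keeps the p-value floor
1/(1 + pool) below the rank-1 BH threshold on a 100-bin locus; the
function-level desk default of 1,000 replicates is adequate for small loci
and diagnostics.

Coarse-graining clusters the specific pairs in (i, j) index space
(average-linkage hierarchical clustering, Chebyshev metric), cuts the tree
at round(0.05 N) clusters, and keeps per cluster the member with smallest
p-value (ties: larger normalized frequency, then lexicographic order). The
5% retention is a configuration parameter.

## Knock-in dependency inference

For every retained contact, the ensemble is refolded with that single pair
constrained; per-pair one-sided p-values compare the perturbed frequencies
to the distance-matched bootstrap null, and BH-significant positive shifts
become candidate dependency edges. Edges are kept only when they point down
a frequency-ranked total order of the retained contacts (larger normalized
Hi-C frequency first, ties lexicographic), which makes the result acyclic
by construction — a deterministic, data-driven resolution of mutual
upregulation.

Geometrically infeasible contact combinations are detected two ways: a
metric pre-check (shortest-path closure of distance upper bounds from
contour, confinement and constraints, contradicted by the rigid bond length
or the excluded-volume floor) and persistent dead-ending of constrained
growth across all chains and restarts. Detected subsets become *forbidden*
sets; the membership test is superset-closed, so any state containing a
forbidden subset is excluded without re-simulation. With the default
geometry (80-nm threshold, 30-nm bonds, 11-nm fiber), proximity-only
constraint sets at pair/triple order are essentially always satisfiable;
forbidden sets arise in tighter geometries (excluded-volume packing).

## Deconvolution

Each of n_cells latent cells carries a binary state over the M retained
contacts. The prior per cell scores an active contact by its base log-odds
logit(f_j), adds log(prior_boost) when at least one dependency parent is
active (default boost e, one nat), subtracts a sparsity penalty per active
contact (default 0.1), and assigns probability zero to states activating a
forbidden subset. The likelihood ties the per-contact active counts
k_j = sum_c s_cj to the targets via Binomial(n_cells, f_j); this binomial
form is the declared stand-in for the (unavailable) original likelihood,
with a `concentration` field reserved for a beta-binomial generalization.

Targets f_j derive from the normalized Hi-C with a folding-background
correction: observed = f + (1 - f) * baseline is inverted at each retained
pair (baseline = that pair's null-ensemble frequency), so that a cell
fraction f with the contact pinned plus the random baseline in the
remaining cells reproduces the observed frequency.

Inference is systematic-scan Gibbs over all (cell, contact) sites with
exact full conditionals; a proposed activation completing a forbidden set
has conditional probability zero. On an enumerable toy (M = 2, 2 cells) the
sampler's empirical distribution matches the exactly normalized posterior
(chi-square test in the suite). Initialization draws s_cj ~ Bernoulli(f_j),
rejects forbidden cells up to 10 times, then repairs deterministically by
deactivating the lowest-target member of each violated set.

The `compare_to_naive` report returns the (unnormalized) log-posterior gap
to an independent-Bernoulli model. Because the aggregate-count binomial
dominates a product-Bernoulli score pointwise, the gap's absolute sign is
not meaningful; the informative quantity, which the suite asserts, is its
*contrast* between genuinely dependent states and independent states with
matched marginals.

## Reconstruction and validation metrics

Every sampled cell state is refolded into `folds_per_cell` conformations
(50 at production scale; infeasible cells are retried 3 times, then dropped
with a logged count). Simulated Hi-C is the weighted contact frequency over
all folds, cells weighted equally. Agreement with the input is reported as
Pearson correlation over the upper triangle with the first two diagonals
excluded, and as a distance-corrected correlation: the pair-count-weighted
mean of per-genomic-distance Pearson correlations (strata with fewer than 3
pairs or zero variance are skipped). The latter is a deliberately simple
stratified correlation, not a reimplementation of the published
stochatic-kernel variant ("SCC-lite" in the logs).

Domain structure is summarized by mean (or single-cell) pairwise distance
matrices and a ratio-form boundary-strength profile: at bin i, the mean
cross-block distance between the two flanking windows divided by the mean
within-block distance (window default 10 bins = 50 kb; ends undefined).
Single-cell concordance with external contact lists uses the overlap
coefficient |A n B| / min(|A|, |B|) after lifting external pairs onto the
bin grid.

## Many-body interactions

A k-body interaction (k >= 3) is a clique of the 80-nm contact graph
(igraph enumeration; pairs closer than 2 bins are not edges). Exact 3-body
complexes are all triangles; maximal complexes are maximal cliques. Each
complex carries its principal loop (longest pairwise genomic span, its
endpoints the anchors, ties broken lexicographically) and minor loop
(shortest span). Tallying keys are the exact member triple for 3-bodies
and (size class, principal anchors) for maximal complexes (size classes 3,
4, 5, 6+) — exact member multisets of large cliques are too sparse to
tally.

The null is a bootstrap over the random ensemble (resampling conformations
with replacement, importance-weighted, 1,000 replicates by default),
pooled within strata of (principal span, minor span) for 3-bodies and
(size class, principal span) for maximal complexes, at 5-kb span
granularity. Specific complexes have add-one within-stratum p-values below
0.05 after BH. Empty strata fall back to pooled neighbours within +/-2
span bins (logged).

Landscape summaries map members (or principal anchors) to super-enhancer /
enhancer / promoter labels and report the no-association fraction, the
">=2 SE with promoter" and ">=3 SE" fractions, and anchor label-pair
proportions. Cluster concordance uses the coverage fraction (proportion of
co-capture clusters containing all members, or both anchors) with per-span
medians and a 1,000-replicate label-permutation test on the proportion of
spans where the specific median exceeds the non-specific one.

## Enrichment predictor

Bins are ranked by specific principal-loop participation; the elbow is the
rank maximizing perpendicular distance to the chord joining the extreme
sorted counts. The top 20% of above-elbow bins are *enriched*, remaining
above-elbow bins are discarded as ambiguous, below-elbow bins are *not
enriched*. A 500-tree random forest is trained with balanced per-tree
bootstraps (equal positives and negatives per tree); generalization is
reported as the balanced (class-averaged) out-of-bag error — the plain OOB
rate is still majority-dominated under bootstrap resampling and would sit
near 0.25 on imbalanced pure noise — and as mean held-out ROC AUC over
stratified 5-fold cross-validation with z-scoring fitted on training folds
only. Feature importances are reported both as mean decrease in accuracy
(per-tree OOB permutation) and mean Gini decrease.

## The synthetic test world

`make_fixture` builds a complete study with known truth: a 100-bin (500-kb)
locus, M = 12 planted contacts, a planted dependency mechanism, 200 cells,
10 folds per cell. Mechanism children are placed genomically nested inside
their parents' loops — the physical situation in which closing the parent
loop promotes the child contact, i.e. exactly what knock-in simulations
detect. Planted loops sit at TAD/sub-TAD spans (roots span 1/4 to 4/5 of
the locus; children 40–85% of the parent span) with strong activation
probabilities (0.8 for roots; 0.35 / 0.95 for children without / with an
active parent): the regime of strong, frequently co-active long-range
loops at highly transcriptionally active, super-enhancer-rich loci, which
yields a few hundred specific calls on a 100-bin locus so that 5%
coarse-graining retains a driver set on the scale of the planted mechanism.
Anchors are sharp by default (an optional anchor-fuzz patch mode exists but
is off): the ground truth then lies exactly in the model class the
pipeline fits, so closure failures indicate pipeline defects rather than
model misspecification.

What the fixture does **not** emulate: sequencing noise (ligation
artifacts, coverage and mappability bias), raw-count statistics (the
target matrix is already on the frequency scale; quantile normalization
makes the pipeline insensitive to this), compartment-scale block structure,
and anchor fuzziness across cells. Passing tests therefore demonstrate
method correctness under the model's own assumptions at desk scale, not
robustness to the full noise structure of experimental Hi-C.

Derived artifacts: annotations label planted anchor bins (SE/P/E cycling);
proximity clusters are sliced from truth conformations around a random
seed bead at a 150-nm capture radius with one indirect expansion hop and
random member subsampling (clusters may contain non-pairwise-proximal
members, as in ligation-cluster experiments); feature tracks plant a
+1.5 z-unit signal for anchor bins on 3 of 8 tracks.

## Problem sizes and numerical choices

Desk-scale defaults (used by the test suite and the acceptance script):
2,000 null chains, 10,000 bootstrap replicates, 2,000 chains per knock-in,
200 cells x 2,000 sweeps (500 burn-in), 10 folds per cell; a full pipeline
run takes a few minutes on one CPU. Production-scale settings from the
modeled study — ~400,000 null conformations, 25,000 reconstructed folds
(500 cells x 50), 75,000-polymer many-body nulls — are plain parameter
changes. Degenerate inputs fail loudly: constant matrices (quantile ranks
and correlations undefined), constant participation counts (no elbow),
single-class training labels, empty ensembles and empty cluster files all
raise. Target frequencies are clamped to [1e-6, 1 - 1e-6] in likelihoods;
all tie-breaks (cluster representatives, principal anchors, DAG ordering)
are deterministic and documented above. Every stochastic stage takes an
explicit seed and logs it together with input sizes and result counts.
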