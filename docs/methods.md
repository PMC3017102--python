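# Methods

This note documents the statistical procedures, the synthetic-study
generator, the numerical choices and the known limitations of the package.
It states no empirical result beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## Data model

The analysis operates on four aligned objects:

* **RegionOntology** — a rooted part-of tree of named regions. The children
  of the root act as the major divisions; leaf selection keeps only regions
  with no measured subpart, because a parent shares signal with its own
  parts by construction.
* **ConnectivityData** — a directed binary adjacency over the full region
  universe (*w* regions) plus, for the *x* regions that also carry
  expression, the x-by-w incoming and outgoing profile submatrices. Absence
  of a documented connection is treated as no connection. Regions with an
  all-zero profile in a direction are excluded from that direction's
  analysis set but stay in the universe.
* **ExpressionMatrix** — image series by region, natural-log expression
  energy, NaN for missing. A gene may own several independent series.
* **SimilarityMatrix** — square symmetric region-pair matrix with a kind
  tag (`correlation`, `distance`, `similarity`, `residual`) that records
  the orientation convention.

Harmonization coarsens an edge list by **up-propagation** (each endpoint is
replaced by its nearest ancestor inside the target region set; unmappable
endpoints drop the edge; duplicates collapse; self-loops are removed — the
operation is idempotent) and reconciles parcellation mismatches by
**virtual regions** whose profile is the element-wise OR of their members.

## Mantel machinery

* Mantel r is the Pearson correlation of the two upper triangles,
  restricted to pairs observed in both matrices (expression correlations
  may be missing where too few complete series overlap).
* The permutation null jointly permutes one matrix's rows and columns;
  the one-sided (greater) p-value uses the add-one rule
  (k+1)/(n_perm+1), which keeps p strictly positive. An exhaustive mode
  enumerates all n! label permutations (including the identity) for small
  n and reports the exact tail fraction; sampled and exhaustive p agree
  within Monte-Carlo error in the tests.
* The partial Mantel test residualizes both matrices on the covariate by
  simple one-covariate OLS over region pairs and permutes the residualized
  second matrix (method of residuals). This scheme is known to be mildly
  liberal under strong autocorrelation; the spatial-confound acceptance
  test bounds its realized rejection rate at twice the nominal level under
  the generator's study conditions.
* The correlogram bins off-diagonal distances into equal-width classes
  (auto: Sturges on the pair count), computes the Mantel r between the data
  matrix and each class's 0/1 indicator, signs it so positive means
  within-class similarity excess, and corrects the two-sided per-class
  permutation p-values progressively (class k corrected for the k tests
  performed so far; Holm by default, progressive Bonferroni and standard
  BH switchable). Empty or all-covering classes are dropped and recorded.

## Backward elimination

The optimizer maximizes the Mantel correlation between the expression
correlation matrix of the *active* series set and a fixed target —
normally the residualized (proximity-controlled) connectivity correlation,
which is computed once up front and held fixed while expression
correlations are recomputed each iteration. Each iteration scores every
active series by the Mantel r obtained without it and removes the series
whose removal maximizes r; ties break to the lexicographically smallest
series id; elimination runs down to `k_min = 3` series, the smallest count
for which pairwise Pearson correlations are non-degenerate.

Leave-one-out scoring is exact, not approximate: the engine maintains, per
region pair, the count, sums, sums of squares and cross-products over
active series in which both regions are observed, so removing a candidate
is a vectorized subtraction and pairwise-complete semantics are preserved
under missing data. Pairs whose downdated statistics become degenerate
(fewer than `min_overlap = 3` complete series, or zero variance) are
treated as missing for that evaluation. Totals are recomputed from scratch
every 32 removals to bound floating-point drift; the acceptance suite
verifies the full removal path against an independent from-scratch
reimplementation to 1e-9.

The **peak set** is the series active at the global maximum of the r
trajectory (first maximum on ties; the pre-removal state is index 0).
Ranking: terminal survivors tie at rank 1, then removed series in reverse
removal order. **High-confidence genes** have at least two independent
image series inside the peak set. The **shuffled-expression control**
reruns the optimizer on copies of the expression matrix with permuted
region labels and reports the distribution and maximum of the peak
correlations, calibrating how far greedy selection can push the statistic
on signal-free data.

## Synthetic-study generator

The generator fabricates what the real inputs of such a study look like at
desk scale, with ground-truth labels per image series. Defaults define the
study conditions used throughout the tests.

* **Ontology**: balanced tree, `branching = 8` groups per level,
  constructed deterministically. The root's children are the divisions.
* **Coordinates** (µm): division centers are isotropic Gaussian draws with
  sd `division_spread = 4000`, redrawn (bounded tries) until each is at
  least one `division_spread` from the others — major divisions occupy
  disjoint territories; a leaf sits at its division center plus isotropic
  jitter with sd `spatial_cluster_scale = 300`.
* **Connectivity**: each ordered pair connects independently with
  probability `logistic(31 − 4·log d)` (plus an optional
  distance-independent long-range floor, default 0). The steep slope puts
  the transition near 2.3 mm: within-division pairs connect with
  probability ≈ 0.85–1, cross-division pairs rarely. This mirrors the
  strong distance rule of real connectomes and is essential for the
  analysis to have anything to find: with a shallow rule, binary profile
  correlations are dominated by Bernoulli noise and carry almost no
  structure.
* **Expression** (log-energy units): every gene owns a deterministic
  pattern; each series is the pattern plus fresh iid N(0, `noise_sd = 1`)
  noise, so duplicate series (`duplicate_rate = 0.1` of genes get a second
  series) agree only through the pattern. Patterns by archetype:
  *background* — zero; *spatial* — a Gaussian-process draw with covariance
  `noise_sd²·exp(−d/ℓ)`, `ℓ = gp_length_scale = 250` µm; *marker* —
  `marker_effect = 3` at one random region (a Pcp2-like restricted
  pattern); *pair* — `pair_effect = 3` on the endpoint union of a dense
  connected edge subset of up to `n_pair_edges = 15` edges (a Pgrmc1-like
  pattern: clusters of interconnected regions co-express the gene).
  Clusters are grown edge-wise from a seed edge, absorbing edges internal
  to the current node set before expanding to the outside region best
  connected into it, confined to one division, and the seed division
  rotates round-robin so the planted clusters tile the connectome.
  A `missing_rate = 0.03` fraction of cells is blanked completely at
  random. All stages draw from streams spawned off one master seed;
  identical configs give byte-identical datasets.

Three parameter choices deserve justification because naive alternatives
silently break the benchmark. First, the steep distance rule (above).
Second, division-center separation: without it, occasional overlapping
divisions produce connectivity blocks with no profile structure, and any
planted gene in such a division is invisible to the objective. Third,
dense division-confined clusters with rotation: scattered-edge clusters
mark regions that share no connectivity-profile structure (the planted
signal is then orthogonal to the objective), clusters that straddle
division boundaries are penalized by the variance they add to
high-similarity boundary pairs, and clusters clumped into one division are
mutually redundant, so each one's marginal leave-one-out contribution
drowns in noise. The GP length scale for spatial genes is set well below
the division diameter so that the spatial confound is strong enough to
mislead the plain Mantel test while remaining (approximately) linearly
explainable by log-distance, which is what the partial Mantel correction
models.

### What the generator does and does not emulate

It reproduces: nested nomenclature, spatially clustered regions,
distance-dependent directed connectivity with region-level binary edges,
spatially autocorrelated background expression, duplicate image series,
missing-at-random cells, and two informative-gene archetypes. It does not
simulate: ISH image artifacts, expression-level baselines per gene,
non-random missingness, curation bias in which connections get reported,
reciprocal-connection excess, or rat/mouse anatomical differences.
Passing tests therefore show that the statistics behave correctly under
the stated generative assumptions — calibrated nulls, effective
deconfounding, recoverable planted signal — not that real atlas data meet
those assumptions.

## Downstream statistics

Connection degree is the sum of a region's propagated incoming and
outgoing connections. Degree-expression screens use Spearman's rho with
average ranks for ties and a Bonferroni multiplier equal to the number of
series actually tested. Group comparisons (connected vs unconnected pairs,
subset vs all gene-gene correlations) default to Welch's unequal-variance
t-test, switchable to pooled. Over-representation analysis filters
annotation groups to 5–200 measured members, computes upper-tail
hypergeometric p-values (verified against exact combinatorial enumeration)
and controls FDR across groups by Benjamini-Hochberg; the default query is
the peak set collapsed to genes.

## Numerical choices and degenerate inputs

* Pairwise Pearson correlations clamp to [−1, 1] and are symmetrized
  against rounding; `min_overlap` defaults to 10 series for reported
  expression-correlation matrices and 3 inside the optimizer.
* Distances of coincident centroids clamp to a 1 µm floor before log.
* A constant covariate degrades residualization to centering (warning);
  constant pair vectors make the Mantel statistic undefined and raise a
  `StatisticError` rather than returning NaN.
* Mantel p-values are never zero by construction; exhaustive-mode tie
  detection uses a 1e-12 tolerance.
* Problem sizes in the validation suite (up to 40 regions, 200 genes,
  hundreds of replicate simulations at 20 regions × 100 genes, 199–999
  permutations) were chosen so the full suite characterizes calibration,
  deconfounding and recovery at desk scale with comfortable statistical
  margins.

## Limitations

* The partial-Mantel residual-permutation scheme does not achieve exact
  nominal level under strong autocorrelation; conclusions near α should
  rely on the correlogram and effect sizes, not the partial p alone.
* Greedy backward elimination overfits by design; peak correlations must
  be read against the shuffled-expression control, and peak-set membership
  of any single series is unstable between near-tied solutions.
* Binary connectivity ignores projection strength and report counts;
  profile correlations treat all partners equally.
* Cross-nomenclature mapping is consumed as a file, not computed; the
  package has no opinion on naming disputes between atlases.
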