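# Methods

This note documents the models implemented in `devatlas`, the defaults
that matter, the numerical conventions at edge cases, and what the
synthetic benchmarks do and do not demonstrate.

## Pseudobulk aggregation and dynamic thresholding

Single-cell UMI counts are normalized by a per-cell size factor, the
cell's total UMI count divided by the geometric mean of all totals; the
factors therefore have geometric mean 1 and equal-depth datasets pass
through unchanged. A cell with zero total is an error (it cannot be
normalized), reported by cell index. Per neuron class we record

- the **detection proportion** `p[g, k]`: the fraction of cells of
  class *k* with at least one raw UMI for gene *g* (detection is
  defined on raw counts; since size factors are positive this equals
  the fraction of nonzero normalized entries), and
- the **TPM**: the mean normalized expression over the class's cells,
  rescaled so every class column sums to 1,000,000 (relative tolerance
  1e-6 is asserted in tests).

Before thresholding, genes detected in more than 1% of cells of *every*
class are exempted as ubiquitous, and genes under 2% in every class are
removed as unexpressed. With these defaults the two rules are mutually
exclusive in practice; if a caller supplies parameters that make them
overlap, the ubiquitous rule wins and a warning is logged rather than
crashing.

The dynamic threshold at fraction *f* gives gene *g* the cutoff
`c_g = f * max_k p[g, k]`. TPM is set to 0 where `p[g, k] < c_g`
(strictly below: a class sitting exactly at the cutoff keeps its
continuous value). Consequences that the tests rely on: thresholding is
idempotent; the zeroed set grows monotonically with *f*; and every
output entry is either 0 or the unthresholded TPM. A gene with maximum
proportion 0 cannot carry a cutoff and is rejected (the prefilter
should have removed it); the calibration routine treats such genes as
removed so they are simply called negative everywhere.

### Calibration

Thresholded expression on the curated ground-truth genes is binarized
(TPM > 0) and scored against the binary truth:
TPR = TP/(TP+FN), FPR = FP/(FP+TN), FDR = FP/(TP+FP), with FDR defined
as 0 when nothing is called positive so the grid never contains NaNs.
Because the per-gene cutoff is a fraction of the gene's own maximum,
calls shrink monotonically in *f* and TPR and FPR are non-increasing
across the grid — a property asserted, not assumed.

The default grid is 272 evenly spaced fractions on [0, 1] inclusive;
the count is configurable and nothing downstream depends on the
spacing. Point estimates are computed directly on all ground-truth
genes and are independent of any resampling. Confidence intervals
(default 95%) come from a stratified bootstrap over ground-truth genes:
genes are binned into quartiles of their positive-class fraction (the
share of classes where the truth is 1), resampled with replacement
within bins (bins with fewer than two genes are merged into a neighbor
with a warning), with `n_boot = 5000` draws by default. Stratifying on
expression breadth keeps each replicate's truth composition close to
the original, which is the property the calibration depends on.
Intervals are bias-corrected and accelerated (BCa): the bias term z0 is
the normal quantile of the bootstrap CDF at the point estimate
(midrank convention at ties, clipped away from 0 and 1), and the
acceleration comes from the skew of leave-one-gene-out jackknife
replicates. A degenerate bootstrap distribution collapses the interval
to the point estimate, and intervals are widened if necessary to
bracket the point estimate, so "CI contains point" holds uniformly.
`scipy.stats.bootstrap` does not support BCa for multi-sample
(stratified) statistics, so this interval is implemented here directly.

`select_levels` maps target (TPR, FPR, FDR) triples to grid fractions
by minimal summed absolute deviation, breaking ties toward the smaller
(less stringent) fraction.

## Cross-stage differential expression

Two stage-level datasets are merged over shared genes and **jointly**
size-factor normalized before log1p transformation, so the two stages
share one normalization; each shared neuron class is then tested gene
by gene with a two-sided Wilcoxon rank-sum test. When the number of
group assignments C(n1+n2, n1) is at most 200,000 the p-value is exact
(enumeration of the rank-sum distribution with midranks for ties);
otherwise the tie-corrected normal approximation is used without a
continuity correction, so identical groups give p = 1 exactly. The
average log2 fold change is computed Seurat-style on the de-logged
scale, `log2(mean(expm1(a)) + pc) - log2(mean(expm1(b)) + pc)` with
pseudocount `pc = 1` by default (surfaced as a parameter because
reference implementations vary); group *a* is the older stage, so
positive values mean higher expression in the older stage. BH
adjustment is applied within each neuron class across genes.

The retention filter keeps records with adjusted p < 0.05,
|avg_log2fc| ≥ 1, detection in strictly more than 10% of cells and in
strictly more than 5 cells of the higher-expressing stage, and drops
genes on a caller-supplied exclusion list (e.g. loci overexpressed in
reporter strains). Filtering is a pure subset operation and idempotent.

Stability and Jaccard use binarized detection across classes present at
both stages: stability = both/(both + young-only), undefined when a
gene is detected in no class at the younger stage; Jaccard =
both/either, undefined when detected at neither stage. The two metrics
coincide exactly when no old-only classes exist.

Fold enrichment is (k/n)/(K/N) with a one-sided Fisher exact test for
over-representation (equal in law to the hypergeometric tail) and an
optional Bonferroni factor for the number of categories in a batch.
The broad-downregulation rule selects genes differentially expressed in
strictly more than 10 classes in the larval comparison (≥ 75% higher at
the younger larval stage) *and* in strictly more than 40 classes in the
embryo comparison (≥ 75% higher in the embryo); both count thresholds
are strict and the fraction thresholds inclusive.

## TF regulon activity

For one neuron's fold-change vector y over genes, the design matrix is
an intercept plus every TF's signed regulon weight column, fit jointly
by OLS; the activity score of a TF is its coefficient t-statistic with
a two-sided p on the residual degrees of freedom. The intercept absorbs
any constant shift in y, so scores are invariant to recentering.
Collinear columns are dropped greedily (never the intercept) with a
warning and the affected TFs reported as untested — dropping keeps the
estimator an exact linear model where ridge regularization would change
the statistic. Degenerate fits are handled explicitly: a zero residual
with a zero coefficient scores t = 0, p = 1 (an all-zero fold-change
vector carries no evidence), while a zero residual with signal gives an
infinite t and p = 0. Significance requires BH-adjusted p < 0.05 within
the neuron *and* detection of the TF transcript in that neuron at one
or more of the compared stages.

## Maturation index

The index is the Euclidean distance of each cell from a caller-supplied
baseline coordinate in the 2-D embedding. The baseline is deliberately
not chosen algorithmically: it marks the branch point between the
progenitor cluster and the post-mitotic cells, a judgment made on the
embedding, and automating it would invent method. The Manhattan
distance is computed and reported for completeness but not used
downstream. Gene correlations are Pearson on log2(x+1)-transformed
expression (log-scale expression is the convention for these displays;
raw/linear is available via a flag), with Bonferroni correction over
the genes actually testable — constant genes have undefined correlation
and are excluded from the denominator rather than diluting it.

## Neuropeptide networks

Interaction tables are filtered to potency EC50 ≤ 500 nM (inclusive)
and to pairs whose ligand and receptor genes are detected somewhere at
*every* stage being compared, so cross-stage comparisons use one common
pair catalog. Proximity is same-bundle at short range and same-region
(head / midbody / tail) at mid range, symmetric with unit diagonal.
Each pair's layer is `A(i,j) = NPP(i) x GPCR(j) x reachable(i,j)`;
self-edges are retained by default since the product formula permits
autocrine signaling (a flag removes them). The weighted network is the
elementwise sum of layers, so a weight counts the pairs supporting an
edge. Degrees are computed on the binarized directed network: in-degree
counts distinct senders, out-degree distinct receivers.

Topology classes use expression breadth with an inclusive boundary:
≤ 50 expressing neurons is "restricted". When a class-size table is
supplied, breadth counts individual neurons (the natural reading of a
whole-nervous-system cutoff); otherwise it counts classes. Both
restricted = local, both broad = pervasive, restricted ligand + broad
receptor = broadcaster, the converse = integrative.

Cross-stage comparison classifies every ordered class pair carrying an
edge in either stage by its supporting pair sets: identical sets,
overlapping sets, disjoint sets (edge conserved but molecularly
rewired), or stage-specific. The categories partition the edge union,
and conserved fractions are reported against per-stage denominators
because the two stages generally have different edge counts.

## Connectome-conditioned enrichment

Cell-level adjacency matrices are collapsed by summing member-cell
entries within each transcriptionally defined class (left/right pairs
merge into one class). To suppress single-animal idiosyncrasies, an
entry survives only if the corresponding class-level entry is nonzero
in every confirmer reconstruction. Contacts are treated as undirected
(symmetrized by max) when grouping neighbors; synapses stay directed.

For a focal neuron, candidate genes are tested with Welch's
unequal-variance t-test (Welch–Satterthwaite degrees of freedom,
two-sided p, implemented in closed form and cross-checked against
scipy in tests) between per-class thresholded TPM values of the two
groups — contacted vs non-contacted classes, or (conditioning on
contact) synaptic partners vs adjacent-only classes, separately for
presynaptic inputs and postsynaptic outputs. Focal neurons with fewer
than three synaptic partners in the queried direction are skipped.
Both groups exclude the focal neuron itself. The effect size is
`log2((mean_in + 1e-5) / (mean_out + 1e-5))`; the pseudocount keeps a
zero-mean group finite (0.5 vs 0 gives ≈ 15.61). Zero-variance groups
with equal means score t = 0, p = 1. BH adjustment runs within each
focal neuron over the genes actually tested — genes expressed in no
class of either group are flagged untested and excluded from the
denominator, a choice recorded here because the adjustment universe is
otherwise ambiguous; tests verify the significant set is unchanged by
pre-removing never-expressed genes. Binding-partner annotation marks a
result when any protein-interaction partner of its gene (including the
gene itself for homophilic pairs) is detected in the focal neuron.

## Synthetic data

The generators define the study conditions for every test; they are
deterministic given a seed.

- **Counts**: detection of gene *g* in a cell of class *k* is
  Bernoulli with the planted probability `detection_prob[g, k]`;
  conditional on detection the count is a zero-truncated negative
  binomial with mean `nb_mean` (default 2.0, matching a low-UMI
  regime of a few hundred UMIs per cell over a few hundred expressed
  genes) scaled by a per-cell log-normal library factor
  (`libsize_sigma = 0.3`) and shape `nb_dispersion = 1.0`. Making
  detection exactly Bernoulli — a hurdle form of the NB/library model —
  is deliberate: every calibration analysis conditions on detection
  proportions, and this form makes the planted quantity identifiable
  without bias from library-size variation, which still drives count
  magnitude. The generators do not emulate doublets, ambient RNA or
  batch effects, so calibration results here quantify the procedure's
  behavior under its own assumptions, not robustness to those
  artifacts.
- **Ground truth** is `detection_prob >= p_on` with an inclusive
  boundary (fixed so fixtures are reproducible), restricted to a
  designated gene subset.
- **Lineages** place a progenitor cluster at the origin (planted
  maturation exactly 0) and branches radiating at integer maturation
  steps; planted genes change by an integer slope per step with
  optional Gaussian noise, so at zero noise expression is exactly
  linear in the planted distance and Pearson recovery is ±1.
- **Connectomes** assign each class one bundle (bundles nest within the
  three regions), draw symmetric Bernoulli contacts, and promote each
  contact to a directed synapse with probability `synapse_frac`, so
  synapse ⊆ contact holds by construction. Planted enrichment adds a
  fixed effect to a gene's expression (baseline N(5, 1) clipped at 0,
  on the normalized scale) in the synaptic-partner set of a designated
  focal class, with the truth recorded.

## Benchmark problem sizes

The test suite's end-to-end checks use: a 100-gene x 10-class fixture
with 100 cells per class and 40 ground-truth genes for calibration
(full 272-point grid, 1,000 bootstrap draws in the grid-wide test;
5,000 remains the library default); 300 genes with 20 planted 4-fold
changes and 100 cells per group for DE recovery; 100 replicates of a
200-gene x 8-TF regulon for activity ranking; and 40-class connectomes
for the 600-test type-I check and 50-replicate power check. These sizes
were chosen as the smallest at which the binomial error bars on the
checked rates are meaningfully tight.

## Known limitations

- The calibration bootstrap stratifies on positive-class fraction;
  other stratification variables (e.g. expression level) would change
  the intervals, not the point estimates.
- The exact composition of a published threshold grid may differ from
  the even spacing used by default; the grid is a parameter.
- Rank-sum p-values switch from exact enumeration to the normal
  approximation at an enumeration-size limit, not at a fixed n; near
  the crossover, borderline p-values can differ slightly between the
  two regimes.
- Mesoscale module clustering of the neuropeptide network and degree-
  convergence summaries are out of scope, as are all upstream
  processing steps (droplet calling, ambient-RNA correction, embedding,
  cluster annotation): embeddings and class labels are consumed as
  inputs.
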