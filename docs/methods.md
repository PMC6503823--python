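# Methods

This note documents the model implemented by `lmaland`, the conventions and
defaults chosen where several reasonable options existed, and the limits of
what the synthetic-data tests demonstrate.

## Scope and assumptions

The framework scores the *local malignant adaptation* (LMA) of a genetic
clone: its potential to progress malignantly in a given tissue context,
estimated purely from occurrence patterns of clonal driver alterations
across a cohort of that tumour type. Two assumptions underpin everything:

1. tumours are of monoclonal origin, so the clonal alterations of a sample
   describe the genotype of its initiating clone; and
2. initiating clones of one tumour type are all similarly adapted to their
   tissue, which licenses both the parameter definitions (observed vs
   expected occurrence across replicate outcomes) and the weight-inference
   objective (minimise score dispersion within a cohort).

The model deliberately ignores alteration ordering, epigenetics, phenotypic
context and tumour–microenvironment interplay; it measures malignant
potential, not proliferative advantage in normal tissue.

## From calls to matrices (`core_data`)

* A mutation is **clonal** when the 95% CI of its cancer cell fraction
  includes 1. Panel data without CCFs fall back to normalised MAF > 0.8
  (strict). Multi-region lesions call a mutation clonal when ≥ 75% of the
  regions do. Copy-number alterations are always treated as clonal, as no
  CNA clonality estimator exists.
* Gene-level CNA calls compare the covering segment's copy number to sample
  ploidy: deviation ≥ +0.6 is a gain, ≤ −0.6 a loss, after dropping
  segments with fewer than 10 probes. When a gene spans a breakpoint the
  segment covering the gene *midpoint* decides — a deterministic stand-in
  for the single-locus intent, chosen because no principled alternative is
  available from occurrence data alone. For targeted panels, sample ploidy
  is the exon-count-weighted mean copy number; panel CNA drivers can also be
  called against the normal-sample segment-mean distribution with a
  one-tailed normal test (α = 0.05).
* Alterations are identified as `<gene>_<mut|gain|loss>`; multiple clonal
  mutations in one gene collapse to a single incidence. CDKN2A and CDKN2B
  losses are merged into one event (`CDKN2A/B_loss`) *before* driver
  ranking, since their chromosomal adjacency would otherwise fabricate a
  perfect co-occurrence.
* Driver selection keeps candidates with cohort frequency strictly above
  0.5%, ranked by frequency (ties broken lexicographically), top 50.
* Coordinates are 1-based inclusive internally; BED input is converted on
  read.

## The three landscape parameters (`landscape`)

**Selective advantage.** For mutations,
`expected_g = M_total · length_g / Σ length` over all genes with ≥ 1 clonal
mutation (median transcript length in bp), and `SA_g = observed_g /
expected_g`. For gains and losses (scored separately) the expectation is
uniform, `E_total / n_genes`. By default `n_genes` counts the genes with at
least one observed event of that class — the exact analogue of the mutation
definition's "genes with ≥ 1 mutation" universe — which keeps SA centred at
1 for CNAs as well; a retained-driver or genome-wide universe can be passed
instead. SA is scale-free: doubling all counts leaves it unchanged.

**Self-sufficiency.** `mu_d` is the mean of `m_s − 1` (additional retained
drivers) over samples carrying `d`; `mu_overall` pools `m_s − 1` over every
(sample, driver) incidence. `SS_d = mu_overall / max(mu_d, 0.5)`; the 0.5
floor (half an additional driver) bounds SS for drivers that always occur
alone, and such drivers are flagged. `m_s` counts retained drivers only.
Per-driver Mann–Whitney tests of partner counts against the pooled rest
(Benjamini–Hochberg, 0.05) provide descriptive fewer/more-partners flags
that enter no score.

**Malignant epistatic interactions.** The null model treats each sample as
drawing its `m_s` alteration events without replacement from the cohort's
pooled `T` events, of which driver `i` accounts for `k_i`. The marginal
presence probability is `P_i(s) = 1 − C(T−k_i, m_s)/C(T, m_s)` (computed in
log space). The default expected co-occurrence uses the exact pairwise
inclusion–exclusion probability

```
P_ij(s) = 1 − q_i − q_j + q_ij,   q_x = C(T−k_x, m_s)/C(T, m_s),
q_ij = C(T−k_i−k_j, m_s)/C(T, m_s)
```

summed over samples, rather than the product `P_i(s)·P_j(s)`. The two
differ because presence of two alterations within one sample is negatively
dependent under without-replacement draws; the inclusion–exclusion form is
exactly unbiased for a label-permutation null that preserves every
per-sample load, which the test suite verifies by Monte-Carlo (10,000
permutations). The independence approximation remains available as
`method="product"`. Finally `E_ij = (obs_ij + 0.5)/(exp_ij + 0.5)`: the
pseudo-count of 0.5 keeps E finite and strictly positive so product-form
score aggregation can never collapse to exactly zero; both the pseudo-count
and the method are recorded in the landscape's settings. Drivers never
observed in the cohort are excluded with a warning, and the diagonal is
undefined.

## Scoring models and weight inference (`lma`)

Per-driver contributions are summed over the sample's drivers. The
*intrinsic* component is `SA_i·SS_i` (combined models) or separately
weighted `SA_i` and `SS_i` terms (separate models); the *interactive*
component aggregates `E_ij` over the *other drivers present in the same
sample*, as a product (`*_prod`) or mean (`*_mean`). A driver with no
partner contributes a neutral aggregate of 1, which keeps single-driver
samples continuous with the two-driver case at E = 1. An empty driver set
scores 0.

The multiplicative intrinsic form is preferred over an additive one because
SA spans orders of magnitude while SS stays near 1, so addition would let SA
swamp SS.

With cooperative interactions (all `E_ij ≥ 1`) the product-aggregation
models are provably monotone: adding a driver can only scale existing terms
up and append a non-negative term. Mean aggregation is *not* monotone —
adding a weakly interacting driver can dilute a strong pairwise mean — which
is one reason the lattice analyses default to `combined_prod`.

Weights come from the fixed 37-value grid
(0.010 … 100, mirrored around 1; the printed list is canonical and is not
recomputed by formula). The search is exhaustive — 37² combinations for
combined models, 37³ for separate — minimising `sd(F)/median(F)` with the
sample standard deviation (n−1). Combinations with non-positive median are
rejected; samples with zero retained drivers are excluded (the objective is
undefined for them); ties keep the first combination in ascending
lexicographic grid order, making the result deterministic. Numerically, the
standard deviation is taken after subtracting the first score — a
mathematical no-op that keeps identical-score cohorts at exactly zero
dispersion despite floating-point round-off, so the tie-break behaves as
specified. Whether weights multiply inside or outside the per-driver sum is
ambiguous for the separate models' intrinsic terms; they are applied per
driver, consistent with the combined models' structure.

Model diagnostics (`model_comparison`) report the optimal weights, the
objective, the OLS R² of F against driver count (undefined when either is
constant) and the intrinsic-share distribution.

## Repeatability (`repeatability`)

Pairwise Jaccard indices over samples' clonal alteration sets are compared
to 10 randomized matrices in which each sample keeps its load `m_s` but
receives that many distinct alterations uniformly from a configurable
universe (default: the number of distinct alterations ever seen in the
cohort; cohort-scale analyses typically use the ~17,000-gene exome).
Null indices are pooled across randomizations before taking the 95th
percentile (type-7 linear interpolation, used for every quantile in the
package); observed indices are normalised by that percentile and the
percentage strictly exceeding it is reported. Two empty sets have Jaccard 0
by convention. Randomization streams are seeded `seed + r` for
reproducibility.

## Cross-landscape scoring (`cross_landscape`)

A lesion scored in a foreign landscape first drops alterations outside that
landscape's retained drivers, then divides its raw score by the landscape's
*native cohort median LMA* so that values are comparable across landscapes
(the native cohort's median normalised score is exactly 1). The median was
chosen over the mean for robustness to the heavy right tail of LMA scores;
the convention is configurable. Paired comparisons use the two-sided
Wilcoxon signed-rank test (all-zero differences report p = 1), unpaired ones
Mann–Whitney. Ambiguous metastatic sites (e.g. lung) are handled by scoring
under each candidate landscape and reporting both.

## Lattice graphs and trajectories (`trajectory`)

The lattice over the `k ≤ 15` most frequent drivers contains every
non-empty subset (2^k − 1 nodes, held as bitmasks and scored exhaustively
and vectorised — no sampling) plus the unaltered root state; each node of
size m has m in-edges (k·2^(k−1) edges in total, counting root→singleton
edges). Level statistics report the mean and maximum score per subset size
over *all* subsets, reachable or not, since the lattice is defined
combinatorially.

A trajectory starts at any singleton and adds one driver at a time. Given a
threshold (typically the native cohort's median LMA), a node is *alive*
when it scores below the threshold and is reachable from a singleton
through an all-below-threshold chain; a node is *terminal* when it meets
the threshold and is a singleton or has an alive predecessor. Terminal
nodes' offspring are pruned. The report counts unique terminal combinations
by default; optionally each terminal is weighted by its number of
qualifying acquisition orders (counted by dynamic programming over the
alive sub-lattice), since it is a modelling choice whether a combination
reachable by many orders should count more. Enumeration is a single pass
over bitmasks in increasing order and is verified against naive depth-first
chain search for k ≤ 6.

## Synthetic cohorts (`simulate`)

The generator emulates the *statistical structure* of the inputs, not their
biology. Driver presence vectors come from a pairwise binary (Ising-style)
model: fields are `logit(f_i)` of the requested marginals, couplings are
user log-odds, sampled by Gibbs sweeps (burn-in 100, thinning 10 — ample
for ≤ 50 drivers, both configurable; successive thinned draws from one
chain are mildly correlated, which the recovery tests tolerate). With
nonzero couplings the achieved marginals drift from the planted ones; a
drift above 0.15 triggers a warning with the achieved values. Passengers
hit genes proportionally to length at a configurable per-Mb rate (default 2,
half of them clonal). Clonal mutations get CCFs of `1 − |ε|` with
`ε ~ N(0, 0.02)` clipped so the ±1.96σ CI (truncated to [0, 1]) always
includes 1; subclonal decoys get CCF ~ U(0.2, 0.7) with CIs excluding 1.
CNA drivers are emitted as ±1.2 segments around diploid next to a large
neutral baseline segment, so the standard calling rules recover the planted
calls exactly — verified by a round-trip test. Paired benign/malignant
lesions remove a fixed number of drivers from a malignant draw; metastatic
panels draw from the primary site's model and annotate a foreign secondary
site. Everything is integer-seeded and fully deterministic.

Because the generator plants exactly the structure the estimators look for
(independent samples, literal pairwise couplings, well-behaved CCFs,
clean segment geometry), passing tests demonstrate *internal consistency* —
estimators recover what was planted, scores behave as the algebra promises —
not accuracy on real cohorts, where drivers violate pairwise-only
interactions, mutation rates vary per sample and per region, and CCF and
copy-number calls carry correlated errors.

## Default problem sizes

Analyses in the test suite and the reproduction script use cohorts of
n = 150–200 samples with 6–15 drivers, 20 replicate seeds for directional
claims, 10 randomizations for nulls and 10,000 permutations for the
co-occurrence oracle — sizes at which the targeted effects are
well-resolved while the full suite runs in well under a minute per module.

## Known limitations

* The epistasis expectation conditions on observed loads; very dense
  matrices (loads close to the driver count) leave little room between null
  and signal, and planted interactions are then partially absorbed by the
  load conditioning.
* SS is undefined for drivers absent from the cohort and floor-capped for
  always-alone drivers; both are surfaced rather than silently imputed.
* The weight objective is scale-free, so only weight *ratios* are
  identified; reported optima are grid points, not continuous estimates.
* Trajectory enumeration treats acquisition steps as unordered set
  extensions; it cannot express order-dependent epistasis.
* Cross-landscape normalisation by the native median is a convention; other
  normalisations would shift absolute values (not directions) of paired
  comparisons.
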