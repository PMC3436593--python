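# Methods

This note records the models implemented in `barcodelim`, the numerical
choices behind them, what the synthetic-data generators do and do not
emulate, and the package's known limitations.

## Substitution models and likelihoods

The model family is the standard reversible hierarchy: JC69, K80, F81,
HKY85, TIM2 (r_AC=r_AT, r_CG=r_GT, free AG and CT transition rates) and
GTR, each optionally extended with a proportion of invariable sites p_inv ∈
[0,1) and discrete-gamma among-site rate variation with shape α > 0. The
rate matrix is Q_ij = r_ij π_j, normalised so −Σ π_i Q_ii = 1 and, with
+I, rescaled by 1/(1−p_inv) so that branch lengths remain expected
substitutions per site averaged over all sites (the convention of the
common ML phylogenetics programs). Transition probabilities come from the
√π-symmetrised eigendecomposition of Q.

The discrete gamma uses 4 equal-probability categories whose rates are the
means of the quantile slices of Gamma(α, 1/α), renormalised to mean exactly
1. The sequence simulator draws per-site rates from the same
discretisation, so simulator and estimator share one definition of Γ.

Tree likelihoods use Felsenstein pruning over compressed site patterns,
with gap/`N`/`?` treated as missing data (all-ones tip partials) and the
invariable-site component added per pattern. Unit tests pin the engine to
an exhaustive sum over internal-state assignments on small trees, to the
two-sequence closed form, to re-rooting invariance, and to the neutrality
of an all-gap taxon.

## Pairwise distances

* p-distance is offered in two definitions: pairwise deletion (drop
  columns with a gap or N in either row) and a total-length variant that
  counts positions where exactly one row is gapped as differences and
  divides by the full masked length.
* K2P uses the closed form; a non-positive logarithm argument flags the
  pair *saturated* instead of raising.
* ML distances maximise the two-sequence +I+Γ mixture likelihood over
  t ∈ [0, 10] by bounded Brent search (absolute tolerance 1e−8); an optimum
  within 0.1% of the upper bound is flagged saturated rather than returned.
  With `profile_rates=True` the free exchangeabilities are profiled out per
  pair; under K80 this joint optimum coincides with the K2P closed form,
  which the tests exploit as an oracle (agreement to 1e−4; observed ~1e−8).

## Model estimation and AIC

`fit_substitution_model` estimates parameters on a fixed topology: a
Jukes–Cantor distance matrix (saturated entries capped at twice the largest
finite entry — the matrix only seeds a starting topology) feeds
neighbor joining, then coordinate ascent alternates L-BFGS-B over the free
model parameters (log-rates, p_inv capped at 0.99, log-α in [0.02, 100],
optionally softmax-parameterised frequencies) with per-branch Brent
optimisation, until the log-likelihood improvement falls below 1e−6
relative. Base frequencies are empirical by default. Alignments with no
variable column short-circuit: the likelihood is flat there and p_inv is
reported at its boundary. AIC counts k = free substitution parameters +
(2n−3) branch lengths; ties rank the smaller k first. Recovery at the study
scale (8 taxa, 5000 sites, GTR+I+Γ with α=0.5, p_inv=0.3, 10 seeds) yields
median α within 20% of truth and median p_inv within 0.08; those are the
tolerances the acceptance tests assert.

## Neighbor joining, clock test, bootstrap

NJ is the standard Saitou–Nei agglomeration with two deterministic
choices: Q-matrix ties break toward the lexicographically smallest pair of
cluster labels, and negative branch lengths clamp to zero with the deficit
recorded on the tree. The strict-clock likelihood-ratio test optimises all
2n−3 branch lengths (free model) against n−1 node-height increments on a
midpoint-rooted (or outgroup-rooted) version of the same topology, and
refers 2ΔlogL to χ²(n−2). The NJ bootstrap resamples columns with a seeded
generator, drops replicates whose distances saturate, and reports support
as the percentage of effective replicates containing each original
bipartition.

## Saturation test

Iss is the mean sitewise entropy (bits, gap-containing columns excluded, N
ignored within a column) divided by the entropy of the global base
frequencies. The externally estimated invariable-site proportion removes
round(p_inv·m) constant columns, allocated across the four constant-column
types by largest remainder — the test expects p_inv from the ML estimators
rather than estimating it internally. Data sets above the chosen OTU count
are averaged over seeded random subsamples (default 100). Iss is compared
to Iss.c by a two-sided one-sample t-test (df = m−1) with the standard
error taken from the sitewise entropy spread; two-sided is a deliberate
choice since the original software's sidedness is not documented. The
verdict follows the usual decision table: significantly below Iss.c → low
saturation; significantly above → useless for phylogeny; not significant →
poor.

**Critical values are synthetic.** The shipped table
(`data/iss_critical_synthetic.tsv`) is not copied from the original
simulation study; it is re-derived by `regenerate_critical_table`:
sequences evolve under JC69 on balanced ("sym") and equally spaced
caterpillar ("asym") ultrametric topologies over a geometric depth
gradient (0.0125–12.8), and Iss.c is the mean Iss interpolated at the depth
where neighbor joining's mean true-bipartition recovery falls below 95% of
its attainable maximum (normalising by the maximum separates
saturation-induced failure from shallow-end lack of signal, which matters
for large caterpillars). Lookups interpolate on log sequence length and
clamp outside the tabulated range. The derived values share the published
table's qualitative structure — Iss.c grows with OTU count and length, and
asymmetric topologies tolerate less saturation — but are not numerically
interchangeable with it.

## Barcode-gap analysis

Distances are binned with class k = ⌊v/width + ε⌋ + 1 (ε = 1e−9 relative,
guarding against binary-representation artefacts at exact multiples of the
width), i.e. closed-lower/open-upper classes, 1-based. Only raw counts are
reported; means and standard deviations of distance sets are deliberately
never computed, because skewed intraspecific and multimodal interspecific
distributions make such summaries misleading about gaps. Gap reports list
interior empty classes and strict interior local minima only — zeros
outside the occupied range are not gaps.

The duplication experiment copies designated taxa (labels `taxon__dupK`,
distance zero to their source and to sibling copies) and/or recodes taxa to
new species, then reports the exact pair-count bookkeeping. The shipped
64-taxon fixture uses the species-size profile
(8,7,5,5,5,4,4,4,3,3,3,3,3,2,2,1,1,1): 64 taxa, Σ C(s,2) = 114
intraspecific pairs, three singletons and several 3-member species. Its
recipe — duplicate two singletons four times each, split one 3-member
species 2+1 — yields 72 taxa, 2556 pairs, 132 intra and 2424 inter
(Δintra = 2·C(5,2) − [C(3,2) − C(2,2)] = +18).

## GMYC

Candidate thresholds are the observed node heights, each evaluated just
rootward of its node (the likelihood is constant in the threshold between
branching events, so no continuous search is needed). Internal nodes are
ranked by decreasing age with pre-order index breaking exact ties, and all
interval bookkeeping is integer-rank-based, which makes cluster membership
stable under height jitter far below the inter-node spacing (regression
tested at 1e−9 of the root height — the failure mode seen when clades of
identical sequences receive arbitrary tiny branch lengths from a Bayesian
clock program).

Likelihood convention. Each interval between successive branching events
(including the final interval down to the present; interval lengths sum to
the root height) contributes −b_i x_i with the pooled hazard
b_i = λ_div k_i^p_div + λ_coal (Σ_j n_ij(n_ij−1))^p_coal, classes with zero
lineages contributing nothing. Each event contributes a log-hazard term of
its own class: a speciation uses the diversification hazard of the interval
rootward of it (forward-time Yule waiting, the root itself carrying no
term), a coalescence uses the coalescent hazard of the interval tipward of
it (backward-time Kingman waiting, a species' first coalescence thereby
seeing its two daughter lineages). This reduces exactly to the Yule
likelihood when every node diversifies — giving the closed-form MLE
λ̂ = (n−2)/Σ k_i x_i at p=1, which the tests assert — and exactly to the
Kingman likelihood when every node coalesces, which makes the
threshold-at-root candidate identical to the coalescent-only null. Because
event terms are class-specific, the log-likelihood separates into the two
parameter pairs for every assignment; each pair is profiled (closed-form λ̂
given p, bounded Brent over p ∈ [−3, 8], tolerance 1e−7), so fits are
deterministic with no multi-start heuristics.

The single-threshold fit scans all candidates; the LR against the null uses
χ²(3) (three extra effective quantities), and the confidence range is the
min–max cluster count among candidates within 2 log-likelihood units of the
optimum. The multiple-threshold fit is a greedy stand-in for the original
(unpublished) algorithm: starting from the single-threshold optimum's
cluster set, it repeatedly applies the best of all single-cluster splits
(replace a cluster by its child subtrees) and sister-entity merges,
accepting gains above 1e−4 and breaking ties toward fewer thresholds. Its
"thresholds" are the distinct switch times just rootward of each cluster
root, and the LR against the single model uses df = number of extra
thresholds — an explicit assumption, configurable in principle, since the
reference implementation does not document its df.

## Synthetic data: what it does and does not emulate

The generators implement exactly the assumptions of the delimitation
model: a constant-rate pure-birth (Yule) process above species boundaries,
neutral single-population Kingman coalescents of constant size within
species (pair rate n(n−1)/2 per θ), grafted so the output stays ultrametric
(a genealogy deeper than 95% of its species' terminal branch is rescaled
into it, with a warning), and reversible site-independent sequence
evolution. They deliberately omit extinction, migration, hybridisation,
population growth, recombination and selection. Passing tests on these data
therefore show that the estimators recover the generating process when the
model is true — they do not show robustness to the many ways real barcode
data violate it, which is precisely the failure territory the analysis
tools (gap reports, saturation verdicts, LR tests) are meant to expose.

The delimitation benchmark fixes the study condition "strong separation" as
θ = (shallowest species divergence)/100, so even the most recent speciation
is 100× deeper than the mean within-species pairwise coalescence; at this
setting single-threshold GMYC recovers the true species count in ≥ 90% of
seeds, and under a pure coalescent the LR test stays below the 5% nominal
rejection rate. With separation ratios near 1 the threshold is genuinely
unidentifiable and the fit collapses toward few clusters — an expected
property of the model, not a search failure (verified by evaluating the
true assignment's likelihood, which is lower in such regimes).

## Problem sizes

Defaults were chosen so the full test suite and the acceptance script each
run in about a minute on one CPU: parameter recovery at 8 taxa × 5000
sites × 10 seeds, GMYC at 25 tips × 20 benchmark + 25 null seeds, oracle
checks at 100 simulated pairs and 4–5-taxon exhaustive sums, saturation
limits at 32 × 2000. All simulators are bit-reproducible given a seed; the
acceptance script derives per-stage seeds from a single `--seed` via
`numpy.random.SeedSequence`.

## Known limitations

* No codon or amino-acid models; the family stops at GTR+I+Γ.
* Model estimation fixes the NJ topology; it does not search topologies.
* The multiple-threshold search is greedy and local; it can stop at the
  single-threshold optimum where an exhaustive search might not.
* Iss.c values are simulation-derived surrogates, suitable for the
  qualitative verdict table, not for numeric comparison with the original
  published table.
* The clock test's χ² reference assumes large samples; at very short
  alignments it is conservative.
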