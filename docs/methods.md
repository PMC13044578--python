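# Methods

This note documents the models, rules, and numerical choices behind
`darkog`, the assumptions of the synthetic-data generator, and the places
where the design was genuinely open.

## Darkness classification

A protein's hits are DIAMOND/BLAST-style records with free-text subject
descriptions. The classification rule is purely lexical: a hit is
*ambiguous* if its description contains (case-insensitive substring) any of
the five phrases `uncharacterized protein`, `hypothetical protein`,
`predicted protein`, `expressed protein`, `unnamed protein product`, or is
blank. A protein is **light** iff it has at least one non-ambiguous hit
with e-value ≤ the cutoff (default `1e-5`, inclusive); otherwise — including
the zero-hit case — it is **dark**. An orthogroup is dark iff every member
protein is dark.

Choices made where the rule's source recipe is silent:

* *Matching semantics.* Case-insensitive substring containment, because
  database descriptions embed these phrases inside longer strings
  ("PREDICTED: uncharacterized protein LOC…").
* *Hits above the cutoff are ignored entirely* (rather than trusted from
  search-time filtering), making classification reproducible from stored
  hit tables regardless of how the search was run.
* *Blank descriptions count as ambiguous* — they carry no usable function.

The e-value comparison is `≤` (a hit at exactly the cutoff counts); all
expression-side thresholds below are strict. Each boundary is pinned by a
dedicated test.

## LCA placement and conserved-family selection

The rank ladder, most specific first, is: `tax_id, isolate, species,
genus, family, order, suborder, class, subphylum, phylum, clade1, kingdom,
clade, superkingdom, no rank`. The `suborder` rank is a custom slot
carrying the Complex/Robust split of stony corals; it is placed between
`order` and `class`, the only position at which it refines Scleractinia.
`tax_id` participates as the most specific pseudo-rank so single-dataset
families resolve to their dataset's taxon id.

The LCA walk scans ranks from most to least specific and stops at the
first rank where **every** member dataset has a non-missing taxon and all
taxa are equal. A dataset missing a value at a rank cannot certify
agreement there, so the scan skips that rank (the conservative choice; the
alternative — treating missing as a wildcard — can invent agreement that
the data do not support). If no rank is shared the family receives a
flagged root sentinel.

Selection of conserved dark families uses nested lineage groups
(Scleractinia ⊆ Hexacorallia ⊆ Cnidaria over dataset ids). A dark family
qualifies iff all member datasets lie inside one of the groups and its
**distinct member datasets** (not proteins — paralogs would inflate the
count) cover ≥ `min_coverage` (default 0.5, inclusive: 59 of 118
qualifies) of the *narrowest* containing group. Assigning the narrowest
group makes the three categories mutually exclusive, which is what allows
per-category counts to sum to the selected total.

Representative selection re-clusters each family's members with a greedy
centroid pass over a symmetric pairwise score matrix (members visited in
descending row-sum order; each unassigned member becomes a centroid and
claims unassigned members scoring at/above a configurable threshold). Each
centroid earns one vote per sequence in its cluster — the tally one gets by
counting how often a sequence appears in the representative column of a
members→representative clustering output. The member with the most votes
wins; ties break lexicographically by id and are recorded as a family
annotation. This internal clustering is a stand-in for an external
clustering tool and is labelled as such; precomputed votes can be supplied
instead.

## Homology detection failure

The model: the best bitscore between the family representative and a
homolog at patristic distance *d* is

    B(d) = a * exp(-b * d) + eps,    eps ~ N(0, sigma^2),

with `a > 0` the self-similarity bitscore at `d = 0` and `b >= 0` the decay
rate per substitution/site. Distances are summed branch lengths on the
species tree between the representative's tip and each other tip
(representative-tip, not member-averaged — a pinned choice).

* *Fitting.* Nonlinear least squares (`scipy.optimize.curve_fit`) with
  bounds `a > 0`, `b >= 0`; initial values from the maximum observed score
  and a log-linear slope. At least 3 observations spanning 2 distinct
  distances are required; anything less raises "underdetermined". The
  residual SD uses n−2 degrees of freedom; the parameter covariance is the
  NLS estimate.
* *Detection floor.* A hit reaches e-value *E* in a search space of size
  *m·n* at the Karlin–Altschul bitscore `B_thr = log2(m*n/E)`, with *m* the
  representative length and *n* the database length. The e-value threshold
  defaults to `1e-3` and **must be positive**: the upstream tool convention
  of passing a literal `0` threshold would put the floor at infinity and
  make every absence an HDF; the package rejects it and documents the
  discrepancy here rather than guessing what a zero threshold was meant to
  do.
* *Prediction.* The bitscore of a hypothetical true homolog at distance
  `d*` is modelled as Gaussian with mean `a*exp(-b*d*)` and variance equal
  to the residual variance plus first-order (delta-method) propagation of
  the parameter covariance through the gradient
  `[exp(-b d*), -a d* exp(-b d*)]`. `P(B < B_thr)` is the HDF probability,
  clipped to [0, 1]; it is monotone non-decreasing in `d*`.
* *Calibration.* The variance estimator is validated by ensemble Monte
  Carlo: over replicate (simulate → fit → predict) experiments the mean
  predicted probability matches the marginal empirical undetected fraction
  to within ±0.03, including at distances where the probability is
  mid-range (where a miscalibrated variance shows immediately). A
  single-fit comparison would confound estimation error with calibration
  and is not used.
* *Aggregation.* Fitting uses datasets where the homolog is present;
  prediction targets absent datasets. Absent datasets *inside* the
  family's LCA clade (plausibly incomplete assemblies) are scored but
  reported separately; only absences *outside* the LCA enter the family
  call. With thresholds `p > 0.95` (support) and `p < 0.05` (against) —
  endpoints ambiguous — the call is `hdf_supported`/`hdf_rejected` when
  ≥ 50 % of the scored non-LCA datasets fall in the corresponding class,
  else `ambiguous`; zero scorable datasets yields an explicit
  "not scorable" flag.

## Expression bias

* Low-expression filter: keep genes with count > 10 in > 10 % of samples
  (both strict).
* Bulk DE: significant iff |log₂FC| > 0.5 **and** adjusted p < 0.05 (both
  strict); rows with missing statistics (independent-filtering NAs) are
  skipped with a warning.
* Proteomics: per protein per time point, Welch's unequal-variance t-test
  between arms on normalized intensities; FC is the **log₂ ratio of arm
  means** (interpreting "FC > 0.5" consistently with the RNA-seq usage;
  configurable). Zero variance in both arms gives p = 1 for equal means
  and p = 0 otherwise. Time points are independent comparisons; no
  cross-time contrasts.
* Single cell: significant iff FC > 2.0, strict; negative FCs are a hard
  error. The three granularity levels (broadcell < cell < metacell) are
  analyzed independently.
* RBH id mapping: a pair maps iff each side is the other's unique best hit
  (ties drop the query) and the forward hit's query **or** subject
  coverage exceeds 60 % (strict). "Query or subject" is read literally as
  EITHER; an `and` mode is available since the conjunctive reading is also
  defensible.
* Proportion statistic: per group (dark/light), the denominator is the
  number of the group's genes significant in ≥ 1 unit; per unit, the
  numerator is the group's genes significant in that unit. A gene
  significant in k units counts k times across numerators but once in the
  denominator, so proportions need not sum to 1 across units. The per-unit
  bias is Δ = prop_dark − prop_light; this is a descriptive statistic (an
  optional two-proportion z-test is provided as an extension, clearly
  flagged as such).

## Remote-homology network

Hits are filtered at probability ≥ `min_probability` and query/subject
coverage ≥ 0.6 (all inclusive), with self-hits removed. Two presets exist
because the filtering recipe and the headline network use different
probability cutoffs (50 vs 90); the default is 50 and both are
first-class. Each hit is scored by `score / aln_len`; for each unordered
family pair only the best-scoring hit survives (ties: higher probability,
then lexicographically smaller query id), which also collapses
forward/reverse duplicates — the only reading of "redundant hits" that
yields a simple undirected graph. The surviving normalized score is the
edge weight. Components come from `networkx`; when a node-attribute table
is supplied it defines the node universe (isolated families appear as
singleton nodes; edges to unknown ids are an error). Output: edge list,
component table, summary JSON, GraphML.

## Synthetic corpus

The generator emulates the statistical structure the analysis assumes —
it never evolves sequences; bitscores and hit descriptions are drawn
directly.

* *Tree and taxonomy.* A random-coalescence tree over five blocks
  (Complex corals, Robust corals, other hexacorals, other cnidarians,
  outgroups) joined so that Scleractinia ⊂ Hexacorallia ⊂ Cnidaria are
  monophyletic; branch lengths exponential (mean 0.15 subst/site). The
  lineage table is consistent with the topology, includes the
  Complex/Robust suborder, and deliberately leaves ranks (isolate,
  subphylum, clade1…) missing to exercise rank-skipping.
* *Families.* Default 2,000 families over 40 datasets. Each family draws
  an origin clade (Scleractinia/Hexacorallia/Cnidaria/all-Metazoa with
  weights 0.35/0.30/0.25/0.10), a darkness label
  (P(dark) = 0.114, the observed dark-protein fraction in the corpus the
  package is modelled on), a decay regime (fast/slow, 50:50), and
  parameters a ~ U(200, 400), b ~ U(1.5, 3.0) fast or U(0.05, 0.2) slow,
  σ = 10 (σ/a ≤ 0.05). Datasets drop out by per-branch loss (p = 0.05,
  cause `loss`) or because their true bitscore falls below the detection
  floor (cause `hdf`) — the mechanism that makes fast families apparently
  lineage-restricted. Both causes are distinguishable in the truth table
  so HDF calibration can be measured separately per cause. Hit
  descriptions are deterministic given the darkness label, so classifier
  recovery of planted darkness must be exact.
* *Expression.* Per unit, a gene is significant with its group's planted
  probability (default: calicoblast dark 0.40 vs light 0.10; all other
  units 0.15/0.15); significant rows then draw values satisfying the
  strict rules, non-significant rows fail at least one rule. Intensities
  are log-normal with a 2× treatment shift planted in 20 % of proteins.
* *Network.* Hubs (broad-LCA, light) connect to their satellites
  (narrow-LCA, dark) with super-threshold probabilities/coverages, plus
  reverse duplicates (exercising deduplication), self-hits, and sub-
  threshold decoys including cross-hub rows that would merge components if
  a filter leaked.
* *Determinism.* One integer seed drives named per-stage substreams
  (`numpy` SeedSequence spawn keys), so stages regenerate independently
  and identical config + seed gives byte-identical files.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: actual sequence evolution (bitscores need not be
realizable by any alignment), correlated gene loss, annotation-database
biases in hit descriptions, compositional effects on Karlin–Altschul
statistics, batch effects or dispersion structure in expression data, and
assembly incompleteness beyond independent per-branch loss.

## Problem sizes and runtime choices

The default synthetic scale — 40 datasets, 2,000 families, 100 expression
replicates for the bias property, 200 replicates for CI coverage, 5,000
Monte-Carlo draws per calibration point — was chosen as the smallest scale
at which every statistical property is measured with comfortable margin
(binomial half-widths well under the tolerances involved); the full test
suite and the acceptance script each complete in well under a minute on a
single CPU.

## Pipeline behaviour

All stage thresholds are named, defaulted config fields, so the default
profile is the full recipe (e-value 1e-5; coverage 0.5; HDF 0.05/0.95/0.5;
DE 0.5/0.05; single-cell FC 2.0; low-expression 10/0.1; network
50 %/0.6/0.6). Input files are validated before any stage runs. The
summary is content-addressed by a hash of the config; rerunning with an
unchanged config returns the cached summary without recomputation.
Families whose bitscore observations cannot support a fit (< 3 points or a
single distinct distance) are carried through as explicitly not-scorable
rather than dropped.

## Known limitations

* The decay model assumes homoscedastic Gaussian noise on bitscores;
  truncation at zero (scores cannot be negative) is handled in the
  generator but not modelled in the likelihood, biasing fits slightly for
  families observed near the floor.
* The LCA walk trusts the lineage table; it has no notion of tree-based
  ancestry beyond rank agreement, so inconsistent taxonomies produce
  broader-than-true placements.
* The greedy representative clustering is order-deterministic but not an
  exact replica of any external clustering tool; supplied vote tables take
  precedence where fidelity matters.
* `run_all` consumes a precomputed representative table and bitscore
  matrix; it does not re-run the clustering/realignment that would produce
  them from raw proteins.
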