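# Methods

## Problem and model

`kgscreen` asks whether a drug is likely to be efficacious for a disease
by examining how the drug's target proteins (DT) relate to the disease's
associated proteins (DP) in a protein-level knowledge graph. The graph is
a multigraph of subject-predicate-object triples between proteins, each
carrying a non-empty set of provenance sources (the databases or
literature extracts attesting it). The unordered pair of endpoints
defines an *edge*; one edge may hold many triples.

Three path scenarios connect a DT set to a DP set:

1. **overlap** — a protein is in both sets, optionally with
   self-relationship triples (e.g. homodimerization);
2. **direct** — a DT and a distinct DP are joined by at least one triple;
3. **indirect** — a two-step path through exactly one intermediate
   protein (IP), with the two steps (DTIP, IPDP) kept separate.

Paths are capped at two steps: longer paths explode combinatorially and
two steps already cover the overwhelming majority of DT-DP connectivity
in dense protein networks. Connectivity is treated as undirected: many
protein-protein predicates are symmetric and nothing in the feature
semantics depends on which endpoint was the subject. An intermediate may
itself be a DT or DP of the combination, provided it differs from the two
endpoints of its own path — excluding such intermediates would silently
drop paths between large sets.

## Features and classification

Every combination is encoded as a fixed-length binary vector: for each
value slot (SELF, DIRECT, DTIP, IPDP) and each predicate label and each
provenance source, a bit records whether at least one triple of that slot
carries that label. Presence, never counts: the feature is "this kind of
evidence exists", which is robust to the wildly varying set sizes. Three
flag features (overlap, has-direct, has-indirect) encode bare
co-occurrence. Five variants isolate the contribution of each information
type: `baseline` (flags only), `predicate`, `provenance`, `full`, and
`indirect_only` (full minus the overlap/SELF/DIRECT slots, probing
whether the method survives without proximity between the sets).

The feature space is derived from the graph's full vocabularies rather
than from training folds. Vocabulary derivation is label-free, so this
leaks nothing, and it keeps columns identical across folds and repeats.

Classification uses random forests (500 trees by default, other
hyperparameters at scikit-learn defaults) under repeated stratified
10-fold cross-validation (100 repeats by default). Positives are used in
full; each repeat draws a fresh equally-sized random sample of negatives,
so the reported standard deviation reflects both fold and sampling
variability (a `resample_negatives=False` flag freezes one sample
instead). ROC AUC and precision-recall AUC are computed per repeat over
that repeat's pooled out-of-fold probabilities. Feature importances are
mean decrease in impurity, averaged over every forest trained and
normalized by their maximum. Training-set imbalance is studied by adding
extra negatives to training folds only, keeping test folds balanced so
AUCs remain comparable across ratios.

Source ablation removes the evidence only derivable from one provenance
source: triples attested solely by that source are deleted, the source's
provenance columns are dropped, and any predicate column left without
graph-wide support disappears; remaining columns are re-extracted from
the filtered graph. This is a triple-level reading of "only derivable
from": a predicate observed in some other source's triple survives.

## Proximity baseline

The benchmark score is the *closest* network distance
`d_c(T, S) = mean_t min_s d(t, s)` (unweighted hops), z-scored against a
degree-matched null: nodes are grouped into degree bins grown until each
holds at least 100 proteins (reduced with a warning on smaller graphs),
and each set member is replaced by a random protein from its bin, 1000
draws by default. `-z` is the efficacy score. Drug targets with no finite
distance are excluded from the mean rather than given a magic penalty
(a fixed-penalty mode exists for sensitivity analysis); combinations with
no defined z rank strictly last. Single-source BFS results are cached per
node, so scoring many combinations on one graph costs at most one BFS per
protein.

## Synthetic benchmark

The graph the method was developed against is commercial, so the package
ships a generator that emulates its statistical shape and serves as the
default benchmark. Background graphs have a heavy-tailed (configurable to
uniform) degree distribution with ~3 edges per protein, each edge
carrying 1-3 predicates from a 45-label vocabulary and each triple 1-3
sources from a 25-label vocabulary, both sampled from Zipf-like
background frequencies. Reference sets draw DT sizes from a geometric
distribution with median 2 (range capped at 51) and DP sizes with median
5 (capped at 273), matching the shape of published drug-target and
disease-protein set collections.

Class signal is planted so the package's central claim — predicate and
provenance labels carry information beyond path co-occurrence — is a
testable property. Positives and negatives receive planted paths by the
identical structural process (3 paths per combination; scenario mix 15%
overlap / 35% direct / 50% indirect), but triples on positive paths
switch their predicate to a designated signal label with probability 0.9
and their provenance with probability 0.6. The predicate effect is set
above the provenance effect so the benchmark mirrors the qualitative
ordering the method is expected to show (predicate features beat
provenance features; both beat co-occurrence alone). Signal labels are
the *rarest* background labels — planting frequent labels would be
swamped by background paths that carry them anyway. Because path
structure is class-matched, the baseline variant and the proximity score
stay at chance on generated data at any effect size; setting both effects
to zero makes the classes fully exchangeable, which is the generator's
null calibration.

`planted_sole_source` stamps planted path triples of *both* classes with
exactly one source. This makes the planted evidence removable by
single-source ablation, and removable symmetrically: if only positives
lost their planted paths, their absence would itself become a learnable
(inverted) signal.

What the generator does not emulate: the real co-occurrence statistics of
predicates and sources, identifier noise, literature-extraction errors,
and the biased curation of real reference sets. Passing tests therefore
demonstrate correctness of the machinery and recoverability of planted
signal, not field performance on a production knowledge graph.

## Numerical and design choices

* Triple identity is (subject, predicate, object); duplicate records
  merge provenance on load. Whether one relationship with two sources is
  one triple or two is a storage convention; merging makes features
  independent of it.
* Feature ordering is deterministic (slot, kind, lexicographic value);
  importance ties break on feature id.
* Folds are stratified by label to avoid single-class folds at small n;
  a degenerate split is re-drawn with a logged warning.
* All randomness flows from one master seed through named
  `numpy.random.SeedSequence` streams (negative sampling, fold shuffling,
  forest seeds, null draws), making every experiment bit-reproducible,
  including across processes.
* The benchmark scale used by the tests and the acceptance script
  (hundreds of proteins, 10x10 or 5x5 cross-validation, 100-200 trees) is
  the package's own desk-scale choice for stable-but-fast estimates;
  every knob accepts larger values.

## Known limitations

* Only protein entities and protein-protein triples are modelled; no
  other entity types, no RDF parsing, no identifier mapping.
* Paths of length ≥ 3, counted (non-binary) features, metapath strings,
  embeddings, and topology features are out of scope.
* Orientation of asymmetric predicates (e.g. "regulates") is recorded
  but deliberately ignored by path extraction.
* On the synthetic benchmark the AUC stratified by drug-target count
  tends to *decrease* with more targets: the generator plants a fixed
  number of signal paths per combination, so larger sets dilute the
  planted evidence with background paths. Real reference sets, where
  more targets mean more real evidence, can show the opposite trend.
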