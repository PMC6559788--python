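# Methods

This note records the models implemented in `gutchem`, the parameter
choices that matter, what the synthetic-data generator does and does
not emulate, and the numerical conventions adopted where a published
description left room for interpretation.

## Fingerprints and similarity

Compounds are represented by 881-bit binary substructure key vectors
(the PubChem/CACTVS fingerprint system). The wire format is a base64
string over a 4-byte big-endian bit-length prefix followed by MSB-first
bit-packed data with zero padding; the decoder rejects any payload
whose declared length is not 881, whose byte count is wrong, or whose
pad bits are set, so a round trip is bit-exact or fails loudly.
Similarity is the Tanimoto coefficient over set bits. The 0/0 case
(two all-zero fingerprints) is defined as 0 rather than 1: featureless
records carry no evidence of shared chemistry. Compounds lacking a
fingerprint are dropped with a logged warning — real compound tables
are incomplete, and a missing fingerprint should cost one row, not the
build.

## Similarity network

Pairs below a minimum similarity of 0.3 (default) are removed; all
compounds remain as nodes so that counts are not silently deflated.
Communities come from Walktrap (walk length 4, the algorithm's
canonical default) on the edge-weighted graph, cut at maximum
modularity; the implementation is delegated to igraph. Walktrap is
deterministic — it operates on random-walk transition probabilities,
not sampled walks — and community ids are renumbered by each
community's lexicographically smallest member, so labellings are stable
across runs and platforms. Isolated nodes form singleton communities.

Edge significance is per community: z = (score − mean) / sd over the
community's intra-community edge scores, with the sample (n−1)
standard deviation, and an edge is significant when z ≥ 1 (default).
The threshold is one-sided upper: in a similarity network,
"significant" should reward unusually high overlap, and a two-sided
reading would flag unusually *dissimilar* pairs. Communities with fewer
than two intra-community edges, or zero spread, yield no significant
edges — the Z-score is undefined there and the conservative call avoids
a division by zero. Inter-community edges stay in the graph but are
never significant, since the statistic is defined only within a
community.

## Toxicity similarity

Concept frequency is the fraction of profiled drugs listing the
concept. The rarity weight is −ln(frequency), the standard
information-content form; a concept present on every label weighs
zero. Concept redundancy is handled as in the side-effect-similarity
literature: pairwise concept co-occurrence (Tanimoto over the drug sets
listing each concept) is converted to distance 1 − corr, agglomerated
with UPGMA (node height = merge distance / 2, giving an ultrametric
tree), and the Gerstein–Sonnhammer–Chothia procedure distributes each
branch length among the leaves below it in proportion to their
accumulated weights (equally while all are zero), processing edges from
the leaves toward the root. Before rescaling, leaf weights sum to the
tree's total branch length — the conservation property that makes an
exact duplicate concept split one concept's weight in half. Weights are
rescaled to mean 1.

A drug pair's raw score sums combined (rarity × GSC) weights over
shared concepts. The published description stops at "sum of products of
weights"; we add a cosine normalisation raw / √(self(a)·self(b)) so
identical profiles score exactly 1, disjoint profiles 0, and "toxicity
overlap ≥ x" queries have a bounded scale. Profiles whose every concept
has zero combined weight cannot be normalised and are rejected (or
skipped with a warning in the all-pairs sweep). Concept ids are taken
as given; no ontology mapping is attempted.

UPGMA ties are broken by scipy's deterministic agglomeration over
lexicographically sorted concepts. A zero-distance duplicate leaf can
reorder tied merges and perturb unrelated weights at the ~10⁻³
relative level; the duplicate-halving property is exact on a fixed
tree.

## Enzyme taxonomic dominance (ECs_D)

D = Σ n(n−1) / (N(N−1)) over species counts, ECs_D = 1 − D. Species
with zero count contribute nothing, so padded tables score identically
to sparse ones. N < 2 leaves the unbiased form undefined; such enzymes
are reported as not scoreable rather than forced to 0 or 1. The
high-dominance/diverse classification threshold is the cohort mean
ECs_D recomputed from the input — it is a property of the dataset, not
a constant.

## Shared-enzyme probability model

Compound pairs are labelled associated when their EC sets intersect.
Pair features are the Tanimoto similarity plus the absolute difference
of each physiochemical descriptor (six families: geometry, functional
groups, aromaticity, amino acid composition, polarity, hydrophobicity)
— a symmetric, order-invariant encoding, since the published work does
not state its pair encoding. The classifier is an RBF support-vector
machine with Platt (sigmoid) probability calibration; the bandwidth
comes from the median heuristic on standardised training features, the
majority class is down-sampled to at most 5:1 before fitting, and the
standardiser is fit on training data only. Reported curves use
out-of-fold predictions from 5-fold stratified cross-validation,
binned uniformly on [0, 1] similarity. On balanced label-shuffled data
the calibrated probability converges to 0.5; on imbalanced shuffled
data it converges to the base rate — null-calibration checks must
balance classes first.

## Network validation

The randomised comparator redraws the edge set uniformly among
unordered node pairs without replacement (G(n, m)), preserving the node
set, edge count and label multiset; node degrees are not preserved (a
degree-preserving double-edge-swap variant is available behind a flag
for sensitivity analysis). The source network's similarity-score
multiset is permuted onto the random edges so that score-binned
comparisons remain defined on the randomised graph. Superclass
agreement is tallied per similarity bin (width 0.05 by default) over
edges whose endpoints are both annotated; the matched fraction is
reported alongside the matched:unmatched ratio because the ratio is
undefined in fully matched bins. The real-vs-random comparison is a
two-sided Wilcoxon rank-sum on the similarity scores of
superclass-matched edges — one consistent reading of an
under-specified published test; all-tied samples are reported as
inconclusive. The structure–toxicity relation is ordinary least
squares of toxicity similarity on substructure similarity over pairs
present in both edge sets, and category self-similarity contrasts are
two-sample Kolmogorov–Smirnov tests on within-category Tanimoto
distributions.

## Property graph

Similarity and toxicity edges are stored once in canonical
(min id → max id) orientation and queried as undirected;
`METABOLIZED_BY` and `HAS_USE` are directed from the compound. ECs_D is
an `Enzyme` node property, not a separate node — it is a per-enzyme
scalar. Queries return deterministic orderings (score descending, id
ascending). The CSV export follows the Neo4j bulk-importer header
conventions (`id:ID`, `:LABEL`, `:START_ID`, `:END_ID`, `:TYPE`, typed
property columns) because the natural deployment target is a graph
database; GraphML is the portable alternative, and both round-trip with
identical nodes, relationships and property values.

## Synthetic data generator

The generator plants the structure each stage assumes. Each cluster
gets a random template bit set covering `shared_bit_fraction` of the
881 positions (default 0.2, so ~176 set bits); members copy it and flip
every bit independently at `bit_flip_noise` (default 0.02). These
defaults put within-cluster Tanimoto near 0.85 and between-cluster near
0.11, comfortably astride the 0.3 filter. Categories default to 30%
drug / 50% food / 20% endogenous — drugs a minority against a dietary
background, as in real gut-exposure corpora. Superclass labels align
with clusters with probability 0.9 (chemical taxonomy tracks, but does
not equal, substructure clusters). Side-effect profiles draw each of 6
concepts from the drug's cluster pool with probability `coupling`
(default 0.7, a moderate structure–toxicity relationship) and from the
30-concept vocabulary otherwise, plus a 5% background prevalence per
concept; coupling 0 severs the structure–toxicity correlation,
coupling 1 makes cluster-mates nearly toxicity-identical. Enzymes are
assigned round-robin to clusters and each compound carries its
cluster's enzymes with probability `enzyme_sharing` (default 0.7;
within-cluster pair association is therefore ~sharing²), with a 2%
background rate for cross-cluster associations. Abundance tables are
Dirichlet draws with concentration `evenness` (default 5) over 20
species scaled to 2000 individuals; given a `target_ecsd`, a
one-dominant-species/rest-even profile is solved in closed form at
N = 10⁴ and lands within 0.02 of the target, which must lie in
[0, 1 − 1/k].

One global seed spawns fixed per-stage child seeds
(`SeedSequence(seed, spawn_key=(stage,))`), so adding a stage never
perturbs earlier stages and identical specs produce byte-identical
files. Fingerprints are statistical stand-ins with the right similarity
geometry, not valid molecules: passing tests demonstrate the pipeline's
statistical behaviour (cluster recovery, coupling detection,
calibration), not chemical realism, and say nothing about fingerprint
semantics on real structures. Test and acceptance runs use 60–1,000
compound fixtures — sizes at which every planted effect is
comfortably detectable while the full suite stays fast.

## Known limitations

* Real-corpus headline statistics (node totals, the structure–toxicity
  effect size, rank-sum p-values) depend on the SIDER/FooDB/PubChem/
  KEGG/iHMP corpora and are not reproduced by the synthetic fixtures;
  the package reproduces the *procedures* and their testable
  properties.
* The rarity formula, GSC rescaling convention, pair-feature encoding
  and toxicity normalisation are explicit choices where the published
  descriptions defer to external references; each is documented above.
* Whether abundance "individuals" are genome counts, gene copies or
  read counts is input-dependent; ECs_D is computed on whatever count
  unit the table provides.
* The PubChem adapter requires network access and is deliberately kept
  out of every offline code path.
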