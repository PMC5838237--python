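# Methods

## Evidence channels

Four kinds of per-gene-pair evidence feed the network:

* **Co-expression.**  Each expression dataset is preprocessed
  independently: log2 transform (values must be strictly positive;
  `offset=c` switches to log2(x + c) for data with zeros), removal of
  probes missing in strictly more than 30% of samples, k-nearest-
  neighbour imputation of remaining missing values, and probe→gene
  collapse by averaging.  Imputation neighbours are probes: the distance
  between two probes is the plain Euclidean distance over samples where
  both are observed (at least two co-observed samples required,
  otherwise the probe's own mean is used and logged), and an imputed
  value is the 1/distance-weighted mean of the k = 10 nearest observed
  neighbours.  The method is named in the source procedure but its
  parameters are not; k = 10 with probe-neighbours and inverse-distance
  weights is this package's documented default.  The channel score is
  the Fisher z-transform atanh(r) of the Pearson correlation, with r
  clipped to ±(1 − 1e−12) so the channel is finite; zero-variance genes
  score 0 against every partner.  Genes absent from a dataset are simply
  missing evidence in that channel.
* **Protein–protein interaction.**  The union of several binary
  interaction sources after pair canonicalization.  The channel is
  treated as fully observed over the gene universe: the absence of an
  interaction is an observed 0, not missing data.
* **Protein docking.**  Continuous scores in [0, 1] given per isoform
  pair; a gene pair's score is the maximum over its isoform pairs, and
  the same maximum rule resolves collisions when homolog mapping
  collapses several source pairs onto one target pair.  Docking is
  sparse evidence: pairs without a score are missing.
* **Phenotype overlap.**  The number of shared annotation labels per
  pair of annotated genes.  Zero overlap between two annotated genes is
  informative negative evidence and is scored 0; genes without any
  annotation are missing.  The source procedure does not state whether
  zero-overlap pairs were included; scoring them is this package's
  choice, on the grounds that an annotated gene pair sharing no
  phenotype genuinely argues against a functional relationship.

Genome-scale channels (co-expression, phenotype overlap) are stored as
dense symmetric matrices with NaN marking missing pairs; sparse channels
as canonical-pair maps.  Serialized pair tables collapse duplicate rows
by keeping the maximum, consistent with the docking convention.

## Gold standard

Positives are within-term pairs of pathway/GO-style gene sets restricted
to 5–300 genes inclusive (smaller terms are too specific, larger ones
too broad to define a meaningful shared process).  Multi-species
collections are mapped to one namespace through homolog maps before pair
enumeration.  Negatives — needed to estimate the ¬FR conditionals — are
pairs of annotated genes never co-annotated to any term, the standard
convention when only positive relationships are curated.  No ontology
propagation is performed; terms are taken as flat sets.

## Two-layer Bayesian integration

Each channel's scores over gold pairs are discretized into
equal-frequency bins (default 20; binary channels use the two natural
bins; heavily tied distributions collapse duplicate quantile edges, so
the effective bin count can be smaller).  Per-bin counts of gold
positives and negatives are Laplace-smoothed (+1) and normalized into
P(E|FR) and P(E|¬FR).  The posterior for a pair multiplies the prior
odds by the likelihood ratio of each **observed** channel — missing
evidence contributes no factor, so a pair with no evidence anywhere sits
exactly at the prior.  Products are accumulated in log space; the
normalizing constant is realized as explicit two-class normalization
over {FR, ¬FR}.  The default prior is the positive fraction among gold
pairs, overridable in configuration.

Integration is layered: the expression channels are first combined into
one continuous co-expression posterior (layer 1); that combined score is
then re-binned and re-calibrated as a single channel alongside PPI,
docking, and phenotype (layer 2).  Re-calibrating rather than carrying
raw layer-1 likelihood ratios keeps each layer a proper calibrated
naive-Bayes model and prevents the (correlated) expression datasets from
dominating the integration.  The network's diagonal is fixed at 0 so
downstream classifier features carry no self-edge.

## Classifier and ranking

Features are FRN rows.  The classifier is a random forest with class
weights inversely proportional to class frequencies, trained under
stratified 5-fold cross-validation; each outer fold runs an inner
3-fold grid search selecting by ROC-AUC.  The default grid is trees ∈
{100, 500}, per-split feature budget ∈ {sqrt, log2}, minimum leaf ∈
{1, 5}; it is plain configuration and fully overridable (the recovery
experiments in the tests and the acceptance script use the compact
subset trees = 100, sqrt features, leaf ∈ {1, 5}, which selects the same
models on the synthetic studies at a fraction of the cost).  Labeled
genes receive the probability from the single fold that held them out —
a structural no-leakage guarantee asserted in the tests — and unlabeled
genes the mean over the five fold models.  Ties in the final ranking
break lexicographically by gene symbol.  Note one known optimism source
retained by design: a labeled gene's feature row includes its network
connections to other labeled genes.

## Decile enrichment

A ranking of N genes is split into ten bins with floor boundaries:
decile d covers 0-based ranks [⌊(d−1)N/10⌋, ⌊dN/10⌋).  This convention
gives a first decile of exactly 2111 genes for N = 21,112.  The expected
top-decile proportion p₀ is the fraction of a neutral background list
(its members present in the ranking; absentees dropped and logged) that
falls in decile 1, kept at full precision — rounding p₀ before testing
visibly shifts extreme p-values.  Enrichment of a candidate list with k
of n ranked genes in decile 1 is the exact upper tail P(X ≥ k),
X ~ Binomial(n, p₀), computed by the survival function with no normal
approximation.  One shared p₀ serves all lists of a validation run, and
no multiple-testing correction is applied across lists.

## Community analysis

The disease network contains a given top gene set plus every gene
connected to one of them at posterior ≥ 0.98; edges are all pairs within
that node set at or above the threshold, including neighbour–neighbour
pairs (the narrower reading — only top-to-neighbour edges — discards
real high-confidence structure).  Communities come from divisive
Girvan–Newman clustering: repeatedly remove the highest-betweenness edge
(unweighted shortest-path betweenness; ties broken by lexicographic edge
label for determinism), record the component partition at each split,
and return the recorded partition with maximal Newman–Girvan modularity
on the original edge set.  The source description names both the
divisive algorithm and a fast-greedy implementation; the divisive
algorithm is implemented because it is the one the description of the
procedure actually matches.  Edge weights only gate inclusion at the
threshold; betweenness is computed on the unweighted graph.  Per
community, gene-set over-representation uses the one-sided
hypergeometric tail with the full network gene set as universe, and
Benjamini–Hochberg correction across the sets tested for that community
(significance at Q ≤ 0.01).

## Synthetic study generator

The generator plants ground truth for every downstream stage.  Defaults
describe the study conditions: a universe of 2000 genes, 40 modules of
20–60 genes, 2 disease modules; 5 expression datasets of 50 samples;
within-module expression correlation 0.6 via a shared latent factor
(gene = √ρ·x_module + √(1−ρ)·noise, exact in expectation, much cheaper
than explicit covariance matrices); 5% missing values; ~40% of probes
mapping many-to-one onto genes (a second probe for a random quarter of
genes, with a constant per-probe offset and small probe noise so
collapse is non-trivial without disturbing the target correlation).
PPI edges are Bernoulli(0.30) within modules and Bernoulli(0.002)
across; docking scores are Beta(5,2) on all within-module pairs and
Beta(2,5) on a sampled 2% background of cross pairs, mirroring the
partial genome coverage of real docking compendia; each module carries
1–3 shared phenotype labels plus 5% uniform label noise.  A random 70%
of modules are emitted as pathway annotations — the gold-standard source
— so the network must generalize beyond its training annotations; truth
genes are a random 60% of disease-module genes and controls are random
non-module genes at 10× the truth size (capped at the available
non-module genes).  Every field is a deterministic function of the seed.

What the generator does **not** emulate: platform or batch effects,
realistic microarray noise structure, scale-free PPI degree
distributions, ascertainment bias in annotations.  Passing recovery
tests therefore demonstrate that the machinery correctly extracts a
planted signal of realistic strength, not that real data of this size
would yield comparable accuracy.

## Problem sizes and numerical choices

The recovery experiments run the full default-scale study (G = 2000)
per seed — five seeds in the test suite, three in the acceptance script
— with the compact classifier grid above; community recovery uses a
300-gene, 6-module study so the divisive clustering (quadratic-ish in
edges) stays in seconds.  Posteriors are computed in log space and are
finite for hundreds of stacked extreme channels.  Probabilities are
serialized with 10 significant digits, enough for exact round-trips of
every analysis the package performs.  Degenerate inputs are handled
explicitly: zero-variance genes score 0 in correlation channels, probes
without imputation neighbours fall back to their own mean, empty
evidence yields the prior, an edgeless graph partitions into singleton
communities with modularity 0.

## Known limitations

* Channel independence is assumed, as in any naive-Bayes integration;
  correlated evidence (e.g. five expression datasets of the same
  tissue) is mitigated but not removed by the two-layer structure.
* The negative gold-standard definition (never co-annotated) mislabels
  truly related pairs whose shared process is simply not annotated;
  smoothing and the calibration-only role of negatives limit the harm.
* No probability calibration is applied to classifier outputs; ranks,
  not absolute probabilities, are the intended product.
* Gene symbols are opaque strings; any aliasing must be resolved
  upstream via explicit mapping files.
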