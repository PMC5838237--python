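# frnrank

Network-based prioritization of disease genes from heterogeneous
functional genomics evidence.

Complex neuropsychiatric disorders such as autism spectrum disorder
involve hundreds of risk genes, only a fraction of which carry mutations
strong enough to reach significance in sequencing studies.  `frnrank`
implements a guilt-by-association strategy for ranking candidate genes:
genes that sit in the same network neighbourhoods as known disease genes
are likely to participate in the same biological processes and are
therefore promising candidates themselves.  The package is aimed at
computational biologists who want to build a tissue-focused functional
relationship network from their own evidence sources, rank genes against
a curated truth set, and validate the ranking — and at methodologists who
want a fully synthetic, ground-truthed benchmark of the whole procedure.

## The model

**Functional relationship network (FRN).**  For every gene pair, evidence
channels (Fisher z-transformed co-expression per dataset, binary
protein–protein interaction, protein-docking scores, shared-phenotype
counts) are combined by naive-Bayes integration.  With evidence
E<sub>1</sub>…E<sub>n</sub>,

P(FR | E₁,…,Eₙ) = P(FR) ∏ᵢ P(Eᵢ | FR) / C,

where C normalizes over the two classes {FR, ¬FR}.  The per-bin
conditionals P(Eᵢ | FR) and P(Eᵢ | ¬FR) are estimated on a gold standard
of co-annotated pathway gene pairs (terms restricted to 5–300 genes)
versus annotated-but-never-co-annotated pairs, with equal-frequency
binning and Laplace smoothing.  Integration is two-layer: the expression
datasets are first combined into a single co-expression posterior, which
is then re-calibrated alongside the interaction channels.  The result is
a symmetric gene × gene matrix of posterior probabilities in [0, 1].

**Classifier ranking.**  Each gene's feature vector is its FRN row.  A
random forest with balanced class weights is trained on labeled
truth/control genes under stratified five-fold cross-validation with a
nested grid search.  Labeled genes are scored only by the fold model
that held them out; unlabeled genes by the mean over fold models.
Sorting the probabilities yields the genome-wide ranking.

**Validation.**  The ranking is split into ten evenly binned deciles.
For a candidate gene list, over-representation in the first decile is
tested with an exact one-sided binomial test against an expected
proportion measured from a neutral background list.  The high-confidence
subnetwork (top-decile genes and their direct connections at posterior
≥ 0.98) is decomposed into communities by divisive Girvan–Newman edge
betweenness clustering with modularity-based selection, and each
community is tested for gene-set over-representation (hypergeometric
test, Benjamini–Hochberg FDR).

## Worked example

A small synthetic study with planted functional modules, built and
ranked end to end:

```python
import numpy as np
from sklearn.metrics import roc_auc_score
from frnrank.synthetic import SyntheticConfig, generate_study, recovery_eval_sets
from frnrank.expression import preprocess, fisher_z_channel
from frnrank.interactions import phenotype_overlap
from frnrank.goldstd import filter_terms, build_gold_standard
from frnrank.bayes import build_frn
from frnrank.ranking import LabeledSet, build_features, train_cv, predict_genomewide

cfg = SyntheticConfig(n_genes=400, n_modules=8, module_size_min=20,
                      module_size_max=30, n_disease_modules=2,
                      n_datasets=2, n_samples=30)
study = generate_study(cfg, seed=1)
channels = [fisher_z_channel(preprocess(m), name=f"expr_{i}")
            for i, m in enumerate(study.expression_datasets)]
gold = build_gold_standard({"study": filter_terms(study.pathway_annotations)})
net, model = build_frn(channels,
                       [("ppi", study.ppi, "binary"),
                        ("docking", study.docking, "score"),
                        ("phenotype", phenotype_overlap(study.phenotypes), "score")],
                       gold, study.universe)
X, genes = build_features(net)
labels = LabeledSet(study.truth_genes, study.control_genes)
cv = train_cv(X, genes, labels, seed=1,
              grid={"n_estimators": [100], "max_features": ["sqrt"],
                    "min_samples_leaf": [1, 5]})
ranking = predict_genomewide(cv, X, genes, labels)
pos, neg = recovery_eval_sets(study, seed=11)
auc = roc_auc_score([1] * len(pos) + [0] * len(neg),
                    ranking.probability_of(pos + neg))
```

Output of the run above:

```
universe: 400 genes, truth: 32, controls: 192
gold standard: 2054 positive / 10349 negative pairs, prior 0.1656
mean FRN posterior: 0.492 within disease modules vs 0.040 overall
cross-validated ROC-AUC: 1.000 +/- 0.000
held-out disease genes: 21; recovery AUC vs 192 non-module genes: 0.998
```

The prior (0.1656) is the positive fraction among gold-standard pairs;
the posterior contrast (0.492 vs 0.040) shows the integration
concentrating probability mass on planted-module pairs; the recovery AUC
(0.998) shows that disease-module genes deliberately withheld from
training are ranked above random non-module genes — the
guilt-by-association signal the whole pipeline exists to exploit.

The same experiment runs from a shell:

```bash
frnrank run-all --outdir run --seed 1 --config config.yaml
```

which executes simulate → curate → evidence → gold-standard →
build-network → rank → validate → cluster → enrich and writes a manifest
with content digests of every output.  Each stage is also its own
subcommand and can be re-run in isolation against the same directory.

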