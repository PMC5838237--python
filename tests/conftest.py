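"""Shared fixtures: a small synthetic study and its derived network.

The small study is sized so the whole evidence → gold standard → network
→ ranking chain runs in a few seconds while keeping every planted signal
(correlated modules, enriched PPI/docking, shared phenotypes) strong
enough to be recovered.
"""

from __future__ import annotations

import numpy as np
import pytest

from frnrank.bayes import build_frn
from frnrank.expression import fisher_z_channel, preprocess
from frnrank.goldstd import build_gold_standard, filter_terms
from frnrank.interactions import phenotype_overlap
from frnrank.ranking import LabeledSet, build_features, predict_genomewide, train_cv
from frnrank.synthetic import SyntheticConfig, generate_study

SMALL_CONFIG = SyntheticConfig(
    n_genes=400,
    n_modules=8,
    module_size_min=20,
    module_size_max=30,
    n_disease_modules=2,
    n_datasets=2,
    n_samples=30,
)

SMALL_GRID = {"n_estimators": [60], "max_features": ["sqrt"], "min_samples_leaf": [1, 5]}


def build_network_for(study):
    channels = [
        fisher_z_channel(preprocess(m), name=f"expression_{i}")
        for i, m in enumerate(study.expression_datasets)
    ]
    gold = build_gold_standard({"study": filter_terms(study.pathway_annotations)})
    network, model = build_frn(
        channels,
        [
            ("ppi", study.ppi, "binary"),
            ("docking", study.docking, "score"),
            ("phenotype", phenotype_overlap(study.phenotypes), "score"),
        ],
        gold,
        study.universe,
    )
    return channels, gold, network, model


@pytest.fixture(scope="session")
def small_study():
    return generate_study(SMALL_CONFIG, seed=1)


@pytest.fixture(scope="session")
def small_network(small_study):
    """(channels, gold, network, model) for the small study."""
    return build_network_for(small_study)


@pytest.fixture(scope="session")
def small_ranking(small_study, small_network):
    _, _, network, _ = small_network
    features, genes = build_features(network)
    labels = LabeledSet(list(small_study.truth_genes), list(small_study.control_genes))
    cv = train_cv(features, genes, labels, seed=1, grid=SMALL_GRID)
    return predict_genomewide(cv, features, genes, labels)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
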