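"""Network-feature classifier and genome-wide disease-gene ranking.

Each gene's feature vector is its row of the functional relationship
network — its posterior connection strength to every other gene in the
universe.  A random-forest classifier is trained on the labeled genes
under stratified five-fold cross-validation with a nested grid search
(selection by inner-CV ROC-AUC) and balanced class weights.  Genome-wide
probabilities follow the labeled/unlabeled convention: a labeled gene
keeps the probability from the single fold in which it was held out; an
unlabeled gene gets the mean probability over all fold models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold

from .bayes import FunctionalNetwork

log = logging.getLogger(__name__)

DEFAULT_GRID: dict[str, list] = {
    "n_estimators": [100, 500],
    "max_features": ["sqrt", "log2"],
    "min_samples_leaf": [1, 5],
}


@dataclass
class LabeledSet:
    positives: list[str]
    negatives: list[str]

    def __post_init__(self) -> None:
        if set(self.positives) & set(self.negatives):
            raise ValueError("positive and negative label sets overlap")


@dataclass
class CVResult:
    fold_models: list
    fold_of_gene: dict[str, int]
    holdout_probability: dict[str, float]
    fold_aucs: list[float]
    train_indices: list[np.ndarray]

    @property
    def auc_mean(self) -> float:
        return float(np.mean(self.fold_aucs))

    @property
    def auc_sd(self) -> float:
        if len(self.fold_aucs) < 2:
            return 0.0
        return float(np.std(self.fold_aucs, ddof=1))


@dataclass
class RankingResult:
    """Genome-wide ranking: per gene a probability, rank, and label status."""

    table: pd.DataFrame  # columns: rank, gene, probability, label_status
    cv_auc_mean: float
    cv_auc_sd: float
    fold_aucs: list[float] = field(default_factory=list)

    def probability_of(self, genes) -> np.ndarray:
        lookup = dict(zip(self.table["gene"], self.table["probability"]))
        return np.array([lookup[g] for g in genes])


def build_features(network: FunctionalNetwork) -> tuple[np.ndarray, list[str]]:
    """Feature matrix: one row per universe gene = its network row."""
    return network.posterior.copy(), list(network.genes)


def train_cv(
    features: np.ndarray,
    genes: list[str],
    labels: LabeledSet,
    folds: int = 5,
    seed: int = 0,
    grid: dict | None = None,
    inner_folds: int = 3,
) -> CVResult:
    """Stratified k-fold CV with nested grid search, balanced class weights.

    Per outer fold, a grid search over *grid* (default
    :data:`DEFAULT_GRID`) selects hyperparameters by inner-CV ROC-AUC; the
    refitted model scores the fold's hold-out genes.  Fully deterministic
    given *seed*.
    """
    grid = DEFAULT_GRID if grid is None else grid
    index = {g: i for i, g in enumerate(genes)}
    missing = [g for g in labels.positives + labels.negatives if g not in index]
    if missing:
        raise ValueError(f"labeled genes absent from the network universe: {missing[:5]}")
    labeled = list(labels.positives) + list(labels.negatives)
    y = np.array([1] * len(labels.positives) + [0] * len(labels.negatives))
    if min(len(labels.positives), len(labels.negatives)) < folds:
        raise ValueError(
            "each class needs at least `folds` genes; add data or reduce folds"
        )
    X = features[[index[g] for g in labeled]]

    outer = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_models, fold_aucs, train_indices = [], [], []
    fold_of_gene: dict[str, int] = {}
    holdout: dict[str, float] = {}
    for f, (tr, te) in enumerate(outer.split(X, y)):
        inner = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=seed + 1)
        search = GridSearchCV(
            RandomForestClassifier(
                class_weight="balanced", random_state=seed * 100 + f, n_jobs=1
            ),
            grid,
            scoring="roc_auc",
            cv=inner,
            n_jobs=1,
        )
        search.fit(X[tr], y[tr])
        model = search.best_estimator_
        p = model.predict_proba(X[te])[:, 1]
        fold_aucs.append(float(roc_auc_score(y[te], p)))
        for i, prob in zip(te, p):
            fold_of_gene[labeled[i]] = f
            holdout[labeled[i]] = float(prob)
        fold_models.append(model)
        train_indices.append(np.array([index[labeled[i]] for i in tr]))
        log.info("fold %d: best params %s, AUC %.3f", f, search.best_params_, fold_aucs[-1])
    return CVResult(fold_models, fold_of_gene, holdout, fold_aucs, train_indices)


def predict_genomewide(
    cv: CVResult,
    features: np.ndarray,
    genes: list[str],
    labels: LabeledSet,
) -> RankingResult:
    """Rank every universe gene by predicted disease-association probability.

    Unlabeled genes: mean of the fold models' probabilities.  Labeled
    genes: the single hold-out probability.  Ties broken by gene symbol.
    """
    pos = set(labels.positives)
    neg = set(labels.negatives)
    fold_probs = np.column_stack(
        [m.predict_proba(features)[:, 1] for m in cv.fold_models]
    )
    mean_probs = fold_probs.mean(axis=1)
    rows = []
    for i, g in enumerate(genes):
        if g in pos or g in neg:
            prob = cv.holdout_probability[g]
            status = "positive" if g in pos else "negative"
        else:
            prob = float(mean_probs[i])
            status = "unlabeled"
        rows.append((g, prob, status))
    df = pd.DataFrame(rows, columns=["gene", "probability", "label_status"])
    df = df.sort_values(
        ["probability", "gene"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return RankingResult(
        table=df,
        cv_auc_mean=cv.auc_mean,
        cv_auc_sd=cv.auc_sd,
        fold_aucs=list(cv.fold_aucs),
    )
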