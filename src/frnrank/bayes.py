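"""Two-layer naive-Bayes integration of evidence channels into a
functional relationship network (FRN).

For a gene pair with evidence E1..En the posterior probability of a
functional relationship FR is

    P(FR | E1..En) = P(FR) prod_i P(Ei|FR) / C ,

where C normalizes over the two classes {FR, not-FR}:

    C = P(FR) prod_i P(Ei|FR) + (1 - P(FR)) prod_i P(Ei|not-FR).

Each channel's score is discretized into equal-frequency bins fitted on
the gold-standard pairs; per-bin conditional probabilities are
Laplace-smoothed counts.  Missing evidence contributes no factor, so a
pair with no evidence anywhere sits at the prior.  Products are computed
in log space.

Integration is layered: the expression datasets are first combined into a
single continuous co-expression posterior (layer 1); that combined score
is then re-binned and re-calibrated alongside the interaction channels
(layer 2) to give the final posterior for every pair in the gene
universe.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit, logit

from .goldstd import GoldStandard
from .pairs import MatrixChannel

log = logging.getLogger(__name__)


@dataclass
class ChannelCPT:
    """Per-bin conditional probability table for one evidence channel.

    ``bin_edges`` are the interior edges; a score s falls in bin
    ``searchsorted(bin_edges, s, side="right")``.  Binary channels use the
    single edge 0.5 (bins {0, 1}).
    """

    name: str
    bin_edges: np.ndarray
    p_given_fr: np.ndarray
    p_given_not_fr: np.ndarray
    binary: bool = False

    def __post_init__(self) -> None:
        for v in (self.p_given_fr, self.p_given_not_fr):
            if not np.isclose(v.sum(), 1.0, atol=1e-9):
                raise ValueError(f"CPT {self.name!r}: probabilities must sum to 1")
            if np.any(v <= 0):
                raise ValueError(f"CPT {self.name!r}: zero probability bin (unsmoothed?)")

    @property
    def n_bins(self) -> int:
        return len(self.p_given_fr)

    def bin_index(self, values: np.ndarray) -> np.ndarray:
        return np.searchsorted(self.bin_edges, values, side="right")

    def log_lr(self) -> np.ndarray:
        return np.log(self.p_given_fr) - np.log(self.p_given_not_fr)


@dataclass
class IntegrationModel:
    """Fitted two-layer model: prior plus per-channel CPTs."""

    prior: float
    layer1_cpts: list[ChannelCPT] = field(default_factory=list)
    layer2_cpts: list[ChannelCPT] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        def enc(c: ChannelCPT) -> dict:
            return {
                "name": c.name,
                "bin_edges": c.bin_edges.tolist(),
                "p_given_fr": c.p_given_fr.tolist(),
                "p_given_not_fr": c.p_given_not_fr.tolist(),
                "binary": c.binary,
            }

        payload = {
            "prior": self.prior,
            "layer1_cpts": [enc(c) for c in self.layer1_cpts],
            "layer2_cpts": [enc(c) for c in self.layer2_cpts],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "IntegrationModel":
        raw = json.loads(Path(path).read_text())

        def dec(d: dict) -> ChannelCPT:
            return ChannelCPT(
                d["name"],
                np.asarray(d["bin_edges"], dtype=float),
                np.asarray(d["p_given_fr"], dtype=float),
                np.asarray(d["p_given_not_fr"], dtype=float),
                d["binary"],
            )

        return cls(
            prior=float(raw["prior"]),
            layer1_cpts=[dec(d) for d in raw["layer1_cpts"]],
            layer2_cpts=[dec(d) for d in raw["layer2_cpts"]],
        )


@dataclass
class FunctionalNetwork:
    """Symmetric gene x gene posterior matrix; diagonal fixed at 0."""

    genes: list[str]
    posterior: np.ndarray

    def __post_init__(self) -> None:
        g = len(self.genes)
        if self.posterior.shape != (g, g):
            raise ValueError("posterior shape does not match gene list")
        if len(set(self.genes)) != g:
            raise ValueError("duplicate gene in network universe")
        np.fill_diagonal(self.posterior, 0.0)
        self._index = {s: i for i, s in enumerate(self.genes)}

    def score(self, a: str, b: str) -> float:
        return float(self.posterior[self._index[a], self._index[b]])


def fit_cpt(
    values_pos: np.ndarray,
    values_neg: np.ndarray,
    n_bins: int = 20,
    smoothing: float = 1.0,
    binary: bool = False,
    name: str = "channel",
) -> ChannelCPT:
    """Fit a CPT from channel scores of gold positive / negative pairs.

    Continuous channels are discretized at the equal-frequency quantiles
    of the pooled gold-pair scores (duplicate edges collapse, so heavily
    tied score distributions may yield fewer effective bins).  Counts are
    Laplace-smoothed by *smoothing* so no bin probability is zero.
    """
    values_pos = np.asarray(values_pos, dtype=float)
    values_neg = np.asarray(values_neg, dtype=float)
    values_pos = values_pos[~np.isnan(values_pos)]
    values_neg = values_neg[~np.isnan(values_neg)]
    if values_pos.size == 0 and values_neg.size == 0:
        raise ValueError(f"channel {name!r} covers no gold-standard pairs")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if binary:
        edges = np.array([0.5])
    else:
        pooled = np.concatenate([values_pos, values_neg])
        qs = np.quantile(pooled, np.linspace(0, 1, n_bins + 1)[1:-1])
        edges = np.unique(qs)
        if edges.size + 1 < n_bins:
            log.info(
                "channel %r: tied scores collapsed %d requested bins to %d",
                name, n_bins, edges.size + 1,
            )
    nb = edges.size + 1
    cp = np.bincount(np.searchsorted(edges, values_pos, side="right"), minlength=nb)
    cn = np.bincount(np.searchsorted(edges, values_neg, side="right"), minlength=nb)
    p_fr = (cp + smoothing) / (cp.sum() + smoothing * nb)
    p_not = (cn + smoothing) / (cn.sum() + smoothing * nb)
    return ChannelCPT(name, edges, p_fr, p_not, binary=binary)


def posterior(
    bin_assignments: Mapping[str, int | None],
    cpts: Sequence[ChannelCPT],
    prior: float,
) -> float:
    """Posterior P(FR | evidence) for one pair from per-channel bins.

    A ``None`` (missing) assignment contributes no factor; with all
    channels missing the posterior is the prior.  Computed in log space.
    """
    if not 0.0 < prior < 1.0:
        raise ValueError("prior must be in (0, 1)")
    L = float(logit(prior))
    by_name = {c.name: c for c in cpts}
    for name, b in bin_assignments.items():
        if b is None:
            continue
        c = by_name[name]
        L += float(c.log_lr()[b])
    return float(expit(L))


def _posterior_matrix(
    channel_mats: Sequence[tuple[ChannelCPT, np.ndarray]], prior: float, shape: tuple
) -> np.ndarray:
    L = np.full(shape, float(logit(prior)))
    for cpt, mat in channel_mats:
        obs = ~np.isnan(mat)
        if not obs.any():
            continue
        llr = cpt.log_lr()
        L[obs] += llr[cpt.bin_index(mat[obs])]
    return expit(L)


def _gold_index_arrays(gold: GoldStandard, index: Mapping[str, int]):
    def to_idx(pairs):
        ii, jj = [], []
        for a, b in pairs:
            ia = index.get(a)
            ib = index.get(b)
            if ia is None or ib is None:
                continue
            ii.append(ia)
            jj.append(ib)
        return np.asarray(ii, dtype=np.intp), np.asarray(jj, dtype=np.intp)

    return to_idx(gold.positives), to_idx(gold.negatives)


def _align_interaction(name, data, kind, genes, index) -> np.ndarray:
    """Dense matrix for an interaction channel over the universe.

    Binary channels are fully observed (absence of an interaction is an
    observed 0); score channels are NaN outside their measured pairs.
    """
    g = len(genes)
    if kind == "binary":
        mat = np.zeros((g, g))
        for a, b in data:
            ia = index.get(a)
            ib = index.get(b)
            if ia is None or ib is None:
                continue
            mat[ia, ib] = 1.0
            mat[ib, ia] = 1.0
        np.fill_diagonal(mat, np.nan)
        return mat
    if isinstance(data, MatrixChannel):
        return data.aligned(list(genes))
    mat = np.full((g, g), np.nan)
    for (a, b), v in data.items():
        ia = index.get(a)
        ib = index.get(b)
        if ia is None or ib is None:
            continue
        mat[ia, ib] = v
        mat[ib, ia] = v
    return mat


def integrate_layer1(
    expression_channels: Sequence[MatrixChannel],
    gold: GoldStandard,
    genes: Sequence[str],
    n_bins: int = 20,
    smoothing: float = 1.0,
    prior: float | None = None,
) -> tuple[list[ChannelCPT], np.ndarray]:
    """Combine expression channels into one co-expression posterior.

    Returns the fitted per-dataset CPTs and the combined matrix over the
    universe; pairs observed in no dataset are NaN (missing downstream).
    """
    if not expression_channels:
        raise ValueError("need at least one expression channel")
    genes = list(genes)
    index = {s: i for i, s in enumerate(genes)}
    if prior is None:
        prior = gold.prior()
    (pi, pj), (ni, nj) = _gold_index_arrays(gold, index)
    cpts, mats = [], []
    for ch in expression_channels:
        mat = ch.aligned(genes)
        cpt = fit_cpt(
            mat[pi, pj], mat[ni, nj], n_bins=n_bins, smoothing=smoothing, name=ch.name
        )
        cpts.append(cpt)
        mats.append(mat)
    combined = _posterior_matrix(list(zip(cpts, mats)), prior, (len(genes), len(genes)))
    observed_any = np.zeros_like(combined, dtype=bool)
    for mat in mats:
        observed_any |= ~np.isnan(mat)
    combined[~observed_any] = np.nan
    np.fill_diagonal(combined, np.nan)
    return cpts, combined


def fit_and_apply(
    expression_channels: Sequence[MatrixChannel],
    interaction_channels: Sequence[tuple[str, object, str]],
    gold: GoldStandard,
    genes: Sequence[str],
    n_bins: int = 20,
    smoothing: float = 1.0,
    prior: float | None = None,
) -> tuple[FunctionalNetwork, IntegrationModel]:
    """Fit the two-layer model and evaluate posteriors for all pairs.

    *interaction_channels* is a sequence of ``(name, data, kind)`` with
    kind ``"binary"`` (a pair set) or ``"score"`` (a pair→score map or a
    :class:`MatrixChannel`).
    """
    genes = list(genes)
    if len(set(genes)) != len(genes):
        raise ValueError("duplicate gene in universe")
    index = {s: i for i, s in enumerate(genes)}
    if prior is None:
        prior = gold.prior()
    (pi, pj), (ni, nj) = _gold_index_arrays(gold, index)
    if pi.size == 0 or ni.size == 0:
        raise ValueError("gold standard has no pairs within the gene universe")

    layer1_cpts: list[ChannelCPT] = []
    layer2: list[tuple[ChannelCPT, np.ndarray]] = []
    if expression_channels:
        layer1_cpts, combined = integrate_layer1(
            expression_channels, gold, genes, n_bins=n_bins,
            smoothing=smoothing, prior=prior,
        )
        cpt = fit_cpt(
            combined[pi, pj], combined[ni, nj], n_bins=n_bins,
            smoothing=smoothing, name="combined_expression",
        )
        layer2.append((cpt, combined))
    for name, data, kind in interaction_channels:
        mat = _align_interaction(name, data, kind, genes, index)
        cpt = fit_cpt(
            mat[pi, pj], mat[ni, nj], n_bins=n_bins, smoothing=smoothing,
            binary=(kind == "binary"), name=name,
        )
        layer2.append((cpt, mat))

    post = _posterior_matrix(layer2, prior, (len(genes), len(genes)))
    model = IntegrationModel(prior, layer1_cpts, [c for c, _ in layer2])
    return FunctionalNetwork(genes, post), model


def build_frn(
    expression_channels: Sequence[MatrixChannel],
    interaction_channels: Sequence[tuple[str, object, str]],
    gold: GoldStandard,
    genes: Sequence[str],
    n_bins: int = 20,
    smoothing: float = 1.0,
    prior: float | None = None,
) -> tuple[FunctionalNetwork, IntegrationModel]:
    """Build the functional relationship network over a gene universe."""
    return fit_and_apply(
        expression_channels, interaction_channels, gold, genes,
        n_bins=n_bins, smoothing=smoothing, prior=prior,
    )


def apply_model(
    model: IntegrationModel,
    expression_channels: Sequence[MatrixChannel],
    interaction_channels: Sequence[tuple[str, object, str]],
    genes: Sequence[str],
) -> FunctionalNetwork:
    """Evaluate an already-fitted model (e.g. reloaded from JSON)."""
    genes = list(genes)
    index = {s: i for i, s in enumerate(genes)}
    layer2: list[tuple[ChannelCPT, np.ndarray]] = []
    cpts = list(model.layer2_cpts)
    if expression_channels:
        mats = [ch.aligned(genes) for ch in expression_channels]
        combined = _posterior_matrix(
            list(zip(model.layer1_cpts, mats)), model.prior,
            (len(genes), len(genes)),
        )
        observed_any = np.zeros_like(combined, dtype=bool)
        for mat in mats:
            observed_any |= ~np.isnan(mat)
        combined[~observed_any] = np.nan
        np.fill_diagonal(combined, np.nan)
        layer2.append((cpts.pop(0), combined))
    for (name, data, kind), cpt in zip(interaction_channels, cpts):
        layer2.append((cpt, _align_interaction(name, data, kind, genes, index)))
    post = _posterior_matrix(layer2, model.prior, (len(genes), len(genes)))
    return FunctionalNetwork(genes, post)
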