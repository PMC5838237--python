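"""Expression preprocessing and per-pair co-expression evidence.

Each microarray-style dataset goes through the same pipeline: log2
transform, removal of probes missing in more than a threshold fraction of
samples, k-nearest-neighbour imputation of the remaining missing values,
probe→gene collapse by averaging, and finally a Fisher z-transformed
Pearson correlation for every gene pair present in the dataset.

The kNN imputation operates over probes (rows): a missing value for probe
p in sample s is the inverse-distance-weighted mean of the k nearest
probes observed in s, with distance the plain Euclidean distance over
samples where both probes are observed (at least two co-observed samples
required; otherwise the probe's own mean is used, with a warning).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .pairs import MatrixChannel

log = logging.getLogger(__name__)

CLIP = 1.0 - 1e-12  # correlation clip before atanh


@dataclass
class ExpressionMatrix:
    """One dataset: probe x sample values, possibly missing (NaN)."""

    probes: list[str]
    samples: list[str]
    values: np.ndarray
    probe_to_gene: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.probes)) != len(self.probes):
            raise ValueError("duplicate probe ids")
        if self.values.shape != (len(self.probes), len(self.samples)):
            raise ValueError("values shape does not match probes x samples")


def _knn_impute(values: np.ndarray, k: int) -> np.ndarray:
    """Impute missing entries from the k nearest probe rows.

    Pairwise squared distances over co-observed samples are computed with
    three matrix products on the zero-filled value and mask matrices.
    """
    X = values.copy()
    mask = ~np.isnan(X)
    if mask.all():
        return X
    Xf = np.where(mask, X, 0.0)
    M = mask.astype(float)
    sq = Xf ** 2
    # d2[i,j] = sum over co-observed s of (x_is - x_js)^2
    d2 = sq @ M.T + M @ sq.T - 2.0 * (Xf @ Xf.T)
    d2 = np.maximum(d2, 0.0)
    co = M @ M.T  # co-observed sample counts
    dist = np.sqrt(d2)
    row_means = np.nanmean(np.where(mask, values, np.nan), axis=1)

    missing_rows = np.where(~mask.all(axis=1))[0]
    n_fallback = 0
    for i in missing_rows:
        valid = (co[i] >= 2)
        valid[i] = False
        for s in np.where(~mask[i])[0]:
            cand = np.where(valid & mask[:, s])[0]
            if cand.size == 0:
                X[i, s] = row_means[i]
                n_fallback += 1
                continue
            d = dist[i, cand]
            order = np.argsort(d, kind="stable")[:k]
            dk = d[order]
            vk = values[cand[order], s]
            if np.any(dk < 1e-12):
                X[i, s] = vk[dk < 1e-12].mean()
            else:
                w = 1.0 / dk
                X[i, s] = float(np.sum(w * vk) / np.sum(w))
    if n_fallback:
        log.warning("kNN imputation: %d value(s) fell back to the probe mean", n_fallback)
    return X


def preprocess(
    matrix: ExpressionMatrix,
    missing_threshold: float = 0.30,
    k_neighbors: int = 10,
    offset: float | None = None,
) -> ExpressionMatrix:
    """log2 → drop high-missingness probes → kNN impute → collapse to genes.

    Values must be strictly positive where observed; pass ``offset=c`` to
    work on log2(x + c) for data containing zeros or negatives.  Probes
    missing in strictly more than *missing_threshold* of the samples are
    discarded.  The returned matrix is gene-level (rows are genes, each
    mapping to itself) with no missing values.
    """
    if k_neighbors < 1:
        raise ValueError("k_neighbors must be >= 1")
    vals = matrix.values.astype(float)
    if offset is not None:
        vals = vals + offset
    observed = ~np.isnan(vals)
    if np.any(vals[observed] <= 0):
        raise ValueError(
            "nonpositive expression values; pass offset=c to use log2(x + c)"
        )
    vals = np.where(observed, np.log2(np.where(observed, vals, 1.0)), np.nan)

    miss_frac = np.isnan(vals).mean(axis=1)
    keep = miss_frac <= missing_threshold  # drop only strictly > threshold
    probes = [p for p, k_ in zip(matrix.probes, keep) if k_]
    vals = vals[keep]
    if not probes:
        raise ValueError("no probes left after the missingness filter")

    vals = _knn_impute(vals, k_neighbors)

    gene_rows: dict[str, list[int]] = {}
    n_unmapped = 0
    for i, p in enumerate(probes):
        g = matrix.probe_to_gene.get(p)
        if g is None:
            n_unmapped += 1
            continue
        gene_rows.setdefault(g, []).append(i)
    if n_unmapped:
        log.warning("dropped %d probe(s) with no gene mapping", n_unmapped)
    if not gene_rows:
        raise ValueError("no probe maps to a gene")
    genes = sorted(gene_rows)
    collapsed = np.vstack([vals[gene_rows[g]].mean(axis=0) for g in genes])
    return ExpressionMatrix(
        probes=genes,
        samples=list(matrix.samples),
        values=collapsed,
        probe_to_gene={g: g for g in genes},
    )


def fisher_z_channel(matrix: ExpressionMatrix, name: str | None = None) -> MatrixChannel:
    """Fisher z-transformed Pearson correlation for every gene pair.

    Requires a preprocessed (gene-level, complete) matrix with >= 3
    samples.  Correlations are clipped to ±(1 − 1e−12) before atanh so the
    channel is finite; pairs involving a zero-variance gene score 0.
    """
    if np.isnan(matrix.values).any():
        raise ValueError("fisher_z_channel requires a complete (imputed) matrix")
    if len(matrix.samples) < 3:
        raise ValueError("need >= 3 samples to correlate")
    vals = matrix.values
    sd = vals.std(axis=1)
    flat = sd == 0
    r = np.corrcoef(vals)
    if flat.any():
        log.warning("%d zero-variance gene(s): their pairs scored 0", int(flat.sum()))
        r[flat, :] = 0.0
        r[:, flat] = 0.0
    r = np.clip(r, -CLIP, CLIP)
    z = np.arctanh(r)
    np.fill_diagonal(z, np.nan)
    return MatrixChannel(name or "expression", list(matrix.probes), z)
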