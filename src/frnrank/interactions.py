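"""Protein interaction, docking, and phenotype-overlap evidence channels.

Covers merging binary protein–protein interaction (PPI) sources, reducing
isoform-level docking scores to gene pairs (maximum over isoform pairs),
counting shared phenotype labels per gene pair, and re-labelling any
channel into a single gene namespace through a homolog map.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np

from .pairs import MatrixChannel, canonical_pair

log = logging.getLogger(__name__)


def merge_ppi(sources: Sequence[Iterable[tuple[str, str]]]) -> set[tuple[str, str]]:
    """Union of interaction sources with redundant pairs removed.

    Each source is an iterable of (possibly non-canonical) gene pairs; the
    result is a canonical pair set.  Idempotent and order-invariant.
    """
    merged: set[tuple[str, str]] = set()
    for i, src in enumerate(sources):
        pairs = {canonical_pair(a, b) for a, b in src if a != b}
        log.info("PPI source %d: %d unique pair(s)", i, len(pairs))
        merged |= pairs
    log.info("merged PPI: %d unique pair(s)", len(merged))
    return merged


def docking_gene_scores(
    isoform_scores: Mapping[tuple[str, str], float],
    isoform_to_gene: Mapping[str, str],
) -> dict[tuple[str, str], float]:
    """Gene-pair docking score = maximum over all of its isoform pairs.

    Isoform pairs whose isoforms map to the same gene collapse to a
    self-pair and are excluded; unmapped isoforms are skipped with a log.
    """
    out: dict[tuple[str, str], float] = {}
    n_unmapped = n_self = 0
    for (ia, ib), s in isoform_scores.items():
        ga = isoform_to_gene.get(ia)
        gb = isoform_to_gene.get(ib)
        if ga is None or gb is None:
            n_unmapped += 1
            continue
        if ga == gb:
            n_self += 1
            continue
        key = canonical_pair(ga, gb)
        if key not in out or s > out[key]:
            out[key] = float(s)
    if n_unmapped:
        log.warning("docking: skipped %d isoform pair(s) with unmapped isoforms", n_unmapped)
    if n_self:
        log.info("docking: excluded %d within-gene isoform pair(s)", n_self)
    return out


def phenotype_overlap(annotations: Mapping[str, set[str]]) -> MatrixChannel:
    """Number of shared phenotype labels for every pair of annotated genes.

    Pairs of annotated genes with zero shared labels score 0 (informative
    negative evidence); genes without any annotation are simply absent
    from the channel, i.e. missing evidence.
    """
    genes = sorted(annotations)
    labels = sorted({lab for labs in annotations.values() for lab in labs})
    lab_idx = {lab: j for j, lab in enumerate(labels)}
    B = np.zeros((len(genes), max(len(labels), 1)))
    for i, g in enumerate(genes):
        for lab in annotations[g]:
            B[i, lab_idx[lab]] = 1.0
    overlap = B @ B.T
    np.fill_diagonal(overlap, np.nan)
    return MatrixChannel("phenotype", genes, overlap)


def map_to_namespace(channel, homolog_map: Mapping[str, str]):
    """Re-label a pair channel into a target gene namespace.

    *channel* is either a pair→score mapping or a pair set (binary).
    Pairs with an unmapped gene are dropped (counted in the log); pairs
    collapsing onto a self-pair are dropped; two source pairs landing on
    the same target pair keep the maximum score.
    """
    binary = not isinstance(channel, Mapping)
    items = ((p, 1.0) for p in channel) if binary else channel.items()
    out: dict[tuple[str, str], float] = {}
    n_unmapped = n_self = n_collide = 0
    for (a, b), s in items:
        ha = homolog_map.get(a)
        hb = homolog_map.get(b)
        if ha is None or hb is None:
            n_unmapped += 1
            continue
        if ha == hb:
            n_self += 1
            continue
        key = canonical_pair(ha, hb)
        if key in out:
            n_collide += 1
            out[key] = max(out[key], s)
        else:
            out[key] = float(s)
    log.info(
        "namespace mapping: %d pair(s) dropped unmapped, %d collapsed to self, "
        "%d collision(s) resolved by max", n_unmapped, n_self, n_collide,
    )
    return set(out) if binary else out


def map_annotations(
    annotations: Mapping[str, set[str]], homolog_map: Mapping[str, str]
) -> dict[str, set[str]]:
    """Re-label per-gene annotation sets; colliding genes union their labels."""
    out: dict[str, set[str]] = {}
    n_unmapped = 0
    for g, labs in annotations.items():
        h = homolog_map.get(g)
        if h is None:
            n_unmapped += 1
            continue
        out.setdefault(h, set()).update(labs)
    if n_unmapped:
        log.warning("annotations: %d unmapped gene(s) dropped", n_unmapped)
    return out
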