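"""Gold-standard functional gene pairs from pathway/GO-style annotations.

Positive pairs are gene pairs co-annotated to at least one term of
moderate size (terms with fewer than 5 or more than 300 genes are too
specific or too broad to be informative and are filtered out).  Negative
pairs — required to calibrate the per-channel conditional probability
tables — are pairs of annotated genes that are never co-annotated, the
standard convention when only positive relationships are curated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping

from .io import GeneSet, GeneSetCollection
from .pairs import canonical_pair

log = logging.getLogger(__name__)


@dataclass
class GoldStandard:
    positives: set[tuple[str, str]]
    negatives: set[tuple[str, str]]
    annotated_genes: frozenset[str]

    def prior(self) -> float:
        """Default prior P(FR): positive fraction among gold pairs."""
        return len(self.positives) / (len(self.positives) + len(self.negatives))


def filter_terms(
    collection: GeneSetCollection, min_size: int = 5, max_size: int = 300
) -> GeneSetCollection:
    """Keep terms with min_size <= |genes| <= max_size (bounds inclusive)."""
    kept = GeneSetCollection()
    for name, gs in collection.sets.items():
        if min_size <= len(gs.genes) <= max_size:
            kept.sets[name] = GeneSet(gs.description, list(gs.genes))
    log.info("term filter: kept %d of %d set(s)", len(kept), len(collection))
    return kept


def build_gold_standard(
    collections: Mapping[str, GeneSetCollection],
    homolog_maps: Mapping[str, Mapping[str, str]] | None = None,
) -> GoldStandard:
    """Assemble positives/negatives from per-species term collections.

    Non-reference species are re-labelled through their homolog map before
    pair enumeration (unmapped genes dropped, within-set duplicates after
    mapping collapsed).  Positives are the union over species and terms of
    all within-term pairs; negatives are all remaining pairs of annotated
    genes.
    """
    homolog_maps = homolog_maps or {}
    positives: set[tuple[str, str]] = set()
    annotated: set[str] = set()
    for species, coll in collections.items():
        hmap = homolog_maps.get(species)
        n_pairs_before = len(positives)
        for _, gs in coll.sets.items():
            if hmap is not None:
                genes = list(dict.fromkeys(
                    hmap[g] for g in gs.genes if g in hmap
                ))
            else:
                genes = list(dict.fromkeys(gs.genes))
            annotated.update(genes)
            for a, b in combinations(sorted(genes), 2):
                positives.add(canonical_pair(a, b))
        log.info(
            "gold standard: species %s added %d new positive pair(s)",
            species, len(positives) - n_pairs_before,
        )
    negatives = {
        (a, b)
        for a, b in combinations(sorted(annotated), 2)
        if (a, b) not in positives
    }
    log.info(
        "gold standard: %d positives, %d negatives over %d annotated gene(s)",
        len(positives), len(negatives), len(annotated),
    )
    return GoldStandard(positives, negatives, frozenset(annotated))
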