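"""Decile enrichment validation of a gene ranking.

The ranking is split into 10 evenly binned deciles; for a candidate gene
list, enrichment in the first (top) decile is tested with an exact
one-sided binomial test against an expected proportion derived from a
background gene list (e.g. genes with synonymous de novo variants in
unaffected siblings, which should carry no disease signal).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .ranking import RankingResult

log = logging.getLogger(__name__)


@dataclass
class DecileAssignment:
    """Decile index (1..10) per gene, with the bin boundaries used.

    Decile d covers 0-based rank indices [floor((d-1)N/10), floor(dN/10)).
    """

    decile_of: dict[str, int]
    boundaries: list[int]

    def genes_in(self, decile: int) -> set[str]:
        return {g for g, d in self.decile_of.items() if d == decile}


def decile_sizes(n: int) -> list[int]:
    bounds = [(d * n) // 10 for d in range(11)]
    return [bounds[d + 1] - bounds[d] for d in range(10)]


def assign_deciles(ranking: RankingResult) -> DecileAssignment:
    """Split the ranking into 10 evenly binned deciles (floor boundaries)."""
    genes = list(ranking.table["gene"])
    n = len(genes)
    if n < 10:
        raise ValueError("need at least 10 ranked genes for deciles")
    bounds = [(d * n) // 10 for d in range(11)]
    decile_of: dict[str, int] = {}
    for d in range(10):
        for g in genes[bounds[d]:bounds[d + 1]]:
            decile_of[g] = d + 1
    return DecileAssignment(decile_of, bounds)


def expected_proportion(
    background: Sequence[str], deciles: DecileAssignment
) -> float:
    """Fraction of background genes (present in the ranking) in decile 1."""
    present = [g for g in background if g in deciles.decile_of]
    dropped = len(background) - len(present)
    if dropped:
        log.info("expected_proportion: %d background gene(s) not in ranking", dropped)
    if not present:
        raise ValueError("no background gene appears in the ranking")
    k = sum(1 for g in present if deciles.decile_of[g] == 1)
    return k / len(present)


def decile_binomial_test(k: int, n: int, p0: float) -> float:
    """Exact upper-tail binomial p-value P(X >= k), X ~ Binomial(n, p0)."""
    if not (0 <= k <= n):
        raise ValueError("need 0 <= k <= n")
    if not (0.0 < p0 < 1.0):
        raise ValueError("need 0 < p0 < 1")
    return float(binomtest(k, n, p0, alternative="greater").pvalue)


@dataclass
class EnrichmentResult:
    name: str
    n_listed: int
    n_tested: int
    k_top: int
    p0: float
    p_value: float


def run_validation(
    ranking: RankingResult,
    lists: Mapping[str, Sequence[str]],
    background: Sequence[str],
) -> tuple[pd.DataFrame, dict[str, list[int]]]:
    """Top-decile enrichment for each named list against one shared p0.

    Returns the result table and, per list, the full 10-bin decile
    histogram (counts of the list's ranked genes per decile).  Lists with
    no gene in the ranking are flagged (NaN p-value) and not tested.
    """
    deciles = assign_deciles(ranking)
    p0 = expected_proportion(background, deciles)
    rows = []
    histograms: dict[str, list[int]] = {}
    for name, genes in lists.items():
        genes = list(dict.fromkeys(genes))
        present = [g for g in genes if g in deciles.decile_of]
        hist = [0] * 10
        for g in present:
            hist[deciles.decile_of[g] - 1] += 1
        histograms[name] = hist
        if not present:
            log.warning("list %r: no gene in the ranking; not tested", name)
            rows.append(EnrichmentResult(name, len(genes), 0, 0, p0, float("nan")))
            continue
        k = hist[0]
        p = decile_binomial_test(k, len(present), p0)
        rows.append(EnrichmentResult(name, len(genes), len(present), k, p0, p))
    df = pd.DataFrame([r.__dict__ for r in rows])
    return df, histograms
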