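"""Curation of training gene sets for disease-gene classification.

The positive ("truth") set is the deduplicated union of several curated
component lists (e.g. a database's high-confidence and syndromic
categories plus a sequencing-study hit list); the negative ("control")
set is an externally curated non-disease list purged of any gene that
appears in the truth set.  Symbols are taken as given — no aliasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence


@dataclass
class CurationReport:
    truth_genes: list[str]
    control_genes: list[str]
    component_sizes: dict[str, int] = field(default_factory=dict)
    pairwise_overlaps: dict[tuple[str, str], int] = field(default_factory=dict)
    removed_from_control: list[str] = field(default_factory=list)


def curate_truth_set(
    lists: Mapping[str, Sequence[str]],
    report: CurationReport | None = None,
) -> list[str]:
    """Deduplicated, lexicographically sorted union of component gene lists.

    Pairwise overlap counts between components are recorded on *report*
    when one is supplied, so curation decisions stay auditable.
    """
    named = {name: list(dict.fromkeys(genes)) for name, genes in lists.items()}
    if not named or all(len(v) == 0 for v in named.values()):
        raise ValueError("curate_truth_set needs at least one non-empty list")
    union: set[str] = set()
    for genes in named.values():
        union.update(genes)
    if report is not None:
        for name, genes in named.items():
            report.component_sizes[name] = len(genes)
        for (na, ga), (nb, gb) in combinations(named.items(), 2):
            report.pairwise_overlaps[(na, nb)] = len(set(ga) & set(gb))
    return sorted(union)


def curate_control_set(
    control: Sequence[str], truth: Sequence[str]
) -> tuple[list[str], list[str]]:
    """Remove truth genes from the control list, preserving order.

    Returns ``(retained, removed)``.
    """
    truth_set = set(truth)
    retained = [g for g in control if g not in truth_set]
    removed = [g for g in control if g in truth_set]
    return retained, removed


def curate(
    truth_lists: Mapping[str, Sequence[str]], control: Sequence[str]
) -> CurationReport:
    """Full curation: union the truth components, purge the control list."""
    report = CurationReport(truth_genes=[], control_genes=[])
    report.truth_genes = curate_truth_set(truth_lists, report)
    report.control_genes, report.removed_from_control = curate_control_set(
        control, report.truth_genes
    )
    return report
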