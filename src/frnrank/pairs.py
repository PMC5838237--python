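"""Canonical gene pairs and per-pair evidence containers.

A gene pair is always stored canonically as a tuple ``(a, b)`` with
``a < b`` lexicographically; self-pairs are invalid.  Evidence over pairs
comes in two shapes:

* small, sparse evidence (protein docking, parsed pair tables) lives in
  plain ``dict[tuple[str, str], float]`` maps;
* genome-scale evidence (expression correlation, phenotype overlap) lives
  in :class:`MatrixChannel`, a dense symmetric matrix with ``NaN`` marking
  pairs for which the data source carries no measurement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "canonical_pair",
    "MatrixChannel",
    "pairs_to_matrix_channel",
]


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Return the unordered pair (a, b) in canonical (sorted) form.

    Raises ``ValueError`` for self-pairs — a gene has no pair with itself.
    """
    if a == b:
        raise ValueError(f"self-pair is not a valid gene pair: {a!r}")
    return (a, b) if a < b else (b, a)


@dataclass
class MatrixChannel:
    """Dense symmetric per-pair evidence for one data source.

    ``values[i, j]`` is the score of the pair ``(genes[i], genes[j])``;
    ``NaN`` means the source does not cover that pair.  The diagonal is
    always ``NaN`` (self-pairs carry no evidence).
    """

    name: str
    genes: list[str]
    values: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        g = len(self.genes)
        if self.values.shape != (g, g):
            raise ValueError(
                f"channel {self.name!r}: matrix shape {self.values.shape} "
                f"does not match {g} genes"
            )
        self._index = {s: i for i, s in enumerate(self.genes)}
        if len(self._index) != g:
            raise ValueError(f"channel {self.name!r}: duplicate gene symbols")
        np.fill_diagonal(self.values, np.nan)

    def score(self, a: str, b: str) -> float:
        """Score of the unordered pair (a, b); NaN if unmeasured or absent."""
        canonical_pair(a, b)
        ia = self._index.get(a)
        ib = self._index.get(b)
        if ia is None or ib is None:
            return float("nan")
        return float(self.values[ia, ib])

    def to_pairs(self) -> dict[tuple[str, str], float]:
        """Materialize measured pairs as a canonical-pair map (small channels)."""
        iu, ju = np.triu_indices(len(self.genes), k=1)
        vals = self.values[iu, ju]
        keep = ~np.isnan(vals)
        out: dict[tuple[str, str], float] = {}
        for i, j, v in zip(iu[keep], ju[keep], vals[keep]):
            out[canonical_pair(self.genes[i], self.genes[j])] = float(v)
        return out

    def aligned(self, universe: list[str]) -> np.ndarray:
        """Project onto a gene universe; genes absent from the channel get NaN."""
        g = len(universe)
        out = np.full((g, g), np.nan)
        pos = [(k, self._index[s]) for k, s in enumerate(universe) if s in self._index]
        if pos:
            rows = np.array([p[0] for p in pos])
            srcs = np.array([p[1] for p in pos])
            out[np.ix_(rows, rows)] = self.values[np.ix_(srcs, srcs)]
        np.fill_diagonal(out, np.nan)
        return out


def pairs_to_matrix_channel(
    name: str,
    scores: Mapping[tuple[str, str], float],
    genes: Iterable[str] | None = None,
) -> MatrixChannel:
    """Build a dense channel from a canonical-pair score map.

    If *genes* is omitted, the channel covers exactly the genes occurring in
    *scores*, in sorted order.
    """
    if genes is None:
        seen: set[str] = set()
        for a, b in scores:
            seen.add(a)
            seen.add(b)
        genes = sorted(seen)
    genes = list(genes)
    index = {s: i for i, s in enumerate(genes)}
    mat = np.full((len(genes), len(genes)), np.nan)
    for (a, b), v in scores.items():
        ia = index.get(a)
        ib = index.get(b)
        if ia is None or ib is None:
            continue
        mat[ia, ib] = v
        mat[ib, ia] = v
    return MatrixChannel(name, genes, mat)
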