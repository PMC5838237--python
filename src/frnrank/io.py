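"""Tabular readers and writers for every format the pipeline touches.

All tabular formats are tab-separated with a header row.  Parsers raise on
malformed input rather than skipping rows silently; recoverable oddities
(duplicate genes within a gene set, duplicate pair rows) are repaired with
a logged warning.  Posterior probabilities are serialized with 10
significant digits so that write → read round-trips exactly at the
precision the downstream analyses consume.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .pairs import canonical_pair

log = logging.getLogger(__name__)

PROB_FORMAT = "%.10g"


@dataclass
class GeneSet:
    description: str
    genes: list[str]


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style): pathway terms, curated lists, modules."""

    sets: dict[str, GeneSet] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def sizes(self) -> dict[str, int]:
        return {name: len(gs.genes) for name, gs in self.sets.items()}


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: per line, set name, description, then member genes.

    Duplicate genes within one set are removed (first occurrence kept) with
    a warning; a line with fewer than three fields is a parse error.
    """
    coll = GeneSetCollection()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: GMT line needs >=3 tab-separated "
                    f"fields, got {len(fields)}"
                )
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            unique = list(dict.fromkeys(genes))
            if len(unique) < len(genes):
                log.warning(
                    "%s: line %d: set %r: removed %d duplicate gene(s)",
                    path, lineno, name, len(genes) - len(unique),
                )
            if name in coll.sets:
                raise ValueError(f"{path}: line {lineno}: duplicate set name {name!r}")
            coll.sets[name] = GeneSet(desc, unique)
    return coll


def write_gmt(path: str | Path, collection: GeneSetCollection) -> None:
    with open(path, "w") as fh:
        for name, gs in collection.sets.items():
            fh.write("\t".join([name, gs.description, *gs.genes]) + "\n")


def read_pair_table(
    path: str | Path, value_column: str | None = None
) -> dict[tuple[str, str], float]:
    """Read a gene-pair score table: two gene columns, then value column(s).

    Pairs are canonicalized; duplicate rows for one unordered pair collapse
    to the maximum value (warning); self-pairs are dropped (warning);
    non-numeric values are a parse error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 3:
        raise ValueError(f"{path}: pair table needs >=3 columns, got {df.shape[1]}")
    ga, gb = df.columns[:2]
    vcol = value_column if value_column is not None else df.columns[2]
    try:
        values = df[vcol].astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric value in column {vcol!r}: {exc}") from exc

    out: dict[tuple[str, str], float] = {}
    n_self = n_dup = 0
    for a, b, v in zip(df[ga], df[gb], values):
        if a == b:
            n_self += 1
            continue
        key = canonical_pair(a, b)
        if key in out:
            n_dup += 1
            out[key] = max(out[key], v)
        else:
            out[key] = float(v)
    if n_self:
        log.warning("%s: dropped %d self-pair row(s)", path, n_self)
    if n_dup:
        log.warning("%s: collapsed %d duplicate pair row(s) keeping max", path, n_dup)
    return out


def write_pair_table(
    path: str | Path,
    scores: Mapping[tuple[str, str], float],
    value_name: str = "score",
) -> None:
    with open(path, "w") as fh:
        fh.write(f"gene_a\tgene_b\t{value_name}\n")
        for (a, b) in sorted(scores):
            fh.write(f"{a}\t{b}\t{PROB_FORMAT % scores[(a, b)]}\n")


def read_expression_tsv(path: str | Path, probe_to_gene: Mapping[str, str] | None = None):
    """Read a probe x sample expression matrix (first column = probe id)."""
    from .expression import ExpressionMatrix

    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate probe rows: {dups[:5]}")
    return ExpressionMatrix(
        probes=list(df.index.astype(str)),
        samples=list(df.columns.astype(str)),
        values=df.to_numpy(dtype=float),
        probe_to_gene=dict(probe_to_gene) if probe_to_gene else {},
    )


def write_expression_tsv(path: str | Path, matrix) -> None:
    df = pd.DataFrame(matrix.values, index=matrix.probes, columns=matrix.samples)
    df.index.name = "probe"
    df.to_csv(path, sep="\t", na_rep="NA")


def read_gene_list(path: str | Path) -> list[str]:
    """Read a plain gene list, one symbol per line; order preserved."""
    genes: list[str] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            g = raw.strip()
            if not g:
                continue
            if any(c.isspace() for c in g):
                raise ValueError(f"{path}: line {lineno}: gene symbol contains whitespace: {g!r}")
            if g in seen:
                log.warning("%s: line %d: duplicate gene %r skipped", path, lineno, g)
                continue
            seen.add(g)
            genes.append(g)
    return genes


def write_gene_list(path: str | Path, genes: list[str]) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(g + "\n")


def read_homolog_map(path: str | Path) -> dict[str, str]:
    """Read a two-column source→target symbol map (also used for probe maps)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: map needs 2 columns, got {df.shape[1]}")
    src, dst = df.columns[:2]
    if df[src].duplicated().any():
        raise ValueError(f"{path}: duplicate source symbols in map")
    return dict(zip(df[src], df[dst]))


def write_homolog_map(path: str | Path, mapping: Mapping[str, str],
                      columns: tuple[str, str] = ("source", "target")) -> None:
    with open(path, "w") as fh:
        fh.write(f"{columns[0]}\t{columns[1]}\n")
        for k in mapping:
            fh.write(f"{k}\t{mapping[k]}\n")


def read_annotations(path: str | Path) -> dict[str, set[str]]:
    """Read gene→label annotation rows (e.g. phenotype labels)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: annotation table needs 2 columns")
    out: dict[str, set[str]] = {}
    gcol, lcol = df.columns[:2]
    for g, lab in zip(df[gcol], df[lcol]):
        out.setdefault(g, set()).add(lab)
    return out


def write_annotations(path: str | Path, annotations: Mapping[str, set[str]]) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tlabel\n")
        for g in sorted(annotations):
            for lab in sorted(annotations[g]):
                fh.write(f"{g}\t{lab}\n")


def write_ranking(path: str | Path, ranking) -> None:
    """Write a ranking: columns rank, gene, probability, label_status."""
    df = ranking.table
    with open(path, "w") as fh:
        fh.write("rank\tgene\tprobability\tlabel_status\n")
        for row in df.itertuples(index=False):
            fh.write(
                f"{row.rank}\t{row.gene}\t{PROB_FORMAT % row.probability}"
                f"\t{row.label_status}\n"
            )


def read_ranking(path: str | Path):
    from .ranking import RankingResult

    df = pd.read_csv(path, sep="\t", dtype={"gene": str})
    if df["gene"].duplicated().any():
        raise ValueError(f"{path}: duplicate gene rows in ranking")
    df = df[["rank", "gene", "probability", "label_status"]]
    return RankingResult(table=df, cv_auc_mean=float("nan"), cv_auc_sd=float("nan"))


def write_network_edges(path: str | Path, network, threshold: float) -> None:
    """Export all network pairs with posterior >= threshold as an edge list."""
    genes = network.genes
    iu, ju = np.triu_indices(len(genes), k=1)
    post = network.posterior[iu, ju]
    keep = post >= threshold
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tposterior\n")
        for i, j, p in zip(iu[keep], ju[keep], post[keep]):
            a, b = canonical_pair(genes[i], genes[j])
            fh.write(f"{a}\t{b}\t{PROB_FORMAT % p}\n")


@dataclass
class RunConfig:
    """A pipeline run: a seed, named input paths, and free parameters.

    The seed fully determines every stochastic choice downstream.
    """

    seed: int
    paths: dict[str, str] = field(default_factory=dict)
    parameters: dict = field(default_factory=dict)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) if str(path).endswith((".yml", ".yaml")) else json.load(fh)
        cfg = cls(
            seed=int(raw.get("seed", 0)),
            paths=dict(raw.get("paths", {})),
            parameters=dict(raw.get("parameters", {})),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        missing = [f"{k}={v}" for k, v in self.paths.items() if not Path(v).exists()]
        if missing:
            raise FileNotFoundError("config paths do not exist: " + ", ".join(missing))
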