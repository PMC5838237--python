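"""End-to-end pipeline orchestration over a run directory.

Stages run in a fixed order — simulate, curate, evidence, gold-standard,
build-network, rank (train + genome-wide prediction), validate, cluster,
enrich.  Every stage is file-based: it reads the persisted outputs of the
stages before it (raising a clear error naming the stage to run first if
one is missing) and writes its own outputs under the run directory, so
any stage can be re-run or resumed in isolation.  ``run_all`` chains all
stages and writes a manifest recording the parameters actually used and
a content digest of every output; with a fixed seed a re-run reproduces
every digest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io as fio
from .bayes import FunctionalNetwork, build_frn
from .community import (
    extract_disease_network,
    girvan_newman_partition,
    hypergeometric_enrichment,
)
from .curation import curate
from .enrichment import assign_deciles, run_validation
from .expression import fisher_z_channel, preprocess
from .goldstd import GoldStandard, build_gold_standard, filter_terms
from .interactions import merge_ppi, phenotype_overlap
from .io import RunConfig
from .ranking import LabeledSet, build_features, predict_genomewide, train_cv
from .synthetic import SyntheticConfig, generate_study, write_study

log = logging.getLogger(__name__)

STAGES = [
    "simulate", "curate", "evidence", "gold-standard", "build-network",
    "rank", "validate", "cluster", "enrich",
]


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _require(path: Path, produced_by: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing input {path}; run the {produced_by!r} stage first"
        )
    return path


def synthetic_config_from(params: dict) -> SyntheticConfig:
    cfg = SyntheticConfig(**params.get("synthetic", {}))
    cfg.validate()
    return cfg


def validate_parameters(params: dict) -> None:
    """Reject an invalid configuration before any stage runs."""
    if int(params.get("folds", 5)) < 2:
        raise ValueError("folds must be >= 2")
    if not 0 < float(params.get("edge_threshold", 0.98)) <= 1:
        raise ValueError("edge_threshold must be in (0, 1]")
    if int(params.get("n_bins", 20)) < 2:
        raise ValueError("n_bins must be >= 2")
    synthetic_config_from(params)


# ----------------------------------------------------------------- stages

def stage_simulate(out: Path, seed: int, params: dict) -> list[Path]:
    cfg = synthetic_config_from(params)
    study = generate_study(cfg, seed=seed)
    paths = write_study(study, out / "study")
    return [Path(p) for p in paths.values()]


def stage_curate(out: Path) -> list[Path]:
    truth = fio.read_gene_list(_require(out / "study" / "truth_genes.txt", "simulate"))
    control = fio.read_gene_list(_require(out / "study" / "control_genes.txt", "simulate"))
    report = curate({"truth": truth}, control)
    fio.write_gene_list(out / "curated_truth.txt", report.truth_genes)
    fio.write_gene_list(out / "curated_control.txt", report.control_genes)
    (out / "curation_report.json").write_text(json.dumps({
        "component_sizes": report.component_sizes,
        "n_truth": len(report.truth_genes),
        "n_control": len(report.control_genes),
        "removed_from_control": report.removed_from_control,
    }, indent=1))
    return [out / "curated_truth.txt", out / "curated_control.txt",
            out / "curation_report.json"]


def stage_evidence(out: Path, params: dict) -> list[Path]:
    """Preprocess expression to gene level and merge the PPI sources."""
    k_neighbors = int(params.get("k_neighbors", 10))
    missing_threshold = float(params.get("missing_threshold", 0.30))
    study_dir = out / "study"
    outputs: list[Path] = []
    d = 0
    while (study_dir / f"expression_{d}.tsv").exists():
        probe_map = fio.read_homolog_map(study_dir / f"probe_map_{d}.tsv")
        mat = fio.read_expression_tsv(study_dir / f"expression_{d}.tsv", probe_map)
        pre = preprocess(mat, missing_threshold=missing_threshold, k_neighbors=k_neighbors)
        p = out / f"expression_gene_{d}.tsv"
        fio.write_expression_tsv(p, pre)
        outputs.append(p)
        d += 1
    if d == 0:
        _require(study_dir / "expression_0.tsv", "simulate")
    ppi_raw = fio.read_pair_table(_require(study_dir / "ppi.tsv", "simulate"))
    ppi = merge_ppi([set(ppi_raw)])
    fio.write_pair_table(out / "ppi_merged.tsv", {p_: 1.0 for p_ in ppi}, "interacts")
    outputs.append(out / "ppi_merged.tsv")
    return outputs


def stage_gold_standard(out: Path, params: dict) -> list[Path]:
    gmt = fio.read_gmt(_require(out / "study" / "pathways.gmt", "simulate"))
    filtered = filter_terms(
        gmt,
        min_size=int(params.get("term_min_size", 5)),
        max_size=int(params.get("term_max_size", 300)),
    )
    gold = build_gold_standard({"study": filtered})
    fio.write_pair_table(out / "gold_positives.tsv",
                         {p: 1.0 for p in gold.positives}, "positive")
    fio.write_pair_table(out / "gold_negatives.tsv",
                         {p: 0.0 for p in gold.negatives}, "positive")
    (out / "gold_summary.json").write_text(json.dumps({
        "n_positives": len(gold.positives),
        "n_negatives": len(gold.negatives),
        "n_annotated_genes": len(gold.annotated_genes),
        "prior": gold.prior(),
    }, indent=1))
    return [out / "gold_positives.tsv", out / "gold_negatives.tsv",
            out / "gold_summary.json"]


def _load_gold(out: Path) -> GoldStandard:
    pos = set(fio.read_pair_table(_require(out / "gold_positives.tsv", "gold-standard")))
    neg = set(fio.read_pair_table(_require(out / "gold_negatives.tsv", "gold-standard")))
    annotated = {g for p in pos | neg for g in p}
    return GoldStandard(pos, neg, frozenset(annotated))


def stage_build_network(out: Path, params: dict) -> list[Path]:
    study_dir = out / "study"
    universe = fio.read_gene_list(_require(study_dir / "universe.txt", "simulate"))
    expr_channels = []
    d = 0
    while (out / f"expression_gene_{d}.tsv").exists():
        mat = fio.read_expression_tsv(out / f"expression_gene_{d}.tsv")
        mat.probe_to_gene = {p: p for p in mat.probes}
        expr_channels.append(fisher_z_channel(mat, name=f"expression_{d}"))
        d += 1
    if d == 0:
        _require(out / "expression_gene_0.tsv", "evidence")
    ppi = set(fio.read_pair_table(_require(out / "ppi_merged.tsv", "evidence")))
    docking = fio.read_pair_table(_require(study_dir / "docking.tsv", "simulate"))
    phen = phenotype_overlap(
        fio.read_annotations(_require(study_dir / "phenotypes.tsv", "simulate"))
    )
    gold = _load_gold(out)
    network, model = build_frn(
        expr_channels,
        [("ppi", ppi, "binary"), ("docking", docking, "score"),
         ("phenotype", phen, "score")],
        gold,
        universe,
        n_bins=int(params.get("n_bins", 20)),
        smoothing=float(params.get("smoothing", 1.0)),
        prior=params.get("prior"),
    )
    model.to_json(out / "integration_model.json")
    threshold = float(params.get("edge_threshold", 0.98))
    fio.write_network_edges(out / "network_edges.tsv", network, threshold)
    pd.DataFrame(network.posterior, index=network.genes, columns=network.genes
                 ).to_csv(out / "network_dense.tsv", sep="\t", float_format="%.10g")
    return [out / "integration_model.json", out / "network_edges.tsv",
            out / "network_dense.tsv"]


def _load_network(out: Path) -> FunctionalNetwork:
    df = pd.read_csv(_require(out / "network_dense.tsv", "build-network"),
                     sep="\t", index_col=0)
    return FunctionalNetwork(list(df.index.astype(str)), df.to_numpy(dtype=float))


def stage_rank(out: Path, params: dict, seed: int) -> list[Path]:
    network = _load_network(out)
    labels = LabeledSet(
        fio.read_gene_list(_require(out / "curated_truth.txt", "curate")),
        fio.read_gene_list(_require(out / "curated_control.txt", "curate")),
    )
    features, genes = build_features(network)
    cv = train_cv(
        features, genes, labels,
        folds=int(params.get("folds", 5)),
        seed=seed,
        grid=params.get("grid"),
        inner_folds=int(params.get("inner_folds", 3)),
    )
    (out / "cv_report.json").write_text(json.dumps({
        "fold_aucs": cv.fold_aucs, "auc_mean": cv.auc_mean, "auc_sd": cv.auc_sd,
    }, indent=1))
    ranking = predict_genomewide(cv, features, genes, labels)
    fio.write_ranking(out / "ranking.tsv", ranking)
    return [out / "cv_report.json", out / "ranking.tsv"]


def stage_validate(out: Path, seed: int) -> list[Path]:
    ranking = fio.read_ranking(_require(out / "ranking.tsv", "rank"))
    study_dir = out / "study"
    heldout = fio.read_gene_list(
        _require(study_dir / "heldout_disease_genes.txt", "simulate"))
    meta = json.loads(_require(study_dir / "study.json", "simulate").read_text())
    universe = fio.read_gene_list(_require(study_dir / "universe.txt", "simulate"))
    module_genes = {g for genes in meta["modules"] for g in genes}
    non_module = sorted(set(universe) - module_genes)
    rng = np.random.default_rng(seed + 1)
    background = [str(g) for g in rng.choice(
        universe, size=min(440, len(universe) // 2), replace=False)]
    neg_rng = np.random.default_rng(seed + 2)
    n_neg = min(10 * len(heldout), len(non_module))
    negative_control = sorted(
        str(g) for g in neg_rng.choice(non_module, size=n_neg, replace=False))
    table, hists = run_validation(
        ranking,
        {"heldout_disease": heldout, "control_non_module": negative_control},
        background,
    )
    table.to_csv(out / "validation.tsv", sep="\t", index=False)
    pd.DataFrame(hists, index=[f"decile_{i}" for i in range(1, 11)]).to_csv(
        out / "validation_histograms.tsv", sep="\t")
    return [out / "validation.tsv", out / "validation_histograms.tsv"]


def stage_cluster(out: Path, params: dict) -> list[Path]:
    network = _load_network(out)
    ranking = fio.read_ranking(_require(out / "ranking.tsv", "rank"))
    deciles = assign_deciles(ranking)
    top_genes = sorted(deciles.genes_in(1))
    graph = extract_disease_network(
        network, top_genes, threshold=float(params.get("edge_threshold", 0.98)))
    partition = girvan_newman_partition(graph)
    with open(out / "communities.tsv", "w") as fh:
        fh.write("gene\tcommunity\n")
        for g in sorted(partition.community_of):
            fh.write(f"{g}\t{partition.community_of[g]}\n")
    (out / "partition.json").write_text(json.dumps({
        "modularity": partition.modularity,
        "n_communities": partition.n_communities,
    }, indent=1))
    return [out / "communities.tsv", out / "partition.json"]


def stage_enrich(out: Path) -> list[Path]:
    gmt = fio.read_gmt(_require(out / "study" / "pathways.gmt", "simulate"))
    network = _load_network(out)
    comm = pd.read_csv(_require(out / "communities.tsv", "cluster"), sep="\t")
    rows = []
    universe = set(network.genes)
    for cid, grp in comm.groupby("community"):
        df = hypergeometric_enrichment(set(grp["gene"]), gmt, universe)
        df.insert(0, "community", cid)
        rows.append(df)
    table = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()
    table.to_csv(out / "community_enrichment.tsv", sep="\t", index=False)
    return [out / "community_enrichment.tsv"]


# ---------------------------------------------------------------- run-all

def run_all(config: RunConfig, outdir: str | Path) -> dict:
    """Execute every stage in order; returns the manifest dict."""
    validate_parameters(config.parameters)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    params = config.parameters
    seed = config.seed

    manifest = {"version": __version__, "seed": seed, "stages": {}}

    def record(stage: str, stage_params: dict, outputs: list[Path]) -> None:
        manifest["stages"][stage] = {
            "parameters": stage_params,
            "outputs": {str(p.relative_to(out)): _digest(p) for p in outputs},
        }
        log.info("stage %s: %d output(s)", stage, len(outputs))

    record("simulate", asdict(synthetic_config_from(params)),
           stage_simulate(out, seed, params))
    record("curate", {}, stage_curate(out))
    record("evidence", {
        "k_neighbors": int(params.get("k_neighbors", 10)),
        "missing_threshold": float(params.get("missing_threshold", 0.30)),
    }, stage_evidence(out, params))
    record("gold-standard", {
        "term_min_size": int(params.get("term_min_size", 5)),
        "term_max_size": int(params.get("term_max_size", 300)),
    }, stage_gold_standard(out, params))
    record("build-network", {
        "n_bins": int(params.get("n_bins", 20)),
        "smoothing": float(params.get("smoothing", 1.0)),
        "edge_threshold": float(params.get("edge_threshold", 0.98)),
    }, stage_build_network(out, params))
    record("rank", {
        "folds": int(params.get("folds", 5)),
        "inner_folds": int(params.get("inner_folds", 3)),
        "grid": params.get("grid") or "default",
    }, stage_rank(out, params, seed))
    record("validate", {}, stage_validate(out, seed))
    record("cluster", {
        "edge_threshold": float(params.get("edge_threshold", 0.98)),
    }, stage_cluster(out, params))
    record("enrich", {}, stage_enrich(out))

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
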