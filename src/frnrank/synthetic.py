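"""Synthetic study generator with planted ground truth.

Generates a complete multi-evidence study over a gene universe: a set of
planted functional modules drives correlated expression (shared latent
factor per module and sample, so two genes of one module have expected
Pearson correlation ``rho_in``), module-enriched binary PPI, continuous
docking scores (Beta(5,2) within modules vs Beta(2,5) elsewhere), shared
phenotype labels, pathway annotations for a gold standard (a random 70%
of modules — the rest are held out so the network must generalize beyond
its training annotations), and truth/control gene lists around a small
number of designated disease modules.  Every field is a deterministic
function of the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import io as fio
from .expression import ExpressionMatrix
from .io import GeneSet, GeneSetCollection
from .pairs import canonical_pair


@dataclass
class SyntheticConfig:
    n_genes: int = 2000
    n_modules: int = 40
    module_size_min: int = 20
    module_size_max: int = 60
    n_disease_modules: int = 2
    # expression
    n_datasets: int = 5
    n_samples: int = 50
    rho_in: float = 0.6
    missing_fraction: float = 0.05
    extra_probe_fraction: float = 0.25  # genes with a 2nd probe -> ~40% of probes many-to-one
    probe_noise_sd: float = 0.1
    # PPI
    ppi_p_in: float = 0.30
    ppi_p_out: float = 0.002
    # docking
    docking_background_fraction: float = 0.02
    # phenotypes
    phenotype_noise: float = 0.05
    # gold standard and labels
    pathway_fraction: float = 0.70
    truth_fraction: float = 0.60
    control_ratio: float = 10.0

    def validate(self) -> None:
        mean_size = (self.module_size_min + self.module_size_max) / 2
        if self.n_genes < 10 * mean_size:
            raise ValueError("universe must be >= 10x the mean module size")
        if not (0.0 <= self.rho_in < 1.0):
            raise ValueError("rho_in must be in [0, 1)")
        if self.ppi_p_in <= self.ppi_p_out:
            raise ValueError("need ppi_p_in > ppi_p_out")


@dataclass
class SyntheticStudy:
    config: SyntheticConfig
    seed: int
    universe: list[str]
    modules: list[list[str]]
    module_of: dict[str, int]  # module index per module gene
    disease_module_ids: list[int]
    expression_datasets: list[ExpressionMatrix]
    ppi: set[tuple[str, str]]
    docking: dict[tuple[str, str], float]
    phenotypes: dict[str, set[str]]
    pathway_annotations: GeneSetCollection
    truth_genes: list[str]
    control_genes: list[str]

    @property
    def disease_genes(self) -> list[str]:
        out: list[str] = []
        for m in self.disease_module_ids:
            out.extend(self.modules[m])
        return out

    @property
    def module_genes(self) -> set[str]:
        return set(self.module_of)


def _sample_cross_pairs(rng, n_genes: int, n_wanted: int, within: np.ndarray):
    """Sample distinct (i < j) pairs avoiding within-module pairs."""
    chosen: set[tuple[int, int]] = set()
    while len(chosen) < n_wanted:
        k = max(1024, int(1.5 * (n_wanted - len(chosen))))
        ii = rng.integers(0, n_genes, size=k)
        jj = rng.integers(0, n_genes, size=k)
        for i, j in zip(ii, jj):
            if i == j:
                continue
            a, b = (i, j) if i < j else (j, i)
            if within[a, b]:
                continue
            chosen.add((int(a), int(b)))
            if len(chosen) >= n_wanted:
                break
    return sorted(chosen)


def generate_study(config: SyntheticConfig | None = None, seed: int = 0) -> SyntheticStudy:
    """Generate the full synthetic study; bit-for-bit reproducible per seed."""
    cfg = config or SyntheticConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)
    G = cfg.n_genes
    universe = [f"G{i:05d}" for i in range(G)]

    sizes = rng.integers(cfg.module_size_min, cfg.module_size_max + 1, size=cfg.n_modules)
    if sizes.sum() > G:
        raise ValueError("infeasible config: module genes exceed the universe")
    perm = rng.permutation(G)
    modules: list[list[str]] = []
    module_idx = np.full(G, -1, dtype=int)
    start = 0
    for m, s in enumerate(sizes):
        members = perm[start:start + s]
        module_idx[members] = m
        modules.append(sorted(universe[i] for i in members))
        start += s
    module_of = {g: m for m, genes in enumerate(modules) for g in genes}
    disease_ids = sorted(
        int(m) for m in rng.choice(cfg.n_modules, cfg.n_disease_modules, replace=False)
    )

    # expression: per dataset, shared latent factor per (module, sample)
    datasets = []
    a, b_ = np.sqrt(cfg.rho_in), np.sqrt(1.0 - cfg.rho_in)
    for d in range(cfg.n_datasets):
        latent = rng.standard_normal((cfg.n_modules, cfg.n_samples))
        noise = rng.standard_normal((G, cfg.n_samples))
        signal = np.where(
            (module_idx >= 0)[:, None], a * latent[np.clip(module_idx, 0, None)], 0.0
        )
        signal = signal + np.where((module_idx >= 0)[:, None], b_ * noise, noise)
        # probes: one per gene plus a second probe for a random subset
        n_extra = int(round(cfg.extra_probe_fraction * G))
        extra_genes = np.sort(rng.choice(G, size=n_extra, replace=False))
        rows = np.concatenate([np.arange(G), extra_genes])
        offsets = rng.normal(0.0, 0.5, size=rows.size)[:, None]
        probe_noise = rng.normal(0.0, cfg.probe_noise_sd, size=(rows.size, cfg.n_samples))
        log_vals = 8.0 + signal[rows] + offsets + probe_noise
        values = np.power(2.0, log_vals)
        values[rng.random(values.shape) < cfg.missing_fraction] = np.nan
        probes = [f"D{d}_P{k:05d}" for k in range(rows.size)]
        probe_to_gene = {p: universe[rows[k]] for k, p in enumerate(probes)}
        datasets.append(
            ExpressionMatrix(
                probes=probes,
                samples=[f"D{d}_S{s:03d}" for s in range(cfg.n_samples)],
                values=values,
                probe_to_gene=probe_to_gene,
            )
        )

    within = (module_idx[:, None] >= 0) & (module_idx[:, None] == module_idx[None, :])
    np.fill_diagonal(within, False)

    # PPI: Bernoulli(p_in) within modules, Bernoulli(p_out) across
    draws = rng.random((G, G))
    p_mat = np.where(within, cfg.ppi_p_in, cfg.ppi_p_out)
    iu, ju = np.triu_indices(G, k=1)
    hit = draws[iu, ju] < p_mat[iu, ju]
    ppi = {
        canonical_pair(universe[i], universe[j])
        for i, j in zip(iu[hit], ju[hit])
    }

    # docking: all within-module pairs Beta(5,2); a sampled background of
    # cross pairs Beta(2,5) (docking assays cover only part of the genome)
    wi, wj = np.where(np.triu(within, k=1))
    docking: dict[tuple[str, str], float] = {}
    for i, j, v in zip(wi, wj, rng.beta(5.0, 2.0, size=wi.size)):
        docking[canonical_pair(universe[i], universe[j])] = float(v)
    n_total = G * (G - 1) // 2
    n_bg = int(round(cfg.docking_background_fraction * (n_total - wi.size)))
    bg_pairs = _sample_cross_pairs(rng, G, n_bg, within)
    for (i, j), v in zip(bg_pairs, rng.beta(2.0, 5.0, size=len(bg_pairs))):
        docking[canonical_pair(universe[i], universe[j])] = float(v)

    # phenotypes: 1-3 labels per module shared by its genes + uniform noise
    phenotypes: dict[str, set[str]] = {}
    label_pool: list[str] = []
    for m in range(cfg.n_modules):
        labels = [f"phen_{m:02d}_{k}" for k in range(int(rng.integers(1, 4)))]
        label_pool.extend(labels)
        for g in modules[m]:
            phenotypes.setdefault(g, set()).update(labels)
    noise_hits = rng.random(G) < cfg.phenotype_noise
    noise_labels = rng.integers(0, len(label_pool), size=G)
    for i in range(G):
        if noise_hits[i]:
            phenotypes.setdefault(universe[i], set()).add(label_pool[noise_labels[i]])

    # pathway annotations: a random fraction of modules, as gold-standard terms
    n_annot = int(round(cfg.pathway_fraction * cfg.n_modules))
    annotated_modules = sorted(
        int(m) for m in rng.choice(cfg.n_modules, n_annot, replace=False)
    )
    pathways = GeneSetCollection()
    for m in annotated_modules:
        pathways.sets[f"module_{m:02d}"] = GeneSet(f"planted module {m}", list(modules[m]))

    disease_genes = sorted(g for m in disease_ids for g in modules[m])
    n_truth = int(round(cfg.truth_fraction * len(disease_genes)))
    truth_genes = sorted(rng.choice(disease_genes, size=n_truth, replace=False))
    non_module = sorted(set(universe) - set(module_of))
    n_control = min(int(round(cfg.control_ratio * n_truth)), len(non_module))
    control_genes = sorted(rng.choice(non_module, size=n_control, replace=False))

    return SyntheticStudy(
        config=cfg,
        seed=seed,
        universe=universe,
        modules=modules,
        module_of=module_of,
        disease_module_ids=disease_ids,
        expression_datasets=datasets,
        ppi=ppi,
        docking=docking,
        phenotypes=phenotypes,
        pathway_annotations=pathways,
        truth_genes=[str(g) for g in truth_genes],
        control_genes=[str(g) for g in control_genes],
    )


def heldout_disease_genes(study: SyntheticStudy) -> list[str]:
    """Disease-module genes not used as training positives."""
    truth = set(study.truth_genes)
    return sorted(g for g in study.disease_genes if g not in truth)


def recovery_eval_sets(
    study: SyntheticStudy, seed: int, ratio: int = 10
) -> tuple[list[str], list[str]]:
    """Evaluation sets for ranking recovery: held-out disease genes as
    positives, a seeded sample of non-module genes as negatives."""
    pos = heldout_disease_genes(study)
    rng = np.random.default_rng(seed)
    non_module = sorted(set(study.universe) - study.module_genes)
    n_neg = min(ratio * len(pos), len(non_module))
    neg = sorted(rng.choice(non_module, size=n_neg, replace=False))
    return pos, [str(g) for g in neg]


def write_study(study: SyntheticStudy, outdir: str | Path) -> dict[str, str]:
    """Persist every study component in the pipeline's tabular formats."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    for d, mat in enumerate(study.expression_datasets):
        p = out / f"expression_{d}.tsv"
        fio.write_expression_tsv(p, mat)
        pm = out / f"probe_map_{d}.tsv"
        fio.write_homolog_map(pm, mat.probe_to_gene, columns=("probe", "gene"))
        paths[f"expression_{d}"] = str(p)
        paths[f"probe_map_{d}"] = str(pm)
    fio.write_pair_table(out / "ppi.tsv", {p: 1.0 for p in study.ppi}, "interacts")
    paths["ppi"] = str(out / "ppi.tsv")
    fio.write_pair_table(out / "docking.tsv", study.docking, "docking_score")
    paths["docking"] = str(out / "docking.tsv")
    fio.write_annotations(out / "phenotypes.tsv", study.phenotypes)
    paths["phenotypes"] = str(out / "phenotypes.tsv")
    fio.write_gmt(out / "pathways.gmt", study.pathway_annotations)
    paths["pathways"] = str(out / "pathways.gmt")
    fio.write_gene_list(out / "truth_genes.txt", study.truth_genes)
    paths["truth_genes"] = str(out / "truth_genes.txt")
    fio.write_gene_list(out / "control_genes.txt", study.control_genes)
    paths["control_genes"] = str(out / "control_genes.txt")
    fio.write_gene_list(out / "universe.txt", study.universe)
    paths["universe"] = str(out / "universe.txt")
    fio.write_gene_list(out / "heldout_disease_genes.txt", heldout_disease_genes(study))
    paths["heldout_disease_genes"] = str(out / "heldout_disease_genes.txt")
    meta = {
        "seed": study.seed,
        "config": asdict(study.config),
        "disease_module_ids": study.disease_module_ids,
        "modules": study.modules,
    }
    (out / "study.json").write_text(json.dumps(meta, indent=1))
    paths["study"] = str(out / "study.json")
    return paths
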