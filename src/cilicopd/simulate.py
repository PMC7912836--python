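"""Synthetic multi-cohort case/control expression data with planted effects.

Emulates the seven-cohort study design — 4 whole-lung datasets totalling 238
non-COPD / 391 COPD samples and 3 SAEC datasets totalling 300 non-COPD / 117
COPD — over a 495-gene curated geneset of which 189 genes are
ciliopathy-flagged. A configurable fraction of genes carries a planted log2
shift in COPD samples; each planted gene is independently "active" in each
dataset with concordance probability rho, and every gene can drop out of a
dataset with a platform-effect probability, so compartment genesets are
proper subsets of the full list. Ground truth (which genes, where active,
which direction) is returned alongside the matrices so recovery is exactly
checkable.

All draws flow from one seed through per-stream `numpy` generators with a
documented stream layout, so identical configs give bit-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .expression import ExpressionDataset, write_expression_matrix
from .geneset import GeneSet, merge_sources
from .singlecell import CellExpressionTable

# Stream offsets: one independent generator per stage, all derived from the
# master seed, so adding draws to one stage never shifts another.
_STREAM = {"geneset": 0, "lung": 1, "saec": 2, "single_cell": 3}


def _even_split(total: int, parts: int) -> list[int]:
    base, rem = divmod(total, parts)
    return [base + (1 if i < rem else 0) for i in range(parts)]


def _default_lung() -> list[tuple[int, int]]:
    # 4 whole-lung cohorts summing to 238 non-COPD / 391 COPD
    return list(zip(_even_split(238, 4), _even_split(391, 4)))


def _default_saec() -> list[tuple[int, int]]:
    # 3 SAEC cohorts summing to 300 non-COPD / 117 COPD
    return list(zip(_even_split(300, 3), _even_split(117, 3)))


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic cohorts.

    Defaults reproduce the seven-cohort design: per-dataset group sizes split
    the compartment totals evenly, the geneset is 495 genes (447
    cilia-associated, 189 ciliopathy-associated, 141 in both), and a platform
    dropout of 10% per gene per dataset yields compartment genesets that are
    strict subsets of the full list.
    """

    seed: int = 0
    lung_datasets: list[tuple[int, int]] = field(default_factory=_default_lung)
    saec_datasets: list[tuple[int, int]] = field(default_factory=_default_saec)
    n_genes: int = 495
    n_cilia: int = 447
    n_ciliopathy: int = 189
    frac_de: float = 0.3
    delta: float = 1.0
    sigma_range: tuple[float, float] = (0.3, 0.8)
    baseline_mean: float = 6.0
    baseline_sd: float = 2.0
    rho: float = 0.6
    dropout: float = 0.1

    def __post_init__(self) -> None:
        for prob in (self.frac_de, self.rho, self.dropout):
            if not 0.0 <= prob <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.n_ciliopathy > self.n_genes or self.n_cilia > self.n_genes:
            raise ValueError("source list sizes cannot exceed n_genes")
        if self.n_cilia + self.n_ciliopathy < self.n_genes:
            raise ValueError("source lists cannot cover n_genes unique symbols")
        for n_non, n_copd in self.lung_datasets + self.saec_datasets:
            if n_non < 2 or n_copd < 2:
                raise ValueError("each group needs >= 2 samples")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STREAM[stream]])


@dataclass
class SimTruth:
    """Planted ground truth for one simulated compartment."""

    de_genes: set[str]
    active: dict[tuple[str, str], bool]
    directions: dict[str, int]
    dropped: dict[str, set[str]]  # dataset_id -> genes absent by platform dropout

    def active_datasets(self, gene: str) -> set[str]:
        """Datasets where ``gene`` is planted active AND not dropped out."""
        return {
            ds
            for (g, ds), on in self.active.items()
            if g == gene and on and g not in self.dropped[ds]
        }


def synthetic_symbols(n_genes: int) -> list[str]:
    """Deterministic synthetic gene symbols CIL0001..CILnnnn."""
    width = max(4, len(str(n_genes)))
    return [f"CIL{i + 1:0{width}d}" for i in range(n_genes)]


def synthetic_source_lists(
    config: SimConfig,
) -> list[tuple[str, list[tuple[str, str, str]]]]:
    """Labelled source lists realizing the configured inclusion–exclusion
    profile (defaults: 447 cilia + 189 ciliopathy sharing 141 symbols = 495
    unique), plus smaller overlapping lists from the compiled libraries.

    Entirely synthetic stand-ins for the curated inputs; symbols are CILnnnn,
    accessions SYNnnnn.
    """
    rng = config.rng("geneset")
    symbols = synthetic_symbols(config.n_genes)
    order = rng.permutation(config.n_genes)
    overlap = config.n_cilia + config.n_ciliopathy - config.n_genes
    cilia_idx = order[: config.n_cilia]
    # ciliopathy = last `overlap` cilia symbols + all symbols outside cilia
    cilio_idx = np.concatenate([cilia_idx[config.n_cilia - overlap :], order[config.n_cilia :]])

    def entries(idx: np.ndarray) -> list[tuple[str, str, str]]:
        return [
            (symbols[i], f"SYN{i + 1:04d}", f"synthetic cilia protein {i + 1}")
            for i in sorted(idx)
        ]

    lists = [
        ("uniprot_cilia", entries(cilia_idx)),
        ("uniprot_ciliopathy", entries(cilio_idx)),
    ]
    for label in ("genomes100k", "centrosomedb", "cildb", "syscilia", "ciliacarta"):
        size = int(rng.integers(40, 120))
        lists.append((label, entries(rng.choice(config.n_genes, size, replace=False))))
    return lists


def synthetic_geneset(config: SimConfig) -> GeneSet:
    """Merged synthetic geneset (size n_genes, n_ciliopathy flagged)."""
    return merge_sources(synthetic_source_lists(config))


def simulate_compartment(
    config: SimConfig, compartment: str
) -> tuple[list[ExpressionDataset], SimTruth]:
    """Simulate one compartment's cohorts plus ground truth.

    Per gene g: log2 baseline mu_g ~ Normal(baseline_mean, baseline_sd) and
    noise sd sigma_g ~ Uniform(sigma_range). A COPD sample of dataset d adds
    direction_g * delta when g is planted differential and active in d
    (activity ~ Bernoulli(rho) per dataset). Each gene independently drops
    out of each dataset with probability ``dropout``. Matrices are emitted on
    log2 scale.
    """
    if compartment not in ("lung", "saec"):
        raise ValueError("compartment must be 'lung' or 'saec'")
    sizes = config.lung_datasets if compartment == "lung" else config.saec_datasets
    rng = config.rng(compartment)
    symbols = synthetic_symbols(config.n_genes)
    n = config.n_genes

    n_de = round(config.frac_de * n)
    de_idx = rng.choice(n, size=n_de, replace=False)
    de_genes = {symbols[i] for i in de_idx}
    direction = {symbols[i]: int(rng.choice([-1, 1])) for i in sorted(de_idx)}

    mu = rng.normal(config.baseline_mean, config.baseline_sd, size=n)
    sigma = rng.uniform(*config.sigma_range, size=n)

    prefix = "SIM-LUNG" if compartment == "lung" else "SIM-SAEC"
    datasets: list[ExpressionDataset] = []
    active: dict[tuple[str, str], bool] = {}
    dropped: dict[str, set[str]] = {}
    for d, (n_non, n_copd) in enumerate(sizes):
        ds_id = f"{prefix}{d + 1}"
        for i in sorted(de_idx):
            active[(symbols[i], ds_id)] = bool(rng.random() < config.rho)
        keep = rng.random(n) >= config.dropout
        dropped[ds_id] = {symbols[i] for i in range(n) if not keep[i]}

        n_samples = n_non + n_copd
        groups = ["non_copd"] * n_non + ["copd"] * n_copd
        values = mu[:, None] + rng.normal(0.0, 1.0, size=(n, n_samples)) * sigma[:, None]
        for i in sorted(de_idx):
            g = symbols[i]
            if active[(g, ds_id)]:
                values[i, n_non:] += direction[g] * config.delta
        datasets.append(
            ExpressionDataset(
                dataset_id=ds_id,
                compartment=compartment,
                gene_ids=[symbols[i] for i in range(n) if keep[i]],
                sample_ids=[f"{ds_id}_S{j + 1}" for j in range(n_samples)],
                values=values[keep, :],
                groups=groups,
                scale="log2",
            )
        )
    truth = SimTruth(
        de_genes=de_genes, active=active, directions=direction, dropped=dropped
    )
    return datasets, truth


def simulate_study(
    config: SimConfig,
) -> tuple[GeneSet, dict[str, list[ExpressionDataset]], dict[str, SimTruth]]:
    """Full seven-cohort study: geneset, both compartments, both truths."""
    geneset = synthetic_geneset(config)
    lung, lung_truth = simulate_compartment(config, "lung")
    saec, saec_truth = simulate_compartment(config, "saec")
    return (
        geneset,
        {"lung": lung, "saec": saec},
        {"lung": lung_truth, "saec": saec_truth},
    )


def simulate_single_cell(
    seed: int,
    n_cells_per_population: Mapping[str, int],
    expr_prob: Mapping[tuple[str, str], float],
) -> CellExpressionTable:
    """Simulate a cell × gene table with planted expression probabilities.

    Each cell's value for gene g is Bernoulli(expr_prob[g, population]) times
    (1 + Poisson(1)), i.e. zero for non-expressing cells and a positive count
    otherwise.
    """
    if not n_cells_per_population or any(
        n <= 0 for n in n_cells_per_population.values()
    ):
        raise ValueError("every population needs at least one cell")
    if any(not 0.0 <= p <= 1.0 for p in expr_prob.values()):
        raise ValueError("expression probabilities must lie in [0, 1]")
    rng = np.random.default_rng([seed, _STREAM["single_cell"]])
    genes = sorted({g for g, _ in expr_prob})
    cell_ids: list[str] = []
    populations: list[str] = []
    for pop in sorted(n_cells_per_population):
        n = n_cells_per_population[pop]
        cell_ids.extend(f"{pop}_C{i + 1}" for i in range(n))
        populations.extend([pop] * n)
    n_cells = len(cell_ids)
    values = np.zeros((n_cells, len(genes)))
    pops = np.asarray(populations)
    for j, gene in enumerate(genes):
        for pop in sorted(n_cells_per_population):
            p = expr_prob.get((gene, pop), 0.0)
            mask = pops == pop
            k = int(mask.sum())
            on = rng.random(k) < p
            counts = 1 + rng.poisson(1.0, size=k)
            values[mask, j] = on * counts
    return CellExpressionTable(
        cell_ids=cell_ids, gene_ids=genes, values=values, populations=populations
    )


# ---------------------------------------------------------------------------
# Emitting a simulated study to disk (manifest + matrices + truth)
# ---------------------------------------------------------------------------


def write_study(config: SimConfig, outdir) -> Path:
    """Write a full simulated study consumable by the pipeline: geneset
    source TSV, per-cohort matrix/metadata TSVs, a YAML manifest, and the
    ground truth as JSON. Returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    source_lists = synthetic_source_lists(config)
    with open(outdir / "geneset_sources.tsv", "w") as fh:
        fh.write("source\tsymbol\taccession\tname\n")
        for label, entries in source_lists:
            for symbol, acc, name in entries:
                fh.write(f"{label}\t{symbol}\t{acc}\t{name}\n")

    manifest_entries = []
    truth_json: dict = {}
    for compartment in ("lung", "saec"):
        datasets, truth = simulate_compartment(config, compartment)
        for ds in datasets:
            matrix = f"{ds.dataset_id}_matrix.tsv"
            metadata = f"{ds.dataset_id}_metadata.tsv"
            write_expression_matrix(ds, outdir / matrix, outdir / metadata)
            manifest_entries.append(
                {
                    "dataset_id": ds.dataset_id,
                    "compartment": compartment,
                    "matrix": matrix,
                    "metadata": metadata,
                    "scale": "log2",
                }
            )
        truth_json[compartment] = {
            "de_genes": sorted(truth.de_genes),
            "directions": {g: d for g, d in sorted(truth.directions.items())},
            "active": {
                g: sorted(
                    ds for (gg, ds), on in truth.active.items() if gg == g and on
                )
                for g in sorted(truth.de_genes)
            },
            "dropped": {ds: sorted(gs) for ds, gs in sorted(truth.dropped.items())},
        }

    manifest_path = outdir / "manifest.yaml"
    with open(manifest_path, "w") as fh:
        yaml.safe_dump({"datasets": manifest_entries}, fh, sort_keys=False)
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth_json, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest_path
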