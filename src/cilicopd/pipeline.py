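"""End-to-end orchestration: curate -> validate -> test -> tier -> report.

Runs the whole concordance analysis from a dataset manifest plus geneset
source lists (or a pre-merged geneset), writes every stage's tables under one
output directory, and emits a machine-readable ``report.json`` whose floats
are serialized at 6 significant digits so reruns with identical inputs are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .concordance import (
    TierSummary,
    common_gene_table,
    cross_compartment_hits,
    direction_consistent_membership,
    percent_of_geneset,
    tier_counts,
)
from .diffexp import DatasetDEResult, run_diffexp
from .expression import ExpressionDataset, ensure_log2, load_manifest
from .geneset import (
    GeneSet,
    compartment_geneset,
    merge_sources,
    read_geneset,
    read_source_lists,
    write_geneset,
)
from .singlecell import annotate_genes, read_cell_table

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """One reproducible pipeline run.

    ``geneset_sources`` are source-list TSVs to merge; alternatively
    ``geneset`` points at a pre-merged geneset TSV. Tier thresholds default
    to the study's: the common-gene table takes >=3 lung or >=2 SAEC
    datasets, cross-compartment hits take >=2 lung and >=1 SAEC.
    """

    manifest: str
    outdir: str
    geneset_sources: list[str] = field(default_factory=list)
    geneset: str | None = None
    ciliopathy_sources: list[str] = field(default_factory=lambda: ["uniprot_ciliopathy"])
    alpha: float = 0.05
    sig_rule: str = "raw_p"
    t_variant: str = "welch"
    table_lung_min: int = 3
    table_saec_min: int = 2
    cross_lung_min: int = 2
    cross_saec_min: int = 1
    require_direction: bool = False
    sc_matrix: str | None = None
    sc_cells: str | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        # YAML configs may deliver "1e-06" as a string
        self.alpha = float(self.alpha)
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must lie in (0, 1]")
        for k in (
            self.table_lung_min,
            self.table_saec_min,
            self.cross_lung_min,
            self.cross_saec_min,
        ):
            if k < 1:
                raise ValueError("tier thresholds must be >= 1")

    def digest(self) -> str:
        fields = asdict(self)
        fields.pop("outdir")  # where results land does not change what they are
        payload = json.dumps(fields, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _round_floats(obj, sig: int = 6):
    """Recursively format floats at ``sig`` significant digits for stable JSON."""
    if isinstance(obj, float):
        return float(f"{obj:.{sig}g}")
    if isinstance(obj, dict):
        return {k: _round_floats(v, sig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, sig) for v in obj]
    return obj


def _compartment_report(
    summary: TierSummary, compartment: str
) -> dict:
    # Percent formats follow the printed convention: whole-lung tiers at 0
    # decimals; the sparse SAEC >=2 tier at 1 decimal.
    percents = {}
    for k, count in summary.tier_counts.items():
        decimals = 1 if (compartment == "saec" and k == 2) else 0
        percents[k] = percent_of_geneset(count, summary.geneset_size, decimals)
    return {
        "dataset_ids": list(summary.dataset_ids),
        "geneset_size": summary.geneset_size,
        "tier_counts": {str(k): v for k, v in summary.tier_counts.items()},
        "tier_percentages": {str(k): v for k, v in percents.items()},
        "venn": {"+".join(region): n for region, n in summary.venn.items()},
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return the report dict (also written to disk).

    Any stage failure aborts with a stage-labelled error; partial outputs are
    retained next to a FAILED marker naming the stage.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        stage = "curate"
        if config.geneset:
            geneset = read_geneset(config.geneset)
        elif config.geneset_sources:
            lists: list = []
            for path in config.geneset_sources:
                lists.extend(read_source_lists(path))
            geneset = merge_sources(lists, ciliopathy_sources=config.ciliopathy_sources)
        else:
            raise ValueError("config needs geneset or geneset_sources")
        write_geneset(geneset, outdir / "geneset_merged.tsv")

        stage = "validate"
        datasets = load_manifest(config.manifest)
        if not datasets:
            raise ValueError("manifest lists no datasets")
        datasets = [ensure_log2(ds) for ds in datasets]
        by_compartment: dict[str, list[ExpressionDataset]] = {}
        for ds in datasets:
            by_compartment.setdefault(ds.compartment, []).append(ds)

        stage = "diffexp"
        de_results: list[DatasetDEResult] = []
        compartment_sets: dict[str, GeneSet] = {}
        summaries: dict[str, TierSummary] = {}
        for compartment, comp_datasets in sorted(by_compartment.items()):
            comp_gs = compartment_geneset(geneset, comp_datasets)
            compartment_sets[compartment] = comp_gs
            sig_sets = {}
            for ds in comp_datasets:
                res = run_diffexp(
                    ds,
                    comp_gs,
                    alpha=config.alpha,
                    sig_rule=config.sig_rule,
                    variant=config.t_variant,
                )
                de_results.append(res)
                sig_sets[ds.dataset_id] = res.significant_genes()
                res.to_frame().to_csv(
                    outdir / f"de_{ds.dataset_id}.tsv", sep="\t", index=False
                )
            summary = tier_counts(
                sig_sets, compartment=compartment, geneset_size=len(comp_gs)
            )
            if config.require_direction:
                summary = direction_consistent_membership(summary, de_results)
            summaries[compartment] = summary
            summary.to_frame().to_csv(
                outdir / f"tiers_{compartment}.tsv", sep="\t", index=False
            )

        stage = "concord"
        report: dict = {
            "schema_version": REPORT_SCHEMA_VERSION,
            "cilicopd_version": __version__,
            "config_digest": config.digest(),
            "seed": config.seed,
            "geneset": geneset.summary(),
            "datasets": [r.summary() for r in de_results],
            "compartments": {
                comp: _compartment_report(summary, comp)
                for comp, summary in summaries.items()
            },
        }
        if "lung" in summaries and "saec" in summaries:
            cross = cross_compartment_hits(
                summaries["lung"],
                summaries["saec"],
                geneset,
                lung_min=config.cross_lung_min,
                saec_min=config.cross_saec_min,
            )
            n_cilio = sum(r.is_ciliopathy for r in geneset)
            report["cross_compartment"] = cross.summary(n_cilio)
            pd.DataFrame(
                {"gene": sorted(cross.hits)}
            ).assign(ciliopathy=lambda d: d.gene.isin(cross.ciliopathy_hits).astype(int)).to_csv(
                outdir / "cross_compartment_hits.tsv", sep="\t", index=False
            )
            table = common_gene_table(
                summaries["lung"],
                summaries["saec"],
                de_results,
                lung_min=config.table_lung_min,
                saec_min=config.table_saec_min,
            )
            table.to_csv(
                outdir / "common_genes.tsv", sep="\t", index=False, float_format="%.4g"
            )
            report["common_gene_table"] = {
                "n_rows": int(len(table)),
                "fully_concordant": sorted(set(table.loc[table.fully_concordant, "gene"])),
            }

        if config.sc_matrix and config.sc_cells:
            stage = "scbin"
            cell_table = read_cell_table(config.sc_matrix, config.sc_cells)
            wanted = [g for g in cell_table.gene_ids if g in geneset]
            ann = annotate_genes(cell_table, sorted(wanted))
            ann.to_csv(outdir / "singlecell_annotations.tsv", sep="\t", index=False)
            report["single_cell"] = {
                "n_genes": int(len(ann)),
                "bins": ann["bin"].value_counts().to_dict() if len(ann) else {},
            }

        stage = "report"
        report = _round_floats(report)
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return report
    except Exception as exc:
        marker = outdir / "FAILED"
        marker.write_text(f"stage: {stage}\nerror: {exc}\n")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
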