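"""Cross-dataset concordance: tiers, Venn partitions, cross-compartment hits.

Per-dataset significance calls are combined within each compartment (whole
lung or SAEC) into tier counts — how many geneset genes are deregulated in at
least k of the compartment's datasets — and exact Venn-region counts.
Cross-compartment candidate genes are those significant in at least
``lung_min`` whole-lung datasets and at least ``saec_min`` SAEC datasets.
"Deregulated" requires significance only, with no fold-change cutoff and no
cross-dataset direction consistency (sign-discordant genes do occur); a
direction-consistent variant is available via ``require_direction``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import pandas as pd

from .diffexp import DatasetDEResult
from .geneset import GeneSet


@dataclass
class TierSummary:
    """Per-compartment concordance bookkeeping.

    ``membership`` maps each gene to the exact set of dataset ids in which it
    was significant; ``venn`` counts genes per exact dataset-subset region;
    ``tier_counts[k]`` counts genes significant in at least k datasets.
    """

    compartment: str
    dataset_ids: tuple[str, ...]
    membership: dict[str, frozenset[str]]
    geneset_size: int | None = None

    @property
    def n_datasets(self) -> int:
        return len(self.dataset_ids)

    @property
    def venn(self) -> dict[tuple[str, ...], int]:
        regions: dict[tuple[str, ...], int] = {}
        for members in self.membership.values():
            key = tuple(sorted(members))
            regions[key] = regions.get(key, 0) + 1
        return dict(sorted(regions.items()))

    @property
    def tier_counts(self) -> dict[int, int]:
        counts = {}
        for k in range(1, self.n_datasets + 1):
            counts[k] = sum(len(m) >= k for m in self.membership.values())
        return counts

    def genes_at_tier(self, k: int) -> list[str]:
        """Genes significant in at least k datasets, lexicographically sorted."""
        return sorted(g for g, m in self.membership.items() if len(m) >= k)

    def percentages(self, decimals: int = 0) -> dict[int, float]:
        """Tier counts as percent of the compartment geneset size."""
        if self.geneset_size is None:
            raise ValueError("geneset_size unset; cannot compute percentages")
        return {
            k: percent_of_geneset(c, self.geneset_size, decimals)
            for k, c in self.tier_counts.items()
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "gene": g,
                "compartment": self.compartment,
                "n_datasets": len(m),
                "datasets": ";".join(sorted(m)),
            }
            for g, m in sorted(self.membership.items())
        ]
        return pd.DataFrame(
            rows, columns=["gene", "compartment", "n_datasets", "datasets"]
        )


def tier_counts(
    sig_sets: Mapping[str, set],
    compartment: str = "lung",
    geneset_size: int | None = None,
) -> TierSummary:
    """Build a TierSummary from per-dataset significant-gene sets.

    ``sig_sets`` maps dataset id to the set of genes called significant in
    it; genes significant nowhere carry no membership entry.
    """
    if not sig_sets:
        raise ValueError("tier_counts requires at least one dataset")
    dataset_ids = tuple(sorted(sig_sets))
    membership: dict[str, frozenset[str]] = {}
    all_genes: set[str] = set().union(*sig_sets.values()) if sig_sets else set()
    for gene in sorted(all_genes):
        members = frozenset(d for d in dataset_ids if gene in sig_sets[d])
        if members:
            membership[gene] = members
    return TierSummary(
        compartment=compartment,
        dataset_ids=dataset_ids,
        membership=membership,
        geneset_size=geneset_size,
    )


def percent_of_geneset(count: int, geneset_size: int, decimals: int = 0) -> float:
    """100 * count / geneset_size, half-up rounded to ``decimals`` places.

    Half-up (not banker's) rounding matches how the printed percentages are
    formed, e.g. 100/350 -> 29 and 10/399 -> 2.5.
    """
    if geneset_size <= 0:
        raise ValueError("geneset_size must be positive")
    if not 0 <= count <= geneset_size:
        raise ValueError(f"count {count} outside [0, {geneset_size}]")
    if decimals not in (0, 1):
        raise ValueError("decimals must be 0 or 1")
    quantum = Decimal(1).scaleb(-decimals)
    pct = (Decimal(100) * Decimal(count) / Decimal(geneset_size)).quantize(
        quantum, rounding=ROUND_HALF_UP
    )
    return int(pct) if decimals == 0 else float(pct)


@dataclass
class CrossCompartmentResult:
    """Genes deregulated across both tissue compartments."""

    hits: set[str]
    ciliopathy_hits: set[str]
    union_deregulated: set[str]
    ciliopathy_union: set[str]
    lung_min: int
    saec_min: int

    def summary(self, n_ciliopathy: int) -> dict:
        return {
            "n_hits": len(self.hits),
            "n_ciliopathy_hits": len(self.ciliopathy_hits),
            "pct_ciliopathy_hits": percent_of_geneset(
                len(self.ciliopathy_hits), n_ciliopathy, 0
            ),
            "n_union_deregulated": len(self.union_deregulated),
            "n_ciliopathy_union": len(self.ciliopathy_union),
            "pct_ciliopathy_union": percent_of_geneset(
                len(self.ciliopathy_union), n_ciliopathy, 0
            ),
            "lung_min": self.lung_min,
            "saec_min": self.saec_min,
        }


def cross_compartment_hits(
    lung: TierSummary,
    saec: TierSummary,
    geneset: GeneSet,
    lung_min: int = 2,
    saec_min: int = 1,
) -> CrossCompartmentResult:
    """Genes significant in >= lung_min lung datasets AND >= saec_min SAEC datasets.

    Also reports the union of tier-1 genes of either compartment and the
    ciliopathy-flagged subsets of both collections.
    """
    if lung.compartment != "lung" or saec.compartment != "saec":
        raise ValueError("expected a lung TierSummary and a saec TierSummary")
    if lung_min < 1 or saec_min < 1:
        raise ValueError("tier thresholds must be >= 1")
    hits = {
        g
        for g, m in lung.membership.items()
        if len(m) >= lung_min and len(saec.membership.get(g, ())) >= saec_min
    }
    union = set(lung.membership) | set(saec.membership)
    cilio = {r.symbol for r in geneset if r.is_ciliopathy}
    return CrossCompartmentResult(
        hits=hits,
        ciliopathy_hits=hits & cilio,
        union_deregulated=union,
        ciliopathy_union=union & cilio,
        lung_min=lung_min,
        saec_min=saec_min,
    )


def common_gene_table(
    lung: TierSummary,
    saec: TierSummary,
    de: Sequence[DatasetDEResult],
    lung_min: int = 3,
    saec_min: int = 2,
) -> pd.DataFrame:
    """Table of the main commonly deregulated genes across cohorts.

    Rows are genes significant in at least ``lung_min`` lung datasets or at
    least ``saec_min`` SAEC datasets. Columns carry the per-dataset log2 fold
    change, blank (NaN) where the gene was not significant or not tested in
    that cohort. Genes significant in every dataset of their compartment are
    flagged fully concordant.
    """
    de_by_id = {r.dataset_id: r for r in de}
    for ds_id in lung.dataset_ids + saec.dataset_ids:
        if ds_id not in de_by_id:
            raise ValueError(f"missing DE results for dataset {ds_id}")

    rows = []
    for summary, min_k in ((lung, lung_min), (saec, saec_min)):
        for gene in summary.genes_at_tier(min_k):
            row: dict = {"gene": gene, "compartment": summary.compartment}
            n_sig = 0
            for ds_id in summary.dataset_ids:
                res = de_by_id[ds_id].results.get(gene)
                if res is not None and res.significant:
                    row[ds_id] = res.log2fc
                    n_sig += 1
                else:
                    row[ds_id] = float("nan")
            row["fully_concordant"] = n_sig == summary.n_datasets
            rows.append(row)

    columns = (
        ["gene", "compartment"]
        + list(lung.dataset_ids)
        + list(saec.dataset_ids)
        + ["fully_concordant"]
    )
    table = pd.DataFrame(rows, columns=columns)
    return table.sort_values(["compartment", "gene"]).reset_index(drop=True)


def direction_consistent_membership(
    summary: TierSummary, de: Sequence[DatasetDEResult]
) -> TierSummary:
    """Stricter membership variant: drop datasets whose log2fc sign disagrees
    with the gene's majority sign across its significant datasets."""
    de_by_id = {r.dataset_id: r for r in de}
    new_membership = {}
    for gene, members in summary.membership.items():
        signs = {
            ds: 1 if de_by_id[ds].results[gene].log2fc >= 0 else -1 for ds in members
        }
        total = sum(signs.values())
        majority = 1 if total >= 0 else -1
        kept = frozenset(ds for ds, s in signs.items() if s == majority)
        if kept:
            new_membership[gene] = kept
    return TierSummary(
        compartment=summary.compartment,
        dataset_ids=summary.dataset_ids,
        membership=new_membership,
        geneset_size=summary.geneset_size,
    )
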