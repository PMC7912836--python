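"""Single-cell expression summaries for candidate genes.

Given a cell × gene table with per-cell population labels (multiciliated
cells MCC, non-differentiated cells NDC, other epithelial cells EC_other,
non-epithelial cells), annotate each gene with the fraction of cells
expressing it (value > 0), a three-level bin (+ below 25%, ++ for 25–50%
inclusive, +++ above 50%), and the principal expressing population. A
population is "principal" when its expressing fraction is at least a
dominance ratio (default 1.5) times the pooled expressing fraction of all
remaining cells; otherwise expression is broad and labelled "All".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

POPULATIONS = ("MCC", "NDC", "EC_other", "non_epithelial")

#: Output label for each input population (EC_other reported as EC; a
#: dominant non-epithelial signal is reported as broad).
_PRINCIPAL_LABEL = {
    "MCC": "MCC",
    "NDC": "NDC",
    "EC_other": "EC",
    "non_epithelial": "All",
}

BINS = ("+", "++", "+++")


@dataclass
class CellExpressionTable:
    """Cell × gene non-negative expression with per-cell population labels."""

    cell_ids: list[str]
    gene_ids: list[str]
    values: np.ndarray
    populations: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"({len(self.cell_ids)} cells, {len(self.gene_ids)} genes)"
            )
        if len(self.populations) != len(self.cell_ids):
            raise ValueError("one population label required per cell")
        if any(not p for p in self.populations):
            raise ValueError("population labels must be non-empty strings")
        if np.any(self.values < 0):
            raise ValueError("expression values must be non-negative")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def population_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for p in self.populations:
            sizes[p] = sizes.get(p, 0) + 1
        return sizes


@dataclass(frozen=True)
class SingleCellAnnotation:
    gene: str
    frac_overall: float
    frac_by_population: dict[str, float]
    bin: str
    principal: str


def fraction_expressing(
    table: CellExpressionTable, gene: str, min_value: float = 0.0
) -> tuple[float, dict[str, float]]:
    """Fraction of cells with expression above ``min_value``, overall and per
    population.

    Populations with zero cells are omitted with a warning. Only the support
    of the expression values matters, so the result is invariant to positive
    rescaling of the matrix.
    """
    try:
        col = table.gene_ids.index(gene)
    except ValueError:
        raise KeyError(f"gene {gene!r} not in table") from None
    expressing = table.values[:, col] > min_value
    frac_overall = float(expressing.mean())
    pops = np.asarray(table.populations)
    frac_by_population = {}
    for pop in dict.fromkeys(table.populations):  # first-appearance order
        mask = pops == pop
        n = int(mask.sum())
        if n == 0:
            logger.warning("population %r has no cells; omitted", pop)
            continue
        frac_by_population[pop] = float(expressing[mask].mean())
    return frac_overall, frac_by_population


def bin_fraction(frac: float) -> str:
    """Three-level bin: '+' below 0.25, '++' on [0.25, 0.50], '+++' above 0.50.

    The boundaries 25% and 50% belong to the intermediate bin, which is the
    closed interval between two open-ended neighbours.
    """
    if not 0.0 <= frac <= 1.0:
        raise ValueError(f"fraction {frac} outside [0, 1]")
    if frac < 0.25:
        return "+"
    if frac <= 0.50:
        return "++"
    return "+++"


def principal_population(
    frac_by_population: Mapping[str, float],
    dominance_ratio: float = 1.5,
    n_by_population: Mapping[str, int] | None = None,
) -> str:
    """Label the principal expressing population, or "All" when none dominates.

    The top population wins when its expressing fraction is at least
    ``dominance_ratio`` times the pooled expressing fraction of the remaining
    cells. Pooling weights populations by cell count when
    ``n_by_population`` is given; otherwise populations are weighted equally.
    EC_other is reported as "EC"; a dominant non-epithelial signal and the
    no-dominance case are both reported as "All".
    """
    if len(frac_by_population) < 2:
        raise ValueError("need fractions for at least 2 populations")
    if any(not 0.0 <= f <= 1.0 for f in frac_by_population.values()):
        raise ValueError("fractions must lie in [0, 1]")
    if all(f == 0.0 for f in frac_by_population.values()):
        logger.warning("all population fractions zero; principal undefined -> All")
        return "All"
    # deterministic tie-break: highest fraction, then label order
    top = max(frac_by_population, key=lambda p: (frac_by_population[p], p))
    others = [p for p in frac_by_population if p != top]
    if n_by_population is None:
        pooled = float(np.mean([frac_by_population[p] for p in others]))
    else:
        weights = np.array([n_by_population[p] for p in others], dtype=float)
        if weights.sum() == 0:
            pooled = 0.0
        else:
            fracs = np.array([frac_by_population[p] for p in others])
            pooled = float((fracs * weights).sum() / weights.sum())
    if frac_by_population[top] >= dominance_ratio * pooled:
        return _PRINCIPAL_LABEL.get(top, top)
    return "All"


def annotate_gene(
    table: CellExpressionTable,
    gene: str,
    min_value: float = 0.0,
    dominance_ratio: float = 1.5,
) -> SingleCellAnnotation:
    frac_overall, frac_by_pop = fraction_expressing(table, gene, min_value=min_value)
    return SingleCellAnnotation(
        gene=gene,
        frac_overall=frac_overall,
        frac_by_population=frac_by_pop,
        bin=bin_fraction(frac_overall),
        principal=principal_population(
            frac_by_pop,
            dominance_ratio=dominance_ratio,
            n_by_population=table.population_sizes(),
        ),
    )


def annotate_genes(
    table: CellExpressionTable,
    genes: Sequence[str] | None = None,
    min_value: float = 0.0,
    dominance_ratio: float = 1.5,
) -> pd.DataFrame:
    """Annotation table (gene, frac_overall, per-population fractions, bin,
    principal) for the requested genes (default: all genes in the table)."""
    if genes is None:
        genes = sorted(table.gene_ids)
    rows = []
    for gene in genes:
        ann = annotate_gene(
            table, gene, min_value=min_value, dominance_ratio=dominance_ratio
        )
        row = {"gene": ann.gene, "frac_overall": ann.frac_overall}
        for pop, frac in ann.frac_by_population.items():
            row[f"frac_{pop}"] = frac
        row["bin"] = ann.bin
        row["principal"] = ann.principal
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_cell_table(
    matrix_path, cells_path, population_map: Mapping[str, str] | None = None
) -> CellExpressionTable:
    """Read a cell × gene TSV (cells in rows) and a cell-annotation TSV
    (`cell_id  population`).

    ``population_map`` optionally collapses finer cluster labels onto the
    four analysis populations.
    """
    frame = pd.read_csv(matrix_path, sep="\t", index_col=0)
    ann = pd.read_csv(cells_path, sep="\t", dtype=str)
    if not {"cell_id", "population"} <= set(ann.columns):
        raise ValueError(f"{cells_path}: expected columns cell_id, population")
    pop_of = dict(zip(ann["cell_id"], ann["population"]))
    missing = [c for c in frame.index if str(c) not in pop_of]
    if missing:
        raise ValueError(f"cells without population annotation: {missing[:5]}")
    populations = [pop_of[str(c)] for c in frame.index]
    if population_map is not None:
        populations = [population_map.get(p, p) for p in populations]
    return CellExpressionTable(
        cell_ids=[str(c) for c in frame.index],
        gene_ids=[str(g) for g in frame.columns],
        values=frame.to_numpy(dtype=float),
        populations=populations,
    )
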