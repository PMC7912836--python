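"""Expression-matrix I/O: per-cohort gene × sample matrices with group labels.

Each cohort (one GEO-style accession or synthetic id) is a TSV matrix of gene
rows by sample columns plus a two-column sample-metadata TSV mapping sample id
to COPD / non-COPD. Duplicate gene rows (multiple probes per symbol) collapse
to the probe with the highest mean expression — the usual microarray
convention. Values are normalized to log2 before testing; the linear-scale
matrix is retained (or back-transformed) for the log10-ratio dot-plot
statistic.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

COMPARTMENTS = ("lung", "saec")
GROUPS = ("copd", "non_copd")

#: Matrices whose maximum exceeds this are assumed linear-scale (auto-detect).
LINEAR_SCALE_MAX = 50.0


def normalize_group(raw: str) -> str:
    """Map a metadata group label to 'copd' / 'non_copd'.

    Case-insensitive and hyphen/underscore/space tolerant, so 'COPD',
    'non-COPD', 'Non COPD' and 'non_copd' all parse.
    """
    g = raw.strip().lower().replace("-", "_").replace(" ", "_")
    if g == "copd":
        return "copd"
    if g in {"non_copd", "noncopd", "noncopd_", "n_copd"}:
        return "non_copd"
    raise ValueError(f"unrecognized group label {raw!r} (expected COPD or non-COPD)")


@dataclass
class ExpressionDataset:
    """One cohort's expression matrix with sample groups and compartment.

    ``values`` is a (n_genes, n_samples) float array; ``scale`` records
    whether it is linear or log2. ``linear_values`` holds the original
    linear-scale matrix when a log transform has been applied, so ratio
    statistics can use true linear means.
    """

    dataset_id: str
    compartment: str
    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    groups: list[str]
    scale: str = "log2"
    linear_values: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise ValueError(f"compartment must be one of {COMPARTMENTS}")
        if self.scale not in ("linear", "log2"):
            raise ValueError("scale must be 'linear' or 'log2'")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"{self.dataset_id}: matrix shape {self.values.shape} does not match "
                f"({len(self.gene_ids)} genes, {len(self.sample_ids)} samples)"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError(f"{self.dataset_id}: duplicate gene ids after collapse")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"{self.dataset_id}: non-finite values in matrix")
        if self.scale == "linear" and np.any(self.values < 0):
            raise ValueError(f"{self.dataset_id}: negative values under linear scale")
        bad = [g for g in self.groups if g not in GROUPS]
        if bad:
            raise ValueError(f"{self.dataset_id}: invalid group labels {bad[:3]}")
        for grp in GROUPS:
            n = sum(g == grp for g in self.groups)
            if n < 2:
                raise ValueError(
                    f"{self.dataset_id}: group {grp!r} has {n} samples (need >= 2)"
                )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def group_sizes(self) -> dict[str, int]:
        return {grp: sum(g == grp for g in self.groups) for grp in GROUPS}

    def group_columns(self, group: str) -> np.ndarray:
        """Column indices of the samples belonging to ``group``."""
        return np.array([i for i, g in enumerate(self.groups) if g == group])

    def linear_matrix(self) -> np.ndarray:
        """The linear-scale matrix: retained original, or 2**values back-transform."""
        if self.linear_values is not None:
            return self.linear_values
        if self.scale == "linear":
            return self.values
        return np.exp2(self.values)


def _collapse_duplicates(frame: pd.DataFrame, dataset_id: str) -> pd.DataFrame:
    """Collapse duplicate gene rows to the row with the highest mean."""
    if frame.index.is_unique:
        return frame
    means = frame.mean(axis=1).to_numpy()
    keep = (
        pd.DataFrame({"gene": frame.index, "mean": means, "pos": range(len(frame))})
        .sort_values(["mean", "pos"], ascending=[False, True], kind="stable")
        .drop_duplicates("gene")
        .sort_values("pos")["pos"]
        .to_numpy()
    )
    n_dropped = len(frame) - len(keep)
    logger.warning(
        "%s: collapsed %d duplicate gene rows (kept max-mean probe)",
        dataset_id,
        n_dropped,
    )
    return frame.iloc[keep]


def read_expression_matrix(
    matrix_path,
    metadata_path,
    dataset_id: str,
    compartment: str,
    scale: str | None = None,
    strict: bool = False,
) -> ExpressionDataset:
    """Read one cohort from a matrix TSV and a sample-metadata TSV.

    The matrix has a header row of sample ids and a first column of gene
    symbols; the metadata maps every sample id to COPD / non-COPD. Samples
    missing from the metadata are dropped with a warning (error under
    ``strict``). ``scale=None`` auto-detects: matrix maximum above
    ``LINEAR_SCALE_MAX`` means linear, else log2.
    """
    frame = pd.read_csv(matrix_path, sep="\t", index_col=0, float_precision="round_trip")
    frame.index = frame.index.astype(str)
    non_numeric = frame.columns[
        [not np.issubdtype(dt, np.number) for dt in frame.dtypes]
    ]
    if len(non_numeric):
        col = non_numeric[0]
        coerced = pd.to_numeric(frame[col], errors="coerce")
        row = frame.index[coerced.isna().to_numpy().argmax()]
        raise ValueError(
            f"{dataset_id}: non-numeric cell at gene {row!r}, sample {col!r}"
        )
    if frame.isna().any().any():
        raise ValueError(f"{dataset_id}: missing values are not allowed")
    frame = _collapse_duplicates(frame, dataset_id)

    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    if not {"sample_id", "group"} <= set(meta.columns):
        raise ValueError(f"{metadata_path}: expected columns sample_id, group")
    group_of = {
        str(row.sample_id): normalize_group(row.group) for row in meta.itertuples()
    }

    missing = [s for s in frame.columns if s not in group_of]
    if missing:
        if strict:
            raise ValueError(f"{dataset_id}: samples without metadata: {missing}")
        logger.warning(
            "%s: dropping %d samples absent from metadata: %s",
            dataset_id,
            len(missing),
            missing,
        )
        frame = frame.drop(columns=missing)

    if scale is None:
        scale = "linear" if float(frame.to_numpy().max()) > LINEAR_SCALE_MAX else "log2"

    return ExpressionDataset(
        dataset_id=dataset_id,
        compartment=compartment,
        gene_ids=[str(g) for g in frame.index],
        sample_ids=[str(s) for s in frame.columns],
        values=frame.to_numpy(dtype=float),
        groups=[group_of[str(s)] for s in frame.columns],
        scale=scale,
    )


def write_expression_matrix(ds: ExpressionDataset, matrix_path, metadata_path) -> None:
    """Write a dataset back to the matrix + metadata TSV pair (full precision)."""
    frame = pd.DataFrame(ds.values, index=ds.gene_ids, columns=ds.sample_ids)
    frame.index.name = "gene"
    frame.to_csv(matrix_path, sep="\t")
    meta = pd.DataFrame({"sample_id": ds.sample_ids, "group": ds.groups})
    meta.to_csv(metadata_path, sep="\t", index=False)


def ensure_log2(ds: ExpressionDataset, pseudocount: float = 1.0) -> ExpressionDataset:
    """Return a log2-scale view of the dataset.

    Linear data becomes ``log2(x + pseudocount)`` with the linear matrix
    retained for ratio statistics; log2 data is returned unchanged
    (idempotent).
    """
    if ds.scale == "log2":
        return ds
    if np.any(ds.values < 0):
        raise ValueError(f"{ds.dataset_id}: negative values cannot be log-transformed")
    return replace(
        ds,
        values=np.log2(ds.values + pseudocount),
        scale="log2",
        linear_values=ds.values,
    )


# ---------------------------------------------------------------------------
# Dataset manifests
# ---------------------------------------------------------------------------


def load_manifest(path, strict: bool = False) -> list[ExpressionDataset]:
    """Load all cohorts listed in a YAML/JSON manifest.

    Each entry carries ``dataset_id``, ``compartment``, ``matrix``,
    ``metadata`` and optionally ``scale``; relative paths resolve against the
    manifest's directory.
    """
    path = Path(path)
    with open(path) as fh:
        if path.suffix == ".json":
            entries = json.load(fh)
        else:
            entries = yaml.safe_load(fh)
    if isinstance(entries, dict):
        entries = entries["datasets"]
    datasets = []
    for entry in entries:
        datasets.append(
            read_expression_matrix(
                matrix_path=path.parent / entry["matrix"],
                metadata_path=path.parent / entry["metadata"],
                dataset_id=entry["dataset_id"],
                compartment=entry["compartment"],
                scale=entry.get("scale"),
                strict=strict,
            )
        )
    return datasets
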