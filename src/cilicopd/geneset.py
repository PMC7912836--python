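"""Curated cilia/ciliopathy geneset construction with source provenance.

Merges labelled gene-identifier lists (UniProt cilia and ciliopathy queries,
100,000 Genomes Project, CentrosomeDB, CilDB, SysCilia, CiliaCarta) into one
deduplicated geneset keyed by normalized gene symbol. Each merged record keeps
the union of contributing source labels, and a gene is flagged
ciliopathy-associated iff at least one of its sources is a ciliopathy-labelled
source. Compartment genesets (the platform-detected subsets of the merged
list) are derived from expression-dataset gene lists.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

logger = logging.getLogger(__name__)

#: The seven provenance labels recognized for curated source lists.
RECOGNIZED_SOURCES = frozenset(
    {
        "uniprot_cilia",
        "uniprot_ciliopathy",
        "genomes100k",
        "centrosomedb",
        "cildb",
        "syscilia",
        "ciliacarta",
    }
)

#: Sources whose membership marks a gene as ciliopathy-associated by default.
DEFAULT_CILIOPATHY_SOURCES = frozenset({"uniprot_ciliopathy"})


def normalize_symbol(symbol: str) -> str:
    """Normalize a gene symbol: strip surrounding whitespace, uppercase."""
    return symbol.strip().upper()


@dataclass(frozen=True)
class GeneRecord:
    """One curated gene entry with provenance.

    Attributes
    ----------
    symbol : str
        Uppercase gene symbol (the dedup key across sources).
    uniprot_id : str or None
        Accession, if any contributing list supplied one.
    name : str
        Free-text protein/gene name.
    sources : frozenset of str
        Non-empty set of provenance labels.
    is_ciliopathy : bool
        True iff at least one source is ciliopathy-labelled.
    """

    symbol: str
    uniprot_id: str | None
    name: str
    sources: frozenset[str]
    is_ciliopathy: bool

    def __post_init__(self) -> None:
        if not self.symbol:
            raise ValueError("GeneRecord symbol must be non-empty")
        if not self.sources:
            raise ValueError(f"GeneRecord {self.symbol}: sources must be non-empty")


class GeneSet:
    """An ordered, symbol-keyed collection of :class:`GeneRecord`.

    Records are stored in lexicographic symbol order so every derived output
    is deterministic.
    """

    def __init__(self, records: Iterable[GeneRecord], label: str = "cilia geneset"):
        self.label = label
        keyed: dict[str, GeneRecord] = {}
        for rec in records:
            if rec.symbol in keyed:
                raise ValueError(f"duplicate symbol in GeneSet: {rec.symbol}")
            keyed[rec.symbol] = rec
        self._records = {sym: keyed[sym] for sym in sorted(keyed)}

    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._records

    def __iter__(self) -> Iterator[GeneRecord]:
        return iter(self._records.values())

    def __getitem__(self, symbol: str) -> GeneRecord:
        return self._records[symbol]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneSet):
            return NotImplemented
        return self._records == other._records

    @property
    def symbols(self) -> list[str]:
        return list(self._records)

    def ciliopathy_subset(self) -> "GeneSet":
        """The ciliopathy-flagged subset (e.g. 189 of the 495-gene list)."""
        return GeneSet(
            (r for r in self if r.is_ciliopathy), label=f"{self.label} (ciliopathy)"
        )

    def subset(self, symbols: Iterable[str], label: str) -> "GeneSet":
        keep = set(symbols)
        return GeneSet((r for r in self if r.symbol in keep), label=label)

    def summary(self) -> dict:
        """JSON-ready summary: total size, ciliopathy count, per-source counts."""
        per_source: dict[str, int] = {}
        for rec in self:
            for src in rec.sources:
                per_source[src] = per_source.get(src, 0) + 1
        return {
            "label": self.label,
            "total": len(self),
            "n_ciliopathy": sum(r.is_ciliopathy for r in self),
            "per_source_counts": dict(sorted(per_source.items())),
        }


SourceList = tuple[str, Sequence[tuple[str, str, str]]]


def merge_sources(
    source_lists: Sequence[SourceList],
    ciliopathy_sources: Iterable[str] = DEFAULT_CILIOPATHY_SOURCES,
    label: str = "cilia geneset",
) -> GeneSet:
    """Merge labelled (symbol, accession, name) lists into one GeneSet.

    Parameters
    ----------
    source_lists
        Sequence of ``(source_label, entries)`` where each entry is a
        ``(symbol, accession, name)`` triple. Symbols are normalized
        (stripped, uppercased) before deduplication; empty symbols are
        rejected with a logged warning.
    ciliopathy_sources
        Labels whose members get ``is_ciliopathy=True``.
    label
        Label for the resulting GeneSet.

    Returns
    -------
    GeneSet
        One record per distinct normalized symbol; ``sources`` is the union
        of contributing labels. When two sources disagree on the accession
        for a symbol, the first seen is kept and the conflict logged.
    """
    cilio = frozenset(ciliopathy_sources)
    merged: dict[str, dict] = {}
    for source_label, entries in source_lists:
        if source_label not in RECOGNIZED_SOURCES:
            raise ValueError(
                f"unrecognized source label {source_label!r}; "
                f"expected one of {sorted(RECOGNIZED_SOURCES)}"
            )
        for raw_symbol, accession, name in entries:
            symbol = normalize_symbol(raw_symbol)
            if not symbol:
                logger.warning(
                    "source %s: empty gene symbol rejected (accession=%r)",
                    source_label,
                    accession,
                )
                continue
            accession = (accession or "").strip() or None
            entry = merged.setdefault(
                symbol,
                {"uniprot_id": accession, "name": name, "sources": set()},
            )
            entry["sources"].add(source_label)
            if accession and entry["uniprot_id"] and accession != entry["uniprot_id"]:
                logger.warning(
                    "symbol %s: conflicting accessions %s vs %s; keeping first",
                    symbol,
                    entry["uniprot_id"],
                    accession,
                )
            elif accession and entry["uniprot_id"] is None:
                entry["uniprot_id"] = accession
            if not entry["name"]:
                entry["name"] = name
    records = [
        GeneRecord(
            symbol=sym,
            uniprot_id=info["uniprot_id"],
            name=info["name"],
            sources=frozenset(info["sources"]),
            is_ciliopathy=bool(info["sources"] & cilio),
        )
        for sym, info in merged.items()
    ]
    return GeneSet(records, label=label)


def compartment_geneset(gs: GeneSet, datasets: Sequence) -> GeneSet:
    """Subset of ``gs`` detected in at least one dataset of one compartment.

    All datasets must share a compartment label (the study never mixes whole
    lung and SAEC when defining the compartment geneset).
    """
    if not datasets:
        raise ValueError("compartment_geneset requires at least one dataset")
    compartments = {ds.compartment for ds in datasets}
    if len(compartments) != 1:
        raise ValueError(f"datasets span multiple compartments: {sorted(compartments)}")
    compartment = compartments.pop()
    detected: set[str] = set()
    for ds in datasets:
        detected.update(ds.gene_ids)
    return gs.subset(detected, label=f"{compartment} cilia geneset")


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

GENESET_INPUT_COLUMNS = ["source", "symbol", "accession", "name"]


def read_source_lists(path) -> list[SourceList]:
    """Read a source TSV (`source  symbol  accession  name`, with header).

    One file may carry several sources; rows are grouped by source label in
    order of first appearance.
    """
    grouped: dict[str, list[tuple[str, str, str]]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(GENESET_INPUT_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        for row in reader:
            grouped.setdefault(row["source"], []).append(
                (row["symbol"], row.get("accession") or "", row.get("name") or "")
            )
    return list(grouped.items())


def write_geneset(gs: GeneSet, path) -> None:
    """Write a merged geneset TSV (symbol, uniprot_id, name, sources, is_ciliopathy)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["symbol", "uniprot_id", "name", "sources", "is_ciliopathy"])
        for rec in gs:
            writer.writerow(
                [
                    rec.symbol,
                    rec.uniprot_id or "",
                    rec.name,
                    ";".join(sorted(rec.sources)),
                    int(rec.is_ciliopathy),
                ]
            )


def read_geneset(path, label: str = "cilia geneset") -> GeneSet:
    """Read a merged geneset TSV written by :func:`write_geneset`."""
    records = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            records.append(
                GeneRecord(
                    symbol=row["symbol"],
                    uniprot_id=row["uniprot_id"] or None,
                    name=row["name"],
                    sources=frozenset(row["sources"].split(";")),
                    is_ciliopathy=bool(int(row["is_ciliopathy"])),
                )
            )
    return GeneSet(records, label=label)


def write_summary(gs: GeneSet, path) -> None:
    with open(path, "w") as fh:
        json.dump(gs.summary(), fh, indent=2, sort_keys=True)
        fh.write("\n")
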