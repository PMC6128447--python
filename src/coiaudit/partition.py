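"""Build the analysis partitions: marker-gene subset, keyword subset, taxon groups."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Optional, TextIO

import yaml

from .records import RecordSet

#: Default marker-gene label synonyms (cytochrome oxidase subunit 1).
DEFAULT_GENE_SYNONYMS = frozenset({"CO1", "COI", "COX1", "COXI"})


@dataclass(frozen=True)
class TaxonGroupSpec:
    """A named taxon group defined by lineage tokens that must appear."""

    group_name: str
    lineage_tokens: FrozenSet[str]

    def __post_init__(self):
        if not self.lineage_tokens:
            raise ValueError("lineage_tokens must be non-empty")
        object.__setattr__(self, "lineage_tokens", frozenset(self.lineage_tokens))


#: High-level freshwater biomonitoring target groups.
FRESHWATER_GROUPS: List[TaxonGroupSpec] = [
    TaxonGroupSpec(name, frozenset({name}))
    for name in (
        "Clitellata", "Polychaeta",            # Annelida classes
        "Coleoptera", "Diptera", "Ephemeroptera", "Megaloptera",
        "Odonata", "Plecoptera", "Trichoptera",  # Insecta orders
        "Amphipoda", "Isopoda",                # Malacostraca orders
        "Bivalvia", "Gastropoda",              # Mollusca classes
        "Turbellaria",                         # Platyhelminthes class
    )
]


def filter_coi(records: RecordSet,
               gene_synonyms: Iterable[str] = DEFAULT_GENE_SYNONYMS) -> RecordSet:
    """Retain records whose gene labels intersect the marker synonyms (case-folded)."""
    wanted = {g.lower() for g in gene_synonyms}
    hits = [
        r for r in records
        if any(label.lower() in wanted for label in r.gene_labels)
    ]
    return RecordSet(records=hits, source_label=records.source_label)


def filter_keyword(records: RecordSet, keyword: str = "BARCODE") -> RecordSet:
    """Retain records carrying ``keyword`` (exact match on normalized keywords)."""
    if not keyword:
        raise ValueError("keyword must be non-empty")
    hits = [r for r in records if keyword in r.keywords]
    return RecordSet(records=hits, source_label=records.source_label)


@dataclass
class TaxaPartition:
    """Union of records matching any group, plus a per-group attribution table."""

    records: RecordSet
    attribution: Dict[str, int]


def filter_taxa(records: RecordSet,
                groups: List[TaxonGroupSpec]) -> TaxaPartition:
    """Retain records whose lineage names any group's tokens (exact match).

    A record matching several groups appears once in the union but is
    attributed to every matching group in the table.
    """
    if not groups:
        raise ValueError("groups must be non-empty")
    attribution = {g.group_name: 0 for g in groups}
    hits = []
    for rec in records:
        lineage = set(rec.lineage)
        matched = False
        for group in groups:
            if lineage & group.lineage_tokens:
                attribution[group.group_name] += 1
                matched = True
        if matched:
            hits.append(rec)
    return TaxaPartition(
        records=RecordSet(records=hits, source_label=records.source_label),
        attribution=attribution,
    )


def load_groups(stream: TextIO, fmt: str = "yaml") -> List[TaxonGroupSpec]:
    """Load taxon-group specs from YAML (name -> tokens) or TSV (name<TAB>tok,tok)."""
    if fmt == "yaml":
        data = yaml.safe_load(stream) or {}
        return [
            TaxonGroupSpec(name, frozenset([tokens] if isinstance(tokens, str)
                                           else tokens))
            for name, tokens in data.items()
        ]
    if fmt == "tsv":
        groups = []
        for line in stream:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            name, _, tokens = line.partition("\t")
            toks = [t.strip() for t in tokens.split(",") if t.strip()] or [name]
            groups.append(TaxonGroupSpec(name.strip(), frozenset(toks)))
        return groups
    raise ValueError(f"unknown groups format {fmt!r}")
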