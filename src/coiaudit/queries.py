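"""Build (never execute) the retrieval query strings for out-of-band reproduction."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

DEFAULT_GENE_SYNONYMS = ("CO1", "COI", "COX1", "COXI")
DEFAULT_ORGANISM_SCOPE = "Eukaryota"


@dataclass(frozen=True)
class QuerySpec:
    gene_synonyms: Tuple[str, ...] = DEFAULT_GENE_SYNONYMS
    organism_scope: str = DEFAULT_ORGANISM_SCOPE
    year: Optional[int] = None
    keyword: Optional[str] = None
    species_clause: Optional[str] = None

    def __post_init__(self):
        if not self.gene_synonyms:
            raise ValueError("gene_synonyms must be non-empty")


def build_nucleotide_query(spec: QuerySpec = QuerySpec()) -> str:
    """Nucleotide-database query: gene disjunction AND organism scope,
    optionally AND year[PDAT], AND "<keyword>"[KYWD], AND a species clause.
    Output always has balanced parentheses and quotes.
    """
    gene_clause = " OR ".join(f'"{g}"[GENE]' for g in spec.gene_synonyms)
    parts = [f"({gene_clause})", f'"{spec.organism_scope}"[ORGN]']
    if spec.year is not None:
        parts.append(f"{spec.year}[PDAT]")
    if spec.keyword:
        parts.append(f'"{spec.keyword}"[KYWD]')
    if spec.species_clause:
        parts.append(f"({spec.species_clause})")
    return " AND ".join(parts)


def build_taxonomy_query(scope: str, rank: str) -> str:
    """Taxonomy-database query in the plus-joined form."""
    if not scope:
        raise ValueError("scope must be non-empty")
    if not rank:
        raise ValueError("rank must be non-empty")
    return f"{scope}[ORGN]+AND+{rank}[RANK]"


def build_bold_query(taxon: str, markers: Sequence[str] = ("COI-3P", "COI-5P")) -> str:
    """BOLD API query term: pipe-joined markers and a taxon."""
    if not taxon:
        raise ValueError("taxon must be non-empty")
    if not markers:
        raise ValueError("markers must be non-empty")
    return f"marker={'|'.join(markers)}&taxon={taxon}"


def chunk_species_clauses(names: Sequence[str], max_len: int = 2000) -> List[str]:
    """OR-join quoted organism names into clauses no longer than ``max_len``.

    Large species lists overflow a single query; the retrieval is batched.
    """
    clauses: List[str] = []
    current: List[str] = []
    current_len = 0
    for name in names:
        term = f'"{name}"[ORGN]'
        extra = len(term) + (4 if current else 0)  # " OR "
        if current and current_len + extra > max_len:
            clauses.append(" OR ".join(current))
            current, current_len = [], 0
            extra = len(term)
        current.append(term)
        current_len += extra
    if current:
        clauses.append(" OR ".join(current))
    return clauses
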