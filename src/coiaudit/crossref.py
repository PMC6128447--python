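"""Three-way reconciliation of BOLD records against GenBank accession sets.

Each BOLD record falls into exactly one category: linked to a BARCODE-flagged
GenBank accession, linked to some other GenBank accession, or carrying no
accession at all (unique to BOLD).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Set, TextIO

from ._round import percent
from .records import BoldRecord, DuplicateRecordError


def normalize_accession(accession: str) -> str:
    """Uppercase and strip a trailing version suffix (``MG000001.1`` -> ``MG000001``)."""
    return accession.strip().upper().split(".")[0]


@dataclass(frozen=True)
class CrossrefPartition:
    source_label: str
    n_barcode_linked: int
    n_accession_linked: int
    n_bold_only: int
    n_total: int
    pct_barcode_linked: int
    pct_accession_linked: int
    pct_bold_only: int
    #: accession present but absent from the supplied full GenBank index
    #: (treated as suppressed); reported only when an index was supplied
    n_suppressed: Optional[int] = None

    def __post_init__(self):
        if (self.n_barcode_linked + self.n_accession_linked
                + self.n_bold_only) != self.n_total:
            raise ValueError("category counts do not sum to total")

    @classmethod
    def from_counts(cls, n_barcode_linked: int, n_accession_linked: int,
                    n_bold_only: int, source_label: str = "",
                    n_suppressed: Optional[int] = None) -> "CrossrefPartition":
        """Build a partition directly from category counts (shared percent rule)."""
        total = n_barcode_linked + n_accession_linked + n_bold_only
        return cls(
            source_label=source_label,
            n_barcode_linked=n_barcode_linked,
            n_accession_linked=n_accession_linked,
            n_bold_only=n_bold_only,
            n_total=total,
            pct_barcode_linked=percent(n_barcode_linked, total),
            pct_accession_linked=percent(n_accession_linked, total),
            pct_bold_only=percent(n_bold_only, total),
            n_suppressed=n_suppressed,
        )


def crossref(bold: Sequence[BoldRecord],
             barcode_accessions: Iterable[str],
             all_accessions: Optional[Iterable[str]] = None,
             source_label: str = "") -> CrossrefPartition:
    """Partition BOLD records by their GenBank linkage.

    Accessions are compared version-stripped and case-folded on both sides.
    When ``all_accessions`` is supplied, accession-linked records missing
    from it are additionally counted as suppressed (sub-count only; the
    category assignment is unchanged).
    """
    barcode_set = {normalize_accession(a) for a in barcode_accessions}
    all_set: Optional[Set[str]] = None
    if all_accessions is not None:
        all_set = {normalize_accession(a) for a in all_accessions}

    seen_ids = set()
    n_barcode = n_accession = n_only = n_suppressed = 0
    for rec in bold:
        if rec.record_id in seen_ids:
            raise DuplicateRecordError(f"duplicate record_id {rec.record_id!r}")
        seen_ids.add(rec.record_id)
        if rec.genbank_accession is None:
            n_only += 1
            continue
        acc = normalize_accession(rec.genbank_accession)
        if acc in barcode_set:
            n_barcode += 1
        else:
            n_accession += 1
            if all_set is not None and acc not in all_set:
                n_suppressed += 1

    return CrossrefPartition.from_counts(
        n_barcode, n_accession, n_only,
        source_label=source_label,
        n_suppressed=n_suppressed if all_set is not None else None,
    )


def partitions_to_tsv(partitions: Iterable[CrossrefPartition],
                      stream: TextIO) -> None:
    """Emit the three-count(percent) table shape, one row per source."""
    writer = csv.writer(stream, delimiter="\t", lineterminator="\n")
    writer.writerow([
        "source", "barcode_linked", "accession_linked", "bold_only", "total",
    ])
    for p in partitions:
        writer.writerow([
            p.source_label,
            f"{p.n_barcode_linked} ({p.pct_barcode_linked}%)",
            f"{p.n_accession_linked} ({p.pct_accession_linked}%)",
            f"{p.n_bold_only} ({p.pct_bold_only}%)",
            p.n_total,
        ])
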