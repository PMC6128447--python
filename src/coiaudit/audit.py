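"""Metadata-completeness audit for a record partition.

For each partition the audit reports how many records are fully identified
and, among the fully identified records, how many have good sequence length
(default >= 500 bp), a country qualifier, and a latitude-longitude qualifier.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass
from typing import Iterable, List, TextIO

from ._round import percent
from .names import DisqualifierSet, GENBANK_DISQUALIFIERS, classify_name
from .records import RecordSet

DEFAULT_LENGTH_THRESHOLD = 500


@dataclass(frozen=True)
class AuditReport:
    partition_label: str
    n_total: int
    n_fully_identified: int
    n_len_ge_500: int
    n_country: int
    n_latlon: int
    pct_fully_identified: int
    pct_len_ge_500: int
    pct_country: int
    pct_latlon: int
    degenerate: bool = False

    def __post_init__(self):
        if self.n_fully_identified > self.n_total:
            raise ValueError("n_fully_identified exceeds n_total")
        for n in (self.n_len_ge_500, self.n_country, self.n_latlon):
            if n > self.n_fully_identified:
                raise ValueError("sub-count exceeds n_fully_identified")


def audit(records: RecordSet,
          disq: DisqualifierSet = GENBANK_DISQUALIFIERS,
          label: str = "All",
          species_list_mode: bool = False,
          length_threshold: int = DEFAULT_LENGTH_THRESHOLD) -> AuditReport:
    """Audit one partition.

    ``species_list_mode`` treats every record as fully identified — the
    convention for checklist-derived partitions, where membership already
    implies a species-rank name.  Completeness percents use the count of
    fully identified records as denominator.
    """
    n_total = len(records)
    n_full = n_len = n_country = n_latlon = 0
    for rec in records:
        full = species_list_mode or classify_name(rec.organism_name, disq).is_full
        if not full:
            continue
        n_full += 1
        if rec.sequence_length >= length_threshold:
            n_len += 1
        if rec.country_raw is not None:
            n_country += 1
        if rec.lat_lon_raw is not None:
            n_latlon += 1
    return AuditReport(
        partition_label=label,
        n_total=n_total,
        n_fully_identified=n_full,
        n_len_ge_500=n_len,
        n_country=n_country,
        n_latlon=n_latlon,
        pct_fully_identified=percent(n_full, n_total),
        pct_len_ge_500=percent(n_len, n_full),
        pct_country=percent(n_country, n_full),
        pct_latlon=percent(n_latlon, n_full),
        degenerate=n_total == 0,
    )


_COLUMNS = [
    "partition_label", "n_total", "n_fully_identified", "n_len_ge_500",
    "n_country", "n_latlon", "pct_fully_identified", "pct_len_ge_500",
    "pct_country", "pct_latlon", "degenerate",
]


def reports_to_tsv(reports: Iterable[AuditReport], stream: TextIO) -> None:
    writer = csv.writer(stream, delimiter="\t", lineterminator="\n")
    writer.writerow(_COLUMNS)
    for rep in reports:
        d = asdict(rep)
        writer.writerow([d[c] for c in _COLUMNS])


def reports_to_json(reports: Iterable[AuditReport], stream: TextIO) -> None:
    json.dump([asdict(r) for r in reports], stream, indent=2)
    stream.write("\n")
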