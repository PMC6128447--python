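"""Readers and writers for the record formats the audit consumes.

Two families of input are supported: GenBank flatfiles (LOCUS ... //) and
BOLD-style sequence dumps, either tab-separated tables or FASTA files with
pipe-delimited headers (``id|taxon|marker|accession``).
"""

from __future__ import annotations

import csv
import io
import logging
from dataclasses import dataclass, field
from datetime import date
from typing import Iterator, List, Optional, Sequence, TextIO

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord as _BioRecord

logger = logging.getLogger(__name__)

MIN_DEPOSIT_YEAR = 1982

_BOLD_PLACEHOLDERS = {"", "na", "n/a", "none", "null", "-"}

# acceptable header spellings for the mandatory BOLD TSV columns
_BOLD_COLUMN_ALIASES = {
    "record_id": ("record_id", "recordid", "processid", "process_id", "sequenceid"),
    "taxon_name": ("taxon_name", "taxon", "species", "species_name", "identification"),
    "marker": ("marker", "markercode", "marker_code"),
    "genbank_accession": ("genbank_accession", "accession", "genbank_acc", "genbank"),
}


class RecordFormatError(ValueError):
    """Malformed input; carries the byte offset and partial accession if known."""

    def __init__(self, message: str, byte_offset: Optional[int] = None,
                 partial_accession: Optional[str] = None):
        self.byte_offset = byte_offset
        self.partial_accession = partial_accession
        detail = message
        if byte_offset is not None:
            detail += f" (byte offset {byte_offset}"
            if partial_accession:
                detail += f", partial accession {partial_accession!r}"
            detail += ")"
        super().__init__(detail)


class DuplicateRecordError(ValueError):
    """A record identifier occurred more than once within one set."""


class RecordValidationError(ValueError):
    """A record violates a structural invariant."""


@dataclass(frozen=True)
class SequenceRecord:
    """One parsed sequence-database record."""

    accession: str
    deposit_year: int
    organism_name: str
    lineage: tuple = ()
    keywords: frozenset = frozenset()
    gene_labels: frozenset = frozenset()
    sequence_length: int = 0
    country_raw: Optional[str] = None
    lat_lon_raw: Optional[str] = None
    sequence: Optional[str] = None

    def __post_init__(self):
        if not self.accession:
            raise RecordValidationError("accession must be non-empty")
        if not (MIN_DEPOSIT_YEAR <= self.deposit_year <= date.today().year):
            raise RecordValidationError(
                f"deposit_year {self.deposit_year} outside "
                f"[{MIN_DEPOSIT_YEAR}, current year]"
            )
        if self.sequence_length < 0:
            raise RecordValidationError("sequence_length must be >= 0")
        if self.sequence is not None and len(self.sequence) != self.sequence_length:
            raise RecordValidationError(
                "sequence_length disagrees with sequence text"
            )
        object.__setattr__(self, "lineage", tuple(self.lineage))
        object.__setattr__(self, "keywords", frozenset(self.keywords))
        object.__setattr__(self, "gene_labels", frozenset(self.gene_labels))


@dataclass(frozen=True)
class BoldRecord:
    """One record from a BOLD-style dump."""

    record_id: str
    taxon_name: str
    marker: str
    genbank_accession: Optional[str] = None

    def __post_init__(self):
        if not self.record_id:
            raise RecordValidationError("record_id must be non-empty")
        if not self.marker:
            raise RecordValidationError("marker must be non-empty")


@dataclass
class RecordSet:
    """An ordered collection of :class:`SequenceRecord` with unique accessions."""

    records: List[SequenceRecord] = field(default_factory=list)
    source_label: str = ""

    def __post_init__(self):
        seen = set()
        for rec in self.records:
            if rec.accession in seen:
                raise DuplicateRecordError(
                    f"duplicate accession {rec.accession!r}"
                )
            seen.add(rec.accession)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def accessions(self) -> set:
        return {r.accession for r in self.records}


# ---------------------------------------------------------------------------
# GenBank flatfile I/O
# ---------------------------------------------------------------------------

def _normalize_keywords(raw: Sequence[str]) -> frozenset:
    # trailing period comes from the flatfile line terminator, not the keyword
    out = set()
    for kw in raw:
        for token in kw.replace(";", " ").split():
            token = token.strip().rstrip(".")
            if token:
                out.add(token)
    return frozenset(out)


def _split_entries(text: str):
    """Yield (byte_offset, chunk_text) per flatfile entry, validating structure."""
    offset = 0
    entry_lines: List[str] = []
    entry_offset = None
    partial_acc = None
    for line in text.splitlines(keepends=True):
        stripped = line.strip()
        if entry_offset is None:
            if stripped.startswith("LOCUS"):
                entry_offset = offset
                entry_lines = [line]
                parts = stripped.split()
                partial_acc = parts[1] if len(parts) > 1 else None
            elif stripped:
                raise RecordFormatError(
                    "content outside a LOCUS.. // entry", byte_offset=offset
                )
        else:
            if stripped.startswith("LOCUS"):
                raise RecordFormatError(
                    "entry not terminated by // before next LOCUS",
                    byte_offset=entry_offset,
                    partial_accession=partial_acc,
                )
            entry_lines.append(line)
            if stripped.startswith("ACCESSION"):
                parts = stripped.split()
                if len(parts) > 1:
                    partial_acc = parts[1]
            if stripped == "//":
                yield entry_offset, "".join(entry_lines)
                entry_offset = None
                entry_lines = []
                partial_acc = None
        offset += len(line.encode("utf-8"))
    if entry_offset is not None:
        raise RecordFormatError(
            "entry not terminated by // before end of stream",
            byte_offset=entry_offset,
            partial_accession=partial_acc,
        )


def _parse_organism_block(chunk: str):
    """Extract (organism, lineage) from the ORGANISM block ourselves.

    Biopython's heuristic folds one-element lineage lines into the organism
    name; the block structure is unambiguous for the records we model
    (organism on the ORGANISM line, lineage on the indented lines below).
    """
    lines = chunk.splitlines()
    organism = None
    lineage_text: List[str] = []
    in_block = False
    for line in lines:
        if line.startswith("  ORGANISM"):
            organism = line[len("  ORGANISM"):].strip()
            in_block = True
            continue
        if in_block:
            if line.startswith("            "):
                lineage_text.append(line.strip())
            else:
                break
    if organism is None:
        return None, ()
    joined = " ".join(lineage_text).strip()
    if joined.endswith("."):
        joined = joined[:-1]
    lineage = tuple(t.strip() for t in joined.split(";") if t.strip())
    return organism, lineage


def _parse_entry(chunk: str, byte_offset: int) -> SequenceRecord:
    try:
        bio = SeqIO.read(io.StringIO(chunk), "genbank")
    except Exception as exc:  # Biopython raises bare ValueError subclasses
        first = chunk.splitlines()[0].split()
        raise RecordFormatError(
            f"unparseable flatfile entry: {exc}",
            byte_offset=byte_offset,
            partial_accession=first[1] if len(first) > 1 else None,
        ) from exc

    ann = bio.annotations
    accession = (ann.get("accessions") or [bio.name])[0]
    date_str = ann.get("date", "")
    try:
        year = int(date_str.rsplit("-", 1)[-1])
    except ValueError:
        raise RecordFormatError(
            f"unparseable LOCUS date {date_str!r}",
            byte_offset=byte_offset,
            partial_accession=accession,
        )

    gene_labels = set()
    country = lat_lon = None
    sources = [f for f in bio.features if f.type == "source"]
    if sources:
        quals = sources[0].qualifiers
        country = (quals.get("country") or quals.get("geo_loc_name") or [None])[0]
        lat_lon = (quals.get("lat_lon") or [None])[0]
        if len(sources) > 1:
            logger.warning(
                "record %s has %d source features; only the first is used",
                accession, len(sources),
            )
    for feat in bio.features:
        if feat.type == "gene":
            gene_labels.update(feat.qualifiers.get("gene", []))

    seq_text = str(bio.seq) if bio.seq is not None else None

    organism, lineage = _parse_organism_block(chunk)
    if organism is None:
        organism, lineage = ann.get("organism", ""), tuple(ann.get("taxonomy", []))

    return SequenceRecord(
        accession=accession,
        deposit_year=year,
        organism_name=organism,
        lineage=lineage,
        keywords=_normalize_keywords(ann.get("keywords", [])),
        gene_labels=frozenset(gene_labels),
        sequence_length=len(seq_text) if seq_text is not None else 0,
        country_raw=country,
        lat_lon_raw=lat_lon,
        sequence=seq_text,
    )


def read_genbank(stream: TextIO, source_label: str = "") -> RecordSet:
    """Parse a GenBank flatfile stream into a :class:`RecordSet`.

    The LOCUS-line date supplies ``deposit_year`` (the offline stand-in for
    a deposition date).  Raises :class:`RecordFormatError` on structural
    damage, naming the byte offset and the partial accession when known, and
    :class:`DuplicateRecordError` on repeated accessions.
    """
    records = []
    seen = set()
    for byte_offset, chunk in _split_entries(stream.read()):
        rec = _parse_entry(chunk, byte_offset)
        if rec.accession in seen:
            raise DuplicateRecordError(f"duplicate accession {rec.accession!r}")
        seen.add(rec.accession)
        records.append(rec)
    return RecordSet(records=records, source_label=source_label)


def write_genbank(rs: RecordSet, stream: TextIO) -> None:
    """Serialize a :class:`RecordSet` as GenBank flatfile entries.

    The output round-trips through :func:`read_genbank` preserving every
    :class:`SequenceRecord` field.
    """
    bio_records = []
    for rec in rs:
        if not rec.accession:
            raise RecordValidationError("record without accession")
        seq_text = rec.sequence if rec.sequence is not None else "N" * rec.sequence_length
        length = len(seq_text)
        bio = _BioRecord(
            Seq(seq_text),
            id=rec.accession,
            name=rec.accession[:16],
            description=f"{rec.organism_name} cytochrome oxidase record",
        )
        bio.annotations["molecule_type"] = "DNA"
        bio.annotations["topology"] = "linear"
        bio.annotations["data_file_division"] = "INV"
        bio.annotations["date"] = f"01-JAN-{rec.deposit_year:04d}"
        bio.annotations["accessions"] = [rec.accession]
        bio.annotations["organism"] = rec.organism_name
        bio.annotations["source"] = rec.organism_name
        bio.annotations["taxonomy"] = list(rec.lineage)
        bio.annotations["keywords"] = sorted(rec.keywords)

        src_quals = {"organism": [rec.organism_name], "mol_type": ["genomic DNA"]}
        if rec.country_raw is not None:
            src_quals["country"] = [rec.country_raw]
        if rec.lat_lon_raw is not None:
            src_quals["lat_lon"] = [rec.lat_lon_raw]
        features = [SeqFeature(SimpleLocation(0, length), type="source",
                               qualifiers=src_quals)]
        for gene in sorted(rec.gene_labels):
            features.append(
                SeqFeature(SimpleLocation(0, length, strand=1), type="gene",
                           qualifiers={"gene": [gene]})
            )
        bio.features = features
        bio_records.append(bio)
    SeqIO.write(bio_records, stream, "genbank")


# ---------------------------------------------------------------------------
# BOLD dump I/O
# ---------------------------------------------------------------------------

def _clean_accession(value: Optional[str]) -> Optional[str]:
    if value is None or value.strip().lower() in _BOLD_PLACEHOLDERS:
        return None
    return value.strip()


def _read_bold_tsv(stream: TextIO) -> List[BoldRecord]:
    reader = csv.reader(stream, delimiter="\t")
    try:
        header = next(reader)
    except StopIteration:
        raise RecordFormatError("missing column: record_id (empty stream)")
    lookup = {name.strip().lower(): i for i, name in enumerate(header)}
    indices = {}
    for canonical, aliases in _BOLD_COLUMN_ALIASES.items():
        for alias in aliases:
            if alias in lookup:
                indices[canonical] = lookup[alias]
                break
        else:
            raise RecordFormatError(f"missing column: {canonical}")
    out = []
    for row in reader:
        if not row or all(not cell.strip() for cell in row):
            continue
        def cell(key):
            i = indices[key]
            return row[i].strip() if i < len(row) else ""
        out.append(BoldRecord(
            record_id=cell("record_id"),
            taxon_name=cell("taxon_name"),
            marker=cell("marker"),
            genbank_accession=_clean_accession(cell("genbank_accession")),
        ))
    return out


def _read_bold_fasta(stream: TextIO) -> List[BoldRecord]:
    out = []
    for line in stream:
        line = line.strip()
        if not line.startswith(">"):
            continue
        fields = [f.strip() for f in line[1:].split("|")]
        if len(fields) < 3:
            raise RecordFormatError(
                f"FASTA header {line!r} lacks id|taxon|marker fields"
            )
        accession = _clean_accession(fields[3]) if len(fields) > 3 else None
        out.append(BoldRecord(
            record_id=fields[0],
            taxon_name=fields[1],
            marker=fields[2],
            genbank_accession=accession,
        ))
    return out


def read_bold_dump(stream: TextIO, dialect: str = "tsv") -> List[BoldRecord]:
    """Parse a BOLD-style dump (``tsv`` or ``fasta`` dialect)."""
    if dialect == "tsv":
        records = _read_bold_tsv(stream)
    elif dialect == "fasta":
        records = _read_bold_fasta(stream)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    seen = set()
    for rec in records:
        if rec.record_id in seen:
            raise DuplicateRecordError(f"duplicate record_id {rec.record_id!r}")
        seen.add(rec.record_id)
    return records


def write_bold_dump(records: Sequence[BoldRecord], stream: TextIO,
                    dialect: str = "tsv") -> None:
    """Serialize BOLD records in either supported dialect."""
    if dialect == "tsv":
        writer = csv.writer(stream, delimiter="\t", lineterminator="\n")
        writer.writerow(["record_id", "taxon_name", "marker", "genbank_accession"])
        for rec in records:
            writer.writerow([rec.record_id, rec.taxon_name, rec.marker,
                             rec.genbank_accession or ""])
    elif dialect == "fasta":
        for rec in records:
            stream.write(f">{rec.record_id}|{rec.taxon_name}|{rec.marker}|"
                         f"{rec.genbank_accession or ''}\n")
            stream.write("N\n")  # dumps carry sequence text we do not model
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
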