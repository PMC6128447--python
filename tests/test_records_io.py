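import io

import pytest
from hypothesis import given, settings, strategies as st

from coiaudit.records import (BoldRecord, DuplicateRecordError,
                              RecordFormatError, RecordSet, SequenceRecord,
                              read_bold_dump, read_genbank, write_bold_dump,
                              write_genbank)

# --- strategies ------------------------------------------------------------

accessions = st.from_regex(r"[A-Z]{2}[0-9]{6}", fullmatch=True)
organisms = st.sampled_from([
    "Homo sapiens", "Gammarus fossarum", "Daphnia pulex", "Gammarus sp.",
    "Bison", "Daphnia cf. pulex",
])
countries = st.one_of(st.none(), st.sampled_from(
    ["Canada: Ontario", "USA", "Germany: Bavaria"]))
lat_lons = st.one_of(st.none(), st.sampled_from(
    ["45.50 N 73.57 W", "12.10 S 96.90 E", "0.00 N 0.00 E"]))


@st.composite
def sequence_records(draw, accession=None):
    length = draw(st.integers(min_value=0, max_value=80))
    seq = "".join(draw(st.lists(st.sampled_from("ACGT"), min_size=length,
                                max_size=length)))
    return SequenceRecord(
        accession=accession or draw(accessions),
        deposit_year=draw(st.integers(min_value=1990, max_value=2017)),
        organism_name=draw(organisms),
        lineage=tuple(draw(st.lists(
            st.sampled_from(["Eukaryota", "Metazoa", "Arthropoda", "Diptera"]),
            max_size=4, unique=True))),
        keywords=frozenset(draw(st.lists(
            st.sampled_from(["BARCODE", "RefSeq"]), max_size=2, unique=True))),
        gene_labels=frozenset(draw(st.lists(
            st.sampled_from(["COI", "CO1", "COX1", "ND5"]), max_size=2,
            unique=True))),
        sequence_length=length,
        country_raw=draw(countries),
        lat_lon_raw=draw(lat_lons),
        sequence=seq,
    )


@st.composite
def record_sets(draw, max_size=8):
    accs = draw(st.lists(accessions, min_size=0, max_size=max_size,
                         unique=True))
    return RecordSet(records=[draw(sequence_records(accession=a))
                              for a in accs])


# --- GenBank flatfile ------------------------------------------------------

def test_empty_stream_yields_empty_set():
    assert len(read_genbank(io.StringIO(""))) == 0


def test_single_synthetic_entry_fields():
    rec = SequenceRecord(
        accession="SYNTEST01", deposit_year=2010, organism_name="Homo sapiens",
        lineage=("Eukaryota", "Metazoa"), keywords=frozenset({"BARCODE"}),
        gene_labels=frozenset({"COI"}), sequence_length=658,
        country_raw="Canada: Ontario", lat_lon_raw="45.50 N 73.57 W",
        sequence="ACGT" * 164 + "AC",
    )
    buf = io.StringIO()
    write_genbank(RecordSet(records=[rec]), buf)
    parsed = read_genbank(io.StringIO(buf.getvalue())).records[0]
    assert parsed.sequence_length == 658
    assert "BARCODE" in parsed.keywords
    assert "COI" in parsed.gene_labels
    assert parsed.country_raw == "Canada: Ontario"
    assert parsed.lat_lon_raw == "45.50 N 73.57 W"
    assert parsed.deposit_year == 2010


def test_round_trip_100_record_synthetic_set(small_data):
    # fixture holds >= 100 records by construction
    assert len(small_data.records) >= 100
    reread = read_genbank(io.StringIO(small_data.genbank_text))
    assert reread.records == small_data.records.records


@settings(max_examples=40, deadline=None)
@given(rs=record_sets())
def test_round_trip_property(rs):
    buf = io.StringIO()
    write_genbank(rs, buf)
    assert read_genbank(io.StringIO(buf.getvalue())).records == rs.records


def test_count_matches_terminators(small_data):
    n_terminators = sum(
        1 for line in small_data.genbank_text.splitlines()
        if line.strip() == "//")
    assert n_terminators == len(small_data.records)


def test_write_zero_records_empty_output():
    buf = io.StringIO()
    write_genbank(RecordSet(), buf)
    assert "LOCUS" not in buf.getvalue()


def test_absent_geo_qualifiers_stay_absent():
    rec = SequenceRecord(accession="AB000001", deposit_year=2005,
                         organism_name="Homo sapiens", sequence_length=4,
                         sequence="ACGT")
    buf = io.StringIO()
    write_genbank(RecordSet(records=[rec]), buf)
    text = buf.getvalue()
    assert "/country" not in text and "/lat_lon" not in text
    parsed = read_genbank(io.StringIO(text)).records[0]
    assert parsed.country_raw is None and parsed.lat_lon_raw is None


def test_unterminated_entry_raises_with_offset():
    text = "junk-free\n"  # leading content outside an entry
    with pytest.raises(RecordFormatError) as exc:
        read_genbank(io.StringIO(text))
    assert exc.value.byte_offset == 0


def test_missing_terminator_names_partial_accession(small_data):
    truncated = small_data.genbank_text.rsplit("//", 1)[0]
    with pytest.raises(RecordFormatError) as exc:
        read_genbank(io.StringIO(truncated))
    assert exc.value.partial_accession is not None
    assert exc.value.byte_offset is not None


def test_duplicate_accession_rejected():
    rec = SequenceRecord(accession="AB000001", deposit_year=2005,
                         organism_name="Homo sapiens", sequence_length=0,
                         sequence="")
    buf = io.StringIO()
    write_genbank(RecordSet(records=[rec]), buf)
    doubled = buf.getvalue() * 2
    with pytest.raises(DuplicateRecordError):
        read_genbank(io.StringIO(doubled))


def test_recordset_rejects_duplicate_accessions():
    rec = SequenceRecord(accession="AB000001", deposit_year=2005,
                         organism_name="x y", sequence_length=0, sequence="")
    with pytest.raises(DuplicateRecordError):
        RecordSet(records=[rec, rec])


# --- BOLD dumps ------------------------------------------------------------

BOLD_SAMPLE = [
    BoldRecord("BOLD001", "Gammarus fossarum", "COI-5P", "MG000001"),
    BoldRecord("BOLD002", "Homo sapiens", "COI-5P", None),
    BoldRecord("BOLD003", "Daphnia pulex", "COI-3P", "MG000002"),
]


def test_bold_tsv_row_parsed():
    text = ("record_id\ttaxon_name\tmarker\tgenbank_accession\n"
            "BOLD001\tGammarus fossarum\tCOI-5P\tMG000001\n")
    (rec,) = read_bold_dump(io.StringIO(text), "tsv")
    assert rec == BoldRecord("BOLD001", "Gammarus fossarum", "COI-5P",
                             "MG000001")


def test_bold_fasta_empty_accession_absent():
    (rec,) = read_bold_dump(io.StringIO(">BOLD002|Homo sapiens|COI-5P|\nACGT\n"),
                            "fasta")
    assert rec.genbank_accession is None


def test_bold_empty_after_header():
    text = "record_id\ttaxon_name\tmarker\tgenbank_accession\n"
    assert read_bold_dump(io.StringIO(text), "tsv") == []


def test_bold_missing_column_named():
    text = "record_id\ttaxon_name\tgenbank_accession\nBOLD001\tX y\tMG1\n"
    with pytest.raises(RecordFormatError, match="marker"):
        read_bold_dump(io.StringIO(text), "tsv")


def test_bold_duplicate_id_rejected():
    text = ("record_id\ttaxon_name\tmarker\tgenbank_accession\n"
            "BOLD001\tA b\tCOI-5P\t\nBOLD001\tC d\tCOI-5P\t\n")
    with pytest.raises(DuplicateRecordError):
        read_bold_dump(io.StringIO(text), "tsv")


def test_bold_tsv_and_fasta_serializations_agree():
    tsv_buf, fasta_buf = io.StringIO(), io.StringIO()
    write_bold_dump(BOLD_SAMPLE, tsv_buf, "tsv")
    write_bold_dump(BOLD_SAMPLE, fasta_buf, "fasta")
    from_tsv = read_bold_dump(io.StringIO(tsv_buf.getvalue()), "tsv")
    from_fasta = read_bold_dump(io.StringIO(fasta_buf.getvalue()), "fasta")
    assert from_tsv == from_fasta == BOLD_SAMPLE
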