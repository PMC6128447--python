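import io
import random
import re

import pytest
from hypothesis import given, settings, strategies as st

from coiaudit.names import (DisqualifierSet, GENBANK_DISQUALIFIERS,
                            IUCN_DISQUALIFIERS, NameValidationError,
                            SpeciesChecklist, classify_name, load_checklist,
                            load_disqualifiers, match_checklist,
                            species_coverage)
from coiaudit.records import RecordSet, SequenceRecord


def _rec(accession, organism):
    return SequenceRecord(accession=accession, deposit_year=2010,
                          organism_name=organism)


# --- independent brute-force oracle ---------------------------------------

_GENUS = re.compile(r"^[A-Z][a-z]+$")
_EPITHET = re.compile(r"^[a-z]+(-[a-z]+)*$")


def oracle_is_full(name: str, disq: DisqualifierSet) -> bool:
    """Enumerate every contiguous token run and compare with each disqualifier."""
    tokens = name.split()
    low = [t.lower() for t in tokens]
    for i in range(len(tokens)):
        for j in range(i + 1, len(tokens) + 1):
            if " ".join(low[i:j]) in {d.lower() for d in disq.tokens}:
                return False
    return (len(tokens) >= 2 and bool(_GENUS.match(tokens[0]))
            and bool(_EPITHET.match(tokens[1])))


# --- classify_name ---------------------------------------------------------

def test_canonical_binomial():
    c = classify_name("Homo sapiens", GENBANK_DISQUALIFIERS)
    assert c.is_full and c.genus == "Homo" and c.epithet == "sapiens"
    assert c.matched_disqualifier is None


def test_sp_disqualifier():
    c = classify_name("Gammarus sp.", GENBANK_DISQUALIFIERS)
    assert not c.is_full and c.matched_disqualifier == "sp."


def test_cf_disqualifier():
    c = classify_name("Daphnia cf. pulex", GENBANK_DISQUALIFIERS)
    assert not c.is_full and c.matched_disqualifier == "cf."


def test_single_token_insufficient():
    assert not classify_name("Bison", GENBANK_DISQUALIFIERS).is_full


def test_trinomial_is_full():
    c = classify_name("Canis lupus familiaris", GENBANK_DISQUALIFIERS)
    assert c.is_full and c.epithet == "lupus"


def test_disqualifier_needs_trailing_period():
    # "sp." must not match inside "spectabilis"
    assert classify_name("Gammarus spectabilis", GENBANK_DISQUALIFIERS).is_full


def test_multiword_disqualifier_matches_as_run():
    c = classify_name("Panthera sp. nov.", IUCN_DISQUALIFIERS)
    assert not c.is_full
    c2 = classify_name("Panthera affinis", IUCN_DISQUALIFIERS)
    assert not c2.is_full and c2.matched_disqualifier == "affinis"


def test_case_insensitive_token_match():
    assert not classify_name("Gammarus SP.", GENBANK_DISQUALIFIERS).is_full


def test_empty_name_rejected():
    with pytest.raises(NameValidationError):
        classify_name("   ", GENBANK_DISQUALIFIERS)


name_tokens = st.sampled_from([
    "Homo", "sapiens", "sp.", "cf.", "nr.", "aff.", "nov.", "Gammarus",
    "pulex", "x", "SP.", "affinis", "spectabilis", "Bison", "lupus-minor",
    "(Linnaeus,", "1758)",
])


@settings(max_examples=300, deadline=None)
@given(tokens=st.lists(name_tokens, min_size=1, max_size=5))
def test_classifier_agrees_with_brute_force_oracle(tokens):
    name = " ".join(tokens)
    assert classify_name(name, GENBANK_DISQUALIFIERS).is_full == \
        oracle_is_full(name, GENBANK_DISQUALIFIERS)


@settings(max_examples=100, deadline=None)
@given(tokens=st.lists(name_tokens, min_size=1, max_size=4),
       extra=st.sampled_from(["nov.", "pulex", "affinis"]))
def test_adding_disqualifier_is_monotone(tokens, extra):
    name = " ".join(tokens)
    base = classify_name(name, GENBANK_DISQUALIFIERS)
    widened = DisqualifierSet(GENBANK_DISQUALIFIERS.tokens + (extra,), "wide")
    after = classify_name(name, widened)
    if not base.is_full:
        assert not after.is_full


# --- checklist matching -----------------------------------------------------

CHECKLIST = SpeciesChecklist(
    canonical_names={"Panthera uncia", "Gammarus fossarum", "Daphnia pulex"},
    synonyms={"Uncia uncia": "Panthera uncia"},
)


def test_canonical_name_retained():
    rs = RecordSet(records=[_rec("A1", "Panthera uncia")])
    assert len(match_checklist(rs, CHECKLIST)) == 1


def test_synonym_resolved_to_canonical():
    rs = RecordSet(records=[_rec("A1", "Uncia uncia")])
    matched = match_checklist(rs, CHECKLIST)
    assert len(matched) == 1
    assert CHECKLIST.resolve("Uncia uncia") == "Panthera uncia"
    cov = species_coverage(rs, CHECKLIST)
    assert cov.n_matched == 1  # tallied under the canonical name


def test_disjoint_checklist_empty_result():
    rs = RecordSet(records=[_rec("A1", "Homo sapiens")])
    assert len(match_checklist(rs, CHECKLIST)) == 0


def test_match_is_subset_and_idempotent(small_recordset, small_data):
    checklist = load_checklist(io.StringIO(small_data.checklist_text))
    matched = match_checklist(small_recordset, checklist)
    assert set(matched.accessions()) <= small_recordset.accessions()
    again = match_checklist(matched, checklist)
    assert again.records == matched.records


def test_coverage_empty_records():
    cov = species_coverage(RecordSet(), CHECKLIST)
    assert cov.n_matched == 0 and cov.pct_matched == 0


def test_coverage_printed_counts():
    # the coverage percent rule applied to the printed checklist numbers
    from coiaudit import percent
    assert percent(1190, 4289) == 28


def test_coverage_synthetic_fraction():
    rng = random.Random(0)
    names = [f"Genus{chr(97 + i)} epithet" for i in range(50)]
    checklist = SpeciesChecklist(canonical_names=set(names))
    sampled = rng.sample(names, 10)
    rs = RecordSet(records=[_rec(f"A{i}", n) for i, n in enumerate(sampled)])
    cov = species_coverage(rs, checklist)
    assert cov.n_matched == 10 and cov.pct_matched == 20


def test_synonym_targets_must_be_canonical():
    with pytest.raises(ValueError):
        SpeciesChecklist(canonical_names={"A b"}, synonyms={"C d": "E f"})


def test_load_disqualifier_presets():
    assert load_disqualifiers("genbank").tokens == ("sp.", "nr.", "aff.", "cf.")
    assert load_disqualifiers("iucn").tokens == ("affinis", "sp.", "sp. nov.")
    with pytest.raises(ValueError):
        load_disqualifiers("bogus")
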