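"""Organism-name grammar: fully vs insufficiently identified, plus checklist matching.

A name is *fully identified* when it forms a Latin binomial (capitalized
genus, lowercase epithet) and contains none of the disqualifier tokens
(``sp.``, ``cf.``, ...).  Everything else is *insufficiently identified*.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Set, TextIO, Tuple

from ._round import percent
from .records import RecordSet

FULLY_IDENTIFIED = "fully_identified"
INSUFFICIENTLY_IDENTIFIED = "insufficiently_identified"

_GENUS_RE = re.compile(r"^[A-Z][a-z]+$")
_EPITHET_RE = re.compile(r"^[a-z]+(?:-[a-z]+)*$")


class NameValidationError(ValueError):
    pass


@dataclass(frozen=True)
class DisqualifierSet:
    """A labelled set of tokens that mark a name as insufficiently identified."""

    tokens: Tuple[str, ...]
    label: str = "custom"

    def __post_init__(self):
        if not self.tokens:
            raise ValueError("disqualifier set must be non-empty")


#: Screen applied to names retrieved from the nucleotide database.
GENBANK_DISQUALIFIERS = DisqualifierSet(("sp.", "nr.", "aff.", "cf."), "genbank")
#: Screen applied to endangered-species checklist entries.
IUCN_DISQUALIFIERS = DisqualifierSet(("affinis", "sp.", "sp. nov."), "iucn")

PRESETS = {"genbank": GENBANK_DISQUALIFIERS, "iucn": IUCN_DISQUALIFIERS}


@dataclass(frozen=True)
class NameClassification:
    verdict: str
    matched_disqualifier: Optional[str] = None
    genus: Optional[str] = None
    epithet: Optional[str] = None

    @property
    def is_full(self) -> bool:
        return self.verdict == FULLY_IDENTIFIED


def _find_disqualifier(tokens, disq: DisqualifierSet) -> Optional[str]:
    lowered = [t.lower() for t in tokens]
    for start in range(len(tokens)):
        for dtok in disq.tokens:
            words = dtok.lower().split()
            if lowered[start:start + len(words)] == words:
                return dtok
    return None


def classify_name(name: str, disq: DisqualifierSet = GENBANK_DISQUALIFIERS) -> NameClassification:
    """Classify one organism name against a disqualifier set.

    Disqualifier tokens are matched case-insensitively as contiguous runs of
    whitespace-delimited tokens, so ``"sp. nov."`` matches as a pair and
    ``"sp."`` never matches inside ``"spectabilis"``.  Trinomials without a
    disqualifier count as fully identified (epithet = second token).
    """
    tokens = name.split()
    if not tokens:
        raise NameValidationError("empty organism name")

    hit = _find_disqualifier(tokens, disq)
    if hit is not None:
        return NameClassification(INSUFFICIENTLY_IDENTIFIED, matched_disqualifier=hit)

    if len(tokens) >= 2 and _GENUS_RE.match(tokens[0]) and _EPITHET_RE.match(tokens[1]):
        return NameClassification(FULLY_IDENTIFIED, genus=tokens[0], epithet=tokens[1])
    return NameClassification(INSUFFICIENTLY_IDENTIFIED)


def _norm(name: str) -> str:
    return " ".join(name.split()).lower()


@dataclass
class SpeciesChecklist:
    """Canonical species names plus a synonym → canonical mapping."""

    canonical_names: Set[str] = field(default_factory=set)
    synonyms: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        missing = set(self.synonyms.values()) - set(self.canonical_names)
        if missing:
            raise ValueError(
                f"synonyms point at unknown canonical names: {sorted(missing)[:5]}"
            )
        self._lookup = {_norm(n): n for n in self.canonical_names}
        self._lookup.update(
            {_norm(syn): canon for syn, canon in self.synonyms.items()}
        )

    def __len__(self) -> int:
        return len(self.canonical_names)

    def resolve(self, name: str) -> Optional[str]:
        """Canonical name for ``name`` (itself, or via synonym), else None."""
        return self._lookup.get(_norm(name))


def load_checklist(stream: TextIO) -> SpeciesChecklist:
    """Read the two-column TSV checklist format (name, optional canonical).

    Rows with a blank second column declare canonical names; rows with a
    second column declare synonyms of that canonical name.
    """
    canonical: Set[str] = set()
    synonyms: Dict[str, str] = {}
    for line in stream:
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        name = parts[0].strip()
        target = parts[1].strip() if len(parts) > 1 else ""
        if target:
            synonyms[name] = target
        else:
            canonical.add(name)
    return SpeciesChecklist(canonical_names=canonical, synonyms=synonyms)


def match_checklist(records: RecordSet, checklist: SpeciesChecklist) -> RecordSet:
    """Records whose organism name hits the checklist (canonical or synonym)."""
    if not checklist.canonical_names:
        raise ValueError("checklist must be non-empty")
    hits = [r for r in records if checklist.resolve(r.organism_name) is not None]
    return RecordSet(records=hits, source_label=records.source_label)


@dataclass(frozen=True)
class CoverageResult:
    n_matched: int
    n_checklist: int
    pct_matched: int


def species_coverage(records: RecordSet, checklist: SpeciesChecklist) -> CoverageResult:
    """How many checklist species have at least one record (synonyms resolved)."""
    if not checklist.canonical_names:
        raise ValueError("checklist must be non-empty")
    matched = {
        canon for r in records
        if (canon := checklist.resolve(r.organism_name)) is not None
    }
    return CoverageResult(
        n_matched=len(matched),
        n_checklist=len(checklist),
        pct_matched=percent(len(matched), len(checklist)),
    )


def load_disqualifiers(spec: str) -> DisqualifierSet:
    """Resolve a preset name or ``custom:<path>`` (one token per line)."""
    if spec in PRESETS:
        return PRESETS[spec]
    if spec.startswith("custom:"):
        path = spec.split(":", 1)[1]
        with open(path, encoding="utf-8") as fh:
            tokens = tuple(line.strip() for line in fh if line.strip())
        return DisqualifierSet(tokens, label="custom")
    raise ValueError(f"unknown disqualifier preset {spec!r}")
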