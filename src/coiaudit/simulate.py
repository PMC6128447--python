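"""Synthetic record generator with fully known ground truth.

Emits a GenBank flatfile, a BOLD dump, and a species checklist whose every
randomized property is recorded exactly, so each pipeline stage can be
checked against generator bookkeeping without any download.
"""

from __future__ import annotations

import io
import json
import math
import random
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Set, Tuple

import yaml

from .names import GENBANK_DISQUALIFIERS
from .records import (BoldRecord, RecordSet, SequenceRecord, write_bold_dump,
                      write_genbank)

#: Bundled country list, most-sampled first (skewed draw emulates the
#: Canada-heavy distribution of real barcode depositions).
DEFAULT_COUNTRIES = (
    "Canada", "United States", "Costa Rica", "Australia", "China", "Germany",
    "Brazil", "India", "Mexico", "South Africa", "France", "Norway", "Japan",
    "Argentina", "Spain", "Finland", "Peru", "Kenya", "New Zealand", "Italy",
    "Sweden", "Indonesia", "Chile", "Portugal", "Vietnam", "Ecuador",
    "Madagascar", "Panama", "Thailand", "Colombia",
)

_GENUS_SYLLABLES = ("bra", "chi", "del", "fen", "gor", "hal", "lim", "mor",
                    "nec", "pol", "ran", "sti", "tur", "vel", "zan")
_EPITHET_SYLLABLES = ("ba", "cu", "den", "fo", "gi", "lan", "mi", "no", "pe",
                      "ru", "sa", "ti", "vo", "xe")

_BACKGROUND_LINEAGE = ("Eukaryota", "Metazoa", "Chordata", "Mammalia")

BARCODE_LINKED = "barcode_linked"
ACCESSION_LINKED = "accession_linked"
BOLD_ONLY = "bold_only"


class ConfigError(ValueError):
    pass


@dataclass
class SyntheticConfig:
    """Knobs controlling the generated record sets."""

    seed: int = 1
    year_start: int = 2003
    year_end: int = 2007
    base_deposits: int = 100
    annual_growth: float = 0.5
    p_full: float = 0.55
    p_barcode: float = 0.28
    p_country: float = 0.74
    p_latlon: float = 0.51
    length_fixed: Optional[int] = None      # fixed length when set
    length_min: int = 400
    length_max: int = 700
    n_species_pool: int = 200
    group_mix: Dict[str, float] = field(default_factory=lambda: {
        "Diptera": 0.20, "Coleoptera": 0.10, "Gastropoda": 0.08,
    })
    bold_mix: Dict[str, float] = field(default_factory=lambda: {
        BARCODE_LINKED: 0.15, ACCESSION_LINKED: 0.48, BOLD_ONLY: 0.37,
    })
    n_bold_records: int = 300
    n_checklist_species: int = 50
    n_checklist_synonyms: int = 10
    country_skew: float = 1.5

    def validate(self) -> None:
        for name in ("p_full", "p_barcode", "p_country", "p_latlon"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if self.annual_growth <= -1.0:
            raise ConfigError("annual_growth must be > -1")
        if self.year_end < self.year_start:
            raise ConfigError("empty year range")
        if any(f < 0 for f in self.group_mix.values()) or sum(self.group_mix.values()) > 1.0 + 1e-9:
            raise ConfigError("group_mix fractions must be >= 0 and sum to <= 1")
        if any(f < 0 for f in self.bold_mix.values()) or sum(self.bold_mix.values()) > 1.0 + 1e-9:
            raise ConfigError("bold_mix fractions must be >= 0 and sum to <= 1")
        if self.length_fixed is None and self.length_min > self.length_max:
            raise ConfigError("length_min exceeds length_max")

    @classmethod
    def from_yaml(cls, stream) -> "SyntheticConfig":
        data = yaml.safe_load(stream) or {}
        cfg = cls(**data)
        cfg.validate()
        return cfg


@dataclass
class GroundTruth:
    """Exact bookkeeping for everything the generator randomized."""

    deposited_by_year: Dict[int, int] = field(default_factory=dict)
    unique_species_by_year: Dict[int, int] = field(default_factory=dict)
    n_records: int = 0
    n_full: int = 0
    n_barcode: int = 0
    n_full_len_ge_500: int = 0
    n_full_country: int = 0
    n_full_latlon: int = 0
    group_counts: Dict[str, int] = field(default_factory=dict)
    n_in_groups: int = 0
    country_counts: Dict[str, int] = field(default_factory=dict)
    n_full_no_country: int = 0
    barcode_accessions: List[str] = field(default_factory=list)
    bold_counts: Dict[str, int] = field(default_factory=dict)
    n_checklist_species: int = 0
    n_checklist_matched: int = 0
    record_labels: List[dict] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


@dataclass
class SyntheticData:
    genbank_text: str
    bold_text: str
    checklist_text: str
    ground_truth: GroundTruth
    records: RecordSet
    bold_records: List[BoldRecord]


def expected_deposits(config: SyntheticConfig) -> Dict[int, int]:
    """Deterministic per-year deposit counts: round(base * (1+g)^k), half-up."""
    return {
        y: int(math.floor(
            config.base_deposits
            * (1.0 + config.annual_growth) ** (y - config.year_start) + 0.5))
        for y in range(config.year_start, config.year_end + 1)
    }


def _species_pool(rng: random.Random, n: int) -> List[str]:
    pool: Set[str] = set()
    while len(pool) < n:
        genus = "".join(rng.choices(_GENUS_SYLLABLES, k=3)).capitalize()
        epithet = "".join(rng.choices(_EPITHET_SYLLABLES, k=3))
        pool.add(f"{genus} {epithet}")
    return sorted(pool)


def _draw_country(rng: random.Random, weights: List[float]) -> str:
    return rng.choices(DEFAULT_COUNTRIES, weights=weights, k=1)[0]


def _draw_lat_lon(rng: random.Random) -> str:
    lat = round(rng.uniform(-90, 90), 2)
    lon = round(rng.uniform(-180, 180), 2)
    ns = "N" if lat >= 0 else "S"
    ew = "E" if lon >= 0 else "W"
    return f"{abs(lat):.2f} {ns} {abs(lon):.2f} {ew}"


def generate(config: SyntheticConfig) -> SyntheticData:
    """Generate all three artifacts plus exact ground truth (seed-deterministic)."""
    config.validate()
    rng = random.Random(config.seed)
    truth = GroundTruth()
    pool = _species_pool(rng, config.n_species_pool)
    country_weights = [1.0 / (i + 1) ** config.country_skew
                       for i in range(len(DEFAULT_COUNTRIES))]
    group_items = list(config.group_mix.items())

    records: List[SequenceRecord] = []
    species_by_year: Dict[int, Set[str]] = {}
    serial = 0
    for year, n_year in expected_deposits(config).items():
        truth.deposited_by_year[year] = n_year
        species_by_year[year] = set()
        for _ in range(n_year):
            serial += 1
            accession = f"SYN{serial:07d}"
            species = rng.choice(pool)
            is_full = rng.random() < config.p_full
            if is_full:
                organism = species
                species_by_year[year].add(species)
            else:
                genus = species.split()[0]
                token = rng.choice(GENBANK_DISQUALIFIERS.tokens)
                # disqualifier goes right after the genus, optionally
                # followed by the epithet ("Daphnia cf. pulex" style)
                if rng.random() < 0.5:
                    organism = f"{genus} {token}"
                else:
                    organism = f"{genus} {token} {species.split()[1]}"

            is_barcode = rng.random() < config.p_barcode
            if config.length_fixed is not None:
                length = config.length_fixed
            else:
                length = rng.randint(config.length_min, config.length_max)
            if is_barcode:
                # BARCODE-flagged records are complete by construction
                length = max(length, 500)
                has_country, has_latlon = True, True
            else:
                has_country = rng.random() < config.p_country
                has_latlon = rng.random() < config.p_latlon

            u = rng.random()
            acc_frac = 0.0
            group = None
            for name, frac in group_items:
                acc_frac += frac
                if u < acc_frac:
                    group = name
                    break
            if group is None:
                lineage = _BACKGROUND_LINEAGE
            else:
                lineage = ("Eukaryota", "Metazoa", "Arthropoda", group)

            country = _draw_country(rng, country_weights) if has_country else None
            lat_lon = _draw_lat_lon(rng) if has_latlon else None
            gene = rng.choice(("COI", "CO1", "COX1", "COXI"))
            sequence = "".join(rng.choices("ACGT", k=length))

            records.append(SequenceRecord(
                accession=accession,
                deposit_year=year,
                organism_name=organism,
                lineage=lineage,
                keywords=frozenset({"BARCODE"}) if is_barcode else frozenset(),
                gene_labels=frozenset({gene}),
                sequence_length=length,
                country_raw=f"{country}: region {rng.randint(1, 9)}"
                            if country else None,
                lat_lon_raw=lat_lon,
                sequence=sequence,
            ))

            truth.n_records += 1
            if is_full:
                truth.n_full += 1
                if length >= 500:
                    truth.n_full_len_ge_500 += 1
                if has_country:
                    truth.n_full_country += 1
                    truth.country_counts[country] = (
                        truth.country_counts.get(country, 0) + 1)
                else:
                    truth.n_full_no_country += 1
                if has_latlon:
                    truth.n_full_latlon += 1
            if is_barcode:
                truth.n_barcode += 1
                truth.barcode_accessions.append(accession)
            if group is not None:
                truth.group_counts[group] = truth.group_counts.get(group, 0) + 1
                truth.n_in_groups += 1
            truth.record_labels.append({
                "accession": accession, "year": year, "species": species,
                "organism": organism, "full": is_full, "barcode": is_barcode,
                "country": country, "has_latlon": has_latlon,
                "length": length, "group": group,
            })

    truth.unique_species_by_year = {
        y: len(s) for y, s in species_by_year.items()
    }

    record_set = RecordSet(records=records, source_label="synthetic")

    # --- BOLD dump -------------------------------------------------------
    barcode_pool = list(truth.barcode_accessions)
    bold_records: List[BoldRecord] = []
    truth.bold_counts = {BARCODE_LINKED: 0, ACCESSION_LINKED: 0, BOLD_ONLY: 0}
    mix = config.bold_mix
    for i in range(config.n_bold_records):
        u = rng.random()
        if u < mix.get(BARCODE_LINKED, 0.0) and barcode_pool:
            category = BARCODE_LINKED
            accession = rng.choice(barcode_pool)
        elif u < mix.get(BARCODE_LINKED, 0.0) + mix.get(ACCESSION_LINKED, 0.0):
            category = ACCESSION_LINKED
            accession = f"EXT{i:07d}"
        else:
            category = BOLD_ONLY
            accession = None
        bold_records.append(BoldRecord(
            record_id=f"SYNBOLD{i:05d}",
            taxon_name=rng.choice(pool),
            marker=rng.choice(("COI-5P", "COI-3P")),
            genbank_accession=accession,
        ))
        truth.bold_counts[category] += 1

    # --- checklist -------------------------------------------------------
    n_canon = min(config.n_checklist_species, len(pool))
    canonicals = rng.sample(pool, n_canon)
    synonym_lines = []
    for j in range(config.n_checklist_synonyms):
        if not canonicals:
            break
        target = canonicals[j % len(canonicals)]
        genus = "".join(rng.choices(_GENUS_SYLLABLES, k=3)).capitalize()
        synonym_lines.append((f"{genus} {target.split()[1]}", target))
    truth.n_checklist_species = len(canonicals)
    used_names = {lab["organism"] for lab in truth.record_labels}
    truth.n_checklist_matched = sum(1 for c in canonicals if c in used_names)

    checklist_buf = io.StringIO()
    for name in canonicals:
        checklist_buf.write(f"{name}\t\n")
    for syn, target in synonym_lines:
        checklist_buf.write(f"{syn}\t{target}\n")

    gb_buf = io.StringIO()
    write_genbank(record_set, gb_buf)
    bold_buf = io.StringIO()
    write_bold_dump(bold_records, bold_buf, dialect="tsv")

    return SyntheticData(
        genbank_text=gb_buf.getvalue(),
        bold_text=bold_buf.getvalue(),
        checklist_text=checklist_buf.getvalue(),
        ground_truth=truth,
        records=record_set,
        bold_records=bold_records,
    )


def write_outputs(config: SyntheticConfig, outdir: str) -> Dict[str, str]:
    """Generate and write all artifacts into ``outdir``; returns the paths."""
    data = generate(config)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genbank": out / "records.gb",
        "bold": out / "bold.tsv",
        "checklist": out / "checklist.tsv",
        "ground_truth": out / "ground_truth.json",
    }
    paths["genbank"].write_text(data.genbank_text, encoding="utf-8")
    paths["bold"].write_text(data.bold_text, encoding="utf-8")
    paths["checklist"].write_text(data.checklist_text, encoding="utf-8")
    paths["ground_truth"].write_text(data.ground_truth.to_json() + "\n",
                                     encoding="utf-8")
    return {k: str(v) for k, v in paths.items()}
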