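"""Geographic summaries: qualifier parsing, per-country tallies, top-5% split."""

from __future__ import annotations

import csv
import logging
import math
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Optional, TextIO, Tuple

from .names import DisqualifierSet, GENBANK_DISQUALIFIERS, classify_name
from .records import RecordSet

logger = logging.getLogger(__name__)

_LAT_LON_RE = re.compile(
    r"^\s*(\d+(?:\.\d+)?)\s*([NS])\s+(\d+(?:\.\d+)?)\s*([EW])\s*$"
)


class LatLonParseError(ValueError):
    def __init__(self, raw: str, reason: str = "malformed lat_lon"):
        self.raw = raw
        super().__init__(f"{reason}: {raw!r}")


@dataclass(frozen=True)
class GeoPoint:
    latitude: float
    longitude: float

    def __post_init__(self):
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude {self.latitude} out of range")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"longitude {self.longitude} out of range")


def parse_lat_lon(raw: str) -> GeoPoint:
    """Parse the ``<deg> N|S <deg> E|W`` qualifier dialect; S/W are negative."""
    m = _LAT_LON_RE.match(raw)
    if not m:
        raise LatLonParseError(raw)
    lat = float(m.group(1)) * (1 if m.group(2) == "N" else -1)
    lon = float(m.group(3)) * (1 if m.group(4) == "E" else -1)
    try:
        return GeoPoint(lat, lon)
    except ValueError as exc:
        raise LatLonParseError(raw, str(exc)) from exc


def format_lat_lon(point: GeoPoint) -> str:
    """Inverse of :func:`parse_lat_lon` for valid points."""
    ns = "N" if point.latitude >= 0 else "S"
    ew = "E" if point.longitude >= 0 else "W"
    return f"{abs(point.latitude):g} {ns} {abs(point.longitude):g} {ew}"


def parse_country(raw: str, aliases: Optional[Dict[str, str]] = None) -> str:
    """Country name before the first colon, trimmed, then alias-resolved."""
    name = raw.split(":", 1)[0].strip()
    if aliases:
        name = aliases.get(name, name)
    return name


def load_aliases(stream: TextIO) -> Dict[str, str]:
    """Two-column TSV alias table (variant<TAB>canonical)."""
    aliases = {}
    for line in stream:
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        variant, _, canonical = line.partition("\t")
        if canonical.strip():
            aliases[variant.strip()] = canonical.strip()
    return aliases


@dataclass
class GeoSummary:
    country_counts: Dict[str, int] = field(default_factory=dict)
    n_no_country: int = 0
    points: List[Tuple[str, GeoPoint]] = field(default_factory=list)
    top_countries: List[str] = field(default_factory=list)
    bottom_countries: List[str] = field(default_factory=list)
    n_latlon_malformed: int = 0


def _split_top(country_counts: Dict[str, int],
               top_fraction: float) -> Tuple[List[str], List[str]]:
    # ties broken by descending count then lexicographic name
    ordered = sorted(country_counts, key=lambda c: (-country_counts[c], c))
    n_top = math.ceil(top_fraction * len(ordered)) if ordered else 0
    return ordered[:n_top], ordered[n_top:]


def summarize_geo(records: RecordSet,
                  disq: DisqualifierSet = GENBANK_DISQUALIFIERS,
                  aliases: Optional[Dict[str, str]] = None,
                  top_fraction: float = 0.05) -> GeoSummary:
    """Per-country tallies and coordinate points over fully identified records.

    Malformed lat_lon strings demote the record to "no lat_lon" (logged),
    never abort the run.
    """
    counts: Counter = Counter()
    n_no_country = 0
    points: List[Tuple[str, GeoPoint]] = []
    n_malformed = 0
    for rec in records:
        if not classify_name(rec.organism_name, disq).is_full:
            continue
        if rec.country_raw is None:
            n_no_country += 1
        else:
            counts[parse_country(rec.country_raw, aliases)] += 1
        if rec.lat_lon_raw is not None:
            try:
                points.append((rec.accession, parse_lat_lon(rec.lat_lon_raw)))
            except LatLonParseError:
                n_malformed += 1
                logger.warning("record %s: unparseable lat_lon %r",
                               rec.accession, rec.lat_lon_raw)
    top, bottom = _split_top(dict(counts), top_fraction)
    return GeoSummary(
        country_counts=dict(counts),
        n_no_country=n_no_country,
        points=points,
        top_countries=top,
        bottom_countries=bottom,
        n_latlon_malformed=n_malformed,
    )


def country_counts_to_tsv(summary: GeoSummary, stream: TextIO) -> None:
    writer = csv.writer(stream, delimiter="\t", lineterminator="\n")
    writer.writerow(["country", "count"])
    for country in sorted(summary.country_counts,
                          key=lambda c: (-summary.country_counts[c], c)):
        writer.writerow([country, summary.country_counts[country]])
    writer.writerow(["(no country)", summary.n_no_country])


def points_to_csv(summary: GeoSummary, stream: TextIO) -> None:
    writer = csv.writer(stream, lineterminator="\n")
    writer.writerow(["latitude", "longitude", "accession"])
    for accession, point in summary.points:
        writer.writerow([point.latitude, point.longitude, accession])


def split_to_tsv(summary: GeoSummary, stream: TextIO) -> None:
    writer = csv.writer(stream, delimiter="\t", lineterminator="\n")
    writer.writerow(["tier", "country", "count"])
    for country in summary.top_countries:
        writer.writerow(["top", country, summary.country_counts[country]])
    for country in summary.bottom_countries:
        writer.writerow(["bottom", country, summary.country_counts[country]])
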