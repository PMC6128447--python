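"""Per-year deposition series and geometric-average annual growth."""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from typing import Dict, Sequence, TextIO, Tuple

from ._round import round_half_up
from .names import DisqualifierSet, GENBANK_DISQUALIFIERS, classify_name
from .records import RecordSet

logger = logging.getLogger(__name__)

CUMULATIVE = "cumulative"
DEPOSITED = "deposited"


class UndefinedGrowthError(ValueError):
    """Geometric growth is undefined when any basis count is zero."""

    def __init__(self, year: int, basis: str):
        self.year = year
        self.basis = basis
        super().__init__(
            f"{basis} count for year {year} is zero; geometric growth undefined"
        )


@dataclass
class YearlySeries:
    """Per-year deposited/unique-species counts over a contiguous year span."""

    year_start: int
    year_end: int
    deposited: Dict[int, int] = field(default_factory=dict)
    unique_species: Dict[int, int] = field(default_factory=dict)
    cumulative: Dict[int, int] = field(default_factory=dict)

    def __post_init__(self):
        if self.year_end < self.year_start:
            raise ValueError("empty year range")
        years = self.years
        for mapping in (self.deposited, self.unique_species):
            for y in years:
                mapping.setdefault(y, 0)
        running = 0
        if not self.cumulative:
            for y in years:
                running += self.deposited[y]
                self.cumulative[y] = running
        else:
            running = 0
            for y in years:
                running += self.deposited[y]
                if self.cumulative.get(y) != running:
                    raise ValueError(
                        f"cumulative[{y}] is not the running sum of deposited"
                    )

    @property
    def years(self) -> range:
        return range(self.year_start, self.year_end + 1)

    def counts(self, basis: str) -> Sequence[int]:
        if basis == CUMULATIVE:
            return [self.cumulative[y] for y in self.years]
        if basis == DEPOSITED:
            return [self.deposited[y] for y in self.years]
        raise ValueError(f"unknown basis {basis!r}")


@dataclass(frozen=True)
class GrowthSummary:
    rate: float  # growth fraction at full precision
    n_intervals: int
    basis: str

    @property
    def rate_percent(self) -> float:
        """Percent at one-decimal precision, rounded half-up."""
        return round_half_up(self.rate * 100.0, 1)

    @property
    def headline_percent(self) -> int:
        """Integer percent for display, rounded half-up from full precision."""
        return int(round_half_up(self.rate * 100.0))


def build_series(records: RecordSet,
                 disq: DisqualifierSet = GENBANK_DISQUALIFIERS,
                 year_range: Tuple[int, int] = (2003, 2017)) -> YearlySeries:
    """Tally deposits and unique fully-identified species per year.

    Records outside ``year_range`` are dropped (their count is logged).
    """
    y0, y1 = year_range
    deposited = {y: 0 for y in range(y0, y1 + 1)}
    species = {y: set() for y in range(y0, y1 + 1)}
    dropped = 0
    for rec in records:
        if not (y0 <= rec.deposit_year <= y1):
            dropped += 1
            continue
        deposited[rec.deposit_year] += 1
        if classify_name(rec.organism_name, disq).is_full:
            species[rec.deposit_year].add(rec.organism_name)
    if dropped:
        logger.info("dropped %d records outside %d-%d", dropped, y0, y1)
    return YearlySeries(
        year_start=y0,
        year_end=y1,
        deposited=deposited,
        unique_species={y: len(s) for y, s in species.items()},
    )


def geometric_rate(counts: Sequence[int], years: Sequence[int] = None) -> float:
    """Geometric average of year-over-year growth ratios, as a fraction.

    Computed as the n-th root of the product of consecutive ratios, which
    telescopes to ``(last/first)**(1/n) - 1``.  Any non-positive count makes
    the mean undefined and raises :class:`UndefinedGrowthError`.
    """
    if len(counts) < 2:
        raise ValueError("need at least two counts")
    if years is None:
        years = list(range(len(counts)))
    for y, c in zip(years, counts):
        if c <= 0:
            raise UndefinedGrowthError(y, "series")
    product = 1.0
    for prev, curr in zip(counts, counts[1:]):
        product *= curr / prev
    return product ** (1.0 / (len(counts) - 1)) - 1.0


def geometric_growth(series: YearlySeries, basis: str = CUMULATIVE) -> GrowthSummary:
    """Geometric-average annual growth of a series on the chosen basis."""
    years = list(series.years)
    counts = series.counts(basis)
    for y, c in zip(years, counts):
        if c <= 0:
            raise UndefinedGrowthError(y, basis)
    return GrowthSummary(
        rate=geometric_rate(counts, years),
        n_intervals=len(years) - 1,
        basis=basis,
    )


def series_to_tsv(series: YearlySeries, stream: TextIO,
                  summary: GrowthSummary = None) -> None:
    writer = csv.writer(stream, delimiter="\t", lineterminator="\n")
    writer.writerow(["year", "deposited", "unique_species", "cumulative"])
    for y in series.years:
        writer.writerow([y, series.deposited[y], series.unique_species[y],
                         series.cumulative[y]])
    if summary is not None:
        stream.write(f"# geometric_growth_basis\t{summary.basis}\n")
        stream.write(f"# geometric_growth_percent\t{summary.rate_percent}\n")
        stream.write(f"# n_intervals\t{summary.n_intervals}\n")
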