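# coiaudit

An offline audit toolkit for COI (cytochrome c oxidase subunit 1) DNA-barcode
reference records. Given GenBank flatfiles, BOLD-style dumps, and species
checklists, it computes:

- **Name classification** — fully identified (complete Latin binomial) vs
  insufficiently identified names (`sp.`, `nr.`, `aff.`, `cf.` screens), with
  checklist matching and synonym resolution.
- **Partitions** — marker-gene subset, BARCODE-keyword subset, taxon-group
  subsets (a bundled freshwater-biomonitoring preset), checklist subset.
- **Annotation audit** — per-partition proportions of fully identified
  records, and (among those) good sequence length (≥ 500 bp), country, and
  latitude-longitude annotations.
- **Growth statistics** — per-year deposition and unique-species counts,
  cumulative series, and the geometric-average annual growth rate.
- **BOLD/GenBank cross-referencing** — three-way partition of BOLD records:
  linked to a BARCODE-flagged accession, linked to another accession, or
  unique to BOLD.
- **Geographic summaries** — per-country tallies, the top-5 % / bottom-95 %
  country split, and lat/lon point tables.
- **Query building** — the Entrez and BOLD API query strings for out-of-band
  retrieval (queries are built, never executed; the package does no network
  I/O at all).
- **Synthetic data** — a seeded generator that emits GenBank flatfiles, BOLD
  dumps, and checklists with exact ground-truth bookkeeping, so the whole
  pipeline is testable without downloads.

## Command-line usage

```sh
# generate a synthetic data set with known ground truth
coiaudit simulate --seed 5 --out sim/

# audit annotation completeness per partition
coiaudit audit --genbank sim/records.gb --groups freshwater \
    --checklist sim/checklist.tsv --out audit/

# deposition growth (cumulative basis by default)
coiaudit growth --genbank sim/records.gb --year-start 2003 --year-end 2007 \
    --out growth/

# reconcile a BOLD dump against a BARCODE accession list
coiaudit crossref --bold sim/bold.tsv \
    --barcode-accessions barcode_accessions.txt --out xref/

# per-country tallies and the top-5% split
coiaudit geo --genbank sim/records.gb --out geo/

# print retrieval query strings
coiaudit queries --year 2016 --keyword BARCODE
```

Every subcommand writes a `manifest.json` beside its outputs (inputs,
digests, seed, counts, tool version); identical inputs and seed reproduce
byte-identical outputs.

## Notes on conventions

- All printed percentages round half-up to integers; growth rates round
  half-up from full precision for headline display.
- Audit denominators for the length/country/lat-lon panels are the *fully
  identified* records of the partition.
- The geometric growth rate is undefined when any yearly count is zero; the
  toolkit raises an error naming the year rather than skipping silently.
- GenBank deposit year is taken from the LOCUS-line date (flatfiles carry no
  deposition date field).
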