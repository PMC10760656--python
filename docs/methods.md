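# Methods

## The audit model

`refgap` treats a reference-library audit as pure accounting over record
*metadata*: no sequences are read, aligned or validated. A species is
"represented" for a marker when at least one record of that marker exists
under a name resolvable to the checklist, regardless of sequence length —
mini-barcodes down to ~100 bp are usable in metabarcoding, so no length
filter is ever applied (length is retained as metadata only). The audit is
species-rank: trinomials collapse to binomials before matching, and names
carrying hybrid or open-nomenclature markers ("x", "sp.", "cf.", "aff.")
are rejected as unidentifiable rather than matched.

Two coverage views are always computed. *Registered* counts public and
private records alike; *public* counts only records visible to a library
user. Private records exist only in BOLD-style sources; GenBank-summary
records are public by construction, never carry a BIN, never carry
collection coordinates, and are flagged as GenBank-mined for the quality
audit.

### Name reconciliation

Canonicalization: trim, collapse whitespace, strip diacritics, capitalize
the genus, lowercase the epithet, drop the third word. Matching is
case-insensitive on the canonical form; a synonym table (two-column CSV,
alias → accepted, one level deep and acyclic by construction) credits
records uploaded under outdated names to the accepted checklist name. A
synonym pointing outside the checklist is a *dangling synonym*: warned,
treated as unmatched. No live taxonomic service is consulted; the synonym
table is an input, which keeps runs reproducible.

### Gap statistics

Percentages are rounded half-away-from-zero (1 decimal for coverage, 2 for
audit compositions), implemented with exact decimal arithmetic rather than
binary-float rounding so printed figures are stable. The four-marker Venn
partition assigns each species to exactly one of 16 regions by its set of
registered markers; records of non-target markers (OTHER) are carried
through ingestion but never count as coverage. Threatened means IUCN
CR/EN/VU.

### Geographic provenance

Point-in-polygon uses even–odd ray casting with planar coordinates.
Boundary points count as inside (checked explicitly before crossing
counting); the half-open vertex rule `(y0 > y) != (y1 > y)` is the
deterministic tie-break for vertices and horizontal edges lying on the
ray — equivalent to nudging on-ray vertices up by an epsilon. Planar
geometry is adequate at continental-polygon scale; polygons spanning more
than 180° of longitude (antimeridian crossers) are rejected outright
rather than misclassified. Unlocated records are excluded from provenance
denominators — they are reported as a separate count, not assumed to be
outside. An empty located set yields `None` percentages with an explicit
`undefined` flag.

### Quality grades

The grade table (A, B, C, D, E*, E**, F) is evaluated in stages: F first
(all specimens unvouchered or GenBank-mined — a procedure flag, so it
outranks the data-deficiency grade D even when fewer than 3 records
exist), then the <3-usable-barcodes test, then the BIN topology. Three
operational choices deserve note:

* *BIN sharing*: a BIN is non-exclusive when it contains any species
  besides the target, judged over the **whole** record universe including
  off-checklist species. The E*/E** grades read as "BIN shared with
  another species"; the alternative literal reading ("BIN contains ≥1
  species") would make grades A/B unreachable, since every BIN trivially
  contains one species.
* *Independent studies* (A vs B) are operationalized as ≥2 distinct
  dataset identifiers among usable records; records without a dataset id
  collapse into one pseudo-dataset.
* *Usable barcode*: vouchered, not GenBank-mined, BIN-assigned. Records
  without a BIN cannot support any branch of a BIN-based scheme and are
  excluded from the ≥3 count.

The audit denominator is the set of species with ≥1 BOLD COI record,
public or private, any grade including F. BINs are consumed as metadata;
the package never computes them from sequences.

### Deduplication

BOLD records mined from GenBank can reappear in a GenBank search under the
same accession. The CLI deduplicates by accession by default (keeping the
BOLD copy, which carries richer metadata); `--no-dedup` reports the raw
union instead, and the run log records how many duplicates were dropped.

## The synthetic-study generator

`SimSpec` requests an exact composition: per-marker registered/public
species counts, the number of species missing all four markers, endemic
and threatened counts with explicit overlap control among the missing
species, a per-grade audit profile, and per-region inside/outside/unlocated
record counts. Counts are realized by deterministic allocation — markers
are placed as contiguous blocks over the covered species so their union
covers exactly the non-missing set, grade-profile records are constructed
to classify to their grade by definition, and inside/outside points are
rejection-sampled against the generated polygons (each accepted point is
double-checked with a winding-number test) — followed by seeded shuffling
of identities and record order. Exact allocation rather than Bernoulli
sampling is deliberate: the audited quantities are census counts, so the
generator must hit them exactly for closed-loop tests to be meaningful.
One RNG stream per output component (names, geography, shuffling), all
spawned from the master seed, keeps components stable when one part of a
spec changes. Identical spec+seed gives byte-identical fixture files;
changing the seed permutes identities and ordering but never any summary
count. Inconsistent requests (public > registered, an audit profile larger
than the COI-registered set, markers that cannot cover the non-missing
species, ...) are rejected at construction with the violated constraint
named.

The default `SimSpec.paper_scale()` encodes the study-scale conditions the
package is tested against: 1506 checklist species, COI 1239 registered /
987 public, CYTB 897, 12S 247, 18S 9, 190 species with no marker at all,
73 endemics (32 missing), 14 threatened-and-missing species (7 endemic),
an audit profile of 1191 BOLD-COI species (A 200, B 138, C 100, E* 100,
E** 89, D 546, F 18 — i.e. A/B 338 and C∪E*∪E** 289), and 68 of 100
located records inside the single generated region. Where a composition
needed a value no census provides (the A/B split within 338, the split of
289 across C/E*/E**, the total threatened count of 60, four datasets),
round numbers consistent with the aggregate counts were fixed once; only
the aggregates are asserted anywhere.

What the generator does *not* emulate: sequence evolution, real
BIN-algorithm behavior, name-frequency realism, spatial clustering beyond
the inside/outside split, or correlated missingness across markers.
Passing closed-loop tests therefore demonstrates that the pipeline's
accounting is exact on data with known structure — not that real BOLD or
GenBank snapshots are clean, nor that a live audit would reproduce any
particular historical figure, which depends on the database state at query
time.

A bundled real-name block — the 14 threatened species with no records for
any screened marker, with families, IUCN categories and endemism marks —
is available via `table1_taxa()`; `table1_gap_fixture()` surrounds it with
10 distractors each failing exactly one criterion of the
threatened-and-missing filter (5 threatened-but-sequenced,
5 unsequenced-but-not-threatened), which makes the filter's correct output
exactly the 14.

## Numerical and degenerate-input choices

* Rounding: half-away-from-zero via `decimal`, never float rounding.
* Zero denominators raise (coverage) or yield flagged `None` (provenance).
* Coordinates: a half-present or out-of-range pair is dropped to absent
  with a warning — never silently clamped; the record itself is kept.
* Zero-area polygons and open rings are rejected at construction.
* Duplicate record ids within one source database are an error; the same
  id may appear in both sources (that is what deduplication is for).
* The JSON summary stores every percentage beside its numerator and
  denominator and is re-verified by `report.self_check` before writing.

## Problem sizes in the test suite

Study-scale closed-loop tests run the full 1506-species composition
(~4.5k records, well under a second); property suites use 100–1000 random
instances per invariant (Venn partitioning, geometry-oracle agreement,
rule-table equivalence on 1000 random audit profiles). These sizes were
chosen to exercise the allocation logic at realistic scale while keeping
the whole suite interactive.

## Known limitations

* Planar geometry; no geodesic edges, no antimeridian support.
* Synonymy is only as good as the supplied table; no fuzzy matching.
* The BOLD reader targets the documented export dialect, not every
  historical column layout BOLD has shipped.
* Live BOLD/GenBank querying is out of scope; the package consumes
  exported tables.
* The audit trusts BIN assignments and voucher fields as given; it cannot
  detect a mislabelled voucher or a wrong BIN.
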