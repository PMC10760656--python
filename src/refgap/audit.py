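"""BIN-based barcode quality audit.

Each species with BOLD COI records is graded by how its specimens cluster
into Barcode Index Numbers (BINs, algorithmic MOTUs used as a proxy for
species boundaries):

=====  ==============================================================
grade  meaning
=====  ==============================================================
A      >=3 usable barcodes, one BIN exclusive to the species,
       records from >=2 independent datasets
B      as A but all records from a single dataset
C      >=3 usable barcodes split over >=2 BINs, every BIN exclusive
       (consistent with geographic structure / candidate splits)
D      <3 usable barcodes (data deficient)
E*     one BIN, shared with another species (BIN incongruence)
E**    >=2 BINs, at least one shared (incongruence + splits)
F      every specimen unvouchered or mined from GenBank
       (inadequate barcoding procedure)
=====  ==============================================================

F is checked first: it flags procedure quality across all specimens of the
species, regardless of how many there are. A "usable" barcode is vouchered,
not mined from GenBank, and BIN-assigned. BIN exclusivity is judged against
the whole record universe (a BIN shared with an off-checklist species still
counts as shared).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from refgap.errors import ValidationError
from refgap.gap_analysis import coverage_percentage
from refgap.ingest import Marker, RecordTable, SequenceRecord, SourceDB

__all__ = [
    "Grade", "BinIndex", "AuditGrade", "AuditComposition", "build_bin_index",
    "classify_species", "audit_species", "audit_composition",
]


class Grade(str, Enum):
    A = "A"
    B = "B"
    C = "C"
    D = "D"
    E_STAR = "E*"
    E_DSTAR = "E**"
    F = "F"


class BinIndex:
    """BIN id -> set of species names observed in that BIN.

    Built over the whole record universe, not only checklist species, so
    BIN sharing with any organism is visible.
    """

    def __init__(self, mapping: dict[str, set[str]] | None = None):
        self._map: dict[str, set[str]] = {}
        for bin_id, species in (mapping or {}).items():
            if not species:
                raise ValidationError(f"BIN {bin_id!r} maps to no species")
            self._map[bin_id] = set(species)

    def species_in(self, bin_id: str) -> set[str]:
        return self._map.get(bin_id, set())

    def is_exclusive(self, bin_id: str, species: str) -> bool:
        """True when the BIN contains no species other than ``species``."""
        return self.species_in(bin_id) <= {species}

    def add(self, bin_id: str, species: str) -> None:
        self._map.setdefault(bin_id, set()).add(species)

    def __len__(self) -> int:
        return len(self._map)

    def __contains__(self, bin_id: str) -> bool:
        return bin_id in self._map


def build_bin_index(records: RecordTable) -> BinIndex:
    """Collect the BIN -> species mapping from every BIN-assigned record."""
    idx = BinIndex()
    for rec in records:
        if rec.bin_id:
            idx.add(rec.bin_id, rec.species_name)
    return idx


@dataclass(frozen=True)
class AuditGrade:
    species: str
    grade: Grade
    n_barcodes: int
    n_bins: int
    n_datasets: int
    rationale: str


def classify_species(
    records: list[SequenceRecord], bins: BinIndex
) -> AuditGrade:
    """Grade one species from its COI record profile.

    ``records`` must all belong to one resolved species. Only COI records
    participate; of these, only vouchered, non-mined, BIN-assigned barcodes
    count toward the >=3 threshold and the BIN logic. Absent dataset ids
    collapse to one pseudo-dataset when counting independent studies.
    """
    if not records:
        raise ValidationError("classify_species needs at least one record")
    species = records[0].species_name
    coi = [r for r in records if r.marker is Marker.COI]
    if not coi:
        raise ValidationError(f"{species}: no COI records to audit")

    if all(not r.has_voucher or r.mined_from_genbank for r in coi):
        return AuditGrade(species, Grade.F, n_barcodes=len(coi), n_bins=0,
                          n_datasets=0, rationale="all-unvouchered-or-mined")

    usable = [r for r in coi
              if r.has_voucher and not r.mined_from_genbank and r.bin_id]
    bin_ids = sorted({r.bin_id for r in usable})
    n_datasets = len({r.dataset_id or "__default__" for r in usable})
    if len(usable) < 3:
        return AuditGrade(species, Grade.D, n_barcodes=len(usable),
                          n_bins=len(bin_ids), n_datasets=n_datasets,
                          rationale="fewer-than-3-barcodes")

    exclusive = [bins.is_exclusive(b, species) for b in bin_ids]
    if len(bin_ids) == 1:
        if exclusive[0]:
            grade = Grade.A if n_datasets >= 2 else Grade.B
            why = ("one-exclusive-bin-multiple-datasets" if grade is Grade.A
                   else "one-exclusive-bin-single-dataset")
        else:
            grade, why = Grade.E_STAR, "single-bin-shared"
    else:
        if all(exclusive):
            grade, why = Grade.C, "multiple-exclusive-bins"
        else:
            grade, why = Grade.E_DSTAR, "multiple-bins-at-least-one-shared"
    return AuditGrade(species, grade, n_barcodes=len(usable),
                      n_bins=len(bin_ids), n_datasets=n_datasets,
                      rationale=why)


def audit_species(
    records: RecordTable, bins: BinIndex | None = None,
    species_whitelist: set[str] | None = None,
) -> list[AuditGrade]:
    """Grade every species with >=1 BOLD COI record.

    The audit denominator is BOLD registration (public or private): GenBank-
    only species never enter. ``species_whitelist`` restricts the audit to
    checklist species when off-checklist records are present in the table.
    """
    if bins is None:
        bins = build_bin_index(records)
    per_species: dict[str, list[SequenceRecord]] = {}
    for rec in records:
        if rec.marker is Marker.COI and rec.source_db is SourceDB.BOLD:
            per_species.setdefault(rec.species_name, []).append(rec)
    grades = []
    for species in sorted(per_species):
        if species_whitelist is not None and species not in species_whitelist:
            continue
        grades.append(classify_species(per_species[species], bins))
    return grades


@dataclass(frozen=True)
class AuditComposition:
    """Per-grade counts and 2-decimal percentages over audited species."""

    counts: dict[Grade, int]
    n_audited: int

    @property
    def empty(self) -> bool:
        return self.n_audited == 0

    def pct(self, grade: Grade) -> float | None:
        if self.empty:
            return None
        return coverage_percentage(self.counts.get(grade, 0),
                                   self.n_audited, decimals=2)

    @property
    def n_good(self) -> int:
        """A/B: well-represented species with concordant BINs."""
        return self.counts.get(Grade.A, 0) + self.counts.get(Grade.B, 0)

    @property
    def n_cryptic(self) -> int:
        """C + E* + E**: profiles pointing to possible cryptic diversity or
        BIN incongruence."""
        return (self.counts.get(Grade.C, 0) + self.counts.get(Grade.E_STAR, 0)
                + self.counts.get(Grade.E_DSTAR, 0))

    @property
    def pct_good(self) -> float | None:
        return None if self.empty else coverage_percentage(
            self.n_good, self.n_audited, decimals=2)

    @property
    def pct_cryptic(self) -> float | None:
        return None if self.empty else coverage_percentage(
            self.n_cryptic, self.n_audited, decimals=2)


def audit_composition(grades: list[AuditGrade]) -> AuditComposition:
    """Summarize one-grade-per-species audit results."""
    seen: set[str] = set()
    counts: dict[Grade, int] = {}
    for g in grades:
        if g.species in seen:
            raise ValidationError(f"species {g.species!r} graded twice")
        seen.add(g.species)
        counts[g.grade] = counts.get(g.grade, 0) + 1
    return AuditComposition(counts=counts, n_audited=len(grades))
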