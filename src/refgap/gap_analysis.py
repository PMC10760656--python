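"""Species-level coverage gap analysis over the four screened markers.

"Registered" coverage counts a species as represented when at least one
record of a marker exists in either database, public or private; "public"
coverage restricts to publicly visible records. Both views are always
reported, since large private holdings (e.g. embargoed barcoding projects)
inflate registered coverage well above what users of a reference library can
actually download.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

from refgap.checklist import (
    Checklist, SynonymMap, Taxon, THREATENED_STATUSES, resolve_name,
)
from refgap.errors import DomainError, UndefinedDenominatorError
from refgap.ingest import Marker, RecordTable, TARGET_MARKERS

__all__ = [
    "MarkerCoverage", "VennCounts", "GapReport", "Rollup",
    "coverage_percentage", "marker_coverage", "venn_counts", "gap_report",
    "resolve_records",
]


def coverage_percentage(n: int, d: int, decimals: int = 1) -> float:
    """Percentage 100*n/d rounded half-away-from-zero to ``decimals`` places.

    Half-away-from-zero (not banker's rounding) matches how coverage figures
    are conventionally printed: 897/1506 -> 59.6, 338/1191 at 2 decimals ->
    28.38.
    """
    if d == 0:
        raise UndefinedDenominatorError("percentage with zero denominator")
    if not 0 <= n <= d:
        raise DomainError(f"numerator {n} outside [0, {d}]")
    q = Decimal(1).scaleb(-decimals)
    return float(
        (Decimal(100) * Decimal(n) / Decimal(d)).quantize(q, ROUND_HALF_UP)
    )


def resolve_records(
    table: RecordTable, syn: SynonymMap, checklist: Checklist,
    keep_unmatched: bool = False,
) -> tuple[RecordTable, dict[str, int]]:
    """Map record names onto checklist names.

    Returns the resolved table plus a tally of match outcomes
    (direct / synonym / unmatched). Records matched only via synonym are
    credited to the accepted checklist name. Unmatched records are dropped
    by default; pass ``keep_unmatched=True`` to retain them under their
    canonical raw name — the BIN index for the quality audit must span the
    whole record universe, since a BIN shared with an off-checklist species
    still counts as shared.
    """
    from refgap.checklist import canonicalize_name
    from refgap.errors import MalformedNameError

    cache: dict[str, tuple[str | None, str]] = {}
    tally = {"direct": 0, "synonym": 0, "unmatched": 0}
    resolved = []
    log = list(table.provenance_log)
    for rec in table:
        hit = cache.get(rec.species_name)
        if hit is None:
            m = resolve_name(rec.species_name, syn, checklist)
            hit = (m.accepted_name, m.status)
            cache[rec.species_name] = hit
        accepted, status = hit
        tally[status] += 1
        if accepted is None:
            if not keep_unmatched:
                continue
            try:
                accepted = canonicalize_name(rec.species_name)
            except MalformedNameError:
                accepted = rec.species_name
        resolved.append(rec.resolved(accepted))
    log.append(
        "name resolution: {direct} direct, {synonym} via synonym, "
        "{unmatched} unmatched ({kept})".format(
            **tally, kept="kept" if keep_unmatched else "dropped")
    )
    return RecordTable(records=resolved, provenance_log=log), tally


def _species_markers(
    checklist: Checklist, records: RecordTable, public_only: bool = False
) -> dict[str, set[Marker]]:
    """Per-species set of registered target markers (OTHER never counts)."""
    out: dict[str, set[Marker]] = {t.scientific_name: set() for t in checklist}
    for rec in records:
        if rec.marker not in TARGET_MARKERS:
            continue
        if public_only and not rec.is_public:
            continue
        if rec.species_name in out:
            out[rec.species_name].add(rec.marker)
    return out


@dataclass(frozen=True)
class MarkerCoverage:
    """Registered vs public species counts for one marker."""

    marker: Marker
    n_species_registered: int
    n_species_public: int
    n_checklist: int

    @property
    def pct_registered(self) -> float:
        return coverage_percentage(self.n_species_registered, self.n_checklist)

    @property
    def pct_public(self) -> float:
        return coverage_percentage(self.n_species_public, self.n_checklist)


def marker_coverage(
    checklist: Checklist, records: RecordTable, marker: Marker
) -> MarkerCoverage:
    """Count checklist species with >=1 registered / >=1 public record of
    ``marker``. Records must already be resolved against the checklist."""
    registered = _species_markers(checklist, records)
    public = _species_markers(checklist, records, public_only=True)
    return MarkerCoverage(
        marker=marker,
        n_species_registered=sum(1 for s in registered.values() if marker in s),
        n_species_public=sum(1 for s in public.values() if marker in s),
        n_checklist=len(checklist),
    )


@dataclass(frozen=True)
class VennCounts:
    """Species counts per non-empty marker subset, plus the uncovered rest.

    ``region_counts`` maps each of the 15 non-empty subsets of the four
    target markers (as a frozenset of Marker) to the number of species whose
    registered marker set is exactly that subset.
    """

    region_counts: dict[frozenset, int]
    n_none: int
    n_checklist: int

    def count(self, *markers: Marker) -> int:
        return self.region_counts.get(frozenset(markers), 0)

    @property
    def total(self) -> int:
        return sum(self.region_counts.values()) + self.n_none


def venn_counts(checklist: Checklist, records: RecordTable) -> VennCounts:
    """Assign each species to exactly one of the 16 Venn regions by its set
    of registered target markers."""
    per_species = _species_markers(checklist, records)
    counts: dict[frozenset, int] = {}
    n_none = 0
    for markers in per_species.values():
        if not markers:
            n_none += 1
        else:
            key = frozenset(markers)
            counts[key] = counts.get(key, 0) + 1
    return VennCounts(region_counts=counts, n_none=n_none,
                      n_checklist=len(checklist))


@dataclass(frozen=True)
class Rollup:
    """Represented-species count within one taxonomic group."""

    group: str
    n_represented: int
    n_total: int

    @property
    def pct(self) -> float:
        return coverage_percentage(self.n_represented, self.n_total)


@dataclass
class GapReport:
    """Gap lists and taxonomic rollups for a checklist/record pairing."""

    missing_any: list[Taxon]
    order_rollups: list[Rollup]
    family_rollups: list[Rollup]
    n_checklist: int
    n_represented: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_represented = self.n_checklist - len(self.missing_any)

    @property
    def missing_endemic(self) -> list[Taxon]:
        return [t for t in self.missing_any if t.endemic]

    @property
    def missing_threatened(self) -> list[Taxon]:
        return [t for t in self.missing_any
                if t.iucn_status in THREATENED_STATUSES]


def gap_report(checklist: Checklist, records: RecordTable) -> GapReport:
    """List species with zero records across all four target markers and
    roll represented counts up per order and per family.

    A species with only OTHER-marker records still counts as missing: the
    audit screens exactly four markers.
    """
    per_species = _species_markers(checklist, records)
    missing = [t for t in checklist if not per_species[t.scientific_name]]
    missing_names = {t.scientific_name for t in missing}

    def _rollup(key) -> list[Rollup]:
        totals: dict[str, int] = {}
        rep: dict[str, int] = {}
        for t in checklist:
            g = key(t)
            totals[g] = totals.get(g, 0) + 1
            if t.scientific_name not in missing_names:
                rep[g] = rep.get(g, 0) + 1
        return [Rollup(group=g, n_represented=rep.get(g, 0), n_total=n)
                for g, n in sorted(totals.items())]

    return GapReport(
        missing_any=missing,
        order_rollups=_rollup(lambda t: t.order),
        family_rollups=_rollup(lambda t: t.family),
        n_checklist=len(checklist),
    )
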