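"""Seeded synthetic study generator.

Builds checklists, record tables, BIN indexes and region polygons whose
summary statistics hit requested compositions *exactly*: coverage counts are
allocated deterministically (contiguous block placement over the covered
species, then seeded shuffling of identities and record order), never drawn
as independent coin flips, because the audited quantities are census counts
rather than estimates. Species destined for a given audit grade receive a
COI record profile that classifies to that grade by construction; BIN
sharing is realized with off-checklist "shadow" species added to the record
universe.

What is emulated: per-marker registered/public species coverage, the
registered-vs-public split driven by private BOLD holdings, endemic and
threatened overlap structure among uncovered species, every audit grade's
record profile, and inside/outside/unlocated geographic composition against
generated region polygons. What is not: sequence content, real BIN-algorithm
behavior, geographic clustering beyond the inside/outside split, or
realistic taxonomic name frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from refgap.audit import BinIndex, Grade, build_bin_index
from refgap.checklist import Checklist, IucnStatus, Taxon
from refgap.errors import ValidationError
from refgap.geo import RegionPolygon, point_in_region
from refgap.ingest import (
    Marker, RecordTable, SequenceRecord, SourceDB, TARGET_MARKERS,
)

__all__ = [
    "SimSpec", "generate", "table1_taxa", "table1_gap_fixture",
    "write_checklist_csv", "write_regions_geojson",
]

# --------------------------------------------------------------------------
# Bundled fixture: the 14 threatened species with no records for any of the
# four markers (name, order, family, endemic, IUCN category).
_TABLE1_ROWS = [
    ("Pauxi koepckeae", "Galliformes", "Cracidae", True, "CR"),
    ("Loddigesia mirabilis", "Apodiformes", "Trochilidae", True, "EN"),
    ("Aulacorhynchus huallagae", "Piciformes", "Ramphastidae", True, "EN"),
    ("Euchrepomis sharpei", "Passeriformes", "Thamnophilidae", False, "EN"),
    ("Myrmoborus lugubris", "Passeriformes", "Thamnophilidae", False, "VU"),
    ("Myrmoborus melanurus", "Passeriformes", "Thamnophilidae", False, "VU"),
    ("Grallaricula ochraceifrons", "Passeriformes", "Grallariidae", True, "VU"),
    ("Synallaxis courseni", "Passeriformes", "Furnariidae", True, "VU"),
    ("Cnipodectes superrufus", "Passeriformes", "Tyrannidae", False, "VU"),
    ("Poecilotriccus luluae", "Passeriformes", "Tyrannidae", True, "EN"),
    ("Zimmerius cinereicapilla", "Passeriformes", "Tyrannidae", False, "VU"),
    ("Phyllomyias weedeni", "Passeriformes", "Tyrannidae", False, "VU"),
    ("Agriornis albicauda", "Passeriformes", "Tyrannidae", False, "VU"),
    ("Cnemathraupis aureodorsalis", "Passeriformes", "Thraupidae", True, "EN"),
]


def table1_taxa() -> list[Taxon]:
    """The bundled block of real threatened-and-unsequenced species."""
    return [
        Taxon(scientific_name=n, order=o, family=f, endemic=e,
              iucn_status=IucnStatus(s))
        for n, o, f, e, s in _TABLE1_ROWS
    ]


def table1_gap_fixture(seed: int = 0) -> tuple[Checklist, RecordTable]:
    """Checklist of the 14 real species plus 10 distractors, with records.

    Each distractor fails exactly one criterion of the threatened-and-missing
    filter: five are threatened but hold one COI record, five lack records
    but are not threatened. The correct filter output is therefore exactly
    the 14 bundled species.
    """
    rng = np.random.default_rng(seed)
    taxa = table1_taxa()
    records: list[SequenceRecord] = []
    statuses = ["CR", "EN", "VU", "VU", "EN"]
    sequenced_epithets = ["sequenceda", "sequencedbe", "sequencedci",
                          "sequencedo", "sequencedu"]
    for i in range(5):  # threatened, but sequenced
        name = f"Phantasma {sequenced_epithets[i]}"
        taxa.append(Taxon(scientific_name=name, order="Passeriformes",
                          family="Tyrannidae", endemic=bool(i % 2),
                          iucn_status=IucnStatus(statuses[i])))
        records.append(SequenceRecord(
            record_id=f"GBFIX{i:04d}", species_name=name, raw_name=name,
            marker=Marker.COI, source_db=SourceDB.GENBANK,
            mined_from_genbank=True,
        ))
    safe_statuses = ["LC", "NT", "LC", "DD", "NE"]
    epithets = ["missinga", "missingbe", "missingci", "missingo", "missingu"]
    for i in range(5):  # unsequenced, but not threatened
        name = f"Phantasma {epithets[i]}"
        taxa.append(Taxon(scientific_name=name, order="Apodiformes",
                          family="Trochilidae", endemic=bool(i % 2),
                          iucn_status=IucnStatus(safe_statuses[i])))
    order = rng.permutation(len(taxa))
    taxa = [taxa[i] for i in order]
    return (Checklist(taxa=taxa, name="table1-fixture"),
            RecordTable(records=records))


# --------------------------------------------------------------------------

_SYLLABLES = ("ba", "ce", "di", "fo", "gu", "la", "me", "ni", "po", "ru",
              "sa", "te", "vi", "xo", "zu", "ka", "lo", "mu", "ne", "ri")

_ORDERS = ("Passeriformes", "Apodiformes", "Piciformes", "Psittaciformes",
           "Accipitriformes", "Charadriiformes")


def _epithet(i: int) -> str:
    digits = []
    for _ in range(5):
        digits.append(_SYLLABLES[i % 20])
        i //= 20
    return "".join(digits)


def _genus(rng: np.random.Generator) -> str:
    k = int(rng.integers(0, 400))
    return (_SYLLABLES[k // 20] + _SYLLABLES[k % 20] + "us").capitalize()


@dataclass
class SimSpec:
    """Requested composition for one synthetic study.

    All counts are exact targets; mutually inconsistent requests are
    rejected at construction with the violated constraint named.
    """

    n_species: int
    registered: dict[Marker, int] = field(default_factory=dict)
    public: dict[Marker, int] = field(default_factory=dict)
    n_missing_all: int = 0
    endemic_count: int = 0
    missing_endemic: int = 0
    threatened_count: int = 0
    missing_threatened: int = 0
    missing_threatened_endemic: int = 0
    audit_profile: dict[Grade, int] | None = None
    geo_inside: dict[str, int] = field(default_factory=dict)
    n_located: int = 0
    n_datasets: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        def _require(cond: bool, msg: str) -> None:
            if not cond:
                raise ValidationError(f"inconsistent SimSpec: {msg}")

        _require(self.n_species > 0, "n_species must be positive")
        _require(0 <= self.n_missing_all <= self.n_species,
                 "n_missing_all outside [0, n_species]")
        covered = self.n_species - self.n_missing_all
        for m, k in self.registered.items():
            _require(m in TARGET_MARKERS, f"marker {m} is not a target marker")
            _require(0 <= k <= covered,
                     f"registered[{m.value}]={k} exceeds covered species {covered}")
            pub = self.public.get(m, k)
            _require(0 <= pub <= k,
                     f"public[{m.value}]={pub} outside [0, registered={k}]")
        _require(sum(self.registered.values()) >= covered,
                 "marker registrations cannot cover every non-missing species")
        _require(self.missing_endemic <= min(self.endemic_count,
                                             self.n_missing_all),
                 "missing_endemic exceeds endemic_count or n_missing_all")
        _require(self.missing_threatened <= min(self.threatened_count,
                                                self.n_missing_all),
                 "missing_threatened exceeds threatened_count or n_missing_all")
        _require(self.missing_threatened_endemic
                 <= min(self.missing_endemic, self.missing_threatened),
                 "missing overlap exceeds its parts")
        _require(self.missing_endemic + self.missing_threatened
                 - self.missing_threatened_endemic <= self.n_missing_all,
                 "endemic/threatened missing species exceed n_missing_all")
        _require(self.endemic_count <= self.n_species
                 and self.threatened_count <= self.n_species,
                 "attribute counts exceed n_species")
        if self.audit_profile is not None:
            n_audit = sum(self.audit_profile.values())
            k_coi = self.registered.get(Marker.COI, 0)
            pub_coi = self.public.get(Marker.COI, k_coi)
            _require(all(v >= 0 for v in self.audit_profile.values()),
                     "negative audit grade count")
            _require(n_audit <= k_coi,
                     "audit profile larger than COI-registered species")
            _require(k_coi - pub_coi <= n_audit,
                     "private COI species must all fit inside the audit profile")
            if self.audit_profile.get(Grade.A, 0) > 0:
                _require(self.n_datasets >= 2,
                         "grade A needs >=2 datasets")
        n_inside = sum(self.geo_inside.values())
        _require(n_inside <= self.n_located,
                 "inside-region records exceed n_located")
        _require(len(self.geo_inside) <= 10, "at most 10 regions supported")

    @classmethod
    def paper_scale(cls, seed: int = 0) -> "SimSpec":
        """The study-scale composition: a 1506-species Amazonian checklist,
        COI 1239 registered / 987 public, CYTB 897, 12S 247, 18S 9, 190
        species missing all four markers, 73 endemics of which 32 missing,
        14 threatened-and-missing species of which 7 endemic, and an audit
        profile totalling 1191 BOLD-COI species with A/B=338, D=546,
        C+E*+E**=289, F=18."""
        return cls(
            n_species=1506,
            registered={Marker.COI: 1239, Marker.CYTB: 897,
                        Marker.R12S: 247, Marker.R18S: 9},
            public={Marker.COI: 987, Marker.CYTB: 897,
                    Marker.R12S: 247, Marker.R18S: 9},
            n_missing_all=190,
            endemic_count=73,
            missing_endemic=32,
            threatened_count=60,
            missing_threatened=14,
            missing_threatened_endemic=7,
            audit_profile={Grade.A: 200, Grade.B: 138, Grade.C: 100,
                           Grade.E_STAR: 100, Grade.E_DSTAR: 89,
                           Grade.D: 546, Grade.F: 18},
            geo_inside={"Neotropic": 68},
            n_located=100,
            n_datasets=4,
            seed=seed,
        )


# -- deterministic allocation helpers --------------------------------------

def _marker_blocks(spec: SimSpec) -> dict[Marker, range]:
    """Place each marker's registered species as a contiguous block over the
    covered index range so that the union covers every non-missing species."""
    covered = spec.n_species - spec.n_missing_all
    blocks: dict[Marker, range] = {}
    end = 0
    for marker, k in sorted(spec.registered.items(),
                            key=lambda kv: -kv[1]):
        if k == 0:
            blocks[marker] = range(0)
            continue
        start = max(0, min(end, covered - k))
        blocks[marker] = range(start, start + k)
        end = max(end, start + k)
    if spec.registered and end < covered:
        raise ValidationError("block allocation failed to cover all species")
    return blocks


def _make_region(i: int, name: str) -> RegionPolygon:
    """A concave L-shaped region with one square hole, regions disjoint."""
    x0 = -170.0 + 24.0 * i
    outer = [(x0, 0.0), (x0 + 10, 0.0), (x0 + 10, 4.0), (x0 + 4, 4.0),
             (x0 + 4, 10.0), (x0, 10.0), (x0, 0.0)]
    hole = [(x0 + 1, 1.0), (x0 + 3, 1.0), (x0 + 3, 3.0), (x0 + 1, 3.0),
            (x0 + 1, 1.0)]
    return RegionPolygon(name=name, outer_rings=(outer,), holes=(hole,))


def _winding_inside(lon: float, lat: float, region: RegionPolygon) -> bool:
    """Winding-number verifier used to double-check sampled points."""

    def _wind(ring) -> int:
        w = 0
        for (x0, y0), (x1, y1) in zip(ring[:-1], ring[1:]):
            if y0 <= lat < y1 and (x1 - x0) * (lat - y0) > (lon - x0) * (y1 - y0):
                w += 1
            elif y1 <= lat < y0 and (x1 - x0) * (lat - y0) < (lon - x0) * (y1 - y0):
                w -= 1
        return w

    if any(_wind(r) != 0 for r in region.outer_rings):
        return not any(_wind(r) != 0 for r in region.holes)
    return False


def _sample_inside(rng: np.random.Generator, region: RegionPolygon,
                   n: int) -> list[tuple[float, float]]:
    xs = [p[0] for r in region.outer_rings for p in r]
    ys = [p[1] for r in region.outer_rings for p in r]
    lo_x, hi_x, lo_y, hi_y = min(xs), max(xs), min(ys), max(ys)
    pts = []
    while len(pts) < n:
        lon = float(rng.uniform(lo_x, hi_x))
        lat = float(rng.uniform(lo_y, hi_y))
        if point_in_region(lon, lat, region) and _winding_inside(lon, lat, region):
            pts.append((lon, lat))
    return pts


def _sample_outside(rng: np.random.Generator,
                    regions: list[RegionPolygon], n: int) -> list[tuple[float, float]]:
    pts = []
    while len(pts) < n:
        lon = float(rng.uniform(100.0, 170.0))
        lat = float(rng.uniform(-60.0, 60.0))
        if not any(point_in_region(lon, lat, r) for r in regions):
            pts.append((lon, lat))
    return pts


# -- audit record profiles --------------------------------------------------

class _Counters:
    def __init__(self):
        self.record = 0
        self.bin = 0
        self.shadow = 0

    def rid(self, prefix: str) -> str:
        self.record += 1
        return f"{prefix}{self.record:07d}"

    def new_bin(self) -> str:
        self.bin += 1
        return f"BOLD:SYN{self.bin:05d}"

    def shadow_name(self) -> str:
        self.shadow += 1
        return f"Umbrax {_epithet(self.shadow)}"


def _grade_profile(
    species: str, grade: Grade, is_public: bool, ctr: _Counters,
    datasets: list[str],
) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """Build a COI/BOLD record profile classifying to ``grade``.

    Returns (records for the species, shadow-species records realizing BIN
    sharing where the grade requires it).
    """

    def rec(bin_id, voucher=True, mined=False, dataset=None):
        return SequenceRecord(
            record_id=ctr.rid("BL"), species_name=species, raw_name=species,
            marker=Marker.COI, source_db=SourceDB.BOLD, is_public=is_public,
            bin_id=bin_id, has_voucher=voucher, mined_from_genbank=mined,
            dataset_id=dataset or datasets[0],
        )

    def shadow(bin_id):
        name = ctr.shadow_name()
        return SequenceRecord(
            record_id=ctr.rid("BL"), species_name=name, raw_name=name,
            marker=Marker.COI, source_db=SourceDB.BOLD, is_public=True,
            bin_id=bin_id, has_voucher=True, dataset_id=datasets[0],
        )

    if grade is Grade.A:
        b = ctr.new_bin()
        return [rec(b, dataset=datasets[0]), rec(b, dataset=datasets[1]),
                rec(b, dataset=datasets[0])], []
    if grade is Grade.B:
        b = ctr.new_bin()
        return [rec(b), rec(b), rec(b)], []
    if grade is Grade.C:
        b1, b2 = ctr.new_bin(), ctr.new_bin()
        return [rec(b1), rec(b1), rec(b2)], []
    if grade is Grade.D:
        b = ctr.new_bin()
        return [rec(b), rec(b)], []
    if grade is Grade.E_STAR:
        b = ctr.new_bin()
        return [rec(b), rec(b), rec(b)], [shadow(b)]
    if grade is Grade.E_DSTAR:
        b1, b2 = ctr.new_bin(), ctr.new_bin()
        return [rec(b1), rec(b1), rec(b1), rec(b2)], [shadow(b2)]
    if grade is Grade.F:
        b = ctr.new_bin()
        return [rec(b, voucher=False, mined=True),
                rec(b, voucher=False, mined=True)], []
    raise ValidationError(f"unknown grade {grade}")


_GRADE_ORDER = (Grade.A, Grade.B, Grade.C, Grade.D, Grade.E_STAR,
                Grade.E_DSTAR, Grade.F)


# -- main entry point -------------------------------------------------------

def generate(
    spec: SimSpec,
) -> tuple[Checklist, RecordTable, BinIndex, list[RegionPolygon]]:
    """Realize a SimSpec into (checklist, records, bin index, regions).

    Identical spec + seed give identical output; different seeds change
    species identities and record order but never any summary count.
    """
    master = np.random.SeedSequence(spec.seed)
    rng_names, rng_geo, rng_shuffle = (
        np.random.default_rng(s) for s in master.spawn(3)
    )
    n = spec.n_species
    covered = n - spec.n_missing_all

    # species identities
    names = [f"{_genus(rng_names)} {_epithet(i)}" for i in range(n)]

    # attribute allocation: missing block is the index tail
    endemic = np.zeros(n, dtype=bool)
    threatened = np.zeros(n, dtype=bool)
    m0 = covered
    both = spec.missing_threatened_endemic
    endemic[m0:m0 + both] = True
    threatened[m0:m0 + both] = True
    e_only = spec.missing_endemic - both
    endemic[m0 + both:m0 + both + e_only] = True
    t_only = spec.missing_threatened - both
    threatened[m0 + both + e_only:m0 + both + e_only + t_only] = True
    e_cov = spec.endemic_count - spec.missing_endemic
    if e_cov:
        endemic[covered - e_cov:covered] = True
    t_cov = spec.threatened_count - spec.missing_threatened
    if t_cov:
        threatened[max(0, covered - e_cov - t_cov):covered - e_cov] = True

    threat_cycle = (IucnStatus.CR, IucnStatus.EN, IucnStatus.VU)
    safe_cycle = (IucnStatus.LC, IucnStatus.NT, IucnStatus.LC, IucnStatus.DD)
    taxa = []
    for i in range(n):
        status = (threat_cycle[i % 3] if threatened[i]
                  else safe_cycle[i % 4])
        order = _ORDERS[i % len(_ORDERS)]
        taxa.append(Taxon(
            scientific_name=names[i], order=order,
            family=f"{order[:-6]}idae{i % 3}",
            endemic=bool(endemic[i]), iucn_status=status,
        ))
    checklist = Checklist(taxa=taxa, name=f"synthetic-{spec.seed}")

    # marker records
    blocks = _marker_blocks(spec)
    ctr = _Counters()
    datasets = [f"DS{j + 1}" for j in range(spec.n_datasets)]
    records: list[SequenceRecord] = []
    bold_records: list[SequenceRecord] = []

    def add(rec: SequenceRecord) -> None:
        records.append(rec)
        if rec.source_db is SourceDB.BOLD:
            bold_records.append(rec)

    coi_block = list(blocks.get(Marker.COI, range(0)))
    k_coi = len(coi_block)
    pub_coi = spec.public.get(Marker.COI, k_coi)
    coi_public = set(coi_block[:pub_coi])

    audited: set[int] = set()
    if spec.audit_profile is not None and coi_block:
        n_audit = sum(spec.audit_profile.values())
        # private species must all be audited (they are BOLD by necessity)
        audit_order = coi_block[pub_coi:] + coi_block[:n_audit - (k_coi - pub_coi)]
        audited = set(audit_order)
        pos = 0
        for grade in _GRADE_ORDER:
            for _ in range(spec.audit_profile.get(grade, 0)):
                idx = audit_order[pos]
                pos += 1
                own, shadows = _grade_profile(
                    names[idx], grade, idx in coi_public, ctr, datasets)
                for r in own + shadows:
                    add(r)

    for marker, block in blocks.items():
        pub_k = spec.public.get(marker, len(block))
        for j, idx in enumerate(block):
            is_pub = j < pub_k
            if marker is Marker.COI:
                if idx in audited:
                    continue  # profile records already emitted
                if spec.audit_profile is None:
                    b = ctr.new_bin()
                    add(SequenceRecord(
                        record_id=ctr.rid("BL"), species_name=names[idx],
                        raw_name=names[idx], marker=Marker.COI,
                        source_db=SourceDB.BOLD, is_public=is_pub,
                        bin_id=b, has_voucher=True, dataset_id=datasets[0],
                    ))
                    continue
                # audited set absorbs every private species; the rest are
                # public and arrive via GenBank
                add(SequenceRecord(
                    record_id=ctr.rid("GB"), species_name=names[idx],
                    raw_name=names[idx], marker=Marker.COI,
                    source_db=SourceDB.GENBANK, mined_from_genbank=True,
                ))
                continue
            if is_pub:
                add(SequenceRecord(
                    record_id=ctr.rid("GB"), species_name=names[idx],
                    raw_name=names[idx], marker=marker,
                    source_db=SourceDB.GENBANK, mined_from_genbank=True,
                ))
            else:
                add(SequenceRecord(
                    record_id=ctr.rid("BL"), species_name=names[idx],
                    raw_name=names[idx], marker=marker,
                    source_db=SourceDB.BOLD, is_public=False,
                    has_voucher=True, dataset_id=datasets[0],
                ))

    # geography: coordinates live on BOLD records only
    regions = [_make_region(i, name)
               for i, name in enumerate(spec.geo_inside)]
    if spec.n_located > len(bold_records):
        raise ValidationError(
            f"inconsistent SimSpec: n_located={spec.n_located} exceeds the "
            f"{len(bold_records)} BOLD records generated"
        )
    points: list[tuple[float, float]] = []
    for region, c in zip(regions, spec.geo_inside.values()):
        points.extend(_sample_inside(rng_geo, region, c))
    points.extend(_sample_outside(
        rng_geo, regions, spec.n_located - len(points)))
    located_ids = {}
    for rec, (lon, lat) in zip(bold_records[:spec.n_located], points):
        located_ids[rec.record_id] = (lat, lon)
    if located_ids:
        from dataclasses import replace
        records = [
            replace(r, latitude=located_ids[r.record_id][0],
                    longitude=located_ids[r.record_id][1])
            if r.record_id in located_ids else r
            for r in records
        ]

    rng_shuffle.shuffle(records)
    table = RecordTable(records=records, provenance_log=[
        f"synthetic table: seed={spec.seed}, {len(records)} records"
    ])
    return checklist, table, build_bin_index(table), regions


# -- fixture writers --------------------------------------------------------

def write_checklist_csv(checklist: Checklist, path: str | Path) -> None:
    lines = ["scientific_name,order,family,endemic,iucn_status"]
    for t in checklist:
        lines.append(f"{t.scientific_name},{t.order},{t.family},"
                     f"{'true' if t.endemic else 'false'},{t.iucn_status.value}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_regions_geojson(regions: list[RegionPolygon],
                          path: str | Path) -> None:
    import json

    features = []
    for r in regions:
        if len(r.outer_rings) != 1:
            raise ValidationError(
                f"{r.name}: writer supports single-outer-ring regions")
        coords = [[list(p) for p in r.outer_rings[0]]]
        coords += [[list(p) for p in h] for h in r.holes]
        features.append({
            "type": "Feature",
            "properties": {"name": r.name},
            "geometry": {"type": "Polygon", "coordinates": coords},
        })
    Path(path).write_text(json.dumps(
        {"type": "FeatureCollection", "features": features},
        sort_keys=True) + "\n")
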