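"""Sequence-record metadata ingestion.

Reads two export dialects — a BOLD-like specimen+sequence TSV and a GenBank
summary TSV — into one normalized record table. Marker names are collapsed
onto the four screened markers (COI, CYTB, 12S, 18S; everything else OTHER).
No minimum sequence-length filter is applied anywhere: even 113-bp mini
barcodes are usable references for metabarcoding, so length is retained as
metadata only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

import pandas as pd

from refgap.errors import SchemaError

__all__ = [
    "Marker", "SourceDB", "SequenceRecord", "RecordTable", "normalize_marker",
    "read_bold_tsv", "read_genbank_summary", "write_records_tsv",
    "read_records_tsv", "TARGET_MARKERS",
]


class Marker(str, Enum):
    COI = "COI"
    CYTB = "CYTB"
    R12S = "12S"
    R18S = "18S"
    OTHER = "OTHER"


#: The four screened markers, in report order.
TARGET_MARKERS = (Marker.COI, Marker.CYTB, Marker.R12S, Marker.R18S)


class SourceDB(str, Enum):
    BOLD = "BOLD"
    GENBANK = "GENBANK"


_MARKER_ALIASES = {
    Marker.COI: {"coi", "cox1", "co1", "coi-5p", "coi-3p"},
    Marker.CYTB: {"cytb", "cyt b", "cob", "mt-cyb"},
    Marker.R12S: {"12s", "12s rrna", "rrns", "mt-rnr1"},
    Marker.R18S: {"18s", "18s rrna", "ssu"},
}


def normalize_marker(raw: str) -> Marker:
    """Map a raw marker code onto the marker enum (total function).

    Aliases are matched case-insensitively; unknown codes map to OTHER.
    """
    token = str(raw).strip().lower()
    for marker, aliases in _MARKER_ALIASES.items():
        if token in aliases:
            return marker
    return Marker.OTHER


@dataclass(frozen=True)
class SequenceRecord:
    """One marker record with provenance, BIN, voucher and visibility flags.

    ``species_name`` holds the post-resolution accepted name once records
    have been matched against a checklist; ``raw_name`` always retains the
    name as it appeared in the export.
    """

    record_id: str
    species_name: str
    marker: Marker
    source_db: SourceDB
    is_public: bool = True
    bin_id: str | None = None
    has_voucher: bool = False
    mined_from_genbank: bool = False
    dataset_id: str | None = None
    latitude: float | None = None
    longitude: float | None = None
    country: str | None = None
    seq_length: int | None = None
    raw_name: str | None = None

    def __post_init__(self) -> None:
        if (self.latitude is None) != (self.longitude is None):
            raise ValueError(
                f"{self.record_id}: coordinates must be both present or both absent"
            )
        if self.latitude is not None and not (
            -90.0 <= self.latitude <= 90.0 and -180.0 <= self.longitude <= 180.0
        ):
            raise ValueError(f"{self.record_id}: coordinates out of range")
        if self.source_db is SourceDB.GENBANK and self.bin_id is not None:
            raise ValueError(f"{self.record_id}: GenBank records carry no BIN")

    @property
    def located(self) -> bool:
        return self.latitude is not None

    def resolved(self, accepted_name: str) -> "SequenceRecord":
        """Return a copy carrying the accepted name (raw name preserved)."""
        return replace(
            self, species_name=accepted_name,
            raw_name=self.raw_name or self.species_name,
        )


@dataclass
class RecordTable:
    """A normalized collection of sequence records plus reader warnings."""

    records: list[SequenceRecord] = field(default_factory=list)
    provenance_log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[SourceDB, str]] = set()
        for r in self.records:
            key = (r.source_db, r.record_id)
            if key in seen:
                raise ValueError(
                    f"duplicate record id {r.record_id!r} in {r.source_db.value}"
                )
            seen.add(key)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def extend(self, other: "RecordTable") -> "RecordTable":
        return RecordTable(
            records=self.records + other.records,
            provenance_log=self.provenance_log + other.provenance_log,
        )

    def by_species(self) -> dict[str, list[SequenceRecord]]:
        out: dict[str, list[SequenceRecord]] = {}
        for r in self.records:
            out.setdefault(r.species_name, []).append(r)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append({
                "record_id": r.record_id,
                "species_name": r.species_name,
                "raw_name": r.raw_name or "",
                "marker": r.marker.value,
                "source_db": r.source_db.value,
                "is_public": int(r.is_public),
                "bin_id": r.bin_id or "",
                "has_voucher": int(r.has_voucher),
                "mined_from_genbank": int(r.mined_from_genbank),
                "dataset_id": r.dataset_id or "",
                "latitude": "" if r.latitude is None else repr(r.latitude),
                "longitude": "" if r.longitude is None else repr(r.longitude),
                "country": r.country or "",
                "seq_length": "" if r.seq_length is None else str(r.seq_length),
            })
        return pd.DataFrame(rows, columns=_INTERNAL_COLUMNS)


_INTERNAL_COLUMNS = [
    "record_id", "species_name", "raw_name", "marker", "source_db",
    "is_public", "bin_id", "has_voucher", "mined_from_genbank", "dataset_id",
    "latitude", "longitude", "country", "seq_length",
]


def _parse_coord(lat_raw, lon_raw, record_id: str, log: list[str]):
    """Parse a lat/lon pair; any defect yields (None, None) plus a warning."""

    def _num(v):
        s = str(v).strip().replace("−", "-")  # unicode minus
        if not s or s.lower() == "nan":
            return None
        try:
            x = float(s)
        except ValueError:
            return math.nan
        return x

    lat, lon = _num(lat_raw), _num(lon_raw)
    if lat is None and lon is None:
        return None, None
    bad = (
        lat is None or lon is None
        or math.isnan(lat) or math.isnan(lon)
        or abs(lat) > 90.0 or abs(lon) > 180.0
    )
    if bad:
        log.append(f"{record_id}: unusable coordinates ({lat_raw!r}, {lon_raw!r})")
        return None, None
    return lat, lon


_BOLD_REQUIRED = ("processid", "species_name", "markercode")


def read_bold_tsv(path: str | Path) -> RecordTable:
    """Read a BOLD-export-like TSV into a RecordTable (source_db=BOLD).

    Rows with an empty species name are dropped and counted in the log.
    A record is vouchered when its institution/voucher field is non-empty;
    ``mined_from_genbank`` is set when the row flags GenBank mining. The
    public flag defaults to true when no visibility column is present.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in _BOLD_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing columns {missing}")
    log: list[str] = []
    records: list[SequenceRecord] = []
    n_nameless = 0
    for _, row in df.iterrows():
        name = str(row["species_name"]).strip()
        if not name:
            n_nameless += 1
            continue
        rid = str(row["processid"]).strip()
        lat, lon = _parse_coord(row.get("lat", ""), row.get("lon", ""), rid, log)
        voucher = str(row.get("institution_storing", "")).strip() or str(
            row.get("voucher_status", "")).strip()
        mined = str(row.get("mined_from_genbank", "")).strip().lower() in (
            "1", "true", "yes") or "genbank" in str(
            row.get("sequence_source", "")).strip().lower()
        public_raw = str(row.get("is_public", "")).strip().lower()
        is_public = public_raw not in ("0", "false", "no", "private")
        length_raw = str(row.get("seq_length", "")).strip()
        records.append(SequenceRecord(
            record_id=rid,
            species_name=name,
            raw_name=name,
            marker=normalize_marker(row["markercode"]),
            source_db=SourceDB.BOLD,
            is_public=is_public,
            bin_id=str(row.get("bin_uri", "")).strip() or None,
            has_voucher=bool(voucher),
            mined_from_genbank=mined,
            dataset_id=str(row.get("dataset_id", "")).strip() or None,
            latitude=lat,
            longitude=lon,
            country=str(row.get("country", "")).strip() or None,
            seq_length=int(length_raw) if length_raw.isdigit() else None,
        ))
    if n_nameless:
        log.append(f"{path.name}: dropped {n_nameless} rows without species name")
    return RecordTable(records=records, provenance_log=log)


_GENBANK_REQUIRED = ("accession", "organism", "marker")


def read_genbank_summary(path: str | Path) -> RecordTable:
    """Read a GenBank summary TSV (source_db=GENBANK).

    GenBank records are always public, never carry a BIN or coordinates
    (collection coordinates are a BOLD-only field in these exports), and are
    flagged as mined from GenBank for the quality audit.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in _GENBANK_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing columns {missing}")
    log: list[str] = []
    records: list[SequenceRecord] = []
    n_nameless = 0
    for _, row in df.iterrows():
        name = str(row["organism"]).strip()
        if not name:
            n_nameless += 1
            continue
        length_raw = str(row.get("length", "")).strip()
        records.append(SequenceRecord(
            record_id=str(row["accession"]).strip(),
            species_name=name,
            raw_name=name,
            marker=normalize_marker(row["marker"]),
            source_db=SourceDB.GENBANK,
            is_public=True,
            bin_id=None,
            has_voucher=False,
            mined_from_genbank=True,
            dataset_id=None,
            country=str(row.get("country", "")).strip() or None,
            seq_length=int(length_raw) if length_raw.isdigit() else None,
        ))
    if n_nameless:
        log.append(f"{path.name}: dropped {n_nameless} rows without organism")
    return RecordTable(records=records, provenance_log=log)


def write_records_tsv(table: RecordTable, path: str | Path) -> None:
    """Write the normalized internal TSV (bit-exact round trip)."""
    table.to_frame().to_csv(path, sep="\t", index=False)


def read_records_tsv(path: str | Path) -> RecordTable:
    """Read the normalized internal TSV written by :func:`write_records_tsv`."""
    df = pd.read_csv(Path(path), sep="\t", dtype=str).fillna("")
    missing = [c for c in _INTERNAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"internal record TSV missing columns {missing}")
    records = []
    for _, row in df.iterrows():
        lat = float(row["latitude"]) if row["latitude"] else None
        lon = float(row["longitude"]) if row["longitude"] else None
        records.append(SequenceRecord(
            record_id=row["record_id"],
            species_name=row["species_name"],
            raw_name=row["raw_name"] or None,
            marker=Marker(row["marker"]),
            source_db=SourceDB(row["source_db"]),
            is_public=row["is_public"] == "1",
            bin_id=row["bin_id"] or None,
            has_voucher=row["has_voucher"] == "1",
            mined_from_genbank=row["mined_from_genbank"] == "1",
            dataset_id=row["dataset_id"] or None,
            latitude=lat,
            longitude=lon,
            country=row["country"] or None,
            seq_length=int(row["seq_length"]) if row["seq_length"] else None,
        ))
    return RecordTable(records=records)
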