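import pytest

from refgap.checklist import Checklist, IucnStatus, Taxon
from refgap.ingest import Marker, RecordTable, SequenceRecord, SourceDB


def make_record(record_id, species, marker=Marker.COI,
                source=SourceDB.BOLD, **kw):
    kw.setdefault("raw_name", species)
    if source is SourceDB.GENBANK:
        kw.setdefault("mined_from_genbank", True)
    return SequenceRecord(record_id=record_id, species_name=species,
                          marker=marker, source_db=source, **kw)


@pytest.fixture
def toy_checklist():
    """Five species across two orders, one endemic, one threatened."""
    return Checklist(taxa=[
        Taxon("Alphaus primus", "Passeriformes", "Tyrannidae"),
        Taxon("Alphaus secundus", "Passeriformes", "Tyrannidae",
              endemic=True),
        Taxon("Betaus tertius", "Passeriformes", "Thraupidae",
              iucn_status=IucnStatus.EN),
        Taxon("Gammaus quartus", "Apodiformes", "Trochilidae"),
        Taxon("Deltaus quintus", "Apodiformes", "Trochilidae",
              iucn_status=IucnStatus.LC),
    ], name="toy")


@pytest.fixture
def toy_records():
    """A:2 public COI, B:1 private COI, C:1 CYTB — D and E uncovered."""
    return RecordTable(records=[
        make_record("R1", "Alphaus primus"),
        make_record("R2", "Alphaus primus"),
        make_record("R3", "Alphaus secundus", is_public=False),
        make_record("R4", "Betaus tertius", marker=Marker.CYTB,
                    source=SourceDB.GENBANK),
    ])
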