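"""BIN-based quality grading and composition summaries."""

import numpy as np
import pytest

from conftest import make_record
from oracle_util import rule_table_grade
from refgap.audit import (
    AuditGrade, BinIndex, Grade, audit_composition, audit_species,
    build_bin_index, classify_species,
)
from refgap.errors import ValidationError
from refgap.ingest import Marker, RecordTable


def coi(rid, species="Alphaus primus", bin_id="BOLD:X1", voucher=True,
        mined=False, dataset="DS1", **kw):
    return make_record(rid, species, marker=Marker.COI, bin_id=bin_id,
                       has_voucher=voucher, mined_from_genbank=mined,
                       dataset_id=dataset, **kw)


def exclusive_index(*bin_ids, species="Alphaus primus"):
    return BinIndex({b: {species} for b in bin_ids})


class TestClassifySpecies:
    def test_grade_a_multiple_datasets_one_exclusive_bin(self):
        recs = [coi("R1"), coi("R2", dataset="DS2"), coi("R3")]
        g = classify_species(recs, exclusive_index("BOLD:X1"))
        assert g.grade is Grade.A and g.n_datasets == 2

    def test_grade_b_single_dataset(self):
        recs = [coi("R1"), coi("R2"), coi("R3")]
        assert classify_species(
            recs, exclusive_index("BOLD:X1")).grade is Grade.B

    def test_grade_c_multiple_exclusive_bins(self):
        recs = [coi("R1"), coi("R2", bin_id="BOLD:X2"), coi("R3")]
        assert classify_species(
            recs, exclusive_index("BOLD:X1", "BOLD:X2")).grade is Grade.C

    def test_grade_d_fewer_than_three_barcodes(self):
        recs = [coi("R1"), coi("R2")]
        assert classify_species(
            recs, exclusive_index("BOLD:X1")).grade is Grade.D

    def test_grade_e_star_shared_single_bin(self):
        recs = [coi("R1"), coi("R2"), coi("R3")]
        bins = BinIndex({"BOLD:X1": {"Alphaus primus", "Betaus tertius"}})
        assert classify_species(recs, bins).grade is Grade.E_STAR

    def test_grade_e_double_star_one_shared_of_two_bins(self):
        recs = [coi("R1"), coi("R2"), coi("R3"),
                coi("R4", bin_id="BOLD:X2")]
        bins = BinIndex({"BOLD:X1": {"Alphaus primus"},
                         "BOLD:X2": {"Alphaus primus", "Betaus tertius"}})
        assert classify_species(recs, bins).grade is Grade.E_DSTAR

    def test_grade_f_all_mined(self):
        recs = [coi(f"R{i}", voucher=False, mined=True) for i in range(5)]
        assert classify_species(
            recs, exclusive_index("BOLD:X1")).grade is Grade.F

    def test_f_takes_precedence_over_d(self):
        """Two unvouchered mined records flag procedure (F), not data
        deficiency (D)."""
        recs = [coi("R1", voucher=False, mined=True),
                coi("R2", voucher=False, mined=True)]
        assert classify_species(
            recs, exclusive_index("BOLD:X1")).grade is Grade.F

    def test_binless_records_do_not_support_the_threshold(self):
        recs = [coi("R1"), coi("R2"), coi("R3", bin_id=None)]
        assert classify_species(
            recs, exclusive_index("BOLD:X1")).grade is Grade.D

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValidationError):
            classify_species([], BinIndex())

    def test_determinism(self):
        recs = [coi("R1"), coi("R2", dataset="DS2"), coi("R3")]
        bins = exclusive_index("BOLD:X1")
        assert classify_species(recs, bins) == classify_species(recs, bins)

    def test_new_barcode_in_existing_exclusive_bin_moves_d_to_a_or_b(self):
        recs = [coi("R1"), coi("R2")]
        bins = exclusive_index("BOLD:X1")
        assert classify_species(recs, bins).grade is Grade.D
        for extra_ds in ("DS1", "DS2"):
            grown = recs + [coi("R3", dataset=extra_ds)]
            assert classify_species(grown, bins).grade in (Grade.A, Grade.B)


def _random_profile(rng):
    """One random species profile in the oracle's vocabulary."""
    n = int(rng.integers(1, 7))
    pool = [f"BOLD:P{i}" for i in range(3)]
    records = []
    for _ in range(n):
        records.append({
            "voucher": bool(rng.integers(0, 2)),
            "mined": bool(rng.integers(0, 2)),
            "bin": (pool[int(rng.integers(0, 3))]
                    if rng.integers(0, 5) else None),
        })
    sharing = {b: bool(rng.integers(0, 2)) for b in pool}
    usable = [r for r in records
              if r["voucher"] and not r["mined"] and r["bin"]]
    datasets = [f"DS{int(rng.integers(1, 4))}" for _ in usable]
    return records, sharing, datasets


def test_equivalence_with_brute_force_rule_table_1000_profiles():
    """The staged classifier and a literal rule-table walk agree on 1000
    seeded random species profiles."""
    rng = np.random.default_rng(2024)
    species = "Alphaus primus"
    for trial in range(1000):
        raw, sharing, datasets = _random_profile(rng)
        records = []
        for i, r in enumerate(raw):
            records.append(coi(f"T{trial}R{i}", bin_id=r["bin"],
                               voucher=r["voucher"], mined=r["mined"]))
        usable_idx = [i for i, r in enumerate(raw)
                      if r["voucher"] and not r["mined"] and r["bin"]]
        for j, i in enumerate(usable_idx):
            records[i] = coi(f"T{trial}R{i}", bin_id=raw[i]["bin"],
                             voucher=True, mined=False, dataset=datasets[j])
        bins = BinIndex({
            b: ({species, "Betaus tertius"} if shared else {species})
            for b, shared in sharing.items()
        })
        expected = rule_table_grade({
            "records": raw,
            "bin_sharing": sharing,
            "n_datasets": len(set(datasets)) if datasets else 1,
        })
        assert classify_species(records, bins).grade.value == expected, \
            f"trial {trial}: profile {raw} sharing {sharing}"


class TestAuditComposition:
    def test_single_species_graded_a(self):
        comp = audit_composition([
            AuditGrade("Alphaus primus", Grade.A, 3, 1, 2, "x")])
        assert comp.pct_good == 100.0

    def test_uniform_seven_grades(self):
        grades = []
        for i, g in enumerate(Grade):
            for j in range(100):
                grades.append(AuditGrade(f"Alphaus {'abcdefg'[i]}{j:03d}",
                                         g, 3, 1, 1, "x"))
        comp = audit_composition(grades)
        for g in Grade:
            assert comp.pct(g) == 14.29

    def test_percentages_sum_to_about_100(self):
        rng = np.random.default_rng(5)
        grades = [
            AuditGrade(f"Alphaus sp{i}", list(Grade)[int(rng.integers(0, 7))],
                       3, 1, 1, "x")
            for i in range(137)
        ]
        comp = audit_composition(grades)
        total = sum(comp.pct(g) for g in Grade)
        assert abs(total - 100.0) <= 0.05

    def test_double_grading_rejected(self):
        g = AuditGrade("Alphaus primus", Grade.A, 3, 1, 2, "x")
        with pytest.raises(ValidationError):
            audit_composition([g, g])

    def test_empty_composition_flagged(self):
        comp = audit_composition([])
        assert comp.empty and comp.pct(Grade.A) is None


def test_audit_species_denominator_is_bold_coi():
    """GenBank-only and non-COI species never enter the audit."""
    from refgap.ingest import SourceDB
    table = RecordTable(records=[
        coi("R1"), coi("R2"), coi("R3"),
        make_record("G1", "Betaus tertius", marker=Marker.COI,
                    source=SourceDB.GENBANK),
        make_record("R4", "Gammaus quartus", marker=Marker.CYTB),
    ])
    grades = audit_species(table, build_bin_index(table))
    assert [g.species for g in grades] == ["Alphaus primus"]
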