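"""Report assembly: CSV tables for humans, one JSON summary as the
machine-readable contract.

Every percentage in the JSON summary sits next to its numerator and
denominator so that a reader (or :func:`self_check`) can recompute it; the
summary is written with stable key order so reruns on identical inputs are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

from refgap.audit import Grade, audit_composition, audit_species, build_bin_index
from refgap.checklist import Checklist
from refgap.errors import ValidationError
from refgap.gap_analysis import (
    coverage_percentage, gap_report, marker_coverage, venn_counts,
)
from refgap.geo import RegionPolygon, provenance_summary
from refgap.ingest import Marker, RecordTable, TARGET_MARKERS

__all__ = [
    "gap_summary", "audit_summary", "geo_summary", "write_gap_outputs",
    "self_check", "file_provenance",
]


def _pct_block(n: int, d: int, decimals: int = 1) -> dict:
    return {
        "n": n,
        "d": d,
        "pct": coverage_percentage(n, d, decimals) if d else None,
    }


def gap_summary(checklist: Checklist, records: RecordTable) -> dict:
    """Coverage table, Venn regions, gap lists and rollups as one dict."""
    cov = {}
    for marker in TARGET_MARKERS:
        mc = marker_coverage(checklist, records, marker)
        cov[marker.value] = {
            "registered": _pct_block(mc.n_species_registered, mc.n_checklist),
            "public": _pct_block(mc.n_species_public, mc.n_checklist),
        }
    venn = venn_counts(checklist, records)
    venn_block = {
        "+".join(sorted(m.value for m in key)): count
        for key, count in sorted(
            venn.region_counts.items(),
            key=lambda kv: "+".join(sorted(m.value for m in kv[0])),
        )
    }
    gaps = gap_report(checklist, records)
    return {
        "n_checklist": len(checklist),
        "coverage": cov,
        "venn": {"regions": venn_block, "none": venn.n_none},
        "gaps": {
            "missing_any": _pct_block(len(gaps.missing_any), len(checklist)),
            "represented_any": _pct_block(gaps.n_represented, len(checklist)),
            "missing_endemic": [t.scientific_name for t in gaps.missing_endemic],
            "missing_threatened": [
                {"species": t.scientific_name, "family": t.family,
                 "iucn_status": t.iucn_status.value, "endemic": t.endemic}
                for t in gaps.missing_threatened
            ],
        },
        "rollups": {
            "order": [
                {"group": r.group, "n": r.n_represented, "d": r.n_total,
                 "pct": r.pct}
                for r in gaps.order_rollups
            ],
            "family": [
                {"group": r.group, "n": r.n_represented, "d": r.n_total,
                 "pct": r.pct}
                for r in gaps.family_rollups
            ],
        },
    }


def audit_summary(records: RecordTable,
                  checklist: Checklist | None = None) -> dict:
    """Grade composition over species with BOLD COI records."""
    bins = build_bin_index(records)
    whitelist = {t.scientific_name for t in checklist} if checklist else None
    grades = audit_species(records, bins, species_whitelist=whitelist)
    comp = audit_composition(grades)
    per_grade = {
        g.value: {"n": comp.counts.get(g, 0), "d": comp.n_audited,
                  "pct": comp.pct(g)}
        for g in Grade
    }
    return {
        "n_audited": comp.n_audited,
        "grades": per_grade,
        "good_AB": {"n": comp.n_good, "d": comp.n_audited,
                    "pct": comp.pct_good},
        "cryptic_C_Estar_Edstar": {"n": comp.n_cryptic, "d": comp.n_audited,
                                   "pct": comp.pct_cryptic},
        "species": [
            {"species": g.species, "grade": g.grade.value,
             "n_barcodes": g.n_barcodes, "n_bins": g.n_bins,
             "n_datasets": g.n_datasets, "rationale": g.rationale}
            for g in grades
        ],
    }


def geo_summary(records: RecordTable,
                regions: list[RegionPolygon]) -> dict:
    """Inside/outside/unlocated accounting per region."""
    out = {}
    for region in regions:
        s = provenance_summary(records, region)
        located = s.n_records_inside + s.n_records_outside
        out[region.name] = {
            "records_inside": _pct_block(s.n_records_inside, located),
            "records_outside": _pct_block(s.n_records_outside, located),
            "n_unlocated": s.n_records_unlocated,
            "species_inside": _pct_block(s.n_species_inside,
                                         s.n_species_located),
            "undefined": s.undefined,
        }
    return {"regions": out}


def self_check(summary: dict) -> None:
    """Recompute every {n, d, pct} block found in a summary tree.

    Raises ValidationError on the first mismatch; percentages must be
    reproducible from the counts stored alongside them.
    """

    def _walk(node, path="$"):
        if isinstance(node, dict):
            if set(node) >= {"n", "d", "pct"}:
                n, d, pct = node["n"], node["d"], node["pct"]
                expect = None
                if d:
                    decimals = 1
                    if pct is not None and round(pct, 1) != pct:
                        decimals = 2
                    expect = coverage_percentage(n, d, decimals)
                if expect != pct:
                    raise ValidationError(
                        f"{path}: stored pct {pct} != recomputed {expect}")
            for k, v in node.items():
                _walk(v, f"{path}.{k}")
        elif isinstance(node, list):
            for i, v in enumerate(node):
                _walk(v, f"{path}[{i}]")

    _walk(summary)


def file_provenance(paths: list[str | Path]) -> list[dict]:
    """SHA256 and line counts of input files, for the run log."""
    out = []
    for p in map(Path, paths):
        data = p.read_bytes()
        out.append({
            "path": str(p),
            "sha256": hashlib.sha256(data).hexdigest(),
            "n_lines": data.count(b"\n"),
        })
    return out


def _write_json(payload: dict, path: Path) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def write_gap_outputs(checklist: Checklist, records: RecordTable,
                      out_dir: str | Path) -> dict:
    """Write coverage.csv, venn.csv, gaps.csv, rollups.csv and summary.json.

    Returns the summary dict (already self-checked).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary = gap_summary(checklist, records)
    self_check(summary)

    lines = ["marker,n_registered,pct_registered,n_public,pct_public,n_checklist"]
    for m in TARGET_MARKERS:
        c = summary["coverage"][m.value]
        lines.append(
            f"{m.value},{c['registered']['n']},{c['registered']['pct']},"
            f"{c['public']['n']},{c['public']['pct']},{summary['n_checklist']}")
    (out_dir / "coverage.csv").write_text("\n".join(lines) + "\n")

    lines = ["markers,n_species"]
    for key, count in summary["venn"]["regions"].items():
        lines.append(f"{key},{count}")
    lines.append(f"NONE,{summary['venn']['none']}")
    (out_dir / "venn.csv").write_text("\n".join(lines) + "\n")

    gaps = gap_report(checklist, records)
    lines = ["scientific_name,order,family,endemic,iucn_status,threatened"]
    for t in gaps.missing_any:
        lines.append(
            f"{t.scientific_name},{t.order},{t.family},"
            f"{'true' if t.endemic else 'false'},{t.iucn_status.value},"
            f"{'true' if t.threatened else 'false'}")
    (out_dir / "gaps.csv").write_text("\n".join(lines) + "\n")

    lines = ["level,group,n_represented,n_total,pct"]
    for level in ("order", "family"):
        for r in summary["rollups"][level]:
            lines.append(f"{level},{r['group']},{r['n']},{r['d']},{r['pct']}")
    (out_dir / "rollups.csv").write_text("\n".join(lines) + "\n")

    _write_json(summary, out_dir / "summary.json")
    return summary
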