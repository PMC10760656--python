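"""Independent oracles used by the test suite.

These deliberately re-derive results through different algorithms than the
package (winding numbers instead of ray casting, a literal rule-table walk
instead of the staged classifier) so agreement is evidence, not tautology.
"""

from __future__ import annotations


def winding_number_inside(lon: float, lat: float, outer_rings, holes=()):
    """Nonzero-winding point-in-polygon, independent of the package's
    even-odd ray casting. Boundary points are resolved by an explicit
    on-edge distance check."""

    def on_boundary(ring, eps=1e-9):
        for (x0, y0), (x1, y1) in zip(ring[:-1], ring[1:]):
            dx, dy = x1 - x0, y1 - y0
            seg2 = dx * dx + dy * dy
            if seg2 == 0:
                continue
            t = max(0.0, min(1.0, ((lon - x0) * dx + (lat - y0) * dy) / seg2))
            px, py = x0 + t * dx, y0 + t * dy
            if (lon - px) ** 2 + (lat - py) ** 2 < eps * eps:
                return True
        return False

    def winding(ring):
        w = 0
        for (x0, y0), (x1, y1) in zip(ring[:-1], ring[1:]):
            if y0 <= lat:
                if y1 > lat and (x1 - x0) * (lat - y0) - (lon - x0) * (y1 - y0) > 0:
                    w += 1
            elif y1 <= lat and (x1 - x0) * (lat - y0) - (lon - x0) * (y1 - y0) < 0:
                w -= 1
        return w

    for ring in (*outer_rings, *holes):
        if on_boundary(ring):
            return True
    if not any(winding(r) != 0 for r in outer_rings):
        return False
    return not any(winding(r) != 0 for r in holes)


def rule_table_grade(profile: dict) -> str:
    """Literal walk of the BIN-audit grade table.

    ``profile`` describes one species' COI records:
      records: list of dicts with keys voucher, mined, bin (bin may be None)
      bin_sharing: dict bin_id -> True when the BIN holds another species
      n_datasets: number of distinct datasets among usable records
    """
    records = profile["records"]
    if all((not r["voucher"]) or r["mined"] for r in records):
        return "F"
    usable = [r for r in records
              if r["voucher"] and not r["mined"] and r["bin"]]
    if len(usable) < 3:
        return "D"
    bins = sorted({r["bin"] for r in usable})
    shared = [profile["bin_sharing"].get(b, False) for b in bins]
    if len(bins) == 1 and not shared[0]:
        return "A" if profile["n_datasets"] >= 2 else "B"
    if len(bins) >= 2 and not any(shared):
        return "C"
    if len(bins) == 1:
        return "E*"
    return "E**"
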